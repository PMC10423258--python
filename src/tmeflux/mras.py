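"""Metabolic reaction activity scores (MRAS) from expression matrices.

Each enzyme-associated reaction is scored per sample by evaluating its GPR
tree bottom-up on promiscuity-weighted gene expression: a gene contributes
``expr / w``, where ``w`` is the number of distinct reactions it appears in.
OR nodes (isoenzymes) sum their children; AND nodes (complex subunits) take
the minimum, the rate-limiting subunit.  Scores are nonnegative and scale
linearly with a sample's expression, which is what makes the downstream
max-normalised flux bounds invariant to library-size rescaling.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .gem import GEMModel
from .gpr import And, Gene, GPRRule, Or

__all__ = [
    "load_expression",
    "validate_expression",
    "promiscuity_weights",
    "compute_mras",
]


def load_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample expression table (TSV/CSV, genes as rows).

    The first column is the gene id.  gzip input is accepted transparently.
    Duplicate gene rows are summed.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.name.rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).sum()
    validate_expression(df)
    return df


def validate_expression(expr: pd.DataFrame) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative entries")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")


def promiscuity_weights(model: GEMModel) -> dict[str, int]:
    """Count, for every gene, the distinct reactions whose GPR mentions it.

    A gene occurring several times inside one rule is counted once for that
    reaction.  Counted over all enzyme-associated reactions of the model,
    regardless of whether the gene is measured.
    """
    counts: dict[str, int] = {}
    for g in model.gpr:
        if g is None:
            continue
        for gene in g.genes():
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def _evaluate(
    node: GPRRule,
    leaf: dict[str, np.ndarray],
    n_samples: int,
    missing_gene: str,
) -> np.ndarray | None:
    """Evaluate one GPR tree to a per-sample activity vector.

    Returns ``None`` for a subtree that is entirely unmeasured under the
    ``drop`` policy.
    """
    if isinstance(node, Gene):
        v = leaf.get(node.name)
        if v is None:
            return np.zeros(n_samples) if missing_gene == "zero" else None
        return v
    vals = [_evaluate(c, leaf, n_samples, missing_gene) for c in node.children]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    if isinstance(node, Or):
        return np.sum(vals, axis=0)
    if isinstance(node, And):
        return np.min(vals, axis=0)
    raise TypeError(f"unknown GPR node {type(node).__name__}")


def compute_mras(
    expr: pd.DataFrame,
    model: GEMModel,
    missing_gene: str = "zero",
) -> pd.DataFrame:
    """Score every enzyme-associated (R1) reaction in every sample.

    Parameters
    ----------
    expr
        Gene-by-sample nonnegative DataFrame; duplicate gene rows are summed.
    model
        The GEM supplying GPR rules and the promiscuity weights.
    missing_gene
        Policy for genes present in a rule but absent from ``expr``:
        ``"zero"`` (default) treats them as unexpressed, so an AND containing
        one forces the complex to zero; ``"drop"`` removes them from the rule.

    Returns
    -------
    DataFrame indexed by R1 reaction ids, columns = samples, values >= 0.
    """
    if missing_gene not in ("zero", "drop"):
        raise ValueError("missing_gene must be 'zero' or 'drop'")
    validate_expression(expr)
    if expr.index.has_duplicates:
        expr = expr.groupby(level=0, sort=False).sum()

    weights = promiscuity_weights(model)
    universe = model.gene_universe
    measured = universe & set(expr.index)
    if not measured:
        raise ValueError(
            "no overlap between the model's gene universe and the expression "
            "matrix gene ids"
        )
    frac = len(measured) / len(universe)
    if frac < 0.5:
        warnings.warn(
            f"only {frac:.0%} of the model's genes are measured", stacklevel=2
        )

    n_samples = expr.shape[1]
    leaf = {
        g: expr.loc[g].to_numpy(dtype=float) / weights[g] for g in measured
    }

    r1 = model.r1
    scores = np.zeros((len(r1), n_samples))
    for row, j in enumerate(r1):
        v = _evaluate(model.gpr[j], leaf, n_samples, missing_gene)
        if v is not None:
            scores[row] = v
    return pd.DataFrame(
        scores, index=[model.reaction_ids[j] for j in r1], columns=expr.columns
    )
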