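"""Synthetic fixtures: toy mass-balanced GEMs and expression matrices.

Every generated model contains a guaranteed linear backbone —
nutrient uptake -> enzyme-catalysed conversions -> biomass sink — so that
biomass is achievable under a full medium and provably zero under an empty
one, which keeps positive/zero-biomass assertions meaningful.  Random
decorations (extra exchanges, unit conversions, GPR rules with shared genes)
are layered on top.  All stoichiometric coefficients are +/-1, so mass can
only enter through exchange reactions.

Expression generators emit nonnegative, TPM-like log-normal values for the
model's gene universe plus decoy genes; single-cell data adds per-cell
multiplicative noise and Bernoulli dropout around group profiles.  None of
this attempts to simulate a realistic human transcriptome — it exists to
exercise the pipeline with known structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .community import SingleCellDataset
from .gem import GEMModel
from .gpr import parse_gpr

__all__ = [
    "ToyGEMSpec",
    "make_toy_gem",
    "make_synthetic_expression",
    "make_synthetic_sc",
]


@dataclass(frozen=True)
class ToyGEMSpec:
    """Shape parameters for a generated toy GEM.

    ``n_reactions`` counts every reaction including exchanges and biomass;
    it must leave room for the backbone:
    one exchange, one conversion per internal metabolite, and the biomass
    sink: ``n_internal_metabolites + n_exchange_metabolites + 1`` reactions.
    """

    n_internal_metabolites: int = 1
    n_exchange_metabolites: int = 1
    n_reactions: int = 3
    fraction_reversible: float = 0.3
    gpr_density: float = 0.7
    genes_per_rule: tuple[int, int] = (1, 3)
    n_genes: int = 12
    seed: int = 0

    @property
    def backbone_size(self) -> int:
        return self.n_internal_metabolites + self.n_exchange_metabolites + 1


def _random_rule(rng: np.random.Generator, genes: list[str], k: int) -> str:
    chosen = rng.choice(genes, size=k, replace=False).tolist()
    if k == 1:
        return chosen[0]
    ops = rng.choice(["and", "or"], size=k - 1)
    rule = chosen[0]
    for g, op in zip(chosen[1:], ops):
        rule = f"({rule}) {op} {g}" if rng.random() < 0.5 else f"{rule} {op} {g}"
    return rule


def make_toy_gem(spec: ToyGEMSpec = ToyGEMSpec()) -> GEMModel:
    """Generate a mass-balanced toy GEM; deterministic under ``spec.seed``.

    The minimal spec (1 internal metabolite, 1 exchange metabolite, 3
    reactions) yields the linear chain
    ``EX_A: A_e <-> empty; R1: A_e -> M0_c (GPR); biomass: M0_c -> empty``.
    """
    if spec.n_internal_metabolites < 1 or spec.n_exchange_metabolites < 1:
        raise ValueError("need at least one internal and one exchange metabolite")
    if spec.n_reactions < spec.backbone_size:
        raise ValueError(
            f"n_reactions={spec.n_reactions} cannot hold the backbone "
            f"({spec.backbone_size} reactions)"
        )
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i}" for i in range(spec.n_genes)]

    ex_mets = [f"X{k}_e" for k in range(spec.n_exchange_metabolites)]
    in_mets = [f"M{k}_c" for k in range(spec.n_internal_metabolites)]
    metabolite_ids = ex_mets + in_mets
    compartments = ["e"] * len(ex_mets) + ["c"] * len(in_mets)
    midx = {m: i for i, m in enumerate(metabolite_ids)}

    rows, cols, vals = [], [], []
    reaction_ids: list[str] = []
    reversible: list[bool] = []
    gpr_strings: list[str] = []

    def add_reaction(rid, stoich, rev, rule=""):
        j = len(reaction_ids)
        reaction_ids.append(rid)
        reversible.append(rev)
        gpr_strings.append(rule)
        for m, c in stoich.items():
            rows.append(midx[m])
            cols.append(j)
            vals.append(float(c))

    # backbone: uptake -> conversions -> biomass sink
    add_reaction("EX_X0", {"X0_e": -1}, rev=True)
    lo, hi = spec.genes_per_rule
    chain = ["X0_e"] + in_mets
    for k in range(len(chain) - 1):
        add_reaction(
            f"R_chain{k}",
            {chain[k]: -1, chain[k + 1]: 1},
            rev=False,
            rule=_random_rule(rng, genes, int(rng.integers(lo, hi + 1))),
        )
    add_reaction("biomass", {in_mets[-1]: -1}, rev=False)
    biomass_index = len(reaction_ids) - 1

    # exchanges for the remaining extracellular metabolites
    for k in range(1, spec.n_exchange_metabolites):
        add_reaction(
            f"EX_X{k}",
            {f"X{k}_e": -1},
            rev=bool(rng.random() < spec.fraction_reversible),
        )

    # random unit-conversion decorations
    while len(reaction_ids) < spec.n_reactions:
        src, dst = rng.choice(metabolite_ids, size=2, replace=False)
        rule = (
            _random_rule(rng, genes, int(rng.integers(lo, hi + 1)))
            if rng.random() < spec.gpr_density
            else ""
        )
        add_reaction(
            f"R_dec{len(reaction_ids)}",
            {src: -1, dst: 1},
            rev=bool(rng.random() < spec.fraction_reversible),
            rule=rule,
        )

    S = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    ).tocsc()
    return GEMModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        reversible=np.array(reversible),
        gpr=[parse_gpr(s) if s else None for s in gpr_strings],
        compartments=compartments,
        exchange_reactions=None,
        biomass_reaction=biomass_index,
    )


def make_synthetic_expression(
    model: GEMModel,
    n_samples: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_decoy_genes: int = 5,
    upregulated: dict[str, float] | None = None,
) -> pd.DataFrame:
    """TPM-like expression for the model's gene universe plus decoys.

    Each gene gets a log-normal baseline shared across samples, then
    per-sample multiplicative log-normal noise of width ``noise_sd``
    (``noise_sd=0`` makes all samples identical).  ``upregulated`` scales
    named genes by a fixed factor in every sample, so the effect of boosting
    a rate-limiting gene on bounds is predictable.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.gene_universe) + [f"decoy{i}" for i in range(n_decoy_genes)]
    base = np.exp(rng.normal(np.log(10.0), 1.0, size=len(genes)))
    noise = (
        np.exp(rng.normal(0.0, noise_sd, size=(len(genes), n_samples)))
        if noise_sd > 0
        else np.ones((len(genes), n_samples))
    )
    values = base[:, None] * noise
    df = pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene"),
        columns=[f"sample{i}" for i in range(n_samples)],
    )
    if upregulated:
        for g, factor in upregulated.items():
            df.loc[g] *= factor
    return df


def make_synthetic_sc(
    model: GEMModel,
    groups: dict[str, int] | dict[str, dict],
    noise_sd: float = 0.3,
    dropout_rate: float = 0.1,
    seed: int = 0,
    n_decoy_genes: int = 5,
) -> SingleCellDataset:
    """Clustered single-cell expression with dropout.

    ``groups`` maps group name to a cell count, or to a dict with keys
    ``n_cells`` and optionally ``profile`` (a per-gene Series used as the
    group mean) or ``scale`` (a factor applied to a shared baseline).  With
    ``noise_sd=0`` and ``dropout_rate=0`` every cell equals its group
    profile exactly.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.gene_universe) + [f"decoy{i}" for i in range(n_decoy_genes)]
    baseline = np.exp(rng.normal(np.log(10.0), 1.0, size=len(genes)))

    blocks, labels, cell_ids = [], [], []
    for g, info in groups.items():
        if isinstance(info, int):
            info = {"n_cells": info}
        n_cells = int(info["n_cells"])
        if n_cells < 1:
            raise ValueError(f"group {g!r} needs >= 1 cell")
        if "profile" in info and info["profile"] is not None:
            profile = (
                pd.Series(info["profile"]).reindex(genes).fillna(0.0).to_numpy()
            )
        else:
            profile = baseline * float(info.get("scale", 1.0))
        noise = (
            np.exp(rng.normal(0.0, noise_sd, size=(len(genes), n_cells)))
            if noise_sd > 0
            else np.ones((len(genes), n_cells))
        )
        block = profile[:, None] * noise
        if dropout_rate > 0:
            keep = rng.random(size=block.shape) >= dropout_rate
            block = block * keep
        blocks.append(block)
        labels.extend([g] * n_cells)
        cell_ids.extend(f"{g}_cell{i}" for i in range(n_cells))

    X = np.concatenate(blocks, axis=1)
    return SingleCellDataset(
        gene_ids=list(genes),
        cell_ids=cell_ids,
        X=X,
        group_labels=np.array(labels, dtype=object),
    )
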