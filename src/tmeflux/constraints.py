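"""Flux bounds from activity scores, and nutrient-medium constraints.

Bounds live on a dimensionless [-1, 1] scale.  For enzyme-associated (R1)
reactions the upper bound is the reaction's MRAS divided by the sample's
maximum MRAS, so exactly one R1 reaction per sample sits at ub = 1; the lower
bound is 0 for irreversible reactions and the negated upper bound otherwise.
Reactions without gene association (R2) get the loose bounds (0, 1) or
(-1, 1).

A medium profile is a binary list of metabolites the system may take up.
Exchange reactions whose metabolite is absent from the medium are made
secretion-only (lb = 0); those present keep their full reversible range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .gem import GEMModel

__all__ = [
    "FluxBounds",
    "MediumProfile",
    "compute_bounds",
    "load_medium",
    "apply_medium",
    "random_medium",
    "BUNDLED_MEDIA",
]

BUNDLED_MEDIA = ("cell_line", "human_blood")


@dataclass
class FluxBounds:
    """Per-reaction, per-sample box constraints on the normalised scale.

    ``lb`` and ``ub`` are DataFrames indexed by the model's full reaction-id
    list with one column per sample; ``-1 <= lb <= 0 <= ub <= 1`` and
    irreversible reactions have ``lb = 0``.
    """

    lb: pd.DataFrame
    ub: pd.DataFrame
    medium_applied: str | None = None

    def __post_init__(self) -> None:
        if not self.lb.index.equals(self.ub.index) or not self.lb.columns.equals(
            self.ub.columns
        ):
            raise ValueError("lb and ub must share index and columns")
        if (self.lb.to_numpy() > self.ub.to_numpy()).any():
            raise ValueError("lb > ub for some reaction/sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lb.columns)

    def column(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(lb, ub) arrays for one sample, in model reaction order."""
        return (
            self.lb[sample].to_numpy(dtype=float),
            self.ub[sample].to_numpy(dtype=float),
        )

    def copy(self) -> "FluxBounds":
        return FluxBounds(self.lb.copy(), self.ub.copy(), self.medium_applied)


@dataclass(frozen=True)
class MediumProfile:
    """A named growth medium: the set of metabolites permitted for uptake."""

    name: str
    metabolites: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.metabolites)

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self.metabolites


def compute_bounds(mras: pd.DataFrame, model: GEMModel) -> FluxBounds:
    """Turn an MRAS matrix into normalised flux bounds for every reaction.

    Raises if any sample's activity scores are all zero, since the per-sample
    max-normalisation is undefined there.
    """
    r1_ids = [model.reaction_ids[j] for j in model.r1]
    missing = set(r1_ids) - set(mras.index)
    if missing:
        raise ValueError(f"MRAS matrix lacks R1 reactions: {sorted(missing)[:5]} ...")
    scores = mras.loc[r1_ids]
    col_max = scores.max(axis=0)
    dead = col_max[col_max <= 0]
    if len(dead):
        raise ValueError(
            f"all-zero MRAS for sample(s) {list(dead.index)}: normalisation undefined"
        )

    n, s = model.n_reactions, mras.shape[1]
    ub = np.ones((n, s))
    lb = np.repeat(np.where(model.reversible, -1.0, 0.0)[:, None], s, axis=1)

    norm = (scores / col_max).to_numpy()
    r1 = model.r1
    ub[r1] = norm
    lb[r1] = np.where(model.reversible[r1][:, None], -norm, 0.0)

    index = pd.Index(model.reaction_ids, name="reaction")
    return FluxBounds(
        lb=pd.DataFrame(lb, index=index, columns=mras.columns),
        ub=pd.DataFrame(ub, index=index, columns=mras.columns),
    )


def _read_medium_lines(path: Path) -> list[str]:
    entries = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            entries.append(line)
    return entries


def load_medium(source: str | Path) -> MediumProfile:
    """Load a medium profile by bundled name or from a one-column file.

    ``"cell_line"`` (44 metabolites, culture conditions) and
    ``"human_blood"`` (64 metabolites, physiological conditions) are bundled;
    any other string is treated as a path to a text file with one metabolite
    per line (``#`` comments allowed).
    """
    if isinstance(source, str) and source in BUNDLED_MEDIA:
        ref = resources.files("tmeflux.data") / f"{source}.txt"
        with resources.as_file(ref) as p:
            return MediumProfile(source, frozenset(_read_medium_lines(p)))
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown medium {source!r}: not one of {BUNDLED_MEDIA} and no such file"
        )
    return MediumProfile(path.stem, frozenset(_read_medium_lines(path)))


def medium_exchange_reactions(
    medium: MediumProfile, model: GEMModel, on_unmatched: str = "warn"
) -> set[int]:
    """Map medium metabolites to exchange-reaction indices (the set GE)."""
    ex_mets = model.exchange_metabolites()
    lower = {m.lower(): j for m, j in ex_mets.items()}
    matched, unmatched = set(), []
    for met in medium.metabolites:
        j = ex_mets.get(met, lower.get(met.lower()))
        if j is None:
            unmatched.append(met)
        else:
            matched.add(j)
    if unmatched:
        msg = (
            f"{len(unmatched)} medium metabolite(s) have no exchange reaction "
            f"in the model: {sorted(unmatched)[:5]} ..."
        )
        if on_unmatched == "error":
            raise KeyError(msg)
        if on_unmatched == "warn":
            warnings.warn(msg, stacklevel=2)
    return matched


def apply_medium(
    bounds: FluxBounds,
    medium: MediumProfile,
    model: GEMModel,
    on_unmatched: str = "warn",
) -> FluxBounds:
    """Restrict exchange reactions to the medium: absent nutrients become
    secretion-only (lb = 0); present nutrients keep their existing range.

    Never widens a bound and touches only exchange reactions.
    """
    ge = medium_exchange_reactions(medium, model, on_unmatched)
    out = bounds.copy()
    lb = out.lb.to_numpy()
    for j in model.exchange_reactions:
        if j not in ge:
            lb[j] = np.maximum(lb[j], 0.0)
    out.lb = pd.DataFrame(lb, index=bounds.lb.index, columns=bounds.lb.columns)
    out.medium_applied = medium.name
    return out


def random_medium(
    model: GEMModel, size: int = 44, seed: int | np.random.Generator = 0
) -> MediumProfile:
    """Uniformly sample ``size`` exchange metabolites without replacement.

    Used by the medium-significance simulation, which compares results under
    the biologically meaningful medium against same-sized random media.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(model.exchange_metabolites())
    if size > len(pool):
        raise ValueError(
            f"requested {size} metabolites but the model has only {len(pool)} "
            "exchange metabolites"
        )
    chosen = rng.choice(len(pool), size=size, replace=False)
    return MediumProfile(
        f"random{size}", frozenset(pool[i] for i in chosen)
    )
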