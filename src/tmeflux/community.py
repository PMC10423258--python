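"""Community flux estimation for single-cell (and flow-sorted) data.

Rather than solving each cell group in isolation, all groups are merged into
one open system sharing a metabolite reservoir: each group keeps a private
copy of the metabolic network, its boundary reactions are rewired into
coupling reactions ``C_i : m_e(group i) <-> rm`` that trade with a reservoir
metabolite ``rm`` (one per exchange metabolite), and shared exchange
reactions ``E(SR) : rm <-> empty`` connect the reservoir to the environment.
Nutrient-medium constraints act on E(SR) only, so groups are free to consume
what other groups secrete — the mechanism behind competition and cooperation
readouts.

Group fluxes are per-cell quantities; a diagonal fraction matrix ``P``
(cell-type proportion p_i on group i's reactions, 1 on shared exchanges)
converts them to community totals inside the QP:

    min 1/2 v'Pv - a c'Pv    s.t.  S P v = 0,  bounds

with ``c`` indicating every group's biomass reaction, i.e. total community
biomass is rewarded.  The reservoir steady-state rows force, for each
exchange metabolite, E(SR) flux = sum_i p_i * (group i coupling flux).

Sampling noise in group means is propagated by stratified bootstrap: each
replicate redraws cells with replacement within each group, preserving group
sizes, and the whole pipeline runs per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .constraints import (
    FluxBounds,
    MediumProfile,
    compute_bounds,
    medium_exchange_reactions,
)
from .fba import FluxVector, QPConfig, SolverError, solve_qp
from .gem import GEMModel
from .mras import compute_mras

__all__ = [
    "SingleCellDataset",
    "CommunityModel",
    "BootstrapConfig",
    "CommunityFluxResult",
    "SCPipelineResult",
    "stratified_bootstrap",
    "group_mean_expression",
    "build_community_model",
    "solve_community",
    "run_sc_pipeline",
    "load_single_cell",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class SingleCellDataset:
    """Gene-by-cell expression with per-cell group labels.

    ``X`` may be dense or scipy-sparse; it is densified per group only when
    group means are taken.  ``group_fractions``, if given, must be positive
    and sum to 1; otherwise observed label proportions are used downstream.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    X: np.ndarray | sp.spmatrix
    group_labels: np.ndarray
    group_fractions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"X is {self.X.shape} but dataset lists {len(self.gene_ids)} "
                f"genes and {len(self.cell_ids)} cells"
            )
        if len(self.group_labels) != len(self.cell_ids):
            raise ValueError("one group label per cell required")
        if sp.issparse(self.X):
            if (self.X.data < 0).any():
                raise ValueError("negative expression values")
        elif (np.asarray(self.X) < 0).any():
            raise ValueError("negative expression values")
        if self.group_fractions is not None:
            vals = np.array(list(self.group_fractions.values()), float)
            if (vals <= 0).any() or abs(vals.sum() - 1.0) > 1e-8:
                raise ValueError("group fractions must be positive and sum to 1")
            if set(self.group_fractions) != set(self.groups):
                raise ValueError("group fractions must cover exactly the labels")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_labels.tolist()))

    def observed_fractions(self) -> dict[str, float]:
        n = len(self.cell_ids)
        return {
            g: float(np.sum(self.group_labels == g)) / n for g in self.groups
        }

    def fractions(self) -> dict[str, float]:
        if self.group_fractions is not None:
            return dict(self.group_fractions)
        warnings.warn(
            "no group fractions supplied; using observed label proportions, "
            "which may deviate from true tissue composition",
            stacklevel=2,
        )
        return self.observed_fractions()


@dataclass(frozen=True)
class BootstrapConfig:
    n_bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


@dataclass
class CommunityModel:
    """The merged n-group network with reservoir and shared exchanges.

    ``S`` has shape ``(n_groups*M + M_ex, n_groups*N + M_ex)`` where ``M_ex``
    is the number of exchange metabolites of the base model.  Column layout:
    group blocks (base reaction order; exchange columns rewired into coupling
    reactions) then E(SR) columns in ``exchange_metabolite_ids`` order.
    ``weights`` is the diagonal of the fraction matrix P.
    """

    base: GEMModel
    groups: list[str]
    fractions: dict[str, float]
    S: sp.csc_matrix
    reaction_ids: list[str]
    metabolite_ids: list[str]
    weights: np.ndarray
    exchange_metabolite_ids: list[str]
    biomass_indices: dict[str, int]
    coupling_indices: dict[str, dict[str, int]]  # group -> met -> column
    esr_indices: dict[str, int]  # met -> column

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class CommunityFluxResult:
    """One solved community instance."""

    model: CommunityModel
    v: np.ndarray  # full stacked solution (per-cell group fluxes + E(SR))
    group_fluxes: dict[str, FluxVector]  # per-cell average fluxes
    esr_fluxes: pd.Series  # community totals, indexed by exchange metabolite
    info: dict = field(default_factory=dict)

    def coupling_fluxes(self, group: str) -> pd.Series:
        idx = self.model.coupling_indices[group]
        return pd.Series(
            {m: float(self.v[j]) for m, j in idx.items()}, name=group
        )


# ---------------------------------------------------------------------------
# Bootstrap and group means
# ---------------------------------------------------------------------------

def stratified_bootstrap(
    data: SingleCellDataset, config: BootstrapConfig
) -> list[np.ndarray]:
    """Resample cells with replacement within each group.

    Every replicate has exactly the original per-group cell counts (hence the
    original group proportions).  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    group_members = {
        g: np.where(data.group_labels == g)[0] for g in data.groups
    }
    for g, members in group_members.items():
        if len(members) == 0:
            raise ValueError(f"group {g!r} has no cells")
    out = []
    for _ in range(config.n_bootstraps):
        parts = [
            rng.choice(members, size=len(members), replace=True)
            for g, members in group_members.items()
        ]
        out.append(np.concatenate(parts))
    return out


def group_mean_expression(
    data: SingleCellDataset, indices: np.ndarray
) -> pd.DataFrame:
    """Mean expression per group over one bootstrap draw (genes x groups).

    Drawn duplicates count with multiplicity; densification happens per
    group, never on the full matrix.
    """
    indices = np.asarray(indices, dtype=int)
    labels = data.group_labels[indices]
    cols = {}
    for g in data.groups:
        sel = indices[labels == g]
        if len(sel) == 0:
            raise ValueError(f"bootstrap draw contains no cells of group {g!r}")
        sub = data.X[:, sel]
        if sp.issparse(sub):
            sub = np.asarray(sub.todense())
        cols[g] = np.asarray(sub, dtype=float).mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(data.gene_ids, name="gene"))


# ---------------------------------------------------------------------------
# Merged model construction
# ---------------------------------------------------------------------------

def build_community_model(
    model: GEMModel, groups: list[str], fractions: dict[str, float]
) -> CommunityModel:
    """Merge n copies of the base network through a shared reservoir.

    Each group's exchange column keeps its intracellular-side entry and gains
    a mirrored entry on the corresponding reservoir metabolite row, turning
    ``m_e <-> empty`` into the coupling reaction ``m_e <-> rm``; new E(SR)
    columns ``rm <-> empty`` open the reservoir to the environment.
    """
    if len(groups) != len(set(groups)):
        raise ValueError("duplicate group names")
    missing = set(groups) - set(fractions)
    if missing:
        raise ValueError(f"no fraction given for groups {sorted(missing)}")
    p = np.array([fractions[g] for g in groups], dtype=float)
    if (p <= 0).any():
        raise ValueError("group fractions must be positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"group fractions sum to {p.sum():.10f}, expected 1")

    M, N = model.n_metabolites, model.n_reactions
    ex_mets = model.exchange_metabolites()  # met id -> base exchange column
    ex_ids = list(ex_mets)
    M_ex = len(ex_ids)
    res_row = {m: len(groups) * M + k for k, m in enumerate(ex_ids)}

    base = model.S.tocoo()
    rows, cols, vals = [], [], []
    reaction_ids: list[str] = []
    metabolite_ids: list[str] = []
    coupling_indices: dict[str, dict[str, int]] = {}
    biomass_indices: dict[str, int] = {}

    csc = model.S.tocsc()
    for gi, g in enumerate(groups):
        rows.extend(base.row + gi * M)
        cols.extend(base.col + gi * N)
        vals.extend(base.data)
        metabolite_ids.extend(f"{g}::{m}" for m in model.metabolite_ids)
        coupling_indices[g] = {}
        for m, j in ex_mets.items():
            # mirror the exchange coefficient onto the reservoir row
            coef = csc.data[csc.indptr[j] : csc.indptr[j + 1]][0]
            rows.append(res_row[m])
            cols.append(gi * N + j)
            vals.append(-coef)
            coupling_indices[g][m] = gi * N + j
        for j, r in enumerate(model.reaction_ids):
            reaction_ids.append(
                f"{g}::C[{r}]" if j in set(ex_mets.values()) else f"{g}::{r}"
            )
        biomass_indices[g] = gi * N + model.biomass_reaction

    metabolite_ids.extend(f"rm::{m}" for m in ex_ids)
    esr_indices = {}
    for k, m in enumerate(ex_ids):
        col = len(groups) * N + k
        rows.append(res_row[m])
        cols.append(col)
        vals.append(-1.0)
        reaction_ids.append(f"ESR[{m}]")
        esr_indices[m] = col

    S = sp.coo_matrix(
        (vals, (rows, cols)),
        shape=(len(groups) * M + M_ex, len(groups) * N + M_ex),
    ).tocsc()
    weights = np.concatenate([np.repeat(p, N), np.ones(M_ex)])
    return CommunityModel(
        base=model,
        groups=list(groups),
        fractions={g: float(fractions[g]) for g in groups},
        S=S,
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        weights=weights,
        exchange_metabolite_ids=ex_ids,
        biomass_indices=biomass_indices,
        coupling_indices=coupling_indices,
        esr_indices=esr_indices,
    )


# ---------------------------------------------------------------------------
# Community QP
# ---------------------------------------------------------------------------

def solve_community(
    cm: CommunityModel,
    group_bounds: dict[str, tuple[np.ndarray, np.ndarray]],
    medium: MediumProfile,
    config: QPConfig | None = None,
    on_unmatched: str = "warn",
) -> CommunityFluxResult:
    """Solve the fraction-weighted community QP.

    ``group_bounds[g]`` is the (lb, ub) pair for group ``g`` in base reaction
    order, as produced by :func:`~tmeflux.constraints.compute_bounds` on that
    group's MRAS (no medium applied: coupling reactions keep their group
    bounds, and the medium constrains the shared E(SR) exchanges only:
    ub = 1, lb = -1 for reservoir metabolites in the medium, else 0).
    """
    config = config or QPConfig()
    model = cm.base
    N = model.n_reactions
    n_var = len(cm.reaction_ids)

    lb = np.empty(n_var)
    ub = np.empty(n_var)
    for gi, g in enumerate(cm.groups):
        if g not in group_bounds:
            raise ValueError(f"no bounds supplied for group {g!r}")
        glb, gub = group_bounds[g]
        if len(glb) != N or len(gub) != N:
            raise ValueError(f"bounds for group {g!r} do not match the base model")
        lb[gi * N : (gi + 1) * N] = glb
        ub[gi * N : (gi + 1) * N] = gub

    ge = medium_exchange_reactions(medium, model, on_unmatched)
    met_by_rxn = {j: m for m, j in model.exchange_metabolites().items()}
    medium_mets = {met_by_rxn[j] for j in ge}
    for m, col in cm.esr_indices.items():
        ub[col] = 1.0
        lb[col] = -1.0 if m in medium_mets else 0.0

    w = cm.weights
    c = np.zeros(n_var)
    for g in cm.groups:
        c[cm.biomass_indices[g]] = 1.0
    q = -config.a * w * c
    SP = cm.S @ sp.diags(w)
    v, info = solve_qp(SP, q, lb, ub, config, hessian_diag=w)

    group_fluxes = {}
    for gi, g in enumerate(cm.groups):
        group_fluxes[g] = FluxVector(
            reaction_ids=list(model.reaction_ids),
            v=v[gi * N : (gi + 1) * N].copy(),
            solve_status=info["status"],
            objective_value=info["objective_value"],
        )
    esr = pd.Series(
        {m: float(v[col]) for m, col in cm.esr_indices.items()},
        name="esr_flux",
    )
    return CommunityFluxResult(
        model=cm, v=v, group_fluxes=group_fluxes, esr_fluxes=esr, info=info
    )


# ---------------------------------------------------------------------------
# End-to-end single-cell pipeline
# ---------------------------------------------------------------------------

@dataclass
class SCPipelineResult:
    """All bootstrap replicates of a community run.

    ``fluxes`` is long-format (bootstrap, group, reaction, flux) over group
    per-cell fluxes; shared exchanges appear under group ``"TME"`` with
    reaction ids ``ESR[met]``.  ``summary`` holds mean and sd per
    (group, reaction) across bootstraps.
    """

    model: CommunityModel
    fluxes: pd.DataFrame
    replicates: list[CommunityFluxResult]

    @property
    def summary(self) -> pd.DataFrame:
        return (
            self.fluxes.groupby(["group", "reaction"], sort=False)["flux"]
            .agg(["mean", "std"])
            .reset_index()
        )


def run_sc_pipeline(
    data: SingleCellDataset,
    model: GEMModel,
    medium: MediumProfile,
    boot: BootstrapConfig | None = None,
    config: QPConfig | None = None,
    missing_gene: str = "zero",
    on_unmatched: str = "warn",
    min_group_size: int = 5,
) -> SCPipelineResult:
    """Bootstrap -> group means -> MRAS -> bounds -> community QP.

    MRAS normalisation is per group column within each replicate, mirroring
    the bulk path applied to each mean expression vector.
    """
    boot = boot or BootstrapConfig()
    config = config or QPConfig()
    fractions = data.fractions()
    for g in data.groups:
        n_g = int(np.sum(data.group_labels == g))
        if n_g < min_group_size:
            warnings.warn(
                f"group {g!r} has only {n_g} cells; group-mean expression "
                "may be unstable",
                stacklevel=2,
            )
    cm = build_community_model(model, data.groups, fractions)
    draws = stratified_bootstrap(data, boot)

    records = []
    replicates = []
    for b, indices in enumerate(draws):
        means = group_mean_expression(data, indices)
        mras = compute_mras(means, model, missing_gene=missing_gene)
        bounds = compute_bounds(mras, model)
        gb = {g: bounds.column(g) for g in cm.groups}
        try:
            res = solve_community(cm, gb, medium, config, on_unmatched="ignore")
        except SolverError as e:
            raise SolverError(f"bootstrap {b}: {e}") from e
        replicates.append(res)
        for g in cm.groups:
            v = res.group_fluxes[g].v
            for r, val in zip(model.reaction_ids, v):
                records.append((b, g, r, float(val)))
        for m, val in res.esr_fluxes.items():
            records.append((b, "TME", f"ESR[{m}]", float(val)))
    fluxes = pd.DataFrame(
        records, columns=["bootstrap", "group", "reaction", "flux"]
    )
    return SCPipelineResult(model=cm, fluxes=fluxes, replicates=replicates)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_single_cell(
    expression: str | Path,
    labels: str | Path,
    fractions: str | Path | None = None,
    barcodes: str | Path | None = None,
    features: str | Path | None = None,
) -> SingleCellDataset:
    """Load single-cell input from disk.

    ``expression`` is a dense gene-by-cell TSV/CSV (genes as rows), or a
    Matrix Market ``.mtx`` file with ``barcodes``/``features`` one-id-per-line
    sidecars.  ``labels`` is a two-column TSV (cell_id, group);
    ``fractions``, if given, a two-column TSV (group, fraction).
    """
    expression = Path(expression)
    if expression.suffix == ".mtx":
        if barcodes is None or features is None:
            raise ValueError("MTX input requires barcodes and features files")
        from scipy.io import mmread

        X = sp.csc_matrix(mmread(str(expression)))
        gene_ids = Path(features).read_text().split()
        cell_ids = Path(barcodes).read_text().split()
    else:
        sep = "," if expression.name.endswith(".csv") else "\t"
        df = pd.read_csv(expression, sep=sep, index_col=0)
        X = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]

    lab = pd.read_csv(labels, sep="\t", header=None, names=["cell_id", "group"])
    lab["cell_id"] = lab["cell_id"].astype(str)
    unknown = set(lab["cell_id"]) - set(cell_ids)
    if unknown:
        raise ValueError(
            f"label file names cells absent from the matrix: {sorted(unknown)[:5]}"
        )
    missing = set(cell_ids) - set(lab["cell_id"])
    if missing:
        raise ValueError(
            f"cells without a group label: {sorted(missing)[:5]}"
        )
    lab_map = dict(zip(lab["cell_id"], lab["group"].astype(str)))
    group_labels = np.array([lab_map[c] for c in cell_ids], dtype=object)

    frac = None
    if fractions is not None:
        fr = pd.read_csv(
            fractions, sep="\t", header=None, names=["group", "fraction"]
        )
        frac = dict(zip(fr["group"].astype(str), fr["fraction"].astype(float)))
    return SingleCellDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        X=X,
        group_labels=group_labels,
        group_fractions=frac,
    )
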