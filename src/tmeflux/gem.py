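"""Genome-scale metabolic models: container, validation, and I/O.

A GEM is held as a sparse stoichiometric matrix ``S`` (metabolites x
reactions; negative coefficients consume, positive produce) plus per-reaction
metadata: reversibility, an optional GPR rule, the exchange-reaction set, and
the biomass pseudo-reaction used as the optimisation objective.

Two on-disk dialects are supported: SBML Level 3 with the fbc extension
(read-only, via cobrapy) for real reconstructions such as Human-GEM, and a
three-file tabular dialect (read/write) used for fixtures and small models:

* ``reactions.tsv``   — reaction_id, reversible, gpr_string, is_exchange, is_biomass
* ``metabolites.tsv`` — metabolite_id, compartment
* ``stoich.tsv``      — metabolite_id, reaction_id, coefficient
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import GPRRule, parse_gpr

__all__ = [
    "GEMModel",
    "GEMValidationError",
    "load_gem",
    "load_tabular",
    "load_sbml",
    "write_tabular",
    "identify_exchange_reactions",
]

#: compartment tags taken to mean "extracellular"
EXTRACELLULAR_TAGS = ("e", "s", "extracellular", "extracellular space")

DEFAULT_BIOMASS_ID = "biomass_human"


class GEMValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class GEMModel:
    """An immutable-by-convention genome-scale metabolic model.

    Attributes
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers; define row/column order of ``S``.
    S
        Sparse CSC matrix, shape ``(n_metabolites, n_reactions)``.
    reversible
        Boolean per reaction; irreversible reactions carry flux >= 0.
    gpr
        Per-reaction :class:`~tmeflux.gpr.GPRRule` or ``None``.  Reactions
        with a rule form the enzyme-associated set R1; the rest form R2.
    compartments
        Per-metabolite compartment tag.
    exchange_reactions
        Indices of boundary reactions (single extracellular metabolite).
    biomass_reaction
        Index of the biomass pseudo-reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    reversible: np.ndarray
    gpr: list[GPRRule | None]
    compartments: list[str]
    exchange_reactions: np.ndarray = field(default=None)  # type: ignore[assignment]
    biomass_reaction: int = -1
    extracellular_tags: tuple[str, ...] = EXTRACELLULAR_TAGS

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        if self.exchange_reactions is None:
            self.exchange_reactions = identify_exchange_reactions(self)
        self.exchange_reactions = np.asarray(
            sorted(self.exchange_reactions), dtype=int
        )
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def r1(self) -> np.ndarray:
        """Indices of enzyme-associated reactions (GPR present, nonempty)."""
        return np.array(
            [j for j, g in enumerate(self.gpr) if g is not None], dtype=int
        )

    @property
    def r2(self) -> np.ndarray:
        """Indices of reactions without any gene association."""
        return np.array(
            [j for j, g in enumerate(self.gpr) if g is None], dtype=int
        )

    @property
    def gene_universe(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for g in self.gpr:
            if g is not None:
                out |= g.genes()
        return out

    def is_extracellular(self, metabolite_index: int) -> bool:
        tag = self.compartments[metabolite_index].lower()
        return tag in self.extracellular_tags

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    def exchange_metabolites(self) -> dict[str, int]:
        """Map extracellular metabolite id -> its exchange reaction index."""
        out: dict[str, int] = {}
        csc = self.S.tocsc()
        for j in self.exchange_reactions:
            rows = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
            out[self.metabolite_ids[rows[0]]] = int(j)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        M, N = self.S.shape
        if M != len(self.metabolite_ids) or N != len(self.reaction_ids):
            raise GEMValidationError(
                f"S is {M}x{N} but model lists {len(self.metabolite_ids)} "
                f"metabolites and {len(self.reaction_ids)} reactions"
            )
        if len(set(self.reaction_ids)) != N:
            raise GEMValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != M:
            raise GEMValidationError("duplicate metabolite ids")
        if len(self.reversible) != N or len(self.gpr) != N:
            raise GEMValidationError("per-reaction metadata length mismatch")
        if len(self.compartments) != M:
            raise GEMValidationError("per-metabolite compartment length mismatch")
        nnz_per_col = np.diff(self.S.tocsc().indptr)
        if (nnz_per_col == 0).any():
            empty = [self.reaction_ids[j] for j in np.where(nnz_per_col == 0)[0]]
            raise GEMValidationError(f"reactions with empty columns: {empty}")
        if not (0 <= self.biomass_reaction < N):
            raise GEMValidationError("biomass reaction index out of range")
        csc = self.S.tocsc()
        for j in self.exchange_reactions:
            rows = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
            if len(rows) != 1 or not self.is_extracellular(rows[0]):
                raise GEMValidationError(
                    f"exchange reaction {self.reaction_ids[j]} must touch exactly "
                    "one extracellular metabolite"
                )


def identify_exchange_reactions(model: GEMModel) -> np.ndarray:
    """Detect boundary reactions structurally.

    A reaction is an exchange iff its column of ``S`` has exactly one nonzero
    entry and that metabolite is extracellular.  Detection is independent of
    column order and idempotent.
    """
    csc = model.S.tocsc()
    out = []
    for j in range(csc.shape[1]):
        rows = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
        if len(rows) == 1 and model.is_extracellular(rows[0]):
            out.append(j)
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def load_tabular(directory: str | Path, biomass_id: str = DEFAULT_BIOMASS_ID) -> GEMModel:
    d = Path(directory)
    rxn = pd.read_csv(d / "reactions.tsv", sep="\t", dtype=str)
    met = pd.read_csv(d / "metabolites.tsv", sep="\t", dtype=str)
    sto = pd.read_csv(d / "stoich.tsv", sep="\t")

    required = {"reaction_id", "reversible", "gpr_string", "is_exchange", "is_biomass"}
    if not required.issubset(rxn.columns):
        raise GEMValidationError(f"reactions.tsv missing columns {required - set(rxn.columns)}")

    reaction_ids = rxn["reaction_id"].tolist()
    metabolite_ids = met["metabolite_id"].tolist()
    ridx = {r: j for j, r in enumerate(reaction_ids)}
    midx = {m: i for i, m in enumerate(metabolite_ids)}

    unknown_r = set(sto["reaction_id"]) - set(ridx)
    unknown_m = set(sto["metabolite_id"]) - set(midx)
    if unknown_r or unknown_m:
        raise GEMValidationError(
            f"stoich.tsv refers to unknown ids: reactions {sorted(unknown_r)}, "
            f"metabolites {sorted(unknown_m)}"
        )

    rows = sto["metabolite_id"].map(midx).to_numpy()
    cols = sto["reaction_id"].map(ridx).to_numpy()
    vals = sto["coefficient"].astype(float).to_numpy()
    S = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    ).tocsc()

    gpr: list[GPRRule | None] = []
    for s in rxn["gpr_string"].fillna(""):
        s = s.strip()
        gpr.append(parse_gpr(s) if s else None)

    bio_flags = rxn["is_biomass"].astype(int).to_numpy()
    if bio_flags.sum() == 1:
        biomass = int(np.where(bio_flags == 1)[0][0])
    elif biomass_id in ridx:
        biomass = ridx[biomass_id]
    else:
        raise GEMValidationError(
            f"no biomass reaction: none flagged and {biomass_id!r} absent"
        )

    exchange = np.where(rxn["is_exchange"].astype(int).to_numpy() == 1)[0]
    return GEMModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        reversible=rxn["reversible"].astype(int).to_numpy().astype(bool),
        gpr=gpr,
        compartments=met["compartment"].tolist(),
        exchange_reactions=exchange if len(exchange) else None,
        biomass_reaction=biomass,
    )


def write_tabular(model: GEMModel, directory: str | Path) -> None:
    """Write a model in the tabular dialect (round-trips bit-exactly)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    exch = set(model.exchange_reactions.tolist())
    pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "reversible": model.reversible.astype(int),
            "gpr_string": [str(g) if g is not None else "" for g in model.gpr],
            "is_exchange": [int(j in exch) for j in range(model.n_reactions)],
            "is_biomass": [
                int(j == model.biomass_reaction) for j in range(model.n_reactions)
            ],
        }
    ).to_csv(d / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"metabolite_id": model.metabolite_ids, "compartment": model.compartments}
    ).to_csv(d / "metabolites.tsv", sep="\t", index=False)
    coo = model.S.tocoo()
    pd.DataFrame(
        {
            "metabolite_id": [model.metabolite_ids[i] for i in coo.row],
            "reaction_id": [model.reaction_ids[j] for j in coo.col],
            "coefficient": coo.data,
        }
    ).to_csv(d / "stoich.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML (read-only, via cobrapy)
# ---------------------------------------------------------------------------

def load_sbml(path: str | Path, biomass_id: str = DEFAULT_BIOMASS_ID) -> GEMModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    reaction_ids = [r.id for r in cm.reactions]
    metabolite_ids = [m.id for m in cm.metabolites]
    compartments = []
    for m in cm.metabolites:
        name = (cm.compartments.get(m.compartment) or m.compartment or "").strip()
        compartments.append(name if name else m.compartment)
    S = sp.csc_matrix(
        cobra.util.array.create_stoichiometric_matrix(cm, array_type="lil")
    )
    reversible = np.array([r.lower_bound < 0 for r in cm.reactions], dtype=bool)
    gpr: list[GPRRule | None] = []
    for r in cm.reactions:
        s = r.gene_reaction_rule.strip()
        gpr.append(parse_gpr(s) if s else None)
    if biomass_id not in set(reaction_ids):
        raise GEMValidationError(f"biomass reaction {biomass_id!r} not in model")
    model = GEMModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        reversible=reversible,
        gpr=gpr,
        compartments=compartments,
        exchange_reactions=None,  # detect structurally
        biomass_reaction=reaction_ids.index(biomass_id),
    )
    return model


def load_gem(
    path: str | Path, format: str = "tabular", biomass_id: str = DEFAULT_BIOMASS_ID
) -> GEMModel:
    """Load a GEM from disk.

    Parameters
    ----------
    path
        Directory (tabular dialect) or ``.xml`` file (SBML).
    format
        ``"tabular"`` or ``"sbml"``.
    biomass_id
        Identifier used to locate the biomass reaction when the file does not
        flag one (default ``"biomass_human"``, the Human-GEM convention).
    """
    if format == "tabular":
        return load_tabular(path, biomass_id=biomass_id)
    if format == "sbml":
        return load_sbml(path, biomass_id=biomass_id)
    raise ValueError(f"unknown GEM format {format!r}")
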