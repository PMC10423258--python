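"""Interpretation of solved fluxes: directions, interaction modes,
competition scores, contributions, and the random-medium significance test.

Sign convention throughout: exchange flux < 0 is uptake from the
environment, > 0 is secretion.  Because QP solutions carry numerical noise,
"zero" means |flux| <= epsilon (default 1e-8 on the normalised scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import MediumProfile, random_medium
from .gem import GEMModel

__all__ = [
    "DEFAULT_EPSILON",
    "classify_direction",
    "direction_accuracy",
    "classify_architype",
    "compute_pccs",
    "cell_type_contribution",
    "SignificanceResult",
    "medium_significance",
]

DEFAULT_EPSILON = 1e-8

#: direction categories
NO_FLUX, UPTAKE, EXCRETE = "no_flux", "uptake", "excrete"


def classify_direction(flux: float, epsilon: float = DEFAULT_EPSILON) -> str:
    """Categorise one flux as ``no_flux``, ``uptake``, or ``excrete``."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if abs(flux) <= epsilon:
        return NO_FLUX
    return UPTAKE if flux < 0 else EXCRETE


def direction_accuracy(
    predicted: Mapping[str, str] | Sequence[str],
    observed: Mapping[str, str] | Sequence[str],
) -> float:
    """Fraction of exact category matches between two direction callsets.

    Mappings are compared key-by-key and must share identical key sets;
    sequences are compared position-by-position and must share length.
    """
    if isinstance(predicted, Mapping) != isinstance(observed, Mapping):
        raise TypeError("predicted and observed must both be mappings or sequences")
    if isinstance(predicted, Mapping):
        if set(predicted) != set(observed):
            raise ValueError("mismatched metabolite sets")
        keys = list(predicted)
        pred = [predicted[k] for k in keys]
        obs = [observed[k] for k in keys]
    else:
        if len(predicted) != len(observed):
            raise ValueError("mismatched lengths")
        pred, obs = list(predicted), list(observed)
    if not pred:
        raise ValueError("empty callsets")
    return sum(p == o for p, o in zip(pred, obs)) / len(pred)


#: interaction modes
COMPETITION, COOPERATION, RELEASE, UNCLASSIFIED = (
    "competition",
    "cooperation",
    "release",
    "unclassified",
)


def classify_architype(
    per_group_flux: Mapping[str, float], epsilon: float = DEFAULT_EPSILON
) -> str:
    """Interaction mode of the groups for one exchange metabolite.

    All groups taking up -> ``competition``; all secreting -> ``release``;
    some secreting while others take up -> ``cooperation`` (the consumers
    benefit from the producers).  Groups at no-flux are ignored; if every
    group is at no-flux the call is ``unclassified``.
    """
    if len(per_group_flux) < 2:
        raise ValueError("architype classification needs >= 2 groups")
    cats = {classify_direction(f, epsilon) for f in per_group_flux.values()}
    cats.discard(NO_FLUX)
    if not cats:
        return UNCLASSIFIED
    if cats == {UPTAKE}:
        return COMPETITION
    if cats == {EXCRETE}:
        return RELEASE
    return COOPERATION


def architype_table(
    per_group_fluxes: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Classify every row of a metabolite-by-group exchange-flux table."""
    modes = [
        classify_architype(row.to_dict(), epsilon)
        for _, row in per_group_fluxes.iterrows()
    ]
    out = per_group_fluxes.copy()
    out.insert(0, "mode", modes)
    return out


def compute_pccs(
    tumor_uptake: float,
    effector_uptake: float,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Per-cell competition score: |tumor uptake| / |effector uptake|.

    Both arguments are per-cell uptake fluxes (negative).  Values above 1
    mean the tumor out-consumes the effector cells per cell.
    """
    if tumor_uptake > epsilon or effector_uptake > epsilon:
        raise ValueError("PCCS is defined for uptake (negative) fluxes")
    if abs(effector_uptake) <= epsilon:
        raise ValueError("effector uptake is zero; PCCS undefined")
    return abs(tumor_uptake) / abs(effector_uptake)


def cell_type_contribution(per_cell_flux: float, abundance: float) -> float:
    """A group's contribution to the community exchange total.

    Per-cell flux times cell-type abundance p_i; summing over groups
    reproduces the shared-exchange flux by reservoir conservation.
    """
    if not 0 <= abundance <= 1:
        raise ValueError("abundance must lie in [0, 1]")
    return per_cell_flux * abundance


# ---------------------------------------------------------------------------
# Random-medium significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    """Null distribution of a statistic under random same-sized media.

    ``p_value`` is the plain counting p-value  #(sim >= observed) / N  with
    no +1 correction, so it can be exactly 0; ``p_value_corrected`` is the
    (k+1)/(N+1) variant.
    """

    observed: float
    simulated: np.ndarray
    n_requested: int
    n_failed: int = 0
    failures: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.simulated)

    @property
    def p_value(self) -> float:
        return float(np.sum(self.simulated >= self.observed) / self.n)

    @property
    def p_value_corrected(self) -> float:
        k = int(np.sum(self.simulated >= self.observed))
        return (k + 1) / (self.n + 1)


def medium_significance(
    model: GEMModel,
    statistic: Callable[[MediumProfile], float],
    observed: float,
    n_simulations: int = 500,
    medium_size: int = 44,
    seed: int = 0,
) -> SignificanceResult:
    """How extreme is a statistic obtained under the real medium?

    Draws ``n_simulations`` random media of ``medium_size`` metabolites from
    the model's exchange set, evaluates ``statistic`` (which should rerun the
    flux pipeline and score against ground truth, e.g. a Spearman correlation
    or a direction accuracy) on each, and counts how often the simulated
    statistic reaches the observed one.  A simulation that raises is recorded
    and excluded, with N reduced accordingly.
    """
    rng = np.random.default_rng(seed)
    sims, failures = [], []
    for i in range(n_simulations):
        medium = random_medium(model, size=medium_size, seed=rng)
        try:
            sims.append(float(statistic(medium)))
        except Exception:
            failures.append(i)
    if not sims:
        raise RuntimeError("every medium simulation failed")
    return SignificanceResult(
        observed=float(observed),
        simulated=np.array(sims),
        n_requested=n_simulations,
        n_failed=len(failures),
        failures=failures,
    )
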