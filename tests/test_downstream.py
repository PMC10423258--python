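import numpy as np
import pytest

import tmeflux as tf
from conftest import full_medium
from tmeflux.downstream import (
    COMPETITION,
    COOPERATION,
    EXCRETE,
    NO_FLUX,
    RELEASE,
    UNCLASSIFIED,
    UPTAKE,
)


class TestDirection:
    @pytest.mark.parametrize(
        "flux, expected",
        [(-0.3, UPTAKE), (0.0, NO_FLUX), (5e-9, NO_FLUX), (0.2, EXCRETE),
         (-5e-9, NO_FLUX), (1e-7, EXCRETE)],
    )
    def test_classification(self, flux, expected):
        assert tf.classify_direction(flux, 1e-8) == expected

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            tf.classify_direction(0.1, -1e-9)

    def test_accuracy_counting(self):
        pred = [UPTAKE] * 7 + [EXCRETE] * 4
        obs = [UPTAKE] * 7 + [NO_FLUX] * 4
        assert tf.direction_accuracy(pred, obs) == pytest.approx(7 / 11)
        assert tf.direction_accuracy(pred, pred) == 1.0
        assert tf.direction_accuracy([UPTAKE] * 3, [EXCRETE] * 3) == 0.0

    def test_accuracy_symmetric(self):
        rng = np.random.default_rng(0)
        pred = rng.choice([UPTAKE, EXCRETE, NO_FLUX], size=20).tolist()
        obs = rng.choice([UPTAKE, EXCRETE, NO_FLUX], size=20).tolist()
        assert tf.direction_accuracy(pred, obs) == tf.direction_accuracy(obs, pred)

    def test_accuracy_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            tf.direction_accuracy({"glc": UPTAKE}, {"lac": UPTAKE})


class TestArchitype:
    def test_all_uptake_is_competition(self):
        fluxes = {"immune": -0.2, "endo": -0.1, "tumor": -0.4, "fibro": -0.05}
        assert tf.classify_architype(fluxes) == COMPETITION

    def test_mixed_signs_is_cooperation(self):
        fluxes = {"immune": 0.1, "endo": 0.2, "tumor": -0.3}
        assert tf.classify_architype(fluxes) == COOPERATION

    def test_all_secretion_is_release(self):
        fluxes = {"a": 0.1, "b": 0.1, "c": 0.2, "d": 0.05}
        assert tf.classify_architype(fluxes) == RELEASE

    def test_no_flux_groups_ignored(self):
        assert tf.classify_architype({"a": -0.2, "b": 0.0, "c": -0.1}) == COMPETITION
        assert tf.classify_architype({"a": 0.0, "b": 0.0}) == UNCLASSIFIED

    def test_invariant_to_relabeling_and_scaling(self):
        fluxes = {"a": 0.1, "b": -0.3, "c": 0.2}
        renamed = {f"{k}_x": v for k, v in fluxes.items()}
        scaled = {k: 17.0 * v for k, v in fluxes.items()}
        base = tf.classify_architype(fluxes)
        assert tf.classify_architype(renamed) == base
        assert tf.classify_architype(scaled) == base

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tf.classify_architype({"only": -0.1})


class TestPCCS:
    def test_magnitude_ratio(self):
        assert tf.compute_pccs(-0.4, -0.2) == pytest.approx(2.0)
        assert tf.compute_pccs(-0.3, -0.3) == pytest.approx(1.0)

    def test_zero_effector_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            tf.compute_pccs(-0.4, 0.0)

    def test_secretion_inputs_rejected(self):
        with pytest.raises(ValueError):
            tf.compute_pccs(0.4, -0.2)


class TestContribution:
    def test_product(self):
        assert tf.cell_type_contribution(-0.4, 0.25) == pytest.approx(-0.1)
        assert tf.cell_type_contribution(-0.4, 0.0) == 0.0

    def test_out_of_range_abundance_rejected(self):
        with pytest.raises(ValueError):
            tf.cell_type_contribution(-0.4, 1.5)

    def test_contributions_sum_to_community_total(self, toy_gem):
        """Reservoir conservation: sum_i p_i * per-cell coupling flux equals
        the shared exchange flux on a solved community instance."""
        expr = tf.make_synthetic_expression(toy_gem, n_samples=2, seed=31)
        expr.columns = ["A", "B"]
        mras = tf.compute_mras(expr, toy_gem)
        bounds = tf.compute_bounds(mras, toy_gem)
        fractions = {"A": 0.6, "B": 0.4}
        cm = tf.build_community_model(toy_gem, ["A", "B"], fractions)
        res = tf.solve_community(
            cm, {g: bounds.column(g) for g in ["A", "B"]}, full_medium(toy_gem)
        )
        for met in cm.exchange_metabolite_ids:
            total = sum(
                tf.cell_type_contribution(
                    res.coupling_fluxes(g)[met], fractions[g]
                )
                for g in ["A", "B"]
            )
            assert res.esr_fluxes[met] == pytest.approx(total, abs=1e-6)


class TestMediumSignificance:
    def _run(self, observed, sim_values):
        it = iter(sim_values)
        model = tf.make_toy_gem(
            tf.ToyGEMSpec(n_internal_metabolites=2, n_exchange_metabolites=4,
                          n_reactions=9, seed=41)
        )
        return tf.medium_significance(
            model, lambda medium: next(it), observed,
            n_simulations=len(sim_values), medium_size=2, seed=0,
        )

    def test_observed_dominates_gives_zero(self):
        res = self._run(0.9, [0.1, 0.2, 0.3, 0.4])
        assert res.p_value == 0.0

    def test_observed_dominated_gives_one(self):
        res = self._run(0.05, [0.1, 0.2, 0.3, 0.4])
        assert res.p_value == 1.0

    def test_exact_counting(self):
        sims = [0.1, 0.2, 0.9, 0.95, 0.99, 0.3, 0.4, 0.5, 0.6, 0.05]
        res = self._run(0.7, sims)
        assert res.p_value == pytest.approx(3 / 10)
        assert res.p_value_corrected == pytest.approx(4 / 11)

    def test_p_is_multiple_of_one_over_n(self):
        rng = np.random.default_rng(3)
        res = self._run(0.5, rng.random(20).tolist())
        assert (res.p_value * res.n) == pytest.approx(round(res.p_value * res.n))

    def test_tie_with_max_counts(self):
        """Observed equal to the max simulated value still fires >= once."""
        res = self._run(0.4, [0.1, 0.2, 0.4])
        assert res.p_value >= 1 / res.n

    def test_failed_simulations_excluded(self):
        vals = iter([0.1, None, 0.3])
        def stat(medium):
            v = next(vals)
            if v is None:
                raise RuntimeError("solver blew up")
            return v
        model = tf.make_toy_gem(
            tf.ToyGEMSpec(n_internal_metabolites=2, n_exchange_metabolites=4,
                          n_reactions=9, seed=41)
        )
        res = tf.medium_significance(model, stat, 0.2, n_simulations=3,
                                     medium_size=2, seed=0)
        assert res.n == 2 and res.n_failed == 1

    def test_end_to_end_statistic_on_toy_model(self):
        """A real re-solve under random media: statistics vary with medium."""
        model = tf.make_toy_gem(
            tf.ToyGEMSpec(n_internal_metabolites=2, n_exchange_metabolites=5,
                          n_reactions=12, seed=43)
        )
        expr = tf.make_synthetic_expression(model, n_samples=1, seed=44)

        def biomass_under(medium):
            flux = tf.run_bulk_pipeline(expr, model, medium,
                                        on_unmatched="ignore")
            return float(flux.iloc[model.biomass_reaction, 0])

        observed = biomass_under(full_medium(model))
        res = tf.medium_significance(model, biomass_under, observed,
                                     n_simulations=10, medium_size=2, seed=3)
        assert res.n == 10
        # full medium gives max achievable biomass, so no subset exceeds it
        assert (res.simulated <= observed + 1e-7).all()
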