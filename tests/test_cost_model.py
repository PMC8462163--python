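import logging
import math

import numpy as np
import pandas as pd
import pytest

import seedwebs as sw
from seedwebs.cost_model import (
    ExtrapolationWarning,
    FitError,
    InteractionCostModel,
    TERM_LABELS,
)
from seedwebs.synth import SynthSpec, generate_cafeteria

TRUE = np.array([-14.2177, 8.739, 1.720, -1.278])


class TestDerivedQuantities:
    @pytest.mark.parametrize("n,ct50,expected", [(50, 5.0, 5.0), (7, 3.5, 1.0),
                                                 (20, 10.0, 1.0)])
    def test_consumption_from_ct50(self, n, ct50, expected):
        assert sw.consumption_from_ct50(n, ct50) == pytest.approx(expected)

    def test_consumption_rejects_bad_ct50(self):
        with pytest.raises(ValueError):
            sw.consumption_from_ct50(10, 0.0)

    @pytest.mark.parametrize("e,x,expected", [(1.0, 1.0, 1.0),
                                              (0.0188, 2.5, 0.00752)])
    def test_h_from_consumption(self, e, x, expected):
        assert sw.h_from_consumption(e, x) == pytest.approx(expected)

    def test_doubling_consumption_halves_cost(self):
        assert sw.h_from_consumption(2.0, 4.0) == pytest.approx(
            sw.h_from_consumption(2.0, 2.0) / 2)

    def test_h_undefined_at_zero_consumption(self):
        with pytest.raises(ValueError):
            sw.h_from_consumption(1.0, 0.0)


class TestPredictLogH:
    def test_printed_equation_at_reference_point(self, coefs):
        expected = (-14.2177 + 8.739 + 1.720 * math.log(10) - 1.278 * math.log(10))
        assert sw.predict_log_h(1.0, 10.0, coefs) == pytest.approx(expected, rel=1e-12)

    def test_cost_always_positive(self, coefs):
        rng = np.random.default_rng(0)
        mi = np.exp(rng.normal(0, 1, 200))
        mj = np.exp(rng.normal(2.5, 0.5, 200))
        h = np.exp(sw.predict_log_h(mi, mj, coefs, extrapolation_threshold_mg=None))
        assert np.all(h > 0)

    def test_crossover_mass(self, coefs):
        assert coefs.crossover_seed_mass_mg == pytest.approx((1.720 / 1.278) ** 3)

    def test_direction_flips_at_crossover(self, coefs):
        """Cost falls with carabid mass for seeds above ~2.44 mg and rises
        below it."""
        mj = np.linspace(2.0, 40.0, 60)
        heavy = sw.predict_log_h(4.0, mj, coefs)
        light = sw.predict_log_h(0.5, mj, coefs)
        assert np.all(np.diff(heavy) < 0)
        assert np.all(np.diff(light) > 0)

    def test_linear_in_transformed_covariates(self, coefs):
        # second differences vanish on a grid linear in M_i^(1/3) at fixed M_j
        u = np.linspace(0.5, 2.5, 9)
        vals = sw.predict_log_h(u ** 3, 12.0, coefs, extrapolation_threshold_mg=None)
        assert np.abs(np.diff(vals, n=2)).max() < 1e-9
        # and in ln(M_j) at fixed M_i
        v = np.linspace(1.0, 3.5, 9)
        vals = sw.predict_log_h(2.0, np.exp(v), coefs)
        assert np.abs(np.diff(vals, n=2)).max() < 1e-9

    def test_study_offset_applied(self):
        coefs = sw.CostModelCoefficients(study_offsets={"s1": 0.7})
        base = sw.predict_log_h(1.0, 10.0, coefs)
        assert sw.predict_log_h(1.0, 10.0, coefs, study="s1") == pytest.approx(base + 0.7)

    def test_extrapolation_warning_above_trial_range(self, coefs):
        with pytest.warns(ExtrapolationWarning):
            sw.predict_log_h(12.0, 10.0, coefs)

    def test_rejects_nonpositive_mass(self, coefs):
        with pytest.raises(ValueError):
            sw.predict_log_h(-1.0, 10.0, coefs)


class TestRiskIndex:
    def test_definition_and_linearity(self):
        assert sw.risk_index(1.0, 1.0) == 1.0
        assert sw.risk_index(3.0, 1.5) == pytest.approx(2 * sw.risk_index(1.5, 1.5))

    def test_larger_beetles_prefer_larger_seeds(self, coefs, config):
        """Normalized risk over a seed-mass grid is unimodal and its mode
        grows with carabid mass."""
        masses = np.exp(np.linspace(math.log(0.05), math.log(8.0), 400))
        energy = masses / 1000.0 * config.default_energy_density_kJ_per_g
        modes = []
        for mj in (5.0, 10.0, 20.0, 40.0):
            h = np.exp(sw.predict_log_h(masses, mj, coefs))
            r = sw.risk_index(energy, h)
            r = r / r.max()
            peak = int(np.argmax(r))
            # unimodal: rises up to the peak, falls after
            assert np.all(np.diff(r[: peak + 1]) > 0)
            assert np.all(np.diff(r[peak:]) < 0)
            modes.append(masses[peak])
        assert all(a < b for a, b in zip(modes, modes[1:]))


class TestCafeteriaRecord:
    def test_requires_exactly_one_consumption_source(self):
        with pytest.raises(ValueError):
            sw.CafeteriaRecord("s", "c", 10.0, "p", 1.0, 0.019)
        with pytest.raises(ValueError):
            sw.CafeteriaRecord("s", "c", 10.0, "p", 1.0, 0.019,
                               consumption_per_day=2.0, n_seeds_offered=10,
                               ct50_days=2.0)

    def test_ct50_route_matches_direct(self):
        rec = sw.CafeteriaRecord("s", "c", 10.0, "p", 1.0, 0.019,
                                 n_seeds_offered=50, ct50_days=5.0)
        assert rec.consumption_per_day == pytest.approx(5.0)
        assert rec.log_h == pytest.approx(math.log(0.019 / 5.0))


class TestFit:
    def test_noise_free_exact_recovery(self):
        spec = SynthSpec(rng_seed=3)
        spec.cafeteria.noise_sd = 0.0
        caf = generate_cafeteria(spec, study_offsets=[0.0, 0.0, 0.0])
        res = sw.fit_cost_model(caf, weighting="none", study_effect="none")
        assert np.abs(res.params - TRUE).max() < 1e-6

    def test_noise_free_recovery_with_random_effect_and_weights(self):
        spec = SynthSpec(rng_seed=4)
        spec.cafeteria.noise_sd = 0.0
        caf = generate_cafeteria(spec, study_offsets=[0.3, -0.3, 0.1])
        res = sw.fit_cost_model(caf)
        assert np.abs(res.params[1:] - TRUE[1:]).max() < 1e-5

    def test_study_offset_ordering_recovered(self):
        spec = SynthSpec(rng_seed=5)
        caf = generate_cafeteria(spec, study_offsets=[0.5, -0.5, 0.0])
        res = sw.fit_cost_model(caf)
        off = res.coefficients.study_offsets
        assert off["study0"] > off["study2"] > off["study1"]

    def test_matches_statsmodels_mixedlm_unweighted(self):
        """Independent oracle: statsmodels MixedLM on the same design."""
        import statsmodels.api as sm

        spec = SynthSpec(rng_seed=6)
        caf = generate_cafeteria(spec)
        model = InteractionCostModel.from_records(caf)
        ours = model.fit(weighting="none", study_effect="random")
        ref = sm.MixedLM(model.y, model.exog, groups=model.study).fit(reml=True)
        assert np.allclose(ours.params, ref.fe_params, rtol=1e-4, atol=1e-4)
        assert np.allclose(ours.bse, ref.bse_fe, rtol=1e-3, atol=1e-3)

    def test_weighting_reduces_large_seed_leverage(self):
        """With 1/M^(1/3) case weights, an 8 mg seed's hat value drops."""
        seed_masses = np.array([0.2, 0.5, 1.0, 2.0, 8.0] * 4)
        carabid_masses = np.repeat([5.0, 10.0, 20.0, 35.0], 5)
        rng = np.random.default_rng(7)
        y = (TRUE[0] + TRUE[1] * np.cbrt(seed_masses)
             + TRUE[2] * np.log(carabid_masses)
             + TRUE[3] * np.cbrt(seed_masses) * np.log(carabid_masses)
             + rng.normal(0, 0.3, seed_masses.size))
        model = InteractionCostModel(y, seed_masses, carabid_masses)

        def hat(weights):
            X = model.exog
            W = np.diag(weights)
            half = np.sqrt(weights)[:, None] * X
            return np.diag(half @ np.linalg.inv(X.T @ W @ X) @ half.T)

        big = seed_masses == 8.0
        h_none = hat(np.ones(y.size))
        h_wtd = hat(seed_masses ** (-1 / 3))
        assert np.all(h_wtd[big] < h_none[big])

    def test_consistency_bias_shrinks_with_sample_size(self):
        """Mean absolute estimation error falls as records grow."""
        errors = []
        for n in (50, 500, 5000):
            errs = []
            for rep in range(10):
                spec = SynthSpec(rng_seed=1000 + rep)
                spec.cafeteria.n_studies = 1
                spec.cafeteria.records_per_study = n
                caf = generate_cafeteria(spec, study_offsets=[0.0])
                res = sw.fit_cost_model(caf, study_effect="none")
                errs.append(np.abs(res.params - TRUE).mean())
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_single_study_falls_back_with_warning(self, caplog):
        spec = SynthSpec(rng_seed=8)
        spec.cafeteria.n_studies = 1
        caf = generate_cafeteria(spec, study_offsets=[0.0])
        with caplog.at_level(logging.WARNING, logger="seedwebs.cost_model"):
            res = sw.fit_cost_model(caf, study_effect="random")
        assert res.study_effect_used == "none"
        assert any("one study" in r.message for r in caplog.records)

    def test_rank_deficiency_names_collinear_terms(self):
        with pytest.raises(FitError, match="seed"):
            InteractionCostModel(np.zeros(6), np.full(6, 2.0),
                                 np.array([5.0, 6, 7, 8, 9, 10]))
        with pytest.raises(FitError, match="carabid"):
            InteractionCostModel(np.zeros(6), np.array([0.2, 0.4, 0.8, 1.0, 2.0, 4.0]),
                                 np.full(6, 10.0))

    def test_per_study_rescaling_absorbed_by_offset(self):
        """Multiplying every x (or E) in one study by a constant shifts that
        study's ln h by a constant; the slopes do not move."""
        spec = SynthSpec(rng_seed=9)
        caf = generate_cafeteria(spec, study_offsets=[0.0, 0.0, 0.0])
        shifted = caf.copy()
        mask = shifted["study_id"] == "study1"
        shifted.loc[mask, "consumption_per_day"] *= 3.0  # ln h -= ln 3
        base = sw.fit_cost_model(caf, study_effect="fixed")
        after = sw.fit_cost_model(shifted, study_effect="fixed")
        assert np.allclose(base.params[1:], after.params[1:], atol=1e-9)
        delta = (after.coefficients.study_offsets["study1"]
                 - base.coefficients.study_offsets["study1"])
        # sum-to-zero coding spreads -ln 3 as offset (K-1)/K plus intercept 1/K
        assert delta == pytest.approx(-math.log(3.0) * 2 / 3, abs=1e-9)

    def test_summary_mentions_all_terms(self):
        spec = SynthSpec(rng_seed=10)
        res = sw.fit_cost_model(generate_cafeteria(spec))
        text = res.summary()
        for label in TERM_LABELS:
            assert label in text

    def test_coefficients_yaml_round_trip(self, tmp_path, coefs):
        coefs.study_offsets = {"a": 0.25}
        path = tmp_path / "coefs.yaml"
        coefs.to_yaml(path)
        back = sw.CostModelCoefficients.from_yaml(path)
        assert back == coefs
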