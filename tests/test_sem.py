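"""SEM engine: model builders, ML fitting and parameter recovery, fit
indices, mediation products, model comparison, sample-size bound and
reliability."""

import numpy as np
import pandas as pd
import pytest

from reguframe.cohort import GeneratorConfig, simulate_cohort
from reguframe.errors import DataError, InvalidConfigError
from reguframe.power import PowerInputs, effect_bound, structure_bound, westland_sample_size
from reguframe.sem import (
    SemFit,
    SemSpec,
    _RamModel,
    build_alternative_models,
    build_theory_model,
    cfi,
    compare_models,
    cronbach_alpha,
    fit_indices,
    fit_sem,
    indirect_effect,
    rmsea,
    tli,
)


class TestModelBuilders:
    def test_theory_model_shape(self, theory_spec):
        assert len(theory_spec.latents()) == 9
        assert len(theory_spec.structural) == 12  # 6 + 3 + 1 + 1 + 1
        theory_spec.validate()  # acyclicity and indicator uniqueness
        parents_of_inv = {a for a, b in theory_spec.structural if b == "involvement"}
        assert parents_of_inv == {"anger", "calm", "hope"}
        assert len(theory_spec.indicators()) == 6 + 6 + 3 * 3 + 3 + 5 + 3 + 3

    def test_alternative_models(self, theory_spec):
        alt1, alt2 = build_alternative_models()
        alt1.validate()
        alt2.validate()
        assert len(alt1.structural) == len(theory_spec.structural) + 1
        assert len(alt2.latents()) == len(theory_spec.latents()) - 1
        assert "intention_pre" not in alt2.measurement
        # one extra free parameter = one fewer degree of freedom
        assert _RamModel(alt1).n_free == _RamModel(theory_spec).n_free + 1

    def test_spec_json_round_trip(self, theory_spec):
        again = SemSpec.from_json(theory_spec.to_json())
        assert again.measurement == theory_spec.measurement
        assert again.structural == theory_spec.structural


class TestFitSem:
    def test_parameter_recovery_large_n(self, theory_spec, cohort_5000):
        """Fit to data generated from the same structural system: every
        standardized path within +/-0.05 of its generating value."""
        fit = fit_sem(theory_spec, cohort_5000)
        assert fit.converged
        for (a, b), truth in GeneratorConfig().structural_paths.items():
            assert fit.estimates[f"{a}->{b}"] == pytest.approx(truth, abs=0.05), f"{a}->{b}"

    def test_calm_involvement_at_study_size(self, theory_spec, cohort_564):
        fit = fit_sem(theory_spec, cohort_564)
        assert fit.converged
        assert fit.estimates["calm->involvement"] == pytest.approx(-0.33, abs=0.10)

    def test_gradient_matches_finite_differences(self, theory_spec, cohort_564):
        model = _RamModel(theory_spec)
        X = cohort_564[model.obs].to_numpy(dtype=float)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        C = np.cov(X, rowvar=False, ddof=1)
        logdet = float(np.linalg.slogdet(C)[1])
        rng = np.random.default_rng(0)
        theta = model.start() + rng.normal(0, 0.02, model.n_free)
        _, grad = model.objective(theta, C, logdet)
        eps = 1e-6
        for i in rng.choice(model.n_free, size=10, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fp, _ = model.objective(tp, C, logdet)
            fm, _ = model.objective(tm, C, logdet)
            assert grad[i] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_saturated_model(self, cohort_564):
        fit = fit_sem(SemSpec({}, [], name="saturated", saturated=True), cohort_564)
        assert fit.chi_square == 0.0
        assert fit.df == 0
        assert fit.indices["rmsea"] == 0.0 and fit.indices["cfi"] == 1.0

    def test_too_few_rows_is_data_error(self, theory_spec, cohort_564):
        with pytest.raises(DataError):
            fit_sem(theory_spec, cohort_564.head(40))


class TestFitIndices:
    def test_reported_study_rmsea(self):
        # chi^2(754) = 1936.50 at N = 564 -> RMSEA 0.05 at two decimals
        assert round(rmsea(1936.50, 754, 564), 2) == 0.05

    def test_ideal_values_when_chi2_equals_df(self):
        assert rmsea(754.0, 754, 564) == 0.0
        assert cfi(754.0, 754, 5000.0, 780) == 1.0

    def test_model_equal_to_baseline_gives_cfi_zero(self):
        assert cfi(5000.0, 780, 5000.0, 780) == 0.0

    def test_tli_raw_may_exceed_one_and_is_truncated(self, theory_spec, cohort_5000):
        fit = fit_sem(theory_spec, cohort_5000)
        idx = fit_indices(fit)
        assert idx["tli"] <= 1.0
        assert idx["tli_raw"] >= idx["tli"]

    def test_df_zero_with_positive_chi2_flags_undefined(self):
        assert np.isnan(rmsea(12.3, 0, 100))


class TestIndirectEffect:
    def test_product_identity_is_exact(self, theory_spec, cohort_564):
        fit = fit_sem(theory_spec, cohort_564)
        res = indirect_effect(fit, ["promotion", "hope", "involvement"])
        expected = fit.estimates["promotion->hope"] * fit.estimates["hope->involvement"]
        assert res["estimate"] == expected  # algebraic identity, not approximation
        assert res["se"] > 0 and 0 <= res["p"] <= 1

    def test_three_step_chain(self, theory_spec, cohort_564):
        fit = fit_sem(theory_spec, cohort_564)
        res = indirect_effect(
            fit, ["hope", "involvement", "deep_processing", "intention_post"]
        )
        manual = (
            fit.estimates["hope->involvement"]
            * fit.estimates["involvement->deep_processing"]
            * fit.estimates["deep_processing->intention_post"]
        )
        assert res["estimate"] == pytest.approx(manual, abs=1e-15)

    def test_absent_edge_is_spec_error(self, theory_spec, cohort_564):
        fit = fit_sem(theory_spec, cohort_564)
        with pytest.raises(InvalidConfigError):
            indirect_effect(fit, ["calm", "intention_post"])


@pytest.fixture(scope="module")
def fits(theory_spec, cohort_564):
    alt1, alt2 = build_alternative_models()
    return [fit_sem(s, cohort_564) for s in (theory_spec, alt1, alt2)]


class TestCompareModels:
    def test_duplicate_fit_ties(self, fits):
        table = compare_models([fits[0], fits[0]])
        assert table["cfi"].nunique() == 1

    def test_theory_beats_model_without_pre_intention(self, theory_spec):
        """When pre-intervention intention matters (it both carries a path
        into post intention and covaries with promotion focus), the model
        that drops it cannot reproduce the focus / post-intention
        covariance and ranks below the theory model."""
        paths = dict(GeneratorConfig().structural_paths)
        paths[("promotion", "intention_pre")] = 0.40
        data = simulate_cohort(
            GeneratorConfig(n_participants=1000, seed=21, structural_paths=paths)
        )
        alt2 = build_alternative_models()[1]
        table = compare_models(
            [fit_sem(theory_spec, data), fit_sem(alt2, data)]
        ).set_index("model")
        assert table.loc["theory", "rank"] < table.loc["alt2_no_pre_intention", "rank"]

    def test_single_fit_table(self, fits):
        assert len(compare_models([fits[0]])) == 1

    def test_different_data_rejected(self, fits, theory_spec):
        other = simulate_cohort(GeneratorConfig(n_participants=564, seed=99))
        with pytest.raises(DataError):
            compare_models([fits[0], fit_sem(theory_spec, other)])


class TestWestlandBound:
    def test_study_inputs_reproduce_printed_n(self):
        assert westland_sample_size(0.05, 0.90, 0.30, 11, 41) == 238
        assert westland_sample_size(PowerInputs()) == 238

    def test_monotone_in_effect_size(self):
        ns = [westland_sample_size(0.05, 0.90, e, 11, 41) for e in (0.1, 0.3, 0.5, 0.7)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_structure_bound_decreases_when_ratio_doubles(self):
        lo = structure_bound(PowerInputs(n_latent=11, n_indicators=41))
        hi = structure_bound(PowerInputs(n_latent=11, n_indicators=82))
        assert hi < lo

    def test_components_on_study_inputs(self):
        p = PowerInputs()
        assert effect_bound(p) == 238
        assert structure_bound(p) == 118

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            westland_sample_size(0.05, 0.9, 1.5, 11, 41)
        with pytest.raises(InvalidConfigError):
            westland_sample_size(0.05, 0.9, 0.3, 11, 5)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        assert cronbach_alpha(np.hstack([x, x, x])) == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_give_zero(self):
        x = np.random.default_rng(1).normal(size=(20000, 4))
        assert cronbach_alpha(x) == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_total_is_nan(self):
        x = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        assert np.isnan(cronbach_alpha(x))

    def test_generated_calm_reliability(self, cohort_5000):
        items = cohort_5000[[f"calm_{i+1}" for i in range(3)]]
        assert cronbach_alpha(items) == pytest.approx(0.86, abs=0.02)
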