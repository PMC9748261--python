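import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fampgs import (
    ConfigError,
    DiseaseModelConfig,
    PrsCategorization,
    SimulationPlan,
    attenuation_summary,
    bonferroni_threshold,
    compare_prs_capture,
    cross_adjust,
    fit_logistic,
    interaction_test,
    prepare_analysis_frame,
    simulate_cohort,
    stratified_prs_effects,
)
from fampgs.association import (
    AttenuationResult,
    ConvergenceError,
    SeparationError,
    assign_bands,
    display_threshold,
    fhp_age_tertile_effects,
    prs_banded_effects,
    prs_percentiles,
)
from fampgs.relatedness import derive_fh_table

from .helpers import contingency_or


def two_by_two(n11, n10, n01, n00):
    """Frame realising a 2x2 exposure/outcome table."""
    y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    x = [1] * (n11 + n10) + [0] * (n01 + n00)
    return pd.DataFrame({"y": y, "x": x})


class TestFitLogistic:
    @pytest.mark.parametrize("table", [(20, 80, 10, 90), (15, 45, 30, 110), (7, 13, 11, 19)])
    def test_single_binary_predictor_reproduces_contingency_or(self, table):
        df = two_by_two(*table)
        res = fit_logistic(df, "y", ["x"], covariates=())[0]
        assert res.or_ == pytest.approx(contingency_or(*table), abs=1e-6)

    def test_worked_example_or_2_25(self):
        res = fit_logistic(two_by_two(20, 80, 10, 90), "y", ["x"], covariates=())[0]
        assert res.or_ == pytest.approx(2.25, abs=1e-6)

    def test_exposure_equal_to_outcome_raises_separation(self):
        df = pd.DataFrame({"y": [0] * 50 + [1] * 50})
        df["x"] = df["y"]
        with pytest.raises(ConvergenceError):
            fit_logistic(df, "y", ["x"], covariates=())

    def test_zero_variance_exposure_rejected(self):
        df = two_by_two(20, 80, 10, 90)
        df["flat"] = 1.0
        with pytest.raises(ConfigError, match="zero variance"):
            fit_logistic(df, "y", ["flat"], covariates=())

    def test_wald_ci_is_exp_beta_pm_196_se(self):
        res = fit_logistic(two_by_two(20, 80, 10, 90), "y", ["x"], covariates=())[0]
        lo, hi = res.ci95
        assert lo == pytest.approx(np.exp(res.beta - 1.96 * res.se))
        assert hi == pytest.approx(np.exp(res.beta + 1.96 * res.se))
        assert res.n == 200 and res.n_cases == 30


class TestBonferroni:
    def test_paper_scale_threshold_at_two_significant_digits(self):
        assert display_threshold(0.05, 24 + 15) == pytest.approx(0.0013)

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.01, 10, 0.001)])
    def test_simple_divisions(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ConfigError):
            bonferroni_threshold(0.05, 0)

    @given(st.integers(min_value=1, max_value=500), st.integers(min_value=1, max_value=500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_threshold_decreases_with_test_count(self, n1, n2):
        if n1 < n2:
            assert bonferroni_threshold(0.05, n1) > bonferroni_threshold(0.05, n2)


class TestAttenuation:
    def test_arithmetic_identities(self):
        r = AttenuationResult("PRS", "fh", beta_unadj=1.0, beta_adj=0.9)
        assert r.ratio == pytest.approx(0.9)
        assert r.decrease == pytest.approx(0.10)

    def test_no_change_means_zero_decrease(self):
        r = AttenuationResult("PRS", "fh", beta_unadj=0.7, beta_adj=0.7)
        assert r.decrease == pytest.approx(0.0)

    @given(st.floats(0.05, 3.0), st.floats(-1.0, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decrease_plus_ratio_is_one(self, unadj, adj):
        r = AttenuationResult("e", "a", unadj, adj)
        assert r.decrease + r.ratio == pytest.approx(1.0)

    def test_summary_of_equal_decreases_has_zero_sd(self):
        mean, sd = attenuation_summary([0.10, 0.10])
        assert (mean, sd) == (pytest.approx(0.10), pytest.approx(0.0))

    def test_summary_two_point_sample_sd(self):
        mean, sd = attenuation_summary([0.0, 0.2])
        assert mean == pytest.approx(0.10)
        assert sd == pytest.approx(0.1414, abs=2e-4)

    def test_summary_requires_two_diseases(self):
        with pytest.raises(ConfigError):
            attenuation_summary([0.1])

    def test_cross_adjust_rejects_degenerate_fh(self):
        df = pd.DataFrame({"y": [0, 1] * 20, "PRS": np.random.default_rng(0).normal(size=40),
                           "fh": 0.0})
        with pytest.raises(ConfigError, match="prevalence"):
            cross_adjust(df, covariates=())


class TestPrsBands:
    def test_percentile_at_boundary_goes_to_lower_band(self):
        scheme = PrsCategorization.seven_band()
        bands = assign_bands(np.array([0.05, 0.10, 0.1001, 0.40, 0.50, 0.90, 0.95]), scheme)
        assert list(bands) == ["0-10", "0-10", "10-20", "20-40", "40-60", "80-90", "90-100"]

    def test_median_value_lands_in_reference_band(self):
        scheme = PrsCategorization.seven_band()
        prs = np.linspace(-3, 3, 1001)
        bands = assign_bands(prs_percentiles(prs), scheme)
        assert bands[500] == scheme.reference

    @given(st.floats(min_value=0.001, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_every_percentile_maps_to_exactly_one_band(self, p):
        for scheme in (PrsCategorization.seven_band(), PrsCategorization.three_group(),
                       PrsCategorization.top_decile_vs_rest()):
            assert assign_bands(np.array([p]), scheme)[0] in scheme.labels

    def test_null_effect_gives_near_unit_top_decile_or(self):
        betas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"y": rng.integers(0, 2, 6000), "PRS": rng.normal(size=6000)})
            res = prs_banded_effects(df, PrsCategorization.top_decile_vs_rest(), covariates=())
            betas.append(res["90-100"].beta)
        # per-replicate SE ~ 0.085, so the mean of 5 sits within ~0.1 of 0
        assert abs(np.mean(betas)) < 0.1

    def test_band_ors_increase_under_monotone_liability_effect(self, demo_data):
        plan, cohort, pairs, fh = demo_data
        frame = prepare_analysis_frame(cohort, fh, "cad", "fh1")
        res = prs_banded_effects(frame, PrsCategorization.seven_band())
        ors = [res[b].or_ for b in ("0-10", "10-20", "20-40")]
        ors_hi = [res[b].or_ for b in ("60-80", "80-90", "90-100")]
        assert all(o < 1.0 for o in ors)
        assert all(o > 1.0 for o in ors_hi)
        assert ors_hi == sorted(ors_hi)

    def test_empty_band_raises(self):
        df = pd.DataFrame({"y": [0, 1] * 10, "PRS": [1.0] * 20})
        with pytest.raises(ConfigError):
            prs_banded_effects(df, PrsCategorization.seven_band(), covariates=())


class TestInteraction:
    def test_flag_uses_bonferroni_threshold(self, demo_data):
        plan, cohort, pairs, fh = demo_data
        frame = prepare_analysis_frame(cohort, fh, "cad", "fh1")
        it = interaction_test(frame, n_tests=39)
        assert it.threshold == pytest.approx(0.05 / 39)
        assert it.significant == (it.p < 0.05 / 39)

    def test_strong_generative_product_effect_is_detected(self):
        rng = np.random.default_rng(2)
        n = 4000
        prs = rng.normal(size=n)
        fh = rng.integers(0, 2, n)
        logit = -2.0 + 0.3 * prs + 0.4 * fh + 0.8 * prs * fh
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"y": y.astype(int), "PRS": prs, "fh": fh})
        it = interaction_test(df, covariates=())
        assert it.significant and it.p < 1e-6


class TestStratifiedAndNestedScores:
    def test_stratified_effects_similar_without_generative_interaction(self, demo_data):
        plan, cohort, pairs, fh = demo_data
        frame = prepare_analysis_frame(cohort, fh, "cad", "fh1")
        res = stratified_prs_effects(frame)
        pos, neg = res["fh_positive"], res["fh_negative"]
        assert pos is not None and neg is not None
        # per-SD effects agree within joint sampling error
        z = abs(pos.beta - neg.beta) / np.hypot(pos.se, neg.se)
        assert z < 4.0
        assert pos.n + neg.n == len(frame.dropna(subset=["PRS", "fh"]))
        assert pos.se > neg.se  # FH-positive stratum is smaller

    def test_larger_capture_score_has_larger_effect_and_attenuation(self):
        dz = DiseaseModelConfig("d", K=0.12, h2=0.5, rho2=0.3, c2=0.05, rho2_small=0.1)
        plan = SimulationPlan(n_families=3000, seed=17, diseases=(dz,))
        cohort, pairs = simulate_cohort(plan)
        fh = derive_fh_table(cohort, pairs, plan.diseases)
        frame = prepare_analysis_frame(cohort, fh, "d", "fh1")
        res = compare_prs_capture(frame, rho2_large=0.3, rho2_small=0.1)
        assert res["effect_large"].beta > res["effect_small"].beta
        assert (res["fh_attenuation_by_large"].decrease
                > res["fh_attenuation_by_small"].decrease)

    def test_equal_capture_fractions_give_identical_results(self):
        dz = DiseaseModelConfig("d", K=0.12, h2=0.5, rho2=0.3, rho2_small=0.3)
        plan = SimulationPlan(n_families=400, seed=17, diseases=(dz,))
        cohort, pairs = simulate_cohort(plan)
        fh = derive_fh_table(cohort, pairs, plan.diseases)
        frame = prepare_analysis_frame(cohort, fh, "d", "fh1")
        res = compare_prs_capture(frame, rho2_large=0.3, rho2_small=0.3)
        assert res["effect_large"].beta == pytest.approx(res["effect_small"].beta)

    def test_inverted_capture_fractions_rejected(self):
        with pytest.raises(ConfigError):
            compare_prs_capture(pd.DataFrame(), rho2_large=0.1, rho2_small=0.3)


class TestAgeTertiles:
    def test_youngest_parental_death_tertile_has_largest_or(self):
        """With the early-onset/high-liability link on, early parental death
        marks higher familial liability, so the youngest tertile carries
        the largest FH_P effect."""
        dz = DiseaseModelConfig("d", K=0.15, h2=0.5, rho2=0.25, c2=0.05,
                                onset_mean=62, onset_sd=10,
                                onset_liability_shift=8.0, onset_death_link=True)
        betas = {1: [], 2: [], 3: []}
        for seed in range(3):
            plan = SimulationPlan(n_families=4000, seed=seed, diseases=(dz,))
            cohort, pairs = simulate_cohort(plan)
            fh = derive_fh_table(cohort, pairs, plan.diseases)
            frame = prepare_analysis_frame(cohort, fh, "d", "fhp")
            res = fhp_age_tertile_effects(frame)
            for t in (1, 2, 3):
                betas[t].append(res["unadjusted"][t].beta)
        assert np.mean(betas[1]) > np.mean(betas[2]) > np.mean(betas[3])

    def test_exchangeable_tertiles_have_similar_effects(self, demo_data):
        # default config has no onset-liability link: tertiles are exchangeable
        plan, cohort, pairs, fh = demo_data
        frame = prepare_analysis_frame(cohort, fh, "cad", "fhp")
        res = fhp_age_tertile_effects(frame)
        bs = [res["unadjusted"][t] for t in res["unadjusted"]]
        for a in bs:
            for b in bs:
                z = abs(a.beta - b.beta) / np.hypot(a.se, b.se)
                assert z < 4.0
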