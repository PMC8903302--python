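import numpy as np
import pandas as pd
import pytest

from tweetfx.causal import (
    PolarityEffectModel, balance_diagnostics, bootstrap_det, det_ipw,
    det_unadjusted, fit_balancing_score, group_t_test, ipw_weight, make_units,
    trim,
)
from tweetfx.exceptions import DataError, EstimationError
from tweetfx.simulate import SyntheticConfig, generate_weekly

from _oracles import (
    hajek_transcription, ipw_ht_transcription, logit_grid_mle,
    random_ipw_instance,
)
from conftest import units_frame


def weekly_frame(sp, covariates=None, **outcomes):
    """Minimal weekly-style frame for estimator tests."""
    n = len(sp)
    frame = pd.DataFrame({"SP": np.asarray(sp, dtype=int)})
    cov = covariates or {}
    for name in ("NT", "LT", "MF", "NI", "HF", "CC", "ND", "OG"):
        frame[name] = np.asarray(cov.get(name, np.zeros(n)), dtype=float)
    for name, vals in outcomes.items():
        frame[name] = np.asarray(vals, dtype=float)
    return frame


class TestIpwWeight:
    @pytest.mark.parametrize("p,group,expected", [
        (0.4, 1, 2.5),
        (0.4, 0, 1.6667),
        (0.5, 1, 2.0),
        (0.5, 0, 2.0),
    ])
    def test_printed_examples(self, p, group, expected):
        assert ipw_weight(p, group) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.7])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            ipw_weight(p, 1)


class TestTrim:
    def test_exclude_outside_band(self):
        units = units_frame([1, 1, 0], [0.2, 0.5, 0.8], RP=[1, 2, 3])
        out = trim(units, 0.3, 0.7, mode="exclude")
        assert list(out.trimmed) == [True, False, True]
        assert out.weight.equals(units.weight)  # weights untouched

    def test_boundary_scores_kept(self):
        units = units_frame([1, 0], [0.3, 0.7], RP=[1, 2])
        out = trim(units)
        assert not out.trimmed.any()

    def test_cap_mode_weight_cutoffs(self):
        units = units_frame([1, 1, 0], [0.1, 0.5, 0.9], RP=[1, 2, 3])
        out = trim(units, 0.3, 0.7, mode="cap")
        # implied closed cut-offs 1/0.7 = 1.43 and 1/0.3 = 3.33 (2 dp)
        assert out.weight.iloc[0] == pytest.approx(1 / 0.3)
        assert round(out.weight.iloc[0], 2) == 3.33
        assert round(out.weight.max(), 2) <= 3.33
        assert out.weight.iloc[1] == pytest.approx(2.0)  # interior unchanged
        assert not out.trimmed.any()

    def test_bad_bounds_rejected(self):
        units = units_frame([1, 0], [0.4, 0.6], RP=[1, 2])
        with pytest.raises(ValueError):
            trim(units, 0.7, 0.3)

    def test_widening_band_monotone(self):
        rng = np.random.default_rng(3)
        units = units_frame(rng.integers(0, 2, 50), rng.uniform(0.01, 0.99, 50),
                            RP=rng.normal(size=50))
        kept = [
            int((~trim(units, lo, 1 - lo).trimmed).sum())
            for lo in (0.45, 0.3, 0.2, 0.1, 0.01)
        ]
        assert kept == sorted(kept)


class TestDetUnadjusted:
    def test_equal_means_zero(self):
        frame = weekly_frame([1, 1, 0, 0], RP=[2, 4, 1, 5])
        assert det_unadjusted(frame, "RP") == pytest.approx(0.0)

    def test_hand_value(self):
        frame = weekly_frame([1, 1, 0, 0], RP=[3, 5, 1, 1])
        assert det_unadjusted(frame, "RP") == pytest.approx(3.0)

    def test_linearity_under_negation(self):
        frame = weekly_frame([1, 0, 0], RP=[4, 1, 3])
        neg = frame.assign(RP=-frame.RP)
        assert det_unadjusted(neg, "RP") == pytest.approx(-det_unadjusted(frame, "RP"))

    def test_empty_group_rejected(self):
        with pytest.raises(EstimationError):
            det_unadjusted(weekly_frame([1, 1], RP=[1, 2]), "RP")


class TestDetIpw:
    def test_hand_value_balanced_scores(self):
        units = units_frame([1, 1, 0, 0], [0.5] * 4, RP=[3, 5, 1, 1])
        assert det_ipw(units, "RP", "ht") == pytest.approx(3.0)
        # equal scores + equal group sizes: HT reduces to the raw difference
        assert det_ipw(units, "RP", "ht") == det_unadjusted(units, "RP")

    def test_zero_outcomes(self):
        units = units_frame([1, 0], [0.4, 0.4], RP=[0, 0])
        assert det_ipw(units, "RP") == 0.0

    def test_trimmed_units_excluded_from_sums(self):
        units = units_frame([1, 1, 0], [0.5, 0.05, 0.5], RP=[4.0, 1000.0, 2.0])
        out = trim(units)
        # n = 2 untrimmed units; the extreme unit contributes nothing
        assert det_ipw(out, "RP", "ht") == pytest.approx((4 / 0.5 - 2 / 0.5) / 2)

    def test_hajek_shift_invariance(self):
        rng = np.random.default_rng(7)
        y, sp, p = random_ipw_instance(rng)
        units = units_frame(sp, p, RP=y)
        shifted = units_frame(sp, p, RP=y + 100.0)
        base = det_ipw(units, "RP", "hajek")
        assert det_ipw(shifted, "RP", "hajek") == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_transcription_oracles(self, seed):
        rng = np.random.default_rng(seed)
        y, sp, p = random_ipw_instance(rng)
        units = units_frame(sp, p, RP=y)
        assert det_ipw(units, "RP", "ht") == pytest.approx(
            ipw_ht_transcription(y, sp, p), abs=1e-12)
        assert det_ipw(units, "RP", "hajek") == pytest.approx(
            hajek_transcription(y, sp, p), abs=1e-12)

    def test_empty_group_after_trimming_rejected(self):
        units = trim(units_frame([1, 0], [0.1, 0.5], RP=[1, 2]))
        with pytest.raises(EstimationError, match="trimming"):
            det_ipw(units, "RP")


class TestFitBalancingScore:
    def test_identical_covariates_give_treated_fraction(self):
        frame = weekly_frame([1, 1, 1, 0, 0, 0, 0, 0],
                             covariates={"NT": np.ones(8)})
        fit = fit_balancing_score(frame)
        assert fit.scores == pytest.approx(np.full(8, 3 / 8), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_mle(self, seed):
        rng = np.random.default_rng(seed)
        # 6 units, one binary covariate, both outcomes within each level
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 1, rng.integers(0, 2), 1, 0, rng.integers(0, 2)])
        frame = weekly_frame(y, covariates={"NT": x})
        fit = fit_balancing_score(frame, covariates=["NT"])
        oracle = logit_grid_mle(x, y)
        assert fit.scores == pytest.approx(oracle, abs=1e-4)

    def test_separation_flagged_scores_interior(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_balancing_score(weekly_frame(y, covariates={"NT": x}),
                                  covariates=["NT"])
        assert fit.separation
        assert np.all(fit.scores > 0) and np.all(fit.scores < 1)

    def test_single_group_rejected(self):
        with pytest.raises(EstimationError):
            fit_balancing_score(weekly_frame([1, 1, 1]))

    def test_non_finite_covariate_named(self):
        frame = weekly_frame([1, 0, 1], covariates={"CC": [1.0, np.nan, 2.0]})
        with pytest.raises(DataError, match="CC"):
            fit_balancing_score(frame)

    def test_coefficients_reproduce_scores(self):
        frame, _ = generate_weekly(SyntheticConfig(seed=5))[0], None
        frame = frame[frame.SP.isin([0, 1])].copy()
        frame["SP"] = frame.SP.astype(int)
        fit = fit_balancing_score(frame)
        X = frame[["NT", "LT", "MF", "NI", "HF", "CC", "ND", "OG"]].to_numpy()
        eta = fit.params.iloc[0] + X @ fit.params.iloc[1:].to_numpy()
        np.testing.assert_allclose(1 / (1 + np.exp(-eta)), fit.scores,
                                   rtol=1e-6, atol=1e-8)


class TestGroupTTest:
    def test_identical_groups_null(self):
        frame = weekly_frame([1, 1, 1, 0, 0, 0], RP=[1, 2, 3, 1, 2, 3])
        t, p = group_t_test(frame, "RP")
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        frame = weekly_frame([1, 1, 1, 0, 0, 0], RP=[10, 12, 11, 1, 2, 1])
        _, p = group_t_test(frame, "RP")
        assert p < 0.01

    def test_label_swap_negates_t(self):
        frame = weekly_frame([1, 1, 0, 0], RP=[5, 6, 1, 2])
        swapped = frame.assign(SP=1 - frame.SP)
        t1, p1 = group_t_test(frame, "RP")
        t2, p2 = group_t_test(swapped, "RP")
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_small_group_rejected(self):
        with pytest.raises(EstimationError):
            group_t_test(weekly_frame([1, 0, 0], RP=[1, 2, 3]), "RP")


class TestBalanceDiagnostics:
    def test_identical_distributions_zero_smd(self):
        units = units_frame([1, 1, 0, 0], [0.5] * 4, RP=[0, 0, 0, 0])
        units["NT"] = [1.0, 2.0, 1.0, 2.0]
        out = balance_diagnostics(units, ["NT"])
        assert out.loc["NT", "smd_unweighted"] == pytest.approx(0.0)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(0)
        units = units_frame(rng.integers(0, 2, 30), np.full(30, 0.5))
        units["NT"] = rng.normal(size=30)
        units["weight"] = 1.0
        out = balance_diagnostics(units, ["NT"])
        assert out.loc["NT", "smd_weighted"] == pytest.approx(
            out.loc["NT", "smd_unweighted"])

    def test_constant_covariate_degenerate(self):
        units = units_frame([1, 1, 0, 0], [0.5] * 4)
        units["OG"] = 1.0
        out = balance_diagnostics(units, ["OG"])
        assert out.loc["OG", "degenerate"]
        assert out.loc["OG", "smd_unweighted"] == 0.0

    def test_weighting_improves_balance_on_confounded_data(self):
        # the generator's confounding loads on NT; averaged over seeds the
        # IPW-weighted SMD must drop below the raw one
        diffs = []
        for seed in range(30):
            frame, _ = generate_weekly(SyntheticConfig(seed=seed))
            frame = frame[frame.SP.isin([0, 1])].copy()
            frame["SP"] = frame.SP.astype(int)
            units = trim(make_units(frame, fit_balancing_score(frame)))
            out = balance_diagnostics(units, ["NT"])
            diffs.append(out.loc["NT", "smd_weighted"]
                         - out.loc["NT", "smd_unweighted"])
        assert np.mean(diffs) < 0

    def test_outside_band_count(self):
        units = units_frame([1, 1, 0, 0], [0.1, 0.5, 0.6, 0.95])
        out = balance_diagnostics(units, ["p"])
        assert out.attrs["n_outside_band"] == 2


@pytest.fixture(scope="module")
def analyzed():
    frame, _ = generate_weekly(SyntheticConfig(seed=2))
    return frame


@pytest.fixture(scope="module")
def results():
    frame, _ = generate_weekly(SyntheticConfig(seed=4))
    return PolarityEffectModel(frame).fit(bootstrap_reps=80, seed=0)


class TestBootstrap:
    def test_seed_reproducibility(self, analyzed):
        model = PolarityEffectModel(analyzed)
        a = bootstrap_det(model.data, "RP", reps=60, seed=11)
        b = bootstrap_det(model.data, "RP", reps=60, seed=11)
        assert a.sd == b.sd and a.ci == b.ci
        c = bootstrap_det(model.data, "RP", reps=60, seed=12)
        assert c.sd != a.sd

    def test_constant_outcome_zero_sd(self, analyzed):
        model = PolarityEffectModel(analyzed)
        const = model.data.assign(RP=5.0)
        res = bootstrap_det(const, "RP", estimator="unadjusted", reps=40, seed=0)
        assert res.sd == pytest.approx(0.0)

    def test_too_few_reps_rejected(self, analyzed):
        with pytest.raises(ValueError):
            bootstrap_det(PolarityEffectModel(analyzed).data, "RP", reps=1)


class TestModelResults:
    def test_excluded_units_never_analyzed(self, results):
        assert results.model.n_excluded > 0
        assert set(results.model.data.SP.unique()) == {0, 1}

    def test_estimates_indexed_by_outcome_and_estimator(self, results):
        assert results.estimates.shape[0] == 9  # 3 outcomes x 3 estimators
        assert results.det("RP", "ipw_ht") == results.estimates.loc[
            ("RP", "ipw_ht"), "estimate"]

    def test_bootstrap_columns_populated(self, results):
        est = results.estimates
        assert (est.boot_sd >= 0).all()
        assert (est.ci_lo <= est.ci_hi).all()

    def test_summary_mentions_key_facts(self, results):
        text = results.summary()
        assert "ipw_ht" in text and "trimming" in text and "bootstrap" in text

    def test_counts_respect_trimming(self, results):
        est = results.estimates
        ht = est.xs("ipw_ht", level="estimator")
        un = est.xs("unadjusted", level="estimator")
        assert (ht.n_treated + ht.n_control <= un.n_treated + un.n_control).all()
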