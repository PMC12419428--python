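"""Estimator correctness against hand arithmetic and explicit WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrdietcvd import (
    ValidationError,
    egger,
    ivw,
    mode_estimate,
    run_all,
    simulate_mr_pair,
    harmonize,
    wald_ratios,
    weighted_median,
    MrSimConfig,
)
from mrdietcvd.mr_estimators import wald_ratio_estimate

from conftest import make_harmonized


class TestWaldRatios:
    def test_hand_arithmetic(self):
        h = make_harmonized([0.1], [0.01], [0.2], [0.05])
        w = wald_ratios(h)
        assert w["ratio"][0] == pytest.approx(2.0)
        assert w["ratio_se"][0] == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        h = make_harmonized([0.1], [0.01], [0.0], [0.05])
        assert wald_ratios(h)["ratio"][0] == 0.0

    def test_zero_exposure_effect_names_rsid(self):
        h = make_harmonized([0.0], [0.01], [0.2], [0.05])
        with pytest.raises(ValidationError, match="rs1"):
            wald_ratios(h)


class TestIvw:
    def test_hand_inverse_variance(self, harmonized_from_ratios):
        h = harmonized_from_ratios([2.0, 1.0], [0.5, 0.25])
        est = ivw(h, effects_model="fixed")
        assert est.beta == pytest.approx(1.2)
        assert est.se == pytest.approx(np.sqrt(1 / 20), abs=1e-6)

    def test_homogeneous_fixed_equals_random(self, harmonized_from_ratios):
        h = harmonized_from_ratios([1.0, 1.0, 1.0], [0.2, 0.2, 0.2])
        assert ivw(h, "fixed").se == pytest.approx(ivw(h, "random").se)

    def test_equals_zero_intercept_wls(self):
        exp, out, _ = simulate_mr_pair(MrSimConfig(n_snps=15, theta=0.3, seed=4))
        h = harmonize(exp, out)
        est = ivw(h, "fixed")
        fit = sm.WLS(
            h.pairs["beta_y"], h.pairs["beta_x"],
            weights=1.0 / h.pairs["se_y"] ** 2,
        ).fit()
        assert est.beta == pytest.approx(float(fit.params.iloc[0]), rel=1e-10)

    def test_auto_switches_to_random_under_heterogeneity(self, harmonized_from_ratios):
        h = harmonized_from_ratios([0.0, 2.0, -2.0, 4.0], [0.1, 0.1, 0.1, 0.1])
        est = ivw(h, "auto")
        assert est.method == "IVW_random"
        assert est.extra["q_pval"] < 0.05

    def test_single_snp_rejected_wald_offered(self, harmonized_from_ratios):
        h = harmonized_from_ratios([1.5], [0.3])
        with pytest.raises(ValidationError, match="Wald"):
            ivw(h)
        assert wald_ratio_estimate(h).beta == pytest.approx(1.5)


class TestEgger:
    def test_two_points_rejected(self, harmonized_from_ratios):
        with pytest.raises(ValidationError):
            egger(harmonized_from_ratios([1.0, 2.0], [0.1, 0.1]))

    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.02 + 0.5 * bx
        h = make_harmonized(bx, np.full(4, 0.01), by, np.full(4, 0.03))
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.02, abs=1e-10)
        assert est.extra["rss_w"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_and_statsmodels(self):
        exp, out, _ = simulate_mr_pair(
            MrSimConfig(n_snps=5, theta=0.4, pleiotropy_sd=0.02, seed=9)
        )
        h = harmonize(exp, out)
        est = egger(h)
        x = h.pairs["beta_x"].to_numpy()
        y = h.pairs["beta_y"].to_numpy()
        w = 1.0 / h.pairs["se_y"].to_numpy() ** 2
        flip = x < 0
        x, y = np.where(flip, -x, x), np.where(flip, -y, y)
        design = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(design.T @ (w[:, None] * design), design.T @ (w * y))
        assert est.extra["intercept"] == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert est.beta == pytest.approx(float(fit.params[1]), rel=1e-8)
        assert est.se == pytest.approx(float(fit.bse[1]), rel=1e-8)


class TestWeightedMedian:
    def test_equal_weight_interpolation_hits_middle(self, harmonized_from_ratios):
        h = harmonized_from_ratios([1.0, 2.0, 10.0], [0.5, 0.5, 0.5])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_constant_ratios(self, harmonized_from_ratios):
        h = harmonized_from_ratios([3.0, 3.0, 3.0], [0.01, 0.01, 0.01])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(3.0)
        assert est.se < 0.02

    def test_seed_reproducible(self, harmonized_from_ratios):
        h = harmonized_from_ratios([1.0, 2.0, 3.0], [0.3, 0.3, 0.3])
        a = weighted_median(h, n_boot=100, seed=5)
        b = weighted_median(h, n_boot=100, seed=5)
        assert a.se == b.se


class TestMode:
    def test_constant_ratios_returned(self, harmonized_from_ratios):
        h = harmonized_from_ratios([2.5, 2.5, 2.5], [0.1, 0.1, 0.1])
        assert mode_estimate(h, n_boot=50, seed=0).beta == pytest.approx(2.5)

    def test_weighted_mode_tracks_precise_cluster(self, harmonized_from_ratios):
        ratios = [1.0] * 7 + [5.0] * 2
        ses = [0.05] * 7 + [1.0] * 2
        h = harmonized_from_ratios(ratios, ses)
        est = mode_estimate(h, weighted=True, n_boot=50, seed=0)
        assert est.beta == pytest.approx(1.0, abs=0.15)

    def test_weighted_equals_simple_on_equal_se(self, harmonized_from_ratios):
        h = harmonized_from_ratios([1.0, 1.2, 0.8, 1.1], [0.2] * 4)
        simple = mode_estimate(h, weighted=False, n_boot=50, seed=0)
        weighted = mode_estimate(h, weighted=True, n_boot=50, seed=0)
        assert simple.beta == pytest.approx(weighted.beta)


class TestRunAll:
    def test_single_snp_gives_wald_only(self, harmonized_from_ratios):
        out = run_all(harmonized_from_ratios([1.5], [0.3]))
        assert [e.method for e in out] == ["WaldRatio"]

    def test_methods_agree_on_tight_instruments(self):
        """With tight outcome SEs every method's estimate falls inside every
        other method's 95% CI."""
        rng = np.random.default_rng(0)
        bx = np.linspace(0.08, 0.24, 5)
        by = 0.5 * bx + rng.normal(0, 0.004, 5)
        h = make_harmonized(bx, np.full(5, 0.005), by, np.full(5, 0.004))
        ests = run_all(h, n_boot=300, seed=1)
        assert len(ests) == 5
        for a in ests:
            assert a.beta == pytest.approx(0.5, abs=0.1)
            for b in ests:
                assert a.or_lci95 <= np.exp(b.beta) <= a.or_uci95

    def test_ci_consistent_with_beta_se(self, harmonized_from_ratios):
        est = ivw(harmonized_from_ratios([1.0, 1.1, 0.9], [0.2] * 3), "fixed")
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.or_lci95 == pytest.approx(np.exp(est.beta - 1.959964 * est.se))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    c=st.floats(0.25, 4.0),
)
def test_sign_and_scale_equivariance(seed, c):
    """Negating outcome effects negates estimates; scaling exposure effects
    by c divides estimates by c."""
    exp, out, _ = simulate_mr_pair(MrSimConfig(n_snps=8, theta=0.3, seed=seed))
    h = harmonize(exp, out)
    base = ivw(h, "fixed").beta

    flipped = h.pairs.copy()
    flipped["beta_y"] *= -1
    neg = ivw(type(h)("e", "o", flipped), "fixed").beta
    assert neg == pytest.approx(-base, rel=1e-9)

    scaled = h.pairs.copy()
    scaled["beta_x"] *= c
    div = ivw(type(h)("e", "o", scaled), "fixed").beta
    assert div == pytest.approx(base / c, rel=1e-9)


def test_egger_unbiased_under_pleiotropy_while_ivw_biased():
    """With directional pleiotropy, Egger's slope stays near theta and its
    intercept absorbs the mean direct effect, while IVW is pulled away."""
    slopes, ivws = [], []
    for seed in range(20):
        exp, out, _ = simulate_mr_pair(MrSimConfig(
            n_snps=200, theta=0.5, n_exp=500_000, n_out=500_000,
            pleiotropy_mean=0.05, pleiotropy_sd=0.01, seed=seed,
        ))
        h = harmonize(exp, out)
        slopes.append(egger(h).beta)
        ivws.append(ivw(h, "fixed").beta)
    assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)
    assert np.mean(ivws) > 0.6  # biased upward by mean pleiotropy
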