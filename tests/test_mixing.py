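import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aocarbon.mixing import (
    DegenerateFitError,
    MixingModel,
    MixingResults,
    compute_loq,
    fit_mixing,
    propagate_aoc_sd,
)
from aocarbon.profiles import SoilLayer, SoilProfile


def ols_oracle(x, y):
    """Closed-form simple linear regression (slope, intercept, r2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    return slope, intercept, r2


# noise-free fixture: aOC = 2 mg/g, active pool F14C = 0.9
FIXTURE_SOC = np.array([10.0, 5.0, 3.0, 2.5])
FIXTURE_F14C = np.array([0.72, 0.54, 0.30, 0.18])


def results_stub(**over):
    base = dict(
        profile_id="stub", slope=0.9, intercept=-1.8, slope_sd=0.01, intercept_sd=0.02,
        cov_slope_intercept=0.0, aoc_mg_g=2.0, aoc_raw_mg_g=2.0, aoc_sd=0.03,
        r2=0.95, n_layers=4, clamped=False, valid=True, max_layer_ratio=0.5,
    )
    base.update(over)
    return MixingResults(**base)


class TestFit:
    def test_exact_fixture_recovers_slope_and_aoc(self):
        res = MixingModel(FIXTURE_SOC, FIXTURE_F14C).fit()
        slope, intercept, r2 = ols_oracle(FIXTURE_SOC, FIXTURE_SOC * FIXTURE_F14C)
        assert (slope, intercept) == (pytest.approx(0.9), pytest.approx(-1.8))
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.aoc_mg_g == pytest.approx(2.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_mixing_identity_on_noise_free_points(self):
        res = MixingModel(FIXTURE_SOC, FIXTURE_F14C).fit()
        lhs = FIXTURE_SOC * FIXTURE_F14C
        rhs = (FIXTURE_SOC - res.aoc_mg_g) * res.slope
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_negative_estimate_clamped(self):
        # points on Y = 0.8 X + 0.4 -> pre-clamp aOC = -0.5
        x = np.array([2.0, 4.0, 6.0, 8.0])
        res = MixingModel(x, (0.8 * x + 0.4) / x).fit()
        assert res.aoc_raw_mg_g == pytest.approx(-0.5, abs=1e-10)
        assert res.aoc_mg_g == 0.0
        assert res.clamped

    def test_degenerate_soc_raises(self):
        with pytest.raises(DegenerateFitError):
            MixingModel([5.0, 5.0, 5.0, 5.0], [0.5, 0.6, 0.7, 0.8]).fit()

    def test_nonpositive_slope_flagged_invalid(self):
        x = np.array([2.0, 3.0, 4.0, 5.0])
        res = MixingModel(x, (-0.5 * x + 5.0) / x).fit()
        assert not res.valid
        assert math.isnan(res.aoc_mg_g)
        res.apply_acceptance()
        assert res.accepted is False

    def test_from_profile_uses_normalized_values(self):
        layers = [
            SoilLayer(i * 20.0, (i + 1) * 20.0, soc, f14c_raw=0.1, f14c_2000=f)
            for i, (soc, f) in enumerate(zip(FIXTURE_SOC, FIXTURE_F14C))
        ]
        res = fit_mixing(SoilProfile("p", 45, 0, 2000, layers=layers))
        assert res.aoc_mg_g == pytest.approx(2.0, abs=1e-10)
        assert res.accepted

    @given(c=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, c):
        base = MixingModel(FIXTURE_SOC, FIXTURE_F14C).fit()
        scaled = MixingModel(c * FIXTURE_SOC, FIXTURE_F14C).fit()
        assert scaled.aoc_mg_g == pytest.approx(c * base.aoc_mg_g, rel=1e-9)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-9)


class TestUncertainty:
    def test_delta_method_matches_hand_example(self):
        cov = np.array([[0.018**2, 0.0], [0.0, 0.009**2]])
        sd = propagate_aoc_sd(slope=0.9, intercept=-1.8, cov=cov)
        expected = math.hypot(0.018 / 0.9, 2.0 * 0.009 / 0.9)
        assert expected == pytest.approx(0.0283, abs=1e-4)
        assert sd == pytest.approx(expected, rel=1e-12)

    def test_reported_sd_consistent_with_empirical_scatter(self, noisy_dataset):
        profiles, truths, _ = noisy_dataset
        errors, reported = [], []
        for p, t in zip(profiles, truths):
            res = fit_mixing(p)
            if res.valid:
                errors.append(res.aoc_raw_mg_g - t["aoc_mg_g"])
                reported.append(res.aoc_sd)
        ratio = np.mean(reported) / np.std(errors)
        assert 0.5 < ratio < 2.0


class TestRatiosAndAcceptance:
    def test_layer_ratios(self):
        res = results_stub(aoc_mg_g=2.0)
        np.testing.assert_allclose(res.layer_ratios([10.0, 4.0]), [0.2, 0.5])
        assert res.max_layer_ratio == pytest.approx(0.5)

    def test_zero_aoc_zero_ratios(self):
        res = results_stub(aoc_mg_g=0.0)
        assert np.all(res.layer_ratios([10.0, 4.0]) == 0.0)

    def test_ratio_above_one_rejects(self):
        res = results_stub(aoc_mg_g=2.0, r2=0.99)
        res.layer_ratios([1.5])
        assert res.max_layer_ratio == pytest.approx(4.0 / 3.0, rel=1e-9)
        res.apply_acceptance()
        assert res.accepted is False and "ratio" in res.rejection_reason

    @pytest.mark.parametrize(
        "r2,max_ratio,accepted",
        [(0.95, 0.6, True), (0.85, 0.6, False), (0.99, 1.2, False), (0.9, 0.5, False)],
    )
    def test_acceptance_thresholds(self, r2, max_ratio, accepted):
        res = results_stub(r2=r2, max_layer_ratio=max_ratio).apply_acceptance()
        assert res.accepted is accepted


class TestLOQ:
    def test_median_of_negatives(self):
        fits = [results_stub(aoc_raw_mg_g=v, aoc_mg_g=max(v, 0.0))
                for v in (-0.05, -0.11, -0.30, 1.2)]
        assert compute_loq(fits) == pytest.approx(0.11)
        assert fits[0].below_loq and not fits[3].below_loq

    def test_no_negatives_warns_and_zero(self):
        fits = [results_stub(aoc_raw_mg_g=1.0)]
        with pytest.warns(UserWarning):
            assert compute_loq(fits) == 0.0

    def test_single_negative(self):
        fits = [results_stub(aoc_raw_mg_g=-0.2, aoc_mg_g=0.0)]
        assert compute_loq(fits) == pytest.approx(0.2)


class TestRecoveryAtScale:
    def test_noise_free_exact_recovery(self, noisefree_dataset):
        profiles, truths, _ = noisefree_dataset
        for p, t in zip(profiles, truths):
            res = fit_mixing(p)
            assert abs(res.aoc_mg_g - t["aoc_mg_g"]) < 1e-8
            assert res.r2 > 1 - 1e-12

    def test_noisy_estimates_unbiased(self, noisy_dataset):
        profiles, truths, _ = noisy_dataset
        errors = [
            fit_mixing(p).aoc_raw_mg_g - t["aoc_mg_g"]
            for p, t in zip(profiles, truths)
        ]
        assert abs(np.median(errors)) < 0.11

    def test_summary_text(self):
        res = MixingModel(FIXTURE_SOC, FIXTURE_F14C, profile_id="fx").fit()
        res.layer_ratios()
        res.apply_acceptance()
        text = res.summary()
        assert "fx" in text and "aOC" in text and "accepted" in text
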