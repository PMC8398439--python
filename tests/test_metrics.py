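import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twdiss as tw
from twdiss.metrics import (
    DegenerateProfileError,
    NotAttainedError,
    TransferProfile,
    f1_f2,
    fit_weibull,
    mdt_ratio,
    time_to_fraction,
)

TIMES_13 = np.array(tw.DISSOLUTION_TIMEPOINTS_MIN, dtype=float)


def weibull_profile(mdt_min: float, b: float, times=TIMES_13) -> TransferProfile:
    y = 100.0 * (1.0 - np.exp(-((times / mdt_min) ** b)))
    return TransferProfile(np.asarray(times, float), y)


class TestFitWeibull:
    def test_exact_recovery(self):
        fit = fit_weibull(weibull_profile(120.0, 1.2))
        assert fit.mdt_min == pytest.approx(120.0, rel=1e-6)
        assert fit.shape == pytest.approx(1.2, rel=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("mdt_h", [0.1, 2.0, 50.0])
    @pytest.mark.parametrize("b", [0.5, 1.0, 3.0])
    def test_recovery_across_parameter_range(self, mdt_h, b):
        # sampling times spanning the rise of the curve, whatever the scale
        times = mdt_h * 60.0 * np.array([0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0])
        fit = fit_weibull(weibull_profile(mdt_h * 60.0, b, times=times))
        assert fit.mdt_hours == pytest.approx(mdt_h, rel=1e-4)
        assert fit.shape == pytest.approx(b, rel=1e-4)

    def test_exponential_case_mean_time(self):
        """At b = 1 the MDT is the mean of the exponential, 1/λ."""
        lam = 1.0 / 90.0  # per minute
        times = TIMES_13
        y = 100.0 * (1.0 - np.exp(-lam * times))
        fit = fit_weibull(TransferProfile(times, y))
        assert fit.mdt_min == pytest.approx(90.0, rel=1e-6)
        assert fit.shape == pytest.approx(1.0, rel=1e-6)

    def test_solution_run_mdt(self, solution_result):
        """The simulated bench solution run has a mean transfer time near 33.6 min."""
        fit = fit_weibull(solution_result.observed_profile())
        assert fit.mdt_min == pytest.approx(33.6, rel=0.15)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateProfileError):
            fit_weibull(TransferProfile(np.array([10.0, 20.0]), np.array([10.0, 20.0])))

    def test_flat_profile_rejected(self):
        with pytest.raises(DegenerateProfileError):
            fit_weibull(
                TransferProfile(np.array([10.0, 20.0, 30.0]), np.array([50.0, 51.0, 52.0]))
            )


class TestF1F2:
    def test_identical_profiles(self):
        p = weibull_profile(120.0, 1.0)
        res = f1_f2(p, p)
        assert res.f1 == 0.0
        assert res.f2 == pytest.approx(100.0, abs=1e-12)
        assert res.verdict == "similar"

    def test_hand_computed_values(self):
        r = TransferProfile(np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0]))
        t = TransferProfile(np.array([1.0, 2.0, 3.0]), np.array([12.0, 22.0, 32.0]))
        res = f1_f2(r, t)
        assert res.f1 == pytest.approx(10.0, rel=1e-12)
        assert res.f2 == pytest.approx(82.53, abs=0.005)
        assert res.verdict == "similar"

    def test_different_requires_both_thresholds(self):
        times = np.array([1.0, 2.0, 3.0])
        r = TransferProfile(times, np.array([40.0, 60.0, 80.0]))
        t = TransferProfile(times, np.array([30.0, 50.0, 70.0]))
        res = f1_f2(r, t)
        assert res.f1 > 15.0 and res.f2 < 50.0
        assert res.verdict == "different"
        # large f1 alone does not flag a difference on a small-magnitude profile
        r2 = TransferProfile(times, np.array([2.0, 4.0, 6.0]))
        t2 = TransferProfile(times, np.array([1.0, 3.0, 5.0]))
        res2 = f1_f2(r2, t2)
        assert res2.f1 > 15.0 and res2.f2 > 50.0
        assert res2.verdict == "similar"

    @given(st.floats(min_value=0.5, max_value=20.0))
    @settings(deadline=None, max_examples=25)
    def test_f2_decreases_with_offset(self, offset):
        times = np.linspace(10, 240, 9)
        base = 100.0 * (1 - np.exp(-times / 60.0))
        r = TransferProfile(times, base)
        shifted = f1_f2(r, TransferProfile(times, np.clip(base - offset, 0, 100))).f2
        more = f1_f2(r, TransferProfile(times, np.clip(base - offset - 0.5, 0, 100))).f2
        assert more < shifted

    def test_common_subset_restriction(self):
        r = weibull_profile(60.0, 1.0, times=np.array([10.0, 20.0, 30.0, 45.0]))
        t = weibull_profile(60.0, 1.0, times=np.array([20.0, 30.0, 45.0, 60.0]))
        res = f1_f2(r, t)
        assert res.f1 == pytest.approx(0.0, abs=1e-12)

    def test_too_few_common_points(self):
        r = weibull_profile(60.0, 1.0, times=np.array([10.0, 20.0, 30.0]))
        t = weibull_profile(60.0, 1.0, times=np.array([30.0, 45.0, 60.0]))
        with pytest.raises(ValueError):
            f1_f2(r, t)

    def test_truncation_after_85_percent(self):
        times = np.array([10.0, 20.0, 30.0, 45.0, 60.0])
        r = TransferProfile(times, np.array([50.0, 80.0, 90.0, 95.0, 99.0]))
        t = TransferProfile(times, np.array([50.0, 80.0, 90.0, 95.0, 50.0]))
        full = f1_f2(r, t)
        truncated = f1_f2(r, t, truncate_after_85=True)
        assert truncated.f2 > full.f2  # late divergence dropped


class TestTimeToFraction:
    def test_weibull_mdt_definition(self):
        """At b = 1 the 63.2% crossing time equals the MDT."""
        times = np.linspace(1, 300, 300)
        p = weibull_profile(60.0, 1.0, times=times)
        assert time_to_fraction(p, 1 - np.exp(-1)) == pytest.approx(60.0, rel=1e-3)

    def test_zero_fraction(self, solution_result):
        assert time_to_fraction(solution_result, 0.0) == 0.0

    def test_unattained_fraction(self):
        p = weibull_profile(60.0, 1.0, times=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(NotAttainedError):
            time_to_fraction(p, 0.99)

    def test_dense_result_used_when_available(self, solution_result):
        t60 = time_to_fraction(solution_result, 0.6)
        # the dense crossing is finer than the observed 30-min grid point
        assert 20.0 < t60 < 40.0


class TestMdtRatio:
    def test_identical_inputs_give_unity(self, solution_result):
        assert mdt_ratio(solution_result, solution_result) == pytest.approx(1.0, rel=1e-9)


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        p = weibull_profile(120.0, 1.3)
        path = tmp_path / "profile.csv"
        p.to_csv(path)
        q = TransferProfile.from_csv(path)
        assert q.times_min == pytest.approx(p.times_min)
        assert q.cumulative_percent == pytest.approx(p.cumulative_percent)

    def test_strict_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("minutes,pct\n10,5\n")
        with pytest.raises(ValueError, match="columns"):
            TransferProfile.from_csv(path)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            TransferProfile(np.array([10.0, 5.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            TransferProfile(np.array([10.0, 20.0]), np.array([1.0, 120.0]))
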