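"""ICC/SEM/MDC reliability statistics and traffic-light flagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from courtwatch import reliability
from courtwatch.reliability import (BaselineWindow, MDC_FACTOR,
                                    ReliabilityError, build_thresholds,
                                    classify, flag_cohort, flag_series,
                                    icc_2_1, sem_mdc, subject_bounds)


def baseline_sample(rng, n=16, k=5, sd_subj=1.0, sd_err=0.3, sd_week=0.0):
    subj = rng.normal(0.0, sd_subj, size=(n, 1))
    week = rng.normal(0.0, sd_week, size=(1, k))
    return subj + week + rng.normal(0.0, sd_err, size=(n, k))


class TestICC:
    def test_identical_columns_gives_one(self):
        x = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))
        assert icc_2_1(x) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ReliabilityError):
            icc_2_1(np.full((5, 4), 2.0))

    def test_pure_noise_mean_near_zero(self):
        import warnings as _warnings
        rng = np.random.default_rng(0)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # clipped ICCs
            estimates = [icc_2_1(baseline_sample(rng, sd_subj=0.0,
                                                 sd_err=1.0))
                         for _ in range(500)]
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.05)

    def test_planted_variance_ratio_recovered(self):
        # sigma_subj^2 / (sigma_subj^2 + sigma_err^2) = 0.9
        rng = np.random.default_rng(1)
        sd_subj, sd_err = 3.0, 1.0
        estimates = [icc_2_1(baseline_sample(rng, sd_subj=sd_subj,
                                             sd_err=sd_err))
                     for _ in range(500)]
        assert np.mean(estimates) == pytest.approx(0.9, abs=0.03)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = baseline_sample(rng, n=10, k=4, sd_week=0.4)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "rater": np.tile(np.arange(4), 10),
            "score": x.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # pingouin labels the two-way random, absolute-agreement,
        # single-measure form "ICC(A,1)"; it equals ICC(2,1)
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_2_1(x) == pytest.approx(icc2, abs=1e-10)

    def test_negative_estimate_clipped_with_warning(self):
        # no subject effect, pure anti-phase error: MS_subjects < MS_error
        x = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            assert icc_2_1(x) == 0.0


class TestSemMdc:
    def test_perfect_reliability_zero_sem(self):
        rng = np.random.default_rng(4)
        x = baseline_sample(rng)
        sem, mdc95 = sem_mdc(x, icc=1.0)
        assert sem == 0.0 and mdc95 == 0.0

    def test_mdc_factor(self):
        rng = np.random.default_rng(5)
        x = baseline_sample(rng)
        sem, mdc95 = sem_mdc(x, icc=0.5)
        assert mdc95 == pytest.approx(MDC_FACTOR * sem)
        assert MDC_FACTOR == pytest.approx(2.772, abs=5e-4)

    def test_sem_estimates_error_sd(self):
        # SD * sqrt(1 - ICC) recovers the planted within-subject error SD
        rng = np.random.default_rng(6)
        sems = []
        for _ in range(500):
            x = baseline_sample(rng, sd_subj=1.5, sd_err=0.5)
            sems.append(sem_mdc(x, icc_2_1(x))[0])
        assert np.mean(sems) == pytest.approx(0.5, abs=0.05)

    def test_ms_err_variant_close_to_default(self):
        rng = np.random.default_rng(7)
        x = baseline_sample(rng, sd_subj=2.0, sd_err=0.6)
        icc = icc_2_1(x)
        sem_a, _ = sem_mdc(x, icc, "baseline_sd")
        sem_b, _ = sem_mdc(x, icc, "ms_err")
        assert sem_a == pytest.approx(sem_b, rel=0.25)

    def test_bad_icc_rejected(self):
        with pytest.raises(ReliabilityError):
            sem_mdc(np.ones((3, 3)), icc=1.2)


class TestBoundsAndFlags:
    def test_subject_bounds_mean_plus_minus_mdc(self):
        thr = reliability.MDCThresholds(metric="m", icc=0.9, sem=0.36,
                                        mdc95=1.0,
                                        subject_baseline_mean={"a": 3.0})
        assert subject_bounds(thr, [3, 3, 3, 3, 3]) == (2.0, 4.0)
        assert thr.bounds("a") == (2.0, 4.0)

    def test_zero_mdc_collapses_to_mean(self):
        thr = reliability.MDCThresholds(metric="m", icc=1.0, sem=0.0,
                                        mdc95=0.0,
                                        subject_baseline_mean={"a": 3.0})
        assert subject_bounds(thr, [3.0]) == (3.0, 3.0)

    def test_incomplete_baseline_rejected(self):
        thr = reliability.MDCThresholds(metric="m", icc=0.9, sem=1.0,
                                        mdc95=2.77,
                                        subject_baseline_mean={})
        with pytest.raises(ReliabilityError):
            subject_bounds(thr, [1.0, np.nan])

    @pytest.mark.parametrize("dev,expected", [
        (0.0, "green"), (0.79, "green"), (0.81, "yellow"), (1.0, "yellow"),
        (1.01, "red"), (-1.01, "red"), (-0.9, "yellow"),
    ])
    def test_classify_bands(self, dev, expected):
        assert classify(dev, mdc95=1.0, yellow_margin=0.2) == expected

    def test_baseline_mean_series_all_green(self):
        series = pd.Series([3.0] * 6, index=range(10, 16))
        flags = flag_series(series, baseline_mean=3.0, mdc95=1.0)
        assert (flags["status"] == "green").all()

    def test_boundary_red(self):
        series = pd.Series([3.0 + 1.01], index=[10])
        flags = flag_series(series, baseline_mean=3.0, mdc95=1.0)
        assert flags["status"].iloc[0] == "red"

    def test_missing_weeks_emit_no_status(self):
        series = pd.Series([3.0, np.nan, 5.0], index=[1, 2, 3])
        flags = flag_series(series, baseline_mean=3.0, mdc95=1.0)
        assert list(flags["week"]) == [1, 3]

    @given(dev1=st.floats(-5, 5), dev2=st.floats(-5, 5))
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity(self, dev1, dev2):
        order = {"green": 0, "yellow": 1, "red": 2}
        lo, hi = sorted([abs(dev1), abs(dev2)])
        assert order[classify(lo, 1.0)] <= order[classify(hi, 1.0)]

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_unit_equivariance(self, c):
        rng = np.random.default_rng(8)
        x = baseline_sample(rng, n=8, k=5)
        icc = icc_2_1(x)
        sem, mdc = sem_mdc(x, icc)
        sem_c, mdc_c = sem_mdc(c * x, icc_2_1(c * x))
        assert icc_2_1(c * x) == pytest.approx(icc, abs=1e-9)
        assert sem_c == pytest.approx(c * sem, rel=1e-9)
        assert mdc_c == pytest.approx(c * mdc, rel=1e-9)
        series = pd.Series(x[0] + np.linspace(-3, 3, 5), index=range(5))
        f1 = flag_series(series, x[0].mean(), mdc)
        f2 = flag_series(c * series, c * x[0].mean(), mdc_c)
        assert list(f1["status"]) == list(f2["status"])


class TestOperationalRates:
    def test_sustained_shift_detected(self):
        # a sustained shift of 2*MDC95 is flagged red in >= 95% of weeks
        rng = np.random.default_rng(9)
        hits = total = 0
        for _ in range(100):
            base = baseline_sample(rng, n=16, k=5, sd_subj=1.0, sd_err=0.4)
            window = BaselineWindow.from_frame(
                "m", pd.DataFrame(base, index=[f"a{i}" for i in range(16)]))
            thr = build_thresholds(window)
            subject = "a0"
            mean = thr.subject_baseline_mean[subject]
            shifted = mean + 2.0 * thr.mdc95 + rng.normal(0, 0.4, size=10)
            flags = flag_series(pd.Series(shifted, index=range(10)),
                                mean, thr.mdc95)
            hits += (flags["status"] == "red").sum()
            total += len(flags)
        assert hits / total >= 0.95

    def test_noise_free_shift_always_red(self):
        thr_mdc = 1.0
        series = pd.Series(np.full(20, 3.0 + 2.0 * thr_mdc), index=range(20))
        flags = flag_series(series, 3.0, thr_mdc)
        assert (flags["status"] == "red").all()

    def test_stationary_mean_bounds_are_conservative(self):
        # flagging against the 5-week baseline *mean* shrinks the reference
        # noise, so the stationary red rate falls well below the nominal 5%
        # two-measurement exceedance (analytically ~1.1%)
        rng = np.random.default_rng(10)
        red = total = 0
        for _ in range(50):
            base = baseline_sample(rng, n=16, k=5, sd_subj=1.0, sd_err=0.4)
            names = [f"a{i}" for i in range(16)]
            window = BaselineWindow.from_frame(
                "m", pd.DataFrame(base, index=names))
            thr = build_thresholds(window)
            subj_effect = base.mean(axis=1) - base.mean()
            for i, name in enumerate(names):
                fresh = (base.mean() + subj_effect[i]
                         + rng.normal(0, 0.4, size=5))
                flags = flag_series(pd.Series(fresh, index=range(5)),
                                    thr.subject_baseline_mean[name],
                                    thr.mdc95)
                red += (flags["status"] == "red").sum()
                total += len(flags)
        assert red / total < 0.03

    def test_flag_cohort_skips_unknown_athletes(self):
        thr = reliability.MDCThresholds(metric="m", icc=0.9, sem=0.5,
                                        mdc95=1.39,
                                        subject_baseline_mean={"a1": 0.0})
        weekly = pd.DataFrame({"athlete_id": ["a1", "a2"], "week": [1, 1],
                               "m": [0.5, 9.9]})
        flags = flag_cohort(weekly, thr)
        assert list(flags["athlete_id"].unique()) == ["a1"]


class TestBaselineWindow:
    def test_incomplete_subjects_excluded(self):
        frame = pd.DataFrame([[1, 2, 3], [2, np.nan, 4], [3, 4, 5]],
                             index=["a", "b", "c"])
        window = BaselineWindow.from_frame("m", frame)
        assert list(window.values.index) == ["a", "c"]

    def test_too_few_survivors_raise(self):
        frame = pd.DataFrame([[1, 2], [np.nan, 3], [np.nan, 4]],
                             index=["a", "b", "c"])
        with pytest.raises(ReliabilityError):
            BaselineWindow.from_frame("m", frame)

    def test_painful_baseline_warning(self):
        pain = pd.DataFrame({"athlete_id": ["a"] * 5 + ["b"] * 5,
                             "pain": [6, 7, 5, 6, 8, 0, 1, 0, 2, 1]})
        assert reliability.baseline_pain_warning(pain, threshold=4.0) == ["a"]
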