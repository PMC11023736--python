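"""Baseline reliability (ICC, SEM, MDC) and subject-specific red-flagging.

The monitoring scheme estimates how repeatable each metric is over a short
unperturbed preseason window (default five consecutive weeks), converts that
repeatability into a minimum detectable change, and then flags in-season
weeks whose deviation from the athlete's own preseason mean exceeds it:

* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation from the ANOVA decomposition of the
  subjects x weeks baseline matrix.
* SEM = SD_baseline * sqrt(1 - ICC), with SD_baseline the pooled SD of all
  baseline values (the classic distribution-based formula; a residual
  mean-square variant is available via ``sem_method``).
* MDC95 = 1.96 * sqrt(2) * SEM — the smallest change between two single
  measurements exceeding measurement error with 95% confidence.
* Traffic lights per athlete-week: red when |value - subject baseline mean|
  exceeds MDC95, yellow when within a margin (default 20%) below it, green
  otherwise.

The MDC is a cohort-level quantity; the bounds it generates are
subject-specific (centred on each athlete's own baseline mean).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MDC_FACTOR = 1.96 * np.sqrt(2.0)

STATUS_GREEN = "green"
STATUS_YELLOW = "yellow"
STATUS_RED = "red"


class ReliabilityError(ValueError):
    pass


@dataclass
class BaselineWindow:
    """A subjects x baseline-weeks matrix of one metric's values.

    Subjects with any missing baseline value are excluded (and logged) at
    construction; at least 2 subjects and 2 weeks must survive.
    """

    metric: str
    values: pd.DataFrame  # index: subject, columns: week

    @classmethod
    def from_frame(cls, metric: str, frame: pd.DataFrame) -> "BaselineWindow":
        complete = frame.dropna(axis=0, how="any")
        dropped = sorted(set(frame.index) - set(complete.index))
        if dropped:
            logger.info("baseline[%s]: excluded %d subject(s) with incomplete "
                        "baselines: %s", metric, len(dropped), dropped)
        if complete.shape[0] < 2 or complete.shape[1] < 2:
            raise ReliabilityError(
                f"baseline[{metric}]: need >= 2 subjects x >= 2 weeks of "
                f"complete data, have {complete.shape}")
        return cls(metric=metric, values=complete.astype(float))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.values.shape[1]


@dataclass
class MDCThresholds:
    """Cohort reliability statistics plus per-subject red-flag bounds."""

    metric: str
    icc: float
    sem: float
    mdc95: float
    subject_baseline_mean: Mapping[str, float]

    def bounds(self, subject) -> tuple:
        mean = self.subject_baseline_mean[subject]
        return (mean - self.mdc95, mean + self.mdc95)


def icc_2_1(baseline_matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``baseline_matrix``: array-like of shape (n_subjects, k_weeks), complete.
    Negative estimates are clipped to 0 with a warning; a matrix with zero
    total variance has no defined ICC.
    """
    x = np.asarray(baseline_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ReliabilityError("ICC needs a (>=2 subjects) x (>=2 weeks) matrix")
    if np.isnan(x).any():
        raise ReliabilityError("ICC input must be complete (no missing cells)")
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        raise ReliabilityError("ICC undefined: zero total variance")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    if denom <= 0:
        raise ReliabilityError("ICC undefined: non-positive denominator")
    icc = (ms_rows - ms_err) / denom
    if icc < 0:
        warnings.warn(f"negative ICC estimate ({icc:.3f}) clipped to 0",
                      RuntimeWarning, stacklevel=2)
        icc = 0.0
    return float(min(icc, 1.0))


def sem_mdc(baseline_matrix, icc: float,
            sem_method: str = "baseline_sd") -> tuple:
    """Standard error of measurement and MDC95 for a baseline matrix.

    ``baseline_sd`` (default): SEM = pooled SD of all baseline values times
    sqrt(1 - ICC).  ``ms_err``: SEM = sqrt(residual mean square) of the
    two-way ANOVA.  MDC95 = 1.96 * sqrt(2) * SEM in either case.
    """
    if not 0.0 <= icc <= 1.0:
        raise ReliabilityError(f"icc must be in [0, 1], got {icc}")
    x = np.asarray(baseline_matrix, dtype=float)
    if sem_method == "baseline_sd":
        sd = float(np.std(x.ravel(), ddof=1))
        sem = sd * np.sqrt(1.0 - icc)
    elif sem_method == "ms_err":
        n, k = x.shape
        grand = x.mean()
        ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
        ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
        ss_err = np.sum((x - grand) ** 2) - ss_rows - ss_cols
        sem = float(np.sqrt(max(ss_err, 0.0) / ((n - 1) * (k - 1))))
    else:
        raise ReliabilityError(f"unknown sem_method {sem_method!r}")
    return float(sem), float(MDC_FACTOR * sem)


def build_thresholds(window: BaselineWindow, sem_method: str = "baseline_sd"
                     ) -> MDCThresholds:
    """Cohort ICC/SEM/MDC95 plus per-subject baseline means and bounds."""
    icc = icc_2_1(window.values.to_numpy())
    sem, mdc95 = sem_mdc(window.values.to_numpy(), icc, sem_method)
    means = window.values.mean(axis=1)
    return MDCThresholds(metric=window.metric, icc=icc, sem=sem, mdc95=mdc95,
                         subject_baseline_mean=means.to_dict())


def subject_bounds(thresholds: MDCThresholds, subject_baseline_values) -> tuple:
    """Bounds = mean(subject baseline) +/- cohort MDC95."""
    vals = np.asarray(subject_baseline_values, dtype=float)
    if vals.size == 0 or np.isnan(vals).any():
        raise ReliabilityError("subject has an incomplete baseline")
    mean = float(vals.mean())
    return (mean - thresholds.mdc95, mean + thresholds.mdc95)


def classify(deviation: float, mdc95: float, yellow_margin: float = 0.2) -> str:
    """Traffic-light status for one deviation from the baseline mean."""
    d = abs(deviation)
    if d > mdc95:
        return STATUS_RED
    if d > (1.0 - yellow_margin) * mdc95:
        return STATUS_YELLOW
    return STATUS_GREEN


def flag_series(weekly_values: pd.Series, baseline_mean: float, mdc95: float,
                yellow_margin: float = 0.2) -> pd.DataFrame:
    """Flag one athlete's weekly metric series against their bounds.

    ``weekly_values`` is indexed by week; missing weeks (NaN) emit no status.
    Returns a frame with value, deviation and status per observed week.
    """
    if mdc95 < 0:
        raise ReliabilityError("mdc95 must be non-negative")
    present = weekly_values.dropna()
    dev = present - baseline_mean
    status = [classify(d, mdc95, yellow_margin) for d in dev]
    return pd.DataFrame({"week": present.index, "value": present.to_numpy(),
                         "deviation": dev.to_numpy(), "status": status})


def flag_cohort(weekly: pd.DataFrame, thresholds: MDCThresholds,
                yellow_margin: float = 0.2) -> pd.DataFrame:
    """Flag every athlete's series of one metric.

    ``weekly``: tidy frame with athlete_id, week and the metric column named
    ``thresholds.metric``.  Athletes without a baseline mean are skipped.
    Returns tidy rows: athlete_id, metric, week, value, baseline_mean, mdc95,
    deviation, status.
    """
    rows = []
    for athlete, group in weekly.groupby("athlete_id", sort=True):
        if athlete not in thresholds.subject_baseline_mean:
            logger.info("flags[%s]: no baseline for %s; skipped",
                        thresholds.metric, athlete)
            continue
        mean = thresholds.subject_baseline_mean[athlete]
        series = group.set_index("week")[thresholds.metric]
        flags = flag_series(series, mean, thresholds.mdc95, yellow_margin)
        flags.insert(0, "athlete_id", athlete)
        flags.insert(1, "metric", thresholds.metric)
        flags["baseline_mean"] = mean
        flags["mdc95"] = thresholds.mdc95
        rows.append(flags)
    if not rows:
        return pd.DataFrame(columns=["athlete_id", "metric", "week", "value",
                                     "deviation", "baseline_mean", "mdc95",
                                     "status"])
    return pd.concat(rows, ignore_index=True)


def baseline_pain_warning(pain_baseline: pd.DataFrame,
                          threshold: float = 4.0) -> list:
    """Warn when an athlete's baseline window is confounded by pain.

    MDC bounds assume the baseline window reflects the athlete's normal,
    unperturbed state; a painful baseline undermines that premise.  Returns
    the athletes whose mean baseline pain exceeds ``threshold`` (and logs a
    warning for each).
    """
    flagged = []
    for athlete, group in pain_baseline.groupby("athlete_id"):
        mean_pain = group["pain"].dropna().mean()
        if np.isfinite(mean_pain) and mean_pain > threshold:
            logger.warning("athlete %s baseline mean pain %.1f exceeds %.1f: "
                           "normative bounds may be confounded",
                           athlete, mean_pain, threshold)
            flagged.append(athlete)
    return flagged
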