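"""Repeated-measures correlation between component scores and psychological
state.

With weekly observations nested in athletes, a pooled Pearson correlation
would conflate stable between-athlete differences with week-to-week
covariation.  The repeated-measures correlation (rmcorr) removes each
subject's own mean via an analysis of covariance with subject as a factor and
a common slope, estimating the within-subject association shared across the
cohort:

    r_rm = sign(b) * sqrt(SS_measure / (SS_measure + SS_error)),
    df   = n_obs - n_subjects - 1,

where b is the common slope fitted to within-subject-centred data, SS_measure
is the covariate sum of squares and SS_error the residual.  The p-value comes
from F(1, df); the 95% CI uses the Fisher z-transform with the effective
sample size implied by df.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class RmcorrResult:
    x_name: str
    y_name: str
    r_rm: float
    df: int
    p_value: float
    ci95: tuple
    n_subjects: int
    n_obs: int

    def as_dict(self) -> dict:
        return {"x": self.x_name, "y": self.y_name, "r_rm": self.r_rm,
                "df": self.df, "p_value": self.p_value,
                "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
                "n_subjects": self.n_subjects, "n_obs": self.n_obs}


def rmcorr(x, y, subject_labels, x_name: str = "x", y_name: str = "y"
           ) -> RmcorrResult:
    """Repeated-measures correlation of paired series nested in subjects.

    Rows with a missing value in either series are dropped (pairwise
    complete); subjects left with fewer than two complete pairs are dropped
    with a warning.  At least two usable subjects are required.
    """
    frame = pd.DataFrame({"x": np.asarray(x, dtype=float),
                          "y": np.asarray(y, dtype=float),
                          "subject": np.asarray(subject_labels)})
    frame = frame.dropna()
    counts = frame.groupby("subject")["x"].size()
    thin = counts[counts < 2]
    if len(thin):
        warnings.warn(f"rmcorr: dropping {len(thin)} subject(s) with < 2 "
                      f"complete pairs", RuntimeWarning, stacklevel=2)
        frame = frame[~frame["subject"].isin(thin.index)]
    n_subjects = frame["subject"].nunique()
    if n_subjects < 2:
        raise AssociationError("rmcorr needs >= 2 subjects with >= 2 complete pairs")
    n_obs = len(frame)

    xc = frame["x"] - frame.groupby("subject")["x"].transform("mean")
    yc = frame["y"] - frame.groupby("subject")["y"].transform("mean")
    sxx = float(np.sum(xc ** 2))
    syy = float(np.sum(yc ** 2))
    sxy = float(np.sum(xc * yc))
    if sxx == 0 or syy == 0:
        raise AssociationError("rmcorr undefined: no within-subject variance")

    ss_measure = sxy ** 2 / sxx          # covariate (common-slope) SS
    ss_error = syy - ss_measure
    df = n_obs - n_subjects - 1
    if df < 1:
        raise AssociationError(f"rmcorr df = {df} < 1")
    r = float(np.sign(sxy) * np.sqrt(ss_measure / (ss_measure + ss_error)))
    r = float(np.clip(r, -1.0, 1.0))

    if abs(r) >= 1.0:
        p = 0.0
        ci = (r, r)
    else:
        f_stat = (r ** 2 / (1.0 - r ** 2)) * df
        p = float(stats.f.sf(f_stat, 1, df))
        # Fisher z with the effective n implied by df (df = n_eff - 2)
        se = 1.0 / np.sqrt(df - 1) if df > 1 else np.inf
        z = np.arctanh(r)
        ci = (float(np.tanh(z - 1.959964 * se)),
              float(np.tanh(z + 1.959964 * se)))
    return RmcorrResult(x_name=x_name, y_name=y_name, r_rm=r, df=int(df),
                        p_value=p, ci95=ci, n_subjects=int(n_subjects),
                        n_obs=int(n_obs))


def association_screen(pc_scores: pd.DataFrame, psych: pd.DataFrame,
                       subject_col: str = "athlete_id",
                       lag: int = 0) -> pd.DataFrame:
    """rmcorr of every component-score column against every psychological
    scale, with Benjamini-Hochberg adjusted p-values reported alongside the
    unadjusted ones (the adjustment never gates the output).

    Both frames must share (athlete_id, season, week) key columns.  ``lag``
    shifts the psychological series forward by that many weeks within each
    athlete-season before pairing (default 0: in-phase associations only).
    Pairs with insufficient overlap are skipped with a log entry.
    """
    keys = [subject_col, "season", "week"]
    score_cols = [c for c in pc_scores.columns if c not in keys]
    psych_cols = [c for c in psych.columns if c not in keys]
    psych_use = psych.copy()
    if lag != 0:
        psych_use["week"] = psych_use["week"] + lag
    merged = pc_scores.merge(psych_use, on=keys, how="inner",
                             suffixes=("", "_psych"))

    rows = []
    for pc, scale in itertools.product(score_cols, psych_cols):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = rmcorr(merged[pc], merged[scale], merged[subject_col],
                             x_name=pc, y_name=scale)
        except AssociationError as exc:
            logger.info("association %s ~ %s skipped: %s", pc, scale, exc)
            continue
        rows.append(res.as_dict())
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
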