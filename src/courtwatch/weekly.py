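"""Athlete-week assembly: join weekly CMJ, on-court and questionnaire
summaries, enforce the complete-case filter, and build the analysis matrix.

An athlete-week observation carries 17 biomechanical variables (7 on-court +
10 CMJ) plus 5 optional psychological scales.  The analysis matrix retains
only weeks in which *all* biomechanical variables were collected; the
psychological scales never gate that filter.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cmj import CMJMetrics
from .oncourt import OnCourtMetrics
from .synthetic import PSYCH_SCALES

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["athlete_id", "season", "week"]

#: Fixed, versioned column order of the 17-variable analysis matrix.
ONCOURT_VARIABLES = list(OnCourtMetrics.FIELD_NAMES)
CMJ_VARIABLES = list(CMJMetrics.FIELD_NAMES)
BIOMECH_VARIABLES = ONCOURT_VARIABLES + CMJ_VARIABLES
PSYCH_VARIABLES = list(PSYCH_SCALES)
MATRIX_VERSION = "courtwatch-matrix-v1"


class WeeklyDataError(ValueError):
    """Malformed weekly inputs (e.g. duplicate athlete-week keys)."""


class PipelineError(RuntimeError):
    """The pipeline cannot continue (e.g. no complete observations)."""


def possible_observations(n_athletes: int, n_weeks: int) -> int:
    """Bookkeeping: number of possible athlete-week observations."""
    return int(n_athletes) * int(n_weeks)


def mean_per_athlete(total_count: int, n_athletes: int) -> float:
    """Bookkeeping: mean collected units per athlete."""
    if n_athletes <= 0:
        raise ValueError("n_athletes must be positive")
    return total_count / n_athletes


def _check_keys(frame: pd.DataFrame, source: str) -> None:
    missing = [c for c in KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise WeeklyDataError(f"{source} is missing key columns {missing}")
    dup = frame.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        keys = frame.loc[dup, KEY_COLUMNS].iloc[0].tolist()
        raise WeeklyDataError(f"duplicate athlete-week key in {source}: {keys}")


def assemble_weeks(cmj_weekly: Optional[pd.DataFrame],
                   oncourt_weekly: Optional[pd.DataFrame],
                   psych_weekly: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join weekly summaries into athlete-week observations.

    Inputs are tidy frames keyed by (athlete_id, season, week); each may be
    ``None`` or empty.  The result has one row per key in the union, all 17
    biomechanical columns (NaN where missing), the 5 psychological columns,
    and a ``complete_biomech`` flag that is True iff every biomechanical
    variable is present.
    """
    frames = []
    for frame, source, cols in [(cmj_weekly, "cmj", CMJ_VARIABLES),
                                (oncourt_weekly, "oncourt", ONCOURT_VARIABLES),
                                (psych_weekly, "psych", PSYCH_VARIABLES)]:
        if frame is None or len(frame) == 0:
            continue
        _check_keys(frame, source)
        keep = KEY_COLUMNS + [c for c in cols if c in frame.columns]
        frames.append(frame[keep])
    if not frames:
        raise WeeklyDataError("no weekly inputs to assemble")

    out = frames[0]
    for frame in frames[1:]:
        out = out.merge(frame, on=KEY_COLUMNS, how="outer")
    for col in BIOMECH_VARIABLES + PSYCH_VARIABLES:
        if col not in out.columns:
            out[col] = np.nan
    out = out.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    out["complete_biomech"] = out[BIOMECH_VARIABLES].notna().all(axis=1)
    logger.info("assembled %d athlete-week observations (%d biomech-complete)",
                len(out), int(out["complete_biomech"].sum()))
    return out[KEY_COLUMNS + BIOMECH_VARIABLES + PSYCH_VARIABLES
               + ["complete_biomech"]]


def complete_case_filter(observations: pd.DataFrame) -> pd.DataFrame:
    """Retain only biomech-complete athlete-weeks as the analysis matrix.

    Returns a frame indexed by (athlete_id, season, week) whose columns are
    exactly the 17 biomechanical variables in their versioned order.  Raises
    :class:`PipelineError` when nothing survives.
    """
    if "complete_biomech" in observations.columns:
        mask = observations["complete_biomech"].astype(bool)
    else:
        mask = observations[BIOMECH_VARIABLES].notna().all(axis=1)
    retained = observations.loc[mask]
    logger.info("complete-case filter: retained %d of %d observations",
                len(retained), len(observations))
    if len(retained) == 0:
        raise PipelineError("complete-case filter retained zero observations")
    matrix = (retained.set_index(KEY_COLUMNS)[BIOMECH_VARIABLES]
              .astype(float))
    assert not matrix.isna().any().any()
    return matrix
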