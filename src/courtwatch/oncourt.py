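"""On-court impact metrics from per-foot IMU impact-event streams.

Each event is one foot strike's peak resultant acceleration (in g) recorded by
an ankle-worn IMU during practice.  A session reduces to seven variables:
total impact load (sum of magnitudes), step count, average intensity, and four
signed interlimb asymmetry indices computed on per-foot summed magnitudes
within the low (1-5 g), moderate (6-20 g) and high (>= 21 g) intensity bins
plus all bins pooled.  Weekly values are unweighted means over the week's
sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cmj import asymmetry_index, UndefinedIndexError

logger = logging.getLogger(__name__)

#: Half-open bin edges reconciling the integer bin labels with continuous
#: magnitudes: low [1, 6), moderate [6, 21), high [21, inf).
BIN_EDGES = (1.0, 6.0, 21.0)
BIN_LABELS = ("low", "moderate", "high")

EVENT_COLUMNS = ("athlete_id", "session_id", "timestamp", "foot", "magnitude_g")


class ImpactDataError(ValueError):
    """Raised for malformed impact-event data (e.g. negative magnitudes)."""


@dataclass(frozen=True)
class OnCourtMetrics:
    """The seven on-court variables for one session (or a weekly average)."""

    total_impact_load: float  # g-sum
    step_count: float         # count (float after weekly averaging)
    avg_intensity: float      # g
    asym_low: float           # signed %, negative = left-dominant
    asym_med: float
    asym_high: float
    asym_total: float

    FIELD_NAMES = ("total_impact_load", "step_count", "avg_intensity",
                   "asym_low", "asym_med", "asym_high", "asym_total")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELD_NAMES}


def bin_impact(magnitude) -> np.ndarray:
    """Classify magnitudes into intensity bins.

    Returns an integer array: -1 for sub-floor events (< 1 g, discarded),
    0 = low, 1 = moderate, 2 = high.  Scalar input returns a scalar label
    string, matching the bin names, or raises for discarded events.
    """
    mags = np.asarray(magnitude, dtype=float)
    if np.any(mags < 0):
        raise ImpactDataError("negative impact magnitude")
    codes = np.searchsorted(BIN_EDGES, mags, side="right") - 1
    if np.isscalar(magnitude) or mags.ndim == 0:
        code = int(codes)
        if code < 0:
            raise ImpactDataError(f"magnitude {float(mags)} g below the 1 g floor")
        return BIN_LABELS[code]
    return codes


def session_metrics(events: pd.DataFrame,
                    asymmetry_method: str = "mean",
                    asymmetry_basis: str = "magnitude") -> Optional[OnCourtMetrics]:
    """Reduce one session's events to the seven on-court variables.

    ``asymmetry_basis`` selects whether per-bin asymmetry uses summed
    magnitudes (default, matching an impact *acceleration* asymmetry) or step
    counts.  Returns ``None`` for an empty session (excluded from weekly
    means).  Sub-1 g events are discarded with a logged count.  A bin with no
    events on either foot yields an asymmetry of 0 (no evidence of imbalance).
    """
    if len(events) == 0:
        return None
    if events["session_id"].nunique() > 1:
        raise ImpactDataError("session_metrics expects events of one session")
    mags = events["magnitude_g"].to_numpy(dtype=float)
    feet = events["foot"].to_numpy()
    bad_feet = set(np.unique(feet)) - {"L", "R"}
    if bad_feet:
        raise ImpactDataError(f"unknown foot labels: {sorted(bad_feet)}")

    codes = bin_impact(mags)
    discarded = int(np.sum(codes < 0))
    if discarded:
        logger.info("session %s: discarded %d sub-1 g events",
                    events["session_id"].iloc[0], discarded)
        keep = codes >= 0
        mags, feet, codes = mags[keep], feet[keep], codes[keep]
    if len(mags) == 0:
        return None

    step_count = len(mags)
    total_load = float(np.sum(mags))
    avg_intensity = total_load / step_count

    is_right = feet == "R"

    def foot_sums(mask: np.ndarray) -> tuple[float, float]:
        if asymmetry_basis == "magnitude":
            left = float(np.sum(mags[mask & ~is_right]))
            right = float(np.sum(mags[mask & is_right]))
        elif asymmetry_basis == "count":
            left = float(np.sum(mask & ~is_right))
            right = float(np.sum(mask & is_right))
        else:
            raise ValueError(f"unknown asymmetry_basis {asymmetry_basis!r}")
        return left, right

    def bin_asym(mask: np.ndarray) -> float:
        left, right = foot_sums(mask)
        if left + right == 0:
            return 0.0
        return asymmetry_index(left, right, method=asymmetry_method)

    return OnCourtMetrics(
        total_impact_load=total_load,
        step_count=step_count,
        avg_intensity=avg_intensity,
        asym_low=bin_asym(codes == 0),
        asym_med=bin_asym(codes == 1),
        asym_high=bin_asym(codes == 2),
        asym_total=bin_asym(codes >= 0),
    )


def weekly_oncourt(session_metrics_list: Iterable[Optional[OnCourtMetrics]]
                   ) -> Optional[OnCourtMetrics]:
    """Unweighted mean of session-level metrics across one athlete-week.

    Empty sessions (``None``) are dropped; a week with no non-empty sessions
    returns ``None`` (missing-week marker).
    """
    sessions = [s for s in session_metrics_list if s is not None]
    if not sessions:
        return None
    return OnCourtMetrics(**{
        name: float(np.mean([getattr(s, name) for s in sessions]))
        for name in OnCourtMetrics.FIELD_NAMES
    })
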