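"""Countermovement-jump (CMJ) feature extraction from bilateral vertical GRF traces.

A CMJ trace is the vertical ground-reaction force (vGRF) recorded separately
under each foot on a dual force plate while the athlete performs a jump
preceded by a rapid downward countermovement.  From a single trace this module
derives the ten weekly monitoring variables used downstream:

* jump height (impulse-momentum method), countermovement depth, time to
  takeoff, modified reactive strength index (RSImod = JH / time to takeoff);
* peak relative braking and propulsive power (W/kg);
* four signed interlimb asymmetry indices: peak braking force, peak
  propulsive force, average braking rate of force development (RFD), and
  peak landing force.

Phases follow the standard force-plate convention: movement onset is detected
against the quiet-standing window, the braking phase runs from the instant of
peak downward centre-of-mass velocity to the zero-velocity crossing, the
propulsive phase from there to takeoff, and the landing phase starts at
touchdown after flight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

GRAVITY = 9.81  # m/s^2

#: Force threshold (N) below which the athlete is considered airborne.
FLIGHT_THRESHOLD_N = 30.0
#: Onset must exceed ``ONSET_SD_MULT`` * SD(quiet window) for this long.
ONSET_SUSTAIN_S = 0.050
ONSET_SD_MULT = 5.0
#: Absolute floor on the onset threshold (N) so that noise-free synthetic
#: traces (quiet-window SD exactly zero) still yield a finite threshold.
ONSET_THRESHOLD_FLOOR_N = 0.01
#: Window after touchdown (s) searched for the peak landing force.
LANDING_WINDOW_S = 0.40
#: Length of the quiet-standing reference window (s).
QUIET_WINDOW_S = 0.40


class CMJError(ValueError):
    """Base class for extraction failures."""


class NoMovementError(CMJError):
    """No movement onset found (e.g. the athlete just stood on the plates)."""


class NoTakeoffError(CMJError):
    """No flight phase found after onset."""


class UndefinedIndexError(CMJError):
    """Asymmetry index undefined (left + right == 0)."""


@dataclass
class ForceTrace:
    """One jump's synchronized left/right vertical GRF.

    Attributes
    ----------
    time : array of s, uniform grid
    f_left, f_right : arrays of N
    body_mass : kg
    sample_rate : Hz
    meta : free-form provenance (synthetic traces store planted ground truth)
    """

    time: np.ndarray
    f_left: np.ndarray
    f_right: np.ndarray
    body_mass: float
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_left = np.asarray(self.f_left, dtype=float)
        self.f_right = np.asarray(self.f_right, dtype=float)
        if not (len(self.time) == len(self.f_left) == len(self.f_right)):
            raise ValueError("time, f_left and f_right must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")

    @property
    def f_total(self) -> np.ndarray:
        return self.f_left + self.f_right

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class PhaseBoundaries:
    """Sample indices of the CMJ phase landmarks (onset < braking_start <
    braking_end < takeoff < touchdown)."""

    onset: int
    braking_start: int
    braking_end: int
    takeoff: int
    touchdown: int

    def __post_init__(self) -> None:
        seq = (self.onset, self.braking_start, self.braking_end,
               self.takeoff, self.touchdown)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"phase boundaries must be strictly increasing: {seq}")


@dataclass(frozen=True)
class CMJMetrics:
    """The ten CMJ variables for one trial (or a weekly average)."""

    jump_height: float               # m
    countermovement_depth: float     # m, negative (downward)
    time_to_takeoff: float           # s
    peak_rel_braking_power: float    # W/kg, negative
    peak_rel_propulsive_power: float  # W/kg
    rsi_mod: float                   # jump_height / time_to_takeoff
    asym_peak_braking_force: float   # signed %
    asym_peak_propulsive_force: float
    asym_avg_braking_rfd: float
    asym_peak_landing_force: float

    FIELD_NAMES = (
        "jump_height", "countermovement_depth", "time_to_takeoff",
        "peak_rel_braking_power", "peak_rel_propulsive_power", "rsi_mod",
        "asym_peak_braking_force", "asym_peak_propulsive_force",
        "asym_avg_braking_rfd", "asym_peak_landing_force",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELD_NAMES}


def asymmetry_index(left_value: float, right_value: float,
                    method: str = "mean") -> float:
    """Signed interlimb asymmetry in percent; negative = left-dominant.

    The default is the mean-referenced percent difference
    ``100 * (right - left) / ((right + left) / 2)``, bounded in [-200, 200].
    ``method="max"`` divides by ``max(|left|, |right|)`` instead (a common
    alternative in the asymmetry literature).
    """
    left = float(left_value)
    right = float(right_value)
    if not (np.isfinite(left) and np.isfinite(right)):
        raise UndefinedIndexError("asymmetry index requires finite inputs")
    if method == "mean":
        denom = (left + right) / 2.0
        if denom == 0.0:
            raise UndefinedIndexError("asymmetry index undefined: left + right = 0")
    elif method == "max":
        denom = max(abs(left), abs(right))
        if denom == 0.0:
            raise UndefinedIndexError("asymmetry index undefined: both values zero")
    else:
        raise ValueError(f"unknown asymmetry method {method!r}")
    return 100.0 * (right - left) / denom


def _velocity(trace: ForceTrace, onset: int) -> np.ndarray:
    """Centre-of-mass vertical velocity by trapezoidal integration of
    net force / mass, zero at onset.  Entries before onset are zero."""
    dt = 1.0 / trace.sample_rate
    accel = trace.f_total / trace.body_mass - GRAVITY
    v = np.zeros(trace.n_samples)
    seg = accel[onset:]
    v[onset:] = np.concatenate(
        ([0.0], np.cumsum((seg[1:] + seg[:-1]) / 2.0) * dt))
    return v


def detect_phases(trace: ForceTrace) -> PhaseBoundaries:
    """Locate onset, braking, takeoff and touchdown landmarks.

    Onset: first sample where |F_total - m g| exceeds 5 x SD of the quiet
    window for at least 50 ms.  Takeoff/touchdown: 30 N flight threshold.
    Braking start: minimum (most negative) integrated velocity; braking end:
    first subsequent zero crossing of velocity.
    """
    f = trace.f_total
    m = trace.body_mass
    fs = trace.sample_rate
    n_quiet = max(2, int(round(QUIET_WINDOW_S * fs)))
    if trace.n_samples <= n_quiet:
        raise NoMovementError("trace shorter than the quiet-standing window")
    quiet = f[:n_quiet]
    threshold = max(ONSET_SD_MULT * float(np.std(quiet)), ONSET_THRESHOLD_FLOOR_N)
    weight = m * GRAVITY

    deviating = np.abs(f - weight) > threshold
    sustain = max(1, int(round(ONSET_SUSTAIN_S * fs)))
    # onset = first index i (>= quiet window) with `sustain` consecutive
    # deviating samples starting at i
    run = np.convolve(deviating.astype(int), np.ones(sustain, dtype=int), "valid")
    candidates = np.flatnonzero(run[n_quiet:] == sustain)
    if candidates.size == 0:
        raise NoMovementError("no movement onset found")
    onset = int(candidates[0]) + n_quiet

    airborne = np.flatnonzero(f[onset:] < FLIGHT_THRESHOLD_N)
    if airborne.size == 0:
        raise NoTakeoffError("no takeoff (force never fell below the flight threshold)")
    takeoff = onset + int(airborne[0])

    grounded = np.flatnonzero(f[takeoff:] > FLIGHT_THRESHOLD_N)
    if grounded.size == 0:
        raise NoTakeoffError("no touchdown after takeoff")
    touchdown = takeoff + int(grounded[0])

    v = _velocity(trace, onset)
    braking_start = onset + int(np.argmin(v[onset:takeoff]))
    crossing = np.flatnonzero(v[braking_start:takeoff] >= 0.0)
    if crossing.size == 0:
        raise CMJError("no zero-velocity crossing before takeoff")
    braking_end = braking_start + int(crossing[0])

    return PhaseBoundaries(onset, braking_start, braking_end, takeoff, touchdown)


def compute_metrics(trace: ForceTrace, phases: PhaseBoundaries,
                    asymmetry_method: str = "mean") -> CMJMetrics:
    """Compute the ten CMJ variables from a trace and its phase landmarks."""
    m = trace.body_mass
    fs = trace.sample_rate
    dt = 1.0 / fs
    f = trace.f_total
    on, bs, be, to, td = (phases.onset, phases.braking_start,
                          phases.braking_end, phases.takeoff, phases.touchdown)

    v = _velocity(trace, on)
    v_takeoff = float(v[to - 1])  # velocity at the last in-contact sample
    jump_height = v_takeoff ** 2 / (2.0 * GRAVITY)
    if jump_height <= 0 or v_takeoff <= 0:
        raise CMJError("non-physical jump: takeoff velocity not positive")

    disp = np.concatenate(
        ([0.0], np.cumsum((v[on + 1:to] + v[on:to - 1]) / 2.0) * dt))
    countermovement_depth = float(np.min(disp))

    time_to_takeoff = (to - on) * dt

    power = f * v / m  # W/kg
    peak_brk_power = float(np.min(power[bs:be]))
    peak_prop_power = float(np.max(power[be:to]))

    lw_end = min(trace.n_samples, td + int(round(LANDING_WINDOW_S * fs)))

    def limb_peaks(lo: int, hi: int) -> tuple[float, float]:
        return (float(np.max(trace.f_left[lo:hi])),
                float(np.max(trace.f_right[lo:hi])))

    brk_l, brk_r = limb_peaks(bs, be + 1)
    prop_l, prop_r = limb_peaks(be, to)
    land_l, land_r = limb_peaks(td, lw_end)

    span = (be - bs) * dt
    rfd_l = (trace.f_left[be] - trace.f_left[bs]) / span
    rfd_r = (trace.f_right[be] - trace.f_right[bs]) / span

    ai = lambda l, r: asymmetry_index(l, r, method=asymmetry_method)
    return CMJMetrics(
        jump_height=jump_height,
        countermovement_depth=countermovement_depth,
        time_to_takeoff=time_to_takeoff,
        peak_rel_braking_power=peak_brk_power,
        peak_rel_propulsive_power=peak_prop_power,
        rsi_mod=jump_height / time_to_takeoff,
        asym_peak_braking_force=ai(brk_l, brk_r),
        asym_peak_propulsive_force=ai(prop_l, prop_r),
        asym_avg_braking_rfd=ai(rfd_l, rfd_r),
        asym_peak_landing_force=ai(land_l, land_r),
    )


def extract_metrics(trace: ForceTrace, asymmetry_method: str = "mean") -> CMJMetrics:
    """Convenience wrapper: detect phases, then compute metrics."""
    return compute_metrics(trace, detect_phases(trace), asymmetry_method)


def flight_time_height(trace: ForceTrace, phases: PhaseBoundaries) -> float:
    """Jump height from flight time, ``g * t_flight^2 / 8``.

    Independent of the impulse-momentum route; used as a cross-check.
    """
    t_flight = (phases.touchdown - phases.takeoff) / trace.sample_rate
    return GRAVITY * t_flight ** 2 / 8.0


def average_trials(metrics_list: Sequence[CMJMetrics]) -> CMJMetrics:
    """Element-wise mean across trials of one week.

    RSImod is averaged as the mean of per-trial ratios (each trial's RSImod is
    already JH/TTT for that jump), not recomputed from the averaged height and
    time.
    """
    if len(metrics_list) == 0:
        raise ValueError("average_trials requires at least one trial")
    return CMJMetrics(**{
        name: float(np.mean([getattr(t, name) for t in metrics_list]))
        for name in CMJMetrics.FIELD_NAMES
    })
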