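"""Synthetic cohort generator for longitudinal basketball monitoring.

Emulates the study design the package targets: a roster of collegiate female
basketball athletes followed over 28-week seasons (offseason -> preseason ->
regular season) with one 3-jump CMJ force-plate session, two-to-three on-court
IMU practice sessions, and one psychological-state questionnaire per week.
Every generated quantity is tied to planted ground truth stored alongside the
data, so downstream extractors can be validated by parameter recovery.

The CMJ trace template is built from half-cosine centre-of-mass acceleration
pulses (quiet standing -> unweighting -> braking/propulsion -> flight ->
landing) whose amplitudes are solved from the planted jump height,
countermovement depth and time to takeoff, making the ground truth
analytically invertible.  The left/right split applies a phase-specific share
so that each planted asymmetry channel is realized exactly at the samples the
extractor reads.

Impact magnitudes are drawn from a lognormal distribution truncated to
[1, 200] g (right-skewed, matching the occupancy of the low/moderate/high
intensity bins), with per-foot, per-bin scaling realizing planted bin-wise
asymmetries in expectation.  Questionnaire scales are integer ordinal values
with independent Bernoulli missingness per scale per week.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cmj import GRAVITY, ForceTrace

ASYM_CHANNELS = (
    "cmj_braking", "cmj_propulsive", "cmj_rfd", "cmj_landing",
    "oncourt_low", "oncourt_med", "oncourt_high",
)
PSYCH_SCALES = ("pain", "sleep_quality", "sleep_quantity", "feeling",
                "academic_workload")
PSYCH_RANGES = {
    "pain": (0, 10),
    "sleep_quality": (0, 3),
    "sleep_quantity": (0, 3),
    "feeling": (0, 10),
    "academic_workload": (0, 10),
}
PHASES = ("offseason", "preseason", "regular")


class GenerationError(RuntimeError):
    """A planted parameter combination cannot be realized."""


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. phases do not tile the season)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AthleteProfile:
    athlete_id: str
    body_mass: float                     # kg
    baseline_jump: dict                  # jump_height (m), countermovement_depth (m, <0), time_to_takeoff (s)
    baseline_asym: dict                  # signed % per channel in ASYM_CHANNELS
    oncourt_rates: dict                  # steps_per_session, lognorm_mu, lognorm_sigma
    psych_baseline: dict                 # per-scale central values
    compliance: dict                     # per-scale response probability in [0, 1]
    biomech_presence: dict               # p_cmj_week, p_oncourt_week

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ConfigurationError("body_mass must be positive")
        if self.baseline_jump["jump_height"] <= 0:
            raise ConfigurationError("jump_height must be positive")
        if self.baseline_jump["countermovement_depth"] >= 0:
            raise ConfigurationError("countermovement_depth must be negative")
        for scale, p in self.compliance.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"compliance[{scale}] outside [0, 1]")


@dataclass(frozen=True)
class SeasonSchedule:
    season_label: str
    start_monday: _dt.date
    weeks: tuple  # of WeekPlan

    def phase_of(self, week_index: int) -> str:
        return self.weeks[week_index - 1].phase


@dataclass(frozen=True)
class WeekPlan:
    week_index: int          # 1-based
    phase: str
    monday: _dt.date
    n_oncourt_sessions: int


@dataclass(frozen=True)
class PerturbationEvent:
    """A planted episode: an asymmetry shift with a pain spike and (optionally)
    reduced on-court load, emulating an athlete managing a niggle."""

    athlete_id: str
    season: str
    onset_week: int
    duration_weeks: int
    asym_shift: Mapping[str, float]    # additive signed % per channel
    pain_shift: float                  # additive 0-10 points (clipped)
    load_reduction: float = 1.0        # multiplicative factor on step count

    def __post_init__(self) -> None:
        if self.duration_weeks < 1:
            raise ConfigurationError("duration_weeks must be >= 1")

    def active(self, season: str, week: int) -> bool:
        return (season == self.season
                and self.onset_week <= week < self.onset_week + self.duration_weeks)


@dataclass
class SyntheticConfig:
    """Generator defaults: the study conditions being emulated.

    Marginal targets follow the cohort's descriptive statistics (16 athletes,
    body mass 73 (11) kg, jump height 0.24 (0.05) m, countermovement depth
    -0.28 (0.04) m, time to takeoff 0.84 (0.11) s, ~6,000 steps and ~72,000 g
    impact load per session at ~12 g average intensity) and the reported
    questionnaire compliance rates (pain 49%, sleep 55%, academic workload
    67%, feeling 80%).
    """

    n_athletes: int = 16
    n_weeks: int = 28
    n_seasons: int = 2
    phase_weeks: Optional[tuple] = None     # (offseason, preseason, regular); None -> scaled 4/8/16
    trials_per_cmj_session: int = 3
    oncourt_sessions_range: tuple = (2, 3)
    sample_rate: float = 1000.0
    force_noise_sd: float = 0.0             # N per channel; 0 = noise-free traces

    body_mass_mean: float = 73.0
    body_mass_sd: float = 11.0
    jump_height_mean: float = 0.24
    jump_height_sd: float = 0.05
    jump_height_range: tuple = (0.16, 0.36)
    depth_mean: float = -0.28
    depth_sd: float = 0.04
    depth_range: tuple = (-0.34, -0.22)
    # time to takeoff co-varies with depth (deeper dips take longer); the
    # residual SD reproduces the reported marginal spread.
    ttt_intercept: float = 0.30
    ttt_per_depth: float = 1.9              # s per m of |depth|
    ttt_resid_sd: float = 0.05
    ttt_range: tuple = (0.65, 1.10)

    # athlete-level signed asymmetry SDs per channel; the reported cohort
    # means of |asymmetry| (half-normal) divided by sqrt(2/pi).
    asym_sd: Mapping[str, float] = field(default_factory=lambda: {
        "cmj_braking": 7.0, "cmj_propulsive": 4.7, "cmj_rfd": 12.0,
        "cmj_landing": 14.0, "oncourt_low": 2.5, "oncourt_med": 4.7,
        "oncourt_high": 9.1,
    })
    asym_week_sd: float = 2.0               # week-to-week drift, all channels
    asym_trial_sd: float = 0.0              # per-trial jitter (CMJ channels)
    jump_week_sd: Mapping[str, float] = field(default_factory=lambda: {
        "jump_height": 0.010, "countermovement_depth": 0.010,
        "time_to_takeoff": 0.020,
    })
    jump_trial_sd: Mapping[str, float] = field(default_factory=lambda: {
        "jump_height": 0.005, "countermovement_depth": 0.005,
        "time_to_takeoff": 0.010,
    })

    steps_mean: float = 6000.0
    steps_athlete_sd: float = 1000.0
    steps_range: tuple = (3000.0, 9000.0)
    steps_session_cv: float = 0.10
    lognorm_mu: float = 2.10                # median exp(2.10) ~ 8.2 g
    lognorm_mu_athlete_sd: float = 0.10
    lognorm_sigma: float = 0.85
    impact_floor_g: float = 1.0
    impact_cap_g: float = 200.0
    foot_switch_prob: float = 0.9           # alternation with stochastic jitter

    psych_mean: Mapping[str, float] = field(default_factory=lambda: {
        "pain": 2.2, "sleep_quality": 1.0, "sleep_quantity": 0.6,
        "feeling": 6.1, "academic_workload": 5.6,
    })
    psych_athlete_sd: Mapping[str, float] = field(default_factory=lambda: {
        "pain": 1.0, "sleep_quality": 0.5, "sleep_quantity": 0.4,
        "feeling": 1.0, "academic_workload": 1.3,
    })
    psych_week_sd: Mapping[str, float] = field(default_factory=lambda: {
        "pain": 1.2, "sleep_quality": 0.7, "sleep_quantity": 0.7,
        "feeling": 1.3, "academic_workload": 1.8,
    })
    compliance_mean: Mapping[str, float] = field(default_factory=lambda: {
        "pain": 0.49, "sleep_quality": 0.55, "sleep_quantity": 0.55,
        "feeling": 0.80, "academic_workload": 0.67,
    })
    compliance_athlete_sd: Mapping[str, float] = field(default_factory=lambda: {
        "pain": 0.29, "sleep_quality": 0.29, "sleep_quantity": 0.29,
        "feeling": 0.11, "academic_workload": 0.16,
    })

    # weekly biomech presence; 0.66 * 0.66 ~ 44% joint completeness, matching
    # the study's complete-case yield (394 of ~900 possible athlete-weeks).
    p_cmj_week: float = 0.66
    p_oncourt_week: float = 0.66
    baseline_weeks: int = 5
    #: biomech collection is enforced during the designated preseason baseline
    #: window of the final season (the team schedules testing for it).
    baseline_full_compliance: bool = True

    perturbations_enabled: bool = True
    n_perturbations: int = 2
    perturbation_duration: int = 4
    perturbation_asym_shift: Mapping[str, float] = field(default_factory=lambda: {
        "oncourt_high": -12.0, "cmj_braking": 8.0,
    })
    perturbation_pain_shift: float = 4.0
    perturbation_load_reduction: float = 0.75

    season_start: _dt.date = _dt.date(2021, 9, 6)   # a Monday; later seasons offset by 52 weeks

    def resolved_phase_weeks(self) -> tuple:
        if self.phase_weeks is not None:
            pw = tuple(int(x) for x in self.phase_weeks)
            if len(pw) != 3 or any(x < 1 for x in pw) or sum(pw) != self.n_weeks:
                raise ConfigurationError(
                    f"phase_weeks {pw} must be three positive counts tiling "
                    f"{self.n_weeks} weeks")
            return pw
        off = max(1, round(self.n_weeks * 4 / 28))
        pre = max(1, round(self.n_weeks * 8 / 28))
        reg = self.n_weeks - off - pre
        if reg < 1:
            raise ConfigurationError(
                f"cannot tile {self.n_weeks} weeks into offseason/preseason/regular phases")
        return (off, pre, reg)

    def validate(self) -> None:
        if self.n_athletes < 2:
            raise ConfigurationError("n_athletes must be >= 2")
        if self.n_weeks < 6:
            raise ConfigurationError(
                "n_weeks must be >= 6 (a >= 5-week preseason baseline window "
                "plus at least one monitored week)")
        off, _pre, _reg = self.resolved_phase_weeks()
        if off + self.baseline_weeks > self.n_weeks:
            raise ConfigurationError(
                f"a {self.baseline_weeks}-week baseline window starting "
                f"after the {off}-week offseason does not fit into "
                f"{self.n_weeks} weeks")


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def season_labels(n_seasons: int) -> list:
    return [f"S{i + 1}" for i in range(n_seasons)]


def generate_cohort(n_athletes: int, n_weeks: int, seed,
                    config: Optional[SyntheticConfig] = None):
    """Generate athlete profiles, per-season schedules and planted
    perturbation events.  Deterministic given ``seed``."""
    config = replace(config or SyntheticConfig(),
                     n_athletes=n_athletes, n_weeks=n_weeks)
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    profiles = []
    for i in range(n_athletes):
        depth = float(_truncnorm(rng, config.depth_mean, config.depth_sd,
                                 *config.depth_range))
        ttt = float(np.clip(
            config.ttt_intercept + config.ttt_per_depth * abs(depth)
            + rng.normal(0.0, config.ttt_resid_sd), *config.ttt_range))
        profiles.append(AthleteProfile(
            athlete_id=f"ath{i + 1:02d}",
            body_mass=float(_truncnorm(rng, config.body_mass_mean,
                                       config.body_mass_sd, 50.0, 110.0)),
            baseline_jump={
                "jump_height": float(_truncnorm(
                    rng, config.jump_height_mean, config.jump_height_sd,
                    *config.jump_height_range)),
                "countermovement_depth": depth,
                "time_to_takeoff": ttt,
            },
            baseline_asym={ch: float(rng.normal(0.0, config.asym_sd[ch]))
                           for ch in ASYM_CHANNELS},
            oncourt_rates={
                "steps_per_session": float(_truncnorm(
                    rng, config.steps_mean, config.steps_athlete_sd,
                    *config.steps_range)),
                "lognorm_mu": float(rng.normal(config.lognorm_mu,
                                               config.lognorm_mu_athlete_sd)),
                "lognorm_sigma": config.lognorm_sigma,
            },
            psych_baseline={
                s: float(np.clip(rng.normal(config.psych_mean[s],
                                            config.psych_athlete_sd[s]),
                                 *PSYCH_RANGES[s]))
                for s in PSYCH_SCALES
            },
            compliance={
                s: float(np.clip(rng.normal(config.compliance_mean[s],
                                            config.compliance_athlete_sd[s]),
                                 0.05, 1.0))
                for s in PSYCH_SCALES
            },
            biomech_presence={"p_cmj_week": config.p_cmj_week,
                              "p_oncourt_week": config.p_oncourt_week},
        ))

    off, pre, reg = config.resolved_phase_weeks()
    phase_by_week = (["offseason"] * off + ["preseason"] * pre + ["regular"] * reg)
    lo_sess, hi_sess = config.oncourt_sessions_range
    schedules = []
    for s, label in enumerate(season_labels(config.n_seasons)):
        start = config.season_start + _dt.timedelta(weeks=52 * s)
        weeks = tuple(
            WeekPlan(week_index=w + 1, phase=phase_by_week[w],
                     monday=start + _dt.timedelta(weeks=w),
                     n_oncourt_sessions=int(rng.integers(lo_sess, hi_sess + 1)))
            for w in range(n_weeks))
        schedules.append(SeasonSchedule(label, start, weeks))

    perturbations = []
    if config.perturbations_enabled and config.n_perturbations > 0:
        target_season = season_labels(config.n_seasons)[-1]
        first_regular = off + pre + 1
        chosen = rng.choice(n_athletes, size=min(config.n_perturbations,
                                                 n_athletes), replace=False)
        for idx in np.sort(chosen):
            latest_onset = max(first_regular,
                               n_weeks - config.perturbation_duration + 1)
            onset = int(rng.integers(first_regular, latest_onset + 1))
            perturbations.append(PerturbationEvent(
                athlete_id=profiles[idx].athlete_id,
                season=target_season,
                onset_week=onset,
                duration_weeks=config.perturbation_duration,
                asym_shift=dict(config.perturbation_asym_shift),
                pain_shift=config.perturbation_pain_shift,
                load_reduction=config.perturbation_load_reduction,
            ))
    return {"profiles": profiles, "schedules": schedules,
            "perturbations": perturbations, "config": config}


# ---------------------------------------------------------------------------
# CMJ trace synthesis
# ---------------------------------------------------------------------------

def _pulse(amplitude: float, duration: float, t: np.ndarray) -> np.ndarray:
    """Half-cosine (haversine) pulse: 0 at both ends, `amplitude` at centre."""
    return amplitude / 2.0 * (1.0 - np.cos(2.0 * np.pi * t / duration))


#: Fractions of the movement time given to the unweighting and braking
#: pulses (the remainder is the propulsion pulse), and the fraction of the
#: downward velocity cancelled by the braking hump.  The residual downward
#: velocity is absorbed early in the propulsion hump, which places the
#: zero-velocity crossing (braking end) at a force well below the propulsive
#: peak -- this keeps the braking-phase and propulsive-phase interlimb-share
#: windows from interacting, and yields the bimodal force profile commonly
#: seen in real countermovement jumps.
_UNWEIGHT_FRAC = 0.35
_BRAKE_FRAC = 0.30
_CANCEL_FRAC = 0.90


def _solve_template(jump_height: float, depth: float, ttt: float,
                    sample_rate: float) -> dict:
    """Solve pulse amplitudes for the planted (JH, CMD, TTT) triple.

    The movement is a negative (unweighting) half-cosine pulse of duration T1,
    a positive braking pulse of duration T2 cancelling 90% of the downward
    velocity, and a positive propulsion pulse of duration T3 = TTT - T1 - T2.
    The unweighting amplitude A1 is found so the doubly-integrated
    displacement minimum equals the planted countermovement depth; the other
    amplitudes follow from the velocity constraints.
    """
    if ttt <= 0 or jump_height <= 0 or depth >= 0:
        raise GenerationError("need jump_height > 0, depth < 0, time_to_takeoff > 0")
    v_to = math.sqrt(2.0 * GRAVITY * jump_height)
    # one extra sample so that the onset/takeoff detection conventions (onset
    # = first deviating sample, takeoff = first airborne sample) recover the
    # planted time to takeoff to within half a sample period
    n_tot = int(round(ttt * sample_rate)) + 1
    n1 = int(round(_UNWEIGHT_FRAC * n_tot))
    n2 = int(round(_BRAKE_FRAC * n_tot))
    n3 = n_tot - n1 - n2
    if min(n1, n2, n3) < 20:
        raise GenerationError(
            f"time_to_takeoff {ttt} s too short at {sample_rate} Hz")
    T1, T2, T3 = n1 / sample_rate, n2 / sample_rate, n3 / sample_rate
    q = _CANCEL_FRAC

    def pieces(a1: float):
        v1 = -a1 * T1 / 2.0
        a2 = 2.0 * q * abs(v1) / T2
        v2 = v1 * (1.0 - q)                   # residual downward velocity
        a3 = 2.0 * (v_to - v2) / T3
        w = 2.0 * np.pi / T3

        def vel3(tau):
            return v2 + a3 / 2.0 * (tau - math.sin(w * tau) / w)

        tau_star = brentq(vel3, 1e-12, T3, xtol=1e-12)
        x1 = -a1 * T1 ** 2 / 4.0
        x2 = x1 + v1 * T2 + a2 * T2 ** 2 / 4.0
        d = (x2 + v2 * tau_star
             + a3 / 2.0 * (tau_star ** 2 / 2.0
                           + (math.cos(w * tau_star) - 1.0) / w ** 2))
        return d, a2, a3, tau_star

    lo, hi = 1e-4, 0.98 * GRAVITY
    if pieces(hi)[0] > depth:
        raise GenerationError(
            f"countermovement depth {depth} m unreachable with "
            f"time_to_takeoff {ttt} s: would require the plates to pull "
            f"(unweighting acceleration > g)")
    a1 = brentq(lambda a: pieces(a)[0] - depth, lo, hi, xtol=1e-10)
    _, a2, a3, tau_star = pieces(a1)
    return {"A1": a1, "A2": a2, "A3": a3, "T1": T1, "T2": T2, "T3": T3,
            "n1": n1, "n2": n2, "n3": n3, "tau_star": tau_star, "v_to": v_to}


def generate_cmj_trace(profile: AthleteProfile, week_params: Mapping,
                       seed, *, sample_rate: float = 1000.0,
                       force_noise_sd: float = 0.0,
                       quiet_s: float = 0.60, tail_s: float = 0.40,
                       landing_s: float = 0.30) -> ForceTrace:
    """Synthesize one bilateral CMJ trace realizing the planted parameters.

    ``week_params`` must contain ``jump_height``, ``countermovement_depth``,
    ``time_to_takeoff`` and an ``asym`` mapping with the four CMJ channels
    (``cmj_braking``, ``cmj_propulsive``, ``cmj_rfd``, ``cmj_landing``,
    signed %).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = profile.body_mass
    fs = sample_rate
    dt = 1.0 / fs
    jh = float(week_params["jump_height"])
    depth = float(week_params["countermovement_depth"])
    ttt = float(week_params["time_to_takeoff"])
    asym = week_params.get("asym", {})
    h_brk_pk = asym.get("cmj_braking", 0.0) / 200.0
    h_prop = asym.get("cmj_propulsive", 0.0) / 200.0
    h_land = asym.get("cmj_landing", 0.0) / 200.0
    rho = asym.get("cmj_rfd", 0.0)

    tpl = _solve_template(jh, depth, ttt, fs)
    A1, A2, A3 = tpl["A1"], tpl["A2"], tpl["A3"]
    T1, T2, T3 = tpl["T1"], tpl["T2"], tpl["T3"]
    n1, n2, n3 = tpl["n1"], tpl["n2"], tpl["n3"]
    v_to, tau_star = tpl["v_to"], tpl["tau_star"]

    n_quiet = int(round(quiet_s * fs))
    n_flight = int(round(2.0 * v_to / GRAVITY * fs))
    n_land = int(round(landing_s * fs))
    n_tail = int(round(tail_s * fs))
    v_td = v_to - GRAVITY * n_flight * dt          # ~ -v_to (grid-rounded)
    A_land = 2.0 * abs(v_td) / (n_land * dt)

    n_total = n_quiet + n1 + n2 + n3 + n_flight + n_land + n_tail
    a = np.zeros(n_total)
    i0 = n_quiet                      # movement onset
    i1 = i0 + n1                      # unweighting end = braking start (min velocity)
    i1b = i1 + n2                     # braking hump end (residual downward velocity)
    i2 = i1b + n3                     # takeoff
    a[i0:i1] = -_pulse(A1, T1, np.arange(n1) * dt)
    a[i1:i1b] = _pulse(A2, T2, np.arange(n2) * dt)
    a[i1b:i2] = _pulse(A3, T3, np.arange(n3) * dt)
    i_td = i2 + n_flight              # touchdown
    i_le = i_td + n_land
    tau_l = np.arange(n_land) * dt
    a[i_td:i_le] = _pulse(A_land, n_land * dt, tau_l)

    f_total = m * (GRAVITY + a)
    f_total[i2:i_td] = 0.0            # flight

    # interlimb share h(t): f_right = F * (0.5 + h/2), f_left = F * (0.5 - h/2)
    h = np.zeros(n_total)
    # braking end: locate the zero-velocity crossing with the same trapezoidal
    # integration (from the first deviating sample) that extraction uses, so
    # the share endpoints are solved at exactly the sample the extractor reads
    accel = f_total / m - GRAVITY
    seg = accel[i0 + 1:i2]
    v_disc = np.concatenate(([0.0], np.cumsum((seg[1:] + seg[:-1]) / 2.0) * dt))
    rel = np.flatnonzero(v_disc[i1 - (i0 + 1):] >= 0.0)
    i_be = i1 + int(rel[0]) if rel.size else i1b + int(round(tau_star * fs))
    i_be = min(max(i_be, i1b + 1), i2 - 2)     # crossing lies in the propulsion pulse
    n_brk = i_be - i1                          # braking-phase samples
    # total-force peak location inside the braking phase, as a fraction
    brk_force = f_total[i1:i_be + 1]
    u_pk = float(np.argmax(brk_force)) / n_brk
    f_bs = m * GRAVITY                         # a = 0 at minimum velocity
    f_be = float(f_total[i_be])
    # solve the linear share endpoints (h0, h1) so that the peak braking force
    # asymmetry and the average braking RFD asymmetry both match the plant
    coeff = np.array([[1.0 - u_pk, u_pk],
                      [-f_bs, f_be]])
    target = np.array([h_brk_pk, rho / 200.0 * (f_be - f_bs)])
    det = np.linalg.det(coeff)
    if abs(det) < 1e-9:
        raise GenerationError("degenerate braking geometry: cannot realize the "
                              "requested braking force and RFD asymmetries")
    h0, h1 = np.linalg.solve(coeff, target)
    if max(abs(h0), abs(h1)) > 0.98:
        raise GenerationError(
            "requested braking/RFD asymmetry combination requires an "
            "interlimb share outside (0, 1)")
    # extend the endpoint shares a few samples beyond the analytic boundaries
    # so +/-1-sample phase-detection error does not change the planted values
    guard = 5
    ramp = h0 + (h1 - h0) * np.arange(n_brk + 1) / n_brk
    h[i1 - guard:i1] = h0
    h[i1:i_be + 1] = ramp
    h[i_be + 1:i_be + 1 + guard] = h1
    h[i_be + 1 + guard:i2] = h_prop
    h[i_td:i_le] = h_land

    f_right = f_total * (0.5 + h / 2.0)
    f_left = f_total * (0.5 - h / 2.0)
    if force_noise_sd > 0:
        f_left = np.clip(f_left + rng.normal(0.0, force_noise_sd, n_total), 0.0, None)
        f_right = np.clip(f_right + rng.normal(0.0, force_noise_sd, n_total), 0.0, None)

    time = np.arange(n_total) * dt
    meta = {
        "planted": {
            "jump_height": jh, "countermovement_depth": depth,
            "time_to_takeoff": ttt,
            "asym": {"cmj_braking": h_brk_pk * 200.0,
                     "cmj_propulsive": h_prop * 200.0,
                     "cmj_rfd": rho, "cmj_landing": h_land * 200.0},
        },
        "onset_idx": i0, "braking_start_idx": i1, "braking_end_idx": i_be,
        "takeoff_idx": i2, "touchdown_idx": i_td, "v_takeoff": v_to,
    }
    return ForceTrace(time=time, f_left=f_left, f_right=f_right,
                      body_mass=m, sample_rate=fs, meta=meta)


# ---------------------------------------------------------------------------
# on-court impact stream synthesis
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         lo: float, hi: float, size: int) -> np.ndarray:
    """Exact inverse-CDF sampling of a lognormal truncated to [lo, hi]."""
    a = norm.cdf((math.log(lo) - mu) / sigma)
    b = norm.cdf((math.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


def generate_impact_stream(profile: AthleteProfile, session_params: Mapping,
                           seed, *, floor_g: float = 1.0, cap_g: float = 200.0,
                           foot_switch_prob: float = 0.9) -> pd.DataFrame:
    """Generate one on-court session's impact events.

    ``session_params``: ``session_id``, ``start`` (datetime), ``step_count``,
    and ``bin_asym`` mapping with signed % targets for ``low``/``med``/``high``.
    Per-foot scaling of event magnitudes realizes the planted bin-wise
    asymmetry in expectation; foot labels alternate with stochastic jitter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(session_params["step_count"])
    if n <= 0:
        raise GenerationError("step count must be positive")
    mu = profile.oncourt_rates["lognorm_mu"]
    sigma = profile.oncourt_rates["lognorm_sigma"]
    mags = _truncated_lognormal(rng, mu, sigma, floor_g, cap_g, n)

    # feet alternate with occasional repeats
    switches = rng.random(n - 1) < foot_switch_prob
    start_foot = int(rng.integers(0, 2))
    feet_idx = (start_foot + np.concatenate(([0], np.cumsum(switches)))) % 2
    feet = np.where(feet_idx == 0, "L", "R")

    bin_asym = session_params.get("bin_asym", {})
    edges = np.array([floor_g, 6.0, 21.0])
    codes = np.searchsorted(edges, mags, side="right") - 1
    h_by_bin = np.array([bin_asym.get("low", 0.0), bin_asym.get("med", 0.0),
                         bin_asym.get("high", 0.0)]) / 100.0
    sign = np.where(feet == "R", 1.0, -1.0)
    factor = 1.0 + sign * h_by_bin[codes] / 2.0
    # scale within the event's intensity bin (clip at the bin edges) so the
    # planted per-bin asymmetry is not distorted by events migrating between
    # bins; the residual clipping bias is well under a percentage point
    lo_edge = edges[codes]
    hi_edge = np.append(edges[1:], cap_g)[codes]
    mags = np.clip(mags * factor, lo_edge, np.nextafter(hi_edge, -np.inf))

    start = session_params.get("start", _dt.datetime(2022, 9, 6, 18, 0))
    gaps = rng.uniform(0.3, 1.5, size=n)
    times = [start + _dt.timedelta(seconds=float(s)) for s in np.cumsum(gaps)]
    return pd.DataFrame({
        "athlete_id": profile.athlete_id,
        "session_id": session_params["session_id"],
        "timestamp": times,
        "foot": feet,
        "magnitude_g": mags,
    })


# ---------------------------------------------------------------------------
# questionnaire synthesis
# ---------------------------------------------------------------------------

def generate_psych_week(profile: AthleteProfile, week_ctx: Mapping,
                        perturbations: Sequence[PerturbationEvent],
                        seed, *, week_sd: Optional[Mapping] = None) -> dict:
    """One week's questionnaire responses: each scale present with its
    compliance probability; pain is elevated by active perturbations and all
    scales are emitted as integers clipped to their ordinal ranges.

    Returns a dict scale -> int, with missing scales absent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    week_sd = week_sd or {s: 1.0 for s in PSYCH_SCALES}
    season = week_ctx.get("season")
    week = week_ctx.get("week")
    pain_shift = sum(p.pain_shift for p in perturbations
                     if p.athlete_id == profile.athlete_id
                     and p.active(season, week))
    out = {}
    for scale in PSYCH_SCALES:
        present = rng.random() < profile.compliance[scale]
        value = profile.psych_baseline[scale] + rng.normal(0.0, week_sd[scale])
        if scale == "pain":
            value += pain_shift
        lo, hi = PSYCH_RANGES[scale]
        if present:
            out[scale] = int(np.clip(round(value), lo, hi))
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A fully self-consistent synthetic cohort with planted ground truth."""

    config: SyntheticConfig
    profiles: list
    schedules: list
    perturbations: list
    cmj_trials: list          # records: dict with athlete_id, season, week, trial, trace
    impact_events: pd.DataFrame
    psych: pd.DataFrame       # athlete_id, season, week + scale columns (NaN = missing)
    week_truth: dict          # (athlete_id, season, week) -> planted weekly parameters


def _min_ttt(depth: float) -> float:
    """Feasibility floor: a countermovement of the given depth cannot be
    performed faster than this without the unweighting acceleration
    exceeding g (the plates cannot pull the athlete down)."""
    return math.sqrt(abs(depth) / 0.42)


def _week_targets(profile: AthleteProfile, config: SyntheticConfig,
                  season: str, week: int,
                  perturbations: Sequence[PerturbationEvent],
                  rng: np.random.Generator) -> dict:
    asym = {ch: profile.baseline_asym[ch] + rng.normal(0.0, config.asym_week_sd)
            for ch in ASYM_CHANNELS}
    load_factor = 1.0
    for p in perturbations:
        if p.athlete_id == profile.athlete_id and p.active(season, week):
            for ch, shift in p.asym_shift.items():
                asym[ch] = asym[ch] + shift
            load_factor *= p.load_reduction
    jump = {k: profile.baseline_jump[k] + rng.normal(0.0, config.jump_week_sd[k])
            for k in ("jump_height", "countermovement_depth", "time_to_takeoff")}
    jump["jump_height"] = float(np.clip(jump["jump_height"], 0.10, 0.45))
    jump["countermovement_depth"] = float(np.clip(jump["countermovement_depth"],
                                                  -0.38, -0.18))
    jump["time_to_takeoff"] = float(np.clip(
        jump["time_to_takeoff"],
        max(0.60, _min_ttt(jump["countermovement_depth"])), 1.15))
    return {"jump": jump, "asym": asym, "load_factor": load_factor}


def generate_dataset(config: Optional[SyntheticConfig] = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate the full multi-season cohort dataset (traces, impact streams,
    questionnaires) with planted ground truth.  Deterministic given ``seed``."""
    config = config or SyntheticConfig()
    cohort = generate_cohort(config.n_athletes, config.n_weeks, seed, config)
    config = cohort["config"]
    profiles = cohort["profiles"]
    schedules = cohort["schedules"]
    perturbations = cohort["perturbations"]

    off, pre, _ = config.resolved_phase_weeks()
    baseline_window = range(off + 1, off + 1 + config.baseline_weeks)
    final_season = schedules[-1].season_label

    root = np.random.SeedSequence(seed).spawn(2)[1]
    athlete_seeds = root.spawn(len(profiles))

    cmj_trials = []
    event_frames = []
    psych_rows = []
    week_truth = {}

    for profile, aseed in zip(profiles, athlete_seeds):
        arng = np.random.default_rng(aseed)
        for schedule in schedules:
            season = schedule.season_label
            for plan in schedule.weeks:
                week = plan.week_index
                targets = _week_targets(profile, config, season, week,
                                        perturbations, arng)
                in_baseline = (config.baseline_full_compliance
                               and season == final_season
                               and week in baseline_window)
                has_cmj = in_baseline or (arng.random()
                                          < profile.biomech_presence["p_cmj_week"])
                has_oncourt = in_baseline or (arng.random()
                                              < profile.biomech_presence["p_oncourt_week"])
                week_truth[(profile.athlete_id, season, week)] = {
                    **targets, "phase": plan.phase,
                    "has_cmj": has_cmj, "has_oncourt": has_oncourt,
                }

                if has_cmj:
                    for trial in range(config.trials_per_cmj_session):
                        params = {
                            k: targets["jump"][k] + arng.normal(
                                0.0, config.jump_trial_sd[k])
                            for k in config.jump_trial_sd}
                        params["countermovement_depth"] = float(np.clip(
                            params["countermovement_depth"], -0.40, -0.16))
                        params["time_to_takeoff"] = float(np.clip(
                            params["time_to_takeoff"],
                            max(0.58, _min_ttt(params["countermovement_depth"])),
                            1.18))
                        params["jump_height"] = float(np.clip(
                            params["jump_height"], 0.08, 0.48))
                        params["asym"] = {
                            ch: targets["asym"][ch]
                            + arng.normal(0.0, config.asym_trial_sd)
                            for ch in ("cmj_braking", "cmj_propulsive",
                                       "cmj_rfd", "cmj_landing")}
                        trace = generate_cmj_trace(
                            profile, params, arng,
                            sample_rate=config.sample_rate,
                            force_noise_sd=config.force_noise_sd)
                        cmj_trials.append({
                            "athlete_id": profile.athlete_id, "season": season,
                            "week": week, "trial": trial + 1,
                            "date": plan.monday, "trace": trace})

                if has_oncourt:
                    steps_base = (profile.oncourt_rates["steps_per_session"]
                                  * targets["load_factor"])
                    for s_idx in range(plan.n_oncourt_sessions):
                        steps = max(500, int(arng.normal(
                            steps_base, config.steps_session_cv * steps_base)))
                        session_id = (f"{profile.athlete_id}-{season}"
                                      f"-w{week:02d}-s{s_idx + 1}")
                        start = _dt.datetime.combine(
                            plan.monday + _dt.timedelta(days=1 + 2 * s_idx),
                            _dt.time(18, 0))
                        frame = generate_impact_stream(
                            profile,
                            {"session_id": session_id, "start": start,
                             "step_count": steps,
                             "bin_asym": {"low": targets["asym"]["oncourt_low"],
                                          "med": targets["asym"]["oncourt_med"],
                                          "high": targets["asym"]["oncourt_high"]}},
                            arng, floor_g=config.impact_floor_g,
                            cap_g=config.impact_cap_g,
                            foot_switch_prob=config.foot_switch_prob)
                        frame.insert(1, "season", season)
                        frame.insert(2, "week", week)
                        event_frames.append(frame)

                responses = generate_psych_week(
                    profile, {"season": season, "week": week},
                    perturbations, arng, week_sd=config.psych_week_sd)
                psych_rows.append({
                    "athlete_id": profile.athlete_id, "season": season,
                    "week": week,
                    **{s: responses.get(s, np.nan) for s in PSYCH_SCALES}})

    impact_events = (pd.concat(event_frames, ignore_index=True)
                     if event_frames else pd.DataFrame(
                         columns=["athlete_id", "season", "week", "session_id",
                                  "timestamp", "foot", "magnitude_g"]))
    psych = pd.DataFrame(psych_rows)
    return SyntheticDataset(config=config, profiles=profiles,
                            schedules=schedules, perturbations=perturbations,
                            cmj_trials=cmj_trials, impact_events=impact_events,
                            psych=psych, week_truth=week_truth)
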