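import numpy as np
import pytest

from courtwatch.synthetic import ASYM_CHANNELS, PSYCH_SCALES, AthleteProfile


def make_profile(body_mass=73.0, asym=None, compliance=None, **over):
    base = dict(
        athlete_id="ath01",
        body_mass=body_mass,
        baseline_jump={"jump_height": 0.24, "countermovement_depth": -0.28,
                       "time_to_takeoff": 0.84},
        baseline_asym={ch: 0.0 for ch in ASYM_CHANNELS},
        oncourt_rates={"steps_per_session": 6000.0, "lognorm_mu": 2.10,
                       "lognorm_sigma": 0.85},
        psych_baseline={"pain": 2.0, "sleep_quality": 1.0,
                        "sleep_quantity": 0.6, "feeling": 6.0,
                        "academic_workload": 5.5},
        compliance={s: 1.0 for s in PSYCH_SCALES},
        biomech_presence={"p_cmj_week": 1.0, "p_oncourt_week": 1.0},
    )
    if asym:
        base["baseline_asym"].update(asym)
    if compliance:
        base["compliance"].update(compliance)
    base.update(over)
    return AthleteProfile(**base)


@pytest.fixture
def profile():
    return make_profile()


def jump_params(jump_height=0.24, depth=-0.28, ttt=0.84, **asym):
    channels = {"cmj_braking": 0.0, "cmj_propulsive": 0.0, "cmj_rfd": 0.0,
                "cmj_landing": 0.0}
    channels.update(asym)
    return {"jump_height": jump_height, "countermovement_depth": depth,
            "time_to_takeoff": ttt, "asym": channels}
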