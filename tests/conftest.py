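import numpy as np
import pytest

from tremorkit import AlgorithmParams, SyntheticScenario, run_subject, simulate_recording


@pytest.fixture(scope="session")
def params():
    return AlgorithmParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Parameters with a negligible minimum-power floor, for constructed PSDs."""
    return AlgorithmParams(p_min_pos_cm=1e-6, p_min_rot_deg=1e-6)


def run_scenario(**kwargs):
    """Simulate one scenario and run the full two-pass pipeline on it."""
    scn = SyntheticScenario(**kwargs)
    rec, gt = simulate_recording(scn)
    report = run_subject([rec])
    return scn, rec, gt, report.recordings[0], report


@pytest.fixture(scope="session")
def rotation_run():
    """1 degree rotational tremor at 5 Hz, default noise."""
    return run_scenario(rot_amp_deg=1.0, rot_freq=5.0, seed=11)


@pytest.fixture(scope="session")
def translation_run():
    """0.5 cm translational tremor at 5 Hz, default noise."""
    return run_scenario(rot_amp_deg=0.0, pos_amp_cm=0.5, pos_freq=5.0, seed=12)
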