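import numpy as np
import pytest

from reachgrasp.kinematics import SegmentationConfig, process_dataset
from reachgrasp.synthgen import preset, simulate_experiment

#: Calibration table used across tests: per-cell (reach time ms, % time to
#: velocity peak, time to velocity peak ms) for the 60 Hz study preset.
EXP1_TABLE = {
    ("I", "AV"): (742.6, 49.4, 367.3),
    ("YOU", "AV"): (685.6, 52.2, 355.6),
    ("HE", "AV"): (744.8, 48.5, 358.6),
    ("I", "IV"): (705.1, 51.8, 360.8),
    ("YOU", "IV"): (729.8, 47.4, 345.6),
    ("HE", "IV"): (720.7, 49.3, 346.8),
}

EXP2_TABLE = {
    ("I", "AV"): (883.4, 31.6, 280.0),
    ("YOU", "AV"): (869.3, 31.7, 277.0),
    ("HE", "AV"): (868.5, 32.3, 283.0),
    ("I", "IV"): (861.2, 31.6, 272.3),
    ("YOU", "IV"): (879.8, 31.0, 276.1),
    ("HE", "IV"): (894.5, 31.2, 281.0),
}


@pytest.fixture(scope="session")
def exp1_noiseless_params():
    """Per-trial parameter table of a zero-noise 60 Hz experiment."""
    config = preset("exp1_italian", noiseless=True)
    dataset = simulate_experiment(config, seed=7)
    seg = SegmentationConfig(variant="displacement_exp1")
    return process_dataset(dataset, seg)


@pytest.fixture(scope="session")
def exp1_noiseless_dataset():
    config = preset("exp1_italian", noiseless=True)
    return simulate_experiment(config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
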