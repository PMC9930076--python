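import numpy as np
import pytest

import prokin


@pytest.fixture(scope="session")
def small_dataset():
    """Two participants, both conditions, default noise (seed-fixed)."""
    config = prokin.SyntheticConfig(n_participants=2, seed=42)
    return config, prokin.generate_kinematic_dataset(config)


@pytest.fixture(scope="session")
def noiseless_set():
    """One participant-condition-task set with every noise source off."""
    config = prokin.SyntheticConfig(
        n_participants=1, amp_noise_sd=0.0, time_warp_sd=0.0,
        additive_noise_sd=0.0, seed=7,
    )
    trials = prokin.generate_kinematic_dataset(config)
    return config, [
        t for t in trials if t.condition == "MHP" and t.task == "RCRT_up"
    ]


def make_trial(angles_by_joint=None, fs=60.0, n=240, **kwargs):
    """A hand-built trial; unspecified joints stay flat at zero."""
    angles = {j: np.zeros(n) for j in prokin.JOINTS}
    if angles_by_joint:
        for j, series in angles_by_joint.items():
            angles[j] = np.asarray(series, dtype=float)
            n = len(angles[j])
        for j in prokin.JOINTS:
            if len(angles[j]) != n:
                angles[j] = np.zeros(n)
    defaults = dict(
        participant_id="PX", condition="MHP", task="RCRT_up", trial_index=0,
        sample_rate_hz=fs, angles=angles,
    )
    defaults.update(kwargs)
    return prokin.JointAngleTrial(**defaults)
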