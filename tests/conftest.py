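import numpy as np
import pytest

from wmfc import SimulationConfig, load_registry, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group cohort small enough for fast unit tests."""
    cfg = SimulationConfig(groups=("CN", "ADD"), n_per_group=8, n_frames=120,
                           n_wm=5, n_gm=7, motion_spike_rate=0.02, seed=7)
    return simulate_cohort(cfg)


def stack_fcms(cohort, kind="WG", fd_threshold=0.5, min_frames=10):
    """Subject FCM stack + group labels for a synthetic cohort."""
    from wmfc import subject_fcms

    mats, labels = [], []
    by_id = cohort.cohort.set_index("subject_id")["group"]
    for sid in cohort.subjects:
        fcms = subject_fcms(cohort.series[sid], cohort.registry,
                           motion=cohort.motion[sid],
                           fd_threshold=fd_threshold, min_frames=min_frames,
                           kinds=(kind,))
        mats.append(fcms[kind].values)
        labels.append(by_id[sid])
    return np.stack(mats), np.array(labels)
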