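import numpy as np
import pytest

from vestgait.signal_io import TrialRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    acc=None,
    gyr=None,
    n=256,
    fs=128.0,
    participant="HS01",
    group="HS",
    task="Walk",
    sensor="SA",
    rng=None,
):
    rng = rng or np.random.default_rng(0)
    if acc is None:
        acc = rng.normal(0, 1, size=(n, 3))
    if gyr is None:
        gyr = rng.normal(0, 10, size=(len(acc), 3))
    return TrialRecording(
        participant_id=participant,
        group=group,
        task=task,
        sensor=sensor,
        acc=np.asarray(acc, dtype=float),
        gyr=np.asarray(gyr, dtype=float),
        sample_rate=fs,
    )


@pytest.fixture
def tiny_sim_config():
    """Small, fast synthetic cohort with planted effects."""
    from vestgait.synthetic_data import default_paper_scenario

    cfg = default_paper_scenario(seed=7)
    cfg.n_per_group = 6
    cfg.base_duration_s = {t: min(v, 8.0) for t, v in cfg.base_duration_s.items()}
    return cfg
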