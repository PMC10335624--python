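import numpy as np
import pytest

from psrscreen import (
    BeatParams,
    CnnConfig,
    RegimeSchedule,
    generate_recording,
    segment_recording,
)
from psrscreen.workflows import build_dataset, ramp_schedule, train_regressor


@pytest.fixture(scope="session")
def clean_ramp_recording():
    """600 s noise-free recording stepping T:R through five levels."""
    sched = ramp_schedule([0.1, 0.2, 0.3, 0.4, 0.5], step_s=120)
    rec, truth = generate_recording(
        {"primary": sched, "alternate": sched}, duration_s=600, seed=11
    )
    return rec, truth


@pytest.fixture(scope="session")
def constant_recording():
    """600 s noise-free recording with a single T:R 0.2 regime."""
    sched = RegimeSchedule.constant(BeatParams(r_amp=1.0, t_amp=0.2))
    rec, truth = generate_recording(
        {"primary": sched, "alternate": sched}, duration_s=600, seed=3
    )
    return rec, truth


@pytest.fixture(scope="session")
def mini_trained_model():
    """A small but real training run shared by the regressor unit tests.

    Four noise-free recordings for training, one held out; ~240 training
    segments spanning T:R 0.05-0.55.  Returns (model, report, train_ds,
    test_ds, cfg).
    """
    rng = np.random.default_rng(2024)
    schedules = []
    for i in range(5):
        schedules.append({
            "primary": ramp_schedule(
                rng.uniform(0.05, 0.55, 8), step_s=40,
                r_amp=[1.0, 0.8, 1.2, 0.9, 1.1][i],
                heart_rate=[60, 72, 80, 66, 75][i],
            ),
            "alternate": ramp_schedule(
                rng.uniform(0.05, 0.55, 8), step_s=40,
                r_amp=[1.1, 1.0, 0.7, 1.3, 0.95][i],
                heart_rate=[72, 60, 66, 80, 70][i],
            ),
        })
    ds = build_dataset(schedules, duration_s=320, seed=91)
    cfg = CnnConfig(seed=7, epochs=40, learning_rate=3e-3)
    model, report, train_ds, test_ds = train_regressor(ds, cfg, held_out=[4])
    return model, report, train_ds, test_ds, cfg
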