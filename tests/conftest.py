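import numpy as np
import pytest

from ethotrack.arena import single_tube_template, sleep_arena_template
from ethotrack.synth import BehaviorProgram, generate_arena_frames


@pytest.fixture(scope="session")
def sleep_template():
    return sleep_arena_template()


@pytest.fixture(scope="session")
def tube_template():
    return single_tube_template()  # 0.1 mm/px, 25 mm tube


@pytest.fixture(scope="session")
def mixed_program():
    return BehaviorProgram(
        segments=[(30.0, "walking"), (30.0, "immobile"), (30.0, "micromovement"), (30.0, "walking")]
    )


@pytest.fixture(scope="session")
def tube_video(tube_template, mixed_program):
    """120 s single-fly video at 4 FPS with modest noise, plus ground truth."""
    seq, gt = generate_arena_frames(
        tube_template, {0: mixed_program}, 120.0, fps_model=(4.0, 0.0), seed=11, noise_sd=3.0
    )
    return seq, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
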