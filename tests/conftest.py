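import numpy as np
import pytest

import cmjkit as ck


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free 19.62 cm jump: its flight time is exactly 0.400 s."""
    return ck.JumpSpec(true_height=19.62, pixel_noise_sd=0.0,
                       marker_noise_sd=0.0, force_noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_motion(clean_spec):
    return ck.simulate_motion(clean_spec)


@pytest.fixture(scope="session")
def clean_recording(clean_spec):
    return ck.simulate_recording(clean_spec)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default noise levels (1 px, 0.5 mm, 2 N), 25 cm jump."""
    return ck.simulate_recording(ck.JumpSpec(true_height=25.0, seed=7))


@pytest.fixture(scope="session")
def bilateral_cohort():
    """16 participants x 3 bilateral reps at default noise."""
    return ck.simulate_cohort(16, 3, "bilateral", seed=11)


def ballistic_apex_oracle(tf: float, n_steps: int = 20000) -> float:
    """Independent numeric oracle: velocity-Verlet integration of a point
    mass launched so that it lands after ``tf`` seconds; returns the apex
    height in cm. Verlet is exact for constant acceleration, and the apex
    time tf/2 lies on the step grid by construction."""
    g = 9.81
    if tf == 0:
        return 0.0
    dt = tf / n_steps
    v0 = g * tf / 2.0
    z, v = 0.0, v0
    apex = 0.0
    for _ in range(n_steps):
        z = z + v * dt - 0.5 * g * dt**2
        v = v - g * dt
        apex = max(apex, z)
    return apex * 100.0
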