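import numpy as np
import pytest

import capstall as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sparse_kymo():
    """Noiseless kymograph with well-separated transits and its truth.

    Low arrival rate keeps shadow separations comfortably above the
    two-pixel limit where passage counting is guaranteed exact.
    """
    spec = cs.KymoSpec(n_lines=24000, rbc_rate=1.0, noise_sd=0.0, seed=42)
    image, truth = cs.generate_kymograph(spec)
    kymo = cs.Kymograph(image=image, line_rate=spec.line_rate,
                        pixel_pitch=spec.pixel_pitch)
    return spec, kymo, truth


@pytest.fixture(scope="session")
def default_kymo():
    """Kymograph at the default acquisition settings (800 Hz, ~15 µm, noisy)."""
    spec = cs.KymoSpec(n_lines=24000, rbc_rate=10.0, noise_sd=0.05, seed=7)
    image, truth = cs.generate_kymograph(spec)
    kymo = cs.Kymograph(image=image, line_rate=spec.line_rate,
                        pixel_pitch=spec.pixel_pitch)
    return spec, kymo, truth


@pytest.fixture(scope="session")
def two_segment_angio():
    """Two crossing capillaries in a 48x48 plane, with ground-truth masks."""
    spec = cs.AngioSpec(
        volume_shape=(48, 48),
        voxel_size=2.0,
        vessel_segments=(((10.0, 10.0), (90.0, 90.0), 3.0, True),
                         ((80.0, 10.0), (10.0, 80.0), 3.0, True)),
        frames_per_timepoint=16,
        dynamic_contrast=0.5,
        noise_sd=0.05,
        seed=3,
    )
    return spec


@pytest.fixture(scope="session")
def replay_table():
    """Reconstructed trial table: 57/95 blockages vs 12/82 in the control."""
    return cs.replay_trial_table({
        "RoseBengal": {"n": 95, "BLOCKAGE": 57, "HEMORRHAGE": 9},
        "FitC": {"n": 82, "BLOCKAGE": 12, "HEMORRHAGE": 8},
    })
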