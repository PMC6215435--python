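import pytest

import zfcardio as z


@pytest.fixture(scope="session")
def heart_video():
    """Default-phenotype heart clip with moderate noise (shared, read-only)."""
    params = z.HeartSimParams(
        image_shape=(96, 96), pixel_size=2.0, duration=2.4, heart_rate=180.0, noise_sd=6.0, seed=7
    )
    video, gt = z.simulate_heart_video(params)
    return params, video, gt


@pytest.fixture(scope="session")
def clean_heart_video():
    """Noiseless heart clip: generator masks are exact oracles."""
    params = z.HeartSimParams(
        image_shape=(96, 96), pixel_size=2.0, duration=2.4, heart_rate=180.0, noise_sd=0.0, seed=1
    )
    video, gt = z.simulate_heart_video(params)
    return params, video, gt


@pytest.fixture(scope="session")
def vein_video():
    params = z.FlowSimParams(duration=1.0, velocity=500.0, seed=2)
    video, gt = z.simulate_flow_video(params)
    return params, video, gt


@pytest.fixture(scope="session")
def vessel_stack():
    params = z.VesselSimParams(
        stack_shape=(48, 240, 240), voxel_size=(0.5, 0.5, 0.5),
        ring_radius=50.0, tube_radius=5.0, include_interferer=True, seed=4,
    )
    stack, gt = z.simulate_vessel_stack(params)
    return params, stack, gt
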