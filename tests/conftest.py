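import numpy as np
import pytest

from spotjump import (
    ImagingModel,
    PopulationMix,
    SimulationConfig,
    calibrate_amplitude_for_snr,
    render_stack,
    simulate_trajectories,
)
from spotjump.simulate import minimal_frame_shape


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


@pytest.fixture(scope="session")
def imaging_snr6():
    """Imaging model with the amplitude calibrated for a measured SNR of 6."""
    return calibrate_amplitude_for_snr(ImagingModel(), 6.0, np.random.default_rng(1))


@pytest.fixture(scope="session")
def isolated_stack_snr6(imaging_snr6):
    """One isolated slowly diffusing particle rendered at SNR 6, with its ground truth."""
    from dataclasses import replace

    model = replace(imaging_snr6, frame_shape=(48, 48))
    cfg = SimulationConfig(
        mix=PopulationMix.single(0.02),
        imaging=model,
        n_particles=1,
        n_frames=20,
        initial_min_spacing_um=1.0,
        rng_seed=7,
    )
    rng = np.random.default_rng(7)
    trajs = simulate_trajectories(cfg, rng)
    stack = render_stack(trajs, model, rng=rng, n_frames=20)
    return stack, trajs, model


def make_grid_stack(imaging, n_particles, n_frames, d_coeff, spacing_um, seed, snr_noise=True):
    """Helper used across test modules: grid-seeded Brownian movie + GT."""
    from dataclasses import replace

    margin = 3.0 * np.sqrt(2.0 * d_coeff * n_frames * imaging.dt_s) if d_coeff > 0 else 0.0
    shape = minimal_frame_shape(n_particles, spacing_um, imaging.pixel_size_um, margin_um=margin)
    model = replace(imaging, frame_shape=shape)
    cfg = SimulationConfig(
        mix=PopulationMix.single(d_coeff),
        imaging=model,
        n_particles=n_particles,
        n_frames=n_frames,
        initial_min_spacing_um=spacing_um,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed)
    trajs = simulate_trajectories(cfg, rng)
    stack = render_stack(trajs, model, rng=rng if snr_noise else None, add_noise=snr_noise)
    return stack, trajs, model
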