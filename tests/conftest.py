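import dataclasses

import numpy as np
import pytest

from porelab import (
    ChannelSpec,
    DriftDiffusionSpec,
    IonTrajectory,
    TraceSpec,
    gen_channel_structure,
    gen_current_trace,
    gen_ion_trajectory,
)


@pytest.fixture(scope="session")
def cylinder_channel():
    return ChannelSpec(knots=[(0.0, 6.0), (40.0, 6.0)])


@pytest.fixture(scope="session")
def cylinder_filled(cylinder_channel):
    """Water-filled cylinder phantom (r = 6 A, L = 40 A), one static frame."""
    structure, filled = gen_channel_structure(cylinder_channel, seed=11)
    return structure, filled


@pytest.fixture(scope="session")
def hourglass_filled():
    """Hourglass phantom with waist r = 3 A at z = 20 A."""
    spec = ChannelSpec(knots=[(0.0, 8.0), (20.0, 3.0), (40.0, 8.0)])
    _, filled = gen_channel_structure(spec, seed=12)
    return filled


@pytest.fixture(scope="session")
def drift_channel():
    return ChannelSpec(knots=[(0.0, 8.0), (100.0, 8.0)], water_number_density=0.5)


@pytest.fixture(scope="session")
def drift_only_trajectory(drift_channel):
    """Deterministic (D = 0) drift phantom with closed-form current."""
    spec = DriftDiffusionSpec(
        n_ions_per_species=50, diffusion_A2_per_ps=0.0, mobility=0.001,
        field_mv_per_A=1.0, duration_ps=2000.0, frame_interval_ps=20.0, seed=3,
    )
    return spec, gen_ion_trajectory(spec, drift_channel)


@pytest.fixture(scope="session")
def clean_trace():
    """10 s two-state trace: deep (50%) events, noise 2% of I0, tau 2 ms."""
    spec = TraceSpec(
        open_current_pa=61.5, noise_sd_pa=0.02 * 61.5, event_rate_hz=20.0,
        dwell_mean_s=2e-3, blockade_depth=0.5, duration_s=10.0,
        sampling_rate_hz=100000.0, seed=4,
    )
    trace, truth = gen_current_trace(spec)
    return spec, trace, truth


def replicate_frames(traj: IonTrajectory, n: int) -> IonTrajectory:
    """Static trajectory with n identical copies of the first frame."""
    return dataclasses.replace(
        traj,
        frame_indices=np.arange(n),
        times_ps=np.arange(n, dtype=float) * traj.dt_ps,
        coords=np.repeat(traj.coords[:1], n, axis=0),
    )
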