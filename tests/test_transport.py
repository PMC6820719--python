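"""Charge-displacement currents, ion densities, Gaussian current statistics."""

import dataclasses

import numpy as np
import pytest

import porelab as pl
from porelab.errors import InputError
from porelab.synthetic import analytic_species_currents_pa


def _ion_trajectory(coords, species, charges, box, dt_ps=100.0, voltage=150.0):
    F = coords.shape[0]
    return pl.IonTrajectory(
        frame_indices=np.arange(F), times_ps=np.arange(F) * dt_ps,
        particle_ids=np.arange(1, coords.shape[1] + 1),
        species=np.asarray(species), charges=np.asarray(charges, float),
        coords=coords, box=box, voltage_mv=voltage, dt_ps=dt_ps)


def test_single_ion_crossing_gives_e_over_t():
    # one +1 ion advances L_z over T = 1 ns in 10 sub-L_z/2 steps:
    # I = e/T = 1.602e-19 C / 1e-9 s = 160.218 pA
    lz = 100.0
    F = 11
    z = np.linspace(0.0, lz, F) % lz
    coords = np.zeros((F, 1, 3))
    coords[:, 0, 2] = z
    traj = _ion_trajectory(coords, ["K"], [1.0], (50.0, 50.0, lz))
    est = pl.compute_species_currents(traj)
    expected = pl.E_PER_PS_TO_PA / 1000.0     # e per 1000 ps, in pA
    assert est.i_total_pa == pytest.approx(expected, rel=1e-12)
    assert est.i_total_pa == pytest.approx(160.2177, rel=1e-6)


def test_drift_only_matches_closed_form(drift_only_trajectory):
    spec, traj = drift_only_trajectory
    est = pl.compute_species_currents(traj)
    analytic = pl.analytic_drift_current_pa(spec, traj.box[2])
    assert abs(est.i_total_pa - analytic) / analytic < 1e-6
    i_k, i_cl = analytic_species_currents_pa(spec, traj.box[2])
    assert est.i_k_pa == pytest.approx(i_k, rel=1e-6)
    assert est.i_cl_pa == pytest.approx(i_cl, rel=1e-6)


def test_stochastic_current_within_block_errors(drift_channel):
    spec = pl.DriftDiffusionSpec(
        n_ions_per_species=50, diffusion_A2_per_ps=0.02,
        mobility=6.2415e-4, field_mv_per_A=1.0,
        duration_ps=20000.0, frame_interval_ps=20.0)
    analytic = pl.analytic_drift_current_pa(spec, 100.0)
    assert analytic == pytest.approx(100.0, rel=1e-3)
    ests = []
    for seed in range(5):
        traj = pl.gen_ion_trajectory(spec, drift_channel, seed=seed)
        ests.append(pl.compute_species_currents(traj))
    pooled = np.mean([e.i_total_pa for e in ests])
    pooled_se = np.sqrt(np.mean([(e.sd_pa / np.sqrt(e.n_blocks)) ** 2
                                 for e in ests]) / len(ests))
    assert abs(pooled - analytic) <= 3 * pooled_se


def test_field_sign_antisymmetry(drift_channel):
    kw = dict(n_ions_per_species=20, diffusion_A2_per_ps=0.0, mobility=0.002,
              duration_ps=400.0, frame_interval_ps=20.0, seed=10)
    fwd = pl.gen_ion_trajectory(
        pl.DriftDiffusionSpec(field_mv_per_A=1.0, **kw), drift_channel)
    rev = pl.gen_ion_trajectory(
        pl.DriftDiffusionSpec(field_mv_per_A=-1.0, **kw), drift_channel)
    ef, er = pl.compute_species_currents(fwd), pl.compute_species_currents(rev)
    assert ef.i_total_pa == pytest.approx(-er.i_total_pa, rel=1e-9)
    assert ef.i_k_pa == pytest.approx(-er.i_k_pa, rel=1e-9)
    assert ef.i_cl_pa == pytest.approx(-er.i_cl_pa, rel=1e-9)


def test_total_is_species_sum(drift_only_trajectory):
    _, traj = drift_only_trajectory
    est = pl.compute_species_currents(traj)
    assert est.i_total_pa == est.i_k_pa + est.i_cl_pa


def test_selectivity_ratio_values():
    def make(i_k, i_cl):
        return pl.CurrentEstimate(i_total_pa=i_k + i_cl, i_k_pa=i_k,
                                  i_cl_pa=i_cl, sd_pa=0.0, voltage_mv=150.0,
                                  n_frames=2)
    assert pl.selectivity_ratio(make(0.0, 50.0)) == 1.0
    assert pl.selectivity_ratio(make(25.0, 25.0)) == 0.5
    with pytest.raises(InputError):
        pl.selectivity_ratio(make(0.0, 0.0))


def test_selectivity_from_mobility_ratio(drift_channel):
    spec = pl.DriftDiffusionSpec(
        n_ions_per_species=20, diffusion_A2_per_ps=0.0, mobility=0.001,
        mobility_cl=0.003, field_mv_per_A=1.0, duration_ps=400.0,
        frame_interval_ps=20.0, seed=9)
    traj = pl.gen_ion_trajectory(spec, drift_channel)
    est = pl.compute_species_currents(traj)
    assert pl.selectivity_ratio(est) == pytest.approx(0.75, abs=1e-9)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

def _uniform_ion_trajectory(n, R, L, n_frames, seed=0, box_fill=False):
    rng = np.random.default_rng(seed)
    # box wide enough that a circle of radius 2R still fits (radius-doubling)
    box = (4 * R + 8.0, 4 * R + 8.0, L)
    cx = box[0] / 2
    coords = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        z = rng.random(n) * L
        if box_fill:
            x = rng.random(n) * box[0]
            y = rng.random(n) * box[1]
        else:
            r = R * np.sqrt(rng.random(n))
            a = rng.random(n) * 2 * np.pi
            x, y = cx + r * np.cos(a), cx + r * np.sin(a)
        coords[f] = np.column_stack([x, y, z])
    return _ion_trajectory(coords, ["K"] * n, [1.0] * n, box)


def _flat_profile(R, L):
    n_layers = int(L)
    return pl.RadiusProfile(z_centers=np.arange(n_layers) + 0.5,
                            radius_mean=np.full(n_layers, R),
                            radius_sd=np.zeros(n_layers), n_frames=1)


def test_uniform_density_matches_count_over_volume():
    R, L, n = 10.0, 40.0, 400
    traj = _uniform_ion_trajectory(n, R, L, n_frames=100, seed=4)
    dens = pl.density_profile(traj, "K", _flat_profile(R, L))
    expected = n / (np.pi * R ** 2 * L)
    mean = np.nanmean(dens.density_mean)
    assert mean == pytest.approx(expected, rel=0.02)


def test_density_independent_of_radius_in_uniform_system():
    # ions uniform over the whole box: count scales with volume, so the
    # density is unchanged when the profile radius doubles
    R, L, n = 5.0, 40.0, 2000
    traj = _uniform_ion_trajectory(n, R, L, n_frames=60, seed=5, box_fill=True)
    d1 = pl.density_profile(traj, "K", _flat_profile(R, L))
    d2 = pl.density_profile(traj, "K", _flat_profile(2 * R, L))
    m1, m2 = np.nanmean(d1.density_mean), np.nanmean(d2.density_mean)
    assert m1 == pytest.approx(m2, rel=0.05)


def test_density_zero_when_species_absent():
    traj = _uniform_ion_trajectory(50, 6.0, 40.0, n_frames=3, seed=6)
    dens = pl.density_profile(traj, "CL", _flat_profile(6.0, 40.0))
    assert np.nansum(dens.density_mean) == 0.0


def test_zero_radius_layer_skipped_and_flagged():
    traj = _uniform_ion_trajectory(50, 6.0, 40.0, n_frames=2, seed=7)
    prof = _flat_profile(6.0, 40.0)
    prof.radius_mean[3] = 0.0
    dens = pl.density_profile(traj, "K", prof)
    assert 3 in dens.skipped_layers
    assert np.isnan(dens.density_mean[3])


# ---------------------------------------------------------------------------
# current histograms
# ---------------------------------------------------------------------------

def test_histogram_constant_samples_degenerate():
    fit = pl.fit_current_histogram(np.full(500, 61.5))
    assert fit.mean_pa == 61.5 and fit.sd_pa == 0.0 and fit.degenerate


def test_histogram_gaussian_recovery():
    rng = np.random.default_rng(8)
    x = rng.normal(61.5, 0.7, size=100000)
    fit = pl.fit_current_histogram(x)
    assert fit.mean_pa == pytest.approx(61.5, abs=0.01)
    assert fit.sd_pa == pytest.approx(0.7, rel=0.05)
    assert not fit.poor_fit


def test_histogram_bimodal_flagged():
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(61.5, 0.7, 50000),
                        rng.normal(30.0, 0.7, 50000)])
    fit = pl.fit_current_histogram(x)
    assert fit.poor_fit
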