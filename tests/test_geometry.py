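"""Axis, slice/ring radius profile, region diameters and RMSF."""

import dataclasses

import numpy as np
import pytest

import porelab as pl
from porelab.errors import InputError, InsufficientDataError

from conftest import replicate_frames


# ---------------------------------------------------------------------------
# pore axis
# ---------------------------------------------------------------------------

def test_axis_at_cylinder_center(cylinder_filled):
    _, filled = cylinder_filled
    axis = pl.compute_pore_axis(filled)
    center = filled.box[0] / 2
    assert axis.point[0] == pytest.approx(center, abs=1e-6)
    assert axis.point[1] == pytest.approx(center, abs=1e-6)
    assert axis.point[2] == pytest.approx(0.0, abs=1e-9)   # pore bottom
    assert np.allclose(axis.direction, [0, 0, 1])


def test_axis_translation_equivariance(cylinder_filled):
    _, filled = cylinder_filled
    shifted = dataclasses.replace(filled, coords=filled.coords + [5.0, 5.0, 0.0])
    a0 = pl.compute_pore_axis(filled)
    a1 = pl.compute_pore_axis(shifted)
    assert np.allclose(a1.point - a0.point, [5.0, 5.0, 0.0], atol=1e-9)
    assert np.allclose(a1.direction, a0.direction)


def test_axis_jitter_within_standard_error():
    rng = np.random.default_rng(0)
    n = 10000
    ang = rng.random(n) * 2 * np.pi
    coords = np.column_stack([
        20 + 6 * np.cos(ang) + 0.1 * rng.standard_normal(n),
        20 + 6 * np.sin(ang) + 0.1 * rng.standard_normal(n),
        rng.random(n) * 40,
    ])
    traj = pl.IonTrajectory(
        frame_indices=np.array([0]), times_ps=np.array([0.0]),
        particle_ids=np.arange(1, n + 1), species=np.array(["PROT"] * n),
        charges=np.zeros(n), coords=coords[None], box=(40.0, 40.0, 40.0),
        voltage_mv=0.0, dt_ps=1.0)
    axis = pl.compute_pore_axis(traj)
    assert abs(axis.point[0] - 20) < 0.02 and abs(axis.point[1] - 20) < 0.02


def test_axis_requires_protein():
    traj = pl.IonTrajectory(
        frame_indices=np.array([0]), times_ps=np.array([0.0]),
        particle_ids=np.array([1]), species=np.array(["WAT"]),
        charges=np.zeros(1), coords=np.zeros((1, 1, 3)),
        box=(10.0, 10.0, 10.0), voltage_mv=0.0, dt_ps=1.0)
    with pytest.raises(InputError):
        pl.compute_pore_axis(traj)


# ---------------------------------------------------------------------------
# radius profile
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("radius", [3.0, 5.0, 8.0, 10.0])
def test_cylinder_radius_recovered_within_one_increment(radius):
    spec = pl.ChannelSpec(knots=[(0.0, radius), (40.0, radius)])
    _, filled = pl.gen_channel_structure(spec, seed=int(radius))
    profile = pl.slice_radius_profile(filled, frames=[0])
    assert np.all(np.abs(profile.radius_mean - radius) <= 0.5)


def test_radius_values_on_increment_grid(cylinder_filled):
    _, filled = cylinder_filled
    profile = pl.slice_radius_profile(filled, frames=[0])
    steps = (profile.per_frame_radii - profile.seed_radius) / profile.increment
    assert np.allclose(steps, np.round(steps))


def test_first_annulus_wall_only_keeps_seed_radius():
    # wall atoms at radial 1.25 A (inside the first ring), water far outside
    n_wall, n_wat = 24, 200
    ang = 2 * np.pi * np.arange(n_wall) / n_wall
    rng = np.random.default_rng(1)
    wall = np.column_stack([10 + 1.25 * np.cos(ang), 10 + 1.25 * np.sin(ang),
                            np.full(n_wall, 0.5)])
    aw = rng.random(n_wat) * 2 * np.pi
    rw = 5 + 3 * rng.random(n_wat)
    wat = np.column_stack([10 + rw * np.cos(aw), 10 + rw * np.sin(aw),
                           rng.random(n_wat)])
    coords = np.vstack([wall, wat])[None]
    traj = pl.IonTrajectory(
        frame_indices=np.array([0]), times_ps=np.array([0.0]),
        particle_ids=np.arange(1, n_wall + n_wat + 1),
        species=np.array(["PROT"] * n_wall + ["WAT"] * n_wat),
        charges=np.zeros(n_wall + n_wat), coords=coords,
        box=(20.0, 20.0, 1.0), voltage_mv=0.0, dt_ps=1.0)
    profile = pl.slice_radius_profile(traj, frames=[0])
    assert profile.radius_mean[0] == pytest.approx(1.0)


def test_hourglass_waist_localized(hourglass_filled):
    profile = pl.slice_radius_profile(hourglass_filled, frames=[0])
    rmin = profile.radius_mean.min()
    waist_z = profile.z_centers[profile.radius_mean == rmin].mean()
    assert abs(waist_z - 20.0) <= 2.0
    assert abs(rmin - 3.0) <= 1.0


def test_profile_rotation_invariance(cylinder_filled):
    _, filled = cylinder_filled
    center = np.array([filled.box[0] / 2, filled.box[1] / 2, 0.0])
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    rotated = dataclasses.replace(
        filled, coords=(filled.coords - center) @ rot.T + center)
    p0 = pl.slice_radius_profile(filled, frames=[0])
    p1 = pl.slice_radius_profile(rotated, frames=[0])
    assert np.array_equal(p0.radius_mean, p1.radius_mean)


def test_frame_selection_default():
    idx = pl.default_frame_selection(200)
    assert idx[0] == 50                # first 25% skipped
    assert len(idx) <= 16


# ---------------------------------------------------------------------------
# region diameters
# ---------------------------------------------------------------------------

def _manual_profile(radii, z0=72.5):
    radii = np.asarray(radii, dtype=float)
    z = z0 + np.arange(len(radii))
    return pl.RadiusProfile(z_centers=z, radius_mean=radii,
                            radius_sd=np.zeros_like(radii), n_frames=1)


def test_uniform_cylinder_diameter_everywhere(cylinder_filled):
    _, filled = cylinder_filled
    profile = pl.slice_radius_profile(filled, frames=[0])
    for z in (5.0, 20.0, 35.0):
        mean, _ = pl.diameter_at_region(profile, z)
        assert mean == pytest.approx(12.0)


def test_region_window_mean_is_arithmetic():
    profile = _manual_profile([5.0, 6.0, 7.0])
    mean, _ = pl.diameter_at_region(profile, "R220")   # landmark 73.5
    assert mean == pytest.approx(12.0)


def test_hourglass_waist_diameter(hourglass_filled):
    profile = pl.slice_radius_profile(hourglass_filled, frames=[0])
    mean, _ = pl.diameter_at_region(profile, 20.0, window=1.0)
    assert abs(mean - 6.0) <= 2.0      # 2 * waist radius within one 1 A step


def test_region_outside_profile_errors():
    profile = _manual_profile([5.0, 6.0], z0=0.5)
    with pytest.raises(InputError):
        pl.diameter_at_region(profile, "R282")


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_rmsf_zero_for_static_trajectory(cylinder_filled):
    _, filled = cylinder_filled
    static = replicate_frames(filled, 4)
    prof = pl.rmsf_profile(static)
    assert np.all(prof.rmsf_A < 1e-10)


def test_rmsf_isotropic_jitter_closed_form(cylinder_filled):
    _, filled = cylinder_filled
    rng = np.random.default_rng(2)
    n_frames, sigma = 300, 0.5
    traj = replicate_frames(filled, n_frames)
    coords = traj.coords.copy()
    coords[:, 0, :] += sigma * rng.standard_normal((n_frames, 3))
    traj = dataclasses.replace(traj, coords=coords)
    prof = pl.rmsf_profile(traj)
    expected = np.sqrt(3) * sigma
    assert prof.rmsf_A[0] == pytest.approx(expected, rel=0.15)
    assert np.all(prof.rmsf_A[1:] < 0.05)


def test_rmsf_invariant_under_rigid_translation(cylinder_filled):
    _, filled = cylinder_filled
    rng = np.random.default_rng(3)
    traj = replicate_frames(filled, 10)
    coords = traj.coords + 0.1 * rng.standard_normal(traj.coords.shape)
    base = dataclasses.replace(traj, coords=coords)
    shifts = rng.standard_normal((10, 1, 3)) * 5.0
    moved = dataclasses.replace(traj, coords=coords + shifts)
    p0 = pl.rmsf_profile(base)
    p1 = pl.rmsf_profile(moved)
    assert np.allclose(p0.rmsf_A, p1.rmsf_A, atol=1e-8)


def test_rmsf_needs_two_frames(cylinder_filled):
    _, filled = cylinder_filled
    with pytest.raises(InsufficientDataError):
        pl.rmsf_profile(filled, frames=[0])
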