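"""Pore axis, slice/ring radius profiles, region diameters and RMSF.

The local radius algorithm follows the water-occupancy convention used for
membrane channels: the pore axis is the protein centre of mass, the volume is
sliced into 1 A layers along z (with z = 0 at the pore bottom), and within
each layer the radius grows from a 1 A seed in 0.5 A rings for as long as the
added annulus holds more than 25% water relative to non-water atoms. The
profile reports mean +/- sd across the selected trajectory frames.

Named z landmarks default to the aerolysin sensing regions: R282 at ~88.5 A
and R220 at ~73.5 A in the cap, K238 at ~22.5 A and K242 at ~10.5 A in the
stem, with region diameters averaged over a 3 A window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, InsufficientDataError
from .io import IonTrajectory, PoreStructure

__all__ = [
    "PoreAxis",
    "RadiusProfile",
    "RmsfProfile",
    "DEFAULT_LANDMARKS",
    "compute_pore_axis",
    "default_frame_selection",
    "slice_radius_profile",
    "diameter_at_region",
    "rmsf_profile",
]

#: z positions (A, pore-bottom reference) of the aerolysin sensing residues.
DEFAULT_LANDMARKS = {"R282": 88.5, "R220": 73.5, "K238": 22.5, "K242": 10.5}

_WATER_LIKE = ("WAT",)
_MOBILE = ("WAT", "K", "CL")   # everything else counts as protein/wall


@dataclass
class PoreAxis:
    point: np.ndarray       # (x, y, z0): axis anchor, z0 = pore bottom
    direction: np.ndarray   # unit vector, +z


@dataclass
class RadiusProfile:
    """Per-layer local pore radius with across-frame dispersion.

    z_centers are relative to the pore bottom (lowest protein atom = 0 A).
    ``per_frame_radii`` (n_frames, n_layers) keeps the raw per-frame values,
    each on the 0.5 A increment grid starting at the 1 A seed.
    """

    z_centers: np.ndarray
    radius_mean: np.ndarray
    radius_sd: np.ndarray
    n_frames: int
    layer_thickness: float = 1.0
    increment: float = 0.5
    seed_radius: float = 1.0
    z_reference: str = "pore bottom = 0 A"
    per_frame_radii: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def diameter_mean(self) -> np.ndarray:
        return 2.0 * self.radius_mean


@dataclass
class RmsfProfile:
    residue_numbers: np.ndarray
    rmsf_A: np.ndarray
    n_frames: int


# ---------------------------------------------------------------------------
# axis
# ---------------------------------------------------------------------------

def _frame_arrays(obj, frame: int = 0):
    if isinstance(obj, PoreStructure):
        return obj.coords, obj.species
    if isinstance(obj, IonTrajectory):
        return obj.coords[frame], obj.species
    raise InputError(f"cannot extract a frame from {type(obj).__name__}")


def compute_pore_axis(obj, frame: int = 0) -> PoreAxis:
    """Axis through the protein centre of mass, along +z (membrane normal).

    The returned anchor point carries z0 = the lowest protein z, the
    pore-bottom reference used by every profile.
    """
    coords, species = _frame_arrays(obj, frame)
    protein = ~np.isin(species, _MOBILE)
    if not np.any(protein):
        raise InputError("no protein (non-water, non-ion) particles in frame")
    com = coords[protein].mean(axis=0)
    z0 = coords[protein, 2].min()
    return PoreAxis(point=np.array([com[0], com[1], z0]),
                    direction=np.array([0.0, 0.0, 1.0]))


def default_frame_selection(n_frames: int, skip_fraction: float = 0.25,
                            max_frames: int = 16) -> np.ndarray:
    """Equilibration-aware default: drop the first quarter, stride to <= 16.

    Mirrors analysing only the tail of a production run with a coarse stride
    (e.g. the last 150 ns sampled every 10 ns).
    """
    start = int(math.floor(n_frames * skip_fraction)) if n_frames >= 4 else 0
    idx = np.arange(start, n_frames)
    if len(idx) > max_frames:
        stride = int(math.ceil(len(idx) / max_frames))
        idx = idx[::stride]
    return idx


# ---------------------------------------------------------------------------
# slice/ring radius profile
# ---------------------------------------------------------------------------

def slice_radius_profile(traj: IonTrajectory, frames=None,
                         layer_thickness: float = 1.0,
                         increment: float = 0.5,
                         ratio_threshold: float = 0.25,
                         seed_radius: float = 1.0,
                         ratio_mode: str = "water_over_nonwater",
                         max_radius: float | None = None) -> RadiusProfile:
    """Iterative ring-growth radius per 1 A layer, averaged over frames.

    Within each layer the candidate radius starts at ``seed_radius`` and the
    annulus (r, r + increment] is tested: it passes when the water/non-water
    count ratio exceeds ``ratio_threshold`` (``ratio_mode="water_fraction"``
    tests water/(water+non-water) instead). An annulus with water but no
    non-water atoms passes; a fully empty annulus stops growth. A hard ceiling
    of min(Lx, Ly)/2 prevents unbounded growth outside the protein.
    """
    species = traj.species
    if not np.any(np.isin(species, _WATER_LIKE)):
        raise InputError("trajectory has no water particles")
    if np.all(np.isin(species, _MOBILE)):
        raise InputError("trajectory has no non-water (wall/protein) particles")
    if ratio_mode not in ("water_over_nonwater", "water_fraction"):
        raise InputError(f"unknown ratio_mode {ratio_mode!r}")
    if frames is None:
        frames = default_frame_selection(traj.n_frames)
    frames = np.atleast_1d(np.asarray(frames, dtype=int))
    if len(frames) == 0:
        raise InputError("empty frame selection")
    if max_radius is None:
        max_radius = min(traj.box[0], traj.box[1]) / 2.0

    water = np.isin(species, _WATER_LIKE)
    wall = ~np.isin(species, _MOBILE)
    flagged_layers = 0

    # layer grid from the first selected frame's protein extent
    coords0 = traj.coords[frames[0]]
    z0_ref = coords0[wall, 2].min()
    z_extent = coords0[wall, 2].max() - z0_ref
    n_layers = max(1, int(math.ceil(z_extent / layer_thickness)))
    per_frame = np.empty((len(frames), n_layers))

    for fi, f in enumerate(frames):
        coords = traj.coords[f]
        axis = compute_pore_axis(traj, f)
        cx, cy, z0 = axis.point
        zrel = coords[:, 2] - z0
        radial = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
        layer_of = np.floor(zrel / layer_thickness).astype(int)
        for k in range(n_layers):
            in_layer = layer_of == k
            w_r = np.sort(radial[in_layer & water])
            p_r = np.sort(radial[in_layer & wall])
            r = seed_radius
            while r + increment <= max_radius:
                w = int(np.searchsorted(w_r, r + increment, side="right")
                        - np.searchsorted(w_r, r, side="right"))
                p = int(np.searchsorted(p_r, r + increment, side="right")
                        - np.searchsorted(p_r, r, side="right"))
                if w == 0 and p == 0:
                    flagged_layers += 1
                    break
                if p == 0:
                    ok = True
                elif ratio_mode == "water_over_nonwater":
                    ok = w / p > ratio_threshold
                else:
                    ok = w / (w + p) > ratio_threshold
                if not ok:
                    break
                r += increment
            per_frame[fi, k] = r

    z_centers = (np.arange(n_layers) + 0.5) * layer_thickness
    return RadiusProfile(
        z_centers=z_centers,
        radius_mean=per_frame.mean(axis=0),
        radius_sd=per_frame.std(axis=0, ddof=1) if len(frames) > 1
        else np.zeros(n_layers),
        n_frames=len(frames),
        layer_thickness=layer_thickness,
        increment=increment,
        seed_radius=seed_radius,
        per_frame_radii=per_frame,
        metadata={
            "ratio_threshold": ratio_threshold,
            "ratio_mode": ratio_mode,
            "max_radius": max_radius,
            "empty_annulus_stops": flagged_layers,
            "frames": frames.tolist(),
        },
    )


def diameter_at_region(profile: RadiusProfile, region,
                       window: float = 3.0,
                       landmarks: dict | None = None
                       ) -> tuple[float, float]:
    """Mean diameter (2r) over layers within +/- window/2 of a landmark.

    ``region`` is a landmark name (R282, R220, K238, K242) or a z value in A
    on the pore-bottom scale. Dispersion pools the per-frame diameters of the
    layers in the window when available.
    """
    landmarks = DEFAULT_LANDMARKS if landmarks is None else landmarks
    if isinstance(region, str):
        if region not in landmarks:
            raise InputError(f"unknown region {region!r}")
        z_star = landmarks[region]
    else:
        z_star = float(region)
    sel = np.abs(profile.z_centers - z_star) <= window / 2.0
    if not np.any(sel):
        raise InputError(
            f"window around z = {z_star} A contains no profile layers"
        )
    if profile.per_frame_radii is not None:
        vals = 2.0 * profile.per_frame_radii[:, sel].ravel()
    else:
        vals = 2.0 * profile.radius_mean[sel]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``reference``."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + reference.mean(axis=0)


def rmsf_profile(traj: IonTrajectory, frames=None,
                 residue_map: dict | None = None) -> RmsfProfile:
    """Per-residue RMSF after rigid superposition onto the mean structure.

    Fluctuations are computed over the protein (non-water, non-ion) particles
    only. ``residue_map`` maps particle_id -> residue number; by default each
    particle is its own residue. Two alignment passes (align to frame mean,
    recompute mean, realign) make the reference self-consistent.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.atleast_1d(np.asarray(frames, dtype=int))
    if len(frames) < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    protein = ~np.isin(traj.species, _MOBILE)
    if not np.any(protein):
        raise InputError("no protein particles for RMSF")
    X = traj.coords[frames][:, protein, :].astype(float)

    ref = X[0]
    for _ in range(2):
        aligned = np.stack([_kabsch(x, ref) for x in X])
        ref = aligned.mean(axis=0)
    disp2 = np.sum((aligned - ref) ** 2, axis=2)      # (F, N)
    msf = disp2.mean(axis=0)                          # per particle

    pids = traj.particle_ids[protein]
    if residue_map is None:
        resnums = pids
    else:
        resnums = np.array([residue_map[p] for p in pids])
    uniq = np.unique(resnums)
    rmsf = np.array([np.sqrt(msf[resnums == r].mean()) for r in uniq])
    return RmsfProfile(residue_numbers=uniq, rmsf_A=rmsf, n_frames=len(frames))
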