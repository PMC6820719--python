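"""Synthetic structures, trajectories and traces with known ground truth.

These generators are the oracles for every analysis stage:

* :func:`gen_channel_structure` builds a pseudo-atom channel wall with a
  prescribed radius profile, filled with water particles — a geometric
  phantom for the slice/ring radius algorithm;
* :func:`gen_ion_trajectory` runs 1-D drift–diffusion of K+/Cl- ions along
  the pore axis under a uniform field, for which the steady-state current
  has a closed form;
* :func:`gen_current_trace` emits a two-state (open/blocked) recording with
  Gaussian noise, Poisson event arrivals and exponential dwell times,
  together with the ground-truth event list;
* :func:`gen_voltage_series` draws dwell-time ensembles across voltages in
  translocating (exponentially decaying dwell) or non-translocating
  (constant dwell) mode, the ground truth for the translocation classifier.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import E_PER_PS_TO_PA
from .errors import InputError, StabilityError
from .events import EventTable
from .io import CurrentTrace, IonTrajectory, PoreStructure

__all__ = [
    "ChannelSpec",
    "DriftDiffusionSpec",
    "TraceSpec",
    "gen_channel_structure",
    "gen_ion_trajectory",
    "gen_current_trace",
    "gen_voltage_series",
    "analytic_drift_current_pa",
    "analytic_species_currents_pa",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Piecewise-linear channel radius profile r(z) plus filling parameters.

    ``water_number_density`` defaults to 3.0 particles/A^3 — much denser than
    the ~0.1 atoms/A^3 of real water — so that even the innermost 0.5 A
    annulus of a 1 A layer (area ~3.9 A^2) is reliably populated in a single
    frame. The phantom is a geometric oracle, not a physical water model.
    """

    knots: list[tuple[float, float]]     # (z_A, r_A), sorted by z
    length_A: float | None = None        # defaults to last knot z
    wall_atom_spacing_A: float = 2.0
    water_number_density: float = 3.0    # particles / A^3

    def __post_init__(self):
        zs = [z for z, _ in self.knots]
        rs = [r for _, r in self.knots]
        if sorted(zs) != zs:
            raise InputError("channel knots must be sorted by z")
        if min(rs) <= 0:
            raise InputError("channel radius must be positive everywhere")
        if self.length_A is None:
            self.length_A = zs[-1]

    def radius_at(self, z):
        zs = np.array([k[0] for k in self.knots])
        rs = np.array([k[1] for k in self.knots])
        return np.interp(z, zs, rs)

    @property
    def max_radius(self) -> float:
        return max(r for _, r in self.knots)


@dataclass
class DriftDiffusionSpec:
    """Parameters of the 1-D biased drift–diffusion ion phantom.

    Mobility is in A^2/(ps * mV/A): the drift velocity of an ion of charge q
    (in e) is ``v = q * mobility * field`` A/ps. The field is uniform and
    axial, in mV/A; positive field drives cations toward +z.
    """

    n_ions_per_species: int = 50
    diffusion_A2_per_ps: float = 0.02
    mobility: float = 0.05               # A^2 / (ps * mV/A), per unit charge
    mobility_cl: float | None = None     # Cl- mobility; defaults to `mobility`
    field_mv_per_A: float = 1.0
    duration_ps: float = 10000.0
    frame_interval_ps: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.duration_ps >= self.frame_interval_ps > 0:
            raise InputError("need duration >= frame_interval > 0")
        if self.diffusion_A2_per_ps < 0:
            raise InputError("diffusion coefficient must be >= 0")
        if self.mobility_cl is None:
            self.mobility_cl = self.mobility


@dataclass
class TraceSpec:
    """Parameters of the two-state (open/blocked) synthetic recording."""

    open_current_pa: float = 61.5
    noise_sd_pa: float = 1.2
    event_rate_hz: float = 10.0          # Poisson arrivals
    dwell_mean_s: float = 2e-3           # exponential dwell
    blockade_depth: float = 0.5          # fraction of open current removed
    duration_s: float = 10.0
    sampling_rate_hz: float = 100000.0
    voltage_mv: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.blockade_depth <= 1:
            raise InputError("blockade_depth must be in (0, 1]")
        if self.event_rate_hz * self.dwell_mean_s >= 0.5:
            raise InputError("events too dense: require rate * dwell_mean < 0.5")


# ---------------------------------------------------------------------------
# channel phantom
# ---------------------------------------------------------------------------

def gen_channel_structure(spec: ChannelSpec, seed: int = 0
                          ) -> tuple[PoreStructure, IonTrajectory]:
    """Build wall pseudo-atoms on the surface r(z) and fill with water.

    Returns the wall structure and a single-frame trajectory holding both
    wall (PROT) and water (WAT) particles, centred in a box of
    ``Lx = Ly = 2*max_r + 8`` A, ``Lz = length``.
    """
    rng = np.random.default_rng(seed)
    L = spec.length_A
    s = spec.wall_atom_spacing_A
    half_xy = spec.max_radius + 4.0
    box = (2 * half_xy, 2 * half_xy, L)
    cx = cy = half_xy

    # wall rings every `s` along z, atoms every ~`s` along the circumference
    wall = []
    n_rings = int(np.floor(L / s)) + 1
    for iring in range(n_rings):
        z = min(iring * s, L)
        r = float(spec.radius_at(z))
        n_atoms = max(3, int(round(2 * np.pi * r / s)))
        # deterministic stagger so consecutive rings interleave
        phase = (iring % 2) * np.pi / n_atoms
        ang = phase + 2 * np.pi * np.arange(n_atoms) / n_atoms
        for a in ang:
            wall.append((cx + r * np.cos(a), cy + r * np.sin(a), z, iring))
    wall_xyz = np.array([w[:3] for w in wall])
    ring_idx = np.array([w[3] for w in wall], dtype=int)
    n_wall = len(wall_xyz)

    structure = PoreStructure(
        atom_ids=np.arange(1, n_wall + 1),
        residue_names=np.array(["WAL"] * n_wall),
        residue_numbers=ring_idx + 1,
        chain_ids=np.array(["A"] * n_wall),
        species=np.array(["PROT"] * n_wall),
        coords=wall_xyz,
        box=box,
        metadata={"generator": "gen_channel_structure", "seed": seed},
    ).validate()

    # water filling: N ~ Poisson(density * interior volume); z sampled with
    # pdf ∝ r(z)^2 so the fill is uniform in 3-D
    z_grid = np.linspace(0.0, L, max(2, int(L / 0.1) + 1))
    r_grid = spec.radius_at(z_grid)
    volume = np.trapezoid(np.pi * r_grid ** 2, z_grid)
    n_water = int(rng.poisson(spec.water_number_density * volume))
    pdf = r_grid ** 2
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(z_grid))])
    cdf /= cdf[-1]
    zw = np.interp(rng.random(n_water), cdf, z_grid)
    rw = spec.radius_at(zw) * np.sqrt(rng.random(n_water))
    aw = rng.random(n_water) * 2 * np.pi
    water_xyz = np.column_stack([cx + rw * np.cos(aw), cy + rw * np.sin(aw), zw])

    layer_edges = np.arange(0.0, L + 1.0, 1.0)
    layer_counts, _ = np.histogram(zw, bins=layer_edges)
    meta = {
        "generator": "gen_channel_structure",
        "seed": seed,
        "interior_volume_A3": float(volume),
        "n_water": n_water,
        "empty_water_layers": int(np.sum(layer_counts == 0)),
        "low_density_warning": bool(np.any(layer_counts == 0)),
    }

    coords = np.vstack([wall_xyz, water_xyz])[None, :, :]
    species = np.array(["PROT"] * n_wall + ["WAT"] * n_water)
    charges = np.zeros(n_wall + n_water)
    traj = IonTrajectory(
        frame_indices=np.array([0]),
        times_ps=np.array([0.0]),
        particle_ids=np.arange(1, n_wall + n_water + 1),
        species=species,
        charges=charges,
        coords=coords,
        box=box,
        voltage_mv=0.0,
        dt_ps=1.0,
        metadata=meta,
    ).validate()
    return structure, traj


# ---------------------------------------------------------------------------
# drift–diffusion ions
# ---------------------------------------------------------------------------

def analytic_drift_current_pa(spec: DriftDiffusionSpec, lz_A: float) -> float:
    """Closed-form steady-state current of the drift phantom, in pA.

    Each species s contributes ``I_s = n_s * q_s * v_s * e / L_z`` with
    ``v_s = q_s * mobility_s * field``; K+ and Cl- both add positively since
    q^2 = 1 for both.
    """
    i_k, i_cl = analytic_species_currents_pa(spec, lz_A)
    return i_k + i_cl


def analytic_species_currents_pa(spec: DriftDiffusionSpec, lz_A: float
                                 ) -> tuple[float, float]:
    """Closed-form (I_K, I_Cl) of the drift phantom, in pA."""
    scale = spec.n_ions_per_species * spec.field_mv_per_A / lz_A  # q^2 = 1
    return (scale * spec.mobility * E_PER_PS_TO_PA,
            scale * spec.mobility_cl * E_PER_PS_TO_PA)


def gen_ion_trajectory(spec: DriftDiffusionSpec, channel: ChannelSpec,
                       seed: int | None = None) -> IonTrajectory:
    """Euler–Maruyama drift–diffusion of K+/Cl- ions in the channel.

    Axial motion: ``dz = q*mobility*field*dt + sqrt(2 D dt) * N(0,1)``;
    z wraps periodically over the box; lateral positions are reflected at
    the local wall radius r(z). Coordinates are stored wrapped; the current
    estimator unwraps by minimum image, which is exact while each stored-frame
    displacement stays below L_z/2 — the generator enforces that bound on the
    drift step (plus a 5-sigma diffusion margin).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_ions_per_species
    L = channel.length_A
    half_xy = channel.max_radius + 4.0
    box = (2 * half_xy, 2 * half_xy, L)
    cx = cy = half_xy

    dt = spec.frame_interval_ps
    mobilities = np.concatenate([np.full(n, spec.mobility),
                                 np.full(n, spec.mobility_cl)])
    drift_steps = mobilities * spec.field_mv_per_A * dt     # per unit charge
    sigma = np.sqrt(2 * spec.diffusion_A2_per_ps * dt)
    if np.max(np.abs(drift_steps)) + 5 * sigma > L / 2:
        raise StabilityError(
            "per-frame displacement exceeds Lz/2; shorten frame_interval"
        )

    charges = np.concatenate([np.ones(n), -np.ones(n)])
    species = np.array(["K"] * n + ["CL"] * n)
    n_frames = int(np.floor(spec.duration_ps / dt)) + 1

    z = rng.random(2 * n) * L
    rad = channel.radius_at(z) * np.sqrt(rng.random(2 * n))
    ang = rng.random(2 * n) * 2 * np.pi
    x, y = rad * np.cos(ang), rad * np.sin(ang)

    coords = np.empty((n_frames, 2 * n, 3))
    coords[0] = np.column_stack([cx + x, cy + y, z])
    for t in range(1, n_frames):
        z = z + charges * drift_steps + sigma * rng.standard_normal(2 * n)
        z %= L
        # lateral reflection at the local wall radius
        rmax = channel.radius_at(z)
        rad = np.hypot(x, y)
        over = rad > rmax
        if np.any(over):
            new_rad = np.where(over, np.maximum(2 * rmax - rad, 0.0), rad)
            scale = np.divide(new_rad, rad, out=np.ones_like(rad), where=rad > 0)
            x, y = x * scale, y * scale
        coords[t] = np.column_stack([cx + x, cy + y, z])

    return IonTrajectory(
        frame_indices=np.arange(n_frames),
        times_ps=np.arange(n_frames) * dt,
        particle_ids=np.arange(1, 2 * n + 1),
        species=species,
        charges=charges,
        coords=coords,
        box=box,
        voltage_mv=spec.field_mv_per_A * L,
        dt_ps=dt,
        metadata={
            "generator": "gen_ion_trajectory",
            "seed": spec.seed if seed is None else seed,
            "max_drift_step_A": float(np.max(np.abs(drift_steps))),
            "analytic_current_pa": analytic_drift_current_pa(spec, L),
            "min_image_safe": True,
        },
    ).validate()


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------

def gen_current_trace(spec: TraceSpec, seed: int | None = None
                      ) -> tuple[CurrentTrace, EventTable]:
    """Two-state trace with Gaussian noise and the ground-truth event list.

    Events arrive as a Poisson process; each drops the current from I0 to
    ``I0 * (1 - blockade_depth)`` for an exponentially distributed dwell.
    Overlapping events are merged (and flagged) because detection cannot
    distinguish them.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))

    starts, ends, merged = [], [], []
    if spec.event_rate_hz > 0:
        t = 0.0
        raw = []
        while True:
            t += rng.exponential(1.0 / spec.event_rate_hz)
            if t >= spec.duration_s:
                break
            raw.append((t, min(t + rng.exponential(spec.dwell_mean_s),
                               spec.duration_s)))
        for s0, e0 in raw:
            if starts and s0 < ends[-1]:
                ends[-1] = max(ends[-1], e0)
                merged[-1] = True
            else:
                starts.append(s0)
                ends.append(e0)
                merged.append(False)

    level = np.full(n, spec.open_current_pa)
    blocked = spec.open_current_pa * (1.0 - spec.blockade_depth)
    for s0, e0 in zip(starts, ends):
        i0, i1 = int(np.ceil(s0 * fs)), int(np.floor(e0 * fs))
        level[i0:max(i1, i0)] = blocked
    currents = level + spec.noise_sd_pa * rng.standard_normal(n)

    trace = CurrentTrace(
        times_s=np.arange(n) / fs,
        currents_pa=currents,
        sampling_hz=fs,
        voltage_mv=spec.voltage_mv,
        label="synthetic",
        metadata={"generator": "gen_current_trace",
                  "seed": spec.seed if seed is None else seed},
    )
    starts = np.array(starts)
    ends = np.array(ends)
    truth = EventTable.from_arrays(
        start_s=starts,
        end_s=ends,
        mean_blockade_pa=np.full(len(starts), blocked),
        i0_pa=spec.open_current_pa,
        voltage_mv=spec.voltage_mv,
        params={"ground_truth": True, "merged": merged,
                "dwell_mean_s": spec.dwell_mean_s,
                "event_rate_hz": spec.event_rate_hz},
    )
    return trace, truth


def gen_voltage_series(base_dwell_s: float, decay_constant_mv: float,
                       voltages_mv, mode: str, seed: int = 0,
                       n_events: int = 1000, rate_hz: float = 50.0
                       ) -> list[tuple[float, EventTable]]:
    """Dwell-time ensembles across voltages for the translocation classifier.

    ``translocating`` mode draws exponential dwells with mean
    ``base_dwell * exp(-|V| / decay_constant)``; ``non-translocating`` mode
    keeps the mean at ``base_dwell`` for every voltage.
    """
    voltages = list(voltages_mv)
    if len(voltages) < 3:
        raise InputError("need at least 3 voltages")
    if mode not in ("translocating", "non-translocating"):
        raise InputError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    for v in voltages:
        mean = (base_dwell_s * np.exp(-abs(v) / decay_constant_mv)
                if mode == "translocating" else base_dwell_s)
        dwells = rng.exponential(mean, size=n_events)
        gaps = rng.exponential(1.0 / rate_hz, size=n_events)
        starts = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(dwells[:-1])])
        table = EventTable.from_arrays(
            start_s=starts,
            end_s=starts + dwells,
            mean_blockade_pa=np.zeros(n_events),
            i0_pa=1.0,
            voltage_mv=float(v),
            params={"ground_truth": True, "dwell_mean_s": float(mean),
                    "mode": mode},
        )
        out.append((float(v), table))
    return out
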