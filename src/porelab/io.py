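"""Readers and writers for pore structures, ion trajectories and current traces.

Three plain-text representations are supported:

* pore structures — PDB ATOM/HETATM fixed columns, or a pseudo-atom CSV
  dialect with ``#`` metadata headers (used for synthetic channels);
* ion/water trajectories — a ``#``-headed, tab-separated dialect with columns
  ``frame time_ps particle_id species charge_e x_A y_A z_A``;
* single-channel current traces — two-column time/current TSV with
  ``# sampling_hz=`` and ``# voltage_mv=`` metadata lines.

All writers emit data values at 6 significant digits; trace timestamps are
written at 10 significant digits so the uniform-sampling invariant survives
the text round trip on long recordings. Readers validate invariants strictly
and raise (they never repair).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import SPECIES_CHARGE
from .errors import (
    HeaderError,
    MetadataError,
    OrderingError,
    ParseError,
    SamplingError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "PoreStructure",
    "IonTrajectory",
    "CurrentTrace",
    "ResultsTable",
    "read_pore_structure",
    "write_pore_structure",
    "read_trajectory",
    "write_trajectory",
    "read_trace",
    "write_trace",
]

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PoreStructure:
    """A (possibly pseudo-atom) channel structure.

    Coordinates are in angstrom, atom numbering is 1-based per PDB
    convention. z is stored untransformed; the pore-bottom z-reference is
    applied by the geometry operations, not here.
    """

    atom_ids: np.ndarray          # (N,) int
    residue_names: np.ndarray     # (N,) str
    residue_numbers: np.ndarray   # (N,) int
    chain_ids: np.ndarray         # (N,) str
    species: np.ndarray           # (N,) str — element or pseudo-atom species
    coords: np.ndarray            # (N, 3) float, angstrom
    radii: np.ndarray | None = None       # (N,) float, angstrom, optional
    box: tuple[float, float, float] | None = None
    membrane_bounds: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def validate(self) -> "PoreStructure":
        ids = np.asarray(self.atom_ids)
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate atom_id in structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in structure")
        if self.membrane_bounds is not None:
            z_lo, z_hi = self.membrane_bounds
            if not z_lo < z_hi:
                raise ValidationError("membrane_bounds must satisfy z_lo < z_hi")
            if self.box is not None and not (0.0 <= z_lo and z_hi <= self.box[2]):
                raise ValidationError("membrane_bounds outside box z-range")
        return self


@dataclass
class IonTrajectory:
    """Fixed-topology particle trajectory under an applied membrane bias.

    ``coords`` has shape (n_frames, n_particles, 3) in angstrom; particle
    order is identical in every frame (sorted by particle_id).
    """

    frame_indices: np.ndarray     # (F,) int, strictly increasing
    times_ps: np.ndarray          # (F,) float
    particle_ids: np.ndarray      # (P,) int
    species: np.ndarray           # (P,) str
    charges: np.ndarray           # (P,) float, elementary charges
    coords: np.ndarray            # (F, P, 3) float, angstrom
    box: tuple[float, float, float]
    voltage_mv: float
    dt_ps: float                  # time between stored frames
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    @property
    def n_particles(self) -> int:
        return len(self.particle_ids)

    def validate(self) -> "IonTrajectory":
        fi = np.asarray(self.frame_indices)
        if len(fi) and np.any(np.diff(fi) <= 0):
            raise OrderingError("frame_index must be strictly increasing")
        if len(np.unique(self.particle_ids)) != self.n_particles:
            raise TopologyError("duplicate particle_id")
        for sp, q in SPECIES_CHARGE.items():
            mask = self.species == sp
            if np.any(mask) and not np.allclose(self.charges[mask], q):
                raise ValidationError(
                    f"species {sp} must carry charge {q:+g} e"
                )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in trajectory")
        return self


@dataclass
class CurrentTrace:
    """Uniformly sampled single-channel current recording."""

    times_s: np.ndarray           # (N,)
    currents_pa: np.ndarray       # (N,)
    sampling_hz: float
    voltage_mv: float
    filter_hz: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.currents_pa)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_hz

    def validate(self) -> "CurrentTrace":
        if not np.all(np.isfinite(self.currents_pa)):
            raise ValidationError("non-finite current sample")
        _check_uniform_sampling(self.times_s, self.sampling_hz)
        return self


@dataclass
class ResultsTable:
    """Named numeric/string columns plus the provenance that produced them."""

    df: pd.DataFrame
    provenance: dict

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.provenance):
                fh.write(f"# {key}={self.provenance[key]}\n")
            self.df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_results_table(path) -> ResultsTable:
    provenance = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            provenance[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return ResultsTable(df=df, provenance=provenance)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _check_uniform_sampling(times: np.ndarray, sampling_hz: float,
                            rel_tol: float = 1e-6) -> None:
    """Verify Δt = 1/sampling_hz within ``rel_tol`` (1 ppm by default)."""
    if len(times) < 2:
        return
    dt_nominal = 1.0 / sampling_hz
    dts = np.diff(times)
    # Median Δt pins the clock rate; per-sample residuals from the ideal
    # grid catch dropped samples without amplifying text rounding noise.
    if abs(np.median(dts) - dt_nominal) > rel_tol * dt_nominal:
        raise SamplingError(
            f"median sample interval {np.median(dts):.9g} s deviates from "
            f"1/sampling_hz = {dt_nominal:.9g} s by more than {rel_tol:g} relative"
        )
    grid = times[0] + np.arange(len(times)) * dt_nominal
    if np.max(np.abs(times - grid)) > 0.05 * dt_nominal:
        raise SamplingError("timestamps deviate from the uniform sampling grid")


def _parse_header(lines: list[str]) -> dict:
    """Collect '# key=value' metadata lines from the top of a file."""
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# pore structures
# ---------------------------------------------------------------------------

_STRUCTURE_COLUMNS = [
    "atom_id", "residue_name", "residue_number", "chain_id",
    "species", "x_A", "y_A", "z_A",
]


def write_pore_structure(structure: PoreStructure, path) -> None:
    """Write the pseudo-atom CSV dialect (``#`` headers + named columns)."""
    structure.validate()
    df = pd.DataFrame({
        "atom_id": structure.atom_ids,
        "residue_name": structure.residue_names,
        "residue_number": structure.residue_numbers,
        "chain_id": structure.chain_ids,
        "species": structure.species,
        "x_A": structure.coords[:, 0],
        "y_A": structure.coords[:, 1],
        "z_A": structure.coords[:, 2],
    })
    if structure.radii is not None:
        df["radius_A"] = structure.radii
    with open(path, "w") as fh:
        fh.write("# porelab_structure=1\n")
        if structure.box is not None:
            fh.write("# box_A=%.6g %.6g %.6g\n" % tuple(structure.box))
        if structure.membrane_bounds is not None:
            fh.write("# membrane_z_A=%.6g %.6g\n" % tuple(structure.membrane_bounds))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_pore_structure(path) -> PoreStructure:
    """Read a structure from PDB fixed columns or the pseudo-atom CSV dialect."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(f"{path}: empty structure file")
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith(("ATOM", "HETATM", "CRYST1", "MODEL", "REMARK")):
            return _read_pdb(lines, path)
        break
    return _read_structure_csv(lines, path)


def _read_pdb(lines: list[str], path) -> PoreStructure:
    ids, resnames, resnums, chains, species, xyz = [], [], [], [], [], []
    box = None
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed CRYST1 record") from exc
        elif rec in ("ATOM", "HETATM"):
            try:
                ids.append(int(line[6:11]))
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed numeric field in {rec} record"
                ) from exc
            resnames.append(line[17:20].strip())
            chains.append(line[21].strip() or "A")
            try:
                resnums.append(int(line[22:26]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed residue number") from exc
            elem = line[76:78].strip() if len(line) >= 78 else ""
            species.append(elem or line[12:16].strip())
            xyz.append((x, y, z))
    if not ids:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return PoreStructure(
        atom_ids=np.array(ids, dtype=int),
        residue_names=np.array(resnames),
        residue_numbers=np.array(resnums, dtype=int),
        chain_ids=np.array(chains),
        species=np.array(species),
        coords=np.array(xyz, dtype=float),
        box=box,
        metadata={"source": str(path), "format": "pdb"},
    ).validate()


def _read_structure_csv(lines: list[str], path) -> PoreStructure:
    meta = _parse_header(lines)
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise ParseError(f"{path}: no data rows in structure file")
    try:
        df = pd.read_csv(_io.StringIO("".join(body)))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV body ({exc})") from exc
    missing = [c for c in _STRUCTURE_COLUMNS if c not in df.columns]
    if missing:
        raise HeaderError(f"{path}: missing structure columns {missing}")
    for col in ("x_A", "y_A", "z_A"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            # +2: 1-based plus the CSV column-name row (headers excluded).
            lineno = len(lines) - len(body) + bad + 2
            raise ParseError(f"{path}:{lineno}: non-numeric {col} field")
        df[col] = vals
    box = None
    if "box_A" in meta:
        box = tuple(float(v) for v in meta["box_A"].split())
    membrane = None
    if "membrane_z_A" in meta:
        membrane = tuple(float(v) for v in meta["membrane_z_A"].split())
    radii = df["radius_A"].to_numpy(float) if "radius_A" in df.columns else None
    return PoreStructure(
        atom_ids=df["atom_id"].to_numpy(int),
        residue_names=df["residue_name"].to_numpy(str),
        residue_numbers=df["residue_number"].to_numpy(int),
        chain_ids=df["chain_id"].to_numpy(str),
        species=df["species"].to_numpy(str),
        coords=df[["x_A", "y_A", "z_A"]].to_numpy(float),
        radii=radii,
        box=box,
        membrane_bounds=membrane,
        metadata={"source": str(path), "format": "csv"},
    ).validate()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["frame", "time_ps", "particle_id", "species",
                 "charge_e", "x_A", "y_A", "z_A"]


def write_trajectory(traj: IonTrajectory, path) -> None:
    traj.validate()
    F, P = traj.n_frames, traj.n_particles
    df = pd.DataFrame({
        "frame": np.repeat(traj.frame_indices, P),
        "time_ps": np.repeat(traj.times_ps, P),
        "particle_id": np.tile(traj.particle_ids, F),
        "species": np.tile(traj.species, F),
        "charge_e": np.tile(traj.charges, F),
        "x_A": traj.coords[:, :, 0].ravel(),
        "y_A": traj.coords[:, :, 1].ravel(),
        "z_A": traj.coords[:, :, 2].ravel(),
    })
    with open(path, "w") as fh:
        fh.write("# box_A=%.6g %.6g %.6g\n" % tuple(traj.box))
        fh.write("# voltage_mv=%.6g\n" % traj.voltage_mv)
        fh.write("# dt_ps=%.6g\n" % traj.dt_ps)
        fh.write("# columns=" + " ".join(_TRAJ_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> IonTrajectory:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    meta = _parse_header(lines)
    for key in ("box_A", "voltage_mv", "dt_ps"):
        if key not in meta:
            raise HeaderError(f"{path}: missing '# {key}=' header line")
    box = tuple(float(v) for v in meta["box_A"].split())
    if len(box) != 3:
        raise HeaderError(f"{path}: box_A must list Lx Ly Lz")
    body = "".join(ln for ln in lines if not ln.startswith("#"))
    if not body.strip():
        raise ParseError(f"{path}: trajectory has no data rows")
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t", names=_TRAJ_COLUMNS,
                         dtype={"species": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse trajectory body ({exc})") from exc

    frame_ids = df["frame"].to_numpy(int)
    uniq_frames, first_pos = np.unique(frame_ids, return_index=True)
    # file order must already be frame-major and monotone
    if np.any(np.diff(first_pos) <= 0) or np.any(np.diff(frame_ids) < 0):
        raise OrderingError(f"{path}: frame index not monotonically increasing")
    counts = np.bincount(np.searchsorted(uniq_frames, frame_ids))
    if np.any(counts != counts[0]):
        raise TopologyError(f"{path}: particle count differs between frames")
    P = int(counts[0])
    F = len(uniq_frames)

    pid = df["particle_id"].to_numpy(int).reshape(F, P)
    order = np.argsort(pid, axis=1, kind="stable")
    pid_sorted = np.take_along_axis(pid, order, axis=1)
    if np.any(pid_sorted != pid_sorted[0]):
        raise TopologyError(f"{path}: particle set differs between frames")

    def _gather(col, dtype=float):
        arr = df[col].to_numpy(dtype).reshape(F, P)
        return np.take_along_axis(arr, order, axis=1)

    coords = np.stack([_gather("x_A"), _gather("y_A"), _gather("z_A")], axis=-1)
    species = _gather("species", dtype=object)[0].astype(str)
    charges = _gather("charge_e")[0]
    times = df["time_ps"].to_numpy(float).reshape(F, P)[:, 0]
    traj = IonTrajectory(
        frame_indices=uniq_frames,
        times_ps=times,
        particle_ids=pid_sorted[0],
        species=species,
        charges=charges,
        coords=coords,
        box=box,
        voltage_mv=float(meta["voltage_mv"]),
        dt_ps=float(meta["dt_ps"]),
        metadata={"source": str(path), "n_frames": F, "n_particles": P},
    )
    return traj.validate()


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------

def write_trace(trace: CurrentTrace, path) -> None:
    trace.validate()
    with open(path, "w") as fh:
        fh.write("# sampling_hz=%.10g\n" % trace.sampling_hz)
        fh.write("# voltage_mv=%.6g\n" % trace.voltage_mv)
        if trace.filter_hz is not None:
            fh.write("# filter_hz=%.6g\n" % trace.filter_hz)
        if trace.label:
            fh.write(f"# label={trace.label}\n")
        df = pd.DataFrame({"time_s": trace.times_s, "current_pa": trace.currents_pa})
        # 10 significant digits on time keep Δt uniform to 1 ppm after rounding
        fh.write(
            df.to_csv(sep="\t", index=False, header=False,
                      float_format="%.10g", lineterminator="\n")
        )


def read_trace(path) -> CurrentTrace:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    meta = _parse_header(lines)
    if "sampling_hz" not in meta:
        raise HeaderError(f"{path}: missing '# sampling_hz=' header line")
    if "voltage_mv" not in meta:
        raise HeaderError(f"{path}: missing '# voltage_mv=' header line")
    body = "".join(ln for ln in lines if not ln.startswith("#"))
    if not body.strip():
        raise ParseError(f"{path}: trace has no samples")
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t",
                         names=["time_s", "current_pa"])
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse trace body ({exc})") from exc
    trace = CurrentTrace(
        times_s=df["time_s"].to_numpy(float),
        currents_pa=df["current_pa"].to_numpy(float),
        sampling_hz=float(meta["sampling_hz"]),
        voltage_mv=float(meta["voltage_mv"]),
        filter_hz=float(meta["filter_hz"]) if "filter_hz" in meta else None,
        label=meta.get("label", ""),
        metadata={"source": str(path), "n_samples": len(df)},
    )
    return trace.validate()
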