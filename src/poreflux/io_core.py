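"""Structure/trajectory I/O and the uniform frame model.

Every analysis in this package consumes three things only: a
:class:`Trajectory` (or single :class:`Frame`), one or more
:class:`Selection` objects, and a :class:`ChannelGeometry`.  No file-format
logic leaks past this module.

Internal units are nm and ns regardless of the source format (PDB Å are
converted on read).  Boxes are orthorhombic; triclinic input is rejected.

Standard formats (PDB, GRO, XTC, DCD, XYZ) are read and written through
MDAnalysis.  In addition a plain-text CSV trajectory dialect is defined for
desk-scale fixtures::

    # box_nm=10.0,10.0,12.0
    frame,time_ns,particle,x,y,z
    0,0.0,0,4.31,5.02,1.77
    ...

with coordinates in nm, particles 0-indexed, and the box on the first line.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyInputError,
    FormatError,
    TrajectoryError,
    UnsupportedFormatError,
    UnwrapAmbiguityError,
    UsageError,
)
from .units import NM_PER_ANGSTROM, NS_PER_PS

Role = Literal[
    "water-oxygen", "lipid-C2", "lipid-tail-carbon", "protein-backbone", "ion"
]

_STRUCTURE_FORMATS = {"pdb", "gro"}
_TRAJECTORY_FORMATS = {"xtc", "dcd", "xyz", "csv"}

#: Default time between frames when the source format carries no time
#: information (XYZ and frame-indexed CSV), ns.
DEFAULT_FRAME_DT_NS = 0.01


@dataclass(frozen=True)
class Frame:
    """One configuration: per-particle positions in an orthorhombic box.

    Parameters
    ----------
    time : float
        Frame time, ns.
    positions : (N, 3) float array
        Cartesian coordinates, nm.
    box : (3,) float array
        Orthorhombic edge lengths, nm.
    """

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise DomainError(f"positions must be (N, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise DomainError("positions contain non-finite values")
        if box.shape != (3,) or not np.all(box > 0):
            raise DomainError("box must be three positive edge lengths (nm)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered frames sharing one particle set and box.

    Stored as dense arrays: ``times`` (T,), ``positions`` (T, N, 3) in nm,
    ``box`` (3,) in nm.  The box is constant (NVT slab convention).
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise TrajectoryError(f"positions must be (T, N, 3), got {pos.shape}")
        if t.shape != (pos.shape[0],):
            raise TrajectoryError("times length must equal number of frames")
        if t.size == 0:
            raise EmptyInputError("trajectory has zero frames")
        if np.any(np.diff(t) < 0):
            raise TrajectoryError("frame times must be nondecreasing")
        if not np.all(np.isfinite(pos)):
            raise TrajectoryError("positions contain non-finite values")
        if box.shape != (3,) or not np.all(box > 0):
            raise TrajectoryError("box must be three positive edge lengths (nm)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Sampled time span, ns."""
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i], self.box)

    def __iter__(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Selection:
    """A named group of particles with an analysis role.

    Indices are 0-based and must be unique; the role gates which analyses
    accept the selection (e.g. crossing counting takes ``water-oxygen``).
    """

    name: str
    indices: np.ndarray
    role: Role

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp).ravel()
        if idx.size != np.unique(idx).size:
            raise DomainError(f"selection {self.name!r} has duplicate indices")
        if idx.size and idx.min() < 0:
            raise DomainError(f"selection {self.name!r} has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size

    def validate_against(self, n_particles: int) -> None:
        if len(self) and self.indices.max() >= n_particles:
            raise DomainError(
                f"selection {self.name!r} indexes particle "
                f"{int(self.indices.max())} but the system has {n_particles}"
            )


@dataclass(frozen=True)
class ChannelGeometry:
    """Cylindrical channel through the membrane.

    ``origin`` sits at the channel center (membrane midplane), so the axial
    coordinate s = (r - origin) . direction is 0 at the midplane.  ``z_lo``
    and ``z_hi`` are the entry/exit plane offsets along the axis, nm;
    ``radius`` is the channel radius, nm.
    """

    origin: np.ndarray
    radius: float
    z_lo: float
    z_hi: float
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if origin.shape != (3,) or direction.shape != (3,):
            raise DomainError("origin and direction must be 3-vectors")
        norm = float(np.linalg.norm(direction))
        if norm == 0:
            raise DomainError("direction must be nonzero")
        if self.radius <= 0:
            raise DomainError("channel radius must be positive")
        if not self.z_lo < self.z_hi:
            raise DomainError("z_lo must be below z_hi")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction / norm)

    def axial(self, positions: np.ndarray) -> np.ndarray:
        """Axial coordinate(s) s along the channel axis, nm."""
        return np.asarray(positions - self.origin) @ self.direction

    def radial(self, positions: np.ndarray) -> np.ndarray:
        """Radial distance(s) from the channel axis, nm."""
        rel = np.asarray(positions, dtype=float) - self.origin
        s = rel @ self.direction
        perp = rel - np.multiply.outer(s, self.direction)
        return np.linalg.norm(perp, axis=-1)


# ---------------------------------------------------------------------------
# helpers


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    if not ext:
        raise UnsupportedFormatError(f"cannot infer format of {path!r}")
    return ext


def _check_orthorhombic(dimensions: np.ndarray, where: str) -> np.ndarray:
    """Validate an MDAnalysis ``dimensions`` array; return edges in nm."""
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise FormatError(f"{where}: missing or degenerate box")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise TrajectoryError(
            f"{where}: triclinic box (angles {dims[3:]}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return dims[:3] * NM_PER_ANGSTROM


def _mda_universe(path: str, topology: str | None = None):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        if topology is None:
            return mda.Universe(path)
        return mda.Universe(topology, path)


# ---------------------------------------------------------------------------
# structures


def read_structure(path: str, format: str | None = None) -> tuple[Frame, pd.DataFrame]:
    """Read a PDB or GRO structure into a :class:`Frame` plus metadata.

    Returns
    -------
    frame : Frame
        Positions in nm (PDB Å are converted).
    metadata : DataFrame
        One row per particle: ``name``, ``resname``, ``resid``.
    """
    fmt = _infer_format(path, format)
    if fmt not in _STRUCTURE_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported structure format {fmt!r} (supported: PDB, GRO)"
        )
    try:
        u = _mda_universe(path)
    except (OSError, ValueError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"{path}: failed to parse as {fmt.upper()}: {exc}") from exc
    box = _check_orthorhombic(u.dimensions, path)
    positions = u.atoms.positions * NM_PER_ANGSTROM  # MDAnalysis is Å-native
    meta = pd.DataFrame(
        {
            "name": u.atoms.names,
            "resname": u.atoms.resnames,
            "resid": u.atoms.resids,
        }
    )
    return Frame(0.0, positions, box), meta


def write_structure(
    path: str,
    frame: Frame,
    metadata: pd.DataFrame | None = None,
    format: str | None = None,
) -> None:
    """Write a :class:`Frame` as PDB or GRO (via MDAnalysis, nm -> Å)."""
    import MDAnalysis as mda

    fmt = _infer_format(path, format)
    if fmt not in _STRUCTURE_FORMATS:
        raise UnsupportedFormatError(f"unsupported structure format {fmt!r}")
    n = frame.n_particles
    u = mda.Universe.empty(n, trajectory=True)
    if metadata is not None:
        u.add_TopologyAttr("names", list(metadata["name"]))
        u.add_TopologyAttr("resnames", [str(metadata["resname"].iloc[0])])
        u.add_TopologyAttr("resids", [int(metadata["resid"].iloc[0])])
    else:
        u.add_TopologyAttr("names", ["X"] * n)
    u.atoms.positions = frame.positions / NM_PER_ANGSTROM
    u.dimensions = np.concatenate([frame.box / NM_PER_ANGSTROM, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


# ---------------------------------------------------------------------------
# trajectories


def read_trajectory(
    path: str,
    format: str | None = None,
    topology: str | None = None,
    dt: float = DEFAULT_FRAME_DT_NS,
    box: Sequence[float] | None = None,
) -> Trajectory:
    """Read a trajectory (XTC, DCD, XYZ, or the CSV dialect) into nm/ns.

    ``topology`` (a PDB/GRO path) is required for XTC/DCD.  ``dt`` supplies
    frame times for formats that do not store them (XYZ); ``box`` (nm)
    supplies the box for XYZ files, which carry none.
    """
    fmt = _infer_format(path, format)
    if fmt not in _TRAJECTORY_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported trajectory format {fmt!r} (supported: XTC, DCD, XYZ, CSV)"
        )
    if fmt == "csv":
        return _read_csv_trajectory(path)

    if fmt in {"xtc", "dcd"} and topology is None:
        raise UsageError(f"{fmt.upper()} trajectories need topology= (a PDB/GRO path)")
    u = _mda_universe(path, topology=topology)
    times, frames_pos = [], []
    box_nm: np.ndarray | None = None
    for i, ts in enumerate(u.trajectory):
        if fmt == "xyz":
            times.append(i * dt)
            if box is None:
                raise TrajectoryError("XYZ carries no box; pass box=(lx, ly, lz) nm")
            box_nm = np.asarray(box, dtype=float)
        else:
            times.append(ts.time * NS_PER_PS)
            box_nm = _check_orthorhombic(ts.dimensions, f"{path} frame {i}")
        frames_pos.append(ts.positions * NM_PER_ANGSTROM)
    if not frames_pos:
        raise EmptyInputError(f"{path}: trajectory has zero frames")
    return Trajectory(np.asarray(times), np.stack(frames_pos), box_nm)


def _read_csv_trajectory(path: str) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# box_nm="):
        raise FormatError(
            f"{path}: line 1 must be '# box_nm=lx,ly,lz', got {header!r}"
        )
    try:
        box = np.array([float(v) for v in header.split("=", 1)[1].split(",")])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1: unparsable box: {header!r}") from exc
    df = pd.read_csv(path, skiprows=1)
    required = ["frame", "time_ns", "particle", "x", "y", "z"]
    if list(df.columns) != required:
        raise FormatError(f"{path}: line 2: columns must be {required}")
    if df.empty:
        raise EmptyInputError(f"{path}: trajectory has zero frames")
    frames = np.sort(df["frame"].unique())
    counts = df.groupby("frame").size()
    if counts.nunique() != 1:
        raise TrajectoryError(f"{path}: particle count varies across frames")
    n = int(counts.iloc[0])
    times = np.empty(frames.size)
    positions = np.empty((frames.size, n, 3))
    for k, fr in enumerate(frames):
        sub = df[df["frame"] == fr].sort_values("particle")
        if not np.array_equal(sub["particle"].to_numpy(), np.arange(n)):
            raise TrajectoryError(
                f"{path}: frame {fr}: particles must be 0..{n - 1} exactly"
            )
        times[k] = sub["time_ns"].iloc[0]
        positions[k] = sub[["x", "y", "z"]].to_numpy()
    if np.any(np.diff(times) < 0):
        raise TrajectoryError(f"{path}: frame times must be nondecreasing")
    return Trajectory(times, positions, box)


def write_trajectory(traj: Trajectory, path: str, format: str | None = None) -> None:
    """Write a trajectory as the CSV dialect or as XTC/DCD/XYZ via MDAnalysis."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv_trajectory(traj, path)
        return
    if fmt not in _TRAJECTORY_FORMATS:
        raise UnsupportedFormatError(f"unsupported trajectory format {fmt!r}")
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_particles, trajectory=True)
    u.add_TopologyAttr("names", ["X"] * traj.n_particles)
    dims = np.concatenate([traj.box / NM_PER_ANGSTROM, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, traj.n_particles) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i] / NM_PER_ANGSTROM
                u.dimensions = dims
                u.trajectory.ts.time = traj.times[i] / NS_PER_PS
                w.write(u.atoms)


def _write_csv_trajectory(traj: Trajectory, path: str) -> None:
    n = traj.n_particles
    rows = {
        "frame": np.repeat(np.arange(traj.n_frames), n),
        "time_ns": np.repeat(traj.times, n),
        "particle": np.tile(np.arange(n), traj.n_frames),
        "x": traj.positions[:, :, 0].ravel(),
        "y": traj.positions[:, :, 1].ravel(),
        "z": traj.positions[:, :, 2].ravel(),
    }
    with open(path, "w") as fh:
        fh.write("# box_nm=" + ",".join(f"{v:.6f}" for v in traj.box) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# periodic unwrapping along the channel axis


def unwrap_axis(
    traj: Trajectory, sel: Selection | None = None, axis: int = 2
) -> Trajectory:
    """Make the axial coordinate continuous across the periodic boundary.

    Applies cumulative minimum-image corrections along ``axis`` (default z)
    for the selected particles (default: all).  Non-axial coordinates are
    untouched.  A per-frame displacement at or beyond half the box edge is
    ambiguous under the minimum-image convention and raises
    :class:`UnwrapAmbiguityError`.
    """
    idx = np.arange(traj.n_particles) if sel is None else sel.indices
    if sel is not None:
        sel.validate_against(traj.n_particles)
    L = float(traj.box[axis])
    z = traj.positions[:, idx, axis]
    dz = np.diff(z, axis=0)
    shifts = np.round(dz / L)
    corrected = dz - shifts * L
    near_half = np.abs(corrected) >= 0.5 * L * (1.0 - 1e-9)
    if np.any(near_half):
        t_bad = int(np.argwhere(near_half)[0, 0]) + 1
        raise UnwrapAmbiguityError(
            f"axial displacement >= half box edge at frame {t_bad}; "
            "sampling too sparse to unwrap — use a denser output stride"
        )
    positions = traj.positions.copy()
    positions[1:, idx, axis] = z[0] + np.cumsum(corrected, axis=0)
    return Trajectory(traj.times, positions, traj.box)


def wrap_axis(traj: Trajectory, axis: int = 2) -> Trajectory:
    """Fold the axial coordinate back into [0, L): inverse of unwrapping."""
    L = float(traj.box[axis])
    positions = traj.positions.copy()
    positions[:, :, axis] = np.mod(positions[:, :, axis], L)
    return Trajectory(traj.times, positions, traj.box)
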