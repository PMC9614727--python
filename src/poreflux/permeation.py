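"""Directed water-crossing detection, sealing check, and net flux.

A crossing is a full plane-to-plane traversal of the channel: a water last
seen beyond one entry plane is next seen beyond the other, with every
intervening frame that lies axially between the planes also radially inside
the channel.  Midplane fluctuations and vestibule visits therefore do not
count, and a brief radial excursion out of the channel while between the
planes voids the event (strict sealing semantics).  Re-crossings cancel in
the net count but are retained individually, so both raw and net counts are
recoverable.

The detector consumes axis-unwrapped trajectories only; wrapped input (a
jump of more than half the box edge) is refused with a pointer to
:func:`poreflux.io_core.unwrap_axis`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, WrappedInputError
from .io_core import ChannelGeometry, Selection, Trajectory
from .units import CM_S_PER_NM_NS, V_WATER_NM3


@dataclass(frozen=True)
class CrossingEvent:
    """One completed traversal of the channel.

    ``direction`` is +1 for I -> II (axial coordinate increasing) and -1 for
    II -> I.  ``t_entry`` is the time of the first frame past the origin-side
    plane, ``t_exit`` the first frame beyond the far plane (equal for a
    single-step jump); t_exit >= t_entry always.
    """

    particle: int
    direction: int
    t_entry: float
    t_exit: float

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise DomainError("direction must be +1 or -1")
        if self.t_exit < self.t_entry:
            raise DomainError("t_exit must be >= t_entry")


@dataclass(frozen=True)
class FluxEstimate:
    """Net water flux through the channel with a block-averaged uncertainty.

    ``J_W`` is the net crossing rate in molecules/ns; ``Q`` the volumetric
    flow per channel in nm^3/ns (J_W * v_W); ``J_v`` the per-area volume
    flux in nm/ns (Q / A), also given in cm/s.  ``J_W_se`` is the
    block-averaged standard error; ``J_W_se_count`` the counting-statistics
    (Poisson) alternative sqrt(N_plus + N_minus)/duration, exact when the
    crossings form a point process.
    """

    N_plus: int
    N_minus: int
    duration: float
    J_W: float
    J_W_se: float
    J_W_se_count: float
    Q: float
    J_v: float
    J_v_cm_s: float

    @property
    def net(self) -> int:
        return self.N_plus - self.N_minus

    @property
    def raw(self) -> int:
        return self.N_plus + self.N_minus


def _axial_and_radial(
    traj: Trajectory, sel: Selection, geom: ChannelGeometry
) -> tuple[np.ndarray, np.ndarray]:
    sel.validate_against(traj.n_particles)
    pos = traj.positions[:, sel.indices, :]
    s = geom.axial(pos)
    rho = geom.radial(pos)
    return s, rho


def _refuse_wrapped(s: np.ndarray, traj: Trajectory, geom: ChannelGeometry) -> None:
    L = float(traj.box @ np.abs(geom.direction))  # box edge along the axis
    if s.shape[0] > 1 and np.abs(np.diff(s, axis=0)).max(initial=0.0) >= 0.5 * L:
        raise WrappedInputError(
            "axial jump >= half box edge: trajectory looks wrapped; "
            "run io_core.unwrap_axis first"
        )


def _scan_particle(
    z: np.ndarray,
    rho: np.ndarray,
    times: np.ndarray,
    z_lo: float,
    z_hi: float,
    radius: float,
) -> list[tuple[int, float, float]]:
    """Traversals of one particle: (direction, t_entry, t_exit) tuples.

    Works on the compressed sequence of outside-channel sightings: between
    two consecutive outside frames on opposite sides lies (at most) a run of
    inside frames, and the traversal is valid only if all of them are
    radially inside the channel.  Frames before the particle's first outside
    sighting are ignored: a particle that starts inside the channel acquires
    its origin side only at its first exit.
    """
    zone = np.zeros(z.shape, dtype=np.int8)
    zone[z < z_lo] = -1
    zone[z > z_hi] = 1
    out_idx = np.flatnonzero(zone)
    if out_idx.size < 2:
        return []
    zones_out = zone[out_idx]
    flips = np.flatnonzero(zones_out[1:] != zones_out[:-1])
    events = []
    for j in flips:
        i0, i1 = out_idx[j], out_idx[j + 1]
        if i1 - i0 > 1 and np.any(rho[i0 + 1 : i1] > radius):
            continue  # radial excursion between the planes voids the event
        events.append((int(zones_out[j + 1]), float(times[i0 + 1]), float(times[i1])))
    return events


def detect_crossings(
    traj: Trajectory, waters: Selection, geom: ChannelGeometry
) -> list[CrossingEvent]:
    """Find every completed channel traversal in an axis-unwrapped trajectory.

    Returns the events sorted by exit time.  Raises
    :class:`WrappedInputError` on wrapped input.
    """
    if waters.role != "water-oxygen":
        raise DomainError("detect_crossings expects a water-oxygen selection")
    s, rho = _axial_and_radial(traj, waters, geom)
    _refuse_wrapped(s, traj, geom)
    events: list[CrossingEvent] = []
    for k, particle in enumerate(waters.indices):
        for direction, t_in, t_out in _scan_particle(
            s[:, k], rho[:, k], traj.times, geom.z_lo, geom.z_hi, geom.radius
        ):
            events.append(CrossingEvent(int(particle), direction, t_in, t_out))
    events.sort(key=lambda e: (e.t_exit, e.particle))
    return events


def seal_check(
    traj: Trajectory,
    waters: Selection,
    geom: ChannelGeometry,
    membrane_interval: tuple[float, float] | None = None,
) -> int:
    """Count membrane traversals that happen radially OUTSIDE the channel.

    A sealed membrane returns exactly 0: every particle that passes from one
    side of the membrane slab to the other does so entirely within the
    channel radius.  ``membrane_interval`` is the slab's axial extent
    (defaults to the channel's (z_lo, z_hi)).
    """
    if len(waters) == 0:
        return 0
    z_lo, z_hi = membrane_interval if membrane_interval is not None else (
        geom.z_lo,
        geom.z_hi,
    )
    s, rho = _axial_and_radial(traj, waters, geom)
    _refuse_wrapped(s, traj, geom)
    leaks = 0
    for k in range(len(waters)):
        # all slab traversals, regardless of radius ...
        all_cross = _scan_particle(
            s[:, k], rho[:, k], traj.times, z_lo, z_hi, np.inf
        )
        # ... minus those that stayed inside the channel
        sealed = _scan_particle(
            s[:, k], rho[:, k], traj.times, z_lo, z_hi, geom.radius
        )
        leaks += len(all_cross) - len(sealed)
    return leaks


def net_flux(
    events: list[CrossingEvent],
    duration: float,
    geom: ChannelGeometry | None = None,
    v_W: float = V_WATER_NM3,
    A: float | None = None,
    n_blocks: int = 5,
    t_start: float = 0.0,
) -> FluxEstimate:
    """Net flux from an event list over a sampling window of ``duration`` ns.

    The membrane area ``A`` (nm^2) defaults to the channel cross-section
    pi r^2 when a geometry is given.  The standard error of J_W comes from
    block averaging: events are assigned to ``n_blocks`` equal time blocks
    by exit time and the block fluxes' SE of the mean is reported.
    """
    if duration <= 0:
        raise DomainError("duration must be positive")
    if n_blocks < 2:
        raise DomainError("need at least 2 blocks for a standard error")
    if A is None:
        if geom is None:
            raise DomainError("provide A or a ChannelGeometry")
        A = float(np.pi * geom.radius**2)
    dirs = np.array([e.direction for e in events], dtype=int)
    n_plus = int(np.count_nonzero(dirs == 1))
    n_minus = int(np.count_nonzero(dirs == -1))
    J_W = (n_plus - n_minus) / duration
    edges = t_start + np.linspace(0.0, duration, n_blocks + 1)
    block_net = np.zeros(n_blocks)
    if events:
        t_exit = np.array([e.t_exit for e in events])
        which = np.clip(
            np.searchsorted(edges, t_exit, side="right") - 1, 0, n_blocks - 1
        )
        np.add.at(block_net, which, dirs)
    block_J = block_net / (duration / n_blocks)
    J_W_se = float(np.std(block_J, ddof=1) / np.sqrt(n_blocks))
    Q = J_W * v_W
    J_v = Q / A
    return FluxEstimate(
        N_plus=n_plus,
        N_minus=n_minus,
        duration=float(duration),
        J_W=float(J_W),
        J_W_se=J_W_se,
        J_W_se_count=float(np.sqrt(n_plus + n_minus) / duration),
        Q=float(Q),
        J_v=float(J_v),
        J_v_cm_s=float(J_v * CM_S_PER_NM_NS),
    )
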