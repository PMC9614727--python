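"""Seeded synthetic systems and trajectories with known ground truth.

The generator emulates, at desk scale, the statistical structure of a
channel-in-membrane NEMD system so the whole analysis chain can be tested
with no MD engine:

* waters traversing a cylindrical channel with a net crossing rate linear
  in the applied pressure difference (expected net rate exactly g * ΔP,
  realized by Poisson event scheduling rather than integrated dynamics, so
  the ground truth is analytic);
* a perfectly sealed lipid--wall annulus: waters outside the channel never
  cross the membrane slab unless leak paths are explicitly planted;
* a lipid annulus whose leaflet separation h(rho) grows with radial
  distance from the central protein, starting at the biological baseline
  h_bio ~ 2.5 nm, with tail chains whose axial elongation rises with rho;
* water/ion axial density with an exclusion zone around the membrane
  (zero for |z| <= z_excl), a ramp, and bulk plateaus for |z| > z_bulk.

Every generated instance carries its ground truth (event logs, imposed
laws) so analyses can be checked event-for-event, and the same seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError
from .io_core import ChannelGeometry, Frame, Selection, Trajectory
from .permeation import CrossingEvent

__all__ = [
    "SyntheticSpec",
    "gen_channel_trajectory",
    "gen_lipid_shell",
    "gen_lipid_trajectory",
    "gen_density_system",
    "replace",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study system (one object for all three
    generators; each uses the fields it needs).

    Defaults describe the baseline study conditions: a 10x10x12 nm box, a
    0.4 nm channel through a 2.5 nm slab (entry planes at z = ±1.25 nm
    about the midplane), crossing-rate coefficient g = 0.2 events/ns/MPa,
    the five applied pressures 10-100 MPa, 10 ns runs sampled every 10 ps,
    and a sealed annulus (no leak paths).
    """

    seed: int = 0
    box: tuple[float, float, float] = (10.0, 10.0, 12.0)
    radius: float = 0.4
    z_lo: float = -1.25
    z_hi: float = 1.25
    g: float = 0.2  # events ns^-1 MPa^-1
    pressures: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0, 100.0)
    duration: float = 10.0  # ns
    stride: float = 0.01  # ns between frames
    r0: float = 0.05  # baseline bidirectional crossing rate, ns^-1
    n_bulk_waters: int = 100
    step_nm: float = 0.35  # axial step during a scripted traversal
    jitter: float = 0.05  # idle positional jitter sigma, nm
    leak_paths: int = 0
    # lipid shell
    n_lipids_per_leaflet: int = 150
    h_bio: float = 2.5
    dh: float = 1.5
    k_exp: float = 2.0
    rho_min: float = 0.5
    rho_max: float = 4.0
    lipid_jitter: float = 0.05
    n_tail_carbons: int = 8
    tail_e_min: float = 0.4
    tail_e_max: float = 1.0
    # axial density system
    z_excl: float = 1.0
    z_bulk: float = 4.0
    bulk_water_density: float = 0.5  # nm^-3 (sparse desk-scale density)
    ion_fraction: float = 0.022  # ion/water number ratio (seawater-like)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.stride <= 0:
            raise DomainError("duration and stride must be positive")
        if self.g < 0 or self.r0 < 0 or self.bulk_water_density < 0:
            raise DomainError("rates and densities must be nonnegative")
        if not self.z_lo < self.z_hi:
            raise DomainError("z_lo must be below z_hi")
        if self.radius <= 0 or min(self.box) <= 0:
            raise DomainError("radius and box edges must be positive")
        if self.rho_max > min(self.box[0], self.box[1]) / 2:
            raise DomainError("rho_max must fit inside the box cross-section")
        if self.ion_fraction < 0 or self.leak_paths < 0:
            raise DomainError("ion_fraction and leak_paths must be nonnegative")

    @property
    def geometry(self) -> ChannelGeometry:
        """Channel geometry with the origin at the box center."""
        cx, cy, cz = (e / 2 for e in self.box)
        return ChannelGeometry(
            origin=np.array([cx, cy, cz]),
            radius=self.radius,
            z_lo=self.z_lo,
            z_hi=self.z_hi,
        )

    @property
    def membrane_area(self) -> float:
        """Cross-sectional area of the box (the slab's area), nm^2."""
        return self.box[0] * self.box[1]


# ---------------------------------------------------------------------------
# channel-crossing trajectories


def _scripted_traversal(
    rng: np.random.Generator,
    times: np.ndarray,
    direction: int,
    k0: int,
    z_lo_abs: float,
    z_hi_abs: float,
    box_z: float,
    step: float,
    jitter: float,
) -> np.ndarray:
    """One particle's full axial path: idle on the origin side, one directed
    walk through the slab starting at frame ``k0``, idle on the far side."""
    T = times.size
    margin = 0.2
    if direction == 1:
        o_lo, o_hi = max(0.3, z_lo_abs - 2.0), z_lo_abs - margin
        f_lo, f_hi = z_hi_abs + margin, min(box_z - 0.3, z_hi_abs + 2.0)
        target = z_hi_abs + 0.5
    else:
        o_lo, o_hi = z_hi_abs + margin, min(box_z - 0.3, z_hi_abs + 2.0)
        f_lo, f_hi = max(0.3, z_lo_abs - 2.0), z_lo_abs - margin
        target = z_lo_abs - 0.5
    anchor = rng.uniform(o_lo + 0.2, o_hi - 0.2)
    far_anchor = rng.uniform(f_lo + 0.2, f_hi - 0.2)
    z = np.clip(anchor + rng.normal(0.0, jitter, T), o_lo, o_hi)
    dist = target - z[k0]
    m = max(4, int(math.ceil(abs(dist) / step)))
    ramp = z[k0] + np.arange(1, m + 1) * (dist / m)
    ramp += rng.normal(0.0, 0.02, m)
    ramp[-1] = target  # guarantee the far plane is passed
    z[k0 + 1 : k0 + 1 + m] = ramp
    tail = T - (k0 + 1 + m)
    z[k0 + 1 + m :] = np.clip(
        far_anchor + rng.normal(0.0, jitter, tail), f_lo, f_hi
    )
    return z


def _truth_event(
    particle: int,
    direction: int,
    z: np.ndarray,
    times: np.ndarray,
    z_lo_abs: float,
    z_hi_abs: float,
) -> CrossingEvent:
    """Generator-side bookkeeping of the one scripted traversal."""
    below = z < z_lo_abs
    above = z > z_hi_abs
    origin, far = (below, above) if direction == 1 else (above, below)
    exit_idx = int(np.argmax(far))
    origin_before = np.flatnonzero(origin[:exit_idx])
    i0 = int(origin_before[-1])
    return CrossingEvent(
        particle=particle,
        direction=direction,
        t_entry=float(times[i0 + 1]),
        t_exit=float(times[exit_idx]),
    )


def _radial_offsets(
    rng: np.random.Generator, T: int, max_r: float
) -> np.ndarray:
    """(T, 2) xy offsets confined to a disc of radius ``max_r``."""
    xy = rng.normal(0.0, max_r / 2, size=(T, 2))
    norm = np.linalg.norm(xy, axis=1)
    over = norm > max_r
    xy[over] *= (max_r / norm[over])[:, None]
    return xy


def gen_channel_trajectory(
    spec: SyntheticSpec, delta_P: float, seed: int | None = None
) -> tuple[Trajectory, Selection, dict]:
    """Synthetic permeation run at one applied pressure difference.

    Forward (I -> II) traversals are scheduled as a Poisson process at rate
    g * ΔP + r0 and backward ones at r0, so the expected net crossing rate
    is exactly g * ΔP.  Each scheduled event is executed by a dedicated
    water as a scripted biased walk through the channel; remaining waters
    jitter in the bulk reservoirs and never touch the membrane slab, except
    for ``spec.leak_paths`` planted traversals outside the channel radius.

    Returns the trajectory, the all-water selection, and a ground-truth
    dict with keys ``events``, ``leak_events``, ``delta_P``, ``net_true``.
    """
    if delta_P < 0:
        raise DomainError("delta_P must be nonnegative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    T = int(round(spec.duration / spec.stride)) + 1
    times = np.arange(T) * spec.stride
    box = np.asarray(spec.box, dtype=float)
    cx, cy, cz = box / 2
    z_lo_abs, z_hi_abs = cz + spec.z_lo, cz + spec.z_hi

    # longest scripted walk, in frames, to guarantee in-window completion
    span = (spec.z_hi - spec.z_lo) + 2.0 + 0.5
    m_max = max(4, int(math.ceil(span / spec.step_nm)))
    k_max = T - m_max - 2
    if k_max < 1:
        raise DomainError("duration too short for a scripted traversal")

    lam_f = spec.g * delta_P + spec.r0
    lam_b = spec.r0
    n_fwd = rng.poisson(lam_f * spec.duration)
    n_bwd = rng.poisson(lam_b * spec.duration)

    z_cols: list[np.ndarray] = []
    xy_cols: list[np.ndarray] = []
    events: list[CrossingEvent] = []
    leak_events: list[CrossingEvent] = []
    particle = 0

    for direction, count in ((1, n_fwd), (-1, n_bwd)):
        for _ in range(count):
            k0 = int(rng.integers(1, k_max + 1))
            z = _scripted_traversal(
                rng, times, direction, k0, z_lo_abs, z_hi_abs, box[2],
                spec.step_nm, spec.jitter,
            )
            events.append(
                _truth_event(particle, direction, z, times, z_lo_abs, z_hi_abs)
            )
            z_cols.append(z)
            xy_cols.append(
                np.array([cx, cy]) + _radial_offsets(rng, T, 0.8 * spec.radius)
            )
            particle += 1

    for _ in range(spec.leak_paths):
        k0 = int(rng.integers(1, k_max + 1))
        direction = int(rng.choice([-1, 1]))
        z = _scripted_traversal(
            rng, times, direction, k0, z_lo_abs, z_hi_abs, box[2],
            spec.step_nm, spec.jitter,
        )
        leak_events.append(
            _truth_event(particle, direction, z, times, z_lo_abs, z_hi_abs)
        )
        rho_leak = rng.uniform(3 * spec.radius, min(cx, cy) - 1.0)
        theta = rng.uniform(0, 2 * np.pi)
        center = np.array(
            [cx + rho_leak * np.cos(theta), cy + rho_leak * np.sin(theta)]
        )
        z_cols.append(z)
        xy_cols.append(center + rng.normal(0.0, spec.jitter, size=(T, 2)))
        particle += 1

    # sparse bulk waters, confined to the two reservoirs (sealed annulus)
    for _ in range(spec.n_bulk_waters):
        if rng.random() < 0.5:
            lo, hi = 0.3, z_lo_abs - 0.3
        else:
            lo, hi = z_hi_abs + 0.3, box[2] - 0.3
        anchor = rng.uniform(lo + 0.2, hi - 0.2)
        z_cols.append(np.clip(anchor + rng.normal(0.0, spec.jitter, T), lo, hi))
        xy_anchor = rng.uniform([0.5, 0.5], [box[0] - 0.5, box[1] - 0.5])
        xy_cols.append(xy_anchor + rng.normal(0.0, spec.jitter, size=(T, 2)))
        particle += 1

    n = particle
    positions = np.empty((T, n, 3))
    for j in range(n):
        positions[:, j, 0] = xy_cols[j][:, 0]
        positions[:, j, 1] = xy_cols[j][:, 1]
        positions[:, j, 2] = z_cols[j]

    traj = Trajectory(times, positions, box)
    waters = Selection("waters", np.arange(n), "water-oxygen")
    net_true = sum(e.direction for e in events)
    truth = {
        "events": sorted(events, key=lambda e: (e.t_exit, e.particle)),
        "leak_events": leak_events,
        "delta_P": float(delta_P),
        "g": spec.g,
        "net_true": int(net_true),
        "seed": spec.seed if seed is None else seed,
    }
    return traj, waters, truth


# ---------------------------------------------------------------------------
# lipid shell


def _lipid_layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Radial/angular placement of the lipids, area-uniform in the annulus."""
    n = spec.n_lipids_per_leaflet
    u = rng.uniform(spec.rho_min**2, spec.rho_max**2, size=2 * n)
    rho = np.sqrt(u)
    theta = rng.uniform(0, 2 * np.pi, size=2 * n)
    leaflet = np.repeat([1, -1], n)  # +1 upper, -1 lower
    return rho, theta, leaflet


def _thickness_law(spec: SyntheticSpec, rho: np.ndarray) -> np.ndarray:
    return spec.h_bio + spec.dh * (rho / spec.rho_max) ** spec.k_exp


def _elongation_law(spec: SyntheticSpec, rho: np.ndarray) -> np.ndarray:
    # linear trans-fraction gradient: elongation rises linearly with rho
    frac = np.clip(rho / spec.rho_max, 0.0, 1.0)
    return spec.tail_e_min + (spec.tail_e_max - spec.tail_e_min) * frac


def _lipid_positions(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    rho: np.ndarray,
    theta: np.ndarray,
    leaflet: np.ndarray,
    jitter: float,
) -> np.ndarray:
    """One frame of C2 + tail-carbon coordinates for the fixed layout."""
    box = np.asarray(spec.box)
    cx, cy, cz = box / 2
    n_lip = rho.size
    nc = spec.n_tail_carbons
    h = _thickness_law(spec, rho)
    e = _elongation_law(spec, rho)
    x0 = cx + rho * np.cos(theta)
    y0 = cy + rho * np.sin(theta)
    z_c2 = cz + leaflet * h / 2

    n_total = n_lip * (1 + 2 * nc)
    pos = np.empty((n_total, 3))
    pos[:n_lip, 0] = x0
    pos[:n_lip, 1] = y0
    pos[:n_lip, 2] = z_c2
    # tails point from the C2 toward the midplane, elongation e(rho) in z
    frac = np.arange(nc) / (nc - 1)
    for c, dx in ((0, -0.05), (1, 0.05)):  # sn-1 / sn-2, laterally offset
        base = n_lip + c * n_lip * nc
        zz = z_c2[:, None] - leaflet[:, None] * e[:, None] * frac[None, :]
        pos[base : base + n_lip * nc, 0] = np.repeat(x0 + dx, nc)
        pos[base : base + n_lip * nc, 1] = np.repeat(y0, nc)
        pos[base : base + n_lip * nc, 2] = zz.ravel()
    if jitter > 0:
        # axial disorder only: the radial layout stays fixed so the binning
        # by rho is deterministic and the imposed laws are exact per-bin
        # oracles
        pos[:, 2] += rng.normal(0.0, jitter, size=pos.shape[0])
    return pos


def _lipid_info(spec: SyntheticSpec, rho: np.ndarray, leaflet: np.ndarray) -> dict:
    n_lip = rho.size
    nc = spec.n_tail_carbons
    upper = np.flatnonzero(leaflet == 1)
    lower = np.flatnonzero(leaflet == -1)
    tails = []
    for i in range(n_lip):
        sn1 = n_lip + i * nc + np.arange(nc)
        sn2 = n_lip + n_lip * nc + i * nc + np.arange(nc)
        tails.append((i, sn1, sn2))
    return {
        "c2_upper": Selection("C2-upper", upper, "lipid-C2"),
        "c2_lower": Selection("C2-lower", lower, "lipid-C2"),
        "lipid_tails": tails,
        "rho": rho,
        "leaflet": leaflet,
        "thickness_law": lambda r: _thickness_law(spec, np.asarray(r, dtype=float)),
        "elongation_law": lambda r: _elongation_law(spec, np.asarray(r, dtype=float)),
    }


def gen_lipid_shell(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[Frame, dict]:
    """One frame of the deformed lipid annulus with ground-truth laws.

    Leaflet C2 markers sit at z = ±h(rho)/2 (plus Gaussian jitter) with
    h(rho) = h_bio + dh (rho/rho_max)^k; each lipid carries two tail chains
    whose axial elongation follows a linear trans-fraction gradient in rho.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rho, theta, leaflet = _lipid_layout(spec, rng)
    pos = _lipid_positions(spec, rng, rho, theta, leaflet, spec.lipid_jitter)
    frame = Frame(0.0, pos, np.asarray(spec.box))
    return frame, _lipid_info(spec, rho, leaflet)


def gen_lipid_trajectory(
    spec: SyntheticSpec, n_frames: int = 50, seed: int | None = None
) -> tuple[Trajectory, dict]:
    """Multi-frame variant of :func:`gen_lipid_shell`: the layout is fixed,
    the jitter is resampled per frame (static disorder -> frame-to-frame
    noise for the standard-error machinery)."""
    if n_frames < 1:
        raise DomainError("need at least one frame")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rho, theta, leaflet = _lipid_layout(spec, rng)
    frames = [
        _lipid_positions(spec, rng, rho, theta, leaflet, spec.lipid_jitter)
        for _ in range(n_frames)
    ]
    traj = Trajectory(
        np.arange(n_frames) * spec.stride, np.stack(frames), np.asarray(spec.box)
    )
    return traj, _lipid_info(spec, rho, leaflet)


# ---------------------------------------------------------------------------
# axial-density system


def density_profile_law(spec: SyntheticSpec, z_axial: np.ndarray) -> np.ndarray:
    """Imposed axial number-density law rho(z), nm^-3 (z about the midplane):
    0 inside the exclusion zone, linear ramp, bulk plateau."""
    a = np.abs(np.asarray(z_axial, dtype=float))
    out = np.zeros_like(a)
    ramp = (a > spec.z_excl) & (a <= spec.z_bulk)
    out[ramp] = (
        spec.bulk_water_density
        * (a[ramp] - spec.z_excl)
        / (spec.z_bulk - spec.z_excl)
    )
    out[a > spec.z_bulk] = spec.bulk_water_density
    return out


def gen_density_system(
    spec: SyntheticSpec, n_frames: int = 50, seed: int | None = None
) -> tuple[Trajectory, Selection, Selection, dict]:
    """Water + ion trajectory following the imposed axial density law.

    Particles are placed i.i.d. per frame by inverse-CDF sampling of the
    law (so every frame is an independent draw from the exact target
    profile); xy are uniform over the box cross-section.  Ion count is
    ``ion_fraction`` of the water count and follows the same law.

    Returns (trajectory, water selection, ion selection, truth) where truth
    carries the law and the expected bulk density.
    """
    if n_frames < 1:
        raise DomainError("need at least one frame")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    box = np.asarray(spec.box, dtype=float)
    cz = box[2] / 2
    area = spec.membrane_area

    grid = np.linspace(-cz, cz, 4001)
    pdf = density_profile_law(spec, grid)
    integral = np.trapezoid(pdf, grid)  # per-area line density, nm^-1
    if integral <= 0:
        raise DomainError("density law integrates to zero")
    n_water = int(round(integral * area))
    n_ion = int(round(spec.ion_fraction * n_water))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    # strictly increasing support for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    cdf_k, grid_k = cdf[keep], grid[keep]

    n_total = n_water + n_ion
    positions = np.empty((n_frames, n_total, 3))
    for t in range(n_frames):
        z = np.interp(rng.random(n_total), cdf_k, grid_k) + cz
        positions[t, :, 0] = rng.uniform(0, box[0], n_total)
        positions[t, :, 1] = rng.uniform(0, box[1], n_total)
        positions[t, :, 2] = z
    traj = Trajectory(np.arange(n_frames) * spec.stride, positions, box)
    waters = Selection("waters", np.arange(n_water), "water-oxygen")
    ions = Selection("ions", n_water + np.arange(n_ion), "ion")
    truth = {
        "law": lambda z: density_profile_law(spec, np.asarray(z, dtype=float)),
        "bulk_density": spec.bulk_water_density,
        "n_water_per_frame": n_water,
        "n_ion_per_frame": n_ion,
        "area": area,
    }
    return traj, waters, ions, truth
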