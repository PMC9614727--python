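"""Region-based constant-force scheme for generating a hydrostatic ΔP.

Under periodic boundary conditions a pressure difference across a membrane
can be created without pistons: the water layer is partitioned into three
z-slabs, with region III isolated from the two faces of the membrane by
regions I and II, and a constant axial force f is applied to every water
oxygen inside region III.  With n waters in region III of thickness d and
membrane area A, the scheme produces

    ΔP = n f / A = f d / v_W,      Δμ = f d,

where v_W is the average volume of one water molecule, so n = A d / v_W.
Both forms of ΔP are algebraically identical; the implementation verifies
and exposes the identity.

This module does the arithmetic and the per-frame force assignment; it does
not integrate dynamics (toy dynamics live in :mod:`poreflux.synthetic`).
Membrane position restraints used alongside the scheme in production MD are
carried as config metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .io_core import Frame, Selection
from .units import KJMOL_PER_MPA_NM3, PN_PER_KJMOL_NM, V_WATER_NM3

Interval = tuple[float, float]


@dataclass(frozen=True)
class PressureDrop:
    """A hydrostatic pressure difference and its chemical-potential twin.

    ``delta_mu = delta_P * v_W`` in consistent units; the sign of ``delta_P``
    is the sign of the applied force.
    """

    delta_P: float  # MPa
    delta_mu: float  # kJ/mol


@dataclass(frozen=True)
class PressureScheme:
    """The three-region partition and the per-molecule force.

    Regions are half-open z-intervals [z_min, z_max) in nm so the partition
    has no double counting.  ``f`` is the per-molecule axial force in
    kJ mol^-1 nm^-1; ``A`` the membrane cross-sectional area in nm^2;
    ``v_W`` the average volume of one water molecule in nm^3.
    """

    region_I: Interval
    region_II: Interval
    region_III: Interval
    f: float
    A: float
    v_W: float = V_WATER_NM3

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("region_I", self.region_I),
            ("region_II", self.region_II),
            ("region_III", self.region_III),
        ):
            if not lo < hi:
                raise DomainError(f"{name}: empty interval [{lo}, {hi})")
        if self.A <= 0 or self.v_W <= 0:
            raise DomainError("A and v_W must be positive")
        ivs = sorted([self.region_I, self.region_II, self.region_III])
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if hi1 > lo2:
                raise DomainError("regions I/II/III must be disjoint")

    @property
    def d(self) -> float:
        """Thickness of region III, nm."""
        return self.region_III[1] - self.region_III[0]

    @property
    def n(self) -> float:
        """Expected water count in region III at bulk density, n = A d / v_W."""
        return self.A * self.d / self.v_W

    def pressure_drop(self) -> PressureDrop:
        return pressure_from_force(self.f, d=self.d, v_W=self.v_W)


def force_for_pressure(delta_P_target: float, d: float, v_W: float = V_WATER_NM3) -> float:
    """Per-molecule force producing a target ΔP.

    Parameters
    ----------
    delta_P_target : float
        Target pressure difference, MPa (sign allowed).
    d : float
        Thickness of region III, nm.
    v_W : float
        Average volume of one water molecule, nm^3.

    Returns
    -------
    f : float
        Axial per-molecule force, kJ mol^-1 nm^-1, from f = ΔP v_W / d.
    """
    if d <= 0 or v_W <= 0:
        raise DomainError("d and v_W must be positive")
    return delta_P_target * v_W * KJMOL_PER_MPA_NM3 / d


def pressure_from_force(
    f: float,
    *,
    d: float | None = None,
    v_W: float = V_WATER_NM3,
    n: float | None = None,
    A: float | None = None,
) -> PressureDrop:
    """ΔP and Δμ generated by per-molecule force ``f``.

    Accepts either the (d, v_W) route (ΔP = f d / v_W) or the (n, A) route
    (ΔP = n f / A); given all four it checks the n = A d / v_W consistency.
    """
    if n is not None and A is not None:
        if A <= 0:
            raise DomainError("A must be positive")
        dp_kjmol_nm3 = n * f / A
        if d is not None:
            if not np.isclose(n, A * d / v_W, rtol=1e-12):
                raise DomainError("inconsistent inputs: n != A d / v_W")
    elif d is not None:
        if d <= 0 or v_W <= 0:
            raise DomainError("d and v_W must be positive")
        dp_kjmol_nm3 = f * d / v_W
    else:
        raise DomainError("provide either d (and v_W) or n and A")
    delta_P = dp_kjmol_nm3 / KJMOL_PER_MPA_NM3
    delta_mu = delta_P * v_W * KJMOL_PER_MPA_NM3
    return PressureDrop(delta_P=delta_P, delta_mu=delta_mu)


def force_to_pN(f_kjmol_nm: float) -> float:
    """Convert a per-molecule force from kJ mol^-1 nm^-1 to pN."""
    return f_kjmol_nm * PN_PER_KJMOL_NM


def apply_scheme(
    frame: Frame, waters: Selection, scheme: PressureScheme
) -> tuple[np.ndarray, int]:
    """Per-particle force vectors for one frame.

    Returns an (N, 3) array that is (0, 0, f) for selected waters whose z
    lies in region III (half-open membership) and zero elsewhere, together
    with the instantaneous region-III occupancy ``n_inst``.  An empty
    region III raises a warning (pressure undefined this frame), not an
    error.
    """
    if waters.role != "water-oxygen":
        raise DomainError("apply_scheme expects a water-oxygen selection")
    waters.validate_against(frame.n_particles)
    lo, hi = scheme.region_III
    if lo < 0 or hi > frame.box[2]:
        raise DomainError("region III must lie within the box")
    forces = np.zeros((frame.n_particles, 3))
    z = frame.positions[waters.indices, 2]
    inside = (z >= lo) & (z < hi)
    n_inst = int(np.count_nonzero(inside))
    if n_inst == 0:
        warnings.warn(
            "region III holds no waters this frame; instantaneous pressure undefined",
            stacklevel=2,
        )
    forces[waters.indices[inside], 2] = scheme.f
    return forces, n_inst
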