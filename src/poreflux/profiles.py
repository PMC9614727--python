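"""Structural-stability profiles: bilayer thickness, axial densities,
lipid-tail elongation, and backbone RMSD.

All profiles use cylindrical coordinates (rho, z) about the channel axis,
with the axis origin at the channel center so the membrane midplane is
z = 0.  Uncertainties are standard errors of the mean over frames after
block-decorrelation (5 blocks by default).  Empty bins are flagged with an
``occupied`` mask and NaN values, never silently zero-filled.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .io_core import ChannelGeometry, Frame, Selection, Trajectory
from .units import N_A

DEFAULT_RHO_BIN_NM = 0.25
DEFAULT_Z_BIN_NM = 0.1
H_BIO_NM = 2.5  # biological bilayer thickness reference


@contextmanager
def _nan_bins_ok():
    """Empty bins are represented as NaN on purpose; keep numpy quiet."""
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.filterwarnings("ignore", "Mean of empty slice")
        warnings.filterwarnings("ignore", "Degrees of freedom <= 0")
        yield


def _block_se(per_frame: np.ndarray, n_blocks: int) -> np.ndarray:
    """SE of the mean over axis 0 (frames) using block averaging.

    ``per_frame`` may contain NaN for frames where a bin is empty; NaN-aware
    means are used so intermittently empty bins stay usable.
    """
    T = per_frame.shape[0]
    n_blocks = max(2, min(n_blocks, T))
    edges = np.linspace(0, T, n_blocks + 1).astype(int)
    with _nan_bins_ok():
        blocks = np.stack(
            [np.nanmean(per_frame[a:b], axis=0) for a, b in zip(edges[:-1], edges[1:])]
        )
        se = np.nanstd(blocks, axis=0, ddof=1) / np.sqrt(n_blocks)
    return se


@dataclass(frozen=True)
class RadialThicknessProfile:
    """Bilayer thickness h(rho) from leaflet C2 markers."""

    bin_edges: np.ndarray
    z_upper: np.ndarray
    z_lower: np.ndarray
    thickness: np.ndarray
    se: np.ndarray
    occupied: np.ndarray
    h_bio: float = H_BIO_NM

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class AxialDensityProfile:
    """Number (or mass) density along the channel axis."""

    bin_edges: np.ndarray
    density: np.ndarray
    se: np.ndarray
    species: str
    area: float
    mean_count: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ChainElongationProfile:
    """Axial tail elongation vs lipid radial position, per chain."""

    bin_edges: np.ndarray
    elongation_sn1: np.ndarray
    elongation_sn2: np.ndarray
    se_sn1: np.ndarray
    se_sn2: np.ndarray
    occupied: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class RmsdSeries:
    """Backbone RMSD vs time, with or without rigid-body superposition."""

    times: np.ndarray
    rmsd: np.ndarray
    superposition: str  # "none" | "rigid-body"


def _centered_axial_radial(
    traj: Trajectory,
    indices: np.ndarray,
    geom: ChannelGeometry,
    center_sel: Selection | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(rho, z) of the given particles about the axis, optionally after
    translating each frame so the centering selection's centroid sits at the
    axis origin (the protein-centering convention)."""
    pos = traj.positions[:, indices, :].astype(float)
    if center_sel is not None:
        center_sel.validate_against(traj.n_particles)
        shift = traj.positions[:, center_sel.indices, :].mean(axis=1) - geom.origin
        pos = pos - shift[:, None, :]
    z = geom.axial(pos)
    rho = geom.radial(pos)
    return rho, z


def radial_thickness(
    traj: Trajectory,
    c2_upper: Selection,
    c2_lower: Selection,
    geom: ChannelGeometry,
    bins: np.ndarray | None = None,
    n_blocks: int = 5,
    center_sel: Selection | None = None,
    h_bio: float = H_BIO_NM,
) -> RadialThicknessProfile:
    """Bilayer thickness as a function of radial position.

    For each rho-bin, the mean axial position of the upper- and lower-leaflet
    C2 markers is accumulated per frame; the thickness is the difference of
    the time-and-molecule averages.  Bins never visited by a lipid are
    flagged via ``occupied`` and hold NaN.
    """
    for sel in (c2_upper, c2_lower):
        if sel.role != "lipid-C2":
            raise DomainError("radial_thickness expects lipid-C2 selections")
        if len(sel) == 0:
            raise DomainError("empty leaflet selection")
        sel.validate_against(traj.n_particles)
    rho_u, z_u = _centered_axial_radial(traj, c2_upper.indices, geom, center_sel)
    rho_l, z_l = _centered_axial_radial(traj, c2_lower.indices, geom, center_sel)
    if bins is None:
        rho_max = max(rho_u.max(), rho_l.max())
        bins = np.arange(0.0, rho_max + DEFAULT_RHO_BIN_NM, DEFAULT_RHO_BIN_NM)
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise DomainError("bins must be a monotone 1-D edge array")
    nb = bins.size - 1

    def per_frame_binned(rho: np.ndarray, z: np.ndarray) -> np.ndarray:
        T = rho.shape[0]
        out = np.full((T, nb), np.nan)
        for t in range(T):
            which = np.digitize(rho[t], bins) - 1
            ok = (which >= 0) & (which < nb)
            sums = np.bincount(which[ok], weights=z[t][ok], minlength=nb)
            cnts = np.bincount(which[ok], minlength=nb)
            nz = cnts > 0
            out[t, nz] = sums[nz] / cnts[nz]
        return out

    zu_tb = per_frame_binned(rho_u, z_u)
    zl_tb = per_frame_binned(rho_l, z_l)
    h_tb = zu_tb - zl_tb
    occupied = ~np.all(np.isnan(h_tb), axis=0)
    with _nan_bins_ok():
        z_upper = np.nanmean(zu_tb, axis=0)
        z_lower = np.nanmean(zl_tb, axis=0)
        thickness = np.nanmean(h_tb, axis=0)
    se = _block_se(h_tb, n_blocks)
    return RadialThicknessProfile(
        bin_edges=bins,
        z_upper=z_upper,
        z_lower=z_lower,
        thickness=thickness,
        se=se,
        occupied=occupied,
        h_bio=h_bio,
    )


def axial_density(
    traj: Trajectory,
    sel: Selection,
    geom: ChannelGeometry,
    bins: np.ndarray,
    area: float,
    mass_per_particle: float | None = None,
    n_blocks: int = 5,
    center_sel: Selection | None = None,
) -> AxialDensityProfile:
    """Axial density profile (number per nm^3, or g/cm^3 when a molar mass
    in g/mol is given).

    Density conservation holds by construction: the sum of count density
    times bin volume equals the mean in-range particle count per frame.
    """
    if area <= 0:
        raise DomainError("area must be positive")
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise DomainError("bins must be a monotone 1-D edge array with nonzero widths")
    sel.validate_against(traj.n_particles)
    widths = np.diff(bins)
    if len(sel) == 0:
        nb = bins.size - 1
        return AxialDensityProfile(bins, np.zeros(nb), np.zeros(nb), sel.role, area, 0.0)
    _, z = _centered_axial_radial(traj, sel.indices, geom, center_sel)
    T = z.shape[0]
    counts = np.stack([np.histogram(z[t], bins=bins)[0] for t in range(T)]).astype(float)
    density_tb = counts / (area * widths)  # number / nm^3
    density = density_tb.mean(axis=0)
    se = _block_se(density_tb, n_blocks)
    mean_count = float(counts.sum(axis=1).mean())
    if mass_per_particle is not None:
        # number/nm^3 -> g/cm^3: * (M / N_A) g * 1e21 nm^3/cm^3
        factor = mass_per_particle / N_A * 1e21
        density = density * factor
        se = se * factor
    return AxialDensityProfile(
        bin_edges=bins,
        density=density,
        se=se,
        species=sel.role,
        area=float(area),
        mean_count=mean_count,
    )


def chain_elongation(
    traj: Trajectory,
    lipid_tails: list[tuple[int, np.ndarray, np.ndarray]],
    geom: ChannelGeometry,
    bins: np.ndarray,
    n_blocks: int = 5,
    center_sel: Selection | None = None,
) -> ChainElongationProfile:
    """Axial elongation of the two tail chains, binned by lipid C2 radius.

    ``lipid_tails`` lists, per lipid, the C2 particle index and the ordered
    (first-to-last carbon) index arrays of the sn-1 and sn-2 chains.  The
    elongation of a chain in a frame is |z(last) - z(first)|.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise DomainError("bins must be a monotone 1-D edge array")
    if not lipid_tails:
        raise DomainError("no lipids given")
    c2_idx = np.array([c2 for c2, _, _ in lipid_tails], dtype=np.intp)
    ends = []
    for c2, sn1, sn2 in lipid_tails:
        sn1 = np.asarray(sn1, dtype=np.intp)
        sn2 = np.asarray(sn2, dtype=np.intp)
        if sn1.size < 2 or sn2.size < 2:
            raise DomainError("each tail chain needs at least 2 atoms")
        ends.append((sn1[0], sn1[-1], sn2[0], sn2[-1]))
    ends = np.array(ends, dtype=np.intp)  # (n_lipids, 4)

    rho_c2, _ = _centered_axial_radial(traj, c2_idx, geom, center_sel)
    _, z_ends = _centered_axial_radial(traj, ends.ravel(), geom, center_sel)
    z_ends = z_ends.reshape(traj.n_frames, len(lipid_tails), 4)
    e1 = np.abs(z_ends[:, :, 1] - z_ends[:, :, 0])
    e2 = np.abs(z_ends[:, :, 3] - z_ends[:, :, 2])

    nb = bins.size - 1
    T = traj.n_frames
    prof1 = np.full((T, nb), np.nan)
    prof2 = np.full((T, nb), np.nan)
    for t in range(T):
        which = np.digitize(rho_c2[t], bins) - 1
        ok = (which >= 0) & (which < nb)
        cnts = np.bincount(which[ok], minlength=nb)
        nz = cnts > 0
        s1 = np.bincount(which[ok], weights=e1[t][ok], minlength=nb)
        s2 = np.bincount(which[ok], weights=e2[t][ok], minlength=nb)
        prof1[t, nz] = s1[nz] / cnts[nz]
        prof2[t, nz] = s2[nz] / cnts[nz]
    occupied = ~np.all(np.isnan(prof1), axis=0)
    with _nan_bins_ok():
        return ChainElongationProfile(
            bin_edges=bins,
            elongation_sn1=np.nanmean(prof1, axis=0),
            elongation_sn2=np.nanmean(prof2, axis=0),
            se_sn1=_block_se(prof1, n_blocks),
            se_sn2=_block_se(prof2, n_blocks),
            occupied=occupied,
        )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates.  Standard SVD solution with
    the determinant sign correction so reflections are never applied.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rmat = Vt.T @ D @ U.T
    return mob_c @ Rmat.T + reference.mean(axis=0)


def backbone_rmsd(
    traj: Trajectory,
    backbone: Selection,
    reference: Frame,
    superpose: bool = True,
    reference_indices: np.ndarray | None = None,
) -> RmsdSeries:
    """Cartesian backbone RMSD of each frame against a reference.

    With ``superpose`` the optimal rotation+translation (Kabsch) is removed
    first, so rigid motions give RMSD 0; without it the raw Cartesian RMSD
    is reported.  ``reference_indices`` defaults to the same indices as the
    trajectory selection.
    """
    backbone.validate_against(traj.n_particles)
    ref_idx = backbone.indices if reference_indices is None else np.asarray(
        reference_indices, dtype=np.intp
    )
    if ref_idx.size != backbone.indices.size:
        raise DomainError("reference and trajectory selections differ in size")
    if ref_idx.size == 0:
        raise DomainError("empty backbone selection")
    if ref_idx.max() >= reference.n_particles:
        raise DomainError("reference_indices exceed reference frame size")
    ref = reference.positions[ref_idx]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        mob = traj.positions[t, backbone.indices]
        if superpose:
            mob = kabsch_superpose(mob, ref)
        out[t] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return RmsdSeries(
        times=traj.times.copy(),
        rmsd=out,
        superposition="rigid-body" if superpose else "none",
    )
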