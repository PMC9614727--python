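"""Hydraulic-permeability fitting and hydraulic <-> osmotic conversion.

Under reverse-osmosis conditions the water flow through a membrane is
linear in the applied hydrostatic pressure difference,

    J_v = L_P ΔP,

with L_P the hydraulic permeability.  When the driving force is instead a
concentration difference ΔC of an impermeable solute, the molar water flux
is J_m = P_f ΔC with P_f the osmotic permeability, and the two driving
forces are equivalent through the van 't Hoff relation ΔP = R T ΔC, so

    P_f = L_P R T / V_W,

with V_W the molar volume of water.  For a single-channel membrane L_P is
conventionally quoted in cm^5 N^-1 s^-1 (volumetric flow per channel per
unit pressure) and P_f in cm^3 s^-1; this module fits L_P from flux-versus-
pressure data and converts exactly between the two, emitting both the MD
units (nm^3 ns^-1 MPa^-1) and the cgs-style units.

The primary fit is a weighted least-squares slope through the origin, since
the linear law has no intercept; a free-intercept fit is also reported as a
linearity diagnostic, never as the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InsufficientDataError, UsageError
from .units import (
    CM5_PER_N_S_PER_NM3_NS_MPA,
    M3_PER_PA_S_PER_CM5_N_S,
    R_GAS,
    V_WATER_MOLAR_CM3,
)

DEFAULT_T_K = 300.0


@dataclass(frozen=True)
class PermeabilityFit:
    """Through-origin flux-pressure fit with unit conversions.

    ``L_P`` and ``L_P_se`` are in the units of the supplied flux per MPa.
    When the flux was a per-channel volumetric flow in nm^3/ns, the
    cgs-style fields (``L_P_cm5_N_s``, and ``P_f_cm3_s`` after conversion)
    are populated.  ``slope_free``/``intercept_free`` hold the diagnostic
    free-intercept fit; ``residuals`` are data minus the through-origin fit.
    """

    L_P: float
    L_P_se: float
    slope_free: float
    intercept_free: float
    residuals: np.ndarray
    L_P_cm5_N_s: float | None = None
    L_P_se_cm5_N_s: float | None = None
    P_f_cm3_s: float | None = None
    P_f_se_cm3_s: float | None = None
    T: float | None = None
    V_W: float | None = None


@dataclass(frozen=True)
class OsmoticEquivalent:
    """A (ΔC, ΔP) pair linked by ΔP = R T ΔC, with the implied molar flux.

    ``delta_C`` in mol m^-3, ``delta_P`` in MPa; ``J_m`` (mol s^-1 per
    channel) is filled when an osmotic permeability is supplied.
    """

    delta_C: float
    delta_P: float
    T: float
    J_m: float | None = None


def fit_LP(
    dp_MPa: np.ndarray,
    flux: np.ndarray,
    flux_se: np.ndarray | None = None,
    *,
    flux_is_channel_flow_nm3_ns: bool = False,
    T: float = DEFAULT_T_K,
    V_W: float = V_WATER_MOLAR_CM3,
) -> PermeabilityFit:
    """Weighted least-squares slope of flux vs ΔP through the origin.

    Parameters
    ----------
    dp_MPa : array
        Applied pressure differences, MPa; at least two distinct positive
        values.
    flux : array
        Measured flux at each pressure (any linear flux measure; the slope
        is returned in those units per MPa).
    flux_se : array, optional
        Per-point standard errors; used as inverse-variance weights.  When
        absent (or any SE is zero) the fit is unweighted and the slope SE
        comes from the residual variance.
    flux_is_channel_flow_nm3_ns : bool
        When the flux is the per-channel volumetric flow Q in nm^3/ns, also
        populate the cm^5 N^-1 s^-1 hydraulic permeability and its osmotic
        conversion P_f = L_P R T / V_W at temperature ``T`` and molar
        volume ``V_W``.
    """
    x = np.asarray(dp_MPa, dtype=float)
    y = np.asarray(flux, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DomainError("dp_MPa and flux must be 1-D arrays of equal length")
    if x.size < 2 or np.unique(x).size < 2:
        raise InsufficientDataError("need at least 2 distinct pressures")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("non-finite input")
    if np.any(x <= 0):
        raise DomainError("pressures must be positive")

    if flux_se is not None:
        se = np.asarray(flux_se, dtype=float)
        if se.shape != y.shape or np.any(se < 0) or not np.all(np.isfinite(se)):
            raise DomainError("flux_se must be finite, nonnegative, same length")
        weighted = bool(np.all(se > 0))
    else:
        weighted = False

    if weighted:
        w = 1.0 / se**2
        sxx = float(np.sum(w * x * x))
        slope = float(np.sum(w * x * y) / sxx)
        slope_var = 1.0 / sxx  # absolute per-point sigmas
    else:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y) / sxx)
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        slope_var = float(np.sum(resid**2) / dof / sxx)
    residuals = y - slope * x
    slope_se = float(np.sqrt(slope_var))

    # free-intercept diagnostic (same weights) so linearity can be audited
    W = 1.0 / se**2 if weighted else np.ones_like(x)
    A = np.vstack([x * np.sqrt(W), np.sqrt(W)]).T
    coef, *_ = np.linalg.lstsq(A, y * np.sqrt(W), rcond=None)
    slope_free, intercept_free = (float(coef[0]), float(coef[1]))

    kwargs: dict = {}
    if flux_is_channel_flow_nm3_ns:
        lp_cm5 = slope * CM5_PER_N_S_PER_NM3_NS_MPA
        lp_se_cm5 = slope_se * CM5_PER_N_S_PER_NM3_NS_MPA
        kwargs = dict(
            L_P_cm5_N_s=lp_cm5,
            L_P_se_cm5_N_s=lp_se_cm5,
            P_f_cm3_s=Pf_from_LP(lp_cm5, T=T, V_W=V_W),
            P_f_se_cm3_s=Pf_from_LP(lp_se_cm5, T=T, V_W=V_W),
            T=T,
            V_W=V_W,
        )
    return PermeabilityFit(
        L_P=slope,
        L_P_se=slope_se,
        slope_free=slope_free,
        intercept_free=intercept_free,
        residuals=residuals,
        **kwargs,
    )


def Pf_from_LP(
    L_P_cm5_N_s: float, T: float = DEFAULT_T_K, V_W: float = V_WATER_MOLAR_CM3
) -> float:
    """Osmotic permeability P_f (cm^3 s^-1) from hydraulic L_P (cm^5 N^-1 s^-1).

    P_f = L_P R T / V_W with R = 8.314462618 J mol^-1 K^-1, T in K and V_W
    in cm^3 mol^-1; the conversion runs through SI exactly.
    """
    if T <= 0 or V_W <= 0:
        raise DomainError("T and V_W must be positive")
    lp_si = L_P_cm5_N_s * M3_PER_PA_S_PER_CM5_N_S  # m^3 Pa^-1 s^-1
    pf_si = lp_si * R_GAS * T / (V_W * 1e-6)  # m^3 s^-1
    return pf_si * 1e6  # cm^3 s^-1


def LP_from_Pf(
    P_f_cm3_s: float, T: float = DEFAULT_T_K, V_W: float = V_WATER_MOLAR_CM3
) -> float:
    """Inverse of :func:`Pf_from_LP`; round-trips to machine precision."""
    if T <= 0 or V_W <= 0:
        raise DomainError("T and V_W must be positive")
    pf_si = P_f_cm3_s * 1e-6
    lp_si = pf_si * (V_W * 1e-6) / (R_GAS * T)
    return lp_si / M3_PER_PA_S_PER_CM5_N_S


def pressure_concentration_equiv(
    delta_C: float | None = None,
    delta_P: float | None = None,
    T: float = DEFAULT_T_K,
    P_f_cm3_s: float | None = None,
) -> OsmoticEquivalent:
    """Fill the missing member of the osmotic pair via ΔP = R T ΔC.

    ``delta_C`` in mol m^-3, ``delta_P`` in MPa.  Exactly one of the two
    must be given.  With ``P_f_cm3_s`` supplied, the implied per-channel
    molar water flux J_m = P_f ΔC (mol/s) is included.
    """
    if T <= 0:
        raise DomainError("T must be positive")
    if (delta_C is None) == (delta_P is None):
        raise UsageError("give exactly one of delta_C, delta_P")
    if delta_C is None:
        delta_C = delta_P * 1e6 / (R_GAS * T)  # MPa -> Pa, Pa = J/m^3
    else:
        delta_P = delta_C * R_GAS * T * 1e-6
    J_m = None
    if P_f_cm3_s is not None:
        J_m = P_f_cm3_s * 1e-6 * delta_C  # (m^3/s) * (mol/m^3)
    return OsmoticEquivalent(delta_C=float(delta_C), delta_P=float(delta_P), T=T, J_m=J_m)
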