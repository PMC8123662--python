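"""Tirado-Garcia de la Torre (TGT) rigid-rod hydrodynamics.

For a rigid rod of length L and hydrodynamic diameter d with aspect ratio
p = L/d in the range 2 <= p <= 30, the translational diffusion coefficient
is given by the interpolation formula

    D(L) = kB*T / (3*pi*eta*L) * (ln p + nu(p)),
    nu(p) = 0.312 + 0.565/p + 0.100/p**2,

with kB the Boltzmann constant, T the temperature and eta the solvent
viscosity.  For stacked G-quadruplexes (d = 2.6 nm including the hydration
sphere, T = 296 K, eta = 0.932 mPa·s) the formula is applicable for rod
lengths of roughly 5-80 nm, i.e. measured D between about 1.2e-10 and
0.22e-10 m^2/s.

D(L) is strictly decreasing, so the inverse problem — rod length from a
measured diffusion coefficient — has a unique solution and is solved here by
bracketed root finding.  Outside the validity window the same formula can be
extrapolated on request; the result is then flagged.

A rod length converts to a count of stacked G-quartet planes through the
axial rise per plane (0.34 nm) and to a count of stacked quadruplex units
through the number of quartet planes each unit contributes (4 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.constants import k as BOLTZMANN
from scipy.optimize import brentq

from .errors import ComputationError, ValidationError

__all__ = [
    "RodHydroParams",
    "RodEstimate",
    "MultimerCount",
    "end_correction",
    "diffusion_of_rod",
    "length_from_diffusion",
    "validity_bounds",
    "validity_report",
    "count_multimers",
]

#: rod length window (m) over which the interpolation is considered reliable
#: for 2.6 nm diameter G-quadruplex stacks
VALID_LENGTH_RANGE = (5e-9, 80e-9)
#: aspect-ratio window of the interpolation formula proper
VALID_ASPECT_RANGE = (2.0, 30.0)


@dataclass(frozen=True)
class RodHydroParams:
    """Hydrodynamic parameters of the rod model."""

    diameter: float = 2.6e-9  # m, includes the hydration sphere
    temperature: float = 296.0  # K
    viscosity: float = 0.932e-3  # Pa·s

    def __post_init__(self) -> None:
        for name in ("diameter", "temperature", "viscosity"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class RodEstimate:
    """Rod length inferred from a diffusion coefficient.

    ``in_validity`` refers to the aspect-ratio window 2 <= p <= 30;
    ``in_length_range`` to the 5-80 nm length window (the two disagree
    slightly at the short end, where p = 1.92 at L = 5 nm).
    ``extrapolated`` is set when the inversion bracket had to be widened
    beyond the length window.
    """

    length: float  # m
    aspect_ratio: float  # L/d
    end_correction: float  # nu(p)
    in_validity: bool
    in_length_range: bool
    extrapolated: bool


@dataclass(frozen=True)
class MultimerCount:
    """Stacked-plane and stacked-unit counts for a rod of given length."""

    n_planes: int  # G-quartet planes
    n_units: int  # stacked quadruplex units
    plane_rise: float = 0.34e-9  # m per plane
    planes_per_unit: int = 4


def end_correction(p: float) -> float:
    """End-effect correction nu(p) = 0.312 + 0.565/p + 0.100/p**2.

    Strictly decreasing in the aspect ratio p, approaching 0.312 for an
    infinitely long rod.
    """
    if not p > 0:
        raise ValidationError(f"aspect ratio must be > 0, got {p}")
    return 0.312 + 0.565 / p + 0.100 / p**2


def diffusion_of_rod(length: float, params: RodHydroParams = RodHydroParams()) -> float:
    """Translational diffusion coefficient (m^2/s) of a rigid rod of given length (m).

    Lengths at or below the rod diameter put the formula in the ln(p) <= 0
    regime; a warning is emitted but the value is still returned.
    """
    if not length > 0:
        raise ValidationError(f"rod length must be > 0, got {length}")
    p = length / params.diameter
    if p <= 1:
        warnings.warn(
            f"rod length {length:.3g} m <= diameter {params.diameter:.3g} m: "
            "ln(p) <= 0, outside any rod-hydrodynamics regime",
            stacklevel=2,
        )
    nu = end_correction(p)
    return (
        BOLTZMANN
        * params.temperature
        / (3 * math.pi * params.viscosity * length)
        * (math.log(p) + nu)
    )


def validity_bounds(params: RodHydroParams = RodHydroParams()) -> tuple[float, float]:
    """(D_min, D_max) in m^2/s corresponding to the 5-80 nm length window.

    D_min belongs to the longest (80 nm) rod, D_max to the shortest (5 nm);
    the bounds are computed from ``params``, never hard-coded.
    """
    lo, hi = VALID_LENGTH_RANGE
    return diffusion_of_rod(hi, params), diffusion_of_rod(lo, params)


def validity_report(D: float, params: RodHydroParams = RodHydroParams()) -> str:
    """Classify a measured D against the validity window of the rod formula.

    Returns ``"below-range"`` (rod longer than 80 nm), ``"in-range"`` or
    ``"above-range"`` (rod shorter than 5 nm).  The boundaries are closed:
    D exactly at a bound is in-range.
    """
    if not D > 0:
        raise ValidationError(f"diffusion coefficient must be > 0, got {D}")
    d_min, d_max = validity_bounds(params)
    # closed boundaries with a hair of tolerance against round-off
    if D < d_min * (1 - 1e-12):
        return "below-range"
    if D > d_max * (1 + 1e-12):
        return "above-range"
    return "in-range"


def length_from_diffusion(
    D: float,
    params: RodHydroParams = RodHydroParams(),
    allow_extrapolation: bool = False,
    rtol: float = 1e-6,
) -> RodEstimate:
    """Invert the rod-diffusion formula: rod length from a measured D (m^2/s).

    The formula is transcendental in L, so the inverse is found by Brent
    root finding on the validity bracket [5 nm, 80 nm]; monotonicity of
    D(L) guarantees a unique root.  When D falls outside the corresponding
    range the bracket is widened to [1.1*d, 1 um] if ``allow_extrapolation``
    is set (the estimate is then flagged ``extrapolated``), otherwise a
    :class:`ValidationError` is raised.
    """
    if not D > 0:
        raise ValidationError(f"diffusion coefficient must be > 0, got {D}")
    d_min, d_max = validity_bounds(params)
    in_range = d_min * (1 - 1e-12) <= D <= d_max * (1 + 1e-12)
    if in_range:
        bracket = VALID_LENGTH_RANGE
        extrapolated = False
    elif allow_extrapolation:
        bracket = (1.1 * params.diameter, 1e-6)
        extrapolated = True
    else:
        raise ValidationError(
            f"D = {D:.3g} m^2/s is outside the TGT validity range "
            f"[{d_min:.3g}, {d_max:.3g}] m^2/s; pass allow_extrapolation=True "
            "to invert anyway"
        )

    def objective(L: float) -> float:
        return diffusion_of_rod(L, params) - D

    lo, hi = bracket
    # guard the bracket edges against round-off when D sits exactly on a bound
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo < 0:  # D above D(lo): rod shorter than the bracket start
        lo *= 0.999
        f_lo = objective(lo)
    if f_hi > 0:
        hi *= 1.001
        f_hi = objective(hi)
    if not (f_lo >= 0 >= f_hi):
        raise ComputationError(
            f"no root for D = {D:.3g} m^2/s in bracket [{lo:.3g}, {hi:.3g}] m"
        )
    length = brentq(objective, lo, hi, rtol=rtol, xtol=1e-15)
    p = length / params.diameter
    p_lo, p_hi = VALID_ASPECT_RANGE
    l_lo, l_hi = VALID_LENGTH_RANGE
    return RodEstimate(
        length=length,
        aspect_ratio=p,
        end_correction=end_correction(p),
        in_validity=p_lo <= p <= p_hi,
        in_length_range=l_lo * (1 - 1e-9) <= length <= l_hi * (1 + 1e-9),
        extrapolated=extrapolated,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def count_multimers(
    length: float, plane_rise: float = 0.34e-9, planes_per_unit: int = 4
) -> MultimerCount:
    """Convert a rod length (m) into stacked-plane and stacked-unit counts.

    n_planes = round(L / plane_rise); n_units = round(n_planes /
    planes_per_unit); both are floored at 1 (a detected rod is at least one
    plane / one unit).  Rounding is round-half-up.  For a 10 nm rod with the
    default 0.34 nm rise and 4 planes per unit this gives 29 planes and 7
    stacked quadruplex units.
    """
    if not length > 0 or not plane_rise > 0:
        raise ValidationError("length and plane_rise must be > 0")
    if not planes_per_unit >= 1:
        raise ValidationError(f"planes_per_unit must be >= 1, got {planes_per_unit}")
    n_planes = max(1, _round_half_up(length / plane_rise))
    n_units = max(1, _round_half_up(n_planes / planes_per_unit))
    return MultimerCount(
        n_planes=n_planes,
        n_units=n_units,
        plane_rise=plane_rise,
        planes_per_unit=planes_per_unit,
    )
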