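"""Forward model of the DLS intensity autocorrelation function.

Dynamic light scattering measures the normalised intensity autocorrelation
g2(t) of light scattered by diffusing particles.  In dilute solutions of
G-quadruplex multimers two diffusive relaxation modes are typically seen: a
fast mode from the quadruplexes/G-wires themselves and a slow mode from
large, loose polyelectrolyte "clusters".  Each mode is described by a
stretched exponential, and the field correlation is mapped to g2 through a
partial-heterodyne Siegert-type relation,

    g2(t) - 1 = [ j_d ( a_f e^{-(t/tau_f)^{s_f}}
                      + (1 - a_f) e^{-(t/tau_s)^{s_s}} ) ]^2 + y0,

where j_d is the inelastic (dynamically scattered) fraction of the total
intensity, a_f the fast-mode amplitude, tau_f/tau_s the relaxation times and
s_f/s_s the stretch exponents (1 for a monodisperse single-rate decay,
< 1 for a distribution of relaxation times).  y0 is a baseline correction.

Angles are degrees at every public interface; radians are used internally.
All other quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "OpticalContext",
    "CorrelationCurve",
    "TwoModeParams",
    "scattering_vector",
    "intensity_from_field",
    "field_correlation",
    "g2_model",
]


@dataclass(frozen=True)
class OpticalContext:
    """Optical/solvent conditions of a light-scattering measurement.

    Defaults are a He-Ne laser in aqueous KCl solution at 296 K:
    wavelength 633 nm, refractive index 1.33, viscosity 0.932 mPa·s.
    """

    wavelength: float = 633e-9  # m
    refractive_index: float = 1.33
    temperature: float = 296.0  # K
    viscosity: float = 0.932e-3  # Pa·s

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValidationError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.refractive_index >= 1:
            raise ValidationError(
                f"refractive index must be >= 1, got {self.refractive_index}"
            )
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.viscosity > 0:
            raise ValidationError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class TwoModeParams:
    """Parameters of the two-mode stretched-exponential correlation model.

    A single-mode decay is expressed as ``a_fast = 1`` (the slow-mode
    parameters are then inert; ``tau_slow = inf`` is the conventional
    placeholder).
    """

    jd: float  # inelastic / total intensity ratio, in (0, 1]
    a_fast: float  # fast-mode amplitude, in [0, 1]
    tau_fast: float  # s
    s_fast: float  # stretch exponent, in (0, 1]
    tau_slow: float = math.inf  # s
    s_slow: float = 1.0  # stretch exponent, in (0, 1]
    y0: float = 0.0  # baseline offset

    def __post_init__(self) -> None:
        if not 0 < self.jd <= 1:
            raise ValidationError(f"jd must be in (0, 1], got {self.jd}")
        if not 0 <= self.a_fast <= 1:
            raise ValidationError(f"a_fast must be in [0, 1], got {self.a_fast}")
        if not self.tau_fast > 0:
            raise ValidationError(f"tau_fast must be > 0, got {self.tau_fast}")
        if not self.tau_slow > 0:
            raise ValidationError(f"tau_slow must be > 0, got {self.tau_slow}")
        for name, s in (("s_fast", self.s_fast), ("s_slow", self.s_slow)):
            if not 0 < s <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {s}")
        # tau ordering only matters when the slow mode carries weight
        if self.a_fast < 1 and not self.tau_fast < self.tau_slow:
            raise ValidationError(
                f"tau_fast ({self.tau_fast}) must be < tau_slow ({self.tau_slow}) "
                "when both modes are present"
            )

    @property
    def n_modes(self) -> int:
        return 1 if self.a_fast == 1.0 else 2


@dataclass(frozen=True)
class CorrelationCurve:
    """One measured or simulated autocorrelation trace at a single angle."""

    lag_times: np.ndarray  # s, strictly increasing, >= 0
    g2: np.ndarray  # dimensionless
    angle_deg: float  # scattering angle, degrees in (0, 180)
    context: OpticalContext

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_times, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "lag_times", lag)
        object.__setattr__(self, "g2", g2)
        if lag.ndim != 1 or lag.size == 0:
            raise ValidationError("lag_times must be a non-empty 1-D array")
        if lag.shape != g2.shape:
            raise ValidationError(
                f"lag_times ({lag.shape}) and g2 ({g2.shape}) must have equal length"
            )
        if lag[0] < 0 or not np.all(np.diff(lag) > 0):
            raise ValidationError("lag_times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(g2)):
            raise ValidationError("g2 values must all be finite")
        if not 0 < self.angle_deg < 180:
            raise ValidationError(
                f"scattering angle must be in (0, 180) degrees, got {self.angle_deg}"
            )

    @property
    def q(self) -> float:
        """Scattering wave vector magnitude for this curve, 1/m."""
        return scattering_vector(self.angle_deg, self.context)

    def __len__(self) -> int:
        return self.lag_times.size


def scattering_vector(angle_deg: float, context: OpticalContext) -> float:
    """Scattering wave vector magnitude q = (4*pi*n/lambda)*sin(theta/2), 1/m.

    ``angle_deg`` is the scattering angle theta in degrees, on [0, 180].
    """
    if not 0 <= angle_deg <= 180:
        raise ValidationError(
            f"scattering angle must be in [0, 180] degrees, got {angle_deg}"
        )
    theta = math.radians(angle_deg)
    return (4 * math.pi * context.refractive_index / context.wavelength) * math.sin(
        theta / 2
    )


def intensity_from_field(g1, jd: float, y0: float):
    """Map a (normalised) field correlation to the intensity correlation g2.

    Implements the partial-heterodyne Siegert-type relation
    ``g2 = 1 + (jd * g1)**2 + y0`` with jd the inelastic intensity fraction.
    The mapping is deliberately isolated here so that an alternative
    heterodyne convention can be swapped in one place.
    """
    return 1.0 + (jd * np.asarray(g1)) ** 2 + y0


def field_correlation(t, params: TwoModeParams):
    """Normalised field correlation g1(t) of the two-mode model (g1(0) = 1)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("lag times must be finite")
    if np.any(t < 0):
        raise ValidationError("lag times must be >= 0")
    fast = np.exp(-((t / params.tau_fast) ** params.s_fast))
    if params.a_fast == 1.0:
        return fast
    with np.errstate(over="ignore"):  # t/inf -> 0 is fine
        slow = np.exp(-((t / params.tau_slow) ** params.s_slow))
    return params.a_fast * fast + (1.0 - params.a_fast) * slow


def g2_model(t, params: TwoModeParams):
    """Intensity autocorrelation g2(t) of the two-mode stretched-exponential model.

    Accepts a scalar or array of lag times (seconds, >= 0).  At t = 0 the
    model equals ``1 + jd**2 + y0``; as t -> inf it decays to ``1 + y0``.
    """
    g1 = field_correlation(t, params)
    return intensity_from_field(g1, params.jd, params.y0)
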