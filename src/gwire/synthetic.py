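"""Synthetic multi-angle DLS datasets with known ground truth.

Every fitting and inversion stage of the package is testable without any
measured data: this module generates correlation curves for

* monodisperse scatterers with a given fast-mode D (optionally plus a slow
  "cluster" mode),
* polydisperse rigid-rod ensembles whose per-component diffusion follows
  rod hydrodynamics and whose scattering weights follow the w ~ L^2 rule
  (scattered intensity grows as the square of the scattering volume, which
  for rods of equal diameter means the squared length), and
* time series mimicking re-assembly after thermal denaturation.

Noise is multiplicative Gaussian on (g2 - 1) plus an additive Gaussian
floor; both default to 0 here and to 0.5 % in :class:`NoiseSpec` when a
"realistic correlator" noise level is wanted.  Component lengths are drawn
once per dataset — the same physical sample is viewed at all angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dls_model import (
    CorrelationCurve,
    OpticalContext,
    TwoModeParams,
    g2_model,
    scattering_vector,
)
from .errors import ValidationError
from .tgt import RodHydroParams, diffusion_of_rod

__all__ = [
    "NoiseSpec",
    "RodEnsembleSpec",
    "SimulatedDataset",
    "simulate_monodisperse",
    "simulate_rod_ensemble",
    "make_denaturation_series",
]

DEFAULT_ANGLES = (30.0, 50.0, 70.0, 90.0, 110.0, 130.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: g2 -> 1 + (g2-1)*(1 + sigma_mult*eps1) + sigma_add*eps2."""

    sigma_additive: float = 0.005
    sigma_multiplicative: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_additive < 0 or self.sigma_multiplicative < 0:
            raise ValidationError("noise sigmas must be >= 0")


NO_NOISE = NoiseSpec(0.0, 0.0, 0)


@dataclass(frozen=True)
class RodEnsembleSpec:
    """Length distribution of a rod ensemble, parameters in metres.

    families: ``delta(length)``, ``lognormal(median, sigma_log)``,
    ``uniform(low, high)``.  Scattering weights are fixed to w ~ L^2.
    """

    family: str  # "delta" | "lognormal" | "uniform"
    params: dict
    hydro: RodHydroParams = RodHydroParams()

    def __post_init__(self) -> None:
        if self.family not in ("delta", "lognormal", "uniform"):
            raise ValidationError(f"unknown length distribution {self.family!r}")
        required = {
            "delta": {"length"},
            "lognormal": {"median", "sigma_log"},
            "uniform": {"low", "high"},
        }[self.family]
        if set(self.params) != required:
            raise ValidationError(
                f"{self.family} distribution needs parameters {sorted(required)}"
            )
        vals = self.params
        if self.family == "delta" and not vals["length"] > 0:
            raise ValidationError("delta length must be > 0")
        if self.family == "lognormal" and (
            not vals["median"] > 0 or vals["sigma_log"] < 0
        ):
            raise ValidationError("lognormal needs median > 0 and sigma_log >= 0")
        if self.family == "uniform" and not 0 < vals["low"] <= vals["high"]:
            raise ValidationError("uniform needs 0 < low <= high")

    def draw_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "delta":
            lengths = np.full(n, self.params["length"], dtype=float)
        elif self.family == "lognormal":
            lengths = self.params["median"] * np.exp(
                rng.normal(0.0, self.params["sigma_log"], size=n)
            )
        else:
            lengths = rng.uniform(self.params["low"], self.params["high"], size=n)
        if np.any(lengths <= 0):
            raise ValidationError("length distribution produced non-positive length")
        return lengths


@dataclass(frozen=True)
class SimulatedDataset:
    """Curves over the stated angles plus the full generating truth."""

    curves: list[CorrelationCurve]
    truth: dict

    @property
    def angles(self) -> list[float]:
        return [c.angle_deg for c in self.curves]


def _lag_grid(tau_min: float, tau_max: float, n_points: int) -> np.ndarray:
    return np.geomspace(1e-3 * tau_min, 1e3 * tau_max, n_points)


def _apply_noise(g2: np.ndarray, noise: NoiseSpec, rng: np.random.Generator):
    out = g2.copy()
    if noise.sigma_multiplicative > 0:
        out = 1.0 + (out - 1.0) * (
            1.0 + noise.sigma_multiplicative * rng.standard_normal(out.size)
        )
    if noise.sigma_additive > 0:
        out = out + noise.sigma_additive * rng.standard_normal(out.size)
    return out


def _check_angles(angles: Sequence[float]) -> None:
    if len(angles) == 0:
        raise ValidationError("need at least one scattering angle")
    for a in angles:
        if not 0 < a < 180:
            raise ValidationError(f"angle {a} outside (0, 180) degrees")


def simulate_monodisperse(
    D_fast: float,
    angles: Sequence[float] = DEFAULT_ANGLES,
    slow_mode: tuple[float, float, float] | None = None,
    jd: float = 0.9,
    y0: float = 0.0,
    noise: NoiseSpec = NO_NOISE,
    context: OpticalContext = OpticalContext(),
    n_points: int = 200,
) -> SimulatedDataset:
    """Simulate curves for monodisperse scatterers of diffusion coefficient D_fast.

    ``slow_mode``, if given, is a ``(D_slow, a_fast, s_slow)`` tuple adding a
    slow "cluster" mode: per angle tau_s = 1/(D_slow*q^2), with fast-mode
    amplitude a_fast and slow-mode stretch s_slow.  Per angle
    tau_f = 1/(D_fast*q^2) and the lag grid spans 1e-3*tau_f to 1e3 times
    the slowest relaxation time.  Deterministic for a given noise seed.
    """
    if not D_fast > 0:
        raise ValidationError(f"D_fast must be > 0, got {D_fast}")
    _check_angles(angles)
    if slow_mode is not None:
        D_slow, a_fast, s_slow = slow_mode
        if not 0 < D_slow < D_fast:
            raise ValidationError("slow mode requires 0 < D_slow < D_fast")
    rng = np.random.default_rng(noise.seed)
    curves = []
    per_angle = []
    for angle in angles:
        q = scattering_vector(angle, context)
        tau_f = 1.0 / (D_fast * q * q)
        if slow_mode is None:
            params = TwoModeParams(jd=jd, a_fast=1.0, tau_fast=tau_f, s_fast=1.0, y0=y0)
            tau_max = tau_f
        else:
            tau_s = 1.0 / (D_slow * q * q)
            params = TwoModeParams(
                jd=jd,
                a_fast=a_fast,
                tau_fast=tau_f,
                s_fast=1.0,
                tau_slow=tau_s,
                s_slow=s_slow,
                y0=y0,
            )
            tau_max = tau_s
        lag = _lag_grid(tau_f, tau_max, n_points)
        g2 = _apply_noise(g2_model(lag, params), noise, rng)
        curves.append(
            CorrelationCurve(lag_times=lag, g2=g2, angle_deg=angle, context=context)
        )
        per_angle.append(
            {"angle_deg": angle, "q": q, "tau_fast": tau_f}
            | ({"tau_slow": tau_s} if slow_mode is not None else {})
        )
    truth = {
        "kind": "monodisperse",
        "D_fast": D_fast,
        "slow_mode": list(slow_mode) if slow_mode is not None else None,
        "jd": jd,
        "y0": y0,
        "noise": {
            "sigma_additive": noise.sigma_additive,
            "sigma_multiplicative": noise.sigma_multiplicative,
            "seed": noise.seed,
        },
        "per_angle": per_angle,
    }
    return SimulatedDataset(curves=curves, truth=truth)


def ensemble_weights(lengths: np.ndarray) -> np.ndarray:
    """Normalised intensity weights w_i ~ L_i^2 of a rod ensemble."""
    w = np.asarray(lengths, dtype=float) ** 2
    return w / w.sum()


def simulate_rod_ensemble(
    spec: RodEnsembleSpec,
    n_components: int,
    angles: Sequence[float] = DEFAULT_ANGLES,
    jd: float = 0.9,
    y0: float = 0.0,
    noise: NoiseSpec = NO_NOISE,
    context: OpticalContext = OpticalContext(),
    n_points: int = 200,
) -> SimulatedDataset:
    """Simulate curves for an L^2-intensity-weighted ensemble of rigid rods.

    ``n_components`` lengths are drawn once from the spec's distribution
    (the same sample at every angle); each component relaxes exponentially
    with rate D(L_i)*q^2 where D comes from rod hydrodynamics, and the
    field correlation is the w_i ~ L_i^2 weighted sum.  A polydisperse
    ensemble therefore produces a strictly multi-exponential decay, which a
    single stretched exponential fits with s_f < 1.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    _check_angles(angles)
    rng = np.random.default_rng(noise.seed)
    lengths = spec.draw_lengths(n_components, rng)
    weights = ensemble_weights(lengths)
    D_comp = np.array([diffusion_of_rod(L, spec.hydro) for L in lengths])
    curves = []
    per_angle = []
    for angle in angles:
        q = scattering_vector(angle, context)
        rates = D_comp * q * q
        tau = 1.0 / rates
        lag = _lag_grid(tau.min(), tau.max(), n_points)
        g1 = np.sum(weights[None, :] * np.exp(-np.outer(lag, rates)), axis=1)
        g2 = 1.0 + (jd * g1) ** 2 + y0
        g2 = _apply_noise(g2, noise, rng)
        curves.append(
            CorrelationCurve(lag_times=lag, g2=g2, angle_deg=angle, context=context)
        )
        per_angle.append({"angle_deg": angle, "q": q})
    truth = {
        "kind": "rod_ensemble",
        "family": spec.family,
        "distribution_params": dict(spec.params),
        "lengths": lengths.tolist(),
        "weights": weights.tolist(),
        "D_components": D_comp.tolist(),
        "jd": jd,
        "y0": y0,
        "noise": {
            "sigma_additive": noise.sigma_additive,
            "sigma_multiplicative": noise.sigma_multiplicative,
            "seed": noise.seed,
        },
        "per_angle": per_angle,
    }
    return SimulatedDataset(curves=curves, truth=truth)


def make_denaturation_series(
    D_trajectory: Sequence[tuple[float, float]],
    angles: Sequence[float] = DEFAULT_ANGLES,
    noise: NoiseSpec = NO_NOISE,
    context: OpticalContext = OpticalContext(),
    **kwargs,
) -> list[tuple[float, SimulatedDataset]]:
    """One monodisperse dataset per (time, D) point of a denaturation series.

    Emulates monitoring re-assembly after thermal denaturation: the
    trajectory lists elapsed times (strictly increasing, hours by
    convention) and the fast-mode D at each time.  Returns
    ``(time, dataset)`` pairs; per-point noise seeds are derived from the
    spec seed so the series is reproducible as a whole.
    """
    times = [t for t, _ in D_trajectory]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValidationError("trajectory times must be strictly increasing")
    out = []
    for i, (time, D) in enumerate(D_trajectory):
        point_noise = NoiseSpec(
            noise.sigma_additive,
            noise.sigma_multiplicative,
            seed=(noise.seed + 10_007 * i) % (2**31),
        )
        dataset = simulate_monodisperse(
            D, angles=angles, noise=point_noise, context=context, **kwargs
        )
        dataset.truth["time"] = float(time)
        out.append((float(time), dataset))
    return out
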