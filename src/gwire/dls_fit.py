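"""Nonlinear fitting of correlation curves and diffusion-coefficient extraction.

The per-curve fit is an unweighted bounded least-squares fit of the
two-mode stretched-exponential model (see :mod:`gwire.dls_model`).  A
deterministic multi-start strategy (seed-derived perturbations of a
heuristic initialisation) guards against local minima.  Per angle, the fast
relaxation rate 1/tau_f is plotted against q^2; for purely diffusive
dynamics 1/tau = D*q^2, so the slope of the (ordinary least squares) line
is the translational diffusion coefficient D.

Stretch exponents are bounded to [0.3, 1.0] during fitting (configurable)
to keep the optimiser away from degenerate ultra-stretched solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .dls_model import CorrelationCurve, TwoModeParams
from .errors import ComputationError, ValidationError

__all__ = [
    "FitResult",
    "RatePoint",
    "DiffusionFit",
    "StretchSummary",
    "default_init",
    "fit_curve",
    "rate_points",
    "diffusion_from_rates",
    "average_stretch",
    "fit_time_series",
]

#: default bounds on the stretch exponents during fitting
STRETCH_BOUNDS = (0.3, 1.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one correlation curve."""

    params: TwoModeParams
    residual_rms: float
    converged: bool
    n_modes_used: int


@dataclass(frozen=True)
class RatePoint:
    """One (q^2, 1/tau_f) point of the rate-versus-q^2 line."""

    q_squared: float  # 1/m^2
    inverse_tau_f: float  # 1/s
    angle_deg: float

    def __post_init__(self) -> None:
        if not self.q_squared > 0:
            raise ValidationError(f"q_squared must be > 0, got {self.q_squared}")
        if not self.inverse_tau_f > 0:
            raise ValidationError(
                f"inverse_tau_f must be > 0, got {self.inverse_tau_f}"
            )


@dataclass(frozen=True)
class DiffusionFit:
    """Diffusion coefficient from the 1/tau_f versus q^2 line."""

    D: float  # m^2/s (slope)
    D_stderr: float  # m^2/s
    intercept: float  # 1/s
    r_squared: float
    n_points: int
    through_origin: bool


@dataclass(frozen=True)
class StretchSummary:
    """Mean fast-mode stretch exponent over scattering angles."""

    s_mean: float
    s_sem: float
    n_angles: int


def default_init(curve: CorrelationCurve) -> TwoModeParams:
    """Heuristic starting parameters for :func:`fit_curve`.

    The t=0 intercept of g2-1 is estimated from the early-lag plateau and
    gives jd (its square root); tau_f comes from the lag where the
    normalised field correlation crosses 1/e; tau_s starts at 100*tau_f,
    a_f at 0.8 and both stretch exponents at 0.95.
    """
    g2m1 = curve.g2 - 1.0
    n_plateau = max(3, len(curve) // 50)
    intercept = float(np.mean(g2m1[:n_plateau]))
    decay_span = intercept - float(np.min(g2m1))
    if intercept <= 1e-4 or decay_span <= 1e-4:
        raise ValidationError("no dynamics detected: curve has no measurable decay")
    intercept = min(intercept, 1.0)
    jd = math.sqrt(intercept)
    # normalised field correlation ~ sqrt((g2-1)/intercept); find 1/e crossing
    g1 = np.sqrt(np.clip(g2m1, 0.0, None) / intercept)
    below = np.nonzero(g1 < math.exp(-1))[0]
    if below.size == 0:
        tau_f = float(curve.lag_times[-1])  # decay not complete; start late
    else:
        tau_f = float(curve.lag_times[below[0]])
    if tau_f <= 0:
        tau_f = float(curve.lag_times[1])
    return TwoModeParams(
        jd=jd,
        a_fast=0.8,
        tau_fast=tau_f,
        s_fast=0.95,
        tau_slow=100 * tau_f,
        s_slow=0.95,
        y0=0.0,
    )


def _lmfit_parameters(
    init: TwoModeParams,
    n_modes: int,
    lag: np.ndarray,
    stretch_bounds: tuple[float, float],
) -> lmfit.Parameters:
    s_lo, s_hi = stretch_bounds
    tau_min = max(lag[0] * 1e-3, 1e-12)
    tau_max = lag[-1] * 1e3
    p = lmfit.Parameters()
    p.add("y0", value=init.y0, min=-0.2, max=0.5)
    p.add("jd", value=float(np.clip(init.jd, 1e-3, 1.0)), min=1e-6, max=1.0)
    p.add(
        "tau_fast",
        value=float(np.clip(init.tau_fast, tau_min, tau_max)),
        min=tau_min,
        max=tau_max,
    )
    p.add("s_fast", value=float(np.clip(init.s_fast, s_lo, s_hi)), min=s_lo, max=s_hi)
    if n_modes == 2:
        ratio0 = init.tau_slow / init.tau_fast if math.isfinite(init.tau_slow) else 100.0
        p.add("a_fast", value=float(np.clip(init.a_fast, 0.0, 1.0)), min=0.0, max=1.0)
        # tau_slow = tau_fast * ratio with ratio >= 1 enforces mode ordering
        p.add("tau_ratio", value=float(np.clip(ratio0, 1.0, 1e8)), min=1.0, max=1e8)
        p.add("tau_slow", expr="tau_fast * tau_ratio")
        p.add(
            "s_slow", value=float(np.clip(init.s_slow, s_lo, s_hi)), min=s_lo, max=s_hi
        )
    else:
        p.add("a_fast", value=1.0, vary=False)
    return p


def _params_from_lmfit(p: lmfit.Parameters, n_modes: int) -> TwoModeParams:
    a_fast = float(p["a_fast"].value)
    if n_modes == 1:
        return TwoModeParams(
            jd=float(p["jd"].value),
            a_fast=1.0,
            tau_fast=float(p["tau_fast"].value),
            s_fast=float(p["s_fast"].value),
            y0=float(p["y0"].value),
        )
    tau_fast = float(p["tau_fast"].value)
    tau_slow = float(p["tau_slow"].value)
    if a_fast < 1.0 and tau_slow <= tau_fast:  # ratio pinned at its bound of 1
        tau_slow = tau_fast * (1 + 1e-9)
    return TwoModeParams(
        jd=float(p["jd"].value),
        a_fast=a_fast,
        tau_fast=tau_fast,
        s_fast=float(p["s_fast"].value),
        tau_slow=tau_slow,
        s_slow=float(p["s_slow"].value),
        y0=float(p["y0"].value),
    )


def _residual(p: lmfit.Parameters, lag: np.ndarray, g2: np.ndarray, n_modes: int):
    params = _params_from_lmfit_unchecked(p, n_modes)
    fast = np.exp(-((lag / params["tau_fast"]) ** params["s_fast"]))
    if n_modes == 1:
        g1 = fast
    else:
        slow = np.exp(-((lag / params["tau_slow"]) ** params["s_slow"]))
        g1 = params["a_fast"] * fast + (1 - params["a_fast"]) * slow
    model = 1.0 + (params["jd"] * g1) ** 2 + params["y0"]
    return model - g2


def _params_from_lmfit_unchecked(p: lmfit.Parameters, n_modes: int) -> dict:
    out = {
        "jd": p["jd"].value,
        "a_fast": p["a_fast"].value,
        "tau_fast": p["tau_fast"].value,
        "s_fast": p["s_fast"].value,
        "y0": p["y0"].value,
    }
    if n_modes == 2:
        out["tau_slow"] = p["tau_slow"].value
        out["s_slow"] = p["s_slow"].value
    return out


def _single_fit(
    curve: CorrelationCurve,
    init: TwoModeParams,
    n_modes: int,
    stretch_bounds: tuple[float, float],
) -> FitResult:
    lag, g2 = curve.lag_times, curve.g2
    pars = _lmfit_parameters(init, n_modes, lag, stretch_bounds)
    with np.errstate(invalid="ignore"):  # lmfit's internal stderr step
        result = lmfit.minimize(
            _residual,
            pars,
            args=(lag, g2, n_modes),
            method="least_squares",
            calc_covar=False,
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=5000,
        )
    resid = _residual(result.params, lag, g2, n_modes)
    rms = float(np.sqrt(np.mean(resid**2)))
    return FitResult(
        params=_params_from_lmfit(result.params, n_modes),
        residual_rms=rms,
        converged=bool(result.success),
        n_modes_used=n_modes,
    )


def _perturbed_inits(
    init: TwoModeParams, n_starts: int, seed: int
) -> list[TwoModeParams]:
    rng = np.random.default_rng(seed)
    inits = [init]
    for _ in range(n_starts - 1):
        tau_f = init.tau_fast * math.exp(rng.normal(0.0, 0.7))
        ratio = (
            (init.tau_slow / init.tau_fast) if math.isfinite(init.tau_slow) else 100.0
        )
        ratio = max(2.0, ratio * math.exp(rng.normal(0.0, 0.7)))
        inits.append(
            replace(
                init,
                tau_fast=tau_f,
                tau_slow=tau_f * ratio,
                a_fast=float(np.clip(init.a_fast + rng.uniform(-0.25, 0.25), 0.05, 0.95)),
                s_fast=float(np.clip(init.s_fast + rng.uniform(-0.1, 0.05), 0.35, 1.0)),
            )
        )
    return inits


def fit_curve(
    curve: CorrelationCurve,
    n_modes: int | str = "auto",
    init: TwoModeParams | None = None,
    seed: int = 0,
    n_starts: int = 5,
    stretch_bounds: tuple[float, float] = STRETCH_BOUNDS,
) -> FitResult:
    """Fit the two-mode stretched-exponential model to one correlation curve.

    Parameters
    ----------
    curve
        Measured or simulated curve; needs at least 10 points spanning at
        least two decades of lag time.
    n_modes
        1, 2, or ``"auto"`` (default).  In auto mode a two-mode fit is
        attempted first; if it collapses (a_f -> 1 or tau_s/tau_f < 5) the
        curve is refit with a single mode and the simpler result is kept
        when its residual is not materially worse.
    init
        Optional starting parameters; defaults to :func:`default_init`.
    seed
        Seeds the deterministic multi-start perturbations; identical
        (curve, init, seed) always give an identical result.
    n_starts
        Number of multi-start attempts per mode count.
    stretch_bounds
        Box bounds on both stretch exponents during optimisation.

    Raises
    ------
    ValidationError
        Too few points, insufficient lag-time span, or no decay present.
    """
    if len(curve) < 10:
        raise ValidationError(f"need >= 10 points to fit, got {len(curve)}")
    lag = curve.lag_times
    positive = lag[lag > 0]
    if positive.size < 8 or positive[-1] / positive[0] < 100:
        raise ValidationError("lag times must span at least two decades")
    if len(curve) < 8:  # seven parameters + one dof
        raise ValidationError("fewer points than model parameters")
    if n_modes not in (1, 2, "auto"):
        raise ValidationError(f"n_modes must be 1, 2 or 'auto', got {n_modes!r}")
    if init is None:
        init = default_init(curve)

    def best_of(mode_count: int) -> FitResult:
        candidates = []
        for start in _perturbed_inits(init, n_starts, seed):
            try:
                candidates.append(_single_fit(curve, start, mode_count, stretch_bounds))
            except (ValueError, ValidationError):
                continue
        if not candidates:
            raise ComputationError("all fit starts failed")
        # smallest residual wins; near-ties go to the smaller tau_fast
        candidates.sort(key=lambda r: (round(r.residual_rms, 12), r.params.tau_fast))
        return candidates[0]

    if n_modes in (1, 2):
        return best_of(n_modes)

    two = best_of(2)
    tau_ratio = (
        two.params.tau_slow / two.params.tau_fast
        if math.isfinite(two.params.tau_slow)
        else math.inf
    )
    # collapsed: one mode absorbed the other (amplitude at either extreme)
    # or the two relaxation times are not separated
    collapsed = two.params.a_fast > 0.99 or two.params.a_fast < 0.1 or tau_ratio < 5
    if not collapsed:
        return two
    one = best_of(1)
    # accept the single-mode refit unless it is materially worse
    if one.residual_rms <= two.residual_rms * 1.10 + 1e-12:
        return one
    return two


def rate_points(
    curves: Sequence[CorrelationCurve], fits: Sequence[FitResult]
) -> list[RatePoint]:
    """Convert per-angle fits into (q^2, 1/tau_f) points, skipping failed fits."""
    if len(curves) != len(fits):
        raise ValidationError("curves and fits must have equal length")
    points = []
    for curve, fit in zip(curves, fits):
        if not fit.converged:
            continue
        q = curve.q
        points.append(
            RatePoint(
                q_squared=q * q,
                inverse_tau_f=1.0 / fit.params.tau_fast,
                angle_deg=curve.angle_deg,
            )
        )
    return points


def diffusion_from_rates(
    points: Sequence[RatePoint], through_origin: bool = False
) -> DiffusionFit:
    """Diffusion coefficient from ordinary least squares of 1/tau_f on q^2.

    For diffusive dynamics 1/tau = D*q^2, so the slope of the fitted line is
    D.  By default the intercept is free (robust to a constant rate offset);
    with ``through_origin=True`` it is constrained to zero.
    """
    n = len(points)
    needed = 2 if through_origin else 3
    if n < needed:
        raise ValidationError(
            f"need >= {needed} rate points "
            f"({'through-origin' if through_origin else 'free-intercept'} fit), got {n}"
        )
    x = np.array([p.q_squared for p in points])
    y = np.array([p.inverse_tau_f for p in points])
    if np.ptp(x) == 0:
        raise ValidationError("single-angle data; cannot regress 1/tau on q^2")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        dof = max(n - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / np.sum(x * x)))
        ss_tot = float(np.sum(y**2))  # uncentered: the model has no mean term
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        intercept = 0.0
    else:
        reg = stats.linregress(x, y)
        slope, intercept, stderr = float(reg.slope), float(reg.intercept), float(
            reg.stderr
        )
        r2 = float(reg.rvalue**2)
    if not slope > 0:
        raise ComputationError(
            f"non-physical fit: slope (D) = {slope:.3g} m^2/s is not positive"
        )
    return DiffusionFit(
        D=slope,
        D_stderr=stderr,
        intercept=intercept,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=n,
        through_origin=through_origin,
    )


def average_stretch(fits: Iterable[FitResult]) -> StretchSummary:
    """Arithmetic mean and standard error of the fast-mode stretch exponent.

    Only converged fits contribute.  For monodisperse scatterers the
    expected value is 1; smaller values indicate a distribution of
    relaxation times (polydispersity).
    """
    s = np.array([f.params.s_fast for f in fits if f.converged])
    if s.size == 0:
        raise ValidationError("no converged fits to average")
    sem = float(np.std(s, ddof=1) / math.sqrt(s.size)) if s.size > 1 else 0.0
    return StretchSummary(s_mean=float(np.mean(s)), s_sem=sem, n_angles=int(s.size))


def fit_time_series(
    series: Iterable[tuple[float, Sequence[CorrelationCurve]]],
    seed: int = 0,
    through_origin: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every time point of a post-denaturation series.

    ``series`` is an iterable of ``(elapsed_time, curves)`` pairs, each
    time point carrying curves at two or more angles.  Per time point the
    full chain fit_curve -> diffusion_from_rates is applied.  Failed time
    points are flagged in the ``ok``/``message`` columns, never dropped.

    Returns a DataFrame sorted by time with columns
    ``time, D, D_stderr, intercept, r_squared, s_mean, n_angles, ok, message``.
    """
    rows = []
    for time, curves in series:
        row = {
            "time": float(time),
            "D": np.nan,
            "D_stderr": np.nan,
            "intercept": np.nan,
            "r_squared": np.nan,
            "s_mean": np.nan,
            "n_angles": len(curves),
            "ok": False,
            "message": "",
        }
        try:
            if len(curves) < 2:
                raise ValidationError("need curves at >= 2 angles per time point")
            fits = [fit_curve(c, seed=seed, **fit_kwargs) for c in curves]
            dfit = diffusion_from_rates(
                rate_points(curves, fits), through_origin=through_origin
            )
            summary = average_stretch(fits)
            row.update(
                D=dfit.D,
                D_stderr=dfit.D_stderr,
                intercept=dfit.intercept,
                r_squared=dfit.r_squared,
                s_mean=summary.s_mean,
                ok=True,
            )
        except (ValidationError, ComputationError) as exc:
            row["message"] = str(exc)
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=[
            "time",
            "D",
            "D_stderr",
            "intercept",
            "r_squared",
            "s_mean",
            "n_angles",
            "ok",
            "message",
        ],
    )
    return frame.sort_values("time", kind="stable").reset_index(drop=True)
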