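"""Gamma-kernel cortisol response-curve mathematics.

The structural model of the acute cortisol stress response is a scaled
gamma probability density plus a baseline,

    g(t) = A * f(t - dT) + b0 + b1 * (t - dT),

where ``f`` is the gamma density with shape ``alpha`` and rate ``beta``
(both per minute on the time axis), ``A`` scales the magnitude of the
response (nmol/L*min), ``b0`` is the pre-stressor baseline cortisol
level (nmol/L), ``b1`` allows a slow linear drift mirroring the diurnal
decline (nmol/L per min) and ``dT`` shifts the onset of the response
(min).  Time is always expressed in real-valued minutes relative to
stressor onset.

The density is defined as 0 for ``t - dT <= 0``: the response begins at
the (possibly shifted) stressor onset, before which the curve reduces to
the baseline-plus-drift line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FlatCurveError, ParameterDomainError

__all__ = [
    "GammaKernelParams",
    "ResponseCurveParams",
    "TimeGrid",
    "gamma_density",
    "evaluate_curve",
    "curve_peak",
    "analytic_auc",
]


@dataclass(frozen=True)
class GammaKernelParams:
    """Shape/rate pair of the gamma kernel. ``alpha`` unitless, ``beta`` 1/min."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ParameterDomainError(f"alpha must be positive, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ParameterDomainError(f"beta must be positive, got {self.beta}")

    @property
    def mode(self) -> float:
        """Location of the density maximum, (alpha - 1) / beta, for alpha > 1."""
        if self.alpha <= 1:
            return 0.0
        return (self.alpha - 1.0) / self.beta


@dataclass(frozen=True)
class ResponseCurveParams:
    """Full six-parameter description of one cortisol response curve."""

    kernel: GammaKernelParams
    A: float
    b0: float
    b1: float = 0.0
    dT: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A", "b0", "b1", "dT"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterDomainError(f"{name} must be finite")


@dataclass(frozen=True)
class TimeGrid:
    """Regular grid of times (min, relative to stressor onset), endpoints included."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ParameterDomainError("start must be <= stop")
        if self.step <= 0:
            raise ParameterDomainError("step must be positive")

    def times(self) -> np.ndarray:
        # include the stop endpoint whenever (stop - start) is an integer
        # multiple of step (up to floating tolerance)
        return np.arange(self.start, self.stop + 0.5 * self.step, self.step)


def gamma_density(x, kernel: GammaKernelParams):
    """Gamma probability density f(x; alpha, beta), 0 for x <= 0.

    Vectorized over ``x``; scalar input returns a scalar.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        stats.gamma.pdf(np.where(x > 0, x, 1.0), a=kernel.alpha, scale=1.0 / kernel.beta),
        0.0,
    )
    if out.ndim == 0:
        return float(out)
    return out


def evaluate_curve(params: ResponseCurveParams, grid) -> np.ndarray:
    """Evaluate g(t) = A f(t - dT) + b0 + b1 (t - dT) on a grid.

    ``grid`` may be a :class:`TimeGrid` or any array of times in minutes.
    """
    if isinstance(grid, TimeGrid):
        t = grid.times()
    else:
        t = np.asarray(grid, dtype=float)
    if t.size == 0:
        return np.empty(0)
    x = t - params.dT
    return params.A * gamma_density(x, params.kernel) + params.b0 + params.b1 * x


def curve_peak(
    params: ResponseCurveParams,
    window: tuple[float, float] = (0.0, 80.0),
    step: float = 0.1,
) -> tuple[float, float]:
    """Argmax of the curve over ``window`` on a fine grid.

    Returns ``(t_peak, value)``; ties resolve to the earliest time.  For a
    pure response (b1 = 0, dT = 0, alpha > 1) this coincides with the
    gamma mode (alpha - 1) / beta.  A flat curve (A = 0 and b1 = 0) has no
    peak and raises :class:`FlatCurveError`.
    """
    if params.A == 0 and params.b1 == 0:
        raise FlatCurveError("curve is constant; no peak is defined")
    t = TimeGrid(window[0], window[1], step).times()
    values = evaluate_curve(params, t)
    i = int(np.argmax(values))  # argmax returns the first maximizer
    return float(t[i]), float(values[i])


def analytic_auc(params: ResponseCurveParams, window: tuple[float, float]) -> float:
    """Closed-form integral of the curve over ``window = (t0, t1)`` in nmol/L*min.

    Uses the gamma CDF F:  A [F(t1-dT) - F(t0-dT)] + b0 (t1-t0)
    + b1 [(t1-dT)^2 - (t0-dT)^2] / 2, with F clipped to 0 below the
    (shifted) onset where the density has no mass.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ParameterDomainError(f"degenerate window {window}")
    k = params.kernel
    x0, x1 = t0 - params.dT, t1 - params.dT
    F0 = stats.gamma.cdf(max(x0, 0.0), a=k.alpha, scale=1.0 / k.beta)
    F1 = stats.gamma.cdf(max(x1, 0.0), a=k.alpha, scale=1.0 / k.beta)
    return (
        params.A * (F1 - F0)
        + params.b0 * (t1 - t0)
        + params.b1 * (x1**2 - x0**2) / 2.0
    )
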