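"""Cortisol stress-response summary indicators.

Four indicators summarize one response: area under the curve with
respect to ground (AUCg, total output) and with respect to increase
(AUCi, change from baseline), reactivity (cortisol at the expected peak
minus baseline) and maximum increase (largest positive excursion above
baseline, non-negative by definition).

Each comes in an observation-based (OBS) flavour computed directly from
the raw samples, and a model-based flavour computed from a fitted curve
evaluated on a common 1-min grid over [0, 80] min — which makes the
model-based indicators independent of the sampling schedule that
produced the fit.  "True" indicators apply the same formulas to a
high-resolution simulated trajectory without measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve import ResponseCurveParams, TimeGrid, evaluate_curve, gamma_density
from .errors import ValidationError
from .preprocess import ParticipantSeries

__all__ = [
    "IndicatorSet",
    "NOMINAL_PEAK_TIME",
    "auc_obs",
    "reactivity_obs",
    "max_increase_obs",
    "indicators_obs",
    "indicators_model_based",
    "true_indicators",
]

#: Default expected peak timing for observation-based reactivity:
#: the midpoint of the 15-45 min responder window.
NOMINAL_PEAK_TIME = 25.0

METHODS = ("OBS", "OBS_s", "MM", "ASM", "TRUE")


@dataclass(frozen=True)
class IndicatorSet:
    """The four summary indicators for one participant under one method."""

    AUCg: float
    AUCi: float
    reactivity: float
    max_increase: float
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.max_increase < 0:
            raise ValidationError("max_increase is non-negative by definition")


def _as_arrays(samples):
    if isinstance(samples, ParticipantSeries):
        return samples.times_array(), samples.cortisol_array()
    t, c = samples
    return np.asarray(t, dtype=float), np.asarray(c, dtype=float)


def auc_obs(samples, with_respect_to: str = "ground") -> float:
    """Trapezoidal AUC of raw samples (nmol/L*min).

    ``ground``: sum of trapezoids between consecutive samples.
    ``increase``: the same minus the rectangle first-value x span,
    i.e. the area of change relative to the first (baseline) sample.
    """
    t, c = _as_arrays(samples)
    if t.size < 2:
        raise ValidationError("AUC needs at least 2 time-ordered samples")
    aucg = float(np.trapezoid(c, t))
    if with_respect_to == "ground":
        return aucg
    if with_respect_to == "increase":
        return aucg - float(c[0]) * float(t[-1] - t[0])
    raise ValidationError(f"with_respect_to must be 'ground' or 'increase'")


def reactivity_obs(
    samples, peak_time: float = NOMINAL_PEAK_TIME, interpolate: bool = False
) -> float:
    """Cortisol near the expected peak minus the t = 0 baseline.

    By default the single post-baseline sample nearest to ``peak_time``
    is used (ties resolve to the earlier sample); with
    ``interpolate=True`` the value is linearly interpolated between the
    two samples bracketing ``peak_time``.
    """
    t, c = _as_arrays(samples)
    base_idx = np.nonzero(t == 0.0)[0]
    if base_idx.size == 0:
        raise ValidationError("reactivity needs a t = 0 baseline sample")
    baseline = float(c[base_idx[0]])
    post = t > 0
    if not post.any():
        raise ValidationError("reactivity needs at least one post-baseline sample")
    tp, cp = t[post], c[post]
    if interpolate:
        value = float(np.interp(peak_time, tp, cp))
    else:
        dist = np.abs(tp - peak_time)
        value = float(cp[int(np.argmin(dist))])  # argmin -> earliest on ties
    return value - baseline


def max_increase_obs(samples) -> float:
    """Largest rise above baseline across all samples; >= 0 (baseline included)."""
    t, c = _as_arrays(samples)
    base_idx = np.nonzero(t == 0.0)[0]
    if base_idx.size == 0:
        raise ValidationError("max increase needs a t = 0 baseline sample")
    baseline = float(c[base_idx[0]])
    return float(c.max() - baseline)


def indicators_obs(
    samples, peak_time: float = NOMINAL_PEAK_TIME, method: str = "OBS"
) -> IndicatorSet:
    """All four observation-based indicators for one series."""
    return IndicatorSet(
        AUCg=auc_obs(samples, "ground"),
        AUCi=auc_obs(samples, "increase"),
        reactivity=reactivity_obs(samples, peak_time),
        max_increase=max_increase_obs(samples),
        method=method,
    )


def _structural_peak_time(curve: ResponseCurveParams, times: np.ndarray) -> float:
    """Peak location of the response deviation A f(t - dT).

    Defined through |A f| so that declining profiles (A < 0) peak where
    the response magnitude does, keeping reactivity proportional to A.
    Flat responses (A = 0) fall back to t = 0.
    """
    if curve.A == 0:
        return float(times[0])
    dev = np.abs(curve.A) * gamma_density(times - curve.dT, curve.kernel)
    return float(times[int(np.argmax(dev))])


def indicators_model_based(
    curve: ResponseCurveParams,
    window: tuple[float, float] = (0.0, 80.0),
    step: float = 1.0,
    method: str = "MM",
) -> IndicatorSet:
    """Indicators from a fitted curve on the common grid over ``window``.

    The baseline is the fitted curve's own value at t = 0 (for the
    amplitude scaling model this equals the observed baseline by
    construction).  Reactivity is the curve at the structural peak minus
    baseline, so a declining curve yields negative reactivity; maximum
    increase is clipped at 0.  A flat curve gives reactivity 0 and
    maximum increase 0 rather than an error.
    """
    t = TimeGrid(window[0], window[1], step).times()
    values = evaluate_curve(curve, t)
    c0 = float(evaluate_curve(curve, np.array([window[0]]))[0])
    aucg = float(np.trapezoid(values, t))
    auci = aucg - c0 * float(window[1] - window[0])
    t_peak = _structural_peak_time(curve, t)
    reactivity = float(evaluate_curve(curve, np.array([t_peak]))[0]) - c0
    max_inc = max(0.0, float(values.max()) - c0)
    return IndicatorSet(aucg, auci, reactivity, max_inc, method)


def true_indicators(times, values, window: tuple[float, float] = (0.0, 80.0)) -> IndicatorSet:
    """"True" indicators from a 1-min trajectory covering ``window``.

    Applied to simulated trajectories carrying synthesis (red) noise but
    no measurement noise.  Reactivity uses the trajectory's own argmax
    as the peak location (earliest on ties).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=float)
    mask = (t >= window[0]) & (t <= window[1])
    t, c = t[mask], c[mask]
    expected = TimeGrid(window[0], window[1], 1.0).times()
    if t.size != expected.size or not np.allclose(t, expected):
        raise ValidationError(
            f"true indicators need full 1-min coverage of [{window[0]}, {window[1]}]"
        )
    c0 = float(c[0])
    aucg = float(np.trapezoid(c, t))
    auci = aucg - c0 * float(window[1] - window[0])
    peak = float(c.max())
    reactivity = peak - c0
    return IndicatorSet(aucg, auci, reactivity, max(0.0, peak - c0), "TRUE")
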