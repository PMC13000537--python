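"""Amplitude scaling model (ASM).

The ASM assumes every individual shares the *shape* of the population
average cortisol stress response and differs only in amplitude.  The
population curve g(t) = A_pop f(t; alpha, beta) + b0_pop is estimated by
nonlinear least squares on pooled data from stress-condition responders,
with the baseline b0_pop fixed to the mean observed cortisol at t = 0
rather than freely estimated.  Whether the time-shift dT and drift b1
terms earn their keep is decided by BIC; individual curves are then
obtained by re-estimating only the amplitude:

1. normalize each participant's values by subtracting their observed
   baseline cortisol,
2. scale the unit-amplitude population shape to the normalized data by
   ordinary least squares (closed form A_i = sum y_j f(t_j) / sum f(t_j)^2),
3. shift the scaled curve back up by the observed baseline.

A_i is unconstrained in sign so that declining control/non-responder
profiles are representable (their expected amplitude is zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .curve import GammaKernelParams, ResponseCurveParams, evaluate_curve, gamma_density
from .errors import ConvergenceError, ValidationError
from .preprocess import ParticipantSeries

__all__ = [
    "PopulationCurve",
    "IndividualAmplitudeFit",
    "AmplitudeScalingModel",
    "fit_population_curve",
    "select_population_model",
    "fit_individual_amplitude",
]


@dataclass(frozen=True)
class PopulationCurve:
    """Fitted population-average responder curve (b0 fixed, not estimated)."""

    kernel: GammaKernelParams
    A_pop: float
    b0_pop: float
    b1: float = 0.0
    dT: float = 0.0
    fit_diagnostics: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def params(self) -> ResponseCurveParams:
        return ResponseCurveParams(self.kernel, self.A_pop, self.b0_pop, self.b1, self.dT)

    def shape_at(self, times) -> np.ndarray:
        """Unit-amplitude population shape f(t - dT) at the given times."""
        return gamma_density(np.asarray(times, dtype=float) - self.dT, self.kernel)

    def to_dict(self) -> dict:
        return {
            "alpha": self.kernel.alpha,
            "beta": self.kernel.beta,
            "A_pop": self.A_pop,
            "b0_pop": self.b0_pop,
            "b1": self.b1,
            "dT": self.dT,
        }

    def to_json(self, path, **metadata) -> None:
        doc = {"population_curve": self.to_dict(), "provenance": metadata}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationCurve":
        return cls(
            GammaKernelParams(d["alpha"], d["beta"]),
            d["A_pop"],
            d["b0_pop"],
            d.get("b1", 0.0),
            d.get("dT", 0.0),
        )

    @classmethod
    def from_json(cls, path) -> "PopulationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh)["population_curve"])


@dataclass(frozen=True)
class IndividualAmplitudeFit:
    """Per-participant amplitude-scaled curve."""

    participant_id: str
    A_i: float
    baseline_obs: float
    curve: ResponseCurveParams


def _pool(data: Iterable[ParticipantSeries]):
    times, values, baselines = [], [], []
    for s in data:
        times.append(s.times_array())
        values.append(s.cortisol_array())
        baselines.append(s.baseline())
    if not times:
        raise ValidationError("no series to fit")
    return np.concatenate(times), np.concatenate(values), float(np.mean(baselines))


def fit_population_curve(
    responder_data: Iterable[ParticipantSeries],
    include_shift_drift: bool = False,
    init: dict | None = None,
) -> PopulationCurve:
    """Pooled nonlinear least-squares fit of the population average curve.

    ``responder_data`` should contain baseline-corrected stress-condition
    responders only.  b0 is fixed to the mean baseline cortisol of the
    sample; alpha, beta and A are estimated (plus dT and b1 when
    ``include_shift_drift``).
    """
    responder_data = list(responder_data)
    t, y, b0_pop = _pool(responder_data)

    init = dict(init or {})
    params = lmfit.Parameters()
    params.add("alpha", value=init.get("alpha", 3.0), min=1e-3)
    params.add("beta", value=init.get("beta", 0.1), min=1e-5)
    params.add("A", value=init.get("A", max(1.0, 10.0 * (y.max() - b0_pop))))
    params.add("dT", value=init.get("dT", 0.0), vary=include_shift_drift)
    params.add("b1", value=init.get("b1", 0.0), vary=include_shift_drift)

    def residual(p):
        kernel = GammaKernelParams(p["alpha"].value, p["beta"].value)
        x = t - p["dT"].value
        pred = p["A"].value * gamma_density(x, kernel) + b0_pop + p["b1"].value * x
        return pred - y

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise ConvergenceError(
            f"population curve fit did not converge: {result.message}",
            diagnostics={"residual_norm": float(np.sum(result.residual**2))},
        )
    p = result.params
    pop = PopulationCurve(
        GammaKernelParams(p["alpha"].value, p["beta"].value),
        float(p["A"].value),
        b0_pop,
        b1=float(p["b1"].value),
        dT=float(p["dT"].value),
    )
    diag = _per_participant_diagnostics(responder_data, pop)
    return PopulationCurve(pop.kernel, pop.A_pop, pop.b0_pop, pop.b1, pop.dT, diag)


def _per_participant_diagnostics(
    data: Sequence[ParticipantSeries], pop: PopulationCurve
) -> pd.DataFrame:
    rows = []
    for s in data:
        pred = evaluate_curve(pop.params, s.times_array())
        err = s.cortisol_array() - pred
        rows.append(
            {"participant_id": s.participant_id, "mae": float(np.abs(err).mean()),
             "bias": float(err.mean())}
        )
    return pd.DataFrame(rows)


def _gaussian_bic(rss: float, n_obs: int, k: int) -> float:
    # k * ln(N) - 2 lnL with the profiled Gaussian likelihood
    sigma2 = rss / n_obs
    loglik = -0.5 * n_obs * (np.log(2 * np.pi * sigma2) + 1.0)
    return k * np.log(n_obs) - 2.0 * loglik


def select_population_model(responder_data: Iterable[ParticipantSeries]) -> dict:
    """Compare the 4-parameter and extended (dT, b1) population curves by BIC.

    Returns a report with both fits, their BICs and the selected variant;
    ties within 1e-9 resolve to the simpler model.
    """
    responder_data = list(responder_data)
    t, y, _ = _pool(responder_data)
    n = t.size
    fits, bics = {}, {}
    for label, extended in (("basic", False), ("extended", True)):
        pop = fit_population_curve(responder_data, include_shift_drift=extended)
        rss = float(np.sum((evaluate_curve(pop.params, t) - y) ** 2))
        k = 5 if extended else 3  # b0 fixed in both variants
        fits[label] = pop
        bics[label] = _gaussian_bic(rss, n, k)
    selected = "basic" if bics["basic"] <= bics["extended"] + 1e-9 else "extended"
    return {"selected": selected, "bic": bics, "fits": fits}


def fit_individual_amplitude(
    series: ParticipantSeries, pop: PopulationCurve
) -> IndividualAmplitudeFit:
    """Re-estimate only the amplitude of the population shape for one series.

    The baseline sample is excluded from the loss (its normalized value
    is 0 and the shape is ~0 at t = 0 for alpha > 1).
    """
    baseline = series.baseline()
    t = series.times_array()
    y = series.cortisol_array()
    mask = t > 0
    if not mask.any():
        raise ValidationError(
            f"{series.participant_id}: no post-baseline sample to scale against"
        )
    f = pop.shape_at(t[mask])
    denom = float(np.sum(f**2))
    if denom == 0:
        raise ValidationError(
            f"{series.participant_id}: population shape is 0 at all sampled times"
        )
    A_i = float(np.sum((y[mask] - baseline) * f) / denom)
    curve = ResponseCurveParams(pop.kernel, A_i, baseline, 0.0, pop.dT)
    return IndividualAmplitudeFit(series.participant_id, A_i, baseline, curve)


class AmplitudeScalingModel(BaseEstimator):
    """Scikit-learn style estimator for the amplitude scaling model.

    Parameters
    ----------
    select_by_bic : bool
        When True, BIC decides between the 4-parameter curve and the
        extended variant with dT and b1; when False the 4-parameter
        curve is always used.
    responder_threshold, responder_window : float, (float, float)
        Responder rule applied to restrict the population fit to
        stress-condition responders.

    After :meth:`fit`: ``population_curve_`` (:class:`PopulationCurve`),
    ``bic_``, ``n_responders_``, ``fit_diagnostics_``.
    """

    def __init__(
        self,
        select_by_bic: bool = True,
        responder_threshold: float = 1.5,
        responder_window: tuple[float, float] = (15.0, 45.0),
    ):
        self.select_by_bic = select_by_bic
        self.responder_threshold = responder_threshold
        self.responder_window = responder_window

    def fit(self, X: Sequence[ParticipantSeries], y=None) -> "AmplitudeScalingModel":
        """Fit the population curve on stress-condition responders in ``X``."""
        from .preprocess import classify_responder
        from .errors import UnclassifiableResponderError

        responders = []
        for s in X:
            if s.condition != "stress":
                continue
            try:
                if classify_responder(s, self.responder_threshold, self.responder_window):
                    responders.append(s)
            except UnclassifiableResponderError:
                continue
        if not responders:
            raise ValidationError("no classifiable stress-condition responders in input")
        self.n_responders_ = len(responders)
        if self.select_by_bic:
            report = select_population_model(responders)
            self.population_curve_ = report["fits"][report["selected"]]
            self.bic_ = report["bic"][report["selected"]]
            self.model_selection_ = report
        else:
            self.population_curve_ = fit_population_curve(responders)
            t, yv, _ = _pool(responders)
            rss = float(np.sum((evaluate_curve(self.population_curve_.params, t) - yv) ** 2))
            self.bic_ = _gaussian_bic(rss, t.size, 3)
        self.fit_diagnostics_ = self.population_curve_.fit_diagnostics
        return self

    def fit_individual(self, series: ParticipantSeries) -> IndividualAmplitudeFit:
        self._check_fitted()
        return fit_individual_amplitude(series, self.population_curve_)

    def transform(self, X: Sequence[ParticipantSeries]) -> pd.DataFrame:
        """Per-participant amplitudes and baselines as a tidy frame."""
        self._check_fitted()
        rows = []
        for s in X:
            f = self.fit_individual(s)
            rows.append(
                {"participant_id": f.participant_id, "A_i": f.A_i,
                 "baseline_obs": f.baseline_obs}
            )
        return pd.DataFrame(rows)

    def predict(self, series: ParticipantSeries, times=None) -> np.ndarray:
        """Predicted cortisol for one series at its own (or given) times."""
        fit = self.fit_individual(series)
        t = series.times_array() if times is None else np.asarray(times, dtype=float)
        return evaluate_curve(fit.curve, t)

    def _check_fitted(self) -> None:
        if not hasattr(self, "population_curve_"):
            raise ValidationError("AmplitudeScalingModel is not fitted yet; call fit first")
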