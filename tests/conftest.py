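"""Shared fixtures: small synthetic series and cohorts, built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from corticurve.curve import GammaKernelParams, ResponseCurveParams, evaluate_curve
from corticurve.preprocess import ParticipantSeries
from corticurve.simulate import SimConfig, simulate_cohort


def make_series(
    times,
    cortisol,
    participant_id="p0",
    study_id="s0",
    condition="stress",
    gender="F",
    test_type="TSST",
    age=None,
):
    return ParticipantSeries(
        participant_id=participant_id,
        study_id=study_id,
        condition=condition,
        gender=gender,
        test_type=test_type,
        age=age,
        times=tuple(float(t) for t in times),
        cortisol=tuple(float(c) for c in cortisol),
    )


def series_from_curve(params: ResponseCurveParams, times, noise_sd=0.0, rng=None,
                      **kwargs) -> ParticipantSeries:
    t = np.asarray(times, dtype=float)
    y = evaluate_curve(params, t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.size)
    return make_series(t, np.maximum(y, 0.01), **kwargs)


def hierarchical_cohort(
    seed,
    n=60,
    times=(0.0, 15.0, 25.0, 40.0, 60.0, 80.0),
    noise_sd=0.8,
    mu=(np.log(3.0), np.log(0.09), np.log(250.0), 5.5),
    sd=(0.2, 0.15, 0.4, 1.0),
):
    """Series drawn from the hierarchical gamma-curve model itself."""
    rng = np.random.default_rng(seed)
    series, truths = [], []
    for i in range(n):
        a = float(np.exp(mu[0] + rng.normal(0, sd[0])))
        b = float(np.exp(mu[1] + rng.normal(0, sd[1])))
        A = float(np.exp(mu[2] + rng.normal(0, sd[2])))
        b0 = float(mu[3] + rng.normal(0, sd[3]))
        p = ResponseCurveParams(GammaKernelParams(a, b), A, b0)
        truths.append(p)
        series.append(
            series_from_curve(p, times, noise_sd, rng, participant_id=f"p{i}")
        )
    return series, truths


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort shared by read-only tests (do not mutate)."""
    return simulate_cohort(SimConfig(n_individuals=200, seed=42))


@pytest.fixture(scope="session")
def responder_training_data():
    """Dense-schedule training dataset for population-curve fits."""
    from corticurve.simulate import downsample

    cohort = simulate_cohort(SimConfig(n_individuals=250, seed=77))
    dense = tuple(float(x) for x in range(0, 81, 10))
    return [downsample(ind, dense) for ind in cohort]
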