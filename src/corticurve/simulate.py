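"""Stochastic cohort simulator for acute stress test cortisol data.

Each virtual individual gets a structural gamma-shaped response curve
g(t) with parameters drawn from population distributions, around which
cortisol synthesis fluctuates as red noise: a mean-zero
Ornstein-Uhlenbeck deviation process D,

    X(t) = g(t) + D(t),    dD = -theta_red D dt + sigma_red dW,

integrated with the Euler-Maruyama method on a 1-min grid from -20 to
80 min relative to stressor onset, D(t_start) = 0 (the 20-min lead-in
lets the red noise approach its stationary SD
sigma_red / sqrt(2 theta_red) before t = 0).  Centring the OU process
on the curve rather than relaxing toward it keeps the cohort mean equal
to the structural response and makes the noise-free limit exact.  Independent white
measurement noise N(0, sigma_white^2) is added on top to produce the
observed trajectory.  The red-noise trajectory without white noise is
what "true" indicator values are computed from.

High-resolution trajectories are then downsampled to realistic sparse
sampling schedules; schedule sets varying a single factor (duration,
frequency, peak timepoint), a representative 12-schedule set and a
5-schedule high-variability set support the combined-data evaluations.

Default population distributions place the population-mean response
peak near 22 min post onset, roughly 6 nmol/L above a ~5.5 nmol/L
baseline, with a 20% non-responder fraction whose amplitude scatters
around zero (so declining profiles occur).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curve import GammaKernelParams, ResponseCurveParams, evaluate_curve
from .errors import ParameterDomainError, ValidationError
from .preprocess import ParticipantSeries

__all__ = [
    "SimNoiseParams",
    "PopulationDistributions",
    "SimConfig",
    "SimulatedIndividual",
    "SimulatedCohort",
    "SamplingSchedule",
    "ScheduleSet",
    "JITTER_TEMPLATES",
    "simulate_cohort",
    "downsample",
    "build_combined_dataset",
    "jitter_schedules",
    "default_schedule_sets",
]


@dataclass(frozen=True)
class SimNoiseParams:
    """Noise structure: white measurement error + red synthesis noise."""

    sigma_white: float = 0.5   # nmol/L, measurement noise SD
    theta_red: float = 0.05    # 1/min, mean-reversion rate of the OU process
    sigma_red: float = 0.3     # nmol/L/sqrt(min), OU diffusion scale

    def __post_init__(self) -> None:
        if min(self.sigma_white, self.theta_red, self.sigma_red) < 0:
            raise ParameterDomainError("noise parameters must be non-negative")
        if self.sigma_red > 0 and self.theta_red <= 0:
            raise ParameterDomainError("theta_red must be > 0 when sigma_red > 0")

    @property
    def red_stationary_sd(self) -> float:
        """Stationary SD sigma_red / sqrt(2 theta_red) of the OU deviation."""
        if self.sigma_red == 0:
            return 0.0
        return self.sigma_red / np.sqrt(2.0 * self.theta_red)


@dataclass(frozen=True)
class PopulationDistributions:
    """Independent per-individual parameter distributions.

    alpha, beta and responder amplitudes are log-normal (parameters on
    the log scale); baselines are normal, truncated below at
    ``b0_floor``.  A ``nonresponder_fraction`` of individuals instead
    draws its amplitude from N(0, nonresponder_A_sd^2), covering flat
    and declining profiles.
    """

    log_alpha_mean: float = float(np.log(3.0))
    log_alpha_sd: float = 0.25
    log_beta_mean: float = float(np.log(0.09))
    log_beta_sd: float = 0.20
    log_A_mean: float = float(np.log(240.0))
    log_A_sd: float = 0.60
    b0_mean: float = 5.5
    b0_sd: float = 1.5
    b0_floor: float = 1.0
    nonresponder_fraction: float = 0.2
    nonresponder_A_sd: float = 15.0

    def __post_init__(self) -> None:
        for name in ("log_alpha_sd", "log_beta_sd", "log_A_sd", "b0_sd",
                     "nonresponder_A_sd"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be non-negative")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ParameterDomainError("nonresponder_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated cohort."""

    n_individuals: int = 500
    female_fraction: float = 0.5
    t_start: float = -20.0
    t_stop: float = 80.0
    dt: float = 1.0
    population: PopulationDistributions = field(default_factory=PopulationDistributions)
    noise: SimNoiseParams = field(default_factory=SimNoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ParameterDomainError("n_individuals must be >= 1")
        if self.dt <= 0:
            raise ParameterDomainError("dt must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ParameterDomainError("female_fraction must be in [0, 1]")

    def grid(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop + 0.5 * self.dt, self.dt)


@dataclass(frozen=True)
class SimulatedIndividual:
    """True curve plus red and observed trajectories on the shared grid."""

    id: str
    params: ResponseCurveParams
    gender: str
    times: np.ndarray
    red: np.ndarray
    observed: np.ndarray


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimConfig
    individuals: tuple[SimulatedIndividual, ...]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a cohort and integrate its trajectories (reproducible by seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    pop = config.population

    alpha = np.exp(rng.normal(pop.log_alpha_mean, pop.log_alpha_sd, n))
    beta = np.exp(rng.normal(pop.log_beta_mean, pop.log_beta_sd, n))
    A = np.exp(rng.normal(pop.log_A_mean, pop.log_A_sd, n))
    nonresp = rng.random(n) < pop.nonresponder_fraction
    A[nonresp] = rng.normal(0.0, pop.nonresponder_A_sd, int(nonresp.sum()))
    b0 = np.maximum(rng.normal(pop.b0_mean, pop.b0_sd, n), pop.b0_floor)
    female = rng.random(n) < config.female_fraction

    t = config.grid()
    params = [
        ResponseCurveParams(GammaKernelParams(alpha[i], beta[i]), A[i], b0[i])
        for i in range(n)
    ]
    G = np.stack([evaluate_curve(p, t) for p in params])  # (n, T) structural curves

    # Euler-Maruyama integration of the OU deviation process, vectorized
    noise = config.noise
    dt = config.dt
    D = np.zeros_like(G)
    if noise.sigma_red > 0:
        dW = rng.normal(0.0, np.sqrt(dt), size=(n, t.size - 1))
        for k in range(t.size - 1):
            D[:, k + 1] = (
                D[:, k] - noise.theta_red * D[:, k] * dt + noise.sigma_red * dW[:, k]
            )
    X = G + D

    white = rng.normal(0.0, noise.sigma_white, size=X.shape) if noise.sigma_white > 0 \
        else np.zeros_like(X)
    observed = X + white

    individuals = tuple(
        SimulatedIndividual(
            id=f"sim{i:05d}",
            params=params[i],
            gender="F" if female[i] else "M",
            times=t,
            red=X[i],
            observed=observed[i],
        )
        for i in range(n)
    )
    return SimulatedCohort(config=config, individuals=individuals)


# ---------------------------------------------------------------------------
# sampling schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered measurement timepoints, first = 0 (baseline), all in [0, 80]."""

    id: str
    timepoints: tuple[float, ...]
    min_duration: float = 30.0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2:
            raise ValidationError(f"schedule {self.id}: needs >= 2 timepoints")
        if tp[0] != 0.0:
            raise ValidationError(f"schedule {self.id}: first timepoint must be 0")
        if not np.all(np.diff(tp) > 0):
            raise ValidationError(f"schedule {self.id}: timepoints must strictly increase")
        if tp[-1] > 80.0 or tp.min() < 0.0:
            raise ValidationError(f"schedule {self.id}: timepoints must lie in [0, 80]")
        if tp[-1] < self.min_duration:
            raise ValidationError(
                f"schedule {self.id}: duration {tp[-1]} below minimum {self.min_duration}"
            )

    @property
    def duration(self) -> float:
        return float(self.timepoints[-1])


@dataclass(frozen=True)
class ScheduleSet:
    """Schedules varying one declared factor (or a mixed realistic set)."""

    factor: str
    schedules: tuple[SamplingSchedule, ...]

    _FACTORS = ("duration", "frequency", "peak_timepoint", "representative",
                "high_variability")

    def __post_init__(self) -> None:
        if self.factor not in self._FACTORS:
            raise ValidationError(f"unknown schedule-set factor {self.factor!r}")
        if not self.schedules:
            raise ValidationError("schedule set may not be empty")


def default_schedule_sets() -> dict[str, ScheduleSet]:
    """Shipped schedule sets honoring the single-factor constraints.

    ``duration``: shared early timepoints, last point 40/60/80 min.
    ``frequency``/``frequency_dense``: same 0-80 span, 3-9 samples.
    ``peak_*``: peak sample at 15/25/35 min with late recovery, early
    recovery, or no recovery samples.  ``representative``: 12 mixed
    schedules; ``high_variability``: 5 schedules including the very
    sparse [0, 30].
    """
    S = SamplingSchedule

    def sched(prefix, i, tp, min_duration=30.0):
        return S(f"{prefix}{i}", tuple(float(x) for x in tp), min_duration)

    duration = ScheduleSet(
        "duration",
        tuple(
            sched("dur", i, tp)
            for i, tp in enumerate(
                [(0, 10, 20, 30, 40), (0, 10, 20, 30, 40, 50, 60),
                 (0, 10, 20, 30, 40, 50, 60, 70, 80)], 1)
        ),
    )
    frequency = ScheduleSet(
        "frequency",
        tuple(
            sched("freq", i, tp)
            for i, tp in enumerate(
                [(0, 40, 80), (0, 25, 55, 80), (0, 20, 40, 60, 80)], 1)
        ),
    )
    frequency_dense = ScheduleSet(
        "frequency",
        tuple(
            sched("freqd", i, tp)
            for i, tp in enumerate(
                [(0, 15, 30, 45, 60, 80), (0, 10, 20, 30, 45, 60, 80),
                 (0, 10, 20, 30, 40, 50, 60, 70, 80)], 1)
        ),
    )
    peak_recovery_late = ScheduleSet(
        "peak_timepoint",
        tuple(sched("pkl", i, (0, p, 60, 80)) for i, p in enumerate((15, 25, 35), 1)),
    )
    peak_recovery_early = ScheduleSet(
        "peak_timepoint",
        tuple(sched("pke", i, (0, p, 50, 65)) for i, p in enumerate((15, 25, 35), 1)),
    )
    peak_no_recovery = ScheduleSet(
        "peak_timepoint",
        tuple(sched("pkn", i, (0, p, 40)) for i, p in enumerate((15, 25, 35), 1)),
    )
    representative = ScheduleSet(
        "representative",
        tuple(
            sched("rep", i, tp)
            for i, tp in enumerate(
                [
                    (0, 15, 30, 45, 60, 75),
                    (0, 10, 20, 30, 40, 50, 60, 70, 80),
                    (0, 20, 40, 60, 80),
                    (0, 15, 25, 35, 45, 60),
                    (0, 10, 25, 40),
                    (0, 15, 30, 45),
                    (0, 20, 40),
                    (0, 25, 50, 80),
                    (0, 15, 45, 75),
                    (0, 10, 20, 40, 60),
                    (0, 30, 60),
                    (0, 15, 35, 55, 80),
                ], 1)
        ),
    )
    high_variability = ScheduleSet(
        "high_variability",
        tuple(
            sched("hv", i, tp, min_duration=30.0)
            for i, tp in enumerate(
                [
                    (0, 30),
                    (0, 20, 40, 60, 80),
                    (0, 15, 25, 35, 45, 55, 65, 75),
                    (0, 40, 80),
                    (0, 25, 45, 65),
                ], 1)
        ),
    )
    return {
        "duration": duration,
        "frequency": frequency,
        "frequency_dense": frequency_dense,
        "peak_recovery_late": peak_recovery_late,
        "peak_recovery_early": peak_recovery_early,
        "peak_no_recovery": peak_no_recovery,
        "representative": representative,
        "high_variability": high_variability,
    }


# ---------------------------------------------------------------------------
# downsampling and combined-data construction
# ---------------------------------------------------------------------------

def _grid_indices(times: np.ndarray, timepoints) -> np.ndarray:
    idx = []
    for tp in timepoints:
        hits = np.nonzero(np.isclose(times, tp))[0]
        if hits.size == 0:
            raise ValidationError(
                f"timepoint {tp} min is off the simulation grid (1-min precision)"
            )
        idx.append(hits[0])
    return np.array(idx)


def downsample(
    individual: SimulatedIndividual, schedule: SamplingSchedule | tuple
) -> ParticipantSeries:
    """Observed-trajectory values at exactly the schedule's timepoints."""
    timepoints = schedule.timepoints if isinstance(schedule, SamplingSchedule) \
        else tuple(schedule)
    idx = _grid_indices(individual.times, timepoints)
    return ParticipantSeries(
        participant_id=individual.id,
        study_id="sim",
        condition="stress",
        gender=individual.gender,
        test_type="TSST",
        times=tuple(float(t) for t in individual.times[idx]),
        cortisol=tuple(float(max(v, 0.0)) for v in individual.observed[idx]),
    )


def build_combined_dataset(
    cohort: SimulatedCohort, schedule_set: ScheduleSet, seed: int = 0
) -> tuple[list[ParticipantSeries], dict[str, str]]:
    """Randomly allocate each individual one schedule from the set.

    Returns the combined dataset plus an allocation map
    participant_id -> schedule_id.  Re-seed per replicate to realize the
    ten-replicate protocol.
    """
    rng = np.random.default_rng(seed)
    schedules = schedule_set.schedules
    picks = rng.integers(0, len(schedules), size=len(cohort))
    dataset, allocation = [], {}
    for ind, k in zip(cohort, picks):
        sched = schedules[int(k)]
        dataset.append(downsample(ind, sched))
        allocation[ind.id] = sched.id
    return dataset, allocation


#: Jittered-schedule templates as (mean, SD) per timepoint; SD 0 anchors.
JITTER_TEMPLATES = {
    "medium": ((0.0, 0.0), (21.7, 1.5), (43.9, 2.2), (66.1, 2.6), (80.0, 0.0)),
    "high": ((0.0, 0.0), (31.8, 5.0), (60.4, 5.6)),
}


def jitter_schedules(
    cohort: SimulatedCohort, variability: str = "medium", seed: int = 0,
    max_retries: int = 100,
) -> list[ParticipantSeries]:
    """Per-individual jittered sampling times drawn from N(M, SD) templates.

    Draws are rounded to the 1-min grid and clipped to [0, 80]; anchored
    timepoints (SD 0) are fixed.  Orderings violated after rounding are
    redrawn (bounded retries).
    """
    if variability not in JITTER_TEMPLATES:
        raise ValidationError(f"variability must be one of {tuple(JITTER_TEMPLATES)}")
    template = JITTER_TEMPLATES[variability]
    rng = np.random.default_rng(seed)
    out = []
    for ind in cohort:
        for _attempt in range(max_retries):
            tp = []
            for mean, sd in template:
                v = mean if sd == 0 else rng.normal(mean, sd)
                tp.append(float(np.clip(np.round(v), 0.0, 80.0)))
            if all(b > a for a, b in zip(tp, tp[1:])):
                break
        else:
            raise ValidationError(
                f"{ind.id}: could not draw strictly ordered jittered schedule"
            )
        out.append(downsample(ind, tuple(tp)))
    return out
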