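"""Data preparation for acute stress test cortisol series.

The pipeline mirrors how a combined multi-study database is cleaned
before curve modeling: all pre-stressor samples in a window around onset
are averaged into a single corrected baseline at t = 0, samples outside
the analysis window [0, 80] min are dropped, extreme cortisol values are
flagged against the pooled mean/SD, and participants are classified as
cortisol responders when they rise at least 1.5 nmol/L above baseline
within 15-45 min post onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import NoBaselineError, UnclassifiableResponderError, ValidationError

__all__ = [
    "CortisolSample",
    "ParticipantSeries",
    "correct_baseline",
    "filter_window",
    "flag_outliers",
    "classify_responder",
    "stratified_split",
]

CONDITIONS = ("stress", "control")
TEST_TYPES = ("TSST", "gTSST", "SECPT", "MAST", "control")


@dataclass(frozen=True)
class CortisolSample:
    """One timed salivary cortisol measurement (min rel. to onset, nmol/L)."""

    time: float
    cortisol: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValidationError(f"non-finite sample time {self.time}")
        if not np.isfinite(self.cortisol) or self.cortisol < 0:
            raise ValidationError(f"cortisol must be finite and >= 0, got {self.cortisol}")


@dataclass(frozen=True)
class ParticipantSeries:
    """One participant-condition's time-ordered cortisol observations."""

    participant_id: str
    study_id: str
    condition: str
    gender: str
    test_type: str
    times: tuple[float, ...]
    cortisol: tuple[float, ...]
    age: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.gender not in ("F", "M"):
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.test_type not in TEST_TYPES:
            raise ValidationError(f"unknown test_type {self.test_type!r}")
        if len(self.times) != len(self.cortisol):
            raise ValidationError("times and cortisol must have equal length")
        t = np.asarray(self.times)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"{self.participant_id}: sample times must be strictly increasing"
            )

    @property
    def samples(self) -> tuple[CortisolSample, ...]:
        return tuple(CortisolSample(t, c) for t, c in zip(self.times, self.cortisol))

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def cortisol_array(self) -> np.ndarray:
        return np.asarray(self.cortisol, dtype=float)

    def baseline(self) -> float:
        """Cortisol at the corrected t = 0 baseline sample."""
        t = self.times_array()
        idx = np.nonzero(t == 0.0)[0]
        if idx.size == 0:
            raise NoBaselineError("series has no t = 0 baseline sample", self.participant_id)
        return float(self.cortisol[idx[0]])

    def with_samples(self, times: Sequence[float], cortisol: Sequence[float]) -> "ParticipantSeries":
        return replace(self, times=tuple(float(t) for t in times),
                       cortisol=tuple(float(c) for c in cortisol))


def correct_baseline(
    series: ParticipantSeries, window: tuple[float, float] = (-20.0, 2.0)
) -> ParticipantSeries:
    """Collapse all samples in ``window`` (closed) into one baseline at t = 0.

    Multiple in-window measurements are averaged into the corrected
    baseline value.  A series without any in-window sample cannot form a
    corrected baseline and raises :class:`NoBaselineError` — participants
    without a baseline are excluded, never imputed.  Idempotent.
    """
    t = series.times_array()
    c = series.cortisol_array()
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise NoBaselineError(
            "no sample in the baseline window; corrected t = 0 unavailable",
            series.participant_id,
        )
    baseline = float(c[mask].mean())
    t_out = np.concatenate(([0.0], t[~mask]))
    c_out = np.concatenate(([baseline], c[~mask]))
    order = np.argsort(t_out, kind="stable")
    return series.with_samples(t_out[order], c_out[order])


def filter_window(
    series: ParticipantSeries, t_min: float = 0.0, t_max: float = 80.0
) -> tuple[ParticipantSeries, int]:
    """Drop samples outside the closed interval [t_min, t_max].

    Returns the filtered series and the number of samples removed.
    """
    t = series.times_array()
    mask = (t >= t_min) & (t <= t_max)
    removed = int((~mask).sum())
    return series.with_samples(t[mask], series.cortisol_array()[mask]), removed


def flag_outliers(cortisol_values, k: float = 5.0) -> np.ndarray:
    """Flag values further than ``k`` pooled SDs from the pooled mean.

    Mean and SD are computed over the entire input collection (database
    level, not per participant).  Zero-variance input yields no flags.
    """
    values = np.asarray(cortisol_values, dtype=float)
    if values.size < 2:
        raise ValidationError("outlier flagging needs at least 2 samples")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - values.mean()) > k * sd


def classify_responder(
    series: ParticipantSeries,
    threshold: float = 1.5,
    window: tuple[float, float] = (15.0, 45.0),
) -> bool:
    """Responder iff max cortisol in ``window`` rises >= ``threshold`` above baseline.

    Both window endpoints are inclusive.  A series with no sample inside
    the window cannot be classified and raises
    :class:`UnclassifiableResponderError` (such procedures are excluded).
    """
    baseline = series.baseline()
    t = series.times_array()
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise UnclassifiableResponderError(
            f"no sampling timepoint in [{window[0]}, {window[1]}] min",
            series.participant_id,
        )
    return float(series.cortisol_array()[mask].max()) - baseline >= threshold


def stratified_split(
    dataset: Iterable[ParticipantSeries], fraction: float = 0.8, seed: int = 0
) -> tuple[list[ParticipantSeries], list[ParticipantSeries]]:
    """Per-study train/test partition at the given training fraction.

    Every study contributes round(fraction * n) participants to the
    training set; studies with a single participant go entirely to
    training.  Deterministic given ``seed``; the two parts partition the
    input exactly.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    dataset = list(dataset)
    rng = np.random.default_rng(seed)
    by_study: dict[str, list[int]] = {}
    for i, s in enumerate(dataset):
        by_study.setdefault(s.study_id, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for study in sorted(by_study):
        idx = np.array(by_study[study])
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(fraction * n))
        n_train = max(1, min(n, n_train))  # singleton studies stay in train
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return [dataset[i] for i in sorted(train_idx)], [dataset[i] for i in sorted(test_idx)]
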