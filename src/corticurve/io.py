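"""Readers, writers, run configuration and manifests.

The exchange format is a long-format CSV with one row per cortisol
sample: participant_id, study_id, condition, gender, age, test_type,
time_min, cortisol_nmol_l (header required, UTF-8, age may be empty).
Simulated cohorts export in the same format plus a truth sidecar CSV
and a JSON manifest tying outputs to their configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .preprocess import ParticipantSeries

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "read_long_csv",
    "write_long_csv",
    "write_truth_csv",
    "write_manifest",
]

REQUIRED_COLUMNS = (
    "participant_id", "study_id", "condition", "gender", "age", "test_type",
    "time_min", "cortisol_nmol_l",
)


@dataclass
class RunConfig:
    """Documented defaults for every pipeline stage.

    Defaults equal the established analysis values: baseline window
    [-20, 2] min, analysis window [0, 80] min, outlier threshold 5 SD,
    responder rise 1.5 nmol/L within [15, 45] min, nominal peak 25 min,
    10 combined-data replicates.
    """

    input_csv: str | None = None
    output_dir: str = "."
    baseline_window: tuple[float, float] = (-20.0, 2.0)
    analysis_window: tuple[float, float] = (0.0, 80.0)
    outlier_k: float = 5.0
    responder_threshold: float = 1.5
    responder_window: tuple[float, float] = (15.0, 45.0)
    nominal_peak_time: float = 25.0
    n_replicates: int = 10
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        for key in ("baseline_window", "analysis_window", "responder_window"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_long_csv(path) -> list[ParticipantSeries]:
    """Read and validate a long-format cortisol CSV into participant series.

    All rows are validated before any series is built; errors carry
    1-based data row numbers.  Duplicate (participant, time) pairs are
    rejected.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "study_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    errors = []
    for col in ("time_min", "cortisol_nmol_l"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for row in df.index[coerced.isna() & df[col].notna()]:
            errors.append(f"row {row + 1}: non-numeric {col} {df.loc[row, col]!r}")
        df[col] = coerced
    for row in df.index[df["cortisol_nmol_l"].isna()]:
        errors.append(f"row {row + 1}: missing cortisol value")
    dup = df.duplicated(subset=["participant_id", "condition", "time_min"], keep=False)
    for row in df.index[dup & ~df.duplicated(subset=["participant_id", "condition", "time_min"])]:
        errors.append(
            f"row {row + 1}: duplicate timepoint {df.loc[row, 'time_min']} for "
            f"participant {df.loc[row, 'participant_id']}"
        )
    if errors:
        raise ValidationError("invalid input CSV:\n" + "\n".join(errors))

    out = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        age = grp["age"].iloc[0]
        out.append(
            ParticipantSeries(
                participant_id=str(pid),
                study_id=str(grp["study_id"].iloc[0]),
                condition=str(cond),
                gender=str(grp["gender"].iloc[0]),
                test_type=str(grp["test_type"].iloc[0]),
                age=None if pd.isna(age) else float(age),
                times=tuple(float(t) for t in grp["time_min"]),
                cortisol=tuple(float(c) for c in grp["cortisol_nmol_l"]),
            )
        )
    return out


def write_long_csv(series_list: Sequence[ParticipantSeries], path) -> None:
    rows = []
    for s in series_list:
        for t, c in zip(s.times, s.cortisol):
            rows.append(
                {"participant_id": s.participant_id, "study_id": s.study_id,
                 "condition": s.condition, "gender": s.gender,
                 "age": "" if s.age is None else s.age, "test_type": s.test_type,
                 "time_min": t, "cortisol_nmol_l": c}
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def write_manifest(path, config: RunConfig, seed: int, **extra) -> None:
    import corticurve

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": seed,
        "versions": {
            "corticurve": corticurve.__version__,
            "python": sys.version.split()[0],
        },
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
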