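"""Cohort data model, CSV I/O, eligibility and discard filtering, labelling.

A cohort is a sequence of :class:`PatientRecord`: one medical checkup plus
the outcome of a colonoscopy performed within a year. Records carry the
maximum observed polyp diameter in millimetres (0 = no polyp; recorded
polyps start at 1 mm) and exclusion flags. The binary classification label
at a polyp-size threshold groups patients whose largest polyp is below the
threshold together with polyp-free patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .schema import FeatureSchema

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
FIT_VALUES = ("positive", "negative", "missing")
KNOWN_FLAGS = ("repeat_colonoscopy", "prior_colorectal_surgery", "ibd", "fap_or_lynch")
SUPPORTED_THRESHOLDS = (0, 6, 8, 10)

#: fixed metadata columns of the cohort CSV dialect, in order
METADATA_COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "fit_result",
    "max_polyp_mm",
    "days_to_colonoscopy",
    "flags",
)


class SchemaError(ValueError):
    """A CSV or configuration does not match the feature schema."""


@dataclass
class PatientRecord:
    """One checkup + colonoscopy outcome."""

    patient_id: str
    sex: str
    age: int
    features: dict[str, float]
    fit_result: str = "missing"
    max_polyp_mm: int = 0
    days_to_colonoscopy: int = 0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.fit_result not in FIT_VALUES:
            raise ValueError(f"fit_result must be one of {FIT_VALUES}")
        if self.max_polyp_mm < 0:
            raise ValueError("max_polyp_mm must be >= 0")
        self.flags = frozenset(self.flags)


@dataclass
class CohortFlow:
    """Record counts at each stage of eligibility filtering."""

    n_input: int = 0
    repeat_excluded: int = 0
    surgery_excluded: int = 0
    ibd_excluded: int = 0
    fap_excluded: int = 0
    age_excluded: int = 0
    window_excluded: int = 0
    eligible: int = 0
    eligible_male: int = 0
    eligible_female: int = 0
    # screening-context constants, carried as metadata when known
    screened: Optional[int] = None
    fit_positive_screened: Optional[int] = None
    polyp_ge_threshold: dict[int, int] = field(default_factory=dict)

    @property
    def colonoscopy_within_365d(self) -> int:
        return self.n_input - self.window_excluded

    def check(self) -> None:
        total_excluded = (
            self.repeat_excluded
            + self.surgery_excluded
            + self.ibd_excluded
            + self.fap_excluded
            + self.age_excluded
            + self.window_excluded
        )
        assert self.eligible == self.n_input - total_excluded
        assert self.eligible == self.eligible_male + self.eligible_female
        thresholds = sorted(self.polyp_ge_threshold)
        counts = [self.polyp_ge_threshold[t] for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


@dataclass
class LabeledDataset:
    """Feature matrix + binary polyp labels at a given size threshold."""

    X: pd.DataFrame
    y: np.ndarray
    sex: str
    threshold_mm: int
    note: str = ""

    @property
    def n(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y[idx],
            self.sex,
            self.threshold_mm,
            self.note,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[PatientRecord], schema: FeatureSchema) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age": r.age,
            "fit_result": r.fit_result,
            "max_polyp_mm": r.max_polyp_mm,
            "days_to_colonoscopy": r.days_to_colonoscopy,
            "flags": ";".join(sorted(r.flags)),
        }
        for name in schema.names:
            if name == "age":
                row[name] = r.age  # single column serves metadata and feature
                continue
            row[name] = r.features.get(name, np.nan)
        rows.append(row)
    cols = list(METADATA_COLUMNS) + [n for n in schema.names if n != "age"]
    return pd.DataFrame(rows, columns=cols)


def write_cohort_csv(records: Sequence[PatientRecord], schema: FeatureSchema, path: str | Path) -> None:
    records_to_frame(records, schema).to_csv(path, index=False)


def read_cohort_csv(path: str | Path, schema: FeatureSchema) -> list[PatientRecord]:
    """Read a cohort CSV (comma-separated, UTF-8, mandatory header).

    Unparseable numeric cells become missing values (NaN); row order is
    preserved. Missing mandatory columns raise :class:`SchemaError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8", dtype=str)
    except (UnicodeDecodeError, pd.errors.EmptyDataError) as exc:
        raise IOError(f"cannot read cohort CSV {path}: {exc}") from exc
    required = list(METADATA_COLUMNS) + [n for n in schema.names if n != "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing mandatory column(s): {missing}")

    records = []
    for _, row in df.iterrows():
        feats = {}
        for name in schema.names:
            raw = row["age"] if name == "age" else row[name]
            feats[name] = pd.to_numeric(raw, errors="coerce")
        flags_cell = row["flags"]
        flags = frozenset(
            f for f in (str(flags_cell).split(";") if pd.notna(flags_cell) else []) if f
        )
        fit = row["fit_result"] if row["fit_result"] in FIT_VALUES else "missing"
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age=int(float(row["age"])),
                features=feats,
                fit_result=fit,
                max_polyp_mm=int(float(row["max_polyp_mm"])),
                days_to_colonoscopy=int(float(row["days_to_colonoscopy"])),
                flags=flags,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_eligibility(
    records: Sequence[PatientRecord],
    *,
    screened: Optional[int] = None,
    fit_positive_screened: Optional[int] = None,
) -> tuple[list[PatientRecord], CohortFlow]:
    """Apply the eligibility filter and tally the cohort flow.

    Removal stages, in order: repeat colonoscopy, prior colorectal surgery,
    IBD, FAP/Lynch syndrome, age <= 20, checkup-to-colonoscopy gap > 365
    days. A record with several flags is counted only at its first matching
    stage, so stage counts are disjoint.
    """
    flow = CohortFlow(
        n_input=len(records), screened=screened, fit_positive_screened=fit_positive_screened
    )
    eligible: list[PatientRecord] = []
    for r in records:
        if "repeat_colonoscopy" in r.flags:
            flow.repeat_excluded += 1
        elif "prior_colorectal_surgery" in r.flags:
            flow.surgery_excluded += 1
        elif "ibd" in r.flags:
            flow.ibd_excluded += 1
        elif "fap_or_lynch" in r.flags:
            flow.fap_excluded += 1
        elif r.age <= 20:
            flow.age_excluded += 1
        elif r.days_to_colonoscopy > 365:
            flow.window_excluded += 1
        else:
            eligible.append(r)
    flow.eligible = len(eligible)
    flow.eligible_male = sum(1 for r in eligible if r.sex == "male")
    flow.eligible_female = flow.eligible - flow.eligible_male
    for t in SUPPORTED_THRESHOLDS:
        cut = max(t, 1)
        flow.polyp_ge_threshold[t] = sum(1 for r in eligible if r.max_polyp_mm >= cut)
    flow.check()
    return eligible, flow


def apply_discard_limits(
    records: Sequence[PatientRecord], schema: FeatureSchema
) -> list[PatientRecord]:
    """Drop records with any feature value strictly above its discard limit."""
    limits = {f.name: f.discard_upper_limit for f in schema if f.discard_upper_limit is not None}
    if not limits:
        return list(records)
    removed_per_feature: dict[str, int] = {}
    kept = []
    for r in records:
        offending = [
            name
            for name, lim in limits.items()
            if name in r.features and pd.notna(r.features[name]) and r.features[name] > lim
        ]
        if offending:
            for name in offending:
                removed_per_feature[name] = removed_per_feature.get(name, 0) + 1
        else:
            kept.append(r)
    for name, n in sorted(removed_per_feature.items()):
        logger.info("discard limit on %s removed %d record(s)", name, n)
    return kept


# ---------------------------------------------------------------------------
# Labelling and splitting
# ---------------------------------------------------------------------------

def make_labels(
    records: Sequence[PatientRecord],
    threshold_mm: int,
    schema: FeatureSchema,
    sex: Optional[str] = None,
) -> LabeledDataset:
    """Build the feature matrix and binary labels at a polyp-size threshold.

    The label is "yes" (1) iff ``max_polyp_mm >= max(threshold_mm, 1)``:
    threshold 0 means any recorded polyp, since recorded sizes start at 1 mm.
    """
    if threshold_mm not in SUPPORTED_THRESHOLDS:
        raise ValueError(
            f"threshold_mm must be one of {SUPPORTED_THRESHOLDS}, got {threshold_mm}"
        )
    if sex is not None:
        records = [r for r in records if r.sex == sex]
    cut = max(threshold_mm, 1)
    X = pd.DataFrame(
        [{n: r.features.get(n, np.nan) for n in schema.names} for r in records],
        columns=schema.names,
    ).astype(float)
    y = np.array([1 if r.max_polyp_mm >= cut else 0 for r in records], dtype=int)
    return LabeledDataset(X, y, sex or "all", threshold_mm, note=f"n={len(records)}")


def split_train_test(
    dataset: LabeledDataset, test_fraction: float = 0.25, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, reproducible train/test split."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = np.bincount(dataset.y)
    if counts.size < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 members for a stratified split")
    idx = np.arange(dataset.n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=dataset.y, random_state=seed
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))
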