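"""Feature schema for health-checkup cohorts.

A schema names every analysis feature, its kind (continuous lab value or
small-integer ordinal lifestyle code), units, an optional upper discard
limit for implausible values, and the expected direction of risk for the
sigmoid-like KDE transform (``lower``/``higher``/``auto``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

VALID_KINDS = ("continuous", "ordinal")
VALID_DIRECTIONS = ("lower", "higher", "auto")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's declaration."""

    name: str
    kind: str = "continuous"
    units: str = ""
    discard_upper_limit: Optional[float] = None
    kde_direction: str = "auto"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"feature {self.name!r}: kind must be one of {VALID_KINDS}")
        if self.kde_direction not in VALID_DIRECTIONS:
            raise ValueError(
                f"feature {self.name!r}: kde_direction must be one of {VALID_DIRECTIONS}"
            )


@dataclass
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterable[FeatureSpec]:
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def subset(self, names: Iterable[str]) -> "FeatureSchema":
        keep = set(names)
        return FeatureSchema([f for f in self.features if f.name in keep])

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "units": f.units,
                    "discard_upper_limit": f.discard_upper_limit,
                    "kde_direction": f.kde_direction,
                }
                for f in self.features
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls([FeatureSpec(**row) for row in d["features"]])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _c(name, units, limit=None):
    return FeatureSpec(name, "continuous", units, limit, "auto")


def _o(name):
    return FeatureSpec(name, "ordinal", "code", None, "auto")


def default_schema() -> FeatureSchema:
    """The default 39-feature checkup panel.

    The roster mirrors a typical Japanese health-checkup battery: physical
    findings, a standard blood panel, and ordinal lifestyle-questionnaire
    items coded 0/1/2. Discard limits mark values beyond plausible assay
    ranges (transcription errors, grossly haemolysed samples).
    """
    feats = [
        _c("age", "years"),
        _c("height", "cm"),
        _c("weight", "kg"),
        _c("bmi", "kg/m^2"),
        _c("waist_circumference", "cm"),
        _c("body_fat_pct", "%"),
        _c("systolic_bp", "mmHg", 300),
        _c("diastolic_bp", "mmHg", 200),
        _c("hdl_cholesterol", "mg/dL"),
        _c("ldl_cholesterol", "mg/dL"),
        _c("triglycerides", "mg/dL", 1000),
        _c("total_cholesterol", "mg/dL"),
        _c("fasting_glucose", "mg/dL", 500),
        _c("hba1c", "%"),
        _c("ast", "U/L", 500),
        _c("alt", "U/L", 500),
        _c("ggt", "U/L", 800),
        _c("uric_acid", "mg/dL"),
        _c("creatinine", "mg/dL"),
        _c("egfr", "mL/min/1.73m^2"),
        _c("hemoglobin", "g/dL"),
        _c("hematocrit", "%"),
        _c("rbc_count", "10^4/uL"),
        _c("wbc_count", "10^3/uL", 30),
        _c("platelet_count", "10^4/uL"),
        _c("crp", "mg/dL", 10),
        _c("albumin", "g/dL"),
        _c("total_protein", "g/dL"),
        _c("amylase", "U/L", 800),
        _c("sleep_hours", "h"),
        _o("drinking_frequency"),
        _o("drinking_amount"),
        _o("smoking_status"),
        _o("exercise_habit"),
        _o("eating_speed"),
        _o("late_dinner"),
        _o("breakfast_skip"),
        _o("stress_level"),
        _o("family_history_crc"),
    ]
    schema = FeatureSchema(feats)
    assert len(schema) == 39
    return schema
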