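"""Synthetic health-checkup cohorts.

Real checkup + colonoscopy data of this kind is hospital-owned and not
publicly available, so the analysis is exercised on synthetic cohorts that
reproduce its statistical structure: sex-stratified samples, class-conditional
feature distributions that overlap heavily between patients with and without
polyps, a configurable polyp prevalence and polyp-size law, and a FIT result
drawn with configurable sensitivity/specificity.

Defaults: 39 features of which 6 carry signal at a +0.5 pooled-SD class
shift — age and BMI (obesity), triglycerides, GGT (alcohol/metabolic), CRP
(inflammation) and ALT (liver) — with prevalence 0.30 for men and 0.20 for
women and FIT sensitivity 0.30 / specificity 0.90. Right-skewed laboratory
values (triglycerides, GGT, CRP, transaminases, ...) are lognormal with
their class shift on the log scale, anthropometrics and most other labs
normal, lifestyle items ordinal codes in {0, 1, 2}. The class-conditional
distributions overlap heavily: the untransformed-baseline classifier lands
at a low-but-clearly-positive MCC.

:func:`reference_cohort_roster` builds a deterministic 1290-record roster
whose eligibility flow and polyp-size tallies match a documented screening
cohort exactly; it serves as a reproducible fixture for the filtering layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import PatientRecord
from .schema import FeatureSchema, default_schema

#: polyp-size bands (mm, inclusive): 1-5, 6-7, 8-9, >=10
SIZE_BANDS = ((1, 5), (6, 7), (8, 9), (10, 20))


class SpecValidationError(ValueError):
    """A synthetic-cohort specification field is invalid."""


@dataclass(frozen=True)
class FeatureLaw:
    """Class-conditional generative law for one feature.

    ``delta`` is the polyp-class shift in pooled-SD units: the "yes" class
    mean is ``loc + delta * scale`` (on the log scale for lognormal
    features). Ordinal features instead use separate level probabilities per
    class.
    """

    name: str
    family: str = "normal"  # normal | lognormal | ordinal
    loc: float = 0.0
    scale: float = 1.0
    delta: float = 0.0
    levels: tuple = (0, 1, 2)
    probs_no: tuple = ()
    probs_yes: tuple = ()
    integer: bool = False
    clip: Optional[tuple] = None

    def validate(self) -> None:
        if self.family not in ("normal", "lognormal", "ordinal"):
            raise SpecValidationError(f"feature {self.name!r}: unknown family {self.family!r}")
        if self.family != "ordinal" and self.scale <= 0:
            raise SpecValidationError(f"feature {self.name!r}: scale must be > 0")
        if self.family == "ordinal":
            for attr in ("probs_no", "probs_yes"):
                p = getattr(self, attr)
                if len(p) != len(self.levels):
                    raise SpecValidationError(
                        f"feature {self.name!r}: {attr} must have one probability per level"
                    )
                if any(q < 0 or q > 1 for q in p) or not math.isclose(sum(p), 1.0, abs_tol=1e-9):
                    raise SpecValidationError(
                        f"feature {self.name!r}: {attr} must be in [0,1] and sum to 1"
                    )


def _ordinal(name, probs_no, probs_yes=None, levels=(0, 1, 2)):
    return FeatureLaw(
        name,
        "ordinal",
        levels=levels,
        probs_no=tuple(probs_no),
        probs_yes=tuple(probs_yes or probs_no),
        integer=True,
    )


def default_feature_laws() -> list[FeatureLaw]:
    """Laws for the default 39-feature panel (6 informative)."""
    ln = math.log
    laws = [
        FeatureLaw("age", "normal", 60, 10, delta=0.5, integer=True, clip=(40, 80)),
        FeatureLaw("height", "normal", 163, 9),
        FeatureLaw("weight", "normal", 62, 11),
        FeatureLaw("bmi", "normal", 23, 3.5, delta=0.5),
        FeatureLaw("waist_circumference", "normal", 84, 9),
        FeatureLaw("body_fat_pct", "normal", 26, 6),
        FeatureLaw("systolic_bp", "normal", 125, 16),
        FeatureLaw("diastolic_bp", "normal", 77, 11),
        FeatureLaw("hdl_cholesterol", "normal", 62, 15),
        FeatureLaw("ldl_cholesterol", "normal", 120, 30),
        FeatureLaw("triglycerides", "lognormal", ln(100), 0.6, delta=0.5),
        FeatureLaw("total_cholesterol", "normal", 205, 33),
        FeatureLaw("fasting_glucose", "lognormal", ln(97), 0.14),
        FeatureLaw("hba1c", "normal", 5.6, 0.5),
        FeatureLaw("ast", "lognormal", ln(22), 0.35),
        FeatureLaw("alt", "lognormal", ln(20), 0.6, delta=0.5),
        FeatureLaw("ggt", "lognormal", ln(30), 0.9, delta=0.5),
        FeatureLaw("uric_acid", "normal", 5.4, 1.3),
        FeatureLaw("creatinine", "normal", 0.78, 0.18),
        FeatureLaw("egfr", "normal", 75, 14),
        FeatureLaw("hemoglobin", "normal", 14.2, 1.4),
        FeatureLaw("hematocrit", "normal", 42.5, 3.8),
        FeatureLaw("rbc_count", "normal", 455, 40),
        FeatureLaw("wbc_count", "lognormal", ln(5.8), 0.28),
        FeatureLaw("platelet_count", "normal", 24.5, 5.5),
        FeatureLaw("crp", "lognormal", ln(0.07), 1.2, delta=0.5),
        FeatureLaw("albumin", "normal", 4.4, 0.25),
        FeatureLaw("total_protein", "normal", 7.2, 0.4),
        FeatureLaw("amylase", "lognormal", ln(75), 0.35),
        FeatureLaw("sleep_hours", "normal", 6.5, 1.0),
        _ordinal("drinking_frequency", (0.45, 0.30, 0.25)),
        _ordinal("drinking_amount", (0.55, 0.30, 0.15)),
        _ordinal("smoking_status", (0.55, 0.20, 0.25)),
        _ordinal("exercise_habit", (0.45, 0.35, 0.20)),
        _ordinal("eating_speed", (0.35, 0.40, 0.25)),
        _ordinal("late_dinner", (0.55, 0.30, 0.15)),
        _ordinal("breakfast_skip", (0.65, 0.20, 0.15)),
        _ordinal("stress_level", (0.40, 0.40, 0.20)),
        _ordinal("family_history_crc", (0.90, 0.10), levels=(0, 1)),
    ]
    return laws


@dataclass
class SyntheticSpec:
    """Generative description of a synthetic cohort."""

    n_male: int = 1000
    n_female: int = 1000
    prevalence_male: float = 0.30
    prevalence_female: float = 0.20
    size_band_probs: tuple = (0.62, 0.18, 0.04, 0.16)
    fit_sensitivity: float = 0.30
    fit_specificity: float = 0.90
    features: list[FeatureLaw] = field(default_factory=default_feature_laws)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_male", "n_female"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        for name in (
            "prevalence_male",
            "prevalence_female",
            "fit_sensitivity",
            "fit_specificity",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SpecValidationError(f"{name} must be in [0, 1], got {v}")
        if len(self.size_band_probs) != len(SIZE_BANDS):
            raise SpecValidationError("size_band_probs must have one entry per size band")
        if any(p < 0 or p > 1 for p in self.size_band_probs) or not math.isclose(
            sum(self.size_band_probs), 1.0, abs_tol=1e-9
        ):
            raise SpecValidationError("size_band_probs must be in [0,1] and sum to 1")
        for law in self.features:
            law.validate()

    def null(self) -> "SyntheticSpec":
        """The matched no-signal spec: every class shift removed."""
        feats = [
            replace(law, delta=0.0, probs_yes=law.probs_no) if law.family == "ordinal"
            else replace(law, delta=0.0)
            for law in self.features
        ]
        return replace(self, features=feats)

    def schema(self) -> FeatureSchema:
        base = default_schema()
        if [l.name for l in self.features] == base.names:
            return base
        from .schema import FeatureSpec

        return FeatureSchema(
            [
                FeatureSpec(l.name, "ordinal" if l.family == "ordinal" else "continuous")
                for l in self.features
            ]
        )


def _draw_feature(law: FeatureLaw, status: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = status.size
    if law.family == "ordinal":
        u = rng.random(n)
        levels = np.asarray(law.levels, dtype=float)
        out = np.empty(n)
        for probs, mask in ((law.probs_no, status == 0), (law.probs_yes, status == 1)):
            cum = np.cumsum(probs)
            out[mask] = levels[np.searchsorted(cum, u[mask], side="right").clip(0, len(levels) - 1)]
        return out
    z = rng.normal(0.0, 1.0, n) + law.delta * status
    if law.family == "normal":
        v = law.loc + law.scale * z
    else:  # lognormal
        v = np.exp(law.loc + law.scale * z)
    if law.clip is not None:
        v = np.clip(v, *law.clip)
    if law.integer:
        v = np.round(v)
    return v


def _draw_sizes(status: np.ndarray, band_probs: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    sizes = np.zeros(status.size, dtype=int)
    pos = np.flatnonzero(status == 1)
    if pos.size == 0:
        return sizes
    bands = rng.choice(len(SIZE_BANDS), size=pos.size, p=list(band_probs))
    for b, (lo, hi) in enumerate(SIZE_BANDS):
        m = pos[bands == b]
        sizes[m] = rng.integers(lo, hi + 1, size=m.size)
    return sizes


def generate_cohort(spec: SyntheticSpec) -> list[PatientRecord]:
    """Draw a cohort from the spec; reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    for sex, n, prev in (
        ("male", spec.n_male, spec.prevalence_male),
        ("female", spec.n_female, spec.prevalence_female),
    ):
        if n == 0:
            continue
        status = (rng.random(n) < prev).astype(int)
        sizes = _draw_sizes(status, spec.size_band_probs, rng)
        feats = {law.name: _draw_feature(law, status, rng) for law in spec.features}
        u = rng.random(n)
        fit_pos = np.where(status == 1, u < spec.fit_sensitivity, u < 1 - spec.fit_specificity)
        days = rng.integers(1, 366, size=n)
        ages = feats.get("age")
        for i in range(n):
            fdict = {k: float(v[i]) for k, v in feats.items()}
            age = int(ages[i]) if ages is not None else int(rng.integers(40, 81))
            records.append(
                PatientRecord(
                    patient_id=f"SYN-{sex[0].upper()}{i:05d}",
                    sex=sex,
                    age=age,
                    features=fdict,
                    fit_result="positive" if fit_pos[i] else "negative",
                    max_polyp_mm=int(sizes[i]),
                    days_to_colonoscopy=int(days[i]),
                    flags=frozenset(),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Deterministic reference roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RosterResult:
    records: list[PatientRecord]
    screened: int
    fit_positive_screened: int


#: screening-context constants of the reference cohort
REFERENCE_SCREENED = 21447
REFERENCE_FIT_POSITIVE_SCREENED = 1133

# eligibility-flow tallies of the reference cohort
_N_ENDOSCOPY = 1290
_N_REPEAT, _N_SURGERY, _N_IBD = 274, 8, 5
_N_ELIGIBLE, _N_MALE = 1003, 611
# nested polyp-size counts among the eligible: >=1, >=6, >=8, >=10 mm
_NESTED = {1: 547, 6: 210, 8: 113, 10: 93}
_FIT_POSITIVE_ELIGIBLE = 704  # 70.2% of 1003


def _reference_sizes() -> list[int]:
    """1003 polyp sizes realising the nested counts 547/210/113/93."""
    counts = {
        0: _N_ELIGIBLE - _NESTED[1],          # 456 without polyp
        "1-5": _NESTED[1] - _NESTED[6],        # 337
        "6-7": _NESTED[6] - _NESTED[8],        # 97
        "8-9": _NESTED[8] - _NESTED[10],       # 20
        "10+": _NESTED[10],                    # 93
    }
    sizes: list[int] = [0] * counts[0]
    for key, pool in (("1-5", (1, 2, 3, 4, 5)), ("6-7", (6, 7)), ("8-9", (8, 9)),
                      ("10+", (10, 11, 12, 13, 15, 20))):
        sizes.extend(pool[i % len(pool)] for i in range(counts[key]))
    assert len(sizes) == _N_ELIGIBLE
    return sizes


def reference_cohort_roster() -> RosterResult:
    """Deterministic 1290-record roster reproducing a known cohort flow.

    Tallies: 274 repeat-colonoscopy, 8 prior-surgery and 5 IBD exclusions
    leave 1003 eligible (611 male / 392 female); nested polyp-size counts
    547 (>=1 mm), 210 (>=6), 113 (>=8), 93 (>=10); 704 FIT-positive among
    the eligible. Feature values are drawn from the default laws with a
    fixed internal seed, so repeated calls are identical.
    """
    rng = np.random.default_rng(20150101)
    laws = default_feature_laws()

    sizes = np.array(_reference_sizes())
    rng.shuffle(sizes)  # mix polyp sizes across sexes deterministically
    status = (sizes >= 1).astype(int)
    feats = {law.name: _draw_feature(law, status, rng) for law in laws}
    fit_positive = np.zeros(_N_ELIGIBLE, dtype=bool)
    fit_positive[rng.permutation(_N_ELIGIBLE)[:_FIT_POSITIVE_ELIGIBLE]] = True
    days = rng.integers(1, 366, size=_N_ELIGIBLE)

    records: list[PatientRecord] = []
    for i in range(_N_ELIGIBLE):
        sex = "male" if i < _N_MALE else "female"
        records.append(
            PatientRecord(
                patient_id=f"REF-{i:04d}",
                sex=sex,
                age=int(feats["age"][i]),
                features={k: float(v[i]) for k, v in feats.items()},
                fit_result="positive" if fit_positive[i] else "negative",
                max_polyp_mm=int(sizes[i]),
                days_to_colonoscopy=int(days[i]),
                flags=frozenset(),
            )
        )

    # excluded records: one flag each, disjoint stages
    n_excl = _N_REPEAT + _N_SURGERY + _N_IBD
    excl_status = (rng.random(n_excl) < 0.3).astype(int)
    excl_sizes = _draw_sizes(excl_status, (0.62, 0.18, 0.04, 0.16), rng)
    excl_feats = {law.name: _draw_feature(law, excl_status, rng) for law in laws}
    excl_days = rng.integers(1, 366, size=n_excl)
    flag_seq = (
        ["repeat_colonoscopy"] * _N_REPEAT
        + ["prior_colorectal_surgery"] * _N_SURGERY
        + ["ibd"] * _N_IBD
    )
    for j in range(n_excl):
        records.append(
            PatientRecord(
                patient_id=f"REF-X{j:03d}",
                sex="male" if j % 2 == 0 else "female",
                age=int(excl_feats["age"][j]),
                features={k: float(v[j]) for k, v in excl_feats.items()},
                fit_result="positive" if j % 3 == 0 else "negative",
                max_polyp_mm=int(excl_sizes[j]),
                days_to_colonoscopy=int(excl_days[j]),
                flags=frozenset([flag_seq[j]]),
            )
        )
    assert len(records) == _N_ENDOSCOPY
    return RosterResult(records, REFERENCE_SCREENED, REFERENCE_FIT_POSITIVE_SCREENED)
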