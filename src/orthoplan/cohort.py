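"""Synthetic patient cohort generator.

Emulates the demographic and clinical marginals of a retrospective adult
orthodontic-orthognathic population: age normally distributed (truncated to
the 18-35 y study range), a female majority, mutually exclusive sagittal
skeletal classes II/III with class-conditional ANB angles, and independent
asymmetry / vertical-discrepancy labels.  Defaults reproduce the published
cohort statistics (age 22.7 +/- 4.3 y, 57.1% female, ANB -2.8 +/- 2.1 deg for
class III and 5.9 +/- 1.8 deg for class II, treatment duration 26.3 +/- 6.7
months).  Sagittal class frequencies 40.9% / 53.9% are renormalised to a
single exclusive draw (p_III = 53.9 / 94.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .state import (
    DEFAULT_SCHEMA,
    CRANIAL_SLICE,
    MANDIBLE_SLICE,
    MAXILLA_SLICE,
    MeasurementSchema,
    N_LANDMARKS,
    N_TEETH,
    N_THICKNESS,
    DentalBlock,
    FunctionalBlock,
    PatientState,
    SkeletalBlock,
    SoftTissueBlock,
    TreatmentStatusBlock,
)

AGE_RANGE = (18.0, 35.0)
VALID_LABELS = {"ClassII", "ClassIII", "Asymmetry", "VerticalDiscrepancy"}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class PatientRecord:
    id: str
    age_years: float
    sex: str                               # "female" | "male"
    deformity_labels: Set[str]
    anb_deg: float
    treatment_duration_months: float       # calibration only
    enrollment_index: int                  # chronological order key

    def validate(self) -> None:
        if not (AGE_RANGE[0] <= self.age_years <= AGE_RANGE[1]):
            raise ValueError(f"age_years={self.age_years} outside study range {AGE_RANGE}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex={self.sex!r} must be 'female' or 'male'")
        if not self.deformity_labels:
            raise ValueError("deformity_labels must be non-empty")
        unknown = set(self.deformity_labels) - VALID_LABELS
        if unknown:
            raise ValueError(f"unknown deformity labels: {sorted(unknown)}")
        if {"ClassII", "ClassIII"} <= set(self.deformity_labels):
            raise ValueError("ClassII and ClassIII are mutually exclusive")
        if not np.isfinite(self.anb_deg):
            raise ValueError("anb_deg must be finite")


@dataclass
class CohortConfig:
    n: int = 347
    seed: int = 0
    age_mean: float = 22.7
    age_sd: float = 4.3
    sex_female_prob: float = 0.571
    # sagittal class: exclusive draw renormalised from 40.9 / 53.9
    class_iii_prob: float = 53.9 / (40.9 + 53.9)
    asymmetry_prob: float = 0.380
    vertical_prob: float = 0.274
    anb_mean_by_class: dict = field(default_factory=lambda: {"ClassII": 5.9, "ClassIII": -2.8})
    anb_sd_by_class: dict = field(default_factory=lambda: {"ClassII": 1.8, "ClassIII": 2.1})
    duration_mean: float = 26.3
    duration_sd: float = 6.7

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n={self.n} must be >= 0")
        for name in ("sex_female_prob", "class_iii_prob", "asymmetry_prob", "vertical_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} must lie in [0, 1]")
        for name in ("age_sd", "duration_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}={getattr(self, name)} must be > 0")
        for cls, sd in self.anb_sd_by_class.items():
            if sd <= 0:
                raise ConfigurationError(f"anb_sd_by_class[{cls}]={sd} must be > 0")


@lru_cache(maxsize=None)
def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Asymmetric truncation (e.g. ages on [18, 35]) shifts the naive truncated
    mean, so the location is solved once so the sampled population reproduces
    the printed mean.
    """
    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(brentq(lambda m: trunc_mean(m) - mean, lo - 10 * sd, hi + 10 * sd))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    # rejection sampling from the calibrated-location normal
    loc = _calibrated_loc(mean, sd, lo, hi)
    for _ in range(1000):
        x = rng.normal(loc, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pragma: no cover - unreachable in practice


def sample_cohort(config: CohortConfig) -> List[PatientRecord]:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Each record uses a named, spawned child stream so records are reproducible
    independently of draw order.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n)
    records: List[PatientRecord] = []
    for idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        age = _truncated_normal(rng, config.age_mean, config.age_sd, *AGE_RANGE)
        sex = "female" if rng.random() < config.sex_female_prob else "male"
        sagittal = "ClassIII" if rng.random() < config.class_iii_prob else "ClassII"
        labels = {sagittal}
        if rng.random() < config.asymmetry_prob:
            labels.add("Asymmetry")
        if rng.random() < config.vertical_prob:
            labels.add("VerticalDiscrepancy")
        # class-conditional ANB truncated to the sign-consistent clinical range
        # (class III: negative ANB; class II: ANB above the ~4 deg norm), with
        # the location calibrated so the conditional mean matches the target
        anb_lo, anb_hi = ((-12.0, -0.05) if sagittal == "ClassIII" else (4.05, 14.0))
        anb = _truncated_normal(rng, config.anb_mean_by_class[sagittal],
                                config.anb_sd_by_class[sagittal], anb_lo, anb_hi)
        duration = max(6.0, rng.normal(config.duration_mean, config.duration_sd))
        records.append(PatientRecord(
            id=f"syn-{config.seed}-{idx:05d}",
            age_years=age,
            sex=sex,
            deformity_labels=labels,
            anb_deg=float(anb),
            treatment_duration_months=float(duration),
            enrollment_index=idx,
        ))
    return records


# ----------------------------------------------------------------------
# full state synthesis
# ----------------------------------------------------------------------
def _landmark_template() -> np.ndarray:
    """Deterministic plausible head-frame landmark template (mm)."""
    t = np.zeros((N_LANDMARKS, 3))
    ang = np.linspace(0, np.pi, 24)
    t[CRANIAL_SLICE, 0] = 45.0 * np.cos(ang)          # cranial vault arc
    t[CRANIAL_SLICE, 1] = 25.0 * np.sin(2 * ang)
    t[CRANIAL_SLICE, 2] = 55.0 + 20.0 * np.sin(ang)
    i = np.arange(22)
    t[MAXILLA_SLICE, 0] = 60.0 + 8.0 * np.cos(i)      # maxillary complex
    t[MAXILLA_SLICE, 1] = 18.0 * np.sin(i * 0.7)
    t[MAXILLA_SLICE, 2] = -5.0 + 4.0 * np.sin(i)
    t[MANDIBLE_SLICE, 0] = 55.0 + 9.0 * np.cos(i + 1)  # mandibular body/ramus
    t[MANDIBLE_SLICE, 1] = 20.0 * np.sin(i * 0.6)
    t[MANDIBLE_SLICE, 2] = -35.0 + 6.0 * np.sin(i)
    return t


def occlusal_class_from_anb(anb: float) -> int:
    """Angle class from ANB: class I for 0-4 deg, II above, III below."""
    if anb > 4.0:
        return 2
    if anb < 0.0:
        return 3
    return 1


def sample_patient_state(record: PatientRecord,
                         schema: MeasurementSchema = DEFAULT_SCHEMA,
                         seed: int = 0) -> PatientState:
    """Populate a full pre-treatment craniofacial state consistent with a record.

    The cephalometric ANB block equals ``record.anb_deg`` exactly; mandibular
    landmarks are displaced anteriorly for class III (negative ANB)
    configurations and posteriorly for class II.  Severity (|ANB - 2|)
    degrades the functional indices and the facial-harmony score.
    """
    record.validate()
    rng = np.random.default_rng(np.random.SeedSequence((seed, record.enrollment_index)))

    anb = record.anb_deg
    sna = 82.0 + rng.normal(0.0, 1.5)
    snb = sna - anb
    severity = abs(anb - 2.0)  # deviation from the ~2 deg norm

    landmarks = _landmark_template() + rng.normal(0.0, 0.8, size=(N_LANDMARKS, 3))
    # sagittal discrepancy shows up as mandibular protrusion/retrusion
    landmarks[MANDIBLE_SLICE, 0] += -1.6 * (anb - 2.0)

    tooth_pos = np.zeros((N_TEETH, 3))
    arc = np.linspace(-1.1, 1.1, 14)
    for row, base_x, base_z in ((slice(0, 14), 58.0, -12.0), (slice(14, 28), 55.0, -18.0)):
        tooth_pos[row, 0] = base_x + 12.0 * np.cos(arc)
        tooth_pos[row, 1] = 24.0 * np.sin(arc)
        tooth_pos[row, 2] = base_z
    tooth_pos += rng.normal(0.0, 0.5, size=(N_TEETH, 3))
    tooth_pos[14:, 0] += -0.8 * (anb - 2.0)  # dental compensation follows the jaws
    # pre-treatment malalignment scales with severity
    tooth_ang = rng.normal(0.0, 2.0 + 0.8 * severity, size=(N_TEETH, 3))

    thickness = np.clip(11.0 + rng.normal(0.0, 1.5, size=N_THICKNESS), 4.0, 20.0)
    harmony = float(np.clip(7.0 - 0.45 * severity + rng.normal(0.0, 0.5), 0.0, 10.0))
    base_fn = np.clip(0.75 - 0.05 * severity + rng.normal(0.0, 0.05, size=3), 0.05, 0.95)

    state = PatientState(
        skeletal=SkeletalBlock(
            landmarks=landmarks, sna=float(sna), snb=float(snb), anb=float(anb),
            occlusal_class=occlusal_class_from_anb(anb),
        ),
        dental=DentalBlock(
            tooth_pos=tooth_pos, tooth_ang=tooth_ang,
            arch_width=float(36.0 + rng.normal(0.0, 2.0)),
            arch_length=float(30.0 + rng.normal(0.0, 2.0)),
        ),
        soft_tissue=SoftTissueBlock(
            thickness=thickness,
            lip_competence=int(rng.random() < 0.6 - 0.03 * severity),
            nasal_breathing=float(np.clip(0.8 + rng.normal(0.0, 0.1), 0.0, 1.0)),
            facial_harmony=harmony,
        ),
        functional=FunctionalBlock(
            occlusal_function=float(base_fn[0]),
            tmj_health=float(base_fn[1]),
            respiratory=float(base_fn[2]),
        ),
        treatment_status=TreatmentStatusBlock(
            phase=1,
            relapse_risk=float(np.clip(0.5 + 0.02 * severity + rng.normal(0.0, 0.05), 0.0, 1.0)),
            bone_density=float(np.clip(0.7 + rng.normal(0.0, 0.05), 0.0, 1.0)),
            tissue_adaptation=float(np.clip(0.2 + rng.normal(0.0, 0.05), 0.0, 1.0)),
            elapsed_months=0.0,
        ),
    )
    return state


# ----------------------------------------------------------------------
# I/O: JSON-lines cohort files, CSV feature tables
# ----------------------------------------------------------------------
def record_to_dict(record: PatientRecord) -> dict:
    d = asdict(record)
    d["deformity_labels"] = sorted(record.deformity_labels)
    return d


def record_from_dict(d: dict) -> PatientRecord:
    allowed = {"id", "age_years", "sex", "deformity_labels", "anb_deg",
               "treatment_duration_months", "enrollment_index"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown patient-record fields: {sorted(unknown)}")
    missing = allowed - set(d)
    if missing:
        raise ValueError(f"missing patient-record fields: {sorted(missing)}")
    rec = PatientRecord(
        id=str(d["id"]), age_years=float(d["age_years"]), sex=str(d["sex"]),
        deformity_labels=set(d["deformity_labels"]), anb_deg=float(d["anb_deg"]),
        treatment_duration_months=float(d["treatment_duration_months"]),
        enrollment_index=int(d["enrollment_index"]),
    )
    rec.validate()
    return rec


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """One JSON record per line; units: years / degrees / months."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec)) + "\n")


def read_cohort(path) -> List[PatientRecord]:
    with open(path) as fh:
        return [record_from_dict(json.loads(line)) for line in fh if line.strip()]


def cohort_feature_table(records: Sequence[PatientRecord],
                         schema: MeasurementSchema = DEFAULT_SCHEMA,
                         seed: int = 0) -> pd.DataFrame:
    """One row per patient, one column per schema measurement."""
    rows = []
    for rec in records:
        st = sample_patient_state(rec, schema, seed=seed)
        row = {"id": rec.id}
        row.update(st.measurements(schema))
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
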