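"""Craniofacial patient state: the MDP state vector.

The state groups five blocks — skeletal, dental, soft tissue, functional and
treatment status — mirroring how combined orthodontic-orthognathic records are
organised clinically.  All geometry lives in a fixed right-handed,
head-centred frame in millimetres: +x = anterior (sagittal), +y = patient
left (transverse), +z = superior (vertical).

A state also answers a canonical 137-measurement schema (45 skeletal + 52
dental + 40 soft-tissue parameters).  The cephalometric angles SNA, SNB and
ANB carry their standard meaning (maxillary / mandibular sagittal position
relative to the cranial base, and their difference); the remaining schema
entries are documented placeholder parameters derived deterministically from
the stored geometry, since only the three named angles and the group counts
are fixed by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np

N_LANDMARKS = 68          # 3D skeletal landmarks
N_TEETH = 28              # permanent dentition minus third molars
N_THICKNESS = 64          # soft-tissue thickness map points

# landmark index blocks: cranial base is the fixed reference; jaw blocks move
CRANIAL_SLICE = slice(0, 24)
MAXILLA_SLICE = slice(24, 46)   # 22 points
MANDIBLE_SLICE = slice(46, 68)  # 22 points

UPPER_TEETH = slice(0, 14)
LOWER_TEETH = slice(14, 28)
UPPER_INCISOR = 6   # upper right central incisor index
LOWER_INCISOR = 20  # lower right central incisor index


@dataclass
class MeasurementSchema:
    """Named 137-measurement craniofacial schema (45 skeletal + 52 dental + 40 soft tissue)."""

    skeletal_names: List[str] = field(default_factory=lambda: _default_names()[0])
    dental_names: List[str] = field(default_factory=lambda: _default_names()[1])
    soft_tissue_names: List[str] = field(default_factory=lambda: _default_names()[2])

    @property
    def all_names(self) -> List[str]:
        return list(self.skeletal_names) + list(self.dental_names) + list(self.soft_tissue_names)

    def __post_init__(self) -> None:
        names = self.all_names
        if len(names) != 137:
            raise ValueError(f"measurement schema must contain 137 names, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("measurement names must be unique")
        if (len(self.skeletal_names), len(self.dental_names), len(self.soft_tissue_names)) != (45, 52, 40):
            raise ValueError("schema groups must count 45 skeletal, 52 dental, 40 soft-tissue")


def _default_names():
    skeletal = ["SNA", "SNB", "ANB"]
    skeletal += [f"S-Mx{i:02d}" for i in range(1, 23)]     # sella->maxillary landmark distances
    skeletal += [f"S-Md{i:02d}" for i in range(1, 21)]     # sella->mandibular landmark distances
    dental = [f"tooth{i:02d}_sag" for i in range(1, 29)]   # per-tooth sagittal position
    for sextant in range(1, 7):
        dental += [f"sx{sextant}_tip", f"sx{sextant}_torque", f"sx{sextant}_rot"]
    dental += ["arch_width", "arch_length", "overjet", "overbite",
               "curve_of_spee", "irregularity_index"]
    soft = [f"st_region{i:02d}" for i in range(1, 33)]     # thickness-map region means
    soft += ["facial_harmony", "lip_competence", "nasal_breathing",
             "nasolabial_angle", "labiomental_angle", "profile_convexity",
             "upper_lip_thickness", "chin_thickness"]
    return skeletal, dental, soft


DEFAULT_SCHEMA = MeasurementSchema()


@dataclass
class SkeletalBlock:
    landmarks: np.ndarray          # (68, 3) mm
    sna: float                     # degrees
    snb: float                     # degrees
    anb: float                     # degrees, = SNA - SNB
    occlusal_class: int            # 1, 2 or 3 (Angle class I/II/III)


@dataclass
class DentalBlock:
    tooth_pos: np.ndarray          # (28, 3) mm
    tooth_ang: np.ndarray          # (28, 3) degrees: tip, torque, rotation
    arch_width: float              # mm
    arch_length: float             # mm


@dataclass
class SoftTissueBlock:
    thickness: np.ndarray          # (64,) mm
    lip_competence: int            # {0, 1}
    nasal_breathing: float         # [0, 1]
    facial_harmony: float          # [0, 10]


@dataclass
class FunctionalBlock:
    occlusal_function: float       # [0, 1]
    tmj_health: float              # [0, 1]
    respiratory: float             # [0, 1]


@dataclass
class TreatmentStatusBlock:
    phase: int                     # {1, 2, 3, 4}
    relapse_risk: float            # [0, 1]
    bone_density: float            # [0, 1]
    tissue_adaptation: float       # [0, 1]
    elapsed_months: float          # >= 0


@dataclass
class PatientState:
    """Full craniofacial MDP state s_t."""

    skeletal: SkeletalBlock
    dental: DentalBlock
    soft_tissue: SoftTissueBlock
    functional: FunctionalBlock
    treatment_status: TreatmentStatusBlock

    def copy(self) -> "PatientState":
        return PatientState(
            skeletal=replace(self.skeletal, landmarks=self.skeletal.landmarks.copy()),
            dental=replace(self.dental, tooth_pos=self.dental.tooth_pos.copy(),
                           tooth_ang=self.dental.tooth_ang.copy()),
            soft_tissue=replace(self.soft_tissue, thickness=self.soft_tissue.thickness.copy()),
            functional=replace(self.functional),
            treatment_status=replace(self.treatment_status),
        )

    # ------------------------------------------------------------------
    # canonical measurement schema
    # ------------------------------------------------------------------
    def measurements(self, schema: MeasurementSchema = DEFAULT_SCHEMA) -> Dict[str, float]:
        """Evaluate all 137 schema measurements from the stored geometry."""
        sk, de, st = self.skeletal, self.dental, self.soft_tissue
        out: Dict[str, float] = {}
        out["SNA"], out["SNB"], out["ANB"] = sk.sna, sk.snb, sk.anb
        sella = sk.landmarks[0]
        mx = sk.landmarks[MAXILLA_SLICE]
        md = sk.landmarks[MANDIBLE_SLICE]
        for i, p in enumerate(mx, start=1):
            out[f"S-Mx{i:02d}"] = float(np.linalg.norm(p - sella))
        for i, p in enumerate(md[:20], start=1):
            out[f"S-Md{i:02d}"] = float(np.linalg.norm(p - sella))

        for i in range(N_TEETH):
            out[f"tooth{i + 1:02d}_sag"] = float(de.tooth_pos[i, 0])
        # six sextants: upper right/anterior/left, lower right/anterior/left
        sextants = [slice(0, 5), slice(5, 9), slice(9, 14),
                    slice(14, 19), slice(19, 23), slice(23, 28)]
        for s_i, sl in enumerate(sextants, start=1):
            out[f"sx{s_i}_tip"] = float(de.tooth_ang[sl, 0].mean())
            out[f"sx{s_i}_torque"] = float(de.tooth_ang[sl, 1].mean())
            out[f"sx{s_i}_rot"] = float(de.tooth_ang[sl, 2].mean())
        out["arch_width"] = de.arch_width
        out["arch_length"] = de.arch_length
        out["overjet"] = float(de.tooth_pos[UPPER_INCISOR, 0] - de.tooth_pos[LOWER_INCISOR, 0])
        out["overbite"] = float(de.tooth_pos[UPPER_INCISOR, 2] - de.tooth_pos[LOWER_INCISOR, 2])
        out["curve_of_spee"] = float(np.ptp(de.tooth_pos[LOWER_TEETH, 2]))
        out["irregularity_index"] = float(np.abs(de.tooth_ang).mean())

        regions = st.thickness.reshape(32, 2).mean(axis=1)
        for i, v in enumerate(regions, start=1):
            out[f"st_region{i:02d}"] = float(v)
        out["facial_harmony"] = st.facial_harmony
        out["lip_competence"] = float(st.lip_competence)
        out["nasal_breathing"] = st.nasal_breathing
        # profile angles: documented proxies driven by the sagittal discrepancy
        out["nasolabial_angle"] = 102.0 - 1.5 * sk.anb
        out["labiomental_angle"] = 120.0 + 1.0 * sk.anb
        out["profile_convexity"] = 12.0 + 1.2 * sk.anb
        out["upper_lip_thickness"] = float(st.thickness[:8].mean())
        out["chin_thickness"] = float(st.thickness[-8:].mean())

        assert set(out) == set(schema.all_names)
        return out

    def feature_vector(self, schema: MeasurementSchema = DEFAULT_SCHEMA) -> np.ndarray:
        """Flat numeric features for learning: 137 measurements + class one-hot
        + functional block + treatment-status block (148 values)."""
        m = self.measurements(schema)
        vals = [m[name] for name in schema.all_names]
        onehot = [0.0, 0.0, 0.0]
        onehot[self.skeletal.occlusal_class - 1] = 1.0
        fn = self.functional
        ts = self.treatment_status
        vals += onehot
        vals += [fn.occlusal_function, fn.tmj_health, fn.respiratory]
        vals += [ts.phase / 4.0, ts.relapse_risk, ts.bone_density,
                 ts.tissue_adaptation, ts.elapsed_months / 36.0]
        return np.asarray(vals, dtype=np.float64)


FEATURE_DIM = 137 + 3 + 3 + 5


def feature_names(schema: MeasurementSchema = DEFAULT_SCHEMA) -> List[str]:
    return (schema.all_names
            + ["class_I", "class_II", "class_III",
               "occlusal_function", "tmj_health", "respiratory",
               "phase_frac", "relapse_risk", "bone_density",
               "tissue_adaptation", "elapsed_frac"])


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------
@dataclass
class Violation:
    field: str
    value: float
    allowed: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"{self.field}={self.value!r} outside {self.allowed}"


def validate_state(state: PatientState) -> List[Violation]:
    """Return all range-invariant violations; empty list means the state is valid."""
    v: List[Violation] = []

    def rng(name, value, lo, hi):
        if not (lo <= value <= hi) or not np.isfinite(value):
            v.append(Violation(name, float(value), f"[{lo}, {hi}]"))

    sk = state.skeletal
    if sk.landmarks.shape != (N_LANDMARKS, 3):
        v.append(Violation("skeletal.landmarks", sk.landmarks.shape[0], f"exactly {N_LANDMARKS} points"))
    if not np.all(np.isfinite(sk.landmarks)):
        v.append(Violation("skeletal.landmarks", float("nan"), "finite coordinates"))
    if sk.occlusal_class not in (1, 2, 3):
        v.append(Violation("skeletal.occlusal_class", sk.occlusal_class, "{1, 2, 3}"))
    if not np.isfinite(sk.anb):
        v.append(Violation("skeletal.anb", sk.anb, "finite degrees"))

    de = state.dental
    if de.tooth_pos.shape != (N_TEETH, 3) or de.tooth_ang.shape != (N_TEETH, 3):
        v.append(Violation("dental.teeth", de.tooth_pos.shape[0], f"exactly {N_TEETH} teeth"))

    st = state.soft_tissue
    if st.thickness.shape != (N_THICKNESS,):
        v.append(Violation("soft_tissue.thickness", st.thickness.shape[0],
                           f"exactly {N_THICKNESS} points"))
    if st.lip_competence not in (0, 1):
        v.append(Violation("soft_tissue.lip_competence", st.lip_competence, "{0, 1}"))
    rng("soft_tissue.nasal_breathing", st.nasal_breathing, 0.0, 1.0)
    rng("soft_tissue.facial_harmony", st.facial_harmony, 0.0, 10.0)

    fn = state.functional
    rng("functional.occlusal_function", fn.occlusal_function, 0.0, 1.0)
    rng("functional.tmj_health", fn.tmj_health, 0.0, 1.0)
    rng("functional.respiratory", fn.respiratory, 0.0, 1.0)

    ts = state.treatment_status
    if ts.phase not in (1, 2, 3, 4):
        v.append(Violation("treatment_status.phase", ts.phase, "{1, 2, 3, 4}"))
    rng("treatment_status.relapse_risk", ts.relapse_risk, 0.0, 1.0)
    rng("treatment_status.bone_density", ts.bone_density, 0.0, 1.0)
    rng("treatment_status.tissue_adaptation", ts.tissue_adaptation, 0.0, 1.0)
    if ts.elapsed_months < 0 or not np.isfinite(ts.elapsed_months):
        v.append(Violation("treatment_status.elapsed_months", ts.elapsed_months, "[0, inf)"))
    return v
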