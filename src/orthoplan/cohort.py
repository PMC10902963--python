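"""Synthetic patient and cohort generation.

A deterministic, bilaterally symmetric template skull (landmarks only)
provides a "normal" anatomy whose cephalometric profile sits inside the
default reference intervals.  Deformity classes are simulated as rigid
motions of the surgical segments applied to the template — maxillary and
mandibular over/under-development as anteroposterior jaw translations,
maxillary deviation as an occlusal-plane roll rotation, mandibular deviation
as a lateral jaw translation — so every synthetic patient carries its
generating motion as ground truth for planner-recovery experiments.

Labels are obtained by thresholding the induced (noise-free) measurements
against the reference intervals, the way a surgeon labels from measurements;
feature vectors are computed from landmark positions perturbed by isotropic
Gaussian digitization noise, so features are noisy while labels remain exact
functions of the generating deformity.

Cohort composition defaults emulate a typical orthognathic surgical
population: 574 patients; maxillary development under/normal/over
35%/36.6%/28.4%; mandibular development 30.5%/24%/45.5%; maxillary deviation
36.2%; mandibular deviation 44.1%; 35.4% male.  Class counts are exact for
any n via largest-remainder apportionment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .cephalometry import (
    CephalometricProfile,
    LandmarkSet,
    ReferenceIntervalTable,
    compute_profile,
    default_reference_intervals,
)
from .kinematics import SurgicalPlan, apply_plan
from .registry import LABELS

__all__ = [
    "CohortError",
    "TEMPLATE_COORDINATES",
    "DeformitySpec",
    "JawClasses",
    "CohortSpec",
    "SyntheticPatient",
    "Cohort",
    "make_template",
    "label_profile",
    "synthesize_patient",
    "synthesize_cohort",
    "prevalence",
    "largest_remainder",
]


class CohortError(ValueError):
    """Invalid cohort or deformity specification."""


#: Canonical template landmark coordinates (mm), patient frame axes
#: (+x left, +y anterior, +z superior), origin at sella.
TEMPLATE_COORDINATES: dict[str, tuple[float, float, float]] = {
    "S": (0.0, 0.0, 0.0),
    "N": (0.0, 65.0, 5.0),
    "A": (0.0, 62.5, -45.0),
    "B": (0.0, 57.0, -75.0),
    "Pog": (0.0, 59.0, -85.0),
    "Me": (0.0, 52.0, -92.0),
    "Gn": (0.0, 57.0, -89.0),
    "ANS": (0.0, 66.0, -40.0),
    "PNS": (0.0, 15.0, -42.0),
    "Or_L": (26.0, 55.0, -15.0),
    "Or_R": (-26.0, 55.0, -15.0),
    "Po_L": (55.0, -8.0, -15.0),
    "Po_R": (-55.0, -8.0, -15.0),
    "Go_L": (45.0, -5.0, -75.0),
    "Go_R": (-45.0, -5.0, -75.0),
    "U1": (0.0, 60.0, -60.0),
    "L1": (0.0, 58.0, -63.0),
    "U6_L": (30.0, 25.0, -55.0),
    "U6_R": (-30.0, 25.0, -55.0),
}


def make_template(scale: float = 1.0, sex: str = "female") -> LandmarkSet:
    """Deterministic symmetric template anatomy.

    ``scale`` isotropically scales the canonical coordinates (1.0 is adult
    size); angles and ratios are scale-invariant, so the profile stays inside
    the reference intervals for any positive scale.
    """
    if scale <= 0:
        raise CohortError("scale must be positive")
    positions = {n: scale * np.array(p) for n, p in TEMPLATE_COORDINATES.items()}
    return LandmarkSet(positions, sex=sex, metadata={"source": "template", "scale": scale})


@dataclass(frozen=True)
class DeformitySpec:
    """Generating motion distributions per deformity class and the landmark
    noise level.

    Magnitude ranges (uniform draws) are chosen so that a zero-noise patient
    always crosses the relevant reference-interval bound and is therefore
    labeled consistently with its generating class:

    - jaw development: anteroposterior translation of the maxilla
      (``maxilla_development_mm``) or mandible (``mandible_development_mm``),
      positive = advancement for overdevelopment, negative for under;
    - maxillary deviation: occlusal roll rotation of the maxilla
      (``maxilla_roll_deg``), random side;
    - mandibular deviation: lateral mandibular translation
      (``mandible_lateral_mm``), random side.
    """

    maxilla_development_mm: tuple[float, float] = (4.0, 7.0)
    mandible_development_mm: tuple[float, float] = (7.0, 11.0)
    maxilla_roll_deg: tuple[float, float] = (3.0, 6.0)
    mandible_lateral_mm: tuple[float, float] = (3.5, 7.0)
    noise_sd_mm: float = 0.5

    def __post_init__(self):
        for name in (
            "maxilla_development_mm",
            "mandible_development_mm",
            "maxilla_roll_deg",
            "mandible_lateral_mm",
        ):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise CohortError(f"{name} range must satisfy 0 < low <= high")
        if self.noise_sd_mm < 0:
            raise CohortError("noise_sd_mm must be nonnegative")


@dataclass(frozen=True)
class JawClasses:
    """Per-jaw generating class assignment."""

    maxilla_development: str = "normal"  # under | normal | over
    mandible_development: str = "normal"
    maxilla_deviation: bool = False
    mandible_deviation: bool = False

    def __post_init__(self):
        for name in ("maxilla_development", "mandible_development"):
            if getattr(self, name) not in ("under", "normal", "over"):
                raise CohortError(f"{name} must be under/normal/over")


def label_profile(
    profile: CephalometricProfile, intervals: ReferenceIntervalTable, sex: str
) -> dict[str, int]:
    """Threshold a profile against the reference intervals -> six binary labels.

    Development labels read SNA (maxilla) / SNB (mandible); deviation labels
    read OP_FHP_roll (maxilla) / Pog_MSP (mandible) falling outside their
    intervals.
    """
    sna_lo, sna_hi = intervals.bounds("SNA", sex)
    snb_lo, snb_hi = intervals.bounds("SNB", sex)
    return {
        "maxillary_overdevelopment": int(profile["SNA"] > sna_hi),
        "maxillary_underdevelopment": int(profile["SNA"] < sna_lo),
        "maxillary_deviation": int(
            not intervals.contains("OP_FHP_roll", sex, profile["OP_FHP_roll"])
        ),
        "mandibular_overdevelopment": int(profile["SNB"] > snb_hi),
        "mandibular_underdevelopment": int(profile["SNB"] < snb_lo),
        "mandibular_deviation": int(
            not intervals.contains("Pog_MSP", sex, profile["Pog_MSP"])
        ),
    }


@dataclass
class SyntheticPatient:
    """One synthetic record: noisy landmarks, features, exact labels and the
    generating motion (ground truth for planner recovery)."""

    landmarks: LandmarkSet
    features: dict[str, float]
    labels: dict[str, int]
    classes: JawClasses
    generating_plan: SurgicalPlan
    clean_profile: CephalometricProfile


def _generating_plan(classes: JawClasses, spec: DeformitySpec, rng) -> SurgicalPlan:
    # draws happen in a fixed order so a given class assignment is
    # reproducible from the rng state
    maxilla_rot = np.zeros(3)
    maxilla_trans = np.zeros(3)
    mandible_trans = np.zeros(3)
    if classes.maxilla_development != "normal":
        mag = rng.uniform(*spec.maxilla_development_mm)
        maxilla_trans[1] = mag if classes.maxilla_development == "over" else -mag
    if classes.mandible_development != "normal":
        mag = rng.uniform(*spec.mandible_development_mm)
        mandible_trans[1] = mag if classes.mandible_development == "over" else -mag
    if classes.maxilla_deviation:
        mag = rng.uniform(*spec.maxilla_roll_deg)
        maxilla_rot[1] = mag * (1.0 if rng.uniform() < 0.5 else -1.0)
    if classes.mandible_deviation:
        mag = rng.uniform(*spec.mandible_lateral_mm)
        mandible_trans[0] = mag * (1.0 if rng.uniform() < 0.5 else -1.0)
    return SurgicalPlan(
        maxilla_rotation=maxilla_rot,
        maxilla_translation=maxilla_trans,
        mandible_translation=mandible_trans,
        provenance="actual",
    )


def synthesize_patient(
    classes: JawClasses,
    spec: DeformitySpec | None = None,
    rng: np.random.Generator | None = None,
    *,
    sex: str = "female",
    age: float | None = None,
    template: LandmarkSet | None = None,
    intervals: ReferenceIntervalTable | None = None,
) -> SyntheticPatient:
    """Generate one patient with a known generating deformity.

    The template is displaced by the class's generating motions; labels come
    from the noise-free induced profile; features are the profile of the
    noise-perturbed landmarks plus demographics.
    """
    spec = spec if spec is not None else DeformitySpec()
    rng = rng if rng is not None else np.random.default_rng()
    base = template if template is not None else make_template(sex=sex)
    base = LandmarkSet(base.positions, sex=sex, metadata=dict(base.metadata))
    intervals = intervals if intervals is not None else default_reference_intervals()

    plan = _generating_plan(classes, spec, rng)
    clean = apply_plan(base, plan)
    clean_profile = compute_profile(clean)
    labels = label_profile(clean_profile, intervals, sex)

    noisy_positions = {
        name: pos + rng.normal(0.0, spec.noise_sd_mm, size=3)
        for name, pos in clean.positions.items()
    }
    noisy = clean.with_positions(noisy_positions)
    features = compute_profile(noisy).as_dict()
    if age is None:
        mean, sd = (23.4, 7.2) if sex == "male" else (26.3, 8.5)
        age = float(np.clip(rng.normal(mean, sd), 16.0, 60.0))
    features["age"] = float(age)
    features["sex_male"] = 1.0 if sex == "male" else 0.0
    return SyntheticPatient(
        landmarks=noisy,
        features=features,
        labels=labels,
        classes=classes,
        generating_plan=plan,
        clean_profile=clean_profile,
    )


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer apportionment of ``n`` by the largest-remainder (Hare) method.

    Quotas are ``n * p / sum(p)``; every class gets its floor, and the
    remaining units go to the largest fractional parts (ties broken by
    position)."""
    if n < 0:
        raise CohortError("n must be nonnegative")
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < 0) or p.sum() <= 0:
        raise CohortError("proportions must be nonnegative and sum to > 0")
    quotas = n * p / p.sum()
    base = np.floor(quotas).astype(int)
    remainder = n - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    counts = base.copy()
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: size, per-class proportions, sex ratio and seed."""

    n: int = 574
    maxillary_development: Mapping[str, float] = field(
        default_factory=lambda: {"under": 0.35, "normal": 0.366, "over": 0.284}
    )
    mandibular_development: Mapping[str, float] = field(
        default_factory=lambda: {"under": 0.305, "normal": 0.24, "over": 0.455}
    )
    maxillary_deviation: float = 0.362
    mandibular_deviation: float = 0.441
    male_fraction: float = 0.354
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise CohortError("n must be nonnegative")
        for name in ("maxillary_development", "mandibular_development"):
            props = getattr(self, name)
            if set(props) != {"under", "normal", "over"}:
                raise CohortError(f"{name} must map under/normal/over to proportions")
            total = sum(props.values())
            if any(v < 0 for v in props.values()) or abs(total - 1.0) > 1e-6:
                raise CohortError(f"{name} proportions must be nonnegative and sum to 1")
        for name in ("maxillary_deviation", "mandibular_deviation", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"{name} must lie in [0, 1]")


@dataclass
class Cohort:
    """A synthesized cohort: the tabular dataset plus the full patient
    records (landmarks and generating plans)."""

    data: pd.DataFrame
    patients: list[SyntheticPatient]
    spec: CohortSpec


def _exact_assignment(n: int, proportions: Sequence[float], labels, rng) -> np.ndarray:
    counts = largest_remainder(n, proportions)
    arr = np.repeat(np.asarray(labels, dtype=object), counts)
    return rng.permutation(arr)


def synthesize_cohort(
    spec: CohortSpec | None = None,
    deformity: DeformitySpec | None = None,
    intervals: ReferenceIntervalTable | None = None,
    template: LandmarkSet | None = None,
) -> Cohort:
    """Generate a cohort with exact class counts.

    Each composition axis (sex, per-jaw development, per-jaw deviation) is
    apportioned exactly by largest remainder and shuffled independently, so
    marginal counts are exact while joint combinations vary with the seed.
    """
    spec = spec if spec is not None else CohortSpec()
    deformity = deformity if deformity is not None else DeformitySpec()
    intervals = intervals if intervals is not None else default_reference_intervals()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    dev_classes = ("under", "normal", "over")
    max_dev = _exact_assignment(
        n, [spec.maxillary_development[c] for c in dev_classes], dev_classes, rng
    )
    mand_dev = _exact_assignment(
        n, [spec.mandibular_development[c] for c in dev_classes], dev_classes, rng
    )
    max_dvn = _exact_assignment(
        n, [spec.maxillary_deviation, 1 - spec.maxillary_deviation], [True, False], rng
    )
    mand_dvn = _exact_assignment(
        n, [spec.mandibular_deviation, 1 - spec.mandibular_deviation], [True, False], rng
    )
    sexes = _exact_assignment(
        n, [spec.male_fraction, 1 - spec.male_fraction], ["male", "female"], rng
    )

    patients: list[SyntheticPatient] = []
    rows: list[dict] = []
    for i in range(n):
        classes = JawClasses(
            maxilla_development=str(max_dev[i]),
            mandible_development=str(mand_dev[i]),
            maxilla_deviation=bool(max_dvn[i]),
            mandible_deviation=bool(mand_dvn[i]),
        )
        patient = synthesize_patient(
            classes,
            deformity,
            rng,
            sex=str(sexes[i]),
            template=template,
            intervals=intervals,
        )
        patients.append(patient)
        row = {"patient_id": i, "sex": str(sexes[i]), **patient.features}
        row.update({label: patient.labels[label] for label in LABELS})
        rows.append(row)

    columns = ["patient_id", "sex"]
    if rows:
        feature_cols = [c for c in rows[0] if c not in ("patient_id", "sex")]
        columns += feature_cols
    data = pd.DataFrame(rows, columns=columns)
    return Cohort(data=data, patients=patients, spec=spec)


def prevalence(data: pd.DataFrame, label: str) -> float:
    """Positive fraction of ``label`` in percent, to one decimal place."""
    if len(data) == 0:
        raise CohortError("prevalence of an empty dataset is undefined")
    if label not in data.columns:
        raise CohortError(f"unknown label column {label!r}")
    return round(100.0 * float(data[label].sum()) / len(data), 1)
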