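"""Rigid-body surgical plan kinematics.

A surgical plan moves three bone segments: the maxilla (Le Fort I level) and
mandible (BSSRO level) each with a full 6-DOF rigid motion about their incisor
movement centers, and the chin (genioplasty segment) with a translation only,
about pogonion.  The chin rides on the mandible, so its motion is the
mandibular motion composed with the chin translation.  Cranial-base landmarks
never move.

Euler convention: rotations are applied about the motion center in the fixed
patient axes, pitch about x then roll about y then yaw about z
(extrinsic x-y-z), angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .cephalometry import DegenerateGeometryError, LandmarkSet

__all__ = [
    "KinematicsError",
    "RigidMotion",
    "SegmentDefinition",
    "SurgicalPlan",
    "OcclusalRegistration",
    "default_segments",
    "apply_motion",
    "apply_plan",
    "occlusal_registration",
    "PLAN_PARAM_NAMES",
]


class KinematicsError(ValueError):
    """Invalid motion, plan, or segment configuration."""


def _vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise KinematicsError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise KinematicsError(f"{name} has non-finite components")
    return a


@dataclass(frozen=True)
class RigidMotion:
    """Rotation (Euler degrees, extrinsic x-y-z) about ``center`` followed by
    a translation, i.e. ``p' = R (p - c) + c + t``."""

    rotation_deg: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation_deg", _vec3(self.rotation_deg, "rotation_deg"))
        object.__setattr__(self, "translation", _vec3(self.translation, "translation"))
        object.__setattr__(self, "center", _vec3(self.center, "center"))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True)

    def apply(self, points) -> np.ndarray:
        """Apply to one point or an (n, 3) array; preserves pairwise distances."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = self.rotation.apply(p - self.center) + self.center + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidMotion":
        """Motion undoing this one: ``inv.apply(self.apply(p)) == p``."""
        rinv = self.rotation.inv()
        return RigidMotion(
            rotation_deg=rinv.as_euler("xyz", degrees=True),
            translation=-self.translation,
            center=self.center + self.translation,
        )


def apply_motion(points, motion: RigidMotion) -> np.ndarray:
    """Functional alias for :meth:`RigidMotion.apply`."""
    return motion.apply(points)


@dataclass(frozen=True)
class SegmentDefinition:
    """A movable bone segment: member landmarks and the movement-center
    landmark (the incisor point for the jaws, pogonion for the chin)."""

    segment_id: str
    members: tuple[str, ...]
    center: str


def default_segments() -> dict[str, SegmentDefinition]:
    """Default segment membership for the packaged landmark registry."""
    return {
        "maxilla": SegmentDefinition(
            "maxilla", ("A", "ANS", "PNS", "U1", "U6_L", "U6_R"), "U1"
        ),
        "mandible": SegmentDefinition("mandible", ("B", "L1", "Go_L", "Go_R"), "L1"),
        "chin": SegmentDefinition("chin", ("Pog", "Me", "Gn"), "Pog"),
    }


#: Canonical ordering of the 15 free plan parameters.
PLAN_PARAM_NAMES: tuple[str, ...] = (
    "maxilla_pitch_deg",
    "maxilla_roll_deg",
    "maxilla_yaw_deg",
    "maxilla_tx_mm",
    "maxilla_ty_mm",
    "maxilla_tz_mm",
    "mandible_pitch_deg",
    "mandible_roll_deg",
    "mandible_yaw_deg",
    "mandible_tx_mm",
    "mandible_ty_mm",
    "mandible_tz_mm",
    "chin_tx_mm",
    "chin_ty_mm",
    "chin_tz_mm",
)


@dataclass(frozen=True)
class SurgicalPlan:
    """The 15 free parameters of a surgical plan.

    Maxilla and mandible each get 3 Euler rotations (deg) + 3 translations
    (mm); the chin is translation-only (its rotation is identically zero by
    construction of the type).  ``provenance`` tags the plan's origin
    (``"ai"``, ``"revised"`` or ``"actual"``).
    """

    maxilla_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    maxilla_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mandible_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mandible_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    chin_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: str = "ai"

    def __post_init__(self):
        for name in (
            "maxilla_rotation",
            "maxilla_translation",
            "mandible_rotation",
            "mandible_translation",
            "chin_translation",
        ):
            object.__setattr__(self, name, _vec3(getattr(self, name), name))

    def to_vector(self) -> np.ndarray:
        """The 15-vector in :data:`PLAN_PARAM_NAMES` order."""
        return np.concatenate(
            [
                self.maxilla_rotation,
                self.maxilla_translation,
                self.mandible_rotation,
                self.mandible_translation,
                self.chin_translation,
            ]
        )

    @classmethod
    def from_vector(cls, v, provenance: str = "ai") -> "SurgicalPlan":
        a = np.asarray(v, dtype=float)
        if a.shape != (15,):
            raise KinematicsError(f"plan vector must have 15 entries, got {a.shape}")
        return cls(
            maxilla_rotation=a[0:3],
            maxilla_translation=a[3:6],
            mandible_rotation=a[6:9],
            mandible_translation=a[9:12],
            chin_translation=a[12:15],
            provenance=provenance,
        )

    @classmethod
    def zero(cls, provenance: str = "ai") -> "SurgicalPlan":
        return cls(provenance=provenance)

    def with_provenance(self, provenance: str) -> "SurgicalPlan":
        return replace(self, provenance=provenance)


def plan_motions(
    landmarks: LandmarkSet,
    plan: SurgicalPlan,
    segments: Mapping[str, SegmentDefinition] | None = None,
) -> dict[str, RigidMotion]:
    """Per-segment world motions implied by a plan on given (pre-move)
    landmarks.  The chin motion is the mandibular motion composed with the
    chin translation."""
    segs = segments if segments is not None else default_segments()
    maxilla = RigidMotion(
        plan.maxilla_rotation, plan.maxilla_translation, landmarks[segs["maxilla"].center]
    )
    mandible = RigidMotion(
        plan.mandible_rotation,
        plan.mandible_translation,
        landmarks[segs["mandible"].center],
    )
    chin = RigidMotion(
        mandible.rotation_deg,
        mandible.translation + plan.chin_translation,
        mandible.center,
    )
    return {"maxilla": maxilla, "mandible": mandible, "chin": chin}


def apply_plan(
    landmarks: LandmarkSet,
    plan: SurgicalPlan,
    segments: Mapping[str, SegmentDefinition] | None = None,
) -> LandmarkSet:
    """Move segment-member landmarks under the plan; everything else is fixed.

    Raises :class:`KinematicsError` if a landmark is claimed by more than one
    segment or a segment member/center is absent.
    """
    segs = segments if segments is not None else default_segments()
    claimed: dict[str, str] = {}
    for seg in segs.values():
        for name in seg.members:
            if name in claimed:
                raise KinematicsError(
                    f"landmark {name!r} assigned to both {claimed[name]!r} and "
                    f"{seg.segment_id!r}"
                )
            claimed[name] = seg.segment_id
        landmarks.require(seg.members)
        landmarks.require([seg.center])

    motions = plan_motions(landmarks, plan, segs)
    new_positions = {n: p.copy() for n, p in landmarks.positions.items()}
    for seg_id, seg in segs.items():
        motion = motions[seg_id]
        for name in seg.members:
            new_positions[name] = motion.apply(landmarks[name])
    return landmarks.with_positions(new_positions)


@dataclass(frozen=True)
class OcclusalRegistration:
    """Terminal occlusion recorded as three marker points on each jaw plus the
    rigid motion mapping the mandibular markers onto the maxillary ones."""

    maxilla_markers: np.ndarray  # (3, 3)
    mandible_markers: np.ndarray  # (3, 3)
    motion: RigidMotion
    residual_rms: float


def _check_triplet(points, name: str) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.shape != (3, 3):
        raise KinematicsError(f"{name} must be three 3D points, got shape {p.shape}")
    span = np.cross(p[1] - p[0], p[2] - p[0])
    scale = max(np.linalg.norm(p[1] - p[0]), np.linalg.norm(p[2] - p[0]), 1.0)
    if np.linalg.norm(span) < 1e-9 * scale**2:
        raise DegenerateGeometryError(f"{name} markers are collinear")
    return p


def occlusal_registration(max_pts, mand_pts) -> OcclusalRegistration:
    """Closed-form (Kabsch) rigid motion mapping mandibular markers onto the
    corresponding maxillary markers, with the residual RMS of the fit."""
    a = _check_triplet(max_pts, "maxillary")
    b = _check_triplet(mand_pts, "mandibular")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    motion = RigidMotion(
        rotation_deg=rot.as_euler("xyz", degrees=True),
        translation=ca - cb,
        center=cb,
    )
    residual = motion.apply(b) - a
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return OcclusalRegistration(
        maxilla_markers=a, mandible_markers=b, motion=motion, residual_rms=rms
    )
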