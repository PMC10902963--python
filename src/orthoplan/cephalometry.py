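"""3D cephalometry: landmarks, the patient coordinate frame, and the
measurement battery.

The patient frame is built from the cranial base: the Frankfort horizontal
plane (FHP) is fitted to the two orbitale points and the midpoint of the two
porion points; the midsagittal plane (MSP) passes through nasion and sella
orthogonal to the FHP.  Axes are +x patient-left, +y anterior, +z superior,
origin at sella.  Every measurement is invariant under a global rigid motion
of the whole landmark set, which makes the frame convention internal.

Sign conventions
----------------
Deflection measurements are signed positive "from top left to bottom right":
occlusal-plane roll is positive when the patient's left side lies inferior to
the right, pitch is positive when the plane descends anteriorly, and Pog_MSP
is the patient-left (+x) coordinate of pogonion.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .registry import (
    ANGLE_MEASUREMENTS,
    LANDMARK_REGISTRY,
    MEASUREMENTS,
    RATIO_MEASUREMENTS,
    SEXES,
)

__all__ = [
    "CephalometryError",
    "MissingLandmarkError",
    "DegenerateGeometryError",
    "LandmarkSet",
    "PatientFrame",
    "CephalometricProfile",
    "ReferenceIntervalTable",
    "angle_at",
    "build_patient_frame",
    "compute_profile",
    "load_reference_intervals",
    "default_reference_intervals",
]


class CephalometryError(ValueError):
    """Base class for cephalometric errors."""


class MissingLandmarkError(CephalometryError):
    """A required landmark is absent from the set."""

    def __init__(self, missing: Iterable[str]):
        self.missing = tuple(sorted(set(missing)))
        super().__init__(f"missing landmark(s): {', '.join(self.missing)}")


class DegenerateGeometryError(CephalometryError):
    """Coincident or collinear points make a construction ill-posed."""


# landmarks needed to construct the patient frame
FRAME_LANDMARKS: tuple[str, ...] = ("Or_L", "Or_R", "Po_L", "Po_R", "N", "S")

#: landmarks each measurement reads (frame landmarks are needed in addition
#: for the frame-referenced measurements)
MEASUREMENT_LANDMARKS: dict[str, tuple[str, ...]] = {
    "SNA": ("S", "N", "A"),
    "SNB": ("S", "N", "B"),
    "ANB": ("S", "N", "A", "B"),
    "SNPog": ("S", "N", "Pog"),
    "OP_FHP_pitch": ("U1", "U6_L", "U6_R"),
    "OP_FHP_roll": ("U1", "U6_L", "U6_R"),
    "OrU6_ratio": ("Or_L", "Or_R", "U6_L", "U6_R"),
    "GoMe_ratio": ("Go_L", "Go_R", "Me"),
    "Pog_MSP": ("Pog",),
    "NANS_ANSMe": ("N", "ANS", "Me"),
}


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise CephalometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise CephalometryError("non-finite coordinate")
    return a


@dataclass
class LandmarkSet:
    """Named 3D anatomical points (mm) in a patient coordinate frame.

    Parameters
    ----------
    positions
        Mapping landmark name -> 3-vector position in mm.
    sex
        ``"male"`` or ``"female"``; selects reference intervals downstream.
    metadata
        Free-form annotations (source file, patient id, ...).
    """

    positions: dict[str, np.ndarray]
    sex: str = "female"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise CephalometryError(f"sex must be one of {SEXES}, got {self.sex!r}")
        clean: dict[str, np.ndarray] = {}
        for name, pos in self.positions.items():
            if name in clean:
                raise CephalometryError(f"duplicate landmark {name!r}")
            clean[str(name)] = _as_point(pos)
        self.positions = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.positions[name]
        except KeyError:
            raise MissingLandmarkError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def names(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def require(self, names: Iterable[str]) -> None:
        """Raise :class:`MissingLandmarkError` listing any absent landmarks."""
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise MissingLandmarkError(missing)

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "LandmarkSet":
        """A copy with ``fn`` applied to every position."""
        return LandmarkSet(
            {n: np.asarray(fn(p), dtype=float) for n, p in self.positions.items()},
            sex=self.sex,
            metadata=dict(self.metadata),
        )

    def with_positions(self, positions: Mapping[str, np.ndarray]) -> "LandmarkSet":
        return LandmarkSet(dict(positions), sex=self.sex, metadata=dict(self.metadata))


@dataclass(frozen=True)
class PatientFrame:
    """Orthonormal right-handed patient frame.

    ``axes`` rows are the unit direction vectors (x mediolateral/patient-left,
    y anteroposterior/anterior, z vertical/superior) expressed in world
    coordinates; ``origin`` sits at sella.
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows x, y, z

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise CephalometryError("axes must be 3x3")
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise CephalometryError("axes must be orthonormal to 1e-9")
        if np.linalg.det(axes) < 0:
            raise CephalometryError("axes must be right-handed")
        object.__setattr__(self, "axes", axes)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates for one point or an (n, 3) array."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T


def angle_at(vertex, p1, p2) -> float:
    """Angle in degrees at ``vertex`` subtended by ``p1`` and ``p2``.

    Symmetric in ``p1``/``p2`` and invariant to the arm lengths; always in
    [0, 180].  Raises :class:`DegenerateGeometryError` for a zero-length arm.
    """
    v, a, b = _as_point(vertex), _as_point(p1), _as_point(p2)
    u1, u2 = a - v, b - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("angle arm coincides with the vertex")
    c = float(np.dot(u1, u2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def build_patient_frame(landmarks: LandmarkSet) -> PatientFrame:
    """Construct the FHP/MSP patient frame from the cranial base.

    The FHP is the plane through ``Or_L``, ``Or_R`` and the porion midpoint;
    its normal, oriented toward nasion, is +z.  The projection of the
    sella-to-nasion direction into the FHP is +y (anterior), and
    x = y x z completes a right-handed triad (+x patient-left).  Origin is
    sella.
    """
    landmarks.require(FRAME_LANDMARKS)
    or_l, or_r = landmarks["Or_L"], landmarks["Or_R"]
    po_mid = 0.5 * (landmarks["Po_L"] + landmarks["Po_R"])
    s, n = landmarks["S"], landmarks["N"]

    scale = max(np.linalg.norm(or_l - po_mid), np.linalg.norm(or_r - po_mid), 1.0)
    normal = np.cross(or_l - po_mid, or_r - po_mid)
    if np.linalg.norm(normal) < 1e-9 * scale**2:
        raise DegenerateGeometryError("FHP points are collinear")
    z = normal / np.linalg.norm(normal)
    if np.dot(z, n - po_mid) < 0:  # superior side holds nasion
        z = -z

    sn = n - s
    y = sn - np.dot(sn, z) * z
    if np.linalg.norm(y) < 1e-9 * max(np.linalg.norm(sn), 1.0):
        raise DegenerateGeometryError("sella-nasion line is orthogonal to the FHP")
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return PatientFrame(origin=s, axes=np.vstack([x, y, z]))


@dataclass(frozen=True)
class CephalometricProfile:
    """The named measurement battery computed from a landmark set.

    Angles are degrees, distances mm, ratios percent.  ``values`` holds the
    canonical battery plus any extra measurements supplied by the caller.
    """

    values: dict[str, float]

    def __post_init__(self):
        for name in self.values:
            v = self.values[name]
            if not np.isfinite(v):
                raise CephalometryError(f"non-finite measurement {name}")
            if name in ANGLE_MEASUREMENTS and not (0.0 <= v <= 180.0):
                raise CephalometryError(f"{name}={v} outside [0, 180] deg")
            if name in RATIO_MEASUREMENTS and v <= 0:
                raise CephalometryError(f"{name}={v} must be positive")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def _occlusal_normal(landmarks: LandmarkSet, frame: PatientFrame) -> np.ndarray:
    """Unit normal (frame coords, z > 0) of the occlusal plane through the
    upper incisor midpoint and the two upper first molar cusps."""
    u1 = frame.to_local(landmarks["U1"])
    u6l = frame.to_local(landmarks["U6_L"])
    u6r = frame.to_local(landmarks["U6_R"])
    n = np.cross(u6l - u1, u6r - u1)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise DegenerateGeometryError("occlusal plane points are collinear")
    n = n / norm
    if n[2] < 0:
        n = -n
    if abs(n[2]) < 1e-12:
        raise DegenerateGeometryError("occlusal plane is vertical")
    return n


def compute_profile(
    landmarks: LandmarkSet,
    frame: PatientFrame | None = None,
    extra_measurements: Mapping[str, Callable[[LandmarkSet, PatientFrame], float]]
    | None = None,
) -> CephalometricProfile:
    """Compute the full cephalometric battery.

    ``ANB`` is the signed difference ``SNA - SNB`` (by definition here, not
    an independently measured 3D angle).  ``extra_measurements`` may add
    caller-defined features to the profile map.
    """
    required = set(FRAME_LANDMARKS)
    for names in MEASUREMENT_LANDMARKS.values():
        required.update(names)
    landmarks.require(required)
    if frame is None:
        frame = build_patient_frame(landmarks)

    def d(a: str, b: str) -> float:
        return float(np.linalg.norm(landmarks[a] - landmarks[b]))

    sna = angle_at(landmarks["N"], landmarks["S"], landmarks["A"])
    snb = angle_at(landmarks["N"], landmarks["S"], landmarks["B"])
    snpog = angle_at(landmarks["N"], landmarks["S"], landmarks["Pog"])

    n = _occlusal_normal(landmarks, frame)
    pitch = float(np.degrees(np.arctan2(n[1], n[2])))
    roll = float(np.degrees(np.arctan2(n[0], n[2])))

    values: dict[str, float] = {
        "SNA": sna,
        "SNB": snb,
        "ANB": sna - snb,
        "SNPog": snpog,
        "OP_FHP_pitch": pitch,
        "OP_FHP_roll": roll,
        "OrU6_ratio": 100.0 * d("Or_R", "U6_R") / d("Or_L", "U6_L"),
        "GoMe_ratio": 100.0 * d("Go_R", "Me") / d("Go_L", "Me"),
        "Pog_MSP": float(frame.to_local(landmarks["Pog"])[0]),
        "NANS_ANSMe": 100.0 * d("N", "ANS") / d("ANS", "Me"),
    }
    if extra_measurements:
        for name, fn in extra_measurements.items():
            values[str(name)] = float(fn(landmarks, frame))
    return CephalometricProfile(values)


@dataclass(frozen=True)
class ReferenceIntervalTable:
    """Per-measurement, per-sex normal intervals.

    The planner treats interval midpoints as default targets; half-widths
    normalize deviations so angles, ratios and distances are commensurate.
    """

    intervals: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self):
        clean: dict[str, dict[str, tuple[float, float]]] = {}
        for meas, by_sex in self.intervals.items():
            clean[meas] = {}
            for sex in SEXES:
                if sex not in by_sex:
                    raise CephalometryError(
                        f"measurement {meas!r} lacks an interval for sex {sex!r}"
                    )
                low, high = (float(v) for v in by_sex[sex])
                if not low < high:
                    raise CephalometryError(
                        f"invalid interval for {meas!r} ({sex}): low {low} >= high {high}"
                    )
                clean[meas][sex] = (low, high)
        object.__setattr__(self, "intervals", clean)

    def validate_complete(self, measurements: Iterable[str] = MEASUREMENTS) -> None:
        missing = [m for m in measurements if m not in self.intervals]
        if missing:
            raise CephalometryError(
                f"reference table missing measurement(s): {', '.join(missing)}"
            )

    def measurements(self) -> tuple[str, ...]:
        return tuple(self.intervals)

    def bounds(self, measurement: str, sex: str) -> tuple[float, float]:
        try:
            return self.intervals[measurement][sex]
        except KeyError:
            raise CephalometryError(
                f"no reference interval for {measurement!r} ({sex})"
            ) from None

    def midpoint(self, measurement: str, sex: str) -> float:
        low, high = self.bounds(measurement, sex)
        return 0.5 * (low + high)

    def half_width(self, measurement: str, sex: str) -> float:
        low, high = self.bounds(measurement, sex)
        return 0.5 * (high - low)

    def contains(self, measurement: str, sex: str, value: float) -> bool:
        low, high = self.bounds(measurement, sex)
        return low <= value <= high


def _table_from_mapping(raw: Mapping) -> ReferenceIntervalTable:
    table = ReferenceIntervalTable(
        {str(m): {str(s): tuple(b) for s, b in by_sex.items()} for m, by_sex in raw.items()}
    )
    table.validate_complete()
    return table


def load_reference_intervals(path: str | Path) -> ReferenceIntervalTable:
    """Load a YAML/JSON interval file keyed measurement -> sex -> [low, high]."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise CephalometryError(f"{path}: expected a mapping of measurements")
    return _table_from_mapping(raw)


def default_reference_intervals() -> ReferenceIntervalTable:
    """The packaged default table (standard Chinese-population adult norms)."""
    from importlib.resources import files

    raw = yaml.safe_load(
        files("orthoplan.data").joinpath("reference_intervals.yaml").read_text()
    )
    return _table_from_mapping(raw)
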