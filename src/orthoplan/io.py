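"""File formats: landmark CSV/JSON, surgical plan JSON, cohort CSV, reports.

Landmark CSV carries ``name,x,y,z`` columns (mm) with ``# key: value``
comment headers for sex/metadata; the JSON form nests the same content.
Plan JSON mirrors the plan type: per-segment rotation/translation with the
chin translation-only (a nonzero chin rotation in a file is rejected).
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cephalometry import LandmarkSet
from .kinematics import SurgicalPlan
from .registry import LANDMARK_REGISTRY

__all__ = [
    "FormatError",
    "read_landmarks",
    "write_landmarks",
    "read_plan",
    "write_plan",
    "read_cohort",
    "write_cohort",
    "write_report",
]


class FormatError(ValueError):
    """Malformed input file."""


def _landmarks_from_rows(rows, sex: str, metadata: dict) -> LandmarkSet:
    positions: dict[str, np.ndarray] = {}
    extras: dict[str, list[float]] = {}
    for name, xyz, lineno in rows:
        if name in positions or name in extras:
            raise FormatError(f"duplicate landmark {name!r} (line {lineno})")
        if name in LANDMARK_REGISTRY:
            positions[name] = np.asarray(xyz, dtype=float)
        else:
            warnings.warn(f"unknown landmark {name!r}; kept in metadata", stacklevel=3)
            extras[name] = [float(v) for v in xyz]
    if extras:
        metadata = {**metadata, "unknown_points": extras}
    return LandmarkSet(positions, sex=sex, metadata=metadata)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (.csv or .json); units are mm.

    Unknown landmark names are retained in metadata with a warning; a
    malformed row raises :class:`FormatError` with its line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        rows = [(str(n), p, 0) for n, p in raw.get("landmarks", {}).items()]
        return _landmarks_from_rows(
            rows, raw.get("sex", "female"), dict(raw.get("metadata", {}))
        )

    metadata: dict = {}
    sex = "female"
    rows = []
    with path.open(newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if ":" in stripped:
                    key, _, value = stripped.lstrip("# ").partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "sex":
                        sex = value
                    else:
                        metadata[key] = value
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                if header[:4] != ["name", "x", "y", "z"]:
                    raise FormatError(
                        f"{path}: expected header name,x,y,z (line {lineno})"
                    )
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}: short row at line {lineno}")
            name = fields[0].strip()
            try:
                xyz = [float(v) for v in fields[1:4]]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric coordinate at line {lineno}"
                ) from None
            rows.append((name, xyz, lineno))
        if header is None:
            raise FormatError(f"{path}: empty landmark file")
    return _landmarks_from_rows(rows, sex, metadata)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set (.csv or .json); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "sex": landmarks.sex,
            "metadata": {
                k: v for k, v in landmarks.metadata.items() if _jsonable(v)
            },
            "landmarks": {n: list(map(float, p)) for n, p in landmarks.positions.items()},
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    lines = [f"# sex: {landmarks.sex}"]
    for key, value in landmarks.metadata.items():
        if isinstance(value, (str, int, float)):
            lines.append(f"# {key}: {value}")
    lines.append("name,x,y,z")
    for name, p in landmarks.positions.items():
        # Python float repr round-trips exactly
        lines.append(f"{name},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}")
    path.write_text("\n".join(lines) + "\n")


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_plan(plan: SurgicalPlan, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize a surgical plan to JSON (lossless round-trip)."""
    payload = {
        "maxilla": {
            "rotation_deg": list(map(float, plan.maxilla_rotation)),
            "translation_mm": list(map(float, plan.maxilla_translation)),
        },
        "mandible": {
            "rotation_deg": list(map(float, plan.mandible_rotation)),
            "translation_mm": list(map(float, plan.mandible_translation)),
        },
        "chin": {"translation_mm": list(map(float, plan.chin_translation))},
        "provenance": plan.provenance,
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2))


def read_plan(path: str | Path) -> SurgicalPlan:
    """Read a plan JSON; rejects a nonzero chin rotation (type invariant)."""
    raw = json.loads(Path(path).read_text())
    for segment in ("maxilla", "mandible", "chin"):
        if segment not in raw:
            raise FormatError(f"plan file missing segment {segment!r}")
    chin = raw["chin"]
    if "rotation_deg" in chin and np.any(np.asarray(chin["rotation_deg"], dtype=float)):
        raise FormatError("chin rotation must be zero (translation-only segment)")
    try:
        return SurgicalPlan(
            maxilla_rotation=raw["maxilla"]["rotation_deg"],
            maxilla_translation=raw["maxilla"]["translation_mm"],
            mandible_rotation=raw["mandible"]["rotation_deg"],
            mandible_translation=raw["mandible"]["translation_mm"],
            chin_translation=chin["translation_mm"],
            provenance=raw.get("provenance", "ai"),
        )
    except KeyError as exc:
        raise FormatError(f"plan file missing key {exc.args[0]!r}") from None


def write_cohort(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(path: str | Path, payload: dict, seed: int | None, options: dict) -> None:
    """Write a JSON report embedding the seed and a digest of the options."""
    digest = hashlib.sha256(
        json.dumps(options, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    full = {"seed": seed, "config_digest": digest, **payload}
    Path(path).write_text(json.dumps(full, indent=2, default=float))
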