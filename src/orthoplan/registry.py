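"""Shared registries: landmark names, the measurement battery, diagnostic labels.

Single source of truth so that the geometry, planner, cohort and diagnosis
layers cannot drift apart on naming or ordering.
"""

from __future__ import annotations

#: Anatomical landmark registry: code -> description.
LANDMARK_REGISTRY: dict[str, str] = {
    "S": "sella, center of the sella turcica",
    "N": "nasion, frontonasal suture",
    "A": "subspinale (point A), deepest point of the anterior maxilla",
    "B": "supramentale (point B), deepest point of the anterior mandible",
    "Pog": "pogonion, most anterior point of the bony chin",
    "Me": "menton, most inferior point of the bony chin",
    "Gn": "gnathion, midpoint between pogonion and menton",
    "ANS": "anterior nasal spine",
    "PNS": "posterior nasal spine",
    "Or_L": "left orbitale, lowest point of the left orbital rim",
    "Or_R": "right orbitale",
    "Po_L": "left porion, superior margin of the left external auditory meatus",
    "Po_R": "right porion",
    "Go_L": "left gonion, mandibular angle",
    "Go_R": "right gonion",
    "U1": "upper central incisor tip (midpoint)",
    "L1": "lower central incisor tip (midpoint)",
    "U6_L": "left upper first molar, mesiobuccal cusp",
    "U6_R": "right upper first molar, mesiobuccal cusp",
}

#: The cephalometric measurement battery, in canonical order.
MEASUREMENTS: tuple[str, ...] = (
    "SNA",
    "SNB",
    "ANB",
    "SNPog",
    "OP_FHP_pitch",
    "OP_FHP_roll",
    "OrU6_ratio",
    "GoMe_ratio",
    "Pog_MSP",
    "NANS_ANSMe",
)

#: Measurements that are plain (unsigned) angles, constrained to [0, 180] deg.
ANGLE_MEASUREMENTS: frozenset[str] = frozenset({"SNA", "SNB", "SNPog"})

#: Measurements that are strictly positive ratios (percent).
RATIO_MEASUREMENTS: frozenset[str] = frozenset(
    {"OrU6_ratio", "GoMe_ratio", "NANS_ANSMe"}
)

#: The six diagnostic labels, in canonical (model output) order.
LABELS: tuple[str, ...] = (
    "maxillary_overdevelopment",
    "maxillary_underdevelopment",
    "maxillary_deviation",
    "mandibular_overdevelopment",
    "mandibular_underdevelopment",
    "mandibular_deviation",
)

SEXES: tuple[str, str] = ("male", "female")

#: Surgical segment identifiers.
SEGMENTS: tuple[str, str, str] = ("maxilla", "mandible", "chin")
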