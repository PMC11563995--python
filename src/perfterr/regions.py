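"""Region taxonomy of the trochanteric analysis.

Four bone regions of interest — greater trochanter (GT), intertrochanteric
(IT), lesser trochanter (LT) and subtrochanteric (ST) — each split into an
anterior and a posterior half, plus a non-enhancing muscle reference region
used for signal normalization. ``FULL`` denotes the union of the four bone
regions (the full trochanteric region).

Integer labels are fixed package-wide: each (region, subregion) pair owns one
label, so a region mask is the union of its two subregion labels and the
anterior/posterior partition holds by construction.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = ("GT", "IT", "LT", "ST")
SUBREGIONS: tuple[str, ...] = ("anterior", "posterior")

FULL = "FULL"
MUSCLE = "MUSCLE"
BACKGROUND = "BACKGROUND"
BACKGROUND_LABEL = 0
MUSCLE_LABEL = 9

ARTERIES: tuple[str, ...] = ("MFCA", "LFCA")
SIDES: tuple[str, ...] = ("left", "right")

#: label -> (region, subregion); subregion is None for the muscle reference.
CANONICAL_LABELS: dict[int, tuple[str, str | None]] = {
    1: ("GT", "anterior"),
    2: ("GT", "posterior"),
    3: ("IT", "anterior"),
    4: ("IT", "posterior"),
    5: ("LT", "anterior"),
    6: ("LT", "posterior"),
    7: ("ST", "anterior"),
    8: ("ST", "posterior"),
    MUSCLE_LABEL: (MUSCLE, None),
}

#: The 8 bone (region, subregion) cells carrying ground-truth fractions.
BONE_SUBREGION_CELLS: tuple[tuple[str, str], ...] = tuple(
    (r, s) for r in REGIONS for s in SUBREGIONS
)

#: The 15 report cells, in report row order: full region, the four regions,
#: their eight subregions, then the full-region anterior/posterior halves.
TABLE_CELLS: tuple[tuple[str, str | None], ...] = (
    (FULL, None),
    ("ST", None),
    ("LT", None),
    ("IT", None),
    ("GT", None),
    ("ST", "anterior"),
    ("ST", "posterior"),
    ("LT", "anterior"),
    ("LT", "posterior"),
    ("IT", "anterior"),
    ("IT", "posterior"),
    ("GT", "anterior"),
    ("GT", "posterior"),
    (FULL, "anterior"),
    (FULL, "posterior"),
)


def cell_name(region: str, subregion: str | None) -> str:
    """Human-readable report-row name for a (region, subregion) cell."""
    names = {
        FULL: "Full trochanteric region",
        "GT": "Greater trochanter (GT)",
        "IT": "Intertrochanteric (IT)",
        "LT": "Lesser trochanter (LT)",
        "ST": "Subtrochanteric (ST)",
    }
    base = names[region]
    if subregion is None:
        return base
    short = {FULL: "Full trochanteric", "GT": "GT", "IT": "IT", "LT": "LT", "ST": "ST"}
    return f"{short[region]} {subregion}"


def other_artery(artery: str) -> str:
    if artery == "MFCA":
        return "LFCA"
    if artery == "LFCA":
        return "MFCA"
    raise ValueError(f"unknown artery {artery!r}; allowed: {ARTERIES}")
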