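"""Antibody panel definitions and cut-off binarization.

The five antibodies used by the published cell-of-origin algorithms are
CD10, BCL6, FOXP1, GCET1 and MUM1, conventionally referred to by numeric
tags 1-5. Staining is scored as the percentage of positive tumor cells
(0-100); a marker is called *positive* when that percentage reaches a
cut-off, inclusive (a "30%" cut-off means >= 30% positive cells).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

#: Canonical antibody order.
MARKERS: tuple[str, ...] = ("CD10", "BCL6", "FOXP1", "GCET1", "MUM1")

#: Numeric tag per antibody (1=CD10, 2=BCL6, 3=FOXP1, 4=GCET1, 5=MUM1).
MARKER_TAGS: dict[str, int] = {m: i + 1 for i, m in enumerate(MARKERS)}
TAG_TO_MARKER: dict[int, str] = {t: m for m, t in MARKER_TAGS.items()}

#: Uniform 30% scheme, the default discretization for the trained
#: (LDA / Bayesian) classifiers.
DEFAULT_CUTOFFS: dict[str, float] = {m: 30.0 for m in MARKERS}

#: Marker-specific staining cut-offs used when simulating cohorts:
#: germinal-center markers CD10/BCL6 and MUM1 are conventionally called at
#: 30%, FOXP1 and GCET1 at higher (60%) thresholds.
STAINING_CUTOFFS: dict[str, float] = {
    "CD10": 30.0,
    "BCL6": 30.0,
    "FOXP1": 60.0,
    "GCET1": 60.0,
    "MUM1": 30.0,
}

MarkerProfile = Mapping[str, float]
CutoffScheme = Mapping[str, float]


class MarkerError(ValueError):
    """Raised for invalid marker names, values or cut-offs."""


def canonical_marker(name: str) -> str:
    """Resolve a marker given by name (any case) or numeric tag."""
    if isinstance(name, (int,)) or (isinstance(name, str) and name.isdigit()):
        tag = int(name)
        if tag not in TAG_TO_MARKER:
            raise MarkerError(f"unknown antibody tag {tag!r}; valid tags are 1-5")
        return TAG_TO_MARKER[tag]
    upper = str(name).strip().upper()
    if upper not in MARKER_TAGS:
        raise MarkerError(
            f"unknown antibody {name!r}; expected one of {', '.join(MARKERS)}"
        )
    return upper


def tags_to_markers(tags) -> tuple[str, ...]:
    """Map an iterable of numeric tags to marker names in canonical order."""
    tagset = set()
    for t in tags:
        t = int(t)
        if t not in TAG_TO_MARKER:
            raise MarkerError(f"unknown antibody tag {t}; valid tags are 1-5")
        tagset.add(t)
    return tuple(TAG_TO_MARKER[t] for t in sorted(tagset))


def markers_to_tags(markers) -> tuple[int, ...]:
    """Map marker names to their sorted numeric tags."""
    return tuple(sorted(MARKER_TAGS[canonical_marker(m)] for m in markers))


def validate_cutoffs(scheme: CutoffScheme) -> dict[str, float]:
    """Validate a cut-off scheme: thresholds must lie in (0, 100]."""
    out = {}
    for marker, cut in scheme.items():
        marker = canonical_marker(marker)
        cut = float(cut)
        if not (0.0 < cut <= 100.0):
            raise MarkerError(f"cut-off for {marker} must be in (0, 100], got {cut}")
        out[marker] = cut
    return out


def is_missing(value) -> bool:
    """True for absent marker readings (None or NaN)."""
    return value is None or (isinstance(value, float) and math.isnan(value))


def binarize(profile: MarkerProfile, scheme: CutoffScheme) -> dict[str, Optional[bool]]:
    """Dichotomize percent-positive staining at per-marker cut-offs.

    A marker is positive when its percentage is >= the cut-off (inclusive).
    Missing readings propagate as ``None`` flags; markers absent from the
    profile are omitted from the result.
    """
    scheme = validate_cutoffs(scheme)
    flags: dict[str, Optional[bool]] = {}
    for marker, cut in scheme.items():
        if marker not in profile:
            continue
        value = profile[marker]
        if is_missing(value):
            flags[marker] = None
        else:
            value = float(value)
            if not (0.0 <= value <= 100.0):
                raise MarkerError(
                    f"{marker} staining percentage {value} outside [0, 100]"
                )
            flags[marker] = value >= cut
    return flags
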