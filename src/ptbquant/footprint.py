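"""Tethered hydroxyl-radical footprint quantification.

A single reactive cysteine engineered near the RNA-binding surface of one
protein domain is conjugated to Fe-BABE; locally generated hydroxyl radicals
cleave RNA close to that domain's binding site, and cleavage products are
read out as gel bands (one lane per probe construct).  The lane from the
Cys-less parental protein defines the background cleavage.

The quantification pipeline is:

1. :func:`normalize_lane` — correct loading differences using designated
   background bands whose intensity is invariant across lanes;
2. :func:`cleavage_ratios` — per-band ratio of normalized probe to
   normalized control intensity;
3. :func:`classify_ratio` — a ratio >= 2 is a strong cleavage, 1.2 <= ratio
   < 2 a weak one, anything below is unclassified;
4. :func:`construct_to_reference_coord` — map construct coordinates across
   the 1060-nt intron deletion back to the full-length reference numbering
   (construct position 327 is immediately adjacent to reference 1388);
5. :func:`build_contact_map` — merge calls from all probes into a sorted
   contact map with per-window summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import DomainError, SchemaError

__all__ = [
    "STRONG_RATIO",
    "WEAK_RATIO",
    "DELETION_JUNCTION",
    "DELETION_LENGTH",
    "DEFAULT_WINDOWS",
    "LaneProfile",
    "CleavageCall",
    "ContactMap",
    "normalize_lane",
    "cleavage_ratios",
    "classify_ratio",
    "construct_to_reference_coord",
    "build_contact_map",
]

#: ratio at or above which a cleavage is classed as strong
STRONG_RATIO = 2.0
#: lower bound of the weak-cleavage ratio range [1.2, 2)
WEAK_RATIO = 1.2

#: last construct position before the intron deletion; the next construct
#: nucleotide corresponds to reference position DELETION_JUNCTION + 1 + DELETION_LENGTH
DELETION_JUNCTION = 327
DELETION_LENGTH = 1060

#: U-rich annotation windows on the reference sequence (1-based, inclusive):
#: the exonic silencer URE6 and the downstream intronic URI6 element
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "URE6": (239, 254),
    "URI6": (284, 300),
}


@dataclass
class LaneProfile:
    """One gel lane: band positions, intensities and background designation.

    Parameters
    ----------
    lane_id : str
    probe : str
        Probe construct label (e.g. C1, C2, C3, CL, C4, Cys-less).
    bands : dict
        Band position (nt, construct coordinates) -> intensity (>= 0).
    background_ids : frozenset of int
        Positions of the designated invariant background bands.
    """

    lane_id: str
    probe: str
    bands: dict[int, float]
    background_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.bands = {int(p): float(v) for p, v in self.bands.items()}
        self.background_ids = frozenset(int(p) for p in self.background_ids)
        if any(v < 0 for v in self.bands.values()):
            raise DomainError("band intensities must be non-negative")
        if not self.background_ids:
            raise DomainError("at least one background band must be designated")
        missing = self.background_ids - self.bands.keys()
        if missing:
            raise DomainError(f"background bands absent from lane: {sorted(missing)}")


@dataclass
class CleavageCall:
    """A classified probe/control cleavage ratio at one reference position."""

    position_ref: int
    probe: str
    ratio: float
    strength: str

    def __post_init__(self) -> None:
        if self.strength != classify_ratio(self.ratio):
            raise DomainError(
                f"strength {self.strength!r} inconsistent with ratio {self.ratio}"
            )


@dataclass
class ContactMap:
    """Merged, sorted cleavage calls with annotation-window summaries."""

    calls: list[CleavageCall]
    windows: dict[str, tuple[int, int]]

    def window_summary(self) -> dict[str, dict[str, int]]:
        """Per-window counts of strong and weak calls (bounds inclusive)."""
        out: dict[str, dict[str, int]] = {}
        for name, (lo, hi) in self.windows.items():
            inside = [c for c in self.calls if lo <= c.position_ref <= hi]
            out[name] = {
                "strong": sum(c.strength == "strong" for c in inside),
                "weak": sum(c.strength == "weak" for c in inside),
            }
        return out


def normalize_lane(lane: LaneProfile, control: LaneProfile) -> LaneProfile:
    """Remove loading differences using the shared background bands.

    Every intensity in ``lane`` is divided by the mean ratio of lane to
    control intensity over the designated background bands, so the
    normalized lane's background bands average to the control's.
    Idempotent, and invariant to any global rescaling of the lane.
    """
    shared = lane.background_ids & control.background_ids
    if not shared:
        raise DomainError("lane and control share no designated background bands")
    ratios = []
    for p in sorted(shared):
        if control.bands[p] <= 0:
            raise DomainError(f"control background band at {p} has no intensity")
        ratios.append(lane.bands[p] / control.bands[p])
    scale = sum(ratios) / len(ratios)
    if scale <= 0:
        raise DomainError("lane background bands have no intensity")
    return LaneProfile(
        lane_id=lane.lane_id,
        probe=lane.probe,
        bands={p: v / scale for p, v in lane.bands.items()},
        background_ids=lane.background_ids,
    )


def cleavage_ratios(
    lane_norm: LaneProfile, control_norm: LaneProfile
) -> list[tuple[int, float]]:
    """Per-band ratio of normalized probe to normalized control intensity.

    Bands whose control intensity is zero cannot be quantified and are
    reported with a NaN ratio rather than raising.
    """
    missing = lane_norm.bands.keys() ^ control_norm.bands.keys()
    if missing:
        raise SchemaError(
            f"lanes do not share the same band positions; unmatched: {sorted(missing)}"
        )
    out: list[tuple[int, float]] = []
    for p in sorted(lane_norm.bands):
        c = control_norm.bands[p]
        out.append((p, lane_norm.bands[p] / c if c > 0 else float("nan")))
    return out


def classify_ratio(ratio: float) -> str:
    """Classify a probe/control cleavage ratio as strong, weak or none.

    Strong: ratio >= 2.  Weak: 1.2 <= ratio < 2.  Below 1.2: none.
    """
    if ratio < 0:
        raise DomainError(f"cleavage ratio must be non-negative, got {ratio}")
    if ratio >= STRONG_RATIO:
        return "strong"
    if ratio >= WEAK_RATIO:
        return "weak"
    return "none"


def construct_to_reference_coord(pos_construct: int) -> int:
    """Map a construct coordinate to full-length reference numbering.

    The construct deletes 1060 nt of the intron downstream of position 327,
    so construct positions <= 327 map to themselves and later positions are
    shifted by the deletion length (construct 328 -> reference 1388).
    """
    pos_construct = int(pos_construct)
    if pos_construct < 1:
        raise DomainError("positions are 1-based and positive")
    if pos_construct <= DELETION_JUNCTION:
        return pos_construct
    return pos_construct + DELETION_LENGTH


def build_contact_map(
    calls: list[CleavageCall],
    windows: dict[str, tuple[int, int]] | None = None,
) -> ContactMap:
    """Merge classified calls from all probes into a sorted contact map.

    Positions must already be in reference coordinates.  Duplicate
    (probe, position) pairs indicate an upstream bookkeeping error and are
    rejected.
    """
    seen: set[tuple[str, int]] = set()
    for c in calls:
        key = (c.probe, c.position_ref)
        if key in seen:
            raise SchemaError(f"duplicate call for probe/position {key}")
        seen.add(key)
    ordered = sorted(calls, key=lambda c: (c.position_ref, c.probe))
    return ContactMap(calls=ordered, windows=dict(windows or DEFAULT_WINDOWS))
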