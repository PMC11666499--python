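"""Points-based quantification of ACMG/AMP evidence.

Each evidence item maps to an integer point value by strength class
(BA/BS -4, BP -1, PP +1, PM +2, PS +4, PVS +8); the per-variant total is
binned into the five classification tiers (<= -4 benign, -3..-1 likely
benign, 0..5 VUS, 6..9 likely pathogenic, >= 10 pathogenic).  Totals inside
the VUS bin are further stratified into Low (0-1), Mid (2-3) and High (4-5)
subcategories.  The point map is an integer adaptation of the Bayesian
odds-of-pathogenicity framework; the posterior machinery itself is out of
scope here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

from .catalog import Polarity, Strength, StrengthProfile, Tier, strength_class

__all__ = [
    "DEFAULT_POINTS",
    "VusBand",
    "QuantificationResult",
    "points_for_strength",
    "quantify",
    "classify_points",
    "vus_band",
    "quantify_profile",
]

#: Point value per strength class.  BA scores -4, the same as BS, which is
#: weaker than the -8 some published calibrations use for stand-alone
#: benign evidence; the map is injectable so alternatives can be tested.
DEFAULT_POINTS: Mapping[str, int] = {
    "BA": -4,
    "BS": -4,
    "BP": -1,
    "PP": 1,
    "PM": 2,
    "PS": 4,
    "PVS": 8,
}


class VusBand(str, enum.Enum):
    LOW = "low"
    MID = "mid"
    HIGH = "high"


@dataclass(frozen=True)
class QuantificationResult:
    points: int
    tier: Tier
    vus_band: Optional[VusBand]


def points_for_strength(
    strength: Strength,
    polarity: Polarity,
    points: Mapping[str, int] = DEFAULT_POINTS,
) -> int:
    """Point value of one evidence item of the given polarity and strength."""
    cls = strength_class(polarity, strength)
    try:
        return points[cls]
    except KeyError:
        raise ValueError(f"no point value for strength class {cls!r}") from None


def quantify(
    profile: StrengthProfile, points: Mapping[str, int] = DEFAULT_POINTS
) -> int:
    """Total points of a strength profile (empty profile scores 0)."""
    counts = profile.as_dict()
    unknown = set(counts) - set(points)
    if unknown:
        raise ValueError(f"point map lacks strength classes: {sorted(unknown)}")
    return sum(points[cls] * n for cls, n in counts.items())


def classify_points(points: int) -> Tier:
    """Tier bin of a points total.

    -4 sits in the benign bin (the table rule); bins are open-ended at both
    extremes, so no clamping is applied.
    """
    if points <= -4:
        return Tier.BENIGN
    if points <= -1:
        return Tier.LIKELY_BENIGN
    if points <= 5:
        return Tier.VUS
    if points <= 9:
        return Tier.LIKELY_PATHOGENIC
    return Tier.PATHOGENIC


def vus_band(points: int) -> Optional[VusBand]:
    """Low/Mid/High subcategory for totals inside the VUS bin, else None."""
    if 0 <= points <= 1:
        return VusBand.LOW
    if 2 <= points <= 3:
        return VusBand.MID
    if 4 <= points <= 5:
        return VusBand.HIGH
    return None


def quantify_profile(
    profile: StrengthProfile, points: Mapping[str, int] = DEFAULT_POINTS
) -> QuantificationResult:
    """Points, tier and (for VUS) subcategory in one call."""
    total = quantify(profile, points)
    tier = classify_points(total)
    band = vus_band(total) if tier is Tier.VUS else None
    return QuantificationResult(points=total, tier=tier, vus_band=band)
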