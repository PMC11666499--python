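"""AlphaMissense score categorization and conversion to ACMG evidence.

AlphaMissense assigns each missense variant a pathogenicity score in
[0, 1].  Scores below 0.34 are categorized benign, scores up to 0.564
ambiguous, and higher scores pathogenic — the same cutpoints the public
release uses for its likely_benign / ambiguous / likely_pathogenic classes.
A pathogenic category is injected into ACMG classification as PP3
(computational, supporting, +1 point), a benign category as BP4 (-1 point);
an ambiguous prediction contributes no evidence.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional, Sequence

import pandas as pd

from .catalog import (
    EvidenceCatalog,
    EvidenceCode,
    Tier,
    VariantRecord,
    load_default_catalog,
    parse_evidence_code,
)

__all__ = [
    "AmCategory",
    "CollapsedTier",
    "BENIGN_UPPER",
    "AMBIGUOUS_UPPER",
    "am_category",
    "am_to_evidence",
    "collapse_tier",
    "tier_equivalence",
    "read_alphamissense_tsv",
    "attach_am_scores",
]

logger = logging.getLogger(__name__)

#: Category cutpoints: score < BENIGN_UPPER -> benign;
#: score <= AMBIGUOUS_UPPER -> ambiguous; above -> pathogenic.
BENIGN_UPPER = 0.34
AMBIGUOUS_UPPER = 0.564


class AmCategory(str, enum.Enum):
    """AlphaMissense prediction class, ordered benign < ambiguous < pathogenic."""

    BENIGN = "benign"
    AMBIGUOUS = "ambiguous"
    PATHOGENIC = "pathogenic"

    @property
    def rank(self) -> int:
        return (AmCategory.BENIGN, AmCategory.AMBIGUOUS, AmCategory.PATHOGENIC).index(
            self
        )


class CollapsedTier(str, enum.Enum):
    """Three-level collapse of the five curated tiers (P/LP, VUS, B/LB)."""

    PATHOGENIC = "pathogenic"
    VUS = "vus"
    BENIGN = "benign"


def am_category(score: float) -> AmCategory:
    """Categorize an AlphaMissense score; scores outside [0, 1] are rejected."""
    try:
        value = float(score)
    except (TypeError, ValueError):
        raise ValueError(f"AlphaMissense score is not numeric: {score!r}") from None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"AlphaMissense score outside [0, 1]: {value}")
    if value < BENIGN_UPPER:
        return AmCategory.BENIGN
    if value <= AMBIGUOUS_UPPER:
        return AmCategory.AMBIGUOUS
    return AmCategory.PATHOGENIC


def am_to_evidence(
    category: AmCategory, catalog: Optional[EvidenceCatalog] = None
) -> Optional[EvidenceCode]:
    """ACMG computational evidence for an AM category.

    Pathogenic -> PP3, benign -> BP4, ambiguous -> None (no evidence, 0
    points).
    """
    if category is AmCategory.AMBIGUOUS:
        return None
    if catalog is None:
        catalog = load_default_catalog()
    code = "PP3" if category is AmCategory.PATHOGENIC else "BP4"
    return parse_evidence_code(code, catalog)


def collapse_tier(tier: Tier) -> CollapsedTier:
    """P/LP -> pathogenic, B/LB -> benign, VUS -> vus."""
    if tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC):
        return CollapsedTier.PATHOGENIC
    if tier in (Tier.BENIGN, Tier.LIKELY_BENIGN):
        return CollapsedTier.BENIGN
    return CollapsedTier.VUS


def tier_equivalence(category: AmCategory) -> CollapsedTier:
    """Collapsed curated tier an AM category is compared against.

    Pathogenic predictions are taken as equivalent to P/LP, benign to B/LB,
    and ambiguous to VUS.
    """
    return {
        AmCategory.PATHOGENIC: CollapsedTier.PATHOGENIC,
        AmCategory.AMBIGUOUS: CollapsedTier.VUS,
        AmCategory.BENIGN: CollapsedTier.BENIGN,
    }[category]


def resolve_am_category(record: VariantRecord) -> Optional[AmCategory]:
    """AM category of a record, derived from its score when available.

    If a precomputed category conflicts with the score-derived one, the
    score wins and the conflict is logged.
    """
    if record.am_score is not None:
        derived = am_category(record.am_score)
        if record.am_category is not None and record.am_category != derived:
            logger.warning(
                "variant %s: supplied AM category %s conflicts with "
                "score-derived %s; using the score",
                record.variant_id,
                getattr(record.am_category, "value", record.am_category),
                derived.value,
            )
        return derived
    if record.am_category is not None:
        return AmCategory(record.am_category)
    return None


def read_alphamissense_tsv(path) -> pd.DataFrame:
    """Read the public AlphaMissense TSV dialect.

    '#'-prefixed header lines are skipped; the first non-comment line is
    taken as the column header (CHROM, POS, ..., protein_variant,
    am_pathogenicity, am_class).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", header=0)
    if "am_pathogenicity" not in frame.columns:
        raise ValueError(
            "not an AlphaMissense table: missing 'am_pathogenicity' column"
        )
    return frame


def attach_am_scores(
    cohort: Sequence[VariantRecord],
    am_table: pd.DataFrame,
    key_column: str = "protein_variant",
) -> list[VariantRecord]:
    """Attach AM scores to cohort records by identifier match.

    Records absent from the table are left without a score; callers should
    flag and exclude them from AM-dependent analyses.
    """
    scores = dict(zip(am_table[key_column].astype(str), am_table["am_pathogenicity"]))
    unmatched = []
    for record in cohort:
        score = scores.get(record.variant_id)
        if score is None:
            unmatched.append(record.variant_id)
            continue
        record.am_score = float(score)
        record.am_category = am_category(record.am_score)
    if unmatched:
        logger.warning(
            "%d of %d variants not found in the AlphaMissense table "
            "(excluded from AM-dependent analyses): %s%s",
            len(unmatched),
            len(cohort),
            ", ".join(unmatched[:5]),
            "..." if len(unmatched) > 5 else "",
        )
    return list(cohort)
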