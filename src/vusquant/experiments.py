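"""Evidence-integration experiments: augmentation and replacement.

Two in-silico experiments probe how AlphaMissense-derived computational
evidence (PP3/BP4) moves points-based classifications:

* **Augmentation** adds the AM-derived item only to curated VUS that carry
  no computational evidence at all; every other variant is untouched.
* **Replacement** strips all existing computational-type evidence from
  in-scope variants (curated VUS, or the whole cohort) and substitutes the
  single AM-derived item — variants with no computational evidence simply
  gain the AM item.

An ambiguous AM prediction contributes nothing in either experiment, so a
variant can be eligible yet unchanged.  Outcomes carry the full per-variant
before/after bookkeeping plus tier-transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .alphamissense import AmCategory, am_to_evidence, resolve_am_category
from .catalog import (
    EvidenceCatalog,
    EvidenceType,
    Tier,
    VariantRecord,
    load_default_catalog,
    strength_profile,
)
from .quantify import quantify_profile

__all__ = [
    "ExperimentOutcome",
    "has_computational_evidence",
    "run_augmentation",
    "run_replacement",
    "transition_matrix",
]

TIER_LABELS = [t.value for t in (
    Tier.BENIGN,
    Tier.LIKELY_BENIGN,
    Tier.VUS,
    Tier.LIKELY_PATHOGENIC,
    Tier.PATHOGENIC,
)]


@dataclass
class ExperimentOutcome:
    """Per-variant and aggregate results of an integration experiment.

    ``per_variant`` has one row per cohort record: points/tier/band before
    and after, and whether the variant's evidence list was modified.
    ``transition_counts`` is the 5x5 tier_before x tier_after matrix over
    the whole cohort.
    """

    per_variant: pd.DataFrame
    n_points_changed: int
    n_tier_changed: int
    transition_counts: pd.DataFrame

    @property
    def n_variants(self) -> int:
        return len(self.per_variant)


def has_computational_evidence(variant: VariantRecord) -> bool:
    """True iff any evidence item is computational-type (PP3/BP4)."""
    return any(
        item.evidence_type is EvidenceType.COMPUTATIONAL for item in variant.evidence
    )


def _required_category(
    variant: VariantRecord, missing: list[str]
) -> Optional[AmCategory]:
    category = resolve_am_category(variant)
    if category is None:
        missing.append(variant.variant_id)
    return category


def _outcome(
    cohort: Sequence[VariantRecord],
    after_evidence: Sequence[list],
    modified_flags: Sequence[bool],
) -> ExperimentOutcome:
    rows = []
    for variant, evidence, modified in zip(cohort, after_evidence, modified_flags):
        before = quantify_profile(variant.profile())
        after = quantify_profile(strength_profile(evidence))
        rows.append(
            {
                "variant_id": variant.variant_id,
                "points_before": before.points,
                "points_after": after.points,
                "tier_before": before.tier.value,
                "tier_after": after.tier.value,
                "band_before": before.vus_band.value if before.vus_band else None,
                "band_after": after.vus_band.value if after.vus_band else None,
                "modified": modified,
            }
        )
    per_variant = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "points_before",
            "points_after",
            "tier_before",
            "tier_after",
            "band_before",
            "band_after",
            "modified",
        ],
    )
    transitions, n_tier_changed, _ = transition_matrix(
        per_variant["tier_before"].tolist(), per_variant["tier_after"].tolist()
    )
    n_points_changed = int(
        (per_variant["points_after"] != per_variant["points_before"]).sum()
    )
    return ExperimentOutcome(
        per_variant=per_variant,
        n_points_changed=n_points_changed,
        n_tier_changed=n_tier_changed,
        transition_counts=transitions,
    )


def run_augmentation(
    cohort: Sequence[VariantRecord],
    catalog: Optional[EvidenceCatalog] = None,
) -> ExperimentOutcome:
    """Add AM-derived PP3/BP4 to curated VUS lacking computational evidence.

    Eligible variants must carry an AM score or category; a missing one is
    an error naming the offending ids.  Ineligible variants pass through
    with ``modified=False`` and zero delta.
    """
    if catalog is None:
        catalog = load_default_catalog()
    missing: list[str] = []
    after_evidence = []
    modified_flags = []
    for variant in cohort:
        eligible = (
            variant.curated_tier is Tier.VUS
            and not has_computational_evidence(variant)
        )
        evidence = list(variant.evidence)
        modified = False
        if eligible:
            category = _required_category(variant, missing)
            if category is not None:
                extra = am_to_evidence(category, catalog)
                if extra is not None:
                    evidence.append(extra)
                    modified = True
        after_evidence.append(evidence)
        modified_flags.append(modified)
    if missing:
        raise ValueError(
            "eligible variants lack an AlphaMissense score/category: "
            + ", ".join(missing)
        )
    return _outcome(cohort, after_evidence, modified_flags)


def run_replacement(
    cohort: Sequence[VariantRecord],
    scope: str = "vus",
    catalog: Optional[EvidenceCatalog] = None,
) -> ExperimentOutcome:
    """Swap existing computational evidence for the single AM-derived item.

    For in-scope variants (curated VUS when ``scope="vus"``; every variant
    when ``scope="all"``) all computational-type items of both polarities
    are removed, then the AM-derived PP3/BP4 appended (nothing for an
    ambiguous prediction).  In-scope variants without computational
    evidence just gain the AM item, so the operation is idempotent: the AM
    item is itself computational and gets swapped for itself on a rerun.
    """
    if scope not in ("vus", "all"):
        raise ValueError(f"scope must be 'vus' or 'all', got {scope!r}")
    if catalog is None:
        catalog = load_default_catalog()
    missing: list[str] = []
    after_evidence = []
    modified_flags = []
    for variant in cohort:
        in_scope = scope == "all" or variant.curated_tier is Tier.VUS
        evidence = list(variant.evidence)
        modified = False
        if in_scope:
            category = _required_category(variant, missing)
            if category is not None:
                kept = [
                    item
                    for item in evidence
                    if item.evidence_type is not EvidenceType.COMPUTATIONAL
                ]
                extra = am_to_evidence(category, catalog)
                new_evidence = kept + ([extra] if extra is not None else [])
                modified = len(kept) != len(evidence) or extra is not None
                evidence = new_evidence
        after_evidence.append(evidence)
        modified_flags.append(modified)
    if missing:
        raise ValueError(
            "in-scope variants lack an AlphaMissense score/category: "
            + ", ".join(missing)
        )
    return _outcome(cohort, after_evidence, modified_flags)


def transition_matrix(
    before: Sequence, after: Sequence
) -> tuple[pd.DataFrame, int, float]:
    """5x5 tier transition counts plus the off-diagonal total and fraction."""
    if len(before) != len(after):
        raise ValueError(
            f"tier vectors differ in length: {len(before)} vs {len(after)}"
        )
    counts = pd.DataFrame(0, index=TIER_LABELS, columns=TIER_LABELS, dtype=int)
    for b, a in zip(before, after):
        b = b.value if isinstance(b, Tier) else str(b)
        a = a.value if isinstance(a, Tier) else str(a)
        counts.loc[b, a] += 1
    n = len(before)
    n_changed = int(counts.values.sum() - counts.values.trace())
    fraction = n_changed / n if n else 0.0
    return counts, n_changed, fraction
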