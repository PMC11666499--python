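"""Deterministic table fixtures and a seeded synthetic cohort generator.

The study cohort (5845 missense variants in 59 neuro/musculoskeletal
disease genes) is not released per-variant, but its published summary
tables determine per-variant cohorts exactly:

* ``fixture_from_contingency`` expands a 3x3 AM-vs-curated count table
  into individual records whose categories round-trip the counts.
* ``fixture_vus_table5`` expands the 20 printed VUS evidence-combination
  rows (4085 variants), including which rows carry computational evidence
  and how many variants per row receive an AM benign or pathogenic
  prediction, so the augmentation experiment is fully reproducible.
* ``fixture_vus_table6`` expands the 26 printed post-replacement rows.

``simulate_cohort`` additionally draws arbitrary-size cohorts emulating
the cohort's statistical structure (tier proportions, per-tier
AlphaMissense score mixtures with a bimodal VUS density, evidence
combinations weighted by their published frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphamissense import am_category, collapse_tier
from .catalog import (
    EvidenceCatalog,
    EvidenceCode,
    StrengthProfile,
    Tier,
    VariantRecord,
    load_default_catalog,
    parse_evidence_code,
)

__all__ = [
    "TABLE2A_COUNTS",
    "TABLE5_ROWS",
    "TABLE6_ROWS",
    "MixtureComponent",
    "CohortSpec",
    "fixture_from_contingency",
    "fixture_table2a",
    "fixture_vus_table5",
    "fixture_vus_table6",
    "simulate_cohort",
]

# AM prediction (rows: pathogenic, ambiguous, benign) vs collapsed curated
# tier (columns: P/LP, VUS, B/LB).
TABLE2A_COUNTS = np.array(
    [
        [1352, 2458, 38],
        [108, 403, 14],
        [116, 1224, 132],
    ]
)

# VUS evidence-combination rows: (count, PS, PM, PP, BP, BS, points,
# n AM-benign additions, n AM-pathogenic additions).  Rows whose addition
# columns are both zero carry pre-existing computational evidence and are
# ineligible for augmentation; in all other rows the remainder beyond the
# two addition counts is AM-ambiguous (eligible but inert).
TABLE5_ROWS: list[tuple[int, int, int, int, int, int, int, int, int]] = [
    (24, 0, 0, 0, 1, 0, -1, 0, 0),
    (16, 0, 0, 0, 0, 0, 0, 12, 1),
    (19, 0, 0, 1, 1, 0, 0, 0, 0),
    (35, 0, 0, 1, 0, 0, 1, 9, 0),
    (4, 0, 0, 2, 1, 0, 1, 0, 0),
    (406, 0, 1, 0, 1, 0, 1, 4, 2),
    (23, 0, 0, 2, 0, 0, 2, 1, 0),
    (546, 0, 1, 0, 0, 0, 2, 150, 318),
    (203, 0, 1, 1, 1, 0, 2, 0, 0),
    (1111, 0, 1, 1, 0, 0, 3, 0, 191),
    (4, 0, 0, 3, 0, 0, 3, 0, 0),
    (29, 0, 1, 2, 1, 0, 3, 0, 0),
    (71, 0, 2, 0, 1, 0, 3, 1, 2),
    (775, 0, 1, 2, 0, 0, 4, 6, 11),
    (2, 0, 1, 3, 1, 0, 4, 0, 0),
    (164, 0, 2, 0, 0, 0, 4, 40, 114),
    (40, 0, 2, 1, 1, 0, 4, 0, 0),
    (1, 1, 0, 1, 1, 0, 4, 0, 0),
    (450, 0, 2, 1, 0, 0, 5, 16, 54),
    (162, 0, 1, 3, 0, 0, 5, 0, 2),
]

# Post-replacement VUS rows: (count, PS, PM, PP, BP, BS, points).
TABLE6_ROWS: list[tuple[int, int, int, int, int, int, int]] = [
    (49, 0, 0, 0, 1, 0, -1),
    (1, 0, 0, 1, 2, 0, -1),
    (12, 0, 0, 0, 0, 0, 0),
    (38, 0, 0, 1, 1, 0, 0),
    (9, 0, 1, 0, 2, 0, 0),
    (9, 0, 0, 1, 0, 0, 1),
    (6, 0, 0, 2, 1, 0, 1),
    (617, 0, 1, 0, 1, 0, 1),
    (1, 0, 1, 1, 2, 0, 1),
    (8, 0, 0, 2, 0, 0, 2),
    (303, 0, 1, 1, 1, 0, 2),
    (186, 0, 1, 0, 0, 0, 2),
    (5, 0, 2, 0, 2, 0, 2),
    (2, 0, 0, 3, 0, 0, 3),
    (1083, 0, 1, 1, 0, 0, 3),
    (36, 0, 1, 2, 1, 0, 3),
    (133, 0, 2, 0, 1, 0, 3),
    (842, 0, 1, 2, 0, 0, 4),
    (2, 0, 1, 3, 1, 0, 4),
    (44, 0, 2, 0, 0, 0, 4),
    (42, 0, 2, 1, 1, 0, 4),
    (1, 1, 0, 1, 1, 0, 4),
    (153, 0, 1, 3, 0, 0, 5),
    (440, 0, 2, 1, 0, 0, 5),
    (2, 0, 1, 4, 0, 0, 6),
    (61, 0, 2, 2, 0, 0, 6),
]

# one canonical (non-computational) code per strength class
_CANONICAL_CODE = {
    "PVS": "PVS1",
    "PS": "PS3",
    "PM": "PM2",
    "PP": "PP1",
    "BP": "BP1",
    "BS": "BS1",
    "BA": "BA1",
}

# representative scores inside each AM category interval
_REPRESENTATIVE_SCORE = {"benign": 0.2, "ambiguous": 0.45, "pathogenic": 0.9}

# score intervals for seeded uniform draws that round-trip the category
_CATEGORY_INTERVAL = {
    "benign": (0.0, 0.33),
    "ambiguous": (0.34, 0.564),
    "pathogenic": (0.57, 1.0),
}


def _codes_from_profile(
    counts: dict[str, int],
    catalog: EvidenceCatalog,
    computational: bool,
) -> list[EvidenceCode]:
    """Realize a strength profile as concrete codes.

    When ``computational`` is set, one pathogenic-supporting item becomes
    PP3 (or, failing that, one benign-supporting item becomes BP4) so the
    variant counts as computational-evidence-bearing.  Which concrete code
    realizes each remaining count is immaterial to quantification, so one
    canonical code per class is used.
    """
    codes: list[str] = []
    remaining = dict(counts)
    if computational:
        if remaining.get("PP", 0) > 0:
            codes.append("PP3")
            remaining["PP"] -= 1
        elif remaining.get("BP", 0) > 0:
            codes.append("BP4")
            remaining["BP"] -= 1
        else:
            raise ValueError(
                "profile has no supporting-strength slot for a "
                "computational code"
            )
    for cls, n in remaining.items():
        codes.extend([_CANONICAL_CODE[cls]] * n)
    return [parse_evidence_code(c, catalog) for c in codes]


def fixture_from_contingency(
    counts, seed: int = 0, catalog: Optional[EvidenceCatalog] = None
) -> list[VariantRecord]:
    """Expand a 3x3 AM-vs-curated count table into per-variant records.

    Rows are AM categories (pathogenic, ambiguous, benign), columns the
    collapsed curated tiers (P/LP, VUS, B/LB).  P/LP and B/LB cells are
    split deterministically (alternating) between their two tiers; AM
    scores are drawn uniformly inside the row category's interval so the
    derived category round-trips exactly.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (3, 3):
        raise ValueError(f"expected a 3x3 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative")
    rng = np.random.default_rng(seed)
    am_names = ["pathogenic", "ambiguous", "benign"]
    tier_pairs = [
        (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC),
        (Tier.VUS, Tier.VUS),
        (Tier.BENIGN, Tier.LIKELY_BENIGN),
    ]
    cohort: list[VariantRecord] = []
    for i, am_name in enumerate(am_names):
        lo, hi = _CATEGORY_INTERVAL[am_name]
        for j, pair in enumerate(tier_pairs):
            for k in range(table[i, j]):
                score = float(rng.uniform(lo, hi))
                cohort.append(
                    VariantRecord(
                        variant_id=f"C{i}{j}-{k:04d}",
                        curated_tier=pair[k % 2],
                        am_score=score,
                        am_category=am_category(score),
                    )
                )
    return cohort


def fixture_table2a(seed: int = 0) -> list[VariantRecord]:
    """The published 5845-variant AM-vs-curated contingency cohort."""
    return fixture_from_contingency(TABLE2A_COUNTS, seed=seed)


def fixture_vus_table5(catalog: Optional[EvidenceCatalog] = None) -> list[VariantRecord]:
    """The 4085-variant curated-VUS cohort behind the augmentation experiment.

    Each published evidence-combination row is expanded into ``count``
    records with the stated strength profile.  Within a row, the first
    ``n_benign`` records carry an AM-benign score, the next
    ``n_pathogenic`` an AM-pathogenic score, and the remainder an
    AM-ambiguous score (eligible for augmentation but contributing no
    evidence).  Rows with no published additions carry PP3 or BP4 among
    their items and are therefore ineligible.
    """
    if catalog is None:
        catalog = load_default_catalog()
    cohort: list[VariantRecord] = []
    for r, (count, ps, pm, pp, bp, bs, _, n_ben, n_path) in enumerate(TABLE5_ROWS):
        computational = n_ben == 0 and n_path == 0
        profile_counts = {"PS": ps, "PM": pm, "PP": pp, "BP": bp, "BS": bs}
        evidence = _codes_from_profile(profile_counts, catalog, computational)
        for k in range(count):
            if not computational and k < n_ben:
                am_name = "benign"
            elif not computational and k < n_ben + n_path:
                am_name = "pathogenic"
            else:
                am_name = "ambiguous"
            cohort.append(
                VariantRecord(
                    variant_id=f"T5R{r + 1:02d}-{k:04d}",
                    curated_tier=Tier.VUS,
                    evidence=list(evidence),
                    am_score=_REPRESENTATIVE_SCORE[am_name],
                )
            )
    return cohort


def fixture_vus_table6(catalog: Optional[EvidenceCatalog] = None) -> list[VariantRecord]:
    """The 4085 post-replacement VUS strength profiles as records."""
    if catalog is None:
        catalog = load_default_catalog()
    cohort: list[VariantRecord] = []
    for r, (count, ps, pm, pp, bp, bs, _) in enumerate(TABLE6_ROWS):
        profile_counts = {"PS": ps, "PM": pm, "PP": pp, "BP": bp, "BS": bs}
        evidence = _codes_from_profile(profile_counts, catalog, computational=False)
        for k in range(count):
            cohort.append(
                VariantRecord(
                    variant_id=f"T6R{r + 1:02d}-{k:04d}",
                    curated_tier=Tier.VUS,
                    evidence=list(evidence),
                )
            )
    return cohort


@dataclass(frozen=True)
class MixtureComponent:
    """One bounded unimodal component on [0, 1].

    Draws come from Beta(mean * concentration, (1 - mean) * concentration),
    so ``mean`` is the exact component mean and ``concentration`` sets the
    spread (larger = tighter).
    """

    mean: float
    concentration: float
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError(f"component mean outside (0, 1): {self.mean}")
        if self.concentration <= 0 or self.weight < 0:
            raise ValueError("concentration must be > 0 and weight >= 0")


def _mixture_mean(components: Sequence[MixtureComponent]) -> float:
    return sum(c.mean * c.weight for c in components)


# evidence-combination templates per tier: (weight, counts, computational)
_VUS_TEMPLATES = [
    (count, {"PS": ps, "PM": pm, "PP": pp, "BP": bp, "BS": bs}, nb == 0 and np_ == 0)
    for count, ps, pm, pp, bp, bs, _, nb, np_ in TABLE5_ROWS
]
_DEFAULT_TEMPLATES: dict[Tier, list[tuple[float, dict[str, int], bool]]] = {
    Tier.VUS: _VUS_TEMPLATES,
    Tier.PATHOGENIC: [
        (1.0, {"PVS": 1, "PS": 1, "PM": 1}, False),
        (1.0, {"PS": 2, "PM": 2}, False),
    ],
    Tier.LIKELY_PATHOGENIC: [
        (1.0, {"PS": 1, "PM": 1, "PP": 1}, False),
        (1.0, {"PM": 3, "PP": 1}, False),
    ],
    Tier.BENIGN: [
        (1.0, {"BA": 1, "BS": 1}, False),
        (1.0, {"BS": 2}, False),
    ],
    Tier.LIKELY_BENIGN: [
        (1.0, {"BP": 1}, False),
        (1.0, {"BP": 2}, False),
    ],
}


def _default_tier_proportions() -> dict[Tier, float]:
    # published collapsed counts 1576 P/LP : 184 B/LB : 4085 VUS out of
    # 5845, with each collapsed pair split evenly between its two tiers
    n = 5845
    return {
        Tier.BENIGN: 92 / n,
        Tier.LIKELY_BENIGN: 92 / n,
        Tier.VUS: 4085 / n,
        Tier.LIKELY_PATHOGENIC: 788 / n,
        Tier.PATHOGENIC: 788 / n,
    }


def _default_am_mixture() -> dict[str, list[MixtureComponent]]:
    # per-collapsed-tier score mixtures; means match the published per-class
    # means (benign 0.3, pathogenic 0.85, VUS 0.64), and the VUS density is
    # bimodal with modes near 0.2 and 0.8
    return {
        "benign": [MixtureComponent(0.3, 5.0, 1.0)],
        "pathogenic": [MixtureComponent(0.85, 12.0, 1.0)],
        "vus": [
            MixtureComponent(0.2, 10.0, 4 / 15),
            MixtureComponent(0.8, 10.0, 11 / 15),
        ],
    }


@dataclass
class CohortSpec:
    """Parameters of the stochastic cohort generator."""

    n_variants: int = 5845
    tier_proportions: dict = field(default_factory=_default_tier_proportions)
    am_mixture: dict = field(default_factory=_default_am_mixture)
    evidence_templates: dict = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_TEMPLATES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.tier_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tier proportions sum to {total}, not 1")
        for name, components in self.am_mixture.items():
            wsum = sum(c.weight for c in components)
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture weights for {name!r} sum to {wsum}, not 1"
                )

    def expected_am_mean(self, collapsed: str) -> float:
        return _mixture_mean(self.am_mixture[collapsed])


def simulate_cohort(
    spec: Optional[CohortSpec] = None,
    catalog: Optional[EvidenceCatalog] = None,
) -> list[VariantRecord]:
    """Draw a seeded synthetic cohort from a :class:`CohortSpec`.

    Each record gets a tier from the tier proportions, an evidence
    combination from the tier's weighted templates, and an AM score from
    the collapsed tier's mixture.  The draw is a pure function of
    (spec, seed): identical specs yield identical cohorts.
    """
    if spec is None:
        spec = CohortSpec()
    if catalog is None:
        catalog = load_default_catalog()
    rng = np.random.default_rng(spec.seed)
    tiers = list(spec.tier_proportions)
    probs = np.array([spec.tier_proportions[t] for t in tiers], dtype=float)
    cohort: list[VariantRecord] = []
    for k in range(spec.n_variants):
        tier = tiers[int(rng.choice(len(tiers), p=probs))]
        templates = spec.evidence_templates[tier]
        weights = np.array([w for w, _, _ in templates], dtype=float)
        weights /= weights.sum()
        _, counts, computational = templates[int(rng.choice(len(templates), p=weights))]
        evidence = _codes_from_profile(dict(counts), catalog, computational)
        components = spec.am_mixture[collapse_tier(tier).value]
        cw = np.array([c.weight for c in components], dtype=float)
        comp = components[int(rng.choice(len(components), p=cw))]
        a = comp.mean * comp.concentration
        b = (1.0 - comp.mean) * comp.concentration
        score = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        cohort.append(
            VariantRecord(
                variant_id=f"SIM-{k:05d}",
                curated_tier=tier,
                evidence=evidence,
                am_score=score,
                am_category=am_category(score),
            )
        )
    return cohort
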