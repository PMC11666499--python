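"""Augmentation and replacement experiments and transition bookkeeping."""

import pandas as pd
import pytest

from vusquant.catalog import Tier, VariantRecord, parse_evidence_list
from vusquant.experiments import (
    has_computational_evidence,
    run_augmentation,
    run_replacement,
    transition_matrix,
)


def make_variant(catalog, vid, tier, codes, am_score=None):
    return VariantRecord(
        vid, tier, parse_evidence_list(codes, catalog), am_score=am_score
    )


@pytest.mark.parametrize(
    "codes, expected",
    [
        (["PM2", "PP3"], True),
        (["BP4"], True),
        (["PM2", "PP1"], False),
        ([], False),
    ],
)
def test_has_computational_evidence(catalog, codes, expected):
    variant = make_variant(catalog, "v", Tier.VUS, codes)
    assert has_computational_evidence(variant) is expected


def test_augmentation_moves_eligible_vus(catalog):
    cohort = [
        # evidence-free VUS, AM benign: 0 -> -1, likely benign
        make_variant(catalog, "ben", Tier.VUS, [], am_score=0.1),
        # PM=2 PP=1 VUS, AM pathogenic: 5 -> 6, likely pathogenic
        make_variant(catalog, "path", Tier.VUS, ["PM2", "PM2", "PP1"], am_score=0.9),
        # evidence-free VUS, AM ambiguous: untouched
        make_variant(catalog, "amb", Tier.VUS, [], am_score=0.45),
        # VUS already carrying PP3: untouched regardless of AM
        make_variant(catalog, "comp", Tier.VUS, ["PM2", "PP3"], am_score=0.9),
        # non-VUS: untouched
        make_variant(catalog, "lp", Tier.LIKELY_PATHOGENIC,
                     ["PS3", "PM2", "PP1"], am_score=0.9),
    ]
    outcome = run_augmentation(cohort)
    pv = outcome.per_variant.set_index("variant_id")
    assert pv.loc["ben", ["points_before", "points_after"]].tolist() == [0, -1]
    assert pv.loc["ben", "tier_after"] == "likely_benign"
    assert pv.loc["path", ["points_before", "points_after"]].tolist() == [5, 6]
    assert pv.loc["path", "tier_after"] == "likely_pathogenic"
    for vid in ("amb", "comp", "lp"):
        assert pv.loc[vid, "points_after"] == pv.loc[vid, "points_before"]
    assert not pv.loc["comp", "modified"]
    assert not pv.loc["lp", "modified"]
    assert outcome.n_points_changed == 2
    assert outcome.n_tier_changed == 2


def test_augmentation_delta_is_at_most_one_supporting_item(catalog, table5_cohort):
    outcome = run_augmentation(table5_cohort)
    deltas = outcome.per_variant.points_after - outcome.per_variant.points_before
    assert set(deltas.unique()) <= {-1, 0, 1}


def test_augmentation_requires_am_on_eligible_variants(catalog):
    cohort = [make_variant(catalog, "noam", Tier.VUS, [])]
    with pytest.raises(ValueError, match="noam"):
        run_augmentation(cohort)


def test_augmentation_tolerates_missing_am_on_ineligible_variants(catalog):
    cohort = [make_variant(catalog, "p", Tier.PATHOGENIC, ["PS3", "PS3", "PM2"])]
    outcome = run_augmentation(cohort)
    assert outcome.n_points_changed == 0


def test_replacement_swaps_computational_items(catalog):
    cohort = [
        # PM=2, PP=2 with one PP3; AM pathogenic -> same profile, 6 points
        make_variant(catalog, "keep6", Tier.VUS,
                     ["PM2", "PM2", "PP1", "PP3"], am_score=0.9),
        # single BP4; AM benign -> single BP4 again, -1
        make_variant(catalog, "keepm1", Tier.VUS, ["BP4"], am_score=0.1),
        # no computational evidence, AM ambiguous -> untouched
        make_variant(catalog, "amb", Tier.VUS, ["PM2"], am_score=0.45),
        # two PP3 collapse to the single AM item: 4 -> 3
        make_variant(catalog, "dedup", Tier.VUS,
                     ["PM2", "PP3", "PP3"], am_score=0.9),
        # benign computational flipped by a pathogenic AM call: 1 -> 3
        make_variant(catalog, "flip", Tier.VUS, ["PM2", "BP4"], am_score=0.9),
    ]
    outcome = run_replacement(cohort, scope="vus")
    pv = outcome.per_variant.set_index("variant_id")
    assert pv.loc["keep6", ["points_before", "points_after"]].tolist() == [6, 6]
    assert pv.loc["keep6", "tier_after"] == "likely_pathogenic"
    assert pv.loc["keepm1", ["points_before", "points_after"]].tolist() == [-1, -1]
    assert pv.loc["amb", "points_after"] == pv.loc["amb", "points_before"]
    assert pv.loc["dedup", ["points_before", "points_after"]].tolist() == [4, 3]
    assert pv.loc["flip", ["points_before", "points_after"]].tolist() == [1, 3]


def test_replacement_scope_controls_non_vus(catalog):
    cohort = [
        make_variant(catalog, "lp", Tier.LIKELY_PATHOGENIC,
                     ["PS3", "PM2", "BP4"], am_score=0.9),
    ]
    vus_only = run_replacement(cohort, scope="vus")
    assert vus_only.per_variant.loc[0, "points_after"] == 5  # untouched
    everyone = run_replacement(cohort, scope="all")
    assert everyone.per_variant.loc[0, "points_after"] == 7  # BP4 -> PP3


def test_replacement_is_idempotent(catalog, table5_cohort):
    first = run_replacement(table5_cohort, scope="vus")
    # apply the replacement to produce the post-replacement cohort, then rerun
    from vusquant.alphamissense import am_to_evidence, resolve_am_category
    from vusquant.catalog import EvidenceType

    replaced = []
    for v in table5_cohort:
        kept = [e for e in v.evidence
                if e.evidence_type is not EvidenceType.COMPUTATIONAL]
        extra = am_to_evidence(resolve_am_category(v), catalog)
        replaced.append(
            VariantRecord(v.variant_id, v.curated_tier,
                          kept + ([extra] if extra else []),
                          am_score=v.am_score)
        )
    second = run_replacement(replaced, scope="vus")
    assert second.per_variant.points_after.tolist() == (
        first.per_variant.points_after.tolist()
    )
    assert second.n_points_changed == 0


def test_invalid_scope_rejected(catalog):
    with pytest.raises(ValueError):
        run_replacement([], scope="some")


def test_transition_matrix_conservation(catalog, table5_cohort):
    outcome = run_augmentation(table5_cohort)
    counts = outcome.transition_counts
    n = len(table5_cohort)
    assert counts.values.sum() == n
    assert counts.values.trace() + outcome.n_tier_changed == n
    # row sums recover the quantified before-tier distribution: 24 of the
    # curated VUS already quantify to -1 (likely benign), the rest to 0..5
    assert counts.sum(axis=1)["vus"] == 4061
    assert counts.sum(axis=1)["likely_benign"] == 24


def test_transition_matrix_identical_vectors_diagonal():
    tiers = ["vus", "vus", "benign", "pathogenic"]
    counts, n_changed, fraction = transition_matrix(tiers, tiers)
    assert n_changed == 0
    assert fraction == 0.0
    assert counts.values.sum() == counts.values.trace() == 4


def test_transition_matrix_length_mismatch():
    with pytest.raises(ValueError):
        transition_matrix(["vus"], ["vus", "benign"])
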