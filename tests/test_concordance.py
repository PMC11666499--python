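"""Contingency tables, binary collapse metrics and auxiliary statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vusquant.alphamissense import AmCategory
from vusquant.catalog import Tier
from vusquant.concordance import (
    ACMG_COLS,
    AM_ROWS,
    BinaryMetrics,
    chi_square_independence,
    comparison_group,
    comparison_group_counts,
    contingency_3x3,
    mean_ci,
    metrics_excluding_uncertain,
    metrics_path_vs_rest,
    spearman_rho,
)
from vusquant.datasets import TABLE2A_COUNTS, fixture_from_contingency


def as_table(values):
    return pd.DataFrame(np.asarray(values), index=AM_ROWS, columns=ACMG_COLS)


@pytest.fixture(scope="module")
def table2a():
    return as_table(TABLE2A_COUNTS)


def test_contingency_reproduces_published_counts(table2a_cohort):
    table = contingency_3x3(table2a_cohort)
    assert (table.to_numpy() == TABLE2A_COUNTS).all()
    assert table.sum(axis=1).tolist() == [3848, 525, 1472]
    assert table.sum(axis=0).tolist() == [1576, 4085, 184]


def test_contingency_empty_cohort_all_zero():
    table = contingency_3x3([])
    assert table.to_numpy().sum() == 0


def test_pathogenic_vs_benign_corner_cells(table2a):
    metrics = metrics_excluding_uncertain(table2a)
    assert (metrics.tp, metrics.fp, metrics.fn, metrics.tn) == (1352, 38, 116, 132)
    rendered = metrics.as_dict()
    assert rendered["sensitivity_percent"] == 92
    assert rendered["specificity_percent"] == 78
    assert rendered["ppv_percent"] == 97
    assert rendered["npv_percent"] == 53


def test_pathogenic_vs_benign_diagonal_table_is_perfect():
    metrics = metrics_excluding_uncertain(as_table([[7, 0, 0], [0, 5, 0], [0, 0, 3]]))
    assert metrics.sensitivity == metrics.specificity == 1.0
    assert metrics.ppv == metrics.npv == 1.0


def test_pathogenic_vs_rest_cells_and_percents(table2a):
    metrics = metrics_path_vs_rest(table2a)
    assert metrics.tp == 1352
    assert metrics.fn == 108 + 116
    assert metrics.fp == 2458 + 38
    assert metrics.tn == 403 + 14 + 1224 + 132
    rendered = metrics.as_dict()
    assert rendered["sensitivity_percent"] == 86
    assert rendered["ppv_percent"] == 35
    assert rendered["npv_percent"] == 89


def test_zero_denominator_metrics_absent():
    metrics = metrics_path_vs_rest(as_table([[0, 0, 0], [0, 5, 0], [0, 0, 3]]))
    assert metrics.sensitivity is None  # no curated-pathogenic column? tp+fn=0
    assert metrics.as_dict()["sensitivity_percent"] is None
    assert BinaryMetrics(0, 0, 0, 0).ppv is None


@settings(deadline=None, max_examples=50)
@given(scale=st.integers(2, 20))
def test_metric_fractions_invariant_to_uniform_scaling(scale):
    base = as_table(TABLE2A_COUNTS)
    scaled = as_table(TABLE2A_COUNTS * scale)
    for collapse in (metrics_excluding_uncertain, metrics_path_vs_rest):
        m0, m1 = collapse(base), collapse(scaled)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(m1, name) == pytest.approx(getattr(m0, name))


@pytest.mark.parametrize(
    "tier, category, label",
    [
        (Tier.VUS, AmCategory.AMBIGUOUS, "VUS-amb"),
        (Tier.PATHOGENIC, AmCategory.BENIGN, "PATH-ben"),
        (Tier.LIKELY_PATHOGENIC, AmCategory.PATHOGENIC, "PATH-path"),
        (Tier.BENIGN, AmCategory.BENIGN, "BEN-ben"),
        (Tier.LIKELY_BENIGN, AmCategory.PATHOGENIC, "BEN-path"),
        (Tier.VUS, AmCategory.PATHOGENIC, "VUS-path"),
        (Tier.VUS, AmCategory.BENIGN, "VUS-ben"),
        (Tier.PATHOGENIC, AmCategory.AMBIGUOUS, "PATH-amb"),
        (Tier.BENIGN, AmCategory.AMBIGUOUS, "BEN-amb"),
    ],
)
def test_comparison_group_grid(tier, category, label):
    assert comparison_group(tier, category) == label


def test_group_counts_match_contingency_cells(table2a_cohort):
    groups = comparison_group_counts(table2a_cohort)
    table = contingency_3x3(table2a_cohort)
    assert groups["PATH-path"] == table.loc["pathogenic", "pathogenic"]
    assert groups["VUS-ben"] == table.loc["benign", "vus"]
    assert groups["BEN-amb"] == table.loc["ambiguous", "benign"]
    assert groups.sum() == table.to_numpy().sum()


def test_chi_square_closed_form_2x2():
    statistic, dof, p = chi_square_independence(
        pd.DataFrame([[10, 0], [0, 10]])
    )
    assert statistic == pytest.approx(20.0)
    assert dof == 1


def test_chi_square_independent_table_is_zero():
    outer = np.outer([1, 2, 3], [4, 5, 6])
    statistic, dof, p = chi_square_independence(pd.DataFrame(outer))
    assert statistic == pytest.approx(0.0, abs=1e-10)
    assert dof == 4
    assert p == pytest.approx(1.0)


def test_chi_square_on_published_table_significant(table2a):
    statistic, dof, p = chi_square_independence(table2a)
    assert dof == 4
    assert p < 0.01


def test_chi_square_rejects_zero_marginal():
    with pytest.raises(ValueError):
        chi_square_independence(pd.DataFrame([[0, 0], [1, 2]]))


def test_spearman_examples():
    assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    # brute-force rank computation: d = (0, 1, -1, 0), rho = 1 - 6*2/60
    assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_spearman_edge_cases():
    assert spearman_rho([1.0, 1.0, 1.0], [1, 2, 3]) is None
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [1, 2])


def test_mean_ci_constant_vector_degenerate():
    assert mean_ci([0.5, 0.5, 0.5, 0.5]) == (0.5, 0.5, 0.5)


def test_mean_ci_symmetric():
    mean, lo, hi = mean_ci([0.0, 1.0])
    assert mean == pytest.approx(0.5)
    assert mean - lo == pytest.approx(hi - mean)


def test_mean_ci_closed_form_t_interval():
    mean, lo, hi = mean_ci([1, 2, 3, 4, 5])
    se = math.sqrt(2.5 / 5)
    t975 = 2.7764451051977987  # t(0.975, df=4)
    assert mean == pytest.approx(3.0)
    assert lo == pytest.approx(3.0 - t975 * se)
    assert hi == pytest.approx(3.0 + t975 * se)


def test_mean_ci_requires_two_observations():
    with pytest.raises(ValueError):
        mean_ci([1.0])
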