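"""Concordance statistics between AlphaMissense categories and curated tiers.

The central object is a 3x3 contingency table: AM prediction (pathogenic /
ambiguous / benign) against the collapsed curated classification (P/LP,
VUS, B/LB).  Two binary collapses of that table are computed:

* **pathogenic vs benign** — the ambiguous row and the VUS column are
  dropped; TP/FP/FN/TN come from the four corner cells.
* **pathogenic vs rest** — curated P/LP against everything else, AM
  pathogenic against everything else; no cell is dropped.

Sensitivity, specificity, PPV and NPV are reported both as raw fractions
and as whole percents (round half away from zero).  Denominator-zero
metrics are reported as absent rather than 0 or 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphamissense import AmCategory, CollapsedTier, collapse_tier, resolve_am_category
from .catalog import Tier, VariantRecord

__all__ = [
    "AM_ROWS",
    "ACMG_COLS",
    "BinaryMetrics",
    "contingency_3x3",
    "metrics_excluding_uncertain",
    "metrics_path_vs_rest",
    "comparison_group",
    "comparison_group_counts",
    "chi_square_independence",
    "spearman_rho",
    "mean_ci",
]

AM_ROWS = ["pathogenic", "ambiguous", "benign"]
ACMG_COLS = ["pathogenic", "vus", "benign"]


def round_half_away(fraction: float) -> int:
    """Whole-percent rendering with half-away-from-zero ties."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


@dataclass(frozen=True)
class BinaryMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        """Counts plus fractions and whole-percent renderings."""
        out: dict = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = value
            out[f"{name}_percent"] = (
                round_half_away(value) if value is not None else None
            )
        return out


def contingency_3x3(cohort: Sequence[VariantRecord]) -> pd.DataFrame:
    """AM category (rows) vs collapsed curated tier (columns) counts.

    Every record must carry an AM score or category.  Row/column marginals
    are available via the DataFrame's ``sum``.
    """
    table = pd.DataFrame(0, index=AM_ROWS, columns=ACMG_COLS, dtype=int)
    for variant in cohort:
        category = resolve_am_category(variant)
        if category is None:
            raise ValueError(
                f"variant {variant.variant_id} has no AlphaMissense "
                "score or category"
            )
        row = category.value
        col = collapse_tier(variant.curated_tier).value
        table.loc[row, col] += 1
    return table


def metrics_excluding_uncertain(table: pd.DataFrame) -> BinaryMetrics:
    """Pathogenic-vs-benign collapse: ambiguous row and VUS column excluded."""
    return BinaryMetrics(
        tp=int(table.loc["pathogenic", "pathogenic"]),
        fp=int(table.loc["pathogenic", "benign"]),
        fn=int(table.loc["benign", "pathogenic"]),
        tn=int(table.loc["benign", "benign"]),
    )


def metrics_path_vs_rest(table: pd.DataFrame) -> BinaryMetrics:
    """Pathogenic-vs-rest collapse using every cell of the 3x3 table."""
    tp = int(table.loc["pathogenic", "pathogenic"])
    fp = int(table.loc["pathogenic", "vus"] + table.loc["pathogenic", "benign"])
    fn = int(table.loc["ambiguous", "pathogenic"] + table.loc["benign", "pathogenic"])
    tn = int(
        table.loc[["ambiguous", "benign"], ["vus", "benign"]].to_numpy().sum()
    )
    return BinaryMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


_GROUP_PREFIX = {
    CollapsedTier.PATHOGENIC: "PATH",
    CollapsedTier.BENIGN: "BEN",
    CollapsedTier.VUS: "VUS",
}
_GROUP_SUFFIX = {
    AmCategory.PATHOGENIC: "path",
    AmCategory.BENIGN: "ben",
    AmCategory.AMBIGUOUS: "amb",
}


def comparison_group(curated_tier: Tier, category: AmCategory) -> str:
    """Label like ``PATH-path`` or ``VUS-amb`` for a (tier, AM) pair."""
    collapsed = collapse_tier(curated_tier)
    return f"{_GROUP_PREFIX[collapsed]}-{_GROUP_SUFFIX[AmCategory(category)]}"


def comparison_group_counts(cohort: Sequence[VariantRecord]) -> pd.Series:
    """Cohort tally by comparison-group label (all nine labels present)."""
    labels = [
        f"{_GROUP_PREFIX[t]}-{_GROUP_SUFFIX[c]}"
        for t in (CollapsedTier.PATHOGENIC, CollapsedTier.VUS, CollapsedTier.BENIGN)
        for c in (AmCategory.PATHOGENIC, AmCategory.AMBIGUOUS, AmCategory.BENIGN)
    ]
    counts = pd.Series(0, index=labels, dtype=int)
    for variant in cohort:
        category = resolve_am_category(variant)
        if category is None:
            raise ValueError(
                f"variant {variant.variant_id} has no AlphaMissense "
                "score or category"
            )
        counts[comparison_group(variant.curated_tier, category)] += 1
    return counts


def chi_square_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Zero row or column marginals are rejected since expected counts must be
    positive.
    """
    values = np.asarray(table, dtype=float)
    if (values.sum(axis=0) == 0).any() or (values.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    result = stats.chi2_contingency(values, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation with average ranks for ties.

    Returns None for a constant vector (the correlation is undefined).
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mean_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Sample mean with a two-sided t-based confidence interval."""
    data = np.asarray(values, dtype=float)
    if data.size < 2:
        raise ValueError("need at least 2 observations for a confidence interval")
    mean = float(data.mean())
    se = float(data.std(ddof=1) / math.sqrt(data.size))
    half = float(stats.t.ppf(0.5 + level / 2, df=data.size - 1)) * se
    return mean, mean - half, mean + half
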