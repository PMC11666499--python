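"""Cohort TSV reading/writing, run configuration, and report export.

The interchange format is a tab-separated table with the exact header
``variant_id, gene, curated_tier, evidence, am_score, am_category,
revel_score``; the evidence field is a semicolon-delimited list of raw
code tokens and optional fields round-trip as empty strings.  TSV was
chosen over VCF because records live at the interpretation level
(curated tier + assigned evidence), not at the call level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alphamissense import AmCategory, am_category
from .catalog import (
    EvidenceCatalog,
    Tier,
    VariantRecord,
    evidence_type_matrix,
    load_default_catalog,
    parse_evidence_list,
)
from .quantify import DEFAULT_POINTS

__all__ = [
    "COHORT_COLUMNS",
    "CohortReadError",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "write_report",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "variant_id",
    "gene",
    "curated_tier",
    "evidence",
    "am_score",
    "am_category",
    "revel_score",
]


class CohortReadError(ValueError):
    """Raised in strict mode when any row fails to parse."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclasses.dataclass
class RunConfig:
    """Run-level knobs; the defaults are the published calibration."""

    points: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_POINTS)
    )
    am_benign_upper: float = 0.34
    am_ambiguous_upper: float = 0.564
    seed: int = 0
    output_dir: Optional[Path] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = json.load(handle)
        config = cls(**{k: v for k, v in raw.items() if k != "output_dir"})
        if "output_dir" in raw:
            config.output_dir = Path(raw["output_dir"])
        overrides = {
            k: v for k, v in raw.items() if getattr(cls(), k, object()) != v
        }
        if overrides:
            logger.info("run config overrides: %s", overrides)
        return config


def _normalize_minus(text: str) -> str:
    # tables in print use U+2212; accept it in numeric fields
    return text.replace("−", "-")


def read_cohort(
    path,
    catalog: Optional[EvidenceCatalog] = None,
    strict: bool = True,
) -> list[VariantRecord]:
    """Parse a cohort TSV into records.

    Evidence tokens are resolved against the catalog and the AM category
    is derived from the score when absent.  Row-level failures are
    collected with line numbers; strict mode raises on any failure,
    lenient mode skips the offending rows and logs them.
    """
    if catalog is None:
        catalog = load_default_catalog()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed cohort header, missing columns: {missing}")
    if frame.empty:
        logger.warning("cohort file %s contains a header but no rows", path)
    records: list[VariantRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(_parse_row(row, catalog))
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        if strict:
            raise CohortReadError(errors)
        for message in errors:
            logger.warning("skipped cohort row (%s)", message)
    return records


def _parse_row(row, catalog: EvidenceCatalog) -> VariantRecord:
    tier = Tier(row["curated_tier"].strip().lower())
    tokens = [t for t in row["evidence"].split(";") if t.strip()]
    evidence = parse_evidence_list(tokens, catalog)
    score = None
    if row["am_score"].strip():
        score = float(_normalize_minus(row["am_score"].strip()))
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"am_score outside [0, 1]: {score}")
    category = None
    if row["am_category"].strip():
        category = AmCategory(row["am_category"].strip().lower())
    if score is not None:
        derived = am_category(score)
        if category is not None and category is not derived:
            logger.warning(
                "variant %s: am_category %s conflicts with score %s; "
                "using the score-derived %s",
                row["variant_id"],
                category.value,
                score,
                derived.value,
            )
        category = derived
    revel = None
    if row["revel_score"].strip():
        revel = float(_normalize_minus(row["revel_score"].strip()))
    return VariantRecord(
        variant_id=row["variant_id"],
        gene=row["gene"] or None,
        curated_tier=tier,
        evidence=evidence,
        am_score=score,
        am_category=category,
        revel_score=revel,
    )


def write_cohort(cohort: Sequence[VariantRecord], path) -> None:
    """Serialize records to the cohort TSV (inverse of :func:`read_cohort`)."""
    rows = []
    for v in cohort:
        if v.am_score is not None:
            category = am_category(v.am_score)  # keeps round-trips byte-stable
        elif v.am_category is not None:
            category = AmCategory(v.am_category)
        else:
            category = None
        rows.append(
            {
                "variant_id": v.variant_id,
                "gene": v.gene or "",
                "curated_tier": v.curated_tier.value,
                "evidence": ";".join(item.format() for item in v.evidence),
                "am_score": "" if v.am_score is None else repr(float(v.am_score)),
                "am_category": "" if category is None else category.value,
                "revel_score": (
                    "" if v.revel_score is None else repr(float(v.revel_score))
                ),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_report(
    summary: Mapping,
    out_dir,
    per_variant: Optional[pd.DataFrame] = None,
    cohort: Optional[Sequence[VariantRecord]] = None,
    group_labels: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Write a JSON summary plus optional tidy TSVs.

    ``summary`` (totals, matrices, metric dictionaries) goes to
    ``summary.json``; a per-variant outcome table to ``per_variant.tsv``;
    and, when a cohort is given, the polarity-by-type evidence matrix to
    ``heatmap_matrix.tsv`` ordered by comparison group.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _jsonable(obj):
        if isinstance(obj, pd.DataFrame):
            return {
                "index": list(obj.index),
                "columns": list(obj.columns),
                "values": obj.to_numpy().tolist(),
            }
        if isinstance(obj, Mapping):
            return {str(k): _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if hasattr(obj, "item"):
            return obj.item()
        if isinstance(obj, (Tier, AmCategory)):
            return obj.value
        return obj

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    written["summary"] = summary_path

    if per_variant is not None:
        pv_path = out / "per_variant.tsv"
        per_variant.to_csv(pv_path, sep="\t", index=False)
        written["per_variant"] = pv_path

    if cohort:
        matrix = evidence_type_matrix(cohort, group_labels)
        hm_path = out / "heatmap_matrix.tsv"
        matrix.to_csv(hm_path, sep="\t")
        written["heatmap_matrix"] = hm_path
    return written
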