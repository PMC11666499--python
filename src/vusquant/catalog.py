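"""ACMG/AMP evidence-code catalog, parsing and per-variant evidence profiles.

Every assigned criterion (``PM2``, ``PS4_M``, ``BP4``, ``PPC HET`` ...) is
resolved against a catalog that records its polarity (pathogenic/benign),
base strength and evidence type (population, functional/allelic, clinical,
computational, molecular impact).  A trailing strength modifier such as
``_M`` re-weights the criterion without changing its identity, so ``PS4_M``
is population evidence applied at moderate rather than strong strength.

The catalog ships as a plain-text table (``data/catalog.tsv``) so that labs
can extend it with local codes without touching the code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Polarity",
    "Strength",
    "EvidenceType",
    "Tier",
    "EvidenceCode",
    "EvidenceCatalog",
    "StrengthProfile",
    "VariantRecord",
    "load_default_catalog",
    "parse_evidence_code",
    "parse_evidence_list",
    "strength_profile",
    "evidence_type_matrix",
]


class Polarity(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, enum.Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class EvidenceType(str, enum.Enum):
    POPULATION = "population"
    FUNCTIONAL_ALLELIC = "functional_allelic"
    CLINICAL = "clinical"
    COMPUTATIONAL = "computational"
    MOLECULAR_IMPACT = "molecular_impact"


class Tier(str, enum.Enum):
    """Five-tier germline classification, ordered benign -> pathogenic."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"

    @property
    def rank(self) -> int:
        return _TIER_ORDER.index(self)


_TIER_ORDER = (
    Tier.BENIGN,
    Tier.LIKELY_BENIGN,
    Tier.VUS,
    Tier.LIKELY_PATHOGENIC,
    Tier.PATHOGENIC,
)

#: Modifier suffix -> strength it applies the criterion at.
MODIFIER_SUFFIXES: Mapping[str, Strength] = {
    "VS": Strength.VERY_STRONG,
    "S": Strength.STRONG,
    "M": Strength.MODERATE,
    "P": Strength.SUPPORTING,
}

#: Evidence types in the fixed reporting order used by the heatmap export.
TYPE_ORDER = (
    EvidenceType.POPULATION,
    EvidenceType.FUNCTIONAL_ALLELIC,
    EvidenceType.CLINICAL,
    EvidenceType.COMPUTATIONAL,
    EvidenceType.MOLECULAR_IMPACT,
)


@dataclass(frozen=True)
class EvidenceCode:
    """A single assigned ACMG criterion.

    ``applied_strength`` equals ``base_strength`` unless the raw token
    carried a modifier suffix.  ``qualifier`` retains whitespace-separated
    annotations such as the zygosity tags on ``PPC`` codes.  ``raw_code``
    keeps the verbatim input token; it is excluded from equality so that
    spelling variants of the same criterion (``pm2``, ``PVS1_VS``) compare
    equal to their canonical form.
    """

    raw_code: str = field(compare=False)
    root: str
    polarity: Polarity
    base_strength: Strength
    applied_strength: Strength
    evidence_type: EvidenceType
    qualifier: Optional[str] = None

    def format(self) -> str:
        """Render back to the canonical token (inverse of parsing)."""
        token = self.root
        if self.applied_strength is not self.base_strength:
            suffix = next(
                s for s, v in MODIFIER_SUFFIXES.items() if v is self.applied_strength
            )
            token += f"_{suffix}"
        if self.qualifier:
            token += f" {self.qualifier}"
        return token

    @property
    def strength_class(self) -> str:
        """The seven-class label (PVS/PS/PM/PP/BA/BS/BP) used for points."""
        return strength_class(self.polarity, self.applied_strength)


def strength_class(polarity: Polarity, strength: Strength) -> str:
    key = (polarity, strength)
    try:
        return _STRENGTH_CLASS[key]
    except KeyError:
        raise ValueError(
            f"no strength class for {polarity.value} evidence at "
            f"{strength.value} strength"
        ) from None


_STRENGTH_CLASS = {
    (Polarity.PATHOGENIC, Strength.VERY_STRONG): "PVS",
    (Polarity.PATHOGENIC, Strength.STRONG): "PS",
    (Polarity.PATHOGENIC, Strength.MODERATE): "PM",
    (Polarity.PATHOGENIC, Strength.SUPPORTING): "PP",
    (Polarity.BENIGN, Strength.STAND_ALONE): "BA",
    (Polarity.BENIGN, Strength.STRONG): "BS",
    (Polarity.BENIGN, Strength.SUPPORTING): "BP",
}

_PREFIX_POLARITY = {
    "PVS": Polarity.PATHOGENIC,
    "PS": Polarity.PATHOGENIC,
    "PM": Polarity.PATHOGENIC,
    "PP": Polarity.PATHOGENIC,
    "BA": Polarity.BENIGN,
    "BS": Polarity.BENIGN,
    "BP": Polarity.BENIGN,
}


@dataclass(frozen=True)
class EvidenceCatalog:
    """Maps code roots to (polarity, base strength, evidence type)."""

    entries: Mapping[str, tuple[Polarity, Strength, EvidenceType]]
    modifier_suffixes: Mapping[str, Strength] = field(
        default_factory=lambda: dict(MODIFIER_SUFFIXES)
    )

    def __post_init__(self) -> None:
        for root, (polarity, _, _) in self.entries.items():
            prefix = _code_prefix(root)
            if prefix is not None and _PREFIX_POLARITY[prefix] is not polarity:
                raise ValueError(
                    f"catalog entry {root!r}: prefix implies "
                    f"{_PREFIX_POLARITY[prefix].value}, entry says {polarity.value}"
                )

    def __contains__(self, root: str) -> bool:
        return root.upper() in self.entries

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "EvidenceCatalog":
        required = {"code", "polarity", "strength", "type"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"catalog table missing columns: {sorted(missing)}")
        entries = {}
        for row in table.itertuples(index=False):
            entries[str(row.code).upper()] = (
                Polarity(row.polarity),
                Strength(row.strength),
                EvidenceType(row.type),
            )
        return cls(entries=entries)

    @classmethod
    def from_tsv(cls, path) -> "EvidenceCatalog":
        return cls.from_table(pd.read_csv(path, sep="\t", comment="#"))


def _code_prefix(root: str) -> Optional[str]:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if root.upper().startswith(prefix):
            return prefix
    return None


def load_default_catalog() -> EvidenceCatalog:
    """Load the bundled catalog of standard and Mastermind clinical codes."""
    ref = resources.files("vusquant").joinpath("data/catalog.tsv")
    with resources.as_file(ref) as path:
        return EvidenceCatalog.from_tsv(path)


def parse_evidence_code(code: str, catalog: EvidenceCatalog) -> EvidenceCode:
    """Resolve a raw token such as ``"PS4_M"`` or ``"PPC HET"``.

    Parsing is case-insensitive on the root; a whitespace-separated
    qualifier (``HET``/``HOM``/``COMHET``) is retained verbatim.  Unknown
    roots or modifier suffixes are rejected with the offending token named.
    """
    token = code.strip()
    if not token:
        raise ValueError("empty evidence code")
    parts = token.split()
    head, qualifier = parts[0], (" ".join(parts[1:]) or None)

    root, _, suffix = head.partition("_")
    root = root.upper()
    if root not in catalog.entries:
        raise ValueError(f"unknown evidence code root: {parts[0]!r}")
    polarity, base_strength, evidence_type = catalog.entries[root]

    applied = base_strength
    if suffix:
        try:
            applied = catalog.modifier_suffixes[suffix.upper()]
        except KeyError:
            raise ValueError(
                f"unknown strength modifier suffix: {suffix!r} in {code!r}"
            ) from None
    # reject combos with no scoring class (e.g. a benign code forced moderate)
    strength_class(polarity, applied)
    return EvidenceCode(
        raw_code=token,
        root=root,
        polarity=polarity,
        base_strength=base_strength,
        applied_strength=applied,
        evidence_type=evidence_type,
        qualifier=qualifier,
    )


def parse_evidence_list(
    codes: Iterable[str], catalog: EvidenceCatalog
) -> list[EvidenceCode]:
    return [parse_evidence_code(c, catalog) for c in codes]


@dataclass(frozen=True)
class StrengthProfile:
    """Evidence-item counts per strength class.

    Items are counted under their applied strength, so a ``PS4_M`` shows up
    in ``n_PM``.  Duplicates of the same code each count once.
    """

    n_PVS: int = 0
    n_PS: int = 0
    n_PM: int = 0
    n_PP: int = 0
    n_BP: int = 0
    n_BS: int = 0
    n_BA: int = 0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"negative count for {name}: {value}")

    def as_dict(self) -> dict[str, int]:
        return {
            "PVS": self.n_PVS,
            "PS": self.n_PS,
            "PM": self.n_PM,
            "PP": self.n_PP,
            "BP": self.n_BP,
            "BS": self.n_BS,
            "BA": self.n_BA,
        }

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())

    def add(self, cls: str, n: int = 1) -> "StrengthProfile":
        field_name = f"n_{cls}"
        if not hasattr(self, field_name):
            raise ValueError(f"unknown strength class: {cls!r}")
        return replace(self, **{field_name: getattr(self, field_name) + n})


def strength_profile(evidence: Sequence[EvidenceCode]) -> StrengthProfile:
    """Tally an evidence list into per-strength-class counts."""
    counts = {cls: 0 for cls in ("PVS", "PS", "PM", "PP", "BP", "BS", "BA")}
    for item in evidence:
        counts[item.strength_class] += 1
    return StrengthProfile(**{f"n_{k}": v for k, v in counts.items()})


@dataclass
class VariantRecord:
    """One variant: curated tier, assigned evidence, optional predictor scores."""

    variant_id: str
    curated_tier: Tier
    evidence: list[EvidenceCode] = field(default_factory=list)
    gene: Optional[str] = None
    am_score: Optional[float] = None
    am_category: Optional["object"] = None  # AmCategory; avoids circular import
    revel_score: Optional[float] = None

    def profile(self) -> StrengthProfile:
        return strength_profile(self.evidence)


# column order of the heatmap matrix: 5 benign-type then 5 pathogenic-type
MATRIX_COLUMNS = tuple(
    f"{polarity.value}_{etype.value}"
    for polarity in (Polarity.BENIGN, Polarity.PATHOGENIC)
    for etype in TYPE_ORDER
)


def evidence_type_matrix(
    cohort: Sequence[VariantRecord],
    group_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-variant evidence multiplicity by polarity x type (heatmap layout).

    Returns one row per variant with ten count columns (benign population,
    functional/allelic, clinical, computational, molecular impact, then the
    pathogenic counterparts) and a leading ``group`` column used to sort and
    block the export by comparison group.  Row order within a group follows
    the input cohort order.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if group_labels is not None and len(group_labels) != len(cohort):
        raise ValueError("group_labels length does not match cohort size")
    rows = []
    for i, variant in enumerate(cohort):
        counts = dict.fromkeys(MATRIX_COLUMNS, 0)
        for item in variant.evidence:
            counts[f"{item.polarity.value}_{item.evidence_type.value}"] += 1
        row = {"variant_id": variant.variant_id}
        row["group"] = group_labels[i] if group_labels is not None else ""
        row.update(counts)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("variant_id")
    if group_labels is not None:
        frame = frame.sort_values("group", kind="stable")
    return frame
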