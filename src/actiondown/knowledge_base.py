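"""Biomarker–drug knowledge base: loading, validation and repurposing queries.

The knowledge base (KB) is a flat table of rules, each linking one genomic
biomarker (a gene plus an alteration pattern) to one drug in one or more
tumour types, with an evidence tier and a sensitivity/resistance association.
The schema mirrors the row structure of curated cancer biomarker catalogues
such as CGI's Cancer Biomarker Database, supplemented with FDA/NCCN-approved
pairs in the OncoKB style.

Evidence tiers form a total order from regulatory guidelines down to
pre-clinical data.  For repurposing summaries the top four tiers collapse
into two headline groups — "approved" (FDA/NCCN guidelines) and "trials"
(late/early clinical trials) — while case-report and pre-clinical rules are
retained in the KB but reported separately.

Tumour-type matching goes through a small flat ontology: a synonym table
mapping dataset cancer labels onto KB labels, with one optional parent level
(e.g. ``solid_tumour``) so that tumour-agnostic approvals such as NTRK-fusion
inhibitors can match any solid-tumour label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AlterationClass",
    "Association",
    "EvidenceTier",
    "BiomarkerRule",
    "TumourOntology",
    "BiomarkerKB",
    "KBValidationError",
    "UnknownTumourError",
    "load_kb",
    "load_ontology",
    "tier_group",
    "repurposing_expansion",
    "shared_biomarker_matrix",
]

KB_COLUMNS = [
    "rule_id",
    "gene",
    "alteration_class",
    "variant_pattern",
    "fusion_partner",
    "tumour_types",
    "drug",
    "association",
    "evidence",
    "driver",
]

ONTOLOGY_COLUMNS = ["dataset_label", "kb_label", "parent"]


class KBValidationError(ValueError):
    """Raised when a KB file contains malformed rows; message lists row-level diagnostics."""


class UnknownTumourError(KeyError):
    """Raised when a tumour label cannot be resolved through the ontology."""


class AlterationClass(str, enum.Enum):
    MUT = "MUT"
    AMP = "AMP"
    DEL = "DEL"
    FUS = "FUS"


class Association(str, enum.Enum):
    SENSITIVITY = "sensitivity"
    RESISTANCE = "resistance"


class EvidenceTier(enum.IntEnum):
    """Strength of a drug–biomarker association; larger value = stronger evidence."""

    PRE_CLINICAL = 1
    CASE_REPORT = 2
    EARLY_TRIALS = 3
    LATE_TRIALS = 4
    NCCN_GUIDELINES = 5
    FDA_GUIDELINES = 6

    @property
    def label(self) -> str:
        return _TIER_TO_LABEL[self]


#: The six permitted evidence labels as they appear in KB files.
EVIDENCE_LABELS: Mapping[str, EvidenceTier] = {
    "FDA guidelines": EvidenceTier.FDA_GUIDELINES,
    "NCCN guidelines": EvidenceTier.NCCN_GUIDELINES,
    "Late trials": EvidenceTier.LATE_TRIALS,
    "Early trials": EvidenceTier.EARLY_TRIALS,
    "Case report": EvidenceTier.CASE_REPORT,
    "Pre-clinical": EvidenceTier.PRE_CLINICAL,
}

_TIER_TO_LABEL = {tier: label for label, tier in EVIDENCE_LABELS.items()}

#: Headline evidence groups used in repurposing summaries.
APPROVED_TIERS = frozenset({EvidenceTier.FDA_GUIDELINES, EvidenceTier.NCCN_GUIDELINES})
TRIALS_TIERS = frozenset({EvidenceTier.LATE_TRIALS, EvidenceTier.EARLY_TRIALS})


def parse_evidence(label: str) -> EvidenceTier:
    """Parse an evidence label (display form or enum name) into a tier."""
    if label in EVIDENCE_LABELS:
        return EVIDENCE_LABELS[label]
    try:
        return EvidenceTier[label]
    except KeyError:
        permitted = ", ".join(repr(k) for k in EVIDENCE_LABELS)
        raise KBValidationError(
            f"unknown evidence label {label!r}; permitted labels: {permitted}"
        ) from None


def tier_group(tier: EvidenceTier) -> str:
    """Map an evidence tier onto its headline group.

    FDA/NCCN guidelines count as ``"approved"``, late/early trials as
    ``"trials"``; case-report and pre-clinical evidence fall into ``"other"``
    and are excluded from headline approved/trials summaries.
    """
    if tier in APPROVED_TIERS:
        return "approved"
    if tier in TRIALS_TIERS:
        return "trials"
    return "other"


@dataclass(frozen=True)
class BiomarkerRule:
    """One KB row: a biomarker–tumour-type–drug–evidence combination.

    ``variant_pattern`` is only meaningful for MUT rules and uses a four-form
    grammar: an exact protein change ("V600E"), a codon wildcard ("V600."),
    the gene-level wildcard ("any"), or the consequence class "LOF".
    ``fusion_partner`` is required for (and only for) FUS rules; "any"
    matches either partner.  ``tumour_types`` is a frozenset of KB labels or
    the singleton {"any"} for tumour-agnostic rules.
    """

    rule_id: str
    gene: str
    alteration_class: AlterationClass
    variant_pattern: str | None
    fusion_partner: str | None
    tumour_types: frozenset[str]
    drug: str
    association: Association
    evidence: EvidenceTier
    driver_catalogued: bool

    def __post_init__(self) -> None:
        if not self.tumour_types:
            raise KBValidationError(f"rule {self.rule_id}: tumour_types must be non-empty or 'any'")
        if (self.alteration_class is AlterationClass.FUS) != (self.fusion_partner is not None):
            raise KBValidationError(
                f"rule {self.rule_id}: fusion_partner must be set iff alteration_class is FUS"
            )
        if self.alteration_class is AlterationClass.MUT and not self.variant_pattern:
            raise KBValidationError(f"rule {self.rule_id}: MUT rules need a variant_pattern")

    @property
    def biomarker(self) -> tuple[str, str, str]:
        """Identity used for biomarker counting: (gene, class, pattern).

        FUS rules use the partner in the pattern slot so distinct fusions of
        the same gene are distinct biomarkers.
        """
        if self.alteration_class is AlterationClass.FUS:
            pattern = f"fusion:{self.fusion_partner}"
        else:
            pattern = self.variant_pattern or self.alteration_class.value
        return (self.gene, self.alteration_class.value, pattern)

    @property
    def tumour_agnostic(self) -> bool:
        return "any" in self.tumour_types


@dataclass
class TumourOntology:
    """Flat synonym table: dataset cancer labels → KB labels, with optional parents."""

    synonyms: dict[str, str] = field(default_factory=dict)
    parents: dict[str, str] = field(default_factory=dict)

    def resolve(self, label: str) -> str:
        """Resolve a dataset label to its KB label; KB labels resolve to themselves."""
        if label in self.synonyms:
            return self.synonyms[label]
        if (
            label in self.parents
            or label in set(self.synonyms.values())
            or label in set(self.parents.values())
        ):
            return label
        raise UnknownTumourError(f"tumour label {label!r} not resolvable in ontology")

    def lineage(self, label: str) -> frozenset[str]:
        """KB label plus its parent (if any) — the labels a rule may list to cover it."""
        kb_label = self.resolve(label)
        out = {kb_label}
        parent = self.parents.get(kb_label)
        if parent:
            out.add(parent)
        return frozenset(out)

    def kb_labels(self) -> list[str]:
        return sorted(set(self.synonyms.values()) | set(self.parents))


@dataclass
class BiomarkerKB:
    """A validated rule list plus the tumour ontology used to interpret labels."""

    rules: list[BiomarkerRule]
    ontology: TumourOntology

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise KBValidationError(f"duplicate rule_ids: {dupes}")
        # every non-'any' tumour label a rule uses must be resolvable
        for rule in self.rules:
            for label in rule.tumour_types - {"any"}:
                self.ontology.resolve(label)

    def rule_matches_tumour(self, rule: BiomarkerRule, tumour: str) -> bool:
        """True if the rule's tumour scope covers the given dataset label."""
        if rule.tumour_agnostic:
            return True
        return bool(rule.tumour_types & self.ontology.lineage(tumour))

    def tumour_types(self) -> list[str]:
        """All KB tumour labels: ontology labels plus any rule-only labels."""
        labels = set(self.ontology.kb_labels())
        for rule in self.rules:
            labels |= rule.tumour_types - {"any"}
        return sorted(labels)

    def rules_in_group(self, group: str) -> list[BiomarkerRule]:
        return [r for r in self.rules if tier_group(r.evidence) == group]


def _parse_rule(row: pd.Series, row_number: int) -> BiomarkerRule:
    def cell(name: str) -> str | None:
        value = row[name]
        if pd.isna(value) or str(value).strip() in ("", "."):
            return None
        return str(value).strip()

    def required(name: str) -> str:
        value = cell(name)
        if value is None:
            raise KBValidationError(f"row {row_number}: field {name!r} is empty")
        return value

    try:
        alt_class = AlterationClass(required("alteration_class"))
    except ValueError:
        raise KBValidationError(
            f"row {row_number}: field 'alteration_class' must be one of MUT/AMP/DEL/FUS, "
            f"got {row['alteration_class']!r}"
        ) from None
    try:
        association = Association(required("association"))
    except ValueError:
        raise KBValidationError(
            f"row {row_number}: field 'association' must be sensitivity or resistance"
        ) from None
    try:
        evidence = parse_evidence(required("evidence"))
    except KBValidationError as exc:
        raise KBValidationError(f"row {row_number}: field 'evidence': {exc}") from None

    driver_raw = required("driver").lower()
    if driver_raw not in {"true", "false", "1", "0", "yes", "no"}:
        raise KBValidationError(f"row {row_number}: field 'driver' must be boolean-like")

    tumours = required("tumour_types")
    tumour_set = frozenset(
        t.strip() for t in tumours.split(";") if t.strip()
    ) if tumours != "any" else frozenset({"any"})

    try:
        return BiomarkerRule(
            rule_id=required("rule_id"),
            gene=required("gene"),
            alteration_class=alt_class,
            variant_pattern=cell("variant_pattern"),
            fusion_partner=cell("fusion_partner"),
            tumour_types=tumour_set,
            drug=required("drug"),
            association=association,
            evidence=evidence,
            driver_catalogued=driver_raw in {"true", "1", "yes"},
        )
    except KBValidationError as exc:
        raise KBValidationError(f"row {row_number}: {exc}") from None


def load_ontology(path: str | Path) -> TumourOntology:
    """Load a tumour ontology TSV with columns dataset_label / kb_label / parent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ONTOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise KBValidationError(f"ontology file missing columns: {sorted(missing)}")
    onto = TumourOntology()
    for _, row in df.iterrows():
        onto.synonyms[row["dataset_label"]] = row["kb_label"]
        parent = row["parent"].strip()
        if parent and parent != ".":
            onto.parents[row["kb_label"]] = parent
    return onto


def load_kb(path: str | Path, ontology: TumourOntology | str | Path | None = None) -> BiomarkerKB:
    """Load and validate a KB-TSV file.

    Parameters
    ----------
    path
        Tab-separated file with header ``rule_id gene alteration_class
        variant_pattern fusion_partner tumour_types drug association evidence
        driver``.  ``tumour_types`` is a semicolon-joined list or ``any``.
    ontology
        A :class:`TumourOntology`, a path to an ontology TSV, or None, in
        which case an identity ontology is built from the labels the rules
        use (each label is its own KB label, no parents).

    Raises
    ------
    KBValidationError
        Collecting all row-level diagnostics (row number and offending field).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != KB_COLUMNS:
        raise KBValidationError(
            f"KB header mismatch: expected {KB_COLUMNS}, got {list(df.columns)}"
        )

    rules: list[BiomarkerRule] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            rules.append(_parse_rule(row, row_number=i + 2))  # +2: header is line 1
        except KBValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise KBValidationError("KB file rejected:\n" + "\n".join(problems))

    if ontology is None:
        labels = sorted({t for r in rules for t in r.tumour_types if t != "any"})
        ontology = TumourOntology(synonyms={lab: lab for lab in labels})
    elif not isinstance(ontology, TumourOntology):
        ontology = load_ontology(ontology)
    return BiomarkerKB(rules=rules, ontology=ontology)


def write_kb(kb: BiomarkerKB, path: str | Path) -> None:
    """Serialize a KB back to the KB-TSV dialect (inverse of :func:`load_kb`)."""
    rows = []
    for r in kb.rules:
        rows.append(
            {
                "rule_id": r.rule_id,
                "gene": r.gene,
                "alteration_class": r.alteration_class.value,
                "variant_pattern": r.variant_pattern or ".",
                "fusion_partner": r.fusion_partner or ".",
                "tumour_types": "any" if r.tumour_agnostic else ";".join(sorted(r.tumour_types)),
                "drug": r.drug,
                "association": r.association.value,
                "evidence": r.evidence.label,
                "driver": str(r.driver_catalogued).lower(),
            }
        )
    pd.DataFrame(rows, columns=KB_COLUMNS).to_csv(path, sep="\t", index=False)


def repurposing_expansion(kb: BiomarkerKB, tumour: str, group: str) -> dict[str, int]:
    """Count on-label vs off-label biomarkers for one tumour type and evidence group.

    A biomarker — identified as (gene, alteration class, pattern) — is
    *on-label* if at least one of its rules in the group covers the tumour
    (directly, via the ontology parent, or tumour-agnostically), and
    *off-label* if it has group-level rules only in other tumour types.
    Each biomarker is counted in exactly one of the two buckets.
    """
    if group not in ("approved", "trials"):
        raise ValueError("group must be 'approved' or 'trials'")
    kb.ontology.resolve(tumour)  # raises UnknownTumourError early
    on: set[tuple] = set()
    off: set[tuple] = set()
    for rule in kb.rules_in_group(group):
        if kb.rule_matches_tumour(rule, tumour):
            on.add(rule.biomarker)
        else:
            off.add(rule.biomarker)
    off -= on
    return {"on_label_biomarkers": len(on), "off_label_biomarkers": len(off)}


def shared_biomarker_matrix(kb: BiomarkerKB, group: str | None = None) -> pd.DataFrame:
    """Symmetric matrix of shared-biomarker counts across KB tumour types.

    Entry (a, b) is the number of biomarkers having at least one rule whose
    tumour scope covers *a* and at least one covering *b* (tumour-agnostic
    rules cover every type); the diagonal is the per-type biomarker count.
    ``group`` optionally restricts to one evidence group.
    """
    types = kb.tumour_types()
    rules: Iterable[BiomarkerRule] = kb.rules if group is None else kb.rules_in_group(group)
    per_type: dict[str, set[tuple]] = {t: set() for t in types}
    for rule in rules:
        for t in types:
            if kb.rule_matches_tumour(rule, t):
                per_type[t].add(rule.biomarker)
    matrix = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for a in types:
        for b in types:
            matrix.loc[a, b] = len(per_type[a] & per_type[b])
    return matrix
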