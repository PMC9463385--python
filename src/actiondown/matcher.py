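"""Match normalized somatic alterations against the biomarker knowledge base.

Alterations are first converted into the matcher vocabulary — mutation,
amplification, deletion, fusion — using fixed thresholds: total copy number
>= 6 (ploidy-uncorrected) is an amplification, < 1 a homozygous deletion;
loss-of-function SVs become gene deletions; intra-intron fusions are
excluded as of unknown significance.  Matching then follows the
"driver-complete" convention: a rule fires only on an alteration that fully
instantiates its pattern, synonymous variants never match, and broad
patterns ("any", "LOF") fire only for catalogued driver biomarkers when
``driver_only`` is set.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Sequence, Union

from .knowledge_base import (
    AlterationClass,
    Association,
    BiomarkerKB,
    BiomarkerRule,
    EvidenceTier,
)
from .platforms import Platform, SampleAlterations, downsample_sample
from .variants import (
    LOF_TERMS,
    NONSYNONYMOUS_TERMS,
    CopyNumberSegment,
    StructuralVariant,
    SVEffect,
)

__all__ = [
    "MatcherConfig",
    "CNAClass",
    "MatchResult",
    "MutationAlteration",
    "AmplificationAlteration",
    "DeletionAlteration",
    "FusionAlteration",
    "classify_cna",
    "sv_to_alterations",
    "normalize_sample",
    "match_alteration",
    "sample_actionability",
]


@dataclass(frozen=True)
class MatcherConfig:
    """Thresholds and filters for alteration→biomarker matching.

    amp_cn_threshold : total CN at or above which a segment is an
        amplification (default 6, no ploidy correction).
    homdel_cn_threshold : total CN strictly below which a segment is a
        homozygous deletion (default 1).
    driver_only : restrict gene-level ("any") and "LOF" mutation patterns to
        rules catalogued as driver biomarkers (default True).
    """

    amp_cn_threshold: float = 6.0
    homdel_cn_threshold: float = 1.0
    driver_only: bool = True

    def __post_init__(self) -> None:
        if self.homdel_cn_threshold < 0 or self.amp_cn_threshold < 0:
            raise ValueError("CN thresholds must be >= 0")
        if self.homdel_cn_threshold >= self.amp_cn_threshold:
            raise ValueError("homdel threshold must be below amp threshold")


class CNAClass(str, enum.Enum):
    AMPLIFICATION = "amplification"
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    NEUTRAL = "neutral"


def classify_cna(seg: CopyNumberSegment, cfg: MatcherConfig | None = None) -> CNAClass:
    """Classify a CN segment: CN >= 6 amplification, CN < 1 homozygous deletion.

    Boundaries: CN = 6 *is* an amplification (>=); CN = 1 is neutral
    (strict <).  Negative CN raises.
    """
    cfg = cfg or MatcherConfig()
    if seg.copy_number < 0:
        raise ValueError(f"negative copy number {seg.copy_number}")
    if seg.copy_number >= cfg.amp_cn_threshold:
        return CNAClass.AMPLIFICATION
    if seg.copy_number < cfg.homdel_cn_threshold:
        return CNAClass.HOMOZYGOUS_DELETION
    return CNAClass.NEUTRAL


# --- normalized matcher vocabulary -----------------------------------------


@dataclass(frozen=True)
class MutationAlteration:
    sample_id: str
    gene: str
    consequence: str
    protein_change: str | None
    chrom: str
    pos: int

    sort_key = property(lambda self: (0, self.chrom, self.pos, self.gene))


@dataclass(frozen=True)
class AmplificationAlteration:
    sample_id: str
    gene: str
    copy_number: float

    sort_key = property(lambda self: (1, self.gene, self.copy_number))


@dataclass(frozen=True)
class DeletionAlteration:
    sample_id: str
    gene: str
    source: str  # "cna" or "sv"

    sort_key = property(lambda self: (2, self.gene, self.source))


@dataclass(frozen=True)
class FusionAlteration:
    sample_id: str
    gene5: str
    gene3: str

    sort_key = property(lambda self: (3, self.gene5, self.gene3))


Alteration = Union[MutationAlteration, AmplificationAlteration, DeletionAlteration, FusionAlteration]


@dataclass(frozen=True)
class MatchResult:
    """One rule firing on one alteration; fully traceable to both."""

    sample_id: str
    rule_id: str
    gene: str
    alteration: Alteration
    matched_pattern: str  # exact | codon | gene_any | lof | amp | del | fusion
    drug: str
    association: Association
    evidence: EvidenceTier


def sv_to_alterations(sv: StructuralVariant) -> list[Alteration]:
    """Normalize one SV: LOF → a deletion per affected gene; viable fusion →
    one fusion alteration; intra-intron fusions and other events are excluded."""
    if sv.predicted_effect is SVEffect.LOSS_OF_FUNCTION:
        return [DeletionAlteration(sv.sample_id, gene, source="sv") for gene in sv.genes]
    if sv.predicted_effect is SVEffect.VIABLE_FUSION:
        g5, g3 = sv.fusion_pair  # type: ignore[misc] # invariant: present
        return [FusionAlteration(sv.sample_id, g5, g3)]
    return []


def normalize_sample(alterations: SampleAlterations, cfg: MatcherConfig | None = None) -> list[Alteration]:
    """Convert a sample's raw calls into the matcher vocabulary.

    Variants without a gene symbol cannot be matched and are skipped;
    CN-neutral segments are dropped.
    """
    cfg = cfg or MatcherConfig()
    out: list[Alteration] = []
    for v in alterations.variants:
        if v.gene is None or v.consequence is None:
            continue
        out.append(
            MutationAlteration(
                sample_id=v.sample_id,
                gene=v.gene,
                consequence=v.consequence,
                protein_change=v.protein_change,
                chrom=v.chrom,
                pos=v.pos,
            )
        )
    for seg in alterations.cnas:
        cls = classify_cna(seg, cfg)
        if cls is CNAClass.AMPLIFICATION:
            out.append(AmplificationAlteration(seg.sample_id, seg.gene, seg.copy_number))
        elif cls is CNAClass.HOMOZYGOUS_DELETION:
            out.append(DeletionAlteration(seg.sample_id, seg.gene, source="cna"))
    for sv in alterations.svs:
        out.extend(sv_to_alterations(sv))
    return out


_CODON_TAIL = re.compile(r"(?!\d)[A-Za-z*=]+\Z")


def _mutation_pattern_fires(rule: BiomarkerRule, alt: MutationAlteration, cfg: MatcherConfig) -> str | None:
    """Return the fired pattern kind for a MUT rule on a mutation, or None.

    Synonymous (non-protein-affecting) variants never match.  Pattern forms:
    exact amino-acid change, codon wildcard ("V600." fires on any
    substitution at that codon), gene-level "any", and "LOF" (nonsense,
    frameshift, splice, start-loss).  Broad forms ("any"/"LOF") honour the
    driver-only filter.
    """
    if alt.gene != rule.gene:
        return None
    if alt.consequence not in NONSYNONYMOUS_TERMS:
        return None
    pattern = rule.variant_pattern
    if pattern == "any":
        if cfg.driver_only and not rule.driver_catalogued:
            return None
        return "gene_any"
    if pattern == "LOF":
        if cfg.driver_only and not rule.driver_catalogued:
            return None
        return "lof" if alt.consequence in LOF_TERMS else None
    if alt.protein_change is None:
        return None
    if pattern.endswith("."):
        prefix = pattern[:-1]
        if alt.protein_change.startswith(prefix) and _CODON_TAIL.fullmatch(
            alt.protein_change[len(prefix):]
        ):
            return "codon"
        return None
    return "exact" if alt.protein_change == pattern else None


def _rule_fires(rule: BiomarkerRule, alt: Alteration, cfg: MatcherConfig) -> str | None:
    if isinstance(alt, MutationAlteration):
        if rule.alteration_class is not AlterationClass.MUT:
            return None
        return _mutation_pattern_fires(rule, alt, cfg)
    if isinstance(alt, AmplificationAlteration):
        return "amp" if rule.alteration_class is AlterationClass.AMP and rule.gene == alt.gene else None
    if isinstance(alt, DeletionAlteration):
        return "del" if rule.alteration_class is AlterationClass.DEL and rule.gene == alt.gene else None
    if isinstance(alt, FusionAlteration):
        if rule.alteration_class is not AlterationClass.FUS:
            return None
        pair = (alt.gene5, alt.gene3)
        if rule.gene not in pair:
            return None
        partner = pair[1] if rule.gene == pair[0] else pair[0]
        if rule.fusion_partner == "any" or rule.fusion_partner == partner:
            return "fusion"
        return None
    return None


def match_alteration(
    alt: Alteration, kb: BiomarkerKB, cfg: MatcherConfig | None = None
) -> list[MatchResult]:
    """All KB rules fired by one normalized alteration (empty list if none)."""
    cfg = cfg or MatcherConfig()
    out = []
    for rule in kb.rules:
        fired = _rule_fires(rule, alt, cfg)
        if fired is not None:
            out.append(
                MatchResult(
                    sample_id=alt.sample_id,
                    rule_id=rule.rule_id,
                    gene=rule.gene,
                    alteration=alt,
                    matched_pattern=fired,
                    drug=rule.drug,
                    association=rule.association,
                    evidence=rule.evidence,
                )
            )
    return out


def sample_actionability(
    alterations: SampleAlterations,
    kb: BiomarkerKB,
    cfg: MatcherConfig | None = None,
    platform: Platform | None = None,
) -> list[MatchResult]:
    """Match all of a sample's alterations, optionally down-sampling first.

    Returns matches in deterministic order (rule_id, then alteration sort
    key) regardless of input order.
    """
    cfg = cfg or MatcherConfig()
    if platform is not None:
        alterations = downsample_sample(alterations, platform)
    results: list[MatchResult] = []
    for alt in normalize_sample(alterations, cfg):
        results.extend(match_alteration(alt, kb, cfg))
    results.sort(key=lambda m: (m.rule_id, m.alteration.sort_key))
    return results
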