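"""Somatic alteration containers and readers for VCF/TSV call formats.

The pipeline consumes *already-called, already-annotated* somatic variants:
SNV/indel calls carrying a gene symbol, a Sequence-Ontology-style consequence
term and an optional protein change; copy-number segments with a total copy
number (ploidy-uncorrected); and structural variants with a predicted effect.
Calling, normalisation and consequence prediction are upstream concerns.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "SomaticVariant",
    "CopyNumberSegment",
    "StructuralVariant",
    "SVEffect",
    "read_variants",
    "write_variants_tsv",
    "read_cna_segments",
    "write_cna_segments",
    "read_structural_variants",
    "write_structural_variants",
    "is_nonsynonymous",
    "NONSYNONYMOUS_TERMS",
    "NEUTRAL_TERMS",
    "LOF_TERMS",
]

# Protein-altering consequence terms (the non-synonymous set). The upstream
# annotator's vocabulary is controlled: every term the pipeline accepts is in
# exactly one of the two sets below.
NONSYNONYMOUS_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "protein_altering_variant",
    }
)

NEUTRAL_TERMS = frozenset(
    {
        "synonymous_variant",
        "stop_retained_variant",
        "start_retained_variant",
        "intron_variant",
        "intergenic_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "non_coding_transcript_exon_variant",
    }
)

CONSEQUENCE_TERMS = NONSYNONYMOUS_TERMS | NEUTRAL_TERMS

# Loss-of-function subset: nonsense, frameshift, splice-site and start-loss.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)


@dataclass(frozen=True)
class SomaticVariant:
    """One SNV/indel call for one sample (one record per ALT allele).

    ``pos`` is the 1-based reference position of the first REF base
    (VCF left-aligned convention); the reference span is
    [pos, pos + len(ref) - 1], 1-based inclusive.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ ({self.ref!r})")
        if self.consequence is not None and self.consequence not in CONSEQUENCE_TERMS:
            raise ValueError(f"unknown consequence term {self.consequence!r}")

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive span covered by the REF allele."""
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number segment over a gene; CN is total copies, ploidy-uncorrected."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    gene: str
    copy_number: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")


class SVEffect(str, enum.Enum):
    LOSS_OF_FUNCTION = "loss_of_function"
    VIABLE_FUSION = "viable_fusion"
    INTRA_INTRON_FUSION = "intra_intron_fusion"
    OTHER = "other"


@dataclass(frozen=True)
class StructuralVariant:
    """A structural variant with two breakpoints and a predicted effect."""

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    genes: tuple[str, ...]
    predicted_effect: SVEffect
    fusion_pair: tuple[str, str] | None = None  # (5' gene, 3' gene)

    def __post_init__(self) -> None:
        if self.predicted_effect is SVEffect.VIABLE_FUSION and self.fusion_pair is None:
            raise ValueError("viable_fusion requires a fusion_pair")


def is_nonsynonymous(v: SomaticVariant) -> bool:
    """Classify a variant as protein-altering (non-synonymous) or not.

    Every controlled consequence term maps to exactly one outcome; a missing
    consequence raises so the caller can decide its policy.
    """
    if v.consequence is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} has no consequence annotation")
    return v.consequence in NONSYNONYMOUS_TERMS


# ---------------------------------------------------------------------------
# Readers / writers

VARIANT_TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "gene", "consequence", "protein_change"]
CNA_TSV_COLUMNS = ["sample", "chrom", "start", "end", "gene", "copy_number"]
SV_TSV_COLUMNS = ["sample", "chrom1", "pos1", "chrom2", "pos2", "genes", "effect", "fusion5", "fusion3"]

_NULL = "."


def _cell(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in ("", _NULL) else s


def read_variants(path: str | Path, sample_id: str | None = None) -> list[SomaticVariant]:
    """Read somatic SNV/indel calls from a VCF 4.x file or the annotated-TSV dialect.

    VCF records are decomposed one output record per ALT allele; annotations
    are taken from the ``GENE``, ``CONSEQUENCE`` and ``PROTEIN_CHANGE`` INFO
    fields (comma-separated per allele, or a single shared value).  An
    unparseable consequence yields a warning and a record with
    ``consequence=None`` rather than dropping the call.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, sample_id=sample_id)
    return _read_variant_tsv(path)


def _read_vcf(path: Path, sample_id: str | None) -> list[SomaticVariant]:
    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample_id is None:
            samples = list(vcf.header.samples)
            sample_id = samples[0] if samples else path.stem.removesuffix(".vcf")
        for rec in vcf:
            alts = rec.alts or ()
            info = rec.info
            for i, alt in enumerate(alts):
                def per_allele(key: str) -> str | None:
                    raw = info.get(key)
                    if raw is None:
                        return None
                    if isinstance(raw, (tuple, list)):
                        raw = raw[i] if i < len(raw) else raw[0]
                    return _cell(raw)

                consequence = per_allele("CONSEQUENCE")
                if consequence is not None and consequence not in CONSEQUENCE_TERMS:
                    warnings.warn(
                        f"{path.name}:{rec.chrom}:{rec.pos}: unparseable consequence "
                        f"{consequence!r}; record retained with consequence=None"
                    )
                    consequence = None
                out.append(
                    SomaticVariant(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam exposes 1-based pos
                        ref=rec.ref,
                        alt=alt,
                        gene=per_allele("GENE"),
                        consequence=consequence,
                        protein_change=per_allele("PROTEIN_CHANGE"),
                    )
                )
    return out


def _read_variant_tsv(path: Path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != VARIANT_TSV_COLUMNS:
        raise ValueError(
            f"variant TSV header mismatch: expected {VARIANT_TSV_COLUMNS}, got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        consequence = _cell(row["consequence"])
        if consequence is not None and consequence not in CONSEQUENCE_TERMS:
            warnings.warn(f"unparseable consequence {consequence!r}; retained as None")
            consequence = None
        out.append(
            SomaticVariant(
                sample_id=row["sample"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=_cell(row["gene"]),
                consequence=consequence,
                protein_change=_cell(row["protein_change"]),
            )
        )
    return out


def write_variants_tsv(variants: list[SomaticVariant], path: str | Path) -> None:
    rows = [
        {
            "sample": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene or _NULL,
            "consequence": v.consequence or _NULL,
            "protein_change": v.protein_change or _NULL,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cna_segments(path: str | Path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != CNA_TSV_COLUMNS:
        raise ValueError(
            f"CNA TSV header mismatch: expected {CNA_TSV_COLUMNS}, got {list(df.columns)}"
        )
    return [
        CopyNumberSegment(
            sample_id=row["sample"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            gene=row["gene"],
            copy_number=float(row["copy_number"]),
        )
        for _, row in df.iterrows()
    ]


def write_cna_segments(segments: list[CopyNumberSegment], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "gene": s.gene,
            "copy_number": s.copy_number,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=CNA_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_structural_variants(path: str | Path) -> list[StructuralVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != SV_TSV_COLUMNS:
        raise ValueError(
            f"SV TSV header mismatch: expected {SV_TSV_COLUMNS}, got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        f5, f3 = _cell(row["fusion5"]), _cell(row["fusion3"])
        out.append(
            StructuralVariant(
                sample_id=row["sample"],
                chrom1=row["chrom1"],
                pos1=int(row["pos1"]),
                chrom2=row["chrom2"],
                pos2=int(row["pos2"]),
                genes=tuple(g for g in row["genes"].split(";") if g and g != _NULL),
                predicted_effect=SVEffect(row["effect"]),
                fusion_pair=(f5, f3) if f5 and f3 else None,
            )
        )
    return out


def write_structural_variants(svs: list[StructuralVariant], path: str | Path) -> None:
    rows = [
        {
            "sample": sv.sample_id,
            "chrom1": sv.chrom1,
            "pos1": sv.pos1,
            "chrom2": sv.chrom2,
            "pos2": sv.pos2,
            "genes": ";".join(sv.genes) or _NULL,
            "effect": sv.predicted_effect.value,
            "fusion5": sv.fusion_pair[0] if sv.fusion_pair else _NULL,
            "fusion3": sv.fusion_pair[1] if sv.fusion_pair else _NULL,
        }
        for sv in svs
    ]
    pd.DataFrame(rows, columns=SV_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
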