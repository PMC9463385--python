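"""Sequencing-platform footprints and in-silico down-sampling.

A *platform* is a named genomic footprint (a merged BED region set and a
fixed megabase size used as the TMB denominator) plus a capability mask
saying whether the assay can call copy-number alterations and gene fusions.
Down-sampling restricts WGS-derived calls to a platform: variants are kept
when their reference span overlaps the footprint by at least one base
(bedtools-intersect any-overlap semantics), and whole event classes are
zeroed out by the capability mask — the hotspot panel sees neither CNAs nor
fusions, the exome sees no fusions.

Coordinate conventions: BED intervals are 0-based half-open; VCF positions
are 1-based.  The conversion lives in exactly one function,
:func:`vcf_span_to_bed`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .variants import CopyNumberSegment, SomaticVariant, StructuralVariant, SVEffect

__all__ = [
    "RegionSet",
    "Platform",
    "PlatformName",
    "SampleAlterations",
    "ChromosomeDialectError",
    "load_regions",
    "filter_variants",
    "downsample_sample",
    "vcf_span_to_bed",
    "WGS_MB",
    "WES_MB",
    "CPANEL_MB",
    "HGP_MB",
]

# Fixed TMB denominators (megabases). The WGS denominator is the conventional
# 3000 Mb constant, not the true mappable genome size; the three capture
# footprints are the exact kit sizes.
WGS_MB = 3000.0
WES_MB = 37.105146
CPANEL_MB = 2.628876
HGP_MB = 0.016951


class ChromosomeDialectError(ValueError):
    """Chromosome naming mismatch (``chr1`` vs ``1``) between calls and regions."""


def vcf_span_to_bed(pos: int, ref: str) -> tuple[int, int]:
    """Convert a 1-based VCF record (pos, REF) to a 0-based half-open span.

    The reference span of a left-aligned record covers len(ref) bases starting
    at ``pos``: 1-based inclusive [pos, pos+len(ref)-1], i.e. half-open
    [pos-1, pos-1+len(ref)).
    """
    start = pos - 1
    return (start, start + max(len(ref), 1))


@dataclass
class RegionSet:
    """A sorted, merged set of genomic intervals in BED (0-based half-open) convention."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end} on {chrom}")
            if start == end:
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)  # merge abutting intervals too
        return cls(trees=trees)

    @property
    def total_bases(self) -> int:
        return sum(iv.end - iv.begin for tree in self.trees.values() for iv in tree)

    @property
    def chroms(self) -> frozenset[str]:
        return frozenset(self.trees)

    def __len__(self) -> int:
        return sum(len(tree) for tree in self.trees.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any-overlap test against a 0-based half-open query span."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.overlaps(chrom, pos0, pos0 + 1)

    def is_subset_of(self, other: "RegionSet") -> bool:
        """Positionwise containment: every base of self lies in other."""
        for chrom, start, end in self.intervals():
            tree = other.trees.get(chrom)
            if tree is None:
                return False
            covered = sorted(tree.overlap(start, end))
            cursor = start
            for iv in covered:
                if iv.begin > cursor:
                    return False
                cursor = max(cursor, iv.end)
                if cursor >= end:
                    break
            if cursor < end:
                return False
        return True


def load_regions(path: str | Path) -> RegionSet:
    """Load a BED3+ file into a merged :class:`RegionSet`.

    Zero-length intervals are dropped with a warning; ``start > end`` is an
    error naming the offending line.  ``track``/``browser``/comment lines are
    skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: BED line has fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path.name}:{lineno}: start {start} > end {end}")
            if start == end:
                warnings.warn(f"{path.name}:{lineno}: zero-length interval dropped")
                continue
            intervals.append((chrom, start, end))
    return RegionSet.from_intervals(intervals)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def _check_chrom_dialect(variant_chroms: set[str], regions: RegionSet) -> None:
    region_chroms = set(regions.chroms)
    if not variant_chroms or not region_chroms:
        return
    if variant_chroms & region_chroms:
        return
    toggled = {
        c.removeprefix("chr") if c.startswith("chr") else f"chr{c}" for c in variant_chroms
    }
    if toggled & region_chroms:
        raise ChromosomeDialectError(
            "chromosome naming mismatch between variants and regions "
            f"(e.g. variants use {sorted(variant_chroms)[:3]}, regions use "
            f"{sorted(region_chroms)[:3]}); rename one side explicitly"
        )


def filter_variants(
    variants: Sequence[SomaticVariant], regions: RegionSet
) -> list[SomaticVariant]:
    """Retain variants whose reference span overlaps the region set by >= 1 base.

    Order is preserved and the input is not modified.  A ``chr``-prefix
    dialect mismatch raises :class:`ChromosomeDialectError` instead of
    silently retaining nothing.
    """
    _check_chrom_dialect({v.chrom for v in variants}, regions)
    out = []
    for v in variants:
        start, end = vcf_span_to_bed(v.pos, v.ref)
        if regions.overlaps(v.chrom, start, end):
            out.append(v)
    return out


class PlatformName(str, enum.Enum):
    WGS = "WGS"
    WES = "WES"
    CPANEL = "CPANEL"
    HGP = "HGP"


# Default capability masks: the hotspot panel cannot call CNAs or fusions,
# and only WGS and the comprehensive panel can call gene fusions.
_DEFAULT_CAPABILITIES = {
    PlatformName.WGS: (True, True),
    PlatformName.WES: (True, False),
    PlatformName.CPANEL: (True, True),
    PlatformName.HGP: (False, False),
}

_DEFAULT_FOOTPRINT_MB = {
    PlatformName.WGS: WGS_MB,
    PlatformName.WES: WES_MB,
    PlatformName.CPANEL: CPANEL_MB,
    PlatformName.HGP: HGP_MB,
}


@dataclass
class Platform:
    """A named sequencing platform: footprint, TMB denominator, capability mask.

    ``regions=None`` means whole-genome (no restriction).  ``footprint_mb``
    is a fixed parameter of the platform, *not* recomputed from the BED: the
    WGS denominator is 3000 Mb by convention and the capture denominators are
    the printed kit sizes.
    """

    name: PlatformName
    regions: RegionSet | None
    footprint_mb: float
    detects_cna: bool
    detects_fusion: bool

    def __post_init__(self) -> None:
        if self.footprint_mb <= 0:
            raise ValueError("footprint_mb must be positive")
        if self.name is PlatformName.WGS and self.regions is not None:
            raise ValueError("WGS is whole-genome; it takes no region restriction")

    @classmethod
    def standard(
        cls,
        name: str | PlatformName,
        regions: RegionSet | None = None,
        footprint_mb: float | None = None,
    ) -> "Platform":
        """Build a platform with the standard denominator and capability mask."""
        name = PlatformName(name.upper() if isinstance(name, str) else name)
        cna, fus = _DEFAULT_CAPABILITIES[name]
        if name is not PlatformName.WGS and regions is None:
            raise ValueError(f"{name.value} requires a region set")
        return cls(
            name=name,
            regions=None if name is PlatformName.WGS else regions,
            footprint_mb=footprint_mb if footprint_mb is not None else _DEFAULT_FOOTPRINT_MB[name],
            detects_cna=cna,
            detects_fusion=fus,
        )


@dataclass
class SampleAlterations:
    """All somatic calls for one sample: SNV/indels, CNA segments, SVs."""

    sample_id: str
    variants: list[SomaticVariant] = field(default_factory=list)
    cnas: list[CopyNumberSegment] = field(default_factory=list)
    svs: list[StructuralVariant] = field(default_factory=list)


def downsample_sample(alterations: SampleAlterations, platform: Platform) -> SampleAlterations:
    """Restrict a sample's calls to a platform's footprint and capabilities.

    SNV/indels are region-filtered (any-overlap); CNA segments are dropped
    entirely when the platform cannot call CNAs, otherwise kept when the
    segment overlaps the footprint; viable-fusion SVs are dropped when the
    platform cannot call fusions, and loss-of-function SVs follow the CNA
    mask (they feed deletion biomarkers).  WGS returns the input unchanged
    (as a shallow copy).
    """
    if platform.regions is None:
        return SampleAlterations(
            sample_id=alterations.sample_id,
            variants=list(alterations.variants),
            cnas=list(alterations.cnas),
            svs=list(alterations.svs),
        )

    regions = platform.regions
    variants = filter_variants(alterations.variants, regions)

    cnas: list[CopyNumberSegment] = []
    if platform.detects_cna:
        for seg in alterations.cnas:
            if regions.overlaps(seg.chrom, seg.start - 1, seg.end):
                cnas.append(seg)

    svs: list[StructuralVariant] = []
    for sv in alterations.svs:
        if sv.predicted_effect is SVEffect.VIABLE_FUSION:
            if platform.detects_fusion:
                svs.append(sv)
        elif sv.predicted_effect is SVEffect.LOSS_OF_FUNCTION:
            if platform.detects_cna:
                svs.append(sv)
        elif platform.detects_fusion:
            # other / intra-intron events need structural sensitivity too;
            # they are excluded downstream by the matcher anyway
            svs.append(sv)

    return SampleAlterations(
        sample_id=alterations.sample_id, variants=variants, cnas=cnas, svs=svs
    )
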