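"""Synthetic toy genome, knowledge base and tumour cohorts with ground truth.

Everything the pipeline consumes can be generated here, so every stage is
testable without controlled-access patient data.  The toy world is a 9 Mb
three-chromosome genome carrying 60 single-interval genes; the platform
footprints are nested by construction (hotspot panel ⊂ comprehensive panel
⊂ exome ⊂ genome) and their sizes are recorded exactly so toy-world TMB
denominators are exact.  Footprints are scaled up relative to the real kits
(the toy hotspot panel is ~0.5% of the toy genome) so that panel mutation
counts are informative at desk scale.

Cohort simulation follows the structure of real pan-cancer cohorts:

* passenger SNVs: Poisson(rate × genome Mb) per sample, placed uniformly,
  with per-sample rates drawn lognormally around the cohort rate
  (``rate_dispersion``) because real cohorts have heterogeneous burdens —
  without that heterogeneity cross-platform TMB correlation would not
  depend on the mutation rate at all;
* actionable hotspots, CNAs, gene fusions and loss-of-function SVs planted
  by independent Bernoulli draws at designed prevalences;
* MSI-high samples receive shifted tumour repeat-length distributions at a
  designed fraction of microsatellite loci.

Passenger mutations are non-actionable by construction: they are never
placed inside genes that carry mutation-class KB rules, so the ground truth
labels are exact rather than probabilistic.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .knowledge_base import (
    AlterationClass,
    Association,
    BiomarkerKB,
    BiomarkerRule,
    EvidenceTier,
    TumourOntology,
    tier_group,
)
from .msi import MicrosatelliteSite, write_msi_sites
from .platforms import Platform, PlatformName, RegionSet, SampleAlterations, write_regions
from .variants import (
    CopyNumberSegment,
    SomaticVariant,
    StructuralVariant,
    SVEffect,
    write_cna_segments,
    write_structural_variants,
)

__all__ = [
    "GeneModel",
    "ToyReference",
    "CohortProfile",
    "SampleGroundTruth",
    "SimulatedCohort",
    "make_toy_reference",
    "make_toy_kb",
    "simulate_cohort",
    "write_reference_files",
    "write_cohort",
    "melanoma_like",
    "pdac_like",
    "mesothelioma_like",
]

# Synonymous : non-synonymous passenger ratio is fixed at 1 : 2.5 so the
# non-synonymous TMB filter has a designed, testable effect in the toy world.
P_NONSYNONYMOUS = 2.5 / 3.5

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneModel:
    """A single-interval toy gene; coordinates 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int

    @property
    def hotspot_pos0(self) -> int:
        """Fixed 0-based hotspot position, inside the gene's HGP window."""
        return self.start + 1000


@dataclass
class ToyReference:
    """Toy genome: chrom sizes, gene table, nested footprints, MSI loci."""

    chrom_sizes: dict[str, int]
    genes: dict[str, GeneModel]
    wes: RegionSet
    cpanel: RegionSet
    hgp: RegionSet
    msi_loci: list[tuple[str, int, int, str]]  # chrom, start, end, unit
    cpanel_genes: list[str]
    mut_rule_genes: frozenset[str] = frozenset()

    @property
    def genome_mb(self) -> float:
        return sum(self.chrom_sizes.values()) / 1e6

    def platforms(self) -> dict[str, Platform]:
        """Toy platforms with exact toy denominators and standard capability masks."""
        return {
            "WGS": Platform(PlatformName.WGS, None, self.genome_mb, True, True),
            "WES": Platform(PlatformName.WES, self.wes, self.wes.total_bases / 1e6, True, False),
            "CPANEL": Platform(
                PlatformName.CPANEL, self.cpanel, self.cpanel.total_bases / 1e6, True, True
            ),
            "HGP": Platform(PlatformName.HGP, self.hgp, self.hgp.total_bases / 1e6, False, False),
        }


_NAMED_GENES = [
    "BRAF", "KRAS", "EGFR", "KIT", "TP53", "BRCA1", "TSC2", "NRAS", "MLL2", "PIK3CA",
    "ERBB2", "CDKN2A", "NF1", "MET",
    "NTRK1", "TPM3", "FGFR2", "BICC1", "RET", "CCDC6",
]

_GENE_LENGTH = 30_000
_HGP_WINDOW = 2_500


def make_toy_reference(seed: int = 0) -> ToyReference:
    """Deterministic toy genome with nested platform footprints.

    The 20 named cancer genes form the comprehensive panel; a 2.5 kb hotspot
    window at the start of each of them forms the hotspot panel; the union
    of all 60 gene bodies forms the exome.  120 microsatellite loci are
    placed half in exonic territory, half intergenic, and none inside a
    hotspot window.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {"1": 4_000_000, "2": 3_000_000, "3": 2_000_000}

    all_names = _NAMED_GENES + [f"GENE{i:02d}" for i in range(1, 41)]
    genes: dict[str, GeneModel] = {}
    chroms = list(chrom_sizes)
    per_chrom = [20, 20, 20]
    idx = 0
    for chrom, n_genes in zip(chroms, per_chrom):
        # evenly spaced gene starts with a small deterministic jitter
        spacing = (chrom_sizes[chrom] - 200_000) // n_genes
        for k in range(n_genes):
            start = 100_000 + k * spacing + int(rng.integers(0, 5_000))
            name = all_names[idx]
            genes[name] = GeneModel(name, chrom, start, start + _GENE_LENGTH)
            idx += 1

    wes = RegionSet.from_intervals((g.chrom, g.start, g.end) for g in genes.values())
    cpanel_genes = list(_NAMED_GENES)
    cpanel = RegionSet.from_intervals(
        (genes[n].chrom, genes[n].start, genes[n].end) for n in cpanel_genes
    )
    hgp = RegionSet.from_intervals(
        (genes[n].chrom, genes[n].start, genes[n].start + _HGP_WINDOW) for n in cpanel_genes
    )

    # microsatellite loci: 20 in panel genes (outside the hotspot windows),
    # 40 in exome-only filler genes, 60 intergenic
    loci: list[tuple[str, int, int, str]] = []
    for n in cpanel_genes:
        g = genes[n]
        loci.append((g.chrom, g.start + 10_000, g.start + 10_020, "A"))
    for i in range(1, 41):
        g = genes[f"GENE{i:02d}"]
        loci.append((g.chrom, g.start + 5_000, g.start + 5_020, "A"))
    for j in range(60):
        chrom = chroms[j % 3]
        pos = 50_000 + j * 1_000  # upstream of every gene: intergenic
        loci.append((chrom, pos, pos + 20, "A"))
    loci.sort()

    return ToyReference(
        chrom_sizes=chrom_sizes,
        genes=genes,
        wes=wes,
        cpanel=cpanel,
        hgp=hgp,
        msi_loci=loci,
        cpanel_genes=cpanel_genes,
    )


_TUMOUR_LABELS = [
    "melanoma_cutaneous", "melanoma_mucosal", "breast_adenocarcinoma",
    "oesophageal_adenocarcinoma", "ovarian_adenocarcinoma",
    "colorectal_adenocarcinoma", "pdac", "pnet", "mesothelioma",
    "lung_adenocarcinoma", "gist", "renal_angiomyolipoma",
    "cholangiocarcinoma", "nsclc", "endometrial_adenocarcinoma",
]


def make_toy_kb(seed: int = 0) -> BiomarkerKB:
    """A small KB covering every rule archetype the matcher must handle.

    Archetypes: exact-hotspot FDA sensitivity (BRAF V600E), codon wildcard
    (BRAF V600., NRAS Q61.), gene-level resistance (KRAS any → cetuximab),
    off-label-only (KIT L576P approved in GIST only), tumour-agnostic fusion
    (NTRK1), partnered fusion (FGFR2–BICC1), LOF patterns (BRCA1, TSC2,
    MLL2), amplification (ERBB2), deletion (CDKN2A, NF1), trials-only
    (TP53), and case-report / pre-clinical rules excluded from headline
    counts.  Deterministic; the seed is accepted for API symmetry.
    """
    del seed
    T = EvidenceTier
    A = Association

    def rule(rid, gene, cls, pattern, partner, tumours, drug, assoc, tier, driver=True):
        return BiomarkerRule(
            rule_id=rid, gene=gene, alteration_class=AlterationClass(cls),
            variant_pattern=pattern, fusion_partner=partner,
            tumour_types=frozenset({tumours}) if isinstance(tumours, str) else frozenset(tumours),
            drug=drug, association=assoc, evidence=tier, driver_catalogued=driver,
        )

    rules = [
        rule("R001", "BRAF", "MUT", "V600E", None, "melanoma_cutaneous", "dabrafenib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R002", "BRAF", "MUT", "V600.", None, "melanoma_cutaneous", "vemurafenib", A.SENSITIVITY, T.NCCN_GUIDELINES),
        rule("R003", "ERBB2", "AMP", None, None, {"breast_adenocarcinoma", "oesophageal_adenocarcinoma"}, "trastuzumab", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R004", "KRAS", "MUT", "any", None, "colorectal_adenocarcinoma", "cetuximab", A.RESISTANCE, T.FDA_GUIDELINES),
        rule("R005", "KIT", "MUT", "L576P", None, "gist", "imatinib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R006", "NTRK1", "FUS", None, "any", "any", "larotrectinib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R007", "FGFR2", "FUS", None, "BICC1", "cholangiocarcinoma", "pemigatinib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R008", "TP53", "MUT", "any", None, "ovarian_adenocarcinoma", "adavosertib+carboplatin", A.SENSITIVITY, T.EARLY_TRIALS),
        rule("R009", "BRCA1", "MUT", "LOF", None, {"ovarian_adenocarcinoma", "breast_adenocarcinoma"}, "olaparib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R010", "TSC2", "MUT", "LOF", None, "renal_angiomyolipoma", "everolimus", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R011", "MLL2", "MUT", "LOF", None, "oesophageal_adenocarcinoma", "toy-epidrug", A.SENSITIVITY, T.PRE_CLINICAL),
        rule("R012", "EGFR", "MUT", "L858R", None, "lung_adenocarcinoma", "erlotinib", A.SENSITIVITY, T.FDA_GUIDELINES),
        rule("R013", "NRAS", "MUT", "Q61.", None, {"melanoma_cutaneous", "melanoma_mucosal"}, "binimetinib", A.SENSITIVITY, T.LATE_TRIALS),
        rule("R014", "CDKN2A", "DEL", None, None, "nsclc", "palbociclib", A.SENSITIVITY, T.EARLY_TRIALS),
        rule("R015", "NF1", "DEL", None, None, "melanoma_cutaneous", "trametinib", A.SENSITIVITY, T.CASE_REPORT),
        rule("R016", "KRAS", "MUT", "G12C", None, "nsclc", "sotorasib", A.SENSITIVITY, T.FDA_GUIDELINES),
    ]
    ontology = TumourOntology(
        synonyms={label: label for label in _TUMOUR_LABELS},
        parents={label: "solid_tumour" for label in _TUMOUR_LABELS},
    )
    return BiomarkerKB(rules=rules, ontology=ontology)


@dataclass
class CohortProfile:
    """Designed characteristics of one simulated cohort.

    hotspot_prevalences / resistance_prevalences map (gene, protein_change)
    to a per-sample Bernoulli probability; a protein_change of "LOF"
    plants a frameshift.  cna_events maps gene → (probability, copy number);
    fusion_events maps (5' gene, 3' gene) → probability; lof_sv_events maps
    gene → probability of a loss-of-function SV.  ``rate_dispersion`` is the
    lognormal sigma of the per-sample mutation rate around
    ``mutation_rate_per_mb`` (mean-preserving).
    """

    cohort_name: str
    tumour_type: str
    n_samples: int
    mutation_rate_per_mb: float
    seed: int
    rate_dispersion: float = 0.5
    hotspot_prevalences: dict[tuple[str, str], float] = field(default_factory=dict)
    resistance_prevalences: dict[tuple[str, str], float] = field(default_factory=dict)
    cna_events: dict[str, tuple[float, float]] = field(default_factory=dict)
    fusion_events: dict[tuple[str, str], float] = field(default_factory=dict)
    lof_sv_events: dict[str, float] = field(default_factory=dict)
    msi_h_fraction: float = 0.0
    msi_unstable_fraction: float = 0.3
    msi_loci_coverage: int = 200
    generate_msi: bool = True  # skip site simulation for TMB-only studies

    def __post_init__(self) -> None:
        if self.mutation_rate_per_mb <= 0:
            raise ValueError("mutation rate must be positive")
        probs = (
            list(self.hotspot_prevalences.values())
            + list(self.resistance_prevalences.values())
            + [p for p, _ in self.cna_events.values()]
            + list(self.fusion_events.values())
            + list(self.lof_sv_events.values())
            + [self.msi_h_fraction, self.msi_unstable_fraction]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


@dataclass
class SampleGroundTruth:
    """What the generator planted in one sample."""

    sample_id: str
    tumour_type: str
    genome_mutation_count: int
    msi_h: bool
    planted_hotspots: list[tuple[str, str]] = field(default_factory=list)
    planted_cnas: list[tuple[str, float]] = field(default_factory=list)
    planted_fusions: list[tuple[str, str]] = field(default_factory=list)
    planted_lof_svs: list[str] = field(default_factory=list)
    # (evidence_group, "on"/"off", association) flags expected at WGS
    expected_flags: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    profile: CohortProfile
    reference: ToyReference
    samples: dict[str, SampleAlterations]
    msi_sites: dict[str, list[MicrosatelliteSite]]
    truth: dict[str, SampleGroundTruth]


def _mut_rule_genes(kb: BiomarkerKB) -> frozenset[str]:
    return frozenset(r.gene for r in kb.rules if r.alteration_class is AlterationClass.MUT)


def _pattern_covers(rule: BiomarkerRule, change: str) -> bool:
    """Generator-side check that a planted protein change satisfies a MUT
    rule pattern — kept deliberately plain so ground truth is independent of
    the matcher implementation."""
    p = rule.variant_pattern
    if p == "any":
        return True
    if p == "LOF":
        return change == "LOF"
    if change == "LOF":
        return False
    if p.endswith("."):
        return change.startswith(p[:-1]) and not change[len(p) - 1 :][:1].isdigit()
    return change == p


def _expected_flags(
    kb: BiomarkerKB,
    tumour: str,
    hotspots: list[tuple[str, str]],
    cnas: list[tuple[str, float]],
    fusions: list[tuple[str, str]],
    lof_svs: list[str],
    amp_threshold: float = 6.0,
    homdel_threshold: float = 1.0,
) -> list[tuple[str, str, str]]:
    flags: set[tuple[str, str, str]] = set()
    for rule in kb.rules:
        fired = False
        if rule.alteration_class is AlterationClass.MUT:
            fired = any(g == rule.gene and _pattern_covers(rule, c) for g, c in hotspots)
        elif rule.alteration_class is AlterationClass.AMP:
            fired = any(g == rule.gene and cn >= amp_threshold for g, cn in cnas)
        elif rule.alteration_class is AlterationClass.DEL:
            fired = any(g == rule.gene and cn < homdel_threshold for g, cn in cnas) or (
                rule.gene in lof_svs
            )
        elif rule.alteration_class is AlterationClass.FUS:
            for g5, g3 in fusions:
                if rule.gene in (g5, g3):
                    partner = g3 if rule.gene == g5 else g5
                    if rule.fusion_partner in ("any", partner):
                        fired = True
        if fired:
            scope = "on" if kb.rule_matches_tumour(rule, tumour) else "off"
            flags.add((tier_group(rule.evidence), scope, rule.association.value))
    return sorted(flags)


def simulate_cohort(
    profile: CohortProfile, reference: ToyReference, kb: BiomarkerKB
) -> SimulatedCohort:
    """Generate a cohort of samples with exact ground truth.

    Deterministic given ``profile.seed``.  Raises if the profile references
    genes absent from the toy gene table.
    """
    for gene in (
        [g for g, _ in profile.hotspot_prevalences]
        + [g for g, _ in profile.resistance_prevalences]
        + list(profile.cna_events)
        + [g for pair in profile.fusion_events for g in pair]
        + list(profile.lof_sv_events)
    ):
        if gene not in reference.genes:
            raise ValueError(f"profile references unknown gene {gene!r}")

    rng = np.random.default_rng(profile.seed)
    forbidden = _mut_rule_genes(kb)
    chroms = list(reference.chrom_sizes)
    offsets = np.cumsum([0] + [reference.chrom_sizes[c] for c in chroms])
    genome_len = int(offsets[-1])

    # per-chromosome sorted gene arrays for overlap lookup
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chroms}
    for g in reference.genes.values():
        genes_by_chrom[g.chrom].append(g)
    for glist in genes_by_chrom.values():
        glist.sort(key=lambda g: g.start)
    gene_starts = {c: [g.start for g in glist] for c, glist in genes_by_chrom.items()}

    def locate(pos_linear: int) -> tuple[str, int]:
        ci = int(np.searchsorted(offsets, pos_linear, side="right") - 1)
        return chroms[ci], int(pos_linear - offsets[ci])

    def gene_at(chrom: str, pos0: int) -> GeneModel | None:
        glist = genes_by_chrom[chrom]
        i = bisect.bisect_right(gene_starts[chrom], pos0) - 1
        if i >= 0 and glist[i].start <= pos0 < glist[i].end:
            return glist[i]
        return None

    samples: dict[str, SampleAlterations] = {}
    msi_sites: dict[str, list[MicrosatelliteSite]] = {}
    truth: dict[str, SampleGroundTruth] = {}

    lognorm_mu = -0.5 * profile.rate_dispersion**2  # mean-preserving

    for i in range(profile.n_samples):
        sid = f"{profile.cohort_name}_s{i:04d}"
        rate = profile.mutation_rate_per_mb * float(
            rng.lognormal(mean=lognorm_mu, sigma=profile.rate_dispersion)
        ) if profile.rate_dispersion > 0 else profile.mutation_rate_per_mb
        n_passengers = int(rng.poisson(rate * reference.genome_mb))

        variants: list[SomaticVariant] = []
        # passenger SNVs, rejected out of mutation-rule genes
        placed = 0
        while placed < n_passengers:
            draw = rng.integers(0, genome_len, size=(n_passengers - placed) + 8)
            for pos_linear in draw:
                if placed == n_passengers:
                    break
                chrom, pos0 = locate(int(pos_linear))
                gene = gene_at(chrom, pos0)
                if gene is not None and gene.name in forbidden:
                    continue
                if gene is not None:
                    consequence = (
                        "missense_variant"
                        if rng.random() < P_NONSYNONYMOUS
                        else "synonymous_variant"
                    )
                    gene_name = gene.name
                else:
                    consequence = "intergenic_variant"
                    gene_name = None
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                variants.append(
                    SomaticVariant(
                        sample_id=sid, chrom=chrom, pos=pos0 + 1,
                        ref=str(ref), alt=str(alt),
                        gene=gene_name, consequence=consequence, protein_change=None,
                    )
                )
                placed += 1

        # planted actionable hotspots
        hotspots: list[tuple[str, str]] = []
        for (gene_name, change), p in {
            **profile.hotspot_prevalences,
            **profile.resistance_prevalences,
        }.items():
            if rng.random() < p:
                gene = reference.genes[gene_name]
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                if change == "LOF":
                    consequence, pchange = "frameshift_variant", "E100fs"
                else:
                    consequence, pchange = "missense_variant", change
                variants.append(
                    SomaticVariant(
                        sample_id=sid, chrom=gene.chrom, pos=gene.hotspot_pos0 + 1,
                        ref=str(ref), alt=str(alt),
                        gene=gene_name, consequence=consequence, protein_change=pchange,
                    )
                )
                hotspots.append((gene_name, change))

        # CNAs: planted events plus one neutral diploid segment as a negative control
        cnas: list[CopyNumberSegment] = []
        planted_cnas: list[tuple[str, float]] = []
        for gene_name, (p, cn) in profile.cna_events.items():
            if rng.random() < p:
                g = reference.genes[gene_name]
                cnas.append(
                    CopyNumberSegment(
                        sample_id=sid, chrom=g.chrom, start=g.start + 1, end=g.end,
                        gene=gene_name, copy_number=float(cn),
                    )
                )
                planted_cnas.append((gene_name, float(cn)))
        neutral_gene = reference.genes["GENE01"]
        cnas.append(
            CopyNumberSegment(
                sample_id=sid, chrom=neutral_gene.chrom, start=neutral_gene.start + 1,
                end=neutral_gene.end, gene=neutral_gene.name, copy_number=2.0,
            )
        )

        # SVs: viable fusions and loss-of-function events
        svs: list[StructuralVariant] = []
        planted_fusions: list[tuple[str, str]] = []
        for (g5, g3), p in profile.fusion_events.items():
            if rng.random() < p:
                a, b = reference.genes[g5], reference.genes[g3]
                svs.append(
                    StructuralVariant(
                        sample_id=sid,
                        chrom1=a.chrom, pos1=(a.start + a.end) // 2,
                        chrom2=b.chrom, pos2=(b.start + b.end) // 2,
                        genes=(g5, g3),
                        predicted_effect=SVEffect.VIABLE_FUSION,
                        fusion_pair=(g5, g3),
                    )
                )
                planted_fusions.append((g5, g3))
        planted_lof_svs: list[str] = []
        for gene_name, p in profile.lof_sv_events.items():
            if rng.random() < p:
                g = reference.genes[gene_name]
                svs.append(
                    StructuralVariant(
                        sample_id=sid,
                        chrom1=g.chrom, pos1=g.start + 500,
                        chrom2=g.chrom, pos2=g.end - 500,
                        genes=(gene_name,),
                        predicted_effect=SVEffect.LOSS_OF_FUNCTION,
                        fusion_pair=None,
                    )
                )
                planted_lof_svs.append(gene_name)

        # microsatellite sites
        is_msi_h = bool(rng.random() < profile.msi_h_fraction)
        sites: list[MicrosatelliteSite] = []
        cov = profile.msi_loci_coverage
        loci = reference.msi_loci if profile.generate_msi else []
        for chrom, start, end, unit in loci:
            ref_len = 15
            normal = rng.multinomial(cov, [0.15, 0.70, 0.15])
            normal_counts = {
                ref_len - 1: int(normal[0]), ref_len: int(normal[1]), ref_len + 1: int(normal[2])
            }
            if is_msi_h and rng.random() < profile.msi_unstable_fraction:
                tum = rng.multinomial(cov, [0.30, 0.50, 0.20])
                tumour_counts = {
                    ref_len - 3: int(tum[0]), ref_len - 2: int(tum[1]), ref_len - 1: int(tum[2])
                }
            else:
                tum = rng.multinomial(cov, [0.15, 0.70, 0.15])
                tumour_counts = {
                    ref_len - 1: int(tum[0]), ref_len: int(tum[1]), ref_len + 1: int(tum[2])
                }
            sites.append(
                MicrosatelliteSite(
                    chrom=chrom, start=start, end=end, repeat_unit=unit,
                    normal_counts=normal_counts, tumour_counts=tumour_counts,
                )
            )

        samples[sid] = SampleAlterations(sample_id=sid, variants=variants, cnas=cnas, svs=svs)
        msi_sites[sid] = sites
        truth[sid] = SampleGroundTruth(
            sample_id=sid,
            tumour_type=profile.tumour_type,
            genome_mutation_count=len(variants),
            msi_h=is_msi_h,
            planted_hotspots=hotspots,
            planted_cnas=planted_cnas,
            planted_fusions=planted_fusions,
            planted_lof_svs=planted_lof_svs,
            expected_flags=_expected_flags(
                kb, profile.tumour_type, hotspots, planted_cnas, planted_fusions, planted_lof_svs
            ),
        )

    return SimulatedCohort(
        profile=profile, reference=reference, samples=samples,
        msi_sites=msi_sites, truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohort presets mirroring the structure of real pan-cancer datasets.


def melanoma_like(n_samples: int = 200, seed: int = 0) -> CohortProfile:
    """High mutation rate; BRAF V600E on-label hotspot at 0.25, KIT L576P
    off-label at 0.10, NRAS Q61K trials-tier at 0.20."""
    return CohortProfile(
        cohort_name="melanoma_like",
        tumour_type="melanoma_cutaneous",
        n_samples=n_samples,
        mutation_rate_per_mb=30.0,
        seed=seed,
        hotspot_prevalences={
            ("BRAF", "V600E"): 0.25,
            ("KIT", "L576P"): 0.10,
            ("NRAS", "Q61K"): 0.20,
        },
        lof_sv_events={"NF1": 0.05},
        msi_h_fraction=0.02,
    )


def pdac_like(n_samples: int = 100, seed: int = 0) -> CohortProfile:
    """Low mutation rate; KRAS resistance biomarker at 0.895; occasional RET fusion."""
    return CohortProfile(
        cohort_name="pdac_like",
        tumour_type="pdac",
        n_samples=n_samples,
        mutation_rate_per_mb=2.0,
        seed=seed,
        resistance_prevalences={("KRAS", "G12D"): 0.895},
        fusion_events={("CCDC6", "RET"): 0.01},
        msi_h_fraction=0.01,
    )


def mesothelioma_like(n_samples: int = 50, seed: int = 0) -> CohortProfile:
    """Very low rate, essentially no actionable events."""
    return CohortProfile(
        cohort_name="mesothelioma_like",
        tumour_type="mesothelioma",
        n_samples=n_samples,
        mutation_rate_per_mb=1.0,
        seed=seed,
        lof_sv_events={"NF1": 0.05},
    )


# ---------------------------------------------------------------------------
# File output


def write_reference_files(reference: ToyReference, outdir: str | Path) -> dict[str, Path]:
    """Write gene table, footprint BEDs and the microsatellite locus BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "wes": outdir / "wes.bed",
        "cpanel": outdir / "cpanel.bed",
        "hgp": outdir / "hgp.bed",
        "msi_loci": outdir / "msi_loci.bed",
    }
    with open(paths["genes"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for name in sorted(reference.genes):
            g = reference.genes[name]
            fh.write(f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}\n")
    write_regions(reference.wes, paths["wes"])
    write_regions(reference.cpanel, paths["cpanel"])
    write_regions(reference.hgp, paths["hgp"])
    with open(paths["msi_loci"], "w") as fh:
        for chrom, start, end, unit in reference.msi_loci:
            fh.write(f"{chrom}\t{start}\t{end}\t{unit}\n")
    return paths


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=actiondown-simulator
{contigs}
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Sequence Ontology consequence">
##INFO=<ID=PROTEIN_CHANGE,Number=1,Type=String,Description="Protein change">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_sample_vcf(
    variants: list[SomaticVariant], chrom_sizes: dict[str, int], path: str | Path
) -> None:
    """Write one sample's SNV/indel calls as a minimal annotated VCF 4.2."""
    contigs = "\n".join(
        f"##contig=<ID={c},length={n}>" for c, n in chrom_sizes.items()
    )
    order = {c: i for i, c in enumerate(chrom_sizes)}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in sorted(variants, key=lambda v: (order.get(v.chrom, 99), v.pos)):
            info = []
            if v.gene:
                info.append(f"GENE={v.gene}")
            if v.consequence:
                info.append(f"CONSEQUENCE={v.consequence}")
            if v.protein_change:
                info.append(f"PROTEIN_CHANGE={v.protein_change}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info) or '.'}\n"
            )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Write per-sample VCF + CNA/SV TSVs, the cohort MSI site table and the
    ground-truth JSON.  Deterministic content: identical seeds give
    byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid in sorted(cohort.samples):
        alts = cohort.samples[sid]
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        write_sample_vcf(alts.variants, cohort.reference.chrom_sizes, sdir / f"{sid}.vcf")
        write_cna_segments(alts.cnas, sdir / f"{sid}.cna.tsv")
        write_structural_variants(alts.svs, sdir / f"{sid}.sv.tsv")
    write_msi_sites(cohort.msi_sites, outdir / "msi_sites.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {sid: asdict(t) for sid, t in sorted(cohort.truth.items())},
            fh, indent=1, sort_keys=True,
        )
    return outdir
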