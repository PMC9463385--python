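# Methods

This note records the models, conventions and parameter choices behind
`actiondown`, and what the synthetic world does and does not establish
about real data.

## Knowledge base and repurposing model

A biomarker rule links one biomarker — identified for counting purposes as
(gene, alteration class, pattern) — to one drug in one or more tumour
types, at one of six evidence tiers. The tiers are totally ordered
(FDA guidelines > NCCN guidelines > late trials > early trials > case
report > pre-clinical) and collapse into headline groups: *approved*
(FDA + NCCN), *trials* (late + early), *other* (case report +
pre-clinical). Grouping NCCN with FDA in "approved" is a deliberate
reading; both are treatment-guideline tiers. Case-report and pre-clinical
rules stay in the KB and are reported, but never enter headline
approved/trials percentages.

Tumour-type matching goes through a flat synonym ontology with one optional
parent level. The parent (`solid_tumour` in the toy world) exists so that
tumour-agnostic approvals (e.g. NTRK-fusion inhibitors) can cover any
solid-tumour label; a rule may equivalently declare `any`. This is the
minimal structure that expresses on/off-label logic without a real disease
ontology; mapping a new dataset's cancer labels onto KB labels is the
user's explicit responsibility via the ontology table, because implicit
label matching is a silent-error magnet.

A match is classified by (evidence group) × (does the fired rule's tumour
scope cover the sample's tumour type): approved/trials × on/off-label, with
"other" evidence kept separate. Cohort summaries count *patients*, not
matches, with the **additive off-label convention**: a patient counts
off-label for a group and association only when they have no on-label
option of that same group and association. Off-label percentages therefore
read as the additional fraction of the cohort that gains an option through
repurposing, and on% + off% equals the percentage of patients with any
option of the group. Denominators are always the full cohort size.
Resistance calls never veto sensitivity calls; the two associations are
tabulated separately.

## Matching rules

* Copy number is total and ploidy-uncorrected: CN ≥ 6 is an amplification
  (the boundary CN = 6 amplifies), CN < 1 a homozygous deletion (CN = 1 is
  neutral). Both thresholds are configurable (`MatcherConfig`), no
  ploidy-aware mode is provided.
* Loss-of-function SVs become deletion biomarkers on each affected gene;
  viable fusions become (5', 3') fusion alterations; intra-intron fusions
  and other SVs are excluded as of unknown significance.
* The protein-change pattern grammar has four forms: exact amino-acid
  change (`V600E`), codon wildcard (`V600.` — any substitution at that
  codon, and `V6000E` must not match), gene-level `any`, and `LOF`
  (nonsense, frameshift, splice donor/acceptor, start-loss). This is the
  smallest grammar covering hotspot, codon-level, gene-level and
  LOF-class catalogue entries.
* Synonymous (non-protein-affecting) variants never match. With the
  default `driver_only=True`, the broad patterns (`any`, `LOF`) fire only
  for rules catalogued as driver biomarkers; fully specified hotspot
  patterns are themselves the catalogued driver and are not additionally
  gated.
* Fusion rules match when the rule gene is either partner and the declared
  partner is the other gene or `any`.

## Platforms and down-sampling

A platform is a BED footprint (0-based half-open, merged, abutting
intervals coalesced), a fixed megabase denominator and a capability mask.
Variant retention uses the any-overlap rule on the reference span
(1-based [pos, pos+len(ref)−1]); the 1-based↔0-based conversion lives in
exactly one function (`vcf_span_to_bed`) and is property-tested. A
`chr1`-vs-`1` naming mismatch raises instead of silently retaining nothing.

Capability masks: WGS calls everything; WES calls no fusions; the
comprehensive panel calls everything; the hotspot panel calls neither CNAs
nor fusions. Loss-of-function SVs are gated by the CNA mask (they feed
deletion biomarkers, i.e. CNA-class events), viable fusions by the fusion
mask. CNA segments on CNA-capable platforms are additionally required to
overlap the footprint; SVs are gated by capability only, since assays
designed for fusion detection target breakpoints outside their nominal
capture.

TMB denominators are *parameters of the platform*, not recomputed from the
BED: 3000 Mb for whole genome (the conventional constant, not the true
mappable size) and the printed kit sizes 37.105146, 2.628876 and
0.016951 Mb for exome, comprehensive and hotspot panels. "TMB-high" uses
the strict `> threshold` rule (default 10 mutations/Mb), configurable.
Cross-platform concordance is Pearson correlation by default (Spearman as
an option); with fewer than three shared samples the correlation is
reported as NaN with a warning while threshold-discordance counts are still
returned. Coverage- and capture-efficiency differences between real
platforms are out of scope: down-sampling assumes equal per-base
sensitivity.

## MSI

Input is per-locus tumour/normal repeat-length read-count tables (length →
count), not alignments; realignment and length extraction are upstream. A
locus is unstable when a chi-square homogeneity test on the 2×K
length-distribution table rejects at level `alpha`, after merging adjacent
sparse bins until every expected cell count is ≥ 1 (merging neighbours in
length order preserves sensitivity to shifts). Loci with fewer than
`min_coverage` reads (default 20) in either sample are non-evaluable and
excluded from the denominator. The sample score is 100 × unstable /
evaluable, MSI-high strictly above `threshold_pct` (default 3.5%, the
conventional cut-off for this style of scoring, exposed in config).

The per-site `alpha` defaults to 0.01 rather than 0.05: on the order of a
hundred loci are tested per sample and the score is itself a fraction of
positive tests, so at alpha = 0.05 the expected false-positive site rate
alone would exceed the 3.5% classification threshold in a perfectly stable
sample. This fixed per-site level is a deliberate simplification of the
full FDR machinery used by read-level MSI callers; it is the piece of the
statistic worth testing here, and the simplification is visible in config.

## Synthetic world

The toy genome is 9 Mb over three chromosomes with 60 single-interval
30 kb genes. Twenty named cancer genes form the comprehensive panel
(0.6 Mb); a 2.5 kb window at the start of each forms the hotspot panel
(0.05 Mb); all 60 gene bodies form the exome (1.8 Mb); footprints are
nested by construction and their exact sizes are the toy TMB denominators.
The footprints are intentionally scaled up relative to real kits (a real
hotspot panel is ~5 × 10⁻⁶ of the genome; the toy one is ~0.5%) so that
per-sample panel mutation counts are informative at desk-scale cohort
sizes; conclusions about *relative* platform behaviour carry, absolute
counts do not.

Cohorts are simulated as:

* per-sample mutation rate = cohort rate × lognormal(σ = `rate_dispersion`,
  mean-preserving; default 0.5). The dispersion term exists because with a
  homogeneous rate the genome-vs-panel TMB correlation is √(panel
  fraction) *independent of the rate*; the empirically observed
  rate-dependent correlation degradation requires between-sample burden
  heterogeneity, which real cohorts have.
* passenger SNVs: Poisson(rate × 9 Mb), uniform, but **never inside genes
  carrying mutation-class KB rules**, so passengers are non-actionable by
  construction and ground-truth labels are exact. In-gene passengers are
  missense vs synonymous at a fixed 2.5 : 1 ratio (a toy-world parameter
  chosen so the non-synonymous TMB filter has a designed effect, not a
  biological estimate). A side effect worth knowing: panel footprints are
  enriched for actionable genes, so toy panel TMB is systematically *below*
  genome TMB — convenient, since capture-platform TMB depression is itself
  a real phenomenon, but quantitatively a toy artefact.
* hotspots / CNAs / fusions / LOF SVs: independent Bernoulli draws at the
  designed prevalences; hotspot positions sit inside the hotspot-panel
  windows so an exact hotspot is visible to every platform. Each sample
  also carries one diploid CN segment as a negative control.
* MSI: a sample is MSI-H with probability `msi_h_fraction`; at MSI-H
  samples each locus is unstable with probability `msi_unstable_fraction`
  (default 0.3). Normal and stable-tumour reads are multinomial over
  lengths {14, 15, 16} with probabilities (0.15, 0.70, 0.15) at 200×
  coverage; unstable loci shift the tumour mass to {12, 13, 14} with
  (0.30, 0.50, 0.20) — a strong, cleanly detectable shift. 120 loci are
  placed so that the exome and comprehensive panel retain subsets and the
  hotspot panel contains none (scoring on it correctly errors).

What passing tests show: the interval arithmetic, matching logic,
classification conventions, estimators and their platform dependence are
correct on data whose ground truth is known exactly. What they do not
show: performance under realistic mutational signatures, subclonality,
caller noise, FFPE artefacts, capture-efficiency variation or realistic
microsatellite length distributions — none of which the generator models.

## Problem sizes and numerical choices

Default verification sizes: oracle equivalence on 100 random instances
(genomes ≤ 10 kb; ≤ 100 alterations × ≤ 50 rules); prevalence recovery on a
400-sample cohort judged at ±3 binomial SDs; TMB concordance contrast
averaged over 20 replicate 40-sample cohorts per rate (1 vs 30
mutations/Mb); MSI accuracy over 50 + 50 samples. All randomness flows
from one top-level seed through derived sub-seeds; reruns are
byte-identical. Ties and boundaries are fixed as: CN thresholds as above,
strict `>` for TMB-high and MSI-H, matches ordered by (rule_id, alteration
position) for deterministic output.

## Known limitations

* Driver status is carried by the catalogue (`driver` column), never
  predicted from sequence.
* Drug names are opaque strings; combinations are a single string; no
  nomenclature normalization.
* Germline actionability, variant pathogenicity scoring, panel-specific
  TMB calibration and read-level MSI genotyping are out of scope.
* The `complete alteration` notion of hosted annotation services is
  interpreted here as "fully specified, driver-catalogued match".
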