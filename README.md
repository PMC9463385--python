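# actiondown

Somatic-variant actionability annotation with in-silico sequencing-platform
down-sampling, drug-repurposing classification, tumour mutation burden (TMB)
and microsatellite instability (MSI) estimation.

## The problem

Precision oncology asks, for each tumour, which somatic alterations are
*actionable* — catalogued biomarkers that predict sensitivity or resistance
to a drug — and whether the evidence is established in the patient's own
tumour type (an **on-label** option) or only in another tumour type (an
**off-label** repurposing candidate). The answer depends heavily on the
assay: a whole genome (WGS) sees every variant class; an exome (WES) misses
most gene fusions; a megabase-scale comprehensive panel (CPanel) and a
kilobase-scale hotspot panel (HGP) see progressively narrower footprints,
which also changes derived biomarkers such as TMB and MSI.

`actiondown` implements that comparison as a tested pipeline:

* a **biomarker knowledge base** in a flat tabular schema: one rule per
  (gene, alteration pattern, tumour type, drug, evidence tier,
  sensitivity/resistance) combination, with a six-tier evidence order
  (FDA guidelines > NCCN guidelines > late trials > early trials > case
  report > pre-clinical) collapsed into headline groups *approved*
  (FDA/NCCN) and *trials* (late/early);
* a **matcher** that converts calls into the matching vocabulary — total
  copy number ≥ 6 (no ploidy correction) is an amplification, < 1 a
  homozygous deletion; loss-of-function structural variants become gene
  deletions; intra-intron fusions are excluded — and fires rules through a
  four-form protein-change grammar (exact `V600E`, codon wildcard `V600.`,
  gene-level `any`, consequence class `LOF`), excluding synonymous variants
  and, by default, non-driver catalogue entries for the broad patterns;
* **platform down-sampling**: variants are kept when their reference span
  overlaps the platform BED footprint by ≥ 1 base (bedtools-intersect
  semantics), and capability masks remove whole event classes (the hotspot
  panel calls neither CNAs nor fusions; the exome calls no fusions);
* **TMB** = mutation count / fixed platform denominator (3000 Mb for WGS,
  37.105146 / 2.628876 / 0.016951 Mb for the capture platforms), with an
  optional non-synonymous filter, plus cross-platform Pearson concordance
  and strict `> 10` mutations/Mb threshold discordance;
* **MSI**: a per-locus chi-square homogeneity test between tumour and
  normal repeat-length read distributions; the sample score is the
  percentage of evaluable loci that are unstable, MSI-high above 3.5%;
* a **synthetic cohort generator** producing every input (toy genome,
  nested platform BEDs, toy knowledge base, per-sample VCF/CNA/SV calls and
  microsatellite site tables) with exact ground truth, so the whole chain
  is testable without controlled-access tumour data.

## Worked example

```python
import actiondown as ad
from actiondown.repurposing import classify_sample, summarize_cohort, cohort_pct

reference = ad.make_toy_reference(seed=0)
kb = ad.make_toy_kb(seed=0)

profile = ad.CohortProfile(
    cohort_name="demo", tumour_type="melanoma_cutaneous", n_samples=100,
    mutation_rate_per_mb=30.0, seed=42,
    hotspot_prevalences={("BRAF", "V600E"): 0.25, ("KIT", "L576P"): 0.10},
)
cohort = ad.simulate_cohort(profile, reference, kb)

calls = {
    sid: classify_sample(ad.sample_actionability(alts, kb), "melanoma_cutaneous", kb)
    for sid, alts in cohort.samples.items()
}
summary = summarize_cohort(calls, {sid: "demo" for sid in calls})
print("approved on-label:  %.1f%%" % cohort_pct(summary, "demo", "approved", "on"))
print("approved off-label: %.1f%%" % cohort_pct(summary, "demo", "approved", "off"))

platforms = reference.platforms()
sid = sorted(cohort.samples)[0]
for name in ("WGS", "WES", "CPANEL", "HGP"):
    r = ad.compute_tmb(cohort.samples[sid].variants, platforms[name])
    print(f"{sid} {name:6s} TMB = {r.mutation_count:4d} / {r.denominator_mb:.4f} Mb = {r.tmb:6.2f}")

msi = ad.msi_score(sid, cohort.msi_sites[sid], platforms["WGS"])
print(f"{sid} MSI: {msi.n_unstable_sites}/{msi.n_evaluable_sites} unstable -> "
      f"score {msi.msi_score:.1f}% ({msi.classification})")
```

prints

```
approved on-label:  22.0%
approved off-label: 10.0%
demo_s0000 WGS    TMB =  275 / 9.0000 Mb =  30.56
demo_s0000 WES    TMB =   39 / 1.8000 Mb =  21.67
demo_s0000 CPANEL TMB =    9 / 0.6000 Mb =  15.00
demo_s0000 HGP    TMB =    1 / 0.0500 Mb =  20.00
demo_s0000 MSI: 0/120 unstable -> score 0.0% (MSS)
```

The 22% of patients with an approved on-label option are the BRAF V600E
carriers (designed prevalence 0.25; binomial sampling at n = 100); the 10%
off-label are KIT L576P carriers without a BRAF hotspot — imatinib is
approved for KIT-mutant GIST, so in melanoma it is a repurposing candidate.
The per-platform TMB rows show the same tumour quantified against each
platform's own footprint and denominator; the sample is microsatellite
stable (0 of 120 evaluable loci unstable).

There is also a CLI (`actiondown simulate | downsample | match | tmb | msi |
summarize | run-all`); `actiondown run-all --out DIR --seed N` writes the
full report bundle (per-platform match tables, repurposing summary, TMB and
MSI tables, `report.json` with provenance) for a simulated multi-cohort
study.

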