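"""CNA classification, SV normalization and KB matching with a brute-force oracle."""

import numpy as np
import pytest

from actiondown.knowledge_base import AlterationClass
from actiondown.matcher import (
    AmplificationAlteration,
    CNAClass,
    DeletionAlteration,
    FusionAlteration,
    MatcherConfig,
    MutationAlteration,
    classify_cna,
    match_alteration,
    normalize_sample,
    sample_actionability,
    sv_to_alterations,
)
from actiondown.platforms import SampleAlterations
from actiondown.variants import (
    LOF_TERMS,
    NONSYNONYMOUS_TERMS,
    CopyNumberSegment,
    SomaticVariant,
    StructuralVariant,
    SVEffect,
)
from conftest import random_kb


def seg(cn, gene="ERBB2"):
    return CopyNumberSegment("s1", "1", 100, 200, gene, cn)


class TestClassifyCNA:
    @pytest.mark.parametrize(
        "cn,expected",
        [
            (6.0, CNAClass.AMPLIFICATION),   # boundary: >= 6 amplifies
            (7.5, CNAClass.AMPLIFICATION),
            (1.0, CNAClass.NEUTRAL),         # boundary: strict < 1 deletes
            (0.99, CNAClass.HOMOZYGOUS_DELETION),
            (0.0, CNAClass.HOMOZYGOUS_DELETION),
            (2.0, CNAClass.NEUTRAL),
        ],
    )
    def test_thresholds(self, cn, expected):
        assert classify_cna(seg(cn)) is expected

    def test_step_function_monotone_in_cn(self):
        order = {CNAClass.HOMOZYGOUS_DELETION: 0, CNAClass.NEUTRAL: 1, CNAClass.AMPLIFICATION: 2}
        values = [classify_cna(seg(cn)) for cn in np.linspace(0, 10, 60)]
        ranks = [order[v] for v in values]
        assert ranks == sorted(ranks)

    def test_negative_cn_errors(self):
        s = CopyNumberSegment.__new__(CopyNumberSegment)  # bypass ctor check
        object.__setattr__(s, "sample_id", "s1")
        object.__setattr__(s, "chrom", "1")
        object.__setattr__(s, "start", 1)
        object.__setattr__(s, "end", 2)
        object.__setattr__(s, "gene", "X")
        object.__setattr__(s, "copy_number", -1.0)
        with pytest.raises(ValueError):
            classify_cna(s)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            MatcherConfig(amp_cn_threshold=1.0, homdel_cn_threshold=2.0)


class TestSVNormalization:
    def test_lof_sv_becomes_deletion_per_gene(self):
        sv = StructuralVariant("s1", "1", 10, "1", 99, ("NF1", "TSC2"),
                               SVEffect.LOSS_OF_FUNCTION)
        alts = sv_to_alterations(sv)
        assert alts == [
            DeletionAlteration("s1", "NF1", source="sv"),
            DeletionAlteration("s1", "TSC2", source="sv"),
        ]

    def test_intra_intron_fusion_excluded(self):
        sv = StructuralVariant("s1", "1", 10, "1", 99, ("NTRK1",),
                               SVEffect.INTRA_INTRON_FUSION)
        assert sv_to_alterations(sv) == []

    def test_viable_fusion_normalized(self):
        sv = StructuralVariant("s1", "1", 10, "2", 99, ("TPM3", "NTRK1"),
                               SVEffect.VIABLE_FUSION, ("TPM3", "NTRK1"))
        assert sv_to_alterations(sv) == [FusionAlteration("s1", "TPM3", "NTRK1")]


def mut(gene, change, consequence="missense_variant"):
    return MutationAlteration("s1", gene, consequence, change, "1", 100)


class TestMatchExamples:
    def test_exact_hotspot_fires_one_rule_per_pattern(self, toy_kb):
        matches = match_alteration(mut("BRAF", "V600E"), toy_kb)
        assert {(m.rule_id, m.matched_pattern) for m in matches} == {
            ("R001", "exact"),
            ("R002", "codon"),  # V600. wildcard also covers V600E
        }

    def test_codon_wildcard_does_not_overreach(self, toy_kb):
        matches = match_alteration(mut("BRAF", "V600K"), toy_kb)
        assert {(m.rule_id, m.matched_pattern) for m in matches} == {("R002", "codon")}
        # V6000E is a different codon and must not fire V600.
        assert match_alteration(mut("BRAF", "V6000E"), toy_kb) == []

    def test_gene_level_resistance_rule(self, toy_kb):
        matches = match_alteration(mut("KRAS", "G12D"), toy_kb)
        assert {m.rule_id for m in matches} == {"R004"}
        assert matches[0].association.value == "resistance"

    def test_synonymous_never_matches(self, toy_kb):
        assert match_alteration(
            mut("KRAS", None, consequence="synonymous_variant"), toy_kb
        ) == []
        assert match_alteration(
            mut("BRAF", "V600E", consequence="synonymous_variant"), toy_kb
        ) == []

    def test_lof_pattern_requires_lof_consequence(self, toy_kb):
        fires = match_alteration(mut("BRCA1", "E100fs", "frameshift_variant"), toy_kb)
        assert {m.rule_id for m in fires} == {"R009"}
        missense = match_alteration(mut("BRCA1", "C61G", "missense_variant"), toy_kb)
        assert missense == []

    def test_driver_only_gates_broad_patterns(self, toy_kb):
        from dataclasses import replace

        undriver = [
            replace(r, driver_catalogued=False) if r.rule_id == "R004" else r
            for r in toy_kb.rules
        ]
        from actiondown.knowledge_base import BiomarkerKB

        kb2 = BiomarkerKB(rules=undriver, ontology=toy_kb.ontology)
        assert match_alteration(mut("KRAS", "G12D"), kb2, MatcherConfig()) == []
        relaxed = MatcherConfig(driver_only=False)
        assert {m.rule_id for m in match_alteration(mut("KRAS", "G12D"), kb2, relaxed)} == {"R004"}

    def test_fusion_partner_matching(self, toy_kb):
        any_partner = match_alteration(FusionAlteration("s1", "TPM3", "NTRK1"), toy_kb)
        assert {m.rule_id for m in any_partner} == {"R006"}
        exact_partner = match_alteration(FusionAlteration("s1", "FGFR2", "BICC1"), toy_kb)
        assert {m.rule_id for m in exact_partner} == {"R007"}
        wrong_partner = match_alteration(FusionAlteration("s1", "FGFR2", "TPM3"), toy_kb)
        assert wrong_partner == []

    def test_amp_and_del_rules(self, toy_kb):
        amp = match_alteration(AmplificationAlteration("s1", "ERBB2", 8.0), toy_kb)
        assert {m.rule_id for m in amp} == {"R003"}
        dele = match_alteration(DeletionAlteration("s1", "CDKN2A", "cna"), toy_kb)
        assert {m.rule_id for m in dele} == {"R014"}


# --- independent predicate oracle ------------------------------------------


def oracle_fires(rule, alt, cfg):
    """Plain restatement of the matching contract, kept separate from the
    implementation: evaluated rule-by-rule with no shared helpers."""
    if isinstance(alt, MutationAlteration):
        if rule.alteration_class is not AlterationClass.MUT or alt.gene != rule.gene:
            return False
        if alt.consequence not in NONSYNONYMOUS_TERMS:
            return False
        p = rule.variant_pattern
        if p == "any":
            return rule.driver_catalogued or not cfg.driver_only
        if p == "LOF":
            return alt.consequence in LOF_TERMS and (rule.driver_catalogued or not cfg.driver_only)
        if alt.protein_change is None:
            return False
        if p.endswith("."):
            tail = alt.protein_change[len(p) - 1:]
            return (
                alt.protein_change.startswith(p[:-1])
                and len(tail) > 0
                and not tail[0].isdigit()
                and all(ch.isalpha() or ch in "*=" for ch in tail)
            )
        return alt.protein_change == p
    if isinstance(alt, AmplificationAlteration):
        return rule.alteration_class is AlterationClass.AMP and rule.gene == alt.gene
    if isinstance(alt, DeletionAlteration):
        return rule.alteration_class is AlterationClass.DEL and rule.gene == alt.gene
    if isinstance(alt, FusionAlteration):
        if rule.alteration_class is not AlterationClass.FUS:
            return False
        if rule.gene == alt.gene5:
            return rule.fusion_partner in ("any", alt.gene3)
        if rule.gene == alt.gene3:
            return rule.fusion_partner in ("any", alt.gene5)
        return False
    return False


def random_alteration(rng):
    genes = ["BRAF", "KRAS", "ERBB2", "NTRK1", "TP53", "KIT", "EGFR", "NF1", "TPM3"]
    kind = rng.integers(0, 4)
    gene = str(rng.choice(genes))
    if kind == 0:
        consequence = str(
            rng.choice(
                ["missense_variant", "synonymous_variant", "frameshift_variant",
                 "stop_gained", "splice_donor_variant", "intron_variant"]
            )
        )
        change = str(rng.choice(["V600E", "V600K", "V6000E", "G12C", "Q61K", "E100fs"]))
        if rng.random() < 0.2:
            change = None
        return MutationAlteration("s1", gene, consequence, change, "1", int(rng.integers(1, 1000)))
    if kind == 1:
        return AmplificationAlteration("s1", gene, float(rng.uniform(6, 20)))
    if kind == 2:
        return DeletionAlteration("s1", gene, source=str(rng.choice(["cna", "sv"])))
    return FusionAlteration("s1", gene, str(rng.choice(genes)))


class TestMatcherOracle:
    def test_equivalence_with_double_loop(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            kb = random_kb(rng, n_rules=int(rng.integers(1, 50)))
            cfg = MatcherConfig(driver_only=bool(rng.random() < 0.5))
            for _ in range(int(rng.integers(1, 30))):
                alt = random_alteration(rng)
                got = {m.rule_id for m in match_alteration(alt, kb, cfg)}
                want = {r.rule_id for r in kb.rules if oracle_fires(r, alt, cfg)}
                assert got == want


class TestSampleActionability:
    def test_neutral_cnas_give_no_matches(self, toy_kb):
        alts = SampleAlterations(
            "s1", variants=[], svs=[],
            cnas=[CopyNumberSegment("s1", "1", 1, 10, "ERBB2", 2.0)],
        )
        assert sample_actionability(alts, toy_kb) == []

    def test_deterministic_order(self, toy_kb, toy_reference):
        braf = toy_reference.genes["BRAF"]
        kras = toy_reference.genes["KRAS"]
        v1 = SomaticVariant("s1", braf.chrom, braf.hotspot_pos0 + 1, "A", "T",
                            gene="BRAF", consequence="missense_variant", protein_change="V600E")
        v2 = SomaticVariant("s1", kras.chrom, kras.hotspot_pos0 + 1, "C", "G",
                            gene="KRAS", consequence="missense_variant", protein_change="G12D")
        a = SampleAlterations("s1", variants=[v1, v2])
        b = SampleAlterations("s1", variants=[v2, v1])
        assert sample_actionability(a, toy_kb) == sample_actionability(b, toy_kb)

    def test_platform_match_sets_nest(self, toy_kb, toy_reference):
        """Mutation matches under a narrower platform are a subset of WGS matches."""
        from actiondown.simulate import melanoma_like, simulate_cohort

        cohort = simulate_cohort(melanoma_like(10, seed=5), toy_reference, toy_kb)
        platforms = toy_reference.platforms()
        for alts in cohort.samples.values():
            per_platform = {
                name: {
                    (m.rule_id, m.alteration)
                    for m in sample_actionability(alts, toy_kb, platform=p)
                    if isinstance(m.alteration, MutationAlteration)
                }
                for name, p in platforms.items()
            }
            assert per_platform["HGP"] <= per_platform["CPANEL"]
            assert per_platform["CPANEL"] <= per_platform["WES"]
            assert per_platform["WES"] <= per_platform["WGS"]

    def test_normalize_skips_unannotated_variants(self, toy_kb):
        alts = SampleAlterations(
            "s1",
            variants=[SomaticVariant("s1", "1", 5, "A", "T", gene=None, consequence=None)],
        )
        assert normalize_sample(alts) == []
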