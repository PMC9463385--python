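"""Knowledge-base loading, evidence tiering and repurposing expansion."""

import numpy as np
import pytest

from actiondown.knowledge_base import (
    AlterationClass,
    Association,
    BiomarkerKB,
    BiomarkerRule,
    EvidenceTier,
    KBValidationError,
    TumourOntology,
    UnknownTumourError,
    load_kb,
    repurposing_expansion,
    shared_biomarker_matrix,
    tier_group,
    write_kb,
)
from conftest import random_kb

HEADER = (
    "rule_id\tgene\talteration_class\tvariant_pattern\tfusion_partner"
    "\ttumour_types\tdrug\tassociation\tevidence\tdriver\n"
)


def _write(tmp_path, body: str):
    path = tmp_path / "kb.tsv"
    path.write_text(HEADER + body)
    return path


class TestLoadKB:
    def test_valid_row_parses(self, tmp_path):
        path = _write(
            tmp_path,
            "R1\tBRAF\tMUT\tV600E\t.\tmelanoma_cutaneous\tdabrafenib\tsensitivity\tFDA guidelines\ttrue\n",
        )
        kb = load_kb(path)
        assert len(kb.rules) == 1
        rule = kb.rules[0]
        assert rule.gene == "BRAF"
        assert rule.variant_pattern == "V600E"
        assert rule.evidence is EvidenceTier.FDA_GUIDELINES
        assert rule.association is Association.SENSITIVITY
        assert rule.driver_catalogued

    def test_header_only_gives_empty_kb(self, tmp_path):
        kb = load_kb(_write(tmp_path, ""))
        assert kb.rules == []

    def test_unknown_evidence_label_rejected_listing_permitted(self, tmp_path):
        path = _write(
            tmp_path,
            "R1\tBRAF\tMUT\tV600E\t.\tmelanoma\tdab\tsensitivity\tPhase I\ttrue\n",
        )
        with pytest.raises(KBValidationError, match="Pre-clinical"):
            load_kb(path)

    def test_malformed_row_names_row_and_field(self, tmp_path):
        path = _write(
            tmp_path,
            "R1\tBRAF\tBOGUS\tV600E\t.\tmelanoma\tdab\tsensitivity\tFDA guidelines\ttrue\n",
        )
        with pytest.raises(KBValidationError, match="row 2.*alteration_class"):
            load_kb(path)

    def test_duplicate_rule_ids_rejected(self, tmp_path):
        row = "R1\tBRAF\tMUT\tV600E\t.\tmelanoma\tdab\tsensitivity\tFDA guidelines\ttrue\n"
        with pytest.raises(KBValidationError, match="duplicate"):
            load_kb(_write(tmp_path, row + row))

    def test_fusion_rule_requires_partner(self):
        with pytest.raises(KBValidationError):
            BiomarkerRule(
                rule_id="R1", gene="NTRK1", alteration_class=AlterationClass.FUS,
                variant_pattern=None, fusion_partner=None,
                tumour_types=frozenset({"any"}), drug="larotrectinib",
                association=Association.SENSITIVITY,
                evidence=EvidenceTier.FDA_GUIDELINES, driver_catalogued=True,
            )

    def test_round_trip(self, tmp_path, toy_kb):
        write_kb(toy_kb, tmp_path / "kb.tsv")
        reread = load_kb(tmp_path / "kb.tsv")
        assert {r.rule_id for r in reread.rules} == {r.rule_id for r in toy_kb.rules}
        by_id = {r.rule_id: r for r in reread.rules}
        for rule in toy_kb.rules:
            assert by_id[rule.rule_id] == rule


class TestTierGroup:
    @pytest.mark.parametrize(
        "tier,group",
        [
            (EvidenceTier.FDA_GUIDELINES, "approved"),
            (EvidenceTier.NCCN_GUIDELINES, "approved"),
            (EvidenceTier.LATE_TRIALS, "trials"),
            (EvidenceTier.EARLY_TRIALS, "trials"),
            (EvidenceTier.CASE_REPORT, "other"),
            (EvidenceTier.PRE_CLINICAL, "other"),
        ],
    )
    def test_mapping(self, tier, group):
        assert tier_group(tier) == group

    def test_total_over_all_tiers(self):
        # every tier maps to exactly one of the three groups
        for tier in EvidenceTier:
            assert tier_group(tier) in {"approved", "trials", "other"}

    def test_tier_order(self):
        assert (
            EvidenceTier.FDA_GUIDELINES > EvidenceTier.NCCN_GUIDELINES
            > EvidenceTier.LATE_TRIALS > EvidenceTier.EARLY_TRIALS
            > EvidenceTier.CASE_REPORT > EvidenceTier.PRE_CLINICAL
        )


def _single_rule_kb():
    rule = BiomarkerRule(
        rule_id="R1", gene="BRAF", alteration_class=AlterationClass.MUT,
        variant_pattern="V600E", fusion_partner=None,
        tumour_types=frozenset({"melanoma"}), drug="dabrafenib",
        association=Association.SENSITIVITY,
        evidence=EvidenceTier.FDA_GUIDELINES, driver_catalogued=True,
    )
    onto = TumourOntology(synonyms={"melanoma": "melanoma", "pdac": "pdac"})
    return BiomarkerKB(rules=[rule], ontology=onto)


class TestRepurposingExpansion:
    def test_on_label_for_matching_tumour(self):
        counts = repurposing_expansion(_single_rule_kb(), "melanoma", "approved")
        assert counts == {"on_label_biomarkers": 1, "off_label_biomarkers": 0}

    def test_off_label_for_other_tumour(self):
        counts = repurposing_expansion(_single_rule_kb(), "pdac", "approved")
        assert counts == {"on_label_biomarkers": 0, "off_label_biomarkers": 1}

    def test_unknown_tumour_errors(self):
        with pytest.raises(UnknownTumourError):
            repurposing_expansion(_single_rule_kb(), "marsupial", "approved")

    def test_matches_brute_force_enumeration(self):
        """On/off counts equal exhaustive enumeration over all rules."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            kb = random_kb(rng, n_rules=int(rng.integers(1, 40)))
            for tumour in kb.ontology.kb_labels():
                for group in ("approved", "trials"):
                    counts = repurposing_expansion(kb, tumour, group)
                    # brute force: classify each distinct biomarker directly
                    on, off = set(), set()
                    for rule in kb.rules:
                        if tier_group(rule.evidence) != group:
                            continue
                        covers = "any" in rule.tumour_types or tumour in rule.tumour_types
                        (on if covers else off).add(rule.biomarker)
                    assert counts["on_label_biomarkers"] == len(on)
                    assert counts["off_label_biomarkers"] == len(off - on)

    def test_monotone_under_rule_addition(self):
        rng = np.random.default_rng(5)
        kb = random_kb(rng, n_rules=15)
        from conftest import random_rule

        extra = random_rule(rng, "R999")
        bigger = BiomarkerKB(rules=kb.rules + [extra], ontology=kb.ontology)
        for tumour in kb.ontology.kb_labels():
            for group in ("approved", "trials"):
                before = repurposing_expansion(kb, tumour, group)
                after = repurposing_expansion(bigger, tumour, group)
                total_before = sum(before.values())
                total_after = sum(after.values())
                assert total_after >= total_before
                assert after["on_label_biomarkers"] >= before["on_label_biomarkers"]

    def test_on_plus_off_bounded_by_group_biomarkers(self):
        rng = np.random.default_rng(21)
        kb = random_kb(rng, n_rules=30)
        for group in ("approved", "trials"):
            total = len({r.biomarker for r in kb.rules_in_group(group)})
            for tumour in kb.ontology.kb_labels():
                counts = repurposing_expansion(kb, tumour, group)
                assert sum(counts.values()) <= total


class TestSharedBiomarkerMatrix:
    def test_tumour_agnostic_rule_covers_everything(self):
        rule = BiomarkerRule(
            rule_id="R1", gene="NTRK1", alteration_class=AlterationClass.FUS,
            variant_pattern=None, fusion_partner="any",
            tumour_types=frozenset({"any"}), drug="larotrectinib",
            association=Association.SENSITIVITY,
            evidence=EvidenceTier.FDA_GUIDELINES, driver_catalogued=True,
        )
        onto = TumourOntology(synonyms={t: t for t in ("a", "b", "c")})
        matrix = shared_biomarker_matrix(BiomarkerKB(rules=[rule], ontology=onto))
        assert (matrix.values == 1).all()

    def test_disjoint_rules_share_nothing(self):
        def rule(rid, gene, tumour):
            return BiomarkerRule(
                rule_id=rid, gene=gene, alteration_class=AlterationClass.MUT,
                variant_pattern="any", fusion_partner=None,
                tumour_types=frozenset({tumour}), drug="d",
                association=Association.SENSITIVITY,
                evidence=EvidenceTier.FDA_GUIDELINES, driver_catalogued=True,
            )

        onto = TumourOntology(synonyms={"a": "a", "b": "b"})
        kb = BiomarkerKB(rules=[rule("R1", "BRAF", "a"), rule("R2", "KRAS", "b")], ontology=onto)
        matrix = shared_biomarker_matrix(kb)
        assert matrix.loc["a", "b"] == 0
        assert matrix.loc["a", "a"] == 1
        assert matrix.loc["b", "b"] == 1

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            kb = random_kb(rng, n_rules=int(rng.integers(1, 50)))
            matrix = shared_biomarker_matrix(kb)
            per_type = {
                t: {
                    r.biomarker
                    for r in kb.rules
                    if "any" in r.tumour_types or t in r.tumour_types
                }
                for t in kb.tumour_types()
            }
            for a in per_type:
                for b in per_type:
                    assert matrix.loc[a, b] == len(per_type[a] & per_type[b])
            assert (matrix.values == matrix.values.T).all()
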