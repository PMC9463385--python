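import numpy as np
import pytest

from actiondown.knowledge_base import (
    AlterationClass,
    Association,
    BiomarkerKB,
    BiomarkerRule,
    EvidenceTier,
    TumourOntology,
)
from actiondown.simulate import make_toy_kb, make_toy_reference


@pytest.fixture(scope="session")
def toy_reference():
    return make_toy_reference(seed=0)


@pytest.fixture(scope="session")
def toy_kb():
    return make_toy_kb(seed=0)


# --- random-KB machinery for oracle tests ----------------------------------

GENES = ["BRAF", "KRAS", "ERBB2", "NTRK1", "TP53", "KIT", "EGFR", "NF1"]
TUMOURS = ["melanoma", "pdac", "breast", "ovarian"]
PATTERNS = ["V600E", "V600.", "G12C", "Q61.", "any", "LOF"]
PARTNERS = ["TPM3", "BICC1", "any"]


def random_rule(rng: np.random.Generator, rule_id: str) -> BiomarkerRule:
    cls = AlterationClass(rng.choice(["MUT", "AMP", "DEL", "FUS"]))
    tumours = (
        frozenset({"any"})
        if rng.random() < 0.2
        else frozenset(rng.choice(TUMOURS, size=rng.integers(1, 3), replace=False).tolist())
    )
    return BiomarkerRule(
        rule_id=rule_id,
        gene=str(rng.choice(GENES)),
        alteration_class=cls,
        variant_pattern=str(rng.choice(PATTERNS)) if cls is AlterationClass.MUT else None,
        fusion_partner=str(rng.choice(PARTNERS)) if cls is AlterationClass.FUS else None,
        tumour_types=tumours,
        drug=f"drug{rng.integers(0, 5)}",
        association=Association(rng.choice(["sensitivity", "resistance"])),
        evidence=EvidenceTier(int(rng.integers(1, 7))),
        driver_catalogued=bool(rng.random() < 0.7),
    )


def random_kb(rng: np.random.Generator, n_rules: int) -> BiomarkerKB:
    rules = [random_rule(rng, f"R{i:03d}") for i in range(n_rules)]
    ontology = TumourOntology(synonyms={t: t for t in TUMOURS})
    return BiomarkerKB(rules=rules, ontology=ontology)
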