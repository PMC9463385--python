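"""Four-way repurposing classification and cohort/platform summaries.

Each biomarker match is assigned one of four headline categories from its
evidence group and the tumour scope of the fired rule — approved on-label,
approved off-label, trials on-label, trials off-label — with case-report and
pre-clinical matches reported separately as "other".  Cohort summaries count
*patients*, not matches, and use the additive off-label convention: a
patient is counted off-label for an evidence group only if they have no
on-label option of the same group and association, so off-label percentages
read as the additional fraction of the cohort gaining a drug option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .knowledge_base import Association, BiomarkerKB, tier_group
from .matcher import MatcherConfig, MatchResult, sample_actionability
from .platforms import Platform, SampleAlterations

__all__ = [
    "RepurposingCall",
    "classify_match",
    "classify_sample",
    "summarize_cohort",
    "platform_comparison",
    "CATEGORIES",
]

CATEGORIES = (
    "approved_on_label",
    "approved_off_label",
    "trials_on_label",
    "trials_off_label",
    "other_evidence",
)


@dataclass(frozen=True)
class RepurposingCall:
    """A match plus its repurposing category for the sample's tumour type."""

    match: MatchResult
    tumour_type: str
    category: str  # one of CATEGORIES
    evidence_group: str  # approved | trials | other
    on_label: bool


def classify_match(m: MatchResult, tumour: str, kb: BiomarkerKB) -> RepurposingCall:
    """Assign the four-way category: evidence group × tumour-type membership.

    The category depends only on the fired rule's evidence tier and whether
    its tumour scope covers the sample's tumour type (directly, via the
    ontology parent, or tumour-agnostically).
    """
    rule = next(r for r in kb.rules if r.rule_id == m.rule_id)
    group = tier_group(m.evidence)
    on_label = kb.rule_matches_tumour(rule, tumour)
    if group == "other":
        category = "other_evidence"
    else:
        category = f"{group}_{'on' if on_label else 'off'}_label"
    return RepurposingCall(
        match=m, tumour_type=tumour, category=category,
        evidence_group=group, on_label=on_label,
    )


def classify_sample(
    matches: Sequence[MatchResult], tumour: str, kb: BiomarkerKB
) -> list[RepurposingCall]:
    rules = {r.rule_id: r for r in kb.rules}
    out = []
    for m in matches:
        rule = rules[m.rule_id]
        group = tier_group(m.evidence)
        on_label = kb.rule_matches_tumour(rule, tumour)
        category = "other_evidence" if group == "other" else f"{group}_{'on' if on_label else 'off'}_label"
        out.append(RepurposingCall(m, tumour, category, group, on_label))
    return out


def _patient_flags(calls: Sequence[RepurposingCall]) -> dict[tuple[str, str, str], bool]:
    """Per-(group, scope, association) indicator for one patient's calls."""
    flags: dict[tuple[str, str, str], bool] = {}
    for c in calls:
        scope = "on" if c.on_label else "off"
        flags[(c.evidence_group, scope, c.match.association.value)] = True
    return flags


def summarize_cohort(
    calls_by_sample: Mapping[str, Sequence[RepurposingCall]],
    cohorts: Mapping[str, str],
) -> pd.DataFrame:
    """Patient-level repurposing percentages per cohort.

    Parameters
    ----------
    calls_by_sample
        Every sample in the cohort, including samples with no calls (their
        presence sets the denominator).
    cohorts
        sample_id → cohort label; every sample must be assigned.

    Returns a tidy frame with columns ``cohort, evidence_group, label_scope,
    association, n_patients, pct, n_cohort``.  Off-label rows follow the
    additive convention: they count only patients with no on-label call of
    the same (group, association).
    """
    missing = set(calls_by_sample) - set(cohorts)
    if missing:
        raise ValueError(f"samples without a cohort assignment: {sorted(missing)[:5]}")
    by_cohort: dict[str, list[str]] = {}
    for sample in calls_by_sample:
        by_cohort.setdefault(cohorts[sample], []).append(sample)

    rows = []
    for cohort, samples in sorted(by_cohort.items()):
        n = len(samples)
        if n == 0:
            raise ValueError(f"cohort {cohort!r} is empty")
        flags = {s: _patient_flags(calls_by_sample[s]) for s in samples}
        for group in ("approved", "trials", "other"):
            for assoc in (Association.SENSITIVITY.value, Association.RESISTANCE.value):
                on = {s for s in samples if flags[s].get((group, "on", assoc))}
                off = {
                    s for s in samples if flags[s].get((group, "off", assoc))
                } - on  # additive convention
                for scope, patients in (("on", on), ("off", off)):
                    rows.append(
                        {
                            "cohort": cohort,
                            "evidence_group": group,
                            "label_scope": scope,
                            "association": assoc,
                            "n_patients": len(patients),
                            "pct": 100.0 * len(patients) / n,
                            "n_cohort": n,
                        }
                    )
    return pd.DataFrame(rows)


def cohort_pct(summary: pd.DataFrame, cohort: str, group: str, scope: str,
               association: str = "sensitivity") -> float:
    """Convenience lookup into a summarize_cohort frame."""
    mask = (
        (summary["cohort"] == cohort)
        & (summary["evidence_group"] == group)
        & (summary["label_scope"] == scope)
        & (summary["association"] == association)
    )
    return float(summary.loc[mask, "pct"].iloc[0])


def platform_comparison(
    samples: Mapping[str, SampleAlterations],
    tumours: Mapping[str, str],
    kb: BiomarkerKB,
    platforms: Mapping[str, Platform],
    cfg: MatcherConfig | None = None,
) -> pd.DataFrame:
    """Percentage of patients with >= 1 actionable call, per platform.

    For each platform the full chain is re-run (down-sample → match →
    classify).  Output columns: ``platform, evidence, association,
    n_patients, pct, n_samples`` where ``evidence`` is "approved" (approved
    only) or "approved_or_trials", and ``association`` is "any",
    "sensitivity" or "resistance".
    """
    cfg = cfg or MatcherConfig()
    n = len(samples)
    if n == 0:
        raise ValueError("no samples")
    rows = []
    for pname, platform in platforms.items():
        calls_by_sample = {}
        for sid, alts in samples.items():
            matches = sample_actionability(alts, kb, cfg, platform=platform)
            calls_by_sample[sid] = classify_sample(matches, tumours[sid], kb)
        for evidence, groups in (("approved", {"approved"}), ("approved_or_trials", {"approved", "trials"})):
            for assoc in ("any", "sensitivity", "resistance"):
                patients = {
                    sid
                    for sid, calls in calls_by_sample.items()
                    if any(
                        c.evidence_group in groups
                        and (assoc == "any" or c.match.association.value == assoc)
                        for c in calls
                    )
                }
                rows.append(
                    {
                        "platform": pname,
                        "evidence": evidence,
                        "association": assoc,
                        "n_patients": len(patients),
                        "pct": 100.0 * len(patients) / n,
                        "n_samples": n,
                    }
                )
    return pd.DataFrame(rows)
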