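"""End-to-end orchestration: simulate → down-sample → match → classify →
TMB → MSI → summarize, with a machine-readable report.

All randomness flows from the single top-level seed: each cohort gets a
derived sub-seed, so reruns with the same config produce byte-identical
outputs (no timestamps are embedded anywhere).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .knowledge_base import BiomarkerKB, write_kb
from .matcher import MatcherConfig, MatchResult, sample_actionability
from .msi import MSIParams, NoEvaluableSitesError, msi_score
from .platforms import SampleAlterations
from .repurposing import classify_sample, platform_comparison, summarize_cohort
from .simulate import (
    CohortProfile,
    ToyReference,
    make_toy_kb,
    make_toy_reference,
    melanoma_like,
    mesothelioma_like,
    pdac_like,
    simulate_cohort,
    write_cohort,
    write_reference_files,
)
from .tmb import cohort_tmb
from .variants import read_cna_segments, read_structural_variants, read_variants

__all__ = ["RunConfig", "run_pipeline", "profile_from_dict", "write_matches"]

_PRESETS = {
    "melanoma_like": melanoma_like,
    "pdac_like": pdac_like,
    "mesothelioma_like": mesothelioma_like,
}


def profile_from_dict(spec: dict, seed: int) -> CohortProfile:
    """Build a CohortProfile from a config mapping.

    Either ``preset: melanoma_like`` (with optional n_samples override) or
    explicit fields; prevalence keys use "GENE:change" / "GENE5:GENE3"
    strings in the on-disk form.
    """
    spec = dict(spec)
    preset = spec.pop("preset", None)
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        profile = _PRESETS[preset](seed=seed)
        if "n_samples" in spec:
            profile.n_samples = int(spec.pop("n_samples"))
        if "cohort_name" in spec:
            profile.cohort_name = str(spec.pop("cohort_name"))
        if spec:
            raise ValueError(f"unexpected keys with preset: {sorted(spec)}")
        return profile

    def split_pairs(mapping, n_parts=2):
        out = {}
        for key, value in (mapping or {}).items():
            parts = tuple(key.split(":"))
            if len(parts) != n_parts:
                raise ValueError(f"malformed key {key!r}")
            out[parts if n_parts > 1 else parts[0]] = value
        return out

    return CohortProfile(
        cohort_name=spec["cohort_name"],
        tumour_type=spec["tumour_type"],
        n_samples=int(spec["n_samples"]),
        mutation_rate_per_mb=float(spec["mutation_rate_per_mb"]),
        seed=seed,
        rate_dispersion=float(spec.get("rate_dispersion", 0.5)),
        hotspot_prevalences=split_pairs(spec.get("hotspot_prevalences")),
        resistance_prevalences=split_pairs(spec.get("resistance_prevalences")),
        cna_events={k: tuple(v) for k, v in (spec.get("cna_events") or {}).items()},
        fusion_events=split_pairs(spec.get("fusion_events")),
        lof_sv_events=dict(spec.get("lof_sv_events") or {}),
        msi_h_fraction=float(spec.get("msi_h_fraction", 0.0)),
        msi_unstable_fraction=float(spec.get("msi_unstable_fraction", 0.3)),
    )


@dataclass
class RunConfig:
    """Validated pipeline configuration; round-trips through YAML."""

    seed: int = 0
    cohorts: list[dict] = field(
        default_factory=lambda: [
            {"preset": "melanoma_like", "n_samples": 20},
            {"preset": "pdac_like", "n_samples": 20},
        ]
    )
    platforms: list[str] = field(default_factory=lambda: ["WGS", "WES", "CPANEL", "HGP"])
    matcher: dict = field(default_factory=dict)
    tmb_filter: str = "all"
    tmb_threshold: float = 10.0
    msi: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def matcher_config(self) -> MatcherConfig:
        return MatcherConfig(**self.matcher)

    def msi_params(self) -> MSIParams:
        return MSIParams(**self.msi)


def write_matches(matches: list[MatchResult], path: str | Path) -> None:
    """Match output TSV: sample rule_id gene alteration drug association evidence matched_pattern."""
    rows = []
    for m in matches:
        alt = m.alteration
        desc = "" if alt is None else type(alt).__name__.replace("Alteration", "")
        detail = getattr(alt, "protein_change", None) or getattr(alt, "gene3", None) or ""
        rows.append(
            {
                "sample": m.sample_id,
                "rule_id": m.rule_id,
                "gene": m.gene,
                "alteration": f"{desc}:{detail}".rstrip(":"),
                "drug": m.drug,
                "association": m.association.value,
                "evidence": m.evidence.label,
                "matched_pattern": m.matched_pattern,
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample", "rule_id", "gene", "alteration", "drug", "association",
                 "evidence", "matched_pattern"],
    ).to_csv(path, sep="\t", index=False)


def _read_sample_from_dir(sdir: Path, sample_id: str) -> SampleAlterations:
    return SampleAlterations(
        sample_id=sample_id,
        variants=read_variants(sdir / f"{sample_id}.vcf", sample_id=sample_id),
        cnas=read_cna_segments(sdir / f"{sample_id}.cna.tsv"),
        svs=read_structural_variants(sdir / f"{sample_id}.sv.tsv"),
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages and write the report bundle under ``out_dir``.

    Generated inputs are written to disk and read back through the standard
    readers, so the run exercises the full file interface.  Returns the
    report dict (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference: ToyReference = make_toy_reference(cfg.seed)
    kb: BiomarkerKB = make_toy_kb(cfg.seed)
    write_reference_files(reference, out / "reference")
    write_kb(kb, out / "reference" / "kb.tsv")

    matcher_cfg = cfg.matcher_config()
    msi_params = cfg.msi_params()
    toy_platforms = reference.platforms()
    unknown = set(cfg.platforms) - set(toy_platforms)
    if unknown:
        raise ValueError(f"unknown platforms in config: {sorted(unknown)}")
    platforms = {name: toy_platforms[name] for name in cfg.platforms}

    all_samples: dict[str, SampleAlterations] = {}
    tumours: dict[str, str] = {}
    cohort_of: dict[str, str] = {}
    msi_by_sample = {}

    for index, cohort_spec in enumerate(cfg.cohorts):
        profile = profile_from_dict(cohort_spec, seed=cfg.seed * 1009 + index)
        cohort = simulate_cohort(profile, reference, kb)
        cohort_dir = out / "cohorts" / profile.cohort_name
        write_cohort(cohort, cohort_dir)
        for sid in sorted(cohort.samples):
            all_samples[sid] = _read_sample_from_dir(cohort_dir / sid, sid)
            tumours[sid] = profile.tumour_type
            cohort_of[sid] = profile.cohort_name
        msi_by_sample.update(cohort.msi_sites)

    # matching + repurposing per platform
    summaries = []
    for pname, platform in platforms.items():
        calls_by_sample = {}
        matches_all: list[MatchResult] = []
        for sid, alts in all_samples.items():
            matches = sample_actionability(alts, kb, matcher_cfg, platform=platform)
            matches_all.extend(matches)
            calls_by_sample[sid] = classify_sample(matches, tumours[sid], kb)
        write_matches(matches_all, out / f"matches_{pname}.tsv")
        summary = summarize_cohort(calls_by_sample, cohort_of)
        summary.insert(0, "platform", pname)
        summaries.append(summary)
    summary_df = pd.concat(summaries, ignore_index=True)
    summary_df.to_csv(out / "repurposing_summary.tsv", sep="\t", index=False)

    comparison = platform_comparison(all_samples, tumours, kb, platforms, matcher_cfg)
    comparison.to_csv(out / "platform_comparison.tsv", sep="\t", index=False)

    # TMB
    tmb_rows = []
    for pname, platform in platforms.items():
        results = cohort_tmb(
            {sid: alts.variants for sid, alts in all_samples.items()},
            platform,
            filter=cfg.tmb_filter,
        )
        for sid in sorted(results):
            r = results[sid]
            tmb_rows.append(
                {
                    "sample": sid, "cohort": cohort_of[sid], "platform": pname,
                    "filter": r.filter, "count": r.mutation_count,
                    "denominator_mb": r.denominator_mb, "tmb": r.tmb,
                }
            )
    tmb_df = pd.DataFrame(tmb_rows)
    tmb_df.to_csv(out / "tmb.tsv", sep="\t", index=False)

    # MSI
    msi_rows = []
    for pname, platform in platforms.items():
        for sid in sorted(msi_by_sample):
            try:
                r = msi_score(sid, msi_by_sample[sid], platform, msi_params)
            except NoEvaluableSitesError:
                msi_rows.append(
                    {"sample": sid, "platform": pname, "evaluable": 0, "unstable": 0,
                     "score": float("nan"), "classification": "not_evaluable"}
                )
                continue
            msi_rows.append(
                {"sample": sid, "platform": pname, "evaluable": r.n_evaluable_sites,
                 "unstable": r.n_unstable_sites, "score": r.msi_score,
                 "classification": r.classification}
            )
    msi_df = pd.DataFrame(msi_rows)
    msi_df.to_csv(out / "msi.tsv", sep="\t", index=False)

    report = {
        "provenance": {
            "tool": "actiondown",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
        },
        "n_samples": len(all_samples),
        "cohorts": sorted(set(cohort_of.values())),
        "platforms": list(platforms),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
        "repurposing": summary_df.to_dict(orient="records"),
        "platform_comparison": comparison.to_dict(orient="records"),
        "msi_classifications": msi_df.groupby(["platform", "classification"])
        .size()
        .reset_index(name="n")
        .to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
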