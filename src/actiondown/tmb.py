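"""Tumour mutation burden per platform and cross-platform concordance.

TMB is the count of somatic SNVs and indels in the platform's footprint
divided by the platform's fixed megabase denominator: 3000 Mb for whole
genome (by convention, not the true genome size), and the printed kit sizes
for the capture platforms.  The non-synonymous filter restricts the count to
protein-altering calls before division.

Concordance between two platforms is the Pearson correlation of paired
per-sample TMB values (Spearman available as an option) plus counts of
samples that are "TMB-high" (strictly above the threshold, default 10
mutations/Mb) on one platform but not the other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .platforms import Platform, filter_variants
from .variants import SomaticVariant, is_nonsynonymous

__all__ = ["TMBResult", "ConcordanceResult", "compute_tmb", "tmb_concordance", "cohort_tmb"]


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    platform: str
    mutation_count: int
    denominator_mb: float
    tmb: float
    filter: str  # "all" | "nonsynonymous"


@dataclass(frozen=True)
class ConcordanceResult:
    platform_a: str
    platform_b: str
    correlation_r: float  # NaN when fewer than 3 shared samples
    n_samples: int
    threshold: float
    discordant_a_high: int  # TMB > threshold on A but <= threshold on B
    discordant_b_high: int


def compute_tmb(
    variants: Sequence[SomaticVariant],
    platform: Platform,
    filter: str = "all",
    sample_id: str | None = None,
    prefiltered: bool = False,
) -> TMBResult:
    """Count mutations on a platform and divide by its fixed denominator.

    By default the variants are region-filtered internally; pass
    ``prefiltered=True`` if they have already been down-sampled.  With
    ``filter="nonsynonymous"`` only protein-altering calls are counted
    (variants lacking a consequence annotation are excluded from the
    non-synonymous count rather than erroring, since the filter cannot
    assert their status).
    """
    if filter not in ("all", "nonsynonymous"):
        raise ValueError("filter must be 'all' or 'nonsynonymous'")
    if platform.footprint_mb <= 0:
        raise ZeroDivisionError("platform denominator must be positive")
    selected = list(variants)
    if not prefiltered and platform.regions is not None:
        selected = filter_variants(selected, platform.regions)
    if filter == "nonsynonymous":
        selected = [v for v in selected if v.consequence is not None and is_nonsynonymous(v)]
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else ""
    count = len(selected)
    return TMBResult(
        sample_id=sample_id,
        platform=platform.name.value,
        mutation_count=count,
        denominator_mb=platform.footprint_mb,
        tmb=count / platform.footprint_mb,
        filter=filter,
    )


def cohort_tmb(
    samples: Mapping[str, Sequence[SomaticVariant]],
    platform: Platform,
    filter: str = "all",
) -> dict[str, TMBResult]:
    """Per-sample TMB for a cohort on one platform."""
    return {
        sid: compute_tmb(variants, platform, filter=filter, sample_id=sid)
        for sid, variants in samples.items()
    }


def _as_tmb_map(table) -> tuple[str, dict[str, float]]:
    """Accept {sample: TMBResult} or {sample: float}; return (platform, values)."""
    platform = ""
    values: dict[str, float] = {}
    for sid, entry in table.items():
        if isinstance(entry, TMBResult):
            platform = entry.platform
            values[sid] = entry.tmb
        else:
            values[sid] = float(entry)
    return platform, values


def tmb_concordance(
    table_a,
    table_b,
    threshold: float = 10.0,
    method: str = "pearson",
) -> ConcordanceResult:
    """Correlation and threshold discordance between two platform TMB tables.

    Samples are paired by ID over the intersection of the two tables.  With
    fewer than 3 shared samples the correlation is reported as NaN with a
    warning (the discordant counts are still meaningful); an empty
    intersection raises.  "TMB-high" uses the strict ``> threshold`` rule on
    each side.
    """
    pa, va = _as_tmb_map(table_a)
    pb, vb = _as_tmb_map(table_b)
    shared = sorted(set(va) & set(vb))
    if not shared:
        raise ValueError("no shared samples between the two TMB tables")
    x = np.array([va[s] for s in shared])
    y = np.array([vb[s] for s in shared])

    if len(shared) < 3:
        warnings.warn("fewer than 3 shared samples; correlation reported as NaN")
        r = math.nan
    elif np.ptp(x) == 0 or np.ptp(y) == 0:
        r = math.nan  # correlation undefined for a constant vector
    elif method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    a_high = (x > threshold) & ~(y > threshold)
    b_high = (y > threshold) & ~(x > threshold)
    return ConcordanceResult(
        platform_a=pa or "A",
        platform_b=pb or "B",
        correlation_r=r,
        n_samples=len(shared),
        threshold=threshold,
        discordant_a_high=int(a_high.sum()),
        discordant_b_high=int(b_high.sum()),
    )
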