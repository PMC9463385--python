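"""Microsatellite instability scoring from tumour/normal repeat-length counts.

Each microsatellite locus carries two read-length distributions — matched
normal and tumour.  A locus is *unstable* when a chi-square homogeneity test
rejects equality of the two distributions; the sample-level MSI score is the
percentage of evaluable loci that are unstable, and a sample is MSI-high
when the score exceeds a threshold (default 3.5%).  For capture platforms
only loci overlapping the platform footprint are evaluated, so small panels
can legitimately have no evaluable loci at all.

This module starts from extracted per-site length-count tables rather than
alignments: read realignment and length extraction are upstream concerns,
and the per-site homogeneity test plus platform restriction are the part
worth testing.  Compared with full MSIsensor the FDR machinery is
deliberately simplified to a fixed per-site significance level (default
alpha = 0.01, chosen conservatively because on the order of a hundred loci
are tested per sample and the MSI score is itself a fraction of positive
tests).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .platforms import Platform

__all__ = [
    "MicrosatelliteSite",
    "MSIParams",
    "MSIResult",
    "SiteStatus",
    "site_chi_square",
    "site_unstable",
    "msi_score",
    "read_msi_sites",
    "write_msi_sites",
]


@dataclass(frozen=True)
class MicrosatelliteSite:
    """One locus: coordinates (0-based half-open), repeat unit, and the two
    repeat-length → read-count maps."""

    chrom: str
    start: int
    end: int
    repeat_unit: str
    normal_counts: dict[int, int]
    tumour_counts: dict[int, int]

    def __post_init__(self) -> None:
        for counts in (self.normal_counts, self.tumour_counts):
            if any(c < 0 for c in counts.values()):
                raise ValueError("read counts must be non-negative")

    @property
    def normal_total(self) -> int:
        return sum(self.normal_counts.values())

    @property
    def tumour_total(self) -> int:
        return sum(self.tumour_counts.values())


@dataclass(frozen=True)
class MSIParams:
    """alpha: per-site significance level; min_coverage: reads required in
    each of tumour and normal; threshold_pct: MSI-high cut-off on the score."""

    alpha: float = 0.01
    min_coverage: int = 20
    threshold_pct: float = 3.5


class SiteStatus(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class MSIResult:
    sample_id: str
    platform: str
    n_evaluable_sites: int
    n_unstable_sites: int
    msi_score: float  # percentage of evaluable sites unstable
    classification: str  # "MSI_H" | "MSS"
    threshold_pct: float


class NoEvaluableSitesError(ValueError):
    """No microsatellite locus passed the platform/coverage filters."""


def _pool_sparse_bins(n: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent length bins until every expected cell count is >= 1.

    Expected counts come from the pooled (row-margin × column-margin / total)
    table; bins are merged into their left neighbour (the first bin merges
    right).  Bin order follows ascending repeat length, so merging neighbours
    keeps the test sensitive to length shifts.
    """
    n = n.astype(float).copy()
    t = t.astype(float).copy()
    while len(n) > 1:
        total = n.sum() + t.sum()
        col = n + t
        expected_min = np.minimum(col * n.sum(), col * t.sum()) / total
        bad = np.nonzero(expected_min < 1.0)[0]
        if bad.size == 0:
            break
        i = bad[0]
        j = i - 1 if i > 0 else 1
        n[j] += n[i]
        t[j] += t[i]
        n = np.delete(n, i)
        t = np.delete(t, i)
    return n, t


def site_chi_square(site: MicrosatelliteSite) -> tuple[float, int]:
    """Chi-square homogeneity statistic (and df) between the tumour and
    normal length distributions, after pooling sparse bins."""
    lengths = sorted(set(site.normal_counts) | set(site.tumour_counts))
    n = np.array([site.normal_counts.get(length, 0) for length in lengths], dtype=float)
    t = np.array([site.tumour_counts.get(length, 0) for length in lengths], dtype=float)
    n, t = _pool_sparse_bins(n, t)
    if len(n) < 2:
        return 0.0, 0
    observed = np.vstack([n, t])
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = len(n) - 1
    return statistic, df


def evaluate_site(site: MicrosatelliteSite, params: MSIParams | None = None) -> SiteStatus:
    params = params or MSIParams()
    if site.normal_total < params.min_coverage or site.tumour_total < params.min_coverage:
        return SiteStatus.NOT_EVALUABLE
    statistic, df = site_chi_square(site)
    if df == 0:
        return SiteStatus.STABLE
    critical = stats.chi2.ppf(1.0 - params.alpha, df)
    return SiteStatus.UNSTABLE if statistic > critical else SiteStatus.STABLE


def site_unstable(
    site: MicrosatelliteSite, alpha: float = 0.01, min_coverage: int = 20
) -> bool:
    """True iff the site's chi-square statistic exceeds the critical value at alpha.

    Raises on insufficient coverage; callers building sample scores should
    use :func:`evaluate_site`, which marks such sites non-evaluable instead.
    """
    status = evaluate_site(site, MSIParams(alpha=alpha, min_coverage=min_coverage))
    if status is SiteStatus.NOT_EVALUABLE:
        raise ValueError(
            f"site {site.chrom}:{site.start}-{site.end} below minimum coverage "
            f"({min_coverage} reads in each of tumour and normal)"
        )
    return status is SiteStatus.UNSTABLE


def msi_score(
    sample_id: str,
    sites: list[MicrosatelliteSite],
    platform: Platform,
    params: MSIParams | None = None,
) -> MSIResult:
    """Score one sample on one platform.

    Sites are restricted to the platform footprint (any-overlap; whole-genome
    platforms keep every site), coverage-gated, tested, and the score is
    100 × unstable / evaluable.  MSI-high iff score > threshold_pct.
    """
    params = params or MSIParams()
    if platform.regions is not None:
        sites = [s for s in sites if platform.regions.overlaps(s.chrom, s.start, s.end)]
    statuses = [evaluate_site(s, params) for s in sites]
    evaluable = sum(st is not SiteStatus.NOT_EVALUABLE for st in statuses)
    if evaluable == 0:
        raise NoEvaluableSitesError(
            f"sample {sample_id}: no evaluable microsatellite sites on platform "
            f"{platform.name.value}"
        )
    unstable = sum(st is SiteStatus.UNSTABLE for st in statuses)
    score = 100.0 * unstable / evaluable
    return MSIResult(
        sample_id=sample_id,
        platform=platform.name.value,
        n_evaluable_sites=evaluable,
        n_unstable_sites=unstable,
        msi_score=score,
        classification="MSI_H" if score > params.threshold_pct else "MSS",
        threshold_pct=params.threshold_pct,
    )


# ---------------------------------------------------------------------------
# Site TSV dialect: chrom start end unit sample normal tumour
# where the count columns are semicolon-joined "length:count" pairs.

SITE_TSV_COLUMNS = ["chrom", "start", "end", "unit", "sample", "normal", "tumour"]


def _format_counts(counts: dict[int, int]) -> str:
    return ";".join(f"{length}:{count}" for length, count in sorted(counts.items()))


def _parse_counts(text: str) -> dict[int, int]:
    out: dict[int, int] = {}
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        length, count = token.split(":")
        out[int(length)] = int(count)
    return out


def read_msi_sites(path: str | Path) -> dict[str, list[MicrosatelliteSite]]:
    """Read a site TSV; returns sample_id → list of sites."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != SITE_TSV_COLUMNS:
        raise ValueError(
            f"site TSV header mismatch: expected {SITE_TSV_COLUMNS}, got {list(df.columns)}"
        )
    out: dict[str, list[MicrosatelliteSite]] = {}
    for _, row in df.iterrows():
        site = MicrosatelliteSite(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            repeat_unit=row["unit"],
            normal_counts=_parse_counts(row["normal"]),
            tumour_counts=_parse_counts(row["tumour"]),
        )
        out.setdefault(row["sample"], []).append(site)
    return out


def write_msi_sites(sites_by_sample: dict[str, list[MicrosatelliteSite]], path: str | Path) -> None:
    rows = []
    for sample in sorted(sites_by_sample):
        for s in sites_by_sample[sample]:
            rows.append(
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "unit": s.repeat_unit,
                    "sample": sample,
                    "normal": _format_counts(s.normal_counts),
                    "tumour": _format_counts(s.tumour_counts),
                }
            )
    pd.DataFrame(rows, columns=SITE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
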