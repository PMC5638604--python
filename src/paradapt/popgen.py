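"""Pooled nucleotide diversity, per-SNP and windowed F_ST.

All estimators work directly on read counts from two population pools.
Site heterozygosity uses the small-sample corrected form
``(c/(c-1)) * (1 - sum((c_a/c)^2))`` with coverage ``c`` the number of base
calls.  Per-SNP F_ST is the classical pooled estimator
``(pi_total - pi_within) / pi_total`` where pi_within averages the two
pools' site heterozygosities and pi_total is the heterozygosity of the
summed counts; negative values are retained, not clamped.  Pool sizes
(numbers of sampled chromosomes) enter nowhere — a documented limitation
of read-count-based estimation.

Windows are non-overlapping, fixed-size (default 1 kb); trailing partial
windows at scaffold ends are discarded, and a window enters the analysis
only when at least half its sites meet the per-pool coverage minimum in
both pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_core import AnalysisConfig, SiteCounts

__all__ = [
    "SnpRecord",
    "WindowStat",
    "FilterResult",
    "filter_site",
    "site_heterozygosity",
    "snp_fst",
    "window_pi",
    "window_fst",
    "window_stats",
    "window_tails",
]


@dataclass
class SnpRecord:
    """A filtered biallelic SNP with per-pool counts and statistics."""

    scaffold: str
    pos: int
    major: str
    minor: str
    # per-pool counts of (major, minor)
    counts: tuple[tuple[int, int], ...]
    fst: float | None = None
    midp_p: float | None = None
    q_value: float | None = None
    outlier: bool = False
    ancestral: str | None = None
    derived: str | None = None
    effect: str | None = None
    gene_id: str | None = None
    arm: str | None = None

    def frequencies(self) -> tuple[tuple[float, float], ...]:
        """(major, minor) frequency per pool."""
        out = []
        for maj, mino in self.counts:
            c = maj + mino
            out.append((maj / c, mino / c) if c else (math.nan, math.nan))
        return tuple(out)


@dataclass
class WindowStat:
    """Summary of one fixed-size genomic window."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    n_sites_covered: int
    covered_fraction: float
    pi: tuple[float, ...] | None  # per pool; None when window is undefined
    fst: float | None
    n_snps: int = 0
    tail_flags: dict[float, bool] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.pi is not None


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the site filter: a SNP, a covered monomorphic site, or a
    rejection with a reason code in {coverage, min_alt, triallelic}."""

    status: str  # 'snp' | 'monomorphic_covered' | 'rejected'
    reason: str | None = None
    snp: SnpRecord | None = None


def site_heterozygosity(counts: Sequence[int]) -> float:
    """Expected heterozygosity of one pool from its allele read counts.

    Returns ``(c/(c-1)) * (1 - sum((c_a/c)^2))``; the ``c/(c-1)`` factor
    removes the bias of the plug-in sum of squared frequencies at finite
    read depth.  Requires coverage >= 2.
    """
    c = sum(counts)
    if c < 2:
        raise ValueError(f"coverage {c} < 2; heterozygosity undefined")
    sumsq = sum((x / c) ** 2 for x in counts)
    return (c / (c - 1)) * (1.0 - sumsq)


def snp_fst(counts1: Sequence[int], counts2: Sequence[int]) -> float | None:
    """Per-SNP F_ST between two pools from matched allele count vectors.

    ``(pi_total - pi_within) / pi_total`` with pi_within the unweighted mean
    of the two pools' heterozygosities and pi_total the heterozygosity of
    the pooled counts.  Returns None when the combined site is monomorphic
    (pi_total = 0), i.e. the quantity is undefined.
    """
    if len(counts1) != len(counts2):
        raise ValueError("allele count vectors must align")
    pooled = [a + b for a, b in zip(counts1, counts2)]
    pi_total = site_heterozygosity(pooled)
    if pi_total == 0.0:
        return None
    pi_within = 0.5 * (site_heterozygosity(counts1) + site_heterozygosity(counts2))
    return (pi_total - pi_within) / pi_total


def filter_site(site: SiteCounts, cfg: AnalysisConfig) -> FilterResult:
    """Apply the site filters of the differentiation scan.

    Rejects sites with any pool below the coverage minimum; covered
    monomorphic sites pass through (they contribute zero to pi); biallelic
    sites become SNPs when the dataset-wide minor-allele count reaches the
    minimum alternate-observation threshold; sites with three or more
    observed alleles are excluded.
    """
    for j in range(len(site.pools)):
        if site.coverage(j) < cfg.min_site_coverage:
            return FilterResult("rejected", reason="coverage")
    combined = site.combined_base_counts()
    observed = [b for b in combined if combined[b] > 0]
    if len(observed) <= 1:
        return FilterResult("monomorphic_covered")
    if len(observed) > 2:
        return FilterResult("rejected", reason="triallelic")
    a1, a2 = sorted(observed, key=lambda b: (-combined[b], b))
    if combined[a2] < cfg.min_alt_observations_popgen:
        return FilterResult("rejected", reason="min_alt")
    counts = tuple(
        (site.base_counts(j)[a1], site.base_counts(j)[a2])
        for j in range(len(site.pools))
    )
    snp = SnpRecord(site.scaffold, site.pos, a1, a2, counts)
    if len(site.pools) == 2:
        snp.fst = snp_fst(counts[0], counts[1])
    return FilterResult("snp", snp=snp)


def _is_covered(r: FilterResult) -> bool:
    # a site counts as covered when it passes the coverage filter, even if a
    # later filter (min_alt, triallelic) excludes it from the SNP set
    return r.status != "rejected" or r.reason != "coverage"


def window_pi(
    results: Sequence[FilterResult], window_size: int, cfg: AnalysisConfig
) -> tuple[float, ...] | None:
    """Per-pool nucleotide diversity of one window.

    The denominator is the number of covered sites (not the window length),
    so missing data is not conflated with invariance.  Undefined (None)
    when fewer than ``min_window_covered_fraction`` of the window's sites
    are covered.
    """
    covered = [r for r in results if _is_covered(r)]
    n_cov = len(covered)
    if n_cov / window_size < cfg.min_window_covered_fraction:
        return None
    n_pools = None
    sums: list[float] = []
    for r in covered:
        if r.status != "snp":
            continue
        snp = r.snp
        if n_pools is None:
            n_pools = len(snp.counts)
            sums = [0.0] * n_pools
        for j, pair in enumerate(snp.counts):
            sums[j] += site_heterozygosity(pair)
    if n_pools is None:  # no SNPs at all
        return (0.0, 0.0)
    return tuple(s / n_cov for s in sums)


def window_fst(snps: Sequence[SnpRecord]) -> float:
    """Unweighted mean per-SNP F_ST of a window; 0 for SNP-free windows."""
    vals = [s.fst for s in snps if s.fst is not None]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def window_stats(
    sites: Iterable[SiteCounts],
    scaffold_lengths: dict[str, int],
    cfg: AnalysisConfig,
) -> Iterator[tuple[WindowStat, list[SnpRecord]]]:
    """Tile each scaffold with non-overlapping windows and summarise them.

    ``sites`` must be position-sorted within scaffolds (the sync contract).
    Trailing windows shorter than ``window_size`` are dropped.  Yields each
    window (defined or not) with the SNPs it contains.
    """
    w = cfg.window_size
    buffers: dict[tuple[str, int], list[FilterResult]] = {}
    order: list[tuple[str, int]] = []
    for site in sites:
        widx = (site.pos - 1) // w
        key = (site.scaffold, widx)
        if key not in buffers:
            buffers[key] = []
            order.append(key)
        buffers[key].append(filter_site(site, cfg))
    for scaffold, widx in order:
        length = scaffold_lengths[scaffold]
        start, end = widx * w + 1, (widx + 1) * w
        if end > length:  # trailing partial window
            continue
        results = buffers[(scaffold, widx)]
        covered = sum(1 for r in results if _is_covered(r))
        snps = [r.snp for r in results if r.status == "snp"]
        pi = window_pi(results, w, cfg)
        stat = WindowStat(
            scaffold=scaffold,
            start=start,
            end=end,
            n_sites_covered=covered,
            covered_fraction=covered / w,
            pi=pi,
            fst=window_fst(snps) if pi is not None else None,
            n_snps=len(snps),
        )
        yield stat, snps


def window_tails(
    windows: Sequence[WindowStat], fractions: Sequence[float] | None = None
) -> dict[float, dict]:
    """Empirical upper-tail thresholds of the window F_ST distribution.

    For each fraction f the threshold is the F_ST of the ceil(f*n)-th
    largest defined window; all windows at or above the threshold are
    flagged (ties kept, a deterministic, conservative superset).  Also
    reports the mean F_ST of each flagged set.  Mutates ``tail_flags`` on
    the input windows.
    """
    defined = [wd for wd in windows if wd.defined]
    if not defined:
        raise ValueError("no defined windows; cannot compute tails")
    if fractions is None:
        fractions = (0.01, 0.025, 0.05)
    values = np.sort(np.array([wd.fst for wd in defined]))
    n = len(values)
    out: dict[float, dict] = {}
    for f in fractions:
        k = max(1, math.ceil(f * n))
        threshold = float(values[n - k])
        flagged = [wd for wd in defined if wd.fst >= threshold]
        for wd in windows:
            wd.tail_flags[f] = wd.defined and wd.fst >= threshold
        out[f] = {
            "threshold": threshold,
            "n_flagged": len(flagged),
            "mean_fst": float(np.mean([wd.fst for wd in flagged])),
        }
    return out
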