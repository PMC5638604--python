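"""Per-SNP exact tests of allele-frequency independence and per-arm FDR.

The test is a mid-p variant of Fisher's exact test on the 2x2 table of
allele read counts by population: the one-sided mid-p counts only half the
probability of the observed table, and the two-sided value doubles the
smaller one-sided value (the central method).  Mid-p is less conservative
than the standard Fisher p and, because pooled read counts pseudo-replicate
chromosomes, the whole scheme is anti-conservative with respect to true
allele sampling — outlier calls are empirical ranks, not calibrated error
rates.

q-values follow Storey: pi0 is estimated from the p-value histogram on a
lambda grid with a cubic smoother, and the FDR step-up runs separately for
every chromosome arm (Muller element).  Small arms fall back to
Benjamini-Hochberg (pi0 = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import interpolate
from scipy.stats import hypergeom

from .io_core import AnalysisConfig
from .popgen import SnpRecord

__all__ = [
    "MidpResult",
    "ArmFdr",
    "midp_test",
    "storey_qvalues",
    "bh_qvalues",
    "qvalues_per_arm",
    "flag_outliers",
    "polarize_ancestral",
]

#: minimum number of tests on an arm before the pi0 smoother is trusted
MIN_TESTS_FOR_PI0 = 100
_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass(frozen=True)
class MidpResult:
    """Mid-p exact test of one 2x2 table (rows: alleles, cols: pools)."""

    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    midp: float
    degenerate: bool = False


def midp_test(a: int, b: int, c: int, d: int) -> MidpResult:
    """Two-sided mid-p test for independence of a 2x2 count table.

    With margins fixed, the top-left cell X is hypergeometric; the upper
    one-sided mid-p is P(X > a) + 0.5*P(X = a), the lower analogous, and
    the two-sided value is min(1, 2*min(upper, lower)).  A zero row or
    column margin makes the table degenerate: p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    if 0 in (row1, row2, col1, col2):
        return MidpResult((a, b, c, d), odds, 1.0, degenerate=True)
    dist = hypergeom(n, row1, col1)
    pmf_a = dist.pmf(a)
    upper = dist.sf(a) + 0.5 * pmf_a
    lower = dist.cdf(a) - 0.5 * pmf_a
    p = min(1.0, 2.0 * min(upper, lower))
    return MidpResult((a, b, c, d), odds, max(p, np.nextafter(0, 1)))


@dataclass
class ArmFdr:
    """q-values for one chromosome arm."""

    arm: str
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float
    method: str  # 'storey' or 'bh'


def _step_up(p: np.ndarray, pi0: float) -> np.ndarray:
    """q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Textbook Benjamini-Hochberg adjusted p-values (pi0 = 1)."""
    return _step_up(np.asarray(p, dtype=float), 1.0)


def estimate_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
    0.05, 0.10, ..., 0.95; a cubic smoothing spline through these points is
    evaluated at the largest lambda and clipped to (0, 1].  Returns a value
    <= 0 unmodified so callers can fall back to BH.
    """
    m = len(p)
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in _LAMBDA_GRID]
    )
    spline = interpolate.UnivariateSpline(_LAMBDA_GRID, pi0_lambda, k=3)
    pi0 = float(spline(_LAMBDA_GRID[-1]))
    return min(pi0, 1.0)


def storey_qvalues(p: Sequence[float], min_tests: int = MIN_TESTS_FOR_PI0):
    """Storey q-values with BH fallback.

    Falls back to pi0 = 1 (plain BH) when fewer than ``min_tests`` p-values
    are supplied or the smoother yields a non-positive pi0.
    Returns (q, pi0, method).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0, "bh"
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < min_tests:
        return _step_up(p, 1.0), 1.0, "bh"
    pi0 = estimate_pi0(p)
    if pi0 <= 0:
        return _step_up(p, 1.0), 1.0, "bh"
    return _step_up(p, pi0), pi0, "storey"


def qvalues_per_arm(p_by_arm: Mapping[str, Sequence[float]]) -> dict[str, ArmFdr]:
    """Storey/BH q-values computed independently for each chromosome arm."""
    out = {}
    for arm, p in p_by_arm.items():
        q, pi0, method = storey_qvalues(p)
        out[arm] = ArmFdr(arm, np.asarray(p, dtype=float), q, pi0, method)
    return out


def flag_outliers(snps: Iterable[SnpRecord], cfg: AnalysisConfig) -> list[SnpRecord]:
    """Flag SNPs with q <= outlier_fdr and F_ST strictly > outlier_fst."""
    flagged = []
    for snp in snps:
        snp.outlier = (
            snp.q_value is not None
            and snp.fst is not None
            and snp.q_value <= cfg.outlier_fdr
            and snp.fst > cfg.outlier_fst
        )
        if snp.outlier:
            flagged.append(snp)
    return flagged


def polarize_ancestral(snp: SnpRecord, outgroup_base: str | None) -> bool:
    """Polarize one SNP against an outgroup base.

    If exactly one of the two alleles matches the outgroup base, that
    allele is ancestral and the other derived; the record is updated and
    True returned.  Otherwise (mismatch to both, N, gap, or missing) the
    SNP is excluded from polarized analyses and False returned.
    """
    if outgroup_base is None:
        return False
    base = outgroup_base.upper()
    if base not in "ACGT":
        return False
    alleles = {snp.major, snp.minor}
    if base not in alleles:
        return False
    snp.ancestral = base
    snp.derived = (alleles - {base}).pop()
    return True
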