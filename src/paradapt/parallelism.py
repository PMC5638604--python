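"""Cross-species sharing statistics for outlier gene sets.

Two routes to the same question ("do two species share more outlier genes
than chance?"):

* `overlap_test` — the closed-form hypergeometric upper tail, assuming all
  genes are equally likely to be outliers; and
* `matched_bootstrap` — an empirical null that redraws each species'
  outlier list from genes with at least as many nonsynonymous SNPs,
  neutralising the confounder that longer / SNP-denser genes harbour more
  outliers in both species by chance alone.

Plus the direction chi-square (are derived-allele frequency shifts biased
toward one latitude?) and Fisher's method for combining independent
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, hypergeom

__all__ = [
    "OverlapResult",
    "BootstrapResult",
    "DirectionResult",
    "overlap_test",
    "matched_bootstrap",
    "direction_chi2",
    "fishers_combined",
]


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric sharing test of two gene sets in a common universe."""

    N: int  # universe size
    K: int  # set-A size
    n: int  # set-B size
    k: int  # observed overlap
    expected: float
    fold: float
    p: float


def overlap_test(N: int, K: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric test P(X >= k) of gene-set overlap.

    ``expected = K*n/N`` and ``fold = k/expected``.  Raises on an overlap
    outside the feasible range [max(0, K+n-N), min(K, n)].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("set sizes must lie within the universe")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} infeasible for N={N}, K={K}, n={n}")
    expected = K * n / N
    p = float(hypergeom(N, K, n).sf(k - 1))
    fold = k / expected if expected > 0 else np.nan
    return OverlapResult(N, K, n, k, expected, fold, min(max(p, 0.0), 1.0))


@dataclass
class BootstrapResult:
    """SNP-count-matched bootstrap null for shared outlier genes."""

    k_obs: int
    replicates: np.ndarray
    expected: float
    fold: float
    p: float
    seed: int


def _draw_matched(
    counts: np.ndarray, outlier_counts: np.ndarray, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """For each replicate draw, per outlier gene with count m, one distinct
    universe gene with count >= m (uniformly, without replacement within the
    replicate).  Returns a boolean matrix (reps x n_genes).

    Genes are pre-sorted by descending count so eligibility sets are nested
    suffixes; sampling is vectorised across replicates with rejection on
    within-replicate collisions.
    """
    order = np.argsort(-counts, kind="stable")
    sorted_counts = counts[order]
    n_genes = len(counts)
    chosen = np.zeros((reps, n_genes), dtype=bool)
    for j, m in enumerate(-np.sort(-outlier_counts)):  # descending
        n_eligible = int(np.searchsorted(-sorted_counts, -m, side="right"))
        if n_eligible <= j:
            raise ValueError(
                f"fewer than {j + 1} universe genes have nsSNP count >= {m}; "
                "matching infeasible"
            )
        pending = np.arange(reps)
        while pending.size:
            cand = rng.integers(0, n_eligible, size=pending.size)
            free = ~chosen[pending, cand]
            ok = pending[free]
            chosen[ok, cand[free]] = True
            pending = pending[~free]
    # map back to original gene order
    out = np.zeros_like(chosen)
    out[:, order] = chosen
    return out


def matched_bootstrap(
    outliers_a: set[str],
    outliers_b: set[str],
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    universe: Sequence[str],
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Empirical sharing null matched on per-gene nsSNP counts.

    ``universe`` lists one-to-one orthologous genes (one shared id per
    pair); ``counts_*`` give each gene's total nsSNP count in each species.
    Per replicate, each species' outlier list is replaced by random genes
    with at least as many nsSNPs, and the replicate overlap recorded.  The
    empirical p is (1 + #{replicate >= observed}) / (reps + 1).
    """
    genes = list(universe)
    index = {g: i for i, g in enumerate(genes)}
    if not (outliers_a <= set(genes) and outliers_b <= set(genes)):
        raise ValueError("outlier sets must be subsets of the universe")
    k_obs = len(outliers_a & outliers_b)
    rng = np.random.default_rng(seed)
    arr_a = np.array([counts_a[g] for g in genes])
    arr_b = np.array([counts_b[g] for g in genes])
    out_a = np.array([counts_a[g] for g in sorted(outliers_a)])
    out_b = np.array([counts_b[g] for g in sorted(outliers_b)])
    draws_a = _draw_matched(arr_a, out_a, reps, rng)
    draws_b = _draw_matched(arr_b, out_b, reps, rng)
    replicates = np.sum(draws_a & draws_b, axis=1)
    expected = float(np.mean(replicates))
    p = (1 + int(np.sum(replicates >= k_obs))) / (reps + 1)
    fold = k_obs / expected if expected > 0 else np.nan
    return BootstrapResult(k_obs, replicates, expected, fold, p, seed)


@dataclass(frozen=True)
class DirectionResult:
    """Chi-square test of directional bias against a 50:50 split."""

    n_up: int
    n_down: int
    chi2: float
    p: float


def direction_chi2(n_up: int, n_down: int) -> DirectionResult:
    """Test whether derived-allele frequency shifts favour one population.

    Pearson chi-square of the (n_up, n_down) split against equal
    proportions, 1 df, no continuity correction.
    """
    total = n_up + n_down
    if total <= 0:
        raise ValueError("need at least one SNP to test directionality")
    e = total / 2.0
    stat = (n_up - e) ** 2 / e + (n_down - e) ** 2 / e
    return DirectionResult(n_up, n_down, float(stat), float(chi2(1).sf(stat)))


def fishers_combined(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: chi-square tail of -2*sum(ln p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.sum(np.log(p))
    return float(chi2(2 * p.size).sf(stat))
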