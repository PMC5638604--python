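"""Latitudinal expression-parallelism analyses on FPKM tables.

With no biological replicates for one species, differential expression is
purely rank-based: genes are ordered by the absolute log2 fold change
between the two populations (with a 0.1 pseudo-count on FPKM) and the
top-N lists of the two species are compared with the hypergeometric
overlap test.  Direction sharing is probed by splitting orthologs into
same-direction and opposite-direction groups and comparing the Pearson
correlation of fold-change magnitudes between the groups, with a Fisher
z test and a size-matched permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, pearsonr

from .parallelism import OverlapResult, overlap_test

__all__ = [
    "FPKM_EPSILON",
    "log2_fold_change",
    "expressed_orthologs",
    "topn_overlap",
    "direction_split_correlation",
    "fisher_z_compare",
    "permutation_compare",
]

#: pseudo-count added to FPKM before taking the log2 population ratio
FPKM_EPSILON = 0.1


def log2_fold_change(fpkm_pop1: float, fpkm_pop2: float) -> float:
    """log2((FPKM1 + eps) / (FPKM2 + eps)) with eps = 0.1."""
    return math.log2((fpkm_pop1 + FPKM_EPSILON) / (fpkm_pop2 + FPKM_EPSILON))


def expressed_orthologs(
    fpkm_a: Mapping[str, tuple[float, float]],
    fpkm_b: Mapping[str, tuple[float, float]],
    orthologs: Sequence[str] | None = None,
) -> list[str]:
    """Orthologs expressed (FPKM > 1 in some population sample) in BOTH
    species.  ``orthologs`` defaults to the ids shared by the two tables."""
    if orthologs is None:
        orthologs = sorted(set(fpkm_a) & set(fpkm_b))
    return [
        g
        for g in orthologs
        if max(fpkm_a[g]) > 1.0 and max(fpkm_b[g]) > 1.0
    ]


def _ranked(fpkm: Mapping[str, tuple[float, float]], genes: Sequence[str]) -> list[str]:
    # rank 1 = largest |log2 fold change|; ties broken by ortholog id
    return sorted(
        genes, key=lambda g: (-abs(log2_fold_change(*fpkm[g])), g)
    )


def topn_overlap(
    fpkm_a: Mapping[str, tuple[float, float]],
    fpkm_b: Mapping[str, tuple[float, float]],
    universe: Sequence[str],
    top_n: int = 300,
) -> OverlapResult:
    """Overlap of the two species' top-N most differentially expressed
    orthologs, tested against the hypergeometric null over ``universe``."""
    if top_n > len(universe):
        raise ValueError(f"top_n={top_n} exceeds universe of {len(universe)}")
    top_a = set(_ranked(fpkm_a, universe)[:top_n])
    top_b = set(_ranked(fpkm_b, universe)[:top_n])
    return overlap_test(len(universe), top_n, top_n, len(top_a & top_b))


@dataclass(frozen=True)
class DirectionSplit:
    """Correlation of fold-change magnitudes by direction concordance."""

    r_same: float | None
    r_opp: float | None
    n_same: int
    n_opp: int


def direction_split_correlation(
    lfc_pairs: Sequence[tuple[float, float]]
) -> DirectionSplit:
    """Split orthologs by fold-change sign agreement and correlate
    magnitudes within each group.

    Pairs with a zero fold change in either species are excluded from both
    groups.  Pearson r is computed on (|lfc_a|, |lfc_b|) and reported as an
    absolute value; a group with fewer than three genes gets None.
    """
    same = [(abs(a), abs(b)) for a, b in lfc_pairs if a * b > 0]
    opp = [(abs(a), abs(b)) for a, b in lfc_pairs if a * b < 0]

    def _corr(group):
        if len(group) < 3:
            return None
        x, y = zip(*group)
        return abs(float(pearsonr(x, y)[0]))

    return DirectionSplit(_corr(same), _corr(opp), len(same), len(opp))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-tailed test of equality of two independent correlations.

    Fisher z-transform each r; the statistic (z1 - z2) / sqrt(1/(n1-3) +
    1/(n2-3)) is standard normal under equality.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each group")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    stat = (z1 - z2) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * norm.sf(abs(stat)))


def permutation_compare(
    lfc_pairs: Sequence[tuple[float, float]],
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Size-matched permutation test of the same- vs opposite-direction
    correlation difference.

    The null redraws two disjoint random gene sets of the observed group
    sizes from the pooled (sign-informative) genes and recomputes the
    absolute-correlation difference; empirical p uses the add-one form.
    """
    import warnings

    if reps < 100:
        warnings.warn(f"permutation_compare with reps={reps} < 100 is noisy")
    obs = direction_split_correlation(lfc_pairs)
    if obs.r_same is None or obs.r_opp is None:
        raise ValueError("both direction groups need >= 3 genes")
    delta_obs = abs(obs.r_same - obs.r_opp)
    pooled = np.array(
        [(abs(a), abs(b)) for a, b in lfc_pairs if a * b != 0], dtype=float
    )
    rng = np.random.default_rng(seed)
    hits = 0
    n_tot = len(pooled)

    def _abs_r(block: np.ndarray) -> float:
        x = block[:, 0] - block[:, 0].mean()
        y = block[:, 1] - block[:, 1].mean()
        denom = math.sqrt(float(x @ x) * float(y @ y))
        return abs(float(x @ y) / denom) if denom > 0 else 0.0

    for _ in range(reps):
        perm = rng.permutation(n_tot)
        ra = _abs_r(pooled[perm[: obs.n_same]])
        rb = _abs_r(pooled[perm[obs.n_same : obs.n_same + obs.n_opp]])
        if abs(ra - rb) >= delta_obs:
            hits += 1
    return (1 + hits) / (reps + 1)
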