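"""McDonald-Kreitman analysis of recurrent adaptive protein evolution.

Per gene, nonsynonymous and synonymous changes are split into polymorphisms
(the two focal alleles differ) and fixed differences (focal alleles agree
but differ from the outgroup), giving the 2x2 table [[Dn, Ds], [Pn, Ps]].
Under neutrality Dn/Ds = Pn/Ps; an excess of Dn signals adaptive protein
divergence.  Summary statistics:

* ``alpha = 1 - (Ds*Pn)/(Dn*Ps)`` — the proportion of amino-acid fixations
  attributable to positive selection (undefined when Dn or Ps is zero);
* ``DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps)`` — the direction-of-selection index,
  positive under adaptive divergence, negative under segregating weakly
  deleterious variants.

A gene is called adaptive when its Fisher exact p < 0.05 with DoS > 0 and
alpha > 0.  Sex-bias classes come from whole-male vs whole-female FPKM:
expressed means FPKM > 1 in at least one sex, biased means a >=2-fold
difference, specific additionally requires the other sex at FPKM <= 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.stats import chi2_contingency, fisher_exact, spearmanr

from .io_core import AnalysisConfig, SiteCounts

__all__ = [
    "MKCounts",
    "MKRecord",
    "SEX_BIAS_CLASSES",
    "build_mk_table",
    "mk_filter_snps",
    "mk_testable",
    "mk_test",
    "call_adaptive",
    "classify_sex_bias",
    "enrichment_chi2",
    "alpha_correlation",
]

SEX_BIAS_CLASSES = (
    "male_specific",
    "male_biased",
    "female_specific",
    "female_biased",
    "unbiased",
    "not_expressed",
)


@dataclass
class MKCounts:
    """The four MK cell counts for one gene."""

    Dn: int = 0
    Ds: int = 0
    Pn: int = 0
    Ps: int = 0

    def as_table(self) -> list[list[int]]:
        return [[self.Dn, self.Ds], [self.Pn, self.Ps]]


@dataclass
class MKRecord:
    """Full per-gene MK result."""

    gene_id: str
    counts: MKCounts
    testable: bool = False
    fisher_p: float | None = None
    alpha: float | None = None
    dos: float | None = None
    adaptive: bool = False
    sex_bias: str | None = None


def _classify_change(codon: str, offset: int, alt_base: str) -> str:
    """syn/nonsyn for one base change against a reference codon context."""
    mutant = codon[:offset] + alt_base + codon[offset + 1 :]
    same = str(Seq(codon).translate()) == str(Seq(mutant).translate())
    return "syn" if same else "nonsyn"


def build_mk_table(
    focal1: str, focal2: str, outgroup: str, gene_id: str = ""
) -> MKCounts:
    """Count Dn/Ds/Pn/Ps from a codon alignment of two focal alleles and an
    outgroup sequence.

    All three sequences must be equal-length, in frame, and gap-stripped to
    a multiple of three.  Codons containing a gap or N in any sequence are
    skipped.  Codons with several variable sites are decomposed site by
    site, each change classified against the first focal allele's codon
    with the other two positions held at their focal state; a codon can
    contribute to both the polymorphism and divergence counts.
    """
    if not (len(focal1) == len(focal2) == len(outgroup)):
        raise ValueError(f"gene {gene_id or '?'}: aligned sequences differ in length")
    if len(focal1) % 3 != 0:
        raise ValueError(f"gene {gene_id or '?'}: alignment length not a multiple of 3")
    counts = MKCounts()
    f1, f2, og = focal1.upper(), focal2.upper(), outgroup.upper()
    for i in range(0, len(f1), 3):
        c1, c2, co = f1[i : i + 3], f2[i : i + 3], og[i : i + 3]
        if any(b not in "ACGT" for b in c1 + c2 + co):
            continue
        for j in range(3):
            if c1[j] != c2[j]:  # polymorphic site
                kind = _classify_change(c1, j, c2[j])
                if kind == "syn":
                    counts.Ps += 1
                else:
                    counts.Pn += 1
            elif c1[j] != co[j]:  # fixed difference
                kind = _classify_change(c1, j, co[j])
                if kind == "syn":
                    counts.Ds += 1
                else:
                    counts.Dn += 1
    return counts


def mk_filter_snps(site: SiteCounts, cfg: AnalysisConfig) -> bool:
    """SNP filter for the MK pipeline (stricter than the scan's).

    Accepts biallelic sites with every pool at >= 20x base-call coverage
    and a dataset-wide minor-allele count of at least 3.
    """
    for j in range(len(site.pools)):
        if site.coverage(j) < cfg.min_site_coverage:
            return False
    combined = site.combined_base_counts()
    observed = sorted((n, b) for b, n in combined.items() if n > 0)
    if len(observed) != 2:
        return False
    minor_count = observed[0][0]
    return minor_count >= cfg.min_minor_allele_mk


def mk_testable(counts: MKCounts) -> bool:
    """At least one variant in each of the four marginal categories:
    polymorphic, fixed, synonymous, nonsynonymous."""
    return (
        counts.Pn + counts.Ps >= 1
        and counts.Dn + counts.Ds >= 1
        and counts.Ps + counts.Ds >= 1
        and counts.Pn + counts.Dn >= 1
    )


def mk_test(counts: MKCounts) -> tuple[float, float | None, float | None]:
    """Fisher's exact test plus alpha and DoS for one MK table.

    Returns (fisher_p, alpha, dos).  The two-sided Fisher p uses the
    standard minimal-likelihood definition.  alpha is None when Dn = 0 or
    Ps = 0; DoS is None when either the divergence or the polymorphism row
    is empty.
    """
    _, p = fisher_exact(counts.as_table(), alternative="two-sided")
    alpha = None
    if counts.Dn > 0 and counts.Ps > 0:
        alpha = 1.0 - (counts.Ds * counts.Pn) / (counts.Dn * counts.Ps)
    dos = None
    if counts.Dn + counts.Ds > 0 and counts.Pn + counts.Ps > 0:
        dos = counts.Dn / (counts.Dn + counts.Ds) - counts.Pn / (counts.Pn + counts.Ps)
    return float(p), alpha, dos


def call_adaptive(record: MKRecord, p_threshold: float = 0.05) -> bool:
    """Adaptive iff significant (p < threshold) with DoS > 0 and alpha > 0."""
    record.adaptive = bool(
        record.fisher_p is not None
        and record.fisher_p < p_threshold
        and record.dos is not None
        and record.dos > 0
        and record.alpha is not None
        and record.alpha > 0
    )
    return record.adaptive


def evaluate_gene(gene_id: str, counts: MKCounts) -> MKRecord:
    """Run the testability filter, MK test and adaptive call for one gene."""
    rec = MKRecord(gene_id, counts, testable=mk_testable(counts))
    if rec.testable:
        rec.fisher_p, rec.alpha, rec.dos = mk_test(counts)
        call_adaptive(rec)
    return rec


def classify_sex_bias(fpkm_male: float, fpkm_female: float) -> str:
    """Partition a gene into exactly one sex-bias class from FPKM.

    not_expressed when neither sex exceeds FPKM 1; biased requires a
    >=2-fold difference; specific additionally requires the other sex at
    FPKM <= 0.2.
    """
    if fpkm_male < 0 or fpkm_female < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm_male <= 1 and fpkm_female <= 1:
        return "not_expressed"
    if fpkm_male >= 2 * fpkm_female:
        return "male_specific" if fpkm_female <= 0.2 else "male_biased"
    if fpkm_female >= 2 * fpkm_male:
        return "female_specific" if fpkm_male <= 0.2 else "female_biased"
    return "unbiased"


def enrichment_chi2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2
    class-by-status contingency table.  Zero margins are an error."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def alpha_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman rank correlation of alpha across clades for shared genes.

    Average ranks for ties; p from the t approximation.  Requires at least
    three complete pairs.
    """
    clean = [(a, b) for a, b in pairs if not (math.isnan(a) or math.isnan(b))]
    if len(clean) < 3:
        raise ValueError("need >= 3 complete alpha pairs")
    x, y = zip(*clean)
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
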