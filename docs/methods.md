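# Methods

This note documents the statistical model behind each component, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Pooled estimators

All population genetic quantities are computed from read counts, never
from estimated chromosome counts. Coverage at a site is the number of
A/C/G/T base calls; N calls and deletions are excluded everywhere.

**Site heterozygosity.** For one pool with allele counts {cₐ}, c = Σcₐ:

    h = (c / (c − 1)) · (1 − Σₐ (cₐ/c)²)

The c/(c−1) factor removes the finite-depth bias of the plug-in Σp̂²
(E[Σp̂²] = Σp² + (1 − Σp²)/c under binomial read sampling), so h is
unbiased for the true heterozygosity at any coverage ≥ 2 — verified
empirically in the tests rather than asserted as a closed form. Window π
divides the summed h over covered sites by the number of covered sites,
not by the window length: missing data is not invariance. "Covered" means
passing the coverage filter, even if a later filter (minimum alternate
count, triallelic) removes the site from the SNP set.

**Per-SNP F_ST.** π_W is the unweighted mean of the two pools'
heterozygosities, π_T the heterozygosity of the summed counts, and
F_ST = (π_T − π_W)/π_T, undefined (excluded) when π_T = 0. Negative
values are retained: clamping at zero would distort the empirical tails
the scan is built on. One consequence worth knowing: because the bias
correction uses each layer's own coverage (c for the pools, 2c for the
total), two *identical* pools give a slightly negative F_ST
(−1/(2c − 1)-order), not exactly zero; the zero identity holds in the
infinite-coverage limit. Pool sizes (numbers of sampled chromosomes)
enter nowhere — a known limitation of read-count-based pooled estimation
shared with the upstream tools this format comes from.

**Windows.** Non-overlapping, fixed 1 kb; trailing sub-window scaffold
ends are discarded; a window is analysed when ≥50% of its sites are
covered in both pools. Window F_ST is the unweighted mean of per-SNP
F_ST; covered windows with no SNPs contribute F_ST = 0 to the
distribution. Tail thresholds at fraction f are the ⌈f·n⌉-th largest
window value; ties at the threshold are all flagged (deterministic,
conservative supersets).

## Outlier testing

**Mid-p exact test.** For the 2×2 table of (allele × population) read
counts with fixed margins, the top-left cell is hypergeometric. The
one-sided mid-p counts half the observed table's probability,
P(X > a) + ½P(X = a); the two-sided value doubles the smaller one-sided
value (the "central" construction, matching the epidemiology toolkits
that popularized the test), capped at 1. Zero-margin tables are
degenerate and get p = 1. Mid-p was chosen over the standard Fisher p for
the scan because discrete conservatism at 20–70× coverage otherwise
swamps the tails; the cost is that mid-p is not guaranteed
sub-uniform. Under a shared-frequency null with Poisson(60)/Poisson(70)
coverage and the scan's site filters, its distribution is uniform to KS
distance < 0.03 (recomputed in the tests and the acceptance script).

**Per-arm FDR.** Storey q-values per chromosome arm: π₀(λ) =
#{p > λ}/(m(1 − λ)) on λ = 0.05, 0.10, …, 0.95, smoothed with a cubic
spline and read off at λ = 0.95, clipped to (0, 1]; q is the usual
step-up min over p_j ≥ p_i of π₀·m·p_j/rank(p_j). Arms with fewer than
100 tests, or a non-positive smoother estimate, fall back to π₀ = 1
(Benjamini–Hochberg). The 100-test floor is our choice; the smoother is
far too noisy below it. Scaffolds without a Muller assignment form a
pseudo-arm. Outliers: q ≤ 10⁻⁵ AND F_ST strictly > 0.15.

**Polarization.** A SNP is polarized only when exactly one allele equals
the outgroup base; outgroup N/gap/mismatch-to-both excludes the SNP from
polarized analyses.

## Annotation

Genes are taken from GFF3 with one transcript per gene (longest CDS when
isoforms exist). A SNP belongs to every gene whose transcript span ±1 kb
(boundary base inclusive) contains it — overlapping genes each get a
record, because collapsing to a "primary" gene loses information the
gene-level outlier lists need. Effect classes are exclusive with priority
CDS > UTR > intron > flanking; coding changes substitute the alternate
allele into the reference codon (other two positions at reference state,
minus-strand genes handled in transcript orientation) and compare amino
acids under the standard nuclear code. Codons containing an ambiguous
base, and CDSs that are out of frame after phase adjustment, are excluded
rather than guessed. An independent oracle — translate the whole mutant
CDS and diff the protein — checks 1000 random coding SNPs in the tests.

Scaffold → Muller element assignment is a majority vote over the
scaffold's genes' best cross-species hits with an inclusive 55%
threshold, insensitive to row order and duplicates.

## Sharing statistics

**Hypergeometric overlap.** p = P(X ≥ k) for X hypergeometric(N, K, n);
expected = Kn/N, fold = k/expected. Exact tail sums; validated against
binomial-coefficient enumeration and exhaustive set-pair enumeration at
small N.

**Matched bootstrap.** The confounder: genes with more nonsynonymous SNPs
have more chances to carry an outlier in *both* species, inflating the
hypergeometric test when SNP density varies. Per replicate, each outlier
gene with nsSNP count m is replaced by a uniformly drawn universe gene
with count ≥ m (without replacement within a replicate and species);
the replicate overlap distribution gives expected sharing, fold, and an
add-one empirical p = (1 + #{rep ≥ k})/(B + 1), B = 1000 by default.
Matching is on the TOTAL per-gene nsSNP count. The source pipeline's
description is ambiguous between total nsSNPs and nsSNP *outlier* counts;
the total-count reading targets the stated confounder (gene size / SNP
density) directly and is implemented; the other reading would condition
on the outcome being tested. In a deliberately confounded simulation
(counts varying 10-fold, outliers drawn proportional to counts, no true
sharing) the hypergeometric test rejects at many times the nominal rate
while the matched bootstrap stays at or below nominal — this is the
statistic's reason for existing.

**Directionality.** χ² of the (up, down) derived-allele direction split
against 50:50, 1 df, no continuity correction (counts in the intended
applications are in the hundreds). Fisher's combined probability
−2Σln pᵢ ~ χ²(2k) combines the per-species tests.

**Calibration checks.** The overlap and bootstrap p-values are discrete
upper-tail probabilities and therefore deliberately sub-uniform (a value
like P(X ≥ k) jumps by the pmf at k); a KS test of the raw p against the
continuous uniform rejects for any such test by construction. Calibration
is therefore assessed on the randomized probability integral transform —
p randomized uniformly within the atom at the observed statistic — which
is exactly uniform for a calibrated test, together with direct checks
that P(p ≤ α) ≤ α (+ Monte-Carlo slack) at α = 0.01/0.05/0.1.

## McDonald–Kreitman analysis

Counting walks the codon alignment (two focal alleles + outgroup) site by
site: focal-allele differences are polymorphisms, shared-focal vs
outgroup differences are fixed, each change classified syn/nonsyn against
the first focal allele's codon with the other two positions at their
focal state. Multi-hit codons are decomposed site-by-site (no pathway
enumeration) — deterministic and standard in MK pipelines, at the cost of
ignoring rare multi-step trajectories. A codon can legitimately
contribute to both the polymorphism and divergence counts. Codons with
gaps or ambiguity in any sequence are skipped.

Testability requires ≥1 variant in each marginal category (polymorphic,
fixed, synonymous, nonsynonymous). The Fisher p is the standard
minimal-likelihood two-sided exact test (distinct from the scan's mid-p;
both are exposed). α = 1 − (Ds·Pn)/(Dn·Ps) is left undefined — not
clipped — when Dn = 0 or Ps = 0, and undefined genes are excluded from
the cross-clade α correlation (Spearman, average ranks, t
approximation). DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps). Adaptive call: p < 0.05
AND DoS > 0 AND α > 0.

Sex bias from whole-male/whole-female FPKM: expressed ⇔ FPKM > 1 in at
least one sex; biased ⇔ ≥2-fold difference (the boundary is inclusive —
"two-fold greater" read as attained); specific ⇔ biased with the other
sex ≤ 0.2. The six classes partition all inputs.

## Expression parallelism

Differential expression is rank-based only (|log₂ fold change| between
populations with a 0.1 FPKM pseudo-count; ties broken by gene id),
because single-library population transcriptomes support no
replicate-based inference. The top-N (default 300) lists of two species
are compared with the hypergeometric overlap test over the
expressed-in-both universe (FPKM > 1 in some sample of each species).
Direction sharing: orthologs split by fold-change sign agreement (zero
fold changes excluded from both groups); Pearson r of the magnitude pairs
within each group, reported as |r|; groups compared by Fisher z and by a
permutation null that redraws two disjoint random gene sets of the
observed group sizes ("correcting gene number" read as size-matched
resampling — plain label shuffling would not hold group sizes fixed).

## Synthetic data

The generators emulate the *structure* the pipeline consumes, not
population-genetic realism — no linkage, no recombination, no selection
dynamics; drift is a single binomial resampling of 200 chromosomes per
population, selection a deterministic +0.35 frequency shift in population
1 for 2% of SNPs. Defaults: per-site segregation probability 0.01;
ancestral derived-allele frequencies from a 1/x density truncated to
[0.025, 0.975]; pool coverages Poisson with means 60 and 70 (the two
populations' sequencing depths); outgroup divergence 0.05 per site,
placeable genome-wide or at third codon positions only. MK counts are
Poisson around means (Ps, Pn, Ds) = (8, 4, 10)·scale with
Dn = (Ds·Pn/Ps)/(1 − α), making the plug-in α consistent as counts grow.
Expression: shared log₂ baseline N(3, 1.5), DE effects N(0, 1) for 5% of
genes per species, 30% of species-A DE genes shared with concordant sign,
log-scale observation noise σ = 0.2. Unstated-by-design values (densities,
drift size, shift, Poisson means, noise scales) were fixed once at
field-plausible magnitudes and are all overridable in `SimConfig`.

Consequently, passing recovery and calibration tests shows the estimators
and tests are correct *given* independent binomial read sampling; it says
nothing about linked selection, mapping artefacts, or pool-construction
variance in real data. Test problem sizes (2–4 scaffolds of 15–50 kb,
hundreds of genes, 150–500 simulated datasets for calibration) were
chosen so the full suite runs in well under a minute per heavy test while
keeping Monte-Carlo error well inside the asserted bounds.

## Degenerate inputs and tie-breaking

- sync positions must be strictly increasing per scaffold; violations are
  errors, not warnings.
- Empty windows, SNP-free windows, and zero-margin tables all have
  defined behaviour (undefined π, F_ST = 0, degenerate p = 1
  respectively) rather than exceptions.
- Quantile ties at tail thresholds: all flagged.
- Expression ranking ties: broken lexicographically by ortholog id.
- Empirical p-values use add-one forms and are never 0; mid-p is floored
  at the smallest positive float.

## Known limitations

- Read-count 2×2 tests pseudo-replicate chromosomes: anti-conservative;
  outlier calls are ranks, not error rates.
- The exact F_ST estimator of the upstream pooled pipelines is not
  restated in their descriptions; the classical (π_T − π_W)/π_T pooled
  form implemented here is an assumption.
- Base-quality filtering (Q ≥ 30) is assumed done upstream of the sync
  input and is not re-implemented.
- No polarized MK, no DFE/asymptotic-α extensions, no LD or scan
  statistics beyond the mid-p/FDR scheme.
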