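# paradapt

Parallel adaptation at two timescales from population genomic data.

`paradapt` asks, for a pair of distantly related species, how repeatable
adaptive evolution is at the level of the gene — on the short timescale of
recent latitudinal population differentiation and on the long timescale of
recurrent adaptive protein divergence between species. It was built for
two-population pooled-sequencing designs in *Drosophila* (a high- and a
low-latitude population per species, ~60–70× pooled coverage) but the
statistics are general.

## What it computes

**Latitudinal differentiation scan** (per species, from pooled read counts
in "sync" format):

- site filters: ≥20× base-call coverage in every pool, ≥2 alternate
  observations dataset-wide, biallelic sites only;
- pooled nucleotide diversity per site,
  π = (c/(c−1))·(1 − Σₐ (cₐ/c)²), summarised in 1-kb non-overlapping
  windows (windows analysed when ≥50% of sites are covered);
- per-SNP F_ST = (π_T − π_W)/π_T with π_W the unweighted mean of the two
  pools' site heterozygosities and π_T that of the pooled counts; window
  F_ST is the unweighted mean over SNPs, with empirical 1% / 2.5% / 5%
  tail thresholds;
- a two-sided mid-p exact test of allele-count independence per SNP, with
  Storey q-values computed independently per chromosome arm (Muller
  element); outliers are SNPs with q ≤ 10⁻⁵ and F_ST > 0.15;
- SNP effect classes (synonymous / nonsynonymous / intronic / UTR /
  flanking) from GFF3 + FASTA, codon-aware and strand-aware, and
  ancestral-state polarization against an outgroup reference.

**Cross-species sharing statistics**:

- hypergeometric overlap of outlier-gene sets over a one-to-one ortholog
  universe, with expected overlap Kn/N and fold enrichment k/(Kn/N);
- a SNP-count-matched bootstrap null that redraws each species' outlier
  list from genes with at least as many nonsynonymous SNPs — the guard
  against SNP-dense genes being shared "outliers" by chance alone;
- directionality χ² (is the derived allele systematically more frequent
  at one latitude?) and Fisher's combined probability across species.

**Recurrent adaptive protein evolution** (per gene, unpolarized
McDonald–Kreitman): the 2×2 table [[Dn, Ds], [Pn, Ps]] of nonsynonymous /
synonymous fixed differences and polymorphisms, Fisher's exact test,
α = 1 − (Ds·Pn)/(Dn·Ps), DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps); genes are called
adaptive when p < 0.05 with DoS > 0 and α > 0. Sex-bias classes from
male/female FPKM and enrichment χ² tests; Spearman correlation of α
across clades for shared adaptive genes.

**Expression parallelism**: rank-based top-N (default 300) differential
expression overlap between species and the same- vs opposite-direction
fold-change correlation comparison (Fisher z and a size-matched
permutation test).

**Synthetic data**: generators for every input format with ground-truth
tables (drifted allele frequencies with a selected fraction, Poisson
coverage, MK count tables with tunable true α, two-species FPKM tables
with controllable shared differential expression), so the whole pipeline
runs end to end with no external data.

## Worked example

```python
from paradapt import overlap_test, mk_test, MKCounts, snp_fst, midp_test

# do two species share more outlier genes than chance? Universe of 9401
# orthologs, 640 and 1031 outlier genes, 110 shared:
ov = overlap_test(9401, 640, 1031, 110)
print(f"shared={ov.k} expected={ov.expected:.1f} fold={ov.fold:.2f} p={ov.p:.3g}")

# McDonald-Kreitman test for one gene
p, alpha, dos = mk_test(MKCounts(Dn=10, Ds=5, Pn=2, Ps=8))
print(f"fisher_p={p:.4f} alpha={alpha:.3f} DoS={dos:.3f}")

# pooled F_ST and mid-p for one SNP (major/minor read counts per pool)
print(f"fst={snp_fst((15, 5), (5, 15)):.5f}")
print(f"midp={midp_test(15, 5, 5, 15).midp:.5f}")
```

prints

```
shared=110 expected=70.2 fold=1.57 p=6.22e-07
fisher_p=0.0414 alpha=0.875 DoS=0.467
fst=0.23026
midp=0.00210
```

So the two outlier lists overlap 1.57-fold more than the independence
expectation (110 shared genes where ~70 are expected; p ≈ 6×10⁻⁷), the
example gene shows an excess of nonsynonymous fixations with α = 0.875
(about 88% of its amino-acid fixations attributed to positive selection),
and the example SNP is strongly differentiated (F_ST = 0.23) and unlikely
under allele-frequency homogeneity (mid-p = 0.002).

The pipeline form of the same analyses runs from a shell:

```
paradapt --out-dir run --seed 1 simulate
paradapt --out-dir run --seed 1 popgen
paradapt --out-dir run --seed 1 outliers
```

writing `windows.tsv`/`windows.bed`, `snps_tested.tsv` (mid-p, q-value,
outlier flag per SNP), an arm-level FDR summary and a run manifest under
`run/`.

A caveat by construction: the mid-p test is applied to read counts, which
pseudo-replicate the underlying chromosomes, so per-SNP p-values are
anti-conservative with respect to true allele sampling; outlier calls
should be read as empirical ranks, not calibrated error rates.

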