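"""Synthetic datasets for every input the pipeline consumes.

Three generators emulate the structure (not the full population-genetic
realism) of a two-population pooled-sequencing study:

* `simulate_popgen_dataset` — annotated scaffolds with per-site read
  counts for two pools.  Ancestral derived-allele frequencies follow a
  neutral-SFS-like density (proportional to 1/x, truncated); each
  population drifts by one binomial resampling step of configurable size;
  a chosen fraction of SNPs gets a deterministic frequency shift in
  population 1 (the "selected" class); read counts are binomial draws at
  Poisson-distributed coverage.  An outgroup sequence carries the
  ancestral allele plus independent divergence.
* `simulate_mk_dataset` — per-gene MK count tables with a known true
  alpha, realised as Poisson counts around expectations tied together by
  Dn = (Ds*Pn/Ps) / (1 - alpha), optionally embedded as planted
  substitutions in in-frame codon-alignment triplets.
* `simulate_expression_dataset` — two-species FPKM tables with a
  controllable fraction of truly differential genes and a controllable
  overlap of shared, sign-concordant differential genes.

Every generator records its full configuration and ground truth so
pipeline output can be joined back to the simulated truth; the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .io_core import SiteCounts, SYNC_BASES, write_sync
from .mk import MKCounts

__all__ = [
    "SimConfig",
    "PopgenSim",
    "MKSim",
    "ExprSim",
    "simulate_popgen_dataset",
    "simulate_mk_dataset",
    "simulate_expression_dataset",
    "mk_alignment_from_counts",
    "write_popgen_dataset",
    "write_mk_dataset",
    "write_expression_dataset",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    Pool coverages default to roughly 60x and 70x (the two populations'
    sequencing depths); ``theta`` is the per-site probability that a site
    segregates; ``frac_selected_snps`` of SNPs get a ``selection_shift``
    added to their population-1 frequency; ``drift_size`` is the number of
    chromosomes in the single binomial resampling step that stands in for
    drift.  MK expectations and expression parameters are documented in
    the methods note.
    """

    # popgen
    n_scaffolds: int = 4
    scaffold_length: int = 50_000
    n_genes: int = 48
    coverage_mean: tuple[float, float] = (60.0, 70.0)
    pool_count: int = 2
    theta: float = 0.01
    frac_selected_snps: float = 0.02
    selection_shift: float = 0.35
    drift_size: int = 200
    divergence: float = 0.05
    divergence_placement: str = "all"  # or 'cds_third'
    # mk
    n_mk_genes: int = 200
    alpha_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    mk_ps_mean: float = 8.0
    mk_pn_mean: float = 4.0
    mk_ds_mean: float = 10.0
    mk_scale: float = 1.0
    # expression
    n_expressed_genes: int = 8760
    frac_de: float = 0.05
    de_lfc_sigma: float = 1.0
    shared_de_fraction: float = 0.3
    expr_noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta", "frac_selected_snps", "frac_de", "shared_de_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pool_count != 2:
            raise ValueError("only two population pools are supported")
        if min(self.coverage_mean) <= 0:
            raise ValueError("coverage means must be positive")
        if any(not (0.0 <= a < 1.0) for a in self.alpha_grid):
            raise ValueError("alpha_grid values must lie in [0, 1)")


def _sfs_frequencies(rng: np.random.Generator, size: int,
                     lo: float = 0.025, hi: float = 0.975) -> np.ndarray:
    # density proportional to 1/x on [lo, hi]: inverse-CDF sampling
    u = rng.random(size)
    return lo * (hi / lo) ** u


# ---------------------------------------------------------------------------
# popgen dataset


@dataclass
class PopgenSim:
    """In-memory popgen dataset plus its ground truth."""

    config: SimConfig
    genome: dict[str, str]
    outgroup: dict[str, str]
    gff3: str
    sites: list[SiteCounts]
    truth: pd.DataFrame  # one row per segregating site


def _gene_features(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Lay out genes on scaffolds: 30 bp UTRs, two 150-bp CDS exons
    separated by a 70-bp intron; strands alternate."""
    per_scaffold = config.n_genes // config.n_scaffolds
    span = 30 + 150 + 70 + 150 + 30  # 430 bp
    genes = []
    idx = 0
    for s in range(config.n_scaffolds):
        scaffold = f"scf{s + 1}"
        if per_scaffold == 0:
            continue
        pitch = config.scaffold_length // per_scaffold
        if pitch < span + 2200:
            raise ValueError(
                "scaffold_length too small for n_genes with 1-kb flanks"
            )
        for g in range(per_scaffold):
            start = g * pitch + 1100 + int(rng.integers(0, pitch - span - 2200))
            strand = "+" if idx % 2 == 0 else "-"
            genes.append(
                {
                    "gene_id": f"g{idx + 1:04d}",
                    "scaffold": scaffold,
                    "strand": strand,
                    "start": start,
                    "end": start + span - 1,
                    "utr5": (start, start + 29) if strand == "+" else (start + span - 30, start + span - 1),
                    "cds1": (start + 30, start + 179),
                    "intron": (start + 180, start + 249),
                    "cds2": (start + 250, start + 399),
                    "utr3": (start + span - 30, start + span - 1) if strand == "+" else (start, start + 29),
                }
            )
            idx += 1
    return genes


def _gff3_text(genes: list[dict]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        sc, st = g["scaffold"], g["strand"]
        gid = g["gene_id"]
        lines.append(f"{sc}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t{st}\t.\tID={gid}")
        mid = f"{gid}.t1"
        lines.append(
            f"{sc}\tsim\tmRNA\t{g['start']}\t{g['end']}\t.\t{st}\t.\tID={mid};Parent={gid}"
        )
        exon1 = (g["start"], g["cds1"][1]) if st == "+" else (g["start"], g["cds1"][1])
        feats = [
            ("exon", g["start"], g["cds1"][1], "."),
            ("exon", g["cds2"][0], g["end"], "."),
            ("CDS", g["cds1"][0], g["cds1"][1], "0"),
            ("CDS", g["cds2"][0], g["cds2"][1], "0"),
            ("five_prime_UTR", *g["utr5"], "."),
            ("three_prime_UTR", *g["utr3"], "."),
        ]
        for kind, a, b, phase in feats:
            lines.append(
                f"{sc}\tsim\t{kind}\t{a}\t{b}\t.\t{st}\t{phase}\t"
                f"ID={mid}.{kind}.{a};Parent={mid}"
            )
    return "\n".join(lines) + "\n"


def simulate_popgen_dataset(config: SimConfig) -> PopgenSim:
    """Generate the full two-pool pooled-sequencing dataset in memory."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_features(config, rng)

    genome: dict[str, str] = {}
    outgroup: dict[str, str] = {}
    sites: list[SiteCounts] = []
    truth_rows: list[dict] = []
    base_index = {b: i for i, b in enumerate(SYNC_BASES)}

    cds_third: dict[str, set[int]] = {}
    if config.divergence_placement == "cds_third":
        for g in genes:
            positions = list(range(g["cds1"][0], g["cds1"][1] + 1)) + list(
                range(g["cds2"][0], g["cds2"][1] + 1)
            )
            if g["strand"] == "-":
                positions = positions[::-1]
            third = {positions[i] for i in range(2, len(positions), 3)}
            cds_third.setdefault(g["scaffold"], set()).update(third)

    for s in range(config.n_scaffolds):
        scaffold = f"scf{s + 1}"
        length = config.scaffold_length
        seq = rng.choice(list(_BASES), size=length)
        genome[scaffold] = "".join(seq)

        # outgroup: ancestral sequence plus independent divergence
        og = seq.copy()
        if config.divergence_placement == "cds_third":
            eligible = np.array(sorted(cds_third.get(scaffold, set()))) - 1
        else:
            eligible = np.arange(length)
        if eligible.size:
            n_div = rng.binomial(eligible.size, config.divergence)
            div_pos = rng.choice(eligible, size=n_div, replace=False)
            for i in div_pos:
                alts = [b for b in _BASES if b != og[i]]
                og[i] = alts[rng.integers(0, 3)]
        outgroup[scaffold] = "".join(og)

        # segregating sites
        is_snp = rng.random(length) < config.theta
        snp_pos = np.flatnonzero(is_snp) + 1  # 1-based
        p_anc = _sfs_frequencies(rng, snp_pos.size)
        selected = rng.random(snp_pos.size) < config.frac_selected_snps
        p1_base = np.where(
            selected, np.minimum(p_anc + config.selection_shift, 0.98), p_anc
        )
        p1 = rng.binomial(config.drift_size, p1_base) / config.drift_size
        p2 = rng.binomial(config.drift_size, p_anc) / config.drift_size

        derived = np.empty(snp_pos.size, dtype="<U1")
        for i, pos in enumerate(snp_pos):
            anc = genome[scaffold][pos - 1]
            alts = [b for b in _BASES if b != anc]
            derived[i] = alts[rng.integers(0, 3)]

        freq_at = dict(zip(snp_pos.tolist(), range(snp_pos.size)))
        cov = tuple(
            rng.poisson(config.coverage_mean[j], size=length)
            for j in range(2)
        )
        for pos in range(1, length + 1):
            anc = genome[scaffold][pos - 1]
            pools = []
            if pos in freq_at:
                i = freq_at[pos]
                der = derived[i]
                for j, p in enumerate((p1[i], p2[i])):
                    c = int(cov[j][pos - 1])
                    d = int(rng.binomial(c, p))
                    sextet = [0] * 6
                    sextet[base_index[anc]] = c - d
                    sextet[base_index[der]] = d
                    pools.append(tuple(sextet))
            else:
                for j in range(2):
                    c = int(cov[j][pos - 1])
                    sextet = [0] * 6
                    sextet[base_index[anc]] = c
                    pools.append(tuple(sextet))
            sites.append(SiteCounts(scaffold, pos, anc, tuple(pools)))

        for i, pos in enumerate(snp_pos):
            truth_rows.append(
                {
                    "scaffold": scaffold,
                    "pos": int(pos),
                    "ancestral": genome[scaffold][pos - 1],
                    "derived": derived[i],
                    "p_pop1": float(p1[i]),
                    "p_pop2": float(p2[i]),
                    "p_ancestral": float(p_anc[i]),
                    "selected": bool(selected[i]),
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "scaffold", "pos", "ancestral", "derived",
            "p_pop1", "p_pop2", "p_ancestral", "selected",
        ],
    )
    return PopgenSim(config, genome, outgroup, _gff3_text(genes), sites, truth)


# ---------------------------------------------------------------------------
# MK dataset


@dataclass
class MKSim:
    """Per-gene MK count tables (and optional codon alignments) with truth."""

    config: SimConfig
    counts: dict[str, MKCounts]
    truth: pd.DataFrame
    alignments: dict[str, tuple[str, str, str]] = field(default_factory=dict)


def mk_alignment_from_counts(
    counts: MKCounts, rng: np.random.Generator, n_codons: int | None = None
) -> tuple[str, str, str]:
    """Build an in-frame codon-alignment triplet carrying exactly the given
    (Dn, Ds, Pn, Ps) when scored site by site.

    Every planted change sits in its own codon: synonymous changes flip the
    third position of a GCT (Ala) codon, nonsynonymous ones flip its second
    position; filler codons are random non-stop codons identical in all
    three sequences.
    """
    total = counts.Dn + counts.Ds + counts.Pn + counts.Ps
    if n_codons is None:
        n_codons = max(2 * total, total + 20)
    if n_codons < total:
        raise ValueError("n_codons too small to plant all changes")
    kinds = (
        ["Dn"] * counts.Dn + ["Ds"] * counts.Ds
        + ["Pn"] * counts.Pn + ["Ps"] * counts.Ps
        + [None] * (n_codons - total)
    )
    perm = rng.permutation(n_codons)
    f1, f2, og = [], [], []
    for slot in perm:
        kind = kinds[slot]
        if kind is None:
            c = _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]
            f1.append(c), f2.append(c), og.append(c)
        elif kind == "Ps":  # focal alleles differ synonymously
            f1.append("GCT"), f2.append("GCC"), og.append("GCT")
        elif kind == "Pn":
            f1.append("GCT"), f2.append("GTT"), og.append("GCT")
        elif kind == "Ds":  # fixed synonymous difference vs outgroup
            f1.append("GCT"), f2.append("GCT"), og.append("GCC")
        else:  # Dn
            f1.append("GCT"), f2.append("GCT"), og.append("GTT")
    return "".join(f1), "".join(f2), "".join(og)


def simulate_mk_dataset(config: SimConfig, alignments: bool = False) -> MKSim:
    """Per-gene MK tables with known true alpha.

    Expected counts: Ps, Pn, Ds at their configured means (scaled by
    ``mk_scale``) and Dn = (Ds_mean * Pn_mean / Ps_mean) / (1 - alpha), so
    the plug-in alpha estimator is consistent for the chosen alpha as the
    counts grow.  Realised counts are independent Poisson draws.
    """
    rng = np.random.default_rng(config.seed + 1)
    s = config.mk_scale
    ps_m, pn_m, ds_m = config.mk_ps_mean * s, config.mk_pn_mean * s, config.mk_ds_mean * s
    out: dict[str, MKCounts] = {}
    rows = []
    aligns: dict[str, tuple[str, str, str]] = {}
    for i in range(config.n_mk_genes):
        gene = f"mk{i + 1:04d}"
        alpha = float(config.alpha_grid[rng.integers(0, len(config.alpha_grid))])
        dn_m = (ds_m * pn_m / ps_m) / (1.0 - alpha)
        counts = MKCounts(
            Dn=int(rng.poisson(dn_m)),
            Ds=int(rng.poisson(ds_m)),
            Pn=int(rng.poisson(pn_m)),
            Ps=int(rng.poisson(ps_m)),
        )
        out[gene] = counts
        rows.append(
            {
                "gene": gene,
                "true_alpha": alpha,
                "Dn": counts.Dn,
                "Ds": counts.Ds,
                "Pn": counts.Pn,
                "Ps": counts.Ps,
            }
        )
        if alignments:
            aligns[gene] = mk_alignment_from_counts(counts, rng)
    return MKSim(config, out, pd.DataFrame(rows), aligns)


# ---------------------------------------------------------------------------
# expression dataset


@dataclass
class ExprSim:
    """Two-species, two-population FPKM tables with DE ground truth."""

    config: SimConfig
    fpkm_a: dict[str, tuple[float, float]]
    fpkm_b: dict[str, tuple[float, float]]
    truth: pd.DataFrame


def simulate_expression_dataset(config: SimConfig) -> ExprSim:
    """FPKM tables for two species sharing an ortholog universe.

    Baseline log2 abundance is shared across species; ``frac_de`` of genes
    per species receive a log2 population effect drawn from
    N(0, de_lfc_sigma); ``shared_de_fraction`` of species-A's differential
    genes are also differential in species B with a concordant sign.
    Log-normal observation noise is added independently per sample.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_expressed_genes
    genes = [f"og{i + 1:05d}" for i in range(n)]
    baseline = rng.normal(3.0, 1.5, size=n)
    n_de = int(round(config.frac_de * n))
    n_shared = int(round(config.shared_de_fraction * n_de))
    perm = rng.permutation(n)
    de_a = perm[:n_de]
    shared = de_a[:n_shared]
    extra_b = perm[n_de : 2 * n_de - n_shared]
    de_b = np.concatenate([shared, extra_b])

    eff_a = np.zeros(n)
    eff_a[de_a] = rng.normal(0.0, config.de_lfc_sigma, size=n_de)
    eff_b = np.zeros(n)
    eff_b[de_b] = rng.normal(0.0, config.de_lfc_sigma, size=len(de_b))
    eff_b[shared] = np.sign(eff_a[shared]) * np.abs(eff_b[shared])

    def _table(effect: np.ndarray) -> dict[str, tuple[float, float]]:
        noise = rng.normal(0.0, config.expr_noise_sigma, size=(n, 2))
        log_p1 = baseline + effect / 2.0 + noise[:, 0]
        log_p2 = baseline - effect / 2.0 + noise[:, 1]
        return {
            g: (float(2.0 ** log_p1[i]), float(2.0 ** log_p2[i]))
            for i, g in enumerate(genes)
        }

    fpkm_a = _table(eff_a)
    fpkm_b = _table(eff_b)
    is_de_a = np.zeros(n, dtype=bool)
    is_de_a[de_a] = True
    is_de_b = np.zeros(n, dtype=bool)
    is_de_b[de_b] = True
    shared_mask = np.zeros(n, dtype=bool)
    shared_mask[shared] = True
    truth = pd.DataFrame(
        {
            "gene": genes,
            "baseline_log2": baseline,
            "effect_a": eff_a,
            "effect_b": eff_b,
            "de_a": is_de_a,
            "de_b": is_de_b,
            "shared_de": shared_mask,
        }
    )
    return ExprSim(config, fpkm_a, fpkm_b, truth)


# ---------------------------------------------------------------------------
# writers


def _write_manifest(outdir: Path, config: SimConfig, outputs: list[str]) -> None:
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _write_fasta(path: Path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_popgen_dataset(sim: PopgenSim, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "sync": outdir / "pools.sync",
        "fasta": outdir / "reference.fasta",
        "outgroup": outdir / "outgroup.fasta",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth" / "popgen_truth.tsv",
    }
    write_sync(paths["sync"], sim.sites)
    _write_fasta(paths["fasta"], sim.genome)
    _write_fasta(paths["outgroup"], sim.outgroup)
    paths["gff3"].write_text(sim.gff3)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    _write_manifest(outdir, sim.config, [p.name for p in paths.values()])
    return paths


def write_mk_dataset(sim: MKSim, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "mk_counts.tsv",
        "truth": outdir / "truth" / "mk_truth.tsv",
    }
    rows = [
        {"gene": g, "Dn": c.Dn, "Ds": c.Ds, "Pn": c.Pn, "Ps": c.Ps}
        for g, c in sim.counts.items()
    ]
    pd.DataFrame(rows).to_csv(paths["counts"], sep="\t", index=False)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    if sim.alignments:
        paths["alignments"] = outdir / "mk_alignments.fasta"
        with open(paths["alignments"], "w") as fh:
            for gene, (f1, f2, og) in sim.alignments.items():
                fh.write(f">{gene}|allele1\n{f1}\n>{gene}|allele2\n{f2}\n>{gene}|outgroup\n{og}\n")
    _write_manifest(outdir, sim.config, [p.name for p in paths.values()])
    return paths


def write_expression_dataset(sim: ExprSim, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "fpkm_a": outdir / "fpkm_species_a.tsv",
        "fpkm_b": outdir / "fpkm_species_b.tsv",
        "truth": outdir / "truth" / "expression_truth.tsv",
    }
    for key, table in (("fpkm_a", sim.fpkm_a), ("fpkm_b", sim.fpkm_b)):
        df = pd.DataFrame(
            [(g, p1, p2) for g, (p1, p2) in table.items()],
            columns=["gene", "fpkm_pop1", "fpkm_pop2"],
        )
        df.to_csv(paths[key], sep="\t", index=False, float_format="%.6g")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    _write_manifest(outdir, sim.config, [p.name for p in paths.values()])
    return paths
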