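"""Stage orchestration: each subcommand reads the previous stage's TSVs
from a run directory, writes its own, and appends to the run manifest.

Stages: simulate -> popgen -> outliers (plus annotate, parallelism, mk,
expression, which consume either simulated or user-supplied tables).  The
manifest records the config hash, the seed, and every file a stage wrote,
so a run is reproducible from its directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import AnalysisConfig, config_hash, read_fasta, read_sync
from .annotation import GeneIndex, assign_muller, gene_models_from_gff3
from .mk import MKCounts, classify_sex_bias, evaluate_gene
from .outliers import midp_test, qvalues_per_arm
from .parallelism import matched_bootstrap, overlap_test
from .popgen import window_stats, window_tails
from .expression import (
    direction_split_correlation,
    expressed_orthologs,
    fisher_z_compare,
    log2_fold_change,
    permutation_compare,
    topn_overlap,
)
from .synthetic_data import (
    SimConfig,
    simulate_expression_dataset,
    simulate_mk_dataset,
    simulate_popgen_dataset,
    write_expression_dataset,
    write_mk_dataset,
    write_popgen_dataset,
)

log = logging.getLogger("paradapt")

STAGES = (
    "simulate",
    "popgen",
    "outliers",
    "annotate",
    "parallelism",
    "mk",
    "expression",
)


class MissingStageError(FileNotFoundError):
    """A required upstream output is absent; names the stage to run."""


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"required input {path} is missing; run the '{produced_by}' "
            "subcommand first"
        )
    return path


def _update_manifest(out_dir: Path, stage: str, cfg: AnalysisConfig, outputs: list[Path]):
    manifest_path = out_dir / "manifest.json"
    manifest = {"version": __version__, "stages": []}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append(
        {
            "stage": stage,
            "config_hash": config_hash(cfg),
            "seed": cfg.rng_seed,
            "outputs": sorted(str(p.relative_to(out_dir)) for p in outputs),
        }
    )
    manifest["stages"].sort(key=lambda s: STAGES.index(s["stage"]))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    cfg: AnalysisConfig, stage: str, out_dir: str | Path, sim_config: SimConfig | None = None
) -> list[Path]:
    """Run one stage in ``out_dir``; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = {
        "simulate": _stage_simulate,
        "popgen": _stage_popgen,
        "outliers": _stage_outliers,
        "annotate": _stage_annotate,
        "parallelism": _stage_parallelism,
        "mk": _stage_mk,
        "expression": _stage_expression,
    }.get(stage)
    if runner is None:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage == "simulate":
        outputs = runner(cfg, out_dir, sim_config)
    else:
        outputs = runner(cfg, out_dir)
    _update_manifest(out_dir, stage, cfg, outputs)
    log.info("stage %s wrote %d files", stage, len(outputs))
    return outputs


def _stage_simulate(cfg: AnalysisConfig, out_dir: Path, sim_config: SimConfig | None):
    sim_cfg = sim_config or SimConfig(seed=cfg.rng_seed)
    sim_dir = out_dir / "sim"
    pop = simulate_popgen_dataset(sim_cfg)
    mk = simulate_mk_dataset(sim_cfg)
    expr = simulate_expression_dataset(sim_cfg)
    paths = {}
    paths.update(write_popgen_dataset(pop, sim_dir))
    paths.update(write_mk_dataset(mk, sim_dir))
    paths.update(write_expression_dataset(expr, sim_dir))
    return list(paths.values())


def _stage_popgen(cfg: AnalysisConfig, out_dir: Path):
    sync = _require(out_dir / "sim" / "pools.sync", "simulate")
    fasta = _require(out_dir / "sim" / "reference.fasta", "simulate")
    lengths = {name: len(seq) for name, seq in read_fasta(fasta).items()}
    windows = []
    snp_rows = []
    n_pass = n_reject = 0
    for stat, snps in window_stats(read_sync(sync, 2), lengths, cfg):
        windows.append(stat)
        n_pass += stat.n_sites_covered
        n_reject += cfg.window_size - stat.n_sites_covered
        for snp in snps:
            snp_rows.append(
                {
                    "scaffold": snp.scaffold,
                    "pos": snp.pos,
                    "major": snp.major,
                    "minor": snp.minor,
                    "maj1": snp.counts[0][0],
                    "min1": snp.counts[0][1],
                    "maj2": snp.counts[1][0],
                    "min2": snp.counts[1][1],
                    "fst": snp.fst,
                }
            )
    log.info("popgen: %d sites covered, %d not covered", n_pass, n_reject)
    defined = [w for w in windows if w.defined]
    if defined:
        window_tails(windows, cfg.window_tail_fractions)
    win_df = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in defined],
            "start": [w.start for w in defined],
            "end": [w.end for w in defined],
            "n_covered": [w.n_sites_covered for w in defined],
            "pi_pop1": [w.pi[0] for w in defined],
            "pi_pop2": [w.pi[1] for w in defined],
            "fst": [w.fst for w in defined],
            **{
                f"tail_{f}": [w.tail_flags.get(f, False) for w in defined]
                for f in cfg.window_tail_fractions
            },
        }
    )
    windows_tsv = out_dir / "windows.tsv"
    win_df.to_csv(windows_tsv, sep="\t", index=False, float_format="%.6g")
    windows_bed = out_dir / "windows.bed"
    with open(windows_bed, "w") as fh:
        for w in defined:  # BED is 0-based half-open
            fh.write(f"{w.scaffold}\t{w.start - 1}\t{w.end}\t{w.fst:.6g}\n")
    snps_tsv = out_dir / "snps.tsv"
    pd.DataFrame(snp_rows).to_csv(snps_tsv, sep="\t", index=False, float_format="%.6g")
    return [windows_tsv, windows_bed, snps_tsv]


def _stage_outliers(cfg: AnalysisConfig, out_dir: Path):
    snps_tsv = _require(out_dir / "snps.tsv", "popgen")
    df = pd.read_csv(snps_tsv, sep="\t")
    muller_path = out_dir / "scaffold_muller.tsv"
    arm_of: dict[str, str] = {}
    if muller_path.exists():
        mt = pd.read_csv(muller_path, sep="\t")
        arm_of = dict(zip(mt["scaffold"], mt["muller"].fillna("unassigned")))
    df["arm"] = df["scaffold"].map(lambda s: arm_of.get(s, "unassigned"))

    midp = np.empty(len(df))
    ors = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        res = midp_test(row.maj1, row.min1, row.maj2, row.min2)
        midp[i], ors[i] = res.midp, res.odds_ratio
    df["odds_ratio"] = ors
    df["midp"] = midp
    fdr = qvalues_per_arm(
        {arm: grp["midp"].to_numpy() for arm, grp in df.groupby("arm")}
    )
    df["q"] = np.nan
    for arm, grp in df.groupby("arm"):
        df.loc[grp.index, "q"] = fdr[arm].q_values
    df["outlier"] = (df["q"] <= cfg.outlier_fdr) & (df["fst"] > cfg.outlier_fst)

    outgroup_path = out_dir / "sim" / "outgroup.fasta"
    df["derived"] = ""
    if outgroup_path.exists():
        og = read_fasta(outgroup_path)
        derived = []
        for row in df.itertuples(index=False):
            base = og.get(row.scaffold, "")[row.pos - 1] if row.scaffold in og else None
            alleles = {row.major, row.minor}
            if base in alleles:
                derived.append((alleles - {base}).pop())
            else:
                derived.append("")
        df["derived"] = derived

    tested_tsv = out_dir / "snps_tested.tsv"
    df.to_csv(tested_tsv, sep="\t", index=False, float_format="%.6g")
    summary = pd.DataFrame(
        [
            {
                "arm": arm,
                "n_tests": len(res.p_values),
                "pi0": res.pi0,
                "method": res.method,
                "n_outliers": int(df[df["arm"] == arm]["outlier"].sum()),
            }
            for arm, res in sorted(fdr.items())
        ]
    )
    summary_tsv = out_dir / "arm_summary.tsv"
    summary.to_csv(summary_tsv, sep="\t", index=False, float_format="%.6g")
    return [tested_tsv, summary_tsv]


def _stage_annotate(cfg: AnalysisConfig, out_dir: Path):
    gff3 = _require(out_dir / "sim" / "genes.gff3", "simulate")
    fasta = _require(out_dir / "sim" / "reference.fasta", "simulate")
    snps_tsv = _require(out_dir / "snps_tested.tsv", "outliers")
    genome = read_fasta(fasta)
    genes = gene_models_from_gff3(gff3, scaffolds=genome)
    index = GeneIndex(genes.values())
    df = pd.read_csv(snps_tsv, sep="\t")
    rows = []
    for row in df.itertuples(index=False):
        # classify the minor allele against the reference/major context
        alt = row.minor if row.major == genome[row.scaffold][row.pos - 1] else row.major
        for gene, effect in index.assign(row.scaffold, row.pos, alt, genome):
            rows.append(
                {
                    "scaffold": row.scaffold,
                    "pos": row.pos,
                    "gene": gene.gene_id,
                    "effect": effect,
                    "outlier": bool(row.outlier),
                }
            )
    effects_tsv = out_dir / "snp_effects.tsv"
    pd.DataFrame(rows).to_csv(effects_tsv, sep="\t", index=False)
    outputs = [effects_tsv]
    hits_path = out_dir / "sim" / "muller_hits.tsv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path, sep="\t")
        assignment = assign_muller(
            list(hits[["scaffold", "gene", "element"]].itertuples(index=False))
        )
        muller_tsv = out_dir / "scaffold_muller.tsv"
        pd.DataFrame(
            [{"scaffold": s, "muller": m or "unassigned"} for s, m in sorted(assignment.items())]
        ).to_csv(muller_tsv, sep="\t", index=False)
        outputs.append(muller_tsv)
    return outputs


def _stage_parallelism(cfg: AnalysisConfig, out_dir: Path):
    lists_tsv = _require(out_dir / "gene_lists.tsv", "annotate")
    df = pd.read_csv(lists_tsv, sep="\t")
    species = sorted(df["species"].unique())
    if len(species) != 2:
        raise ValueError("gene_lists.tsv must contain exactly two species")
    a = df[df["species"] == species[0]].set_index("gene")
    b = df[df["species"] == species[1]].set_index("gene")
    universe = sorted(set(a.index) & set(b.index))
    out_a = {g for g in universe if a.loc[g, "outlier"]}
    out_b = {g for g in universe if b.loc[g, "outlier"]}
    k = len(out_a & out_b)
    ov = overlap_test(len(universe), len(out_a), len(out_b), k)
    boot = matched_bootstrap(
        out_a,
        out_b,
        a["nssnp_count"].to_dict(),
        b["nssnp_count"].to_dict(),
        universe,
        reps=cfg.bootstrap_reps,
        seed=cfg.rng_seed,
    )
    overlap_tsv = out_dir / "overlap.tsv"
    pd.DataFrame([asdict(ov)]).to_csv(overlap_tsv, sep="\t", index=False, float_format="%.6g")
    boot_tsv = out_dir / "bootstrap.tsv"
    pd.DataFrame(
        [
            {
                "k_obs": boot.k_obs,
                "expected": boot.expected,
                "fold": boot.fold,
                "p": boot.p,
                "reps": len(boot.replicates),
                "seed": boot.seed,
            }
        ]
    ).to_csv(boot_tsv, sep="\t", index=False, float_format="%.6g")
    return [overlap_tsv, boot_tsv]


def _stage_mk(cfg: AnalysisConfig, out_dir: Path):
    counts_tsv = _require(out_dir / "sim" / "mk_counts.tsv", "simulate")
    df = pd.read_csv(counts_tsv, sep="\t")
    fpkm_path = out_dir / "sim" / "fpkm_sex.tsv"
    sex: dict[str, tuple[float, float]] = {}
    if fpkm_path.exists():
        ft = pd.read_csv(fpkm_path, sep="\t")
        sex = {r.gene: (r.fpkm_male, r.fpkm_female) for r in ft.itertuples(index=False)}
    rows = []
    for row in df.itertuples(index=False):
        rec = evaluate_gene(row.gene, MKCounts(row.Dn, row.Ds, row.Pn, row.Ps))
        if row.gene in sex:
            rec.sex_bias = classify_sex_bias(*sex[row.gene])
        rows.append(
            {
                "gene": rec.gene_id,
                "Dn": rec.counts.Dn,
                "Ds": rec.counts.Ds,
                "Pn": rec.counts.Pn,
                "Ps": rec.counts.Ps,
                "testable": rec.testable,
                "fisher_p": rec.fisher_p,
                "alpha": rec.alpha,
                "dos": rec.dos,
                "adaptive": rec.adaptive,
                "sex_bias": rec.sex_bias,
            }
        )
    mk_tsv = out_dir / "mk_results.tsv"
    pd.DataFrame(rows).to_csv(mk_tsv, sep="\t", index=False, float_format="%.6g")
    return [mk_tsv]


def _stage_expression(cfg: AnalysisConfig, out_dir: Path):
    fa = _require(out_dir / "sim" / "fpkm_species_a.tsv", "simulate")
    fb = _require(out_dir / "sim" / "fpkm_species_b.tsv", "simulate")

    def _load(path):
        df = pd.read_csv(path, sep="\t")
        return {r.gene: (r.fpkm_pop1, r.fpkm_pop2) for r in df.itertuples(index=False)}

    fpkm_a, fpkm_b = _load(fa), _load(fb)
    universe = expressed_orthologs(fpkm_a, fpkm_b)
    ov = topn_overlap(fpkm_a, fpkm_b, universe, top_n=cfg.top_n_expression)
    pairs = [
        (log2_fold_change(*fpkm_a[g]), log2_fold_change(*fpkm_b[g])) for g in universe
    ]
    split = direction_split_correlation(pairs)
    results = {
        "n_expressed": len(universe),
        "overlap_k": ov.k,
        "overlap_expected": ov.expected,
        "overlap_fold": ov.fold,
        "overlap_p": ov.p,
        "r_same": split.r_same,
        "r_opp": split.r_opp,
        "n_same": split.n_same,
        "n_opp": split.n_opp,
    }
    if split.r_same is not None and split.r_opp is not None:
        results["fisher_z_p"] = fisher_z_compare(
            split.r_same, split.n_same, split.r_opp, split.n_opp
        )
        results["permutation_p"] = permutation_compare(
            pairs, reps=cfg.bootstrap_reps, seed=cfg.rng_seed
        )
    expr_tsv = out_dir / "expr_overlap.tsv"
    pd.DataFrame([results]).to_csv(expr_tsv, sep="\t", index=False, float_format="%.6g")
    ranks_tsv = out_dir / "expr_ranks.tsv"
    pd.DataFrame(
        [
            {
                "gene": g,
                "lfc_a": la,
                "lfc_b": lb,
            }
            for g, (la, lb) in zip(universe, pairs)
        ]
    ).to_csv(ranks_tsv, sep="\t", index=False, float_format="%.6g")
    return [expr_tsv, ranks_tsv]
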