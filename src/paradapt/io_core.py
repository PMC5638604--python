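"""Readers, writers and configuration for the pipeline's external formats.

The central text format is "sync" (one line per genomic site, one
``A:T:C:G:N:del`` read-count sextet per population pool), the de-facto
interchange format of pooled-sequencing variant callers.  Gene models come
in as GFF3 + genome FASTA, everything else as plain TSV.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "SiteCounts",
    "AnalysisConfig",
    "GenomeSizeEstimate",
    "SyncParseError",
    "SyncOrderError",
    "read_sync",
    "write_sync",
    "read_fasta",
    "read_gff3",
    "estimate_genome_size",
    "load_config",
    "config_hash",
]

#: order of the bases inside a sync count sextet
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
#: indices of real base calls (N and deletions never count toward coverage)
BASE_SLOTS = (0, 1, 2, 3)


class SyncParseError(ValueError):
    """A sync line could not be parsed; the message names the line number."""


class SyncOrderError(ValueError):
    """Positions within a scaffold were not strictly increasing."""


@dataclass(frozen=True)
class SiteCounts:
    """Per-site read counts for every population pool.

    ``pools`` is an ordered tuple of (A, T, C, G, N, del) count sextets, one
    per pool; pool order is fixed for a whole dataset.  Coverage and allele
    frequencies are always computed from the four base slots only.
    """

    scaffold: str
    pos: int  # 1-based
    ref: str
    pools: tuple[tuple[int, int, int, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for sextet in self.pools:
            if len(sextet) != 6 or any(c < 0 for c in sextet):
                raise ValueError(f"malformed count sextet {sextet!r}")

    def coverage(self, pool: int) -> int:
        """Base-call coverage of one pool (A+T+C+G; N and del excluded)."""
        sextet = self.pools[pool]
        return sum(sextet[i] for i in BASE_SLOTS)

    def base_counts(self, pool: int) -> dict[str, int]:
        sextet = self.pools[pool]
        return {SYNC_BASES[i]: sextet[i] for i in BASE_SLOTS}

    def combined_base_counts(self) -> dict[str, int]:
        """Base counts summed over all pools."""
        out = {SYNC_BASES[i]: 0 for i in BASE_SLOTS}
        for sextet in self.pools:
            for i in BASE_SLOTS:
                out[SYNC_BASES[i]] += sextet[i]
        return out


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the scan, with the study's defaults.

    Defaults: 20x minimum per-pool site coverage, >=2 alternate base calls
    across the dataset for the differentiation scan, >=3 minor-allele calls
    for the MK SNP set, 1-kb windows analysed when at least half their sites
    are covered, outliers at q <= 1e-5 with F_ST > 0.15, window tails at
    1% / 2.5% / 5%, 1000 bootstrap replicates, top-300 expression ranks and
    top-400 SNP-ranked genes.
    """

    min_site_coverage: int = 20
    min_alt_observations_popgen: int = 2
    min_minor_allele_mk: int = 3
    window_size: int = 1000
    min_window_covered_fraction: float = 0.5
    outlier_fdr: float = 1e-5
    outlier_fst: float = 0.15
    window_tail_fractions: tuple[float, ...] = (0.01, 0.025, 0.05)
    bootstrap_reps: int = 1000
    top_n_expression: int = 300
    top_n_snps: int = 400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_site_coverage",
            "min_alt_observations_popgen",
            "min_minor_allele_mk",
            "window_size",
            "min_window_covered_fraction",
            "outlier_fdr",
            "outlier_fst",
            "bootstrap_reps",
            "top_n_expression",
            "top_n_snps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.window_tail_fractions = tuple(sorted(self.window_tail_fractions))
        if any(not (0.0 < f < 1.0) for f in self.window_tail_fractions):
            raise ValueError("window tail fractions must lie in (0, 1)")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """k-mer based genome size: total k-mers divided by mean k-mer depth."""

    kmer_num: float
    kmer_depth: float
    size_bp: float


def estimate_genome_size(kmer_num: float, kmer_depth: float) -> GenomeSizeEstimate:
    """Estimate genome size as G = kmer_num / kmer_depth.

    ``kmer_num`` is the total number of k-mers observed across all reads and
    ``kmer_depth`` their modal/average depth; both must be positive.
    """
    if kmer_num <= 0 or kmer_depth <= 0:
        raise ValueError("kmer_num and kmer_depth must both be positive")
    return GenomeSizeEstimate(kmer_num, kmer_depth, kmer_num / kmer_depth)


def _parse_sextet(token: str, lineno: int) -> tuple[int, ...]:
    parts = token.split(":")
    if len(parts) != 6:
        raise SyncParseError(
            f"line {lineno}: count field {token!r} has {len(parts)} entries, expected 6"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise SyncParseError(f"line {lineno}: non-integer count in {token!r}") from exc
    if any(c < 0 for c in counts):
        raise SyncParseError(f"line {lineno}: negative count in {token!r}")
    return counts


def read_sync(path: str | Path, n_pools: int) -> Iterator[SiteCounts]:
    """Stream `SiteCounts` from a sync file.

    Each data line must carry ``3 + n_pools`` tab-separated fields
    (scaffold, 1-based position, reference base, then one ``A:T:C:G:N:del``
    sextet per pool).  Positions must be strictly increasing within a
    scaffold; blank lines and ``#`` comments are ignored.
    """
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise SyncParseError(
                    f"line {lineno}: expected {3 + n_pools} fields, got {len(fields)}"
                )
            scaffold, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: bad position {pos_s!r}") from exc
            if scaffold in last and pos <= last[scaffold]:
                raise SyncOrderError(
                    f"line {lineno}: position {pos} on {scaffold} not greater "
                    f"than previous position {last[scaffold]}"
                )
            last[scaffold] = pos
            pools = tuple(_parse_sextet(tok, lineno) for tok in fields[3:])
            yield SiteCounts(scaffold, pos, ref, pools)


def write_sync(path: str | Path, sites: Sequence[SiteCounts] | Iterator[SiteCounts]) -> None:
    with open(path, "w") as fh:
        for site in sites:
            sextets = "\t".join(":".join(str(c) for c in s) for s in site.pools)
            fh.write(f"{site.scaffold}\t{site.pos}\t{site.ref}\t{sextets}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {scaffold id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path: str | Path, scaffolds: dict[str, str] | None = None):
    """Parse GFF3 gene models; see `paradapt.annotation.gene_models_from_gff3`.

    When ``scaffolds`` (from `read_fasta`) is given, every gene's seqid is
    checked against it and a missing scaffold raises ``KeyError``.
    """
    from .annotation import gene_models_from_gff3

    return gene_models_from_gff3(path, scaffolds=scaffolds)


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build an `AnalysisConfig` from an optional TOML file plus overrides.

    CLI flags (the overrides) take precedence over file values; ``None``
    overrides are ignored so flags can be optional.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    if "window_tail_fractions" in values:
        values["window_tail_fractions"] = tuple(values["window_tail_fractions"])
    cfg = AnalysisConfig(**values)
    return cfg.with_overrides(**overrides)


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable short hash of a config, for run manifests."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
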