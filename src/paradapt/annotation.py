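"""Gene models, SNP effect classification and Muller-element assignment.

A SNP is attached to every gene whose transcript span (padded by 1 kb of
flank on each side, boundary inclusive) contains it, then classified into
exactly one effect class per gene with priority CDS > UTR > intron >
flanking.  Coding changes are classified by substituting the alternate
allele into the reference codon and translating with the standard nuclear
code; minus-strand genes are handled in transcript orientation.

Scaffolds are tied to Muller elements (the six ancestral Drosophila
chromosome arms, A-F) by majority vote of their genes' best cross-species
alignment hits: an element is assigned iff at least 55% of a scaffold's
genes agree on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "EFFECT_CLASSES",
    "FLANK_BP",
    "gene_models_from_gff3",
    "GeneIndex",
    "classify_effect",
    "assign_muller",
]

#: flank distance around the transcript span, inclusive of the boundary base
FLANK_BP = 1000

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "intronic", "UTR3", "UTR5", "flanking")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneModel:
    """One gene with a single (longest-CDS) transcript model.

    All coordinates are 1-based inclusive genomic intervals.  ``cds`` holds
    (start, end, phase) in genomic order; transcription order is derived
    from the strand.
    """

    gene_id: str
    scaffold: str
    strand: str  # '+' or '-'
    start: int  # transcript span
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    muller: str | None = None
    orthologs: dict[str, str] = field(default_factory=dict)
    untranslatable: bool = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def cds_in_transcription_order(self) -> list[tuple[int, int, int]]:
        ordered = sorted(self.cds)
        return ordered if self.strand == "+" else ordered[::-1]

    def contains(self, pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        """CDS sequence in transcript orientation, phase-trimmed to frame."""
        seq = "".join(
            genome[self.scaffold][s - 1 : e] for s, e, _ in sorted(self.cds)
        )
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        first_phase = self.cds_in_transcription_order()[0][2] if self.cds else 0
        return seq[first_phase:]

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the phase-trimmed CDS."""
        offset = 0
        for s, e, _ in self.cds_in_transcription_order():
            if s <= pos <= e:
                offset += (pos - s) if self.strand == "+" else (e - pos)
                first_phase = self.cds_in_transcription_order()[0][2]
                offset -= first_phase
                return offset if offset >= 0 else None
            offset += e - s + 1
        return None


def _feature_children(db, parent, featuretype):
    return sorted(
        (f.start, f.end, int(f.frame) if f.frame not in (".", None) else 0)
        for f in db.children(parent, featuretype=featuretype)
    )


def gene_models_from_gff3(
    path: str | Path, scaffolds: Mapping[str, str] | None = None
) -> dict[str, GeneModel]:
    """Parse a GFF3 file into `GeneModel` objects, one transcript per gene.

    When a gene has several mRNA isoforms the one with the longest total CDS
    is kept.  Genes whose CDS length is not a multiple of three after phase
    adjustment are flagged ``untranslatable`` (and a warning is emitted) but
    still returned for non-coding classification.
    """
    import warnings

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        if scaffolds is not None and gene.seqid not in scaffolds:
            raise KeyError(
                f"gene {gene.id} references scaffold {gene.seqid!r} absent from FASTA"
            )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        best, best_len = None, -1
        for parent in parents:
            cds = _feature_children(db, parent, "CDS")
            total = sum(e - s + 1 for s, e, _ in cds)
            if total > best_len:
                best, best_len = parent, total
        parent = best
        exons = [(s, e) for s, e, _ in _feature_children(db, parent, "exon")]
        cds = _feature_children(db, parent, "CDS")
        utr5 = [(s, e) for s, e, _ in _feature_children(db, parent, "five_prime_UTR")]
        utr3 = [(s, e) for s, e, _ in _feature_children(db, parent, "three_prime_UTR")]
        model = GeneModel(
            gene_id=gene.id,
            scaffold=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            start=parent.start,
            end=parent.end,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
        )
        if cds:
            first_phase = model.cds_in_transcription_order()[0][2]
            if (model.cds_length - first_phase) % 3 != 0:
                model.untranslatable = True
                warnings.warn(
                    f"gene {gene.id}: CDS length {model.cds_length} not a multiple "
                    "of 3 after phase adjustment; flagged untranslatable"
                )
        models[gene.id] = model
    return models


class GeneIndex:
    """Interval index answering 'which genes does this SNP belong to?'.

    Membership means lying within the transcript span extended by
    `FLANK_BP` on each side (inclusive).
    """

    def __init__(self, genes: Iterable[GeneModel], flank: int = FLANK_BP):
        self.flank = flank
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.scaffold, IntervalTree())
            lo = max(1, g.start - flank)
            # half-open interval end
            tree[lo : g.end + flank + 1] = g

    def genes_at(self, scaffold: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.gene_id)

    def assign(self, scaffold: str, pos: int, alt: str, genome: Mapping[str, str]):
        """All (gene, effect class) records for one SNP; may be empty."""
        out = []
        for gene in self.genes_at(scaffold, pos):
            eff = classify_effect(pos, alt, gene, genome)
            if eff is not None:
                out.append((gene, eff))
        return out


def classify_effect(
    pos: int,
    alt: str,
    gene: GeneModel,
    genome: Mapping[str, str],
    ref: str | None = None,
) -> str | None:
    """Classify one SNP relative to one gene.

    Returns one of `EFFECT_CLASSES`, or ``None`` when the affected codon
    contains an ambiguous base (excluded from coding analyses).  Priority
    when features overlap: CDS > UTR > intron > flanking.  When the SNP's
    recorded reference allele ``ref`` is supplied it is checked against the
    genome sequence.
    """
    if ref is not None and genome[gene.scaffold][pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {gene.scaffold}:{pos}: SNP record has "
            f"{ref}, FASTA has {genome[gene.scaffold][pos - 1]}"
        )
    in_cds = any(s <= pos <= e for s, e, _ in gene.cds)
    if in_cds:
        if gene.untranslatable:
            return None
        offset = gene.cds_offset(pos)
        if offset is None:  # inside the phase-trimmed prefix; no full codon
            return None
        cds_seq = gene.spliced_cds(genome)
        tx_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        codon_start = 3 * (offset // 3)
        codon = cds_seq[codon_start : codon_start + 3]
        if len(codon) < 3 or "N" in codon or tx_alt == "N":
            return None
        mutant = codon[: offset % 3] + tx_alt + codon[offset % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutant).translate())
        return "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    if gene.contains(pos, gene.utr5):
        return "UTR5"
    if gene.contains(pos, gene.utr3):
        return "UTR3"
    if gene.start <= pos <= gene.end:
        return "intronic"
    return "flanking"


def assign_muller(
    best_hits: Iterable[tuple[str, str, str]], threshold: float = 0.55
) -> dict[str, str | None]:
    """Assign scaffolds to Muller elements by the majority-vote rule.

    ``best_hits`` holds (scaffold, gene, element) rows; duplicates are
    ignored.  A scaffold gets element X iff at least ``threshold`` (55%) of
    its distinct genes have their best alignment on X; otherwise it is left
    unassigned (``None``).  Scaffolds with no annotated genes are unassigned.
    """
    votes: dict[str, dict[str, set[str]]] = {}
    for scaffold, gene, element in best_hits:
        votes.setdefault(scaffold, {}).setdefault(element, set()).add(gene)
    out: dict[str, str | None] = {}
    for scaffold, by_element in votes.items():
        genes_seen: set[str] = set()
        for g in by_element.values():
            genes_seen |= g
        n = len(genes_seen)
        out[scaffold] = None
        if n == 0:
            continue
        best_el, best_count = None, -1
        for element in sorted(by_element):
            count = len(by_element[element])
            if count > best_count:
                best_el, best_count = element, count
        if best_count / n >= threshold:
            out[scaffold] = best_el
    return out
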