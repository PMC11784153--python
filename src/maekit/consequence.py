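"""Lightweight variant-consequence annotation against CDS gene models.

"Coding" means inside the CDS footprint only (introns and UTRs count as
non-coding).  SNV consequences come from codon comparison on the gene
strand with the standard nuclear codon table; CDS indels are frameshift
or in-frame by length mod 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import GeneModel, Genome, Variant, revcomp

CONSEQUENCES = ("missense", "synonymous", "stop_gained", "stop_lost",
                "start_lost", "frameshift", "inframe_indel", "noncoding")

#: Severity order used when a variant hits multiple genes (most severe first).
SEVERITY = ("frameshift", "stop_gained", "stop_lost", "start_lost",
            "missense", "inframe_indel", "synonymous", "noncoding")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else _STANDARD.forward_table.get(codon, "X")


@dataclass
class Annotation:
    consequence: str
    gene_ids: list[str] = field(default_factory=list)
    all_consequences: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


class GeneIndex:
    """Interval index of CDS segments for fast variant overlap lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for seg_idx, (s, e) in enumerate(g.cds):
                if e > s:
                    tree[s:e] = (g, seg_idx)

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(start, end),
                      key=lambda iv: iv.data[0].gene_id)

    def cds_footprint(self, genome: Genome) -> int:
        """Total bases covered by at least one CDS segment."""
        total = 0
        for chrom, tree in self._trees.items():
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total


def _cds_coordinate(gene: GeneModel, pos: int) -> int:
    """Position within the spliced CDS (transcription direction)."""
    segs = sorted(gene.cds)
    if gene.strand == "+":
        offset = 0
        for s, e in segs:
            if s <= pos < e:
                return offset + (pos - s)
            offset += e - s
    else:
        offset = 0
        for s, e in reversed(segs):
            if s <= pos < e:
                return offset + (e - 1 - pos)
            offset += e - s
    raise ValueError("position not inside CDS")


def _snv_consequence(v: Variant, gene: GeneModel, genome: Genome) -> tuple[str, list[str]]:
    flags = []
    if gene.flags:
        return "noncoding", ["unannotatable: " + ";".join(gene.flags)]
    cds_seq = gene.spliced_cds(genome)
    cpos = _cds_coordinate(gene, v.pos)
    alt_base = v.alt if gene.strand == "+" else revcomp(v.alt)
    codon_i = cpos // 3
    ref_codon = cds_seq[codon_i * 3: codon_i * 3 + 3]
    if len(ref_codon) < 3:
        return "noncoding", ["unannotatable: truncated terminal codon"]
    alt_codon = (ref_codon[: cpos % 3] + alt_base + ref_codon[cpos % 3 + 1:])
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost", flags
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost", flags
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained", flags
    if ref_aa == alt_aa:
        return "synonymous", flags
    return "missense", flags


def annotate(v: Variant, index: GeneIndex, genome: Genome) -> Annotation:
    """Consequence of one normalized variant.

    A variant hitting several genes reports the most severe consequence
    first, with the full per-gene list retained.  Indels spanning a CDS
    boundary are flagged and counted as coding (frameshift/in-frame by
    length).
    """
    span_start = v.pos
    span_end = v.pos + len(v.ref)
    if v.is_indel and len(v.alt) < len(v.ref):
        span_start = v.pos + len(v.alt)  # deleted bases only
    hits = index.overlapping(v.chrom, span_start, span_end)
    if not hits:
        return Annotation("noncoding")
    per_gene: dict[str, str] = {}
    flags: list[str] = []
    for iv in hits:
        gene, _ = iv.data
        if gene.gene_id in per_gene:
            continue
        if v.is_snv:
            cons, gflags = _snv_consequence(v, gene, genome)
            flags.extend(gflags)
        else:
            inside = (iv.begin <= span_start and span_end <= iv.end)
            if not inside:
                flags.append(f"boundary-spanning:{gene.gene_id}")
            cons = "frameshift" if v.indel_length % 3 else "inframe_indel"
        per_gene[gene.gene_id] = cons
    ordered = sorted(per_gene.items(), key=lambda kv: SEVERITY.index(kv[1]))
    return Annotation(
        consequence=ordered[0][1],
        gene_ids=[g for g, _ in ordered],
        all_consequences=[c for _, c in ordered],
        flags=flags,
    )


def annotate_all(variants: Sequence[Variant], genes: Iterable[GeneModel],
                 genome: Genome) -> list[Annotation]:
    index = GeneIndex(genes)
    return [annotate(v, index, genome) for v in variants]


@dataclass
class CodingFractionTest:
    n_coding: int
    n_noncoding: int
    coding_fraction_genome: float
    statistic: float
    pvalue: float


def coding_fraction_test(variants: Sequence[Variant],
                         genes: Iterable[GeneModel],
                         genome: Genome) -> CodingFractionTest:
    """Chi-squared (1 df) test of coding vs non-coding variant counts
    against the genomic CDS footprint fraction."""
    if not variants:
        raise ValueError("no variants to test")
    index = GeneIndex(genes)
    anns = [annotate(v, index, genome) for v in variants]
    n_coding = sum(1 for a in anns if a.consequence != "noncoding")
    n_non = len(anns) - n_coding
    frac = index.cds_footprint(genome) / genome.total_length
    n = len(anns)
    expected = [n * frac, n * (1 - frac)]
    chi2, p = stats.chisquare([n_coding, n_non], expected)
    return CodingFractionTest(n_coding, n_non, frac, float(chi2), float(p))
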