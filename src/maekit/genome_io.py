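"""Reference genome, gene model, and variant I/O.

Fixes the coordinate and allele conventions used by every downstream
module: internal coordinates are 0-based half-open, VCF I/O is 1-based,
and indels are left-aligned and parsimony-trimmed against the reference
(the standard VCF normalization convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Malformed genome input (bad alphabet, duplicate records, empty file)."""


class VariantError(ValueError):
    """Malformed or inconsistent variant record."""


@dataclass
class Genome:
    """Reference genome held in memory as uppercase nucleotide strings.

    Only {A, C, G, T, N} are permitted; soft-masked (lowercase) input is
    uppercased on load, discarding the masking.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice [start, end) of a chromosome; out-of-range is an error."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise GenomeError(
                f"fetch {chrom}:{start}-{end} outside [0, {len(seq)})"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)


@dataclass
class GeneModel:
    """Single-transcript gene: ordered CDS intervals on one strand.

    ``cds`` holds 0-based half-open (start, end) genomic intervals ordered
    in transcription direction (descending genomic order on the minus
    strand). ``phases`` gives the GFF3 phase of each segment.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                self.flags.append("overlapping_cds")
                break
        if not self.phases:
            self.phases = [0] * len(self.cds)
        total = sum(e - s for s, e in self.cds)
        if self.phases and (total - self.phases[0]) % 3 != 0:
            self.flags.append("cds_length_not_multiple_of_3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def spliced_cds(self, genome: Genome) -> str:
        """CDS sequence in transcription direction (reverse-complemented on -)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in sorted(self.cds)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class Variant:
    """One called small variant in internal (0-based, left-aligned) form.

    For indels the anchor-base representation is kept: one allele is a
    strict prefix of the other, e.g. ref="CA", alt="C" for a 1 bp deletion.
    """

    line_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantError("empty allele; use anchor-base representation")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if len(self.ref) != len(self.alt):
            short, long_ = sorted((self.ref, self.alt), key=len)
            if not long_.startswith(short):
                raise VariantError(
                    f"indel alleles not in prefix form: {self.ref}>{self.alt}"
                )

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snv(self) -> bool:
        return self.vclass == "SNV"

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("insertion", "deletion")

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted bases (without the anchor)."""
        if len(self.alt) > len(self.ref):
            return self.alt[len(self.ref):]
        return self.ref[len(self.alt):]


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Load a (possibly multi-record) FASTA into a :class:`Genome`.

    Sequences are uppercased; duplicate record names and non-nucleotide
    characters are errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeError(f"duplicate FASTA record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3: CDS features grouped by Parent.

    CDS rows are grouped by their Parent attribute (falling back to ID);
    segment order follows transcription direction.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    grouped: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or ["?"]
        grouped.setdefault(parents[0], []).append(cds)
    genes = []
    for gid, segs in grouped.items():
        strand = segs[0].strand if segs[0].strand in "+-" else "+"
        segs.sort(key=lambda c: c.start, reverse=(strand == "-"))
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=segs[0].seqid,
                strand=strand,
                cds=[(c.start - 1, c.end) for c in segs],
                phases=[int(c.frame) if c.frame not in (None, ".") else 0 for c in segs],
            )
        )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene + CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gstart = min(s for s, _ in g.cds)
            gend = max(e for _, e in g.cds)
            fh.write(
                f"{g.chrom}\tmaekit\tgene\t{gstart + 1}\t{gend}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for (s, e), ph in zip(g.cds, g.phases):
                fh.write(
                    f"{g.chrom}\tmaekit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )


def gc_content(genome: Genome) -> float:
    """Genome GC fraction: (#G + #C) / (#A + #C + #G + #T); N ignored."""
    gc = at = 0
    for seq in genome.sequences.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise GenomeError("genome contains no unambiguous bases")
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Allele normalization
# ---------------------------------------------------------------------------

def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      genome: Genome) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an allele pair against the reference.

    Standard variant-normalization algorithm: repeatedly strip a shared
    trailing base (extending left with the reference base when an allele
    would empty), then strip shared leading bases. Idempotent; SNVs pass
    through unchanged. ``pos`` is 0-based.
    """
    seq = genome.sequences[chrom]
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and \
                (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    raise VariantError(
                        f"cannot left-extend past start of {chrom} while "
                        f"normalizing {ref}>{alt}"
                    )
                pos -= 1
                base = seq[pos]
                ref, alt = base + ref, base + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _check_ref(v: Variant, genome: Genome) -> None:
    observed = genome.fetch(v.chrom, v.pos, v.pos + len(v.ref))
    if observed != v.ref:
        raise VariantError(
            f"ref mismatch at {v.chrom}:{v.pos + 1} (1-based): variant says "
            f"{v.ref!r}, genome has {observed!r}"
        )


def _make_variants(line_id: str, chrom: str, pos1: int, ref: str,
                   alts: Iterable[str], genome: Genome) -> Iterator[Variant]:
    """Split multi-allelic records, normalize, ref-check.

    Multi-nucleotide substitutions (|ref| == |alt| > 1 after trimming) are
    rejected with a warning rather than silently split into SNVs.
    """
    for alt in alts:
        if alt is None or alt in (".", "*", "<NON_REF>"):
            continue
        pos, nref, nalt = normalize_variant(chrom, pos1 - 1, ref, alt, genome)
        if len(nref) == len(nalt) and len(nref) > 1:
            warnings.warn(
                f"multi-nucleotide substitution {nref}>{nalt} at "
                f"{chrom}:{pos + 1} rejected (not a supported class)",
                stacklevel=3,
            )
            continue
        v = Variant(line_id, chrom, pos, nref, nalt)
        _check_ref(v, genome)
        yield v


def read_variants(path: str | Path, genome: Genome, line_id: str) -> list[Variant]:
    """Read variants from a VCF v4.x file or a 4-column TSV.

    The TSV dialect has a header row ``chrom  pos_1based  ref  alt``.
    Alleles are left-aligned/trimmed and ref-checked against ``genome``;
    multi-allelic VCF records are split into one variant per alt.
    """
    path = Path(path)
    out: list[Variant] = []
    if path.suffix.lower() in (".tsv", ".txt", ".tab"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        for row in df.itertuples(index=False):
            out.extend(
                _make_variants(line_id, str(row.chrom), int(row.pos_1based),
                               row.ref, str(row.alt).split(","), genome)
            )
    else:
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        for rec in vcf:
            out.extend(
                _make_variants(line_id, rec.CHROM, rec.POS, rec.REF,
                               rec.ALT, genome)
            )
        vcf.close()
    return out


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=maekit\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_variants(variants: Iterable[Variant], path: str | Path,
                   genome: Genome | None = None) -> None:
    """Write variants to a minimal sites-only VCF (1-based positions)."""
    variants = list(variants)
    with open(path, "w") as fh:
        if genome is not None:
            fh.write("##fileformat=VCFv4.2\n##source=maekit\n")
            for name, seq in genome.sequences.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        else:
            fh.write(VCF_HEADER)
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")
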