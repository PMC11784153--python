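"""Synthetic mutation-accumulation experiment generator.

Produces complete, deterministic test datasets — genome, gene annotation,
per-line variants, depth tracks, and a ground-truth record — with the
statistical structure the analysis modules assume:

* event counts per line are Poisson with mean ``rate * N * cycles * t``
  (independent divisions, negligible selection — the MAE design);
* substitutions are placed with configurable trinucleotide-context bias
  (importance sampling over precomputed eligible-site indices);
* slippage indels expand or contract mononucleotide runs by whole units,
  the remainder is rejection-sampled into non-repeat sites;
* rare whole-chromosome and segmental copy-number events;
* per-window read depth is Poisson(mean_depth * copy_state).

The built-in condition presets carry the per-class rate magnitudes
observed for spontaneous growth and for UV, MMS, and Zeocin mutagenesis
of *Yarrowia lipolytica* (per-base rates of order 1e-11 to 1e-8 per
division, a 5'-G-pyrimidine bias for the Zeocin radiomimetic, a 5'
pyrimidine bias for UV photoproducts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import Genome, GeneModel, Variant, revcomp, normalize_variant
from .rates import LineRecord
from .spectrum import SUBSTITUTION_CLASSES, PURINES
from .indels import repeat_context, DEFAULT_MIN_COPIES
from .structural import DepthTrack

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

INDEL_BINS = ("del1", "ins1", "del2", "ins2", "del3+", "ins3+")


@dataclass
class ConditionProfile:
    """Generative parameters for one growth/mutagenesis condition.

    Rates are per base per cell division (SNV/indel) or per cell division
    (structural). ``context_bias`` maps a substitution class to relative
    weights over pyrimidine-normalized trinucleotides (default weight 1).
    """

    label: str
    snv_rates: dict[str, float]          # per SUBSTITUTION_CLASSES entry
    indel_rates: dict[str, float]        # per INDEL_BINS entry
    context_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    slippage_fraction: float = 0.82
    aneuploidy_rate: float = 0.0         # per cell division
    rearrangement_rate: float = 0.0      # per cell division

    def __post_init__(self) -> None:
        if not 0 <= self.slippage_fraction <= 1:
            raise ValueError("slippage_fraction must lie in [0, 1]")
        for d in (self.snv_rates, self.indel_rates):
            if any(r < 0 for r in d.values()):
                raise ValueError("rates must be >= 0")

    @property
    def total_snv_rate(self) -> float:
        return sum(self.snv_rates.values())

    @property
    def total_indel_rate(self) -> float:
        return sum(self.indel_rates.values())


def _scale(weights: dict[str, float], total: float) -> dict[str, float]:
    s = sum(weights.values())
    return {k: total * w / s for k, w in weights.items()}


# Per-class rate magnitudes and context biases for the built-in presets.
# Spontaneous SNVs are transition-heavy (C>T 43%, C>A 19% of events);
# Zeocin SNVs sit on thymines downstream of a 5' G (T>A about twice T>G);
# UV is dominated by C>T at dipyrimidines; MMS elevates T>A / T>G.
PRESETS: dict[str, ConditionProfile] = {
    "spontaneous": ConditionProfile(
        label="spontaneous",
        snv_rates=_scale({"C>A": 0.19, "C>G": 0.08, "C>T": 0.43,
                          "T>A": 0.09, "T>C": 0.13, "T>G": 0.08}, 2.07e-10),
        indel_rates={"del1": 8.36e-11, "ins1": 4.27e-11, "del2": 0.59e-11,
                     "ins2": 1.25e-11, "del3+": 0.92e-11, "ins3+": 0.67e-11},
        slippage_fraction=0.82,
        aneuploidy_rate=1.71e-5,
        rearrangement_rate=5.14e-5,
    ),
    "uv": ConditionProfile(
        label="uv",
        snv_rates=_scale({"C>A": 0.06, "C>G": 0.04, "C>T": 0.70,
                          "T>A": 0.08, "T>C": 0.08, "T>G": 0.04}, 1.104e-8),
        indel_rates={"del1": 29.08e-11, "ins1": 20.64e-11, "del2": 4.69e-11,
                     "ins2": 5.63e-11, "del3+": 5.63e-11, "ins3+": 1.88e-11},
        context_bias={
            "C>T": {f"{five}C{three}": 5.0
                    for five in "CT" for three in "ACGT"},
            "T>C": {"TTA": 5.0}, "T>A": {"TTA": 5.0},
        },
        slippage_fraction=0.8,
        rearrangement_rate=5.77e-4,
    ),
    "mms": ConditionProfile(
        label="mms",
        snv_rates=_scale({"C>A": 0.05, "C>G": 0.02, "C>T": 0.33,
                          "T>A": 0.30, "T>C": 0.10, "T>G": 0.20}, 6.91e-9),
        indel_rates={"del1": 11.58e-11, "ins1": 11.58e-11, "del2": 0.0,
                     "ins2": 0.0, "del3+": 0.0, "ins3+": 0.0},
        context_bias={
            "T>C": {"GTC": 5.0}, "T>A": {"GTC": 5.0},
            "T>G": {"CTG": 5.0, "GTG": 5.0},
        },
        slippage_fraction=0.8,
        rearrangement_rate=3.39e-4,
    ),
    "zeocin": ConditionProfile(
        label="zeocin",
        snv_rates=_scale({"C>A": 0.15, "C>G": 0.03, "C>T": 0.12,
                          "T>A": 0.38, "T>C": 0.14, "T>G": 0.18}, 5.32e-9),
        indel_rates={"del1": 149.54e-11, "ins1": 36.78e-11, "del2": 27.99e-11,
                     "ins2": 7.20e-11, "del3+": 173.53e-11, "ins3+": 5.60e-11},
        context_bias={
            "T>A": {f"GT{three}": 5.0 for three in "ACGT"},
            "T>G": {f"GT{three}": 5.0 for three in "ACGT"},
            "T>C": {"GTA": 5.0},
            "C>A": {"GCC": 5.0}, "C>T": {"GCA": 5.0},
        },
        slippage_fraction=0.8,
        rearrangement_rate=1.64e-4,
    ),
}


@dataclass
class TruthSet:
    """Record-for-record ground truth for a simulated experiment."""

    condition: str
    lines: dict[str, dict] = field(default_factory=dict)

    def add_line(self, line_id: str) -> dict:
        rec = {"snvs": [], "indels": [], "cnvs": []}
        self.lines[line_id] = rec
        return rec

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"condition": self.condition, "lines": self.lines},
                      fh, indent=1)


# ---------------------------------------------------------------------------
# Genome + gene generation
# ---------------------------------------------------------------------------

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _markov_sequence(length: int, gc: float, boost: float,
                     rng: np.random.Generator) -> str:
    """First-order Markov nucleotide chain with self-transition boost.

    ``boost == 1`` gives i.i.d. draws at the stationary composition; a
    boost > 1 multiplies the probability of repeating the previous base,
    inflating homopolymer run lengths.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = "ACGT"
    if boost == 1.0:
        idx = rng.choice(4, size=length, p=p)
        return "".join(bases[i] for i in idx)
    cum = np.empty((4, 4))
    for i in range(4):
        row = p.copy()
        row[i] *= boost
        row /= row.sum()
        cum[i] = np.cumsum(row)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    state = int(rng.choice(4, p=p))
    for n in range(length):
        row = cum[state]
        x = u[n]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[n] = state
    return "".join(bases[i] for i in out)


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + TAA; ``length`` % 3 == 0."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    bases = "ACGT"
    while len(codons) < length // 3 - 1:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOP_CODONS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def generate_genome(length: int = 100_000, gc: float = 0.5,
                    homopolymer_boost: float = 1.0, n_genes: int = 20,
                    seed: int = 0, n_chromosomes: int = 1,
                    gene_length_range: tuple[int, int] = (300, 1500),
                    ) -> tuple[Genome, list[GeneModel]]:
    """Simulate a genome and non-overlapping single-CDS genes.

    The background is a (possibly homopolymer-boosted) Markov chain at GC
    fraction ``gc``; genes are complete ORFs written into the sequence on
    random strands. Deterministic given ``seed``.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb for meaningful tests")
    rng = np.random.default_rng(seed)
    chrom_len = length // n_chromosomes
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    genes_per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        genes_per_chrom[i] += 1
    for ci in range(n_chromosomes):
        name = f"chr{ci + 1}"
        seq = list(_markov_sequence(chrom_len, gc, homopolymer_boost, rng))
        n_here = genes_per_chrom[ci]
        if n_here:
            slot = chrom_len // n_here
            if slot < gene_length_range[1] + 200:
                raise ValueError("infeasible gene packing: genome too small "
                                 f"for {n_genes} genes up to {gene_length_range[1]} bp")
            for gi in range(n_here):
                glen = int(rng.integers(gene_length_range[0] // 3,
                                        gene_length_range[1] // 3 + 1)) * 3
                lo = gi * slot + 100
                hi = (gi + 1) * slot - glen - 100
                start = int(rng.integers(lo, max(lo + 1, hi)))
                strand = "+" if rng.random() < 0.5 else "-"
                orf = _random_orf(glen, rng)
                placed = orf if strand == "+" else revcomp(orf)
                seq[start:start + glen] = list(placed)
                genes.append(GeneModel(
                    gene_id=f"gene_{name}_{gi + 1}", chrom=name,
                    strand=strand, cds=[(start, start + glen)],
                ))
        sequences[name] = "".join(seq)
    return Genome(sequences), genes


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

class _SitePicker:
    """Importance sampler of SNV sites with per-class context weights."""

    def __init__(self, genome: Genome, profile: ConditionProfile):
        self.positions: dict[str, np.ndarray] = {}   # class-independent, per center
        self.chrom_of: dict[str, np.ndarray] = {}
        self._probs: dict[str, np.ndarray] = {}
        chrom_names = list(genome.sequences)
        # Flatten genome into (chrom index, position) with normalized center
        # base and oriented trinucleotide per site.
        ctx_per_center: dict[str, list[str]] = {"C": [], "T": []}
        pos_per_center: dict[str, list[tuple[int, int]]] = {"C": [], "T": []}
        for ci, name in enumerate(chrom_names):
            seq = genome.sequences[name]
            for p in range(1, len(seq) - 1):
                base = seq[p]
                if base == "N":
                    continue
                tri = seq[p - 1:p + 2]
                if "N" in tri:
                    continue
                if base in PURINES:
                    tri = revcomp(tri)
                center = tri[1]
                ctx_per_center[center].append(tri)
                pos_per_center[center].append((ci, p))
        self.chrom_names = chrom_names
        self._ctx = {c: np.array(v) for c, v in ctx_per_center.items()}
        self._pos = {c: np.array(v, dtype=np.int64)
                     for c, v in pos_per_center.items()}
        self.profile = profile

    def probs(self, cls: str) -> np.ndarray:
        if cls not in self._probs:
            center = cls[0]
            bias = self.profile.context_bias.get(cls, {})
            ctx = self._ctx[center]
            w = np.ones(len(ctx))
            for tri, weight in bias.items():
                w[ctx == tri] = weight
            self._probs[cls] = w / w.sum()
        return self._probs[cls]

    def sample(self, cls: str, n: int, rng: np.random.Generator
               ) -> list[tuple[str, int]]:
        center = cls[0]
        pool = self._pos[center]
        if len(pool) == 0:
            raise ValueError(f"no eligible sites for class {cls}")
        idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False,
                         p=self.probs(cls))
        return [(self.chrom_names[pool[i, 0]], int(pool[i, 1])) for i in idx]


def _mono_runs(genome: Genome, min_len: int = 2) -> list[tuple[str, int, int, str]]:
    """(chrom, start, end, base) of maximal mononucleotide runs >= min_len."""
    runs = []
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.flatnonzero(np.diff(arr) != 0)
        starts = np.concatenate(([0], b + 1))
        ends = np.concatenate((b + 1, [len(arr)]))
        for s, e in zip(starts, ends):
            if e - s >= min_len and seq[s] != "N":
                runs.append((name, int(s), int(e), seq[s]))
    return runs


def _bin_length(bin_name: str, rng: np.random.Generator) -> int:
    if bin_name.endswith("1"):
        return 1
    if bin_name.endswith("2"):
        return 2
    # >=3 bp: 3 plus a geometric tail (mean ~4)
    return 3 + int(rng.geometric(0.6)) - 1


def simulate_lines(genome: Genome, genes: Sequence[GeneModel] | None,
                   profile: ConditionProfile, n_lines: int, n_cycles: int,
                   t: int = 25, seed: int = 0,
                   min_copies: int = DEFAULT_MIN_COPIES,
                   ) -> tuple[list[LineRecord], TruthSet]:
    """Simulate one condition's lines: Poisson event counts, context-biased
    SNV placement, slippage indels in mononucleotide runs, and CNV truth.

    Returns the per-line variant records plus a truth set whose entries
    match the emitted variants record for record.
    """
    rng = np.random.default_rng(seed)
    N = genome.total_length
    divisions = n_cycles * t
    picker = _SitePicker(genome, profile)
    runs = _mono_runs(genome)
    truth = TruthSet(profile.label)
    lines: list[LineRecord] = []
    chrom_names = list(genome.sequences)
    chrom_sizes = {c: len(genome.sequences[c]) for c in chrom_names}

    for li in range(n_lines):
        line_id = f"{profile.label}_{li + 1}"
        rec = truth.add_line(line_id)
        used: set[tuple[str, int]] = set()
        variants: list[Variant] = []

        for cls in SUBSTITUTION_CLASSES:
            rate = profile.snv_rates.get(cls, 0.0)
            n = int(rng.poisson(rate * N * divisions))
            if n == 0:
                continue
            for chrom, pos in picker.sample(cls, n, rng):
                if (chrom, pos) in used:
                    continue
                used.add((chrom, pos))
                ref = genome.sequences[chrom][pos]
                alt = cls[2] if ref == cls[0] else _COMP[cls[2]]
                variants.append(Variant(line_id, chrom, pos, ref, alt))
                rec["snvs"].append({"chrom": chrom, "pos": pos,
                                    "class": cls, "ref": ref, "alt": alt})

        for bin_name in INDEL_BINS:
            rate = profile.indel_rates.get(bin_name, 0.0)
            n = int(rng.poisson(rate * N * divisions))
            for _ in range(n):
                length = _bin_length(bin_name, rng)
                is_del = bin_name.startswith("del")
                slip = bool(rng.random() < profile.slippage_fraction)
                v = _place_indel(genome, line_id, length, is_del, slip,
                                 runs, used, rng, min_copies)
                if v is None:
                    continue
                variants.append(v)
                rec["indels"].append({
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                    "alt": v.alt, "bin": bin_name, "length": length,
                    "slippage": slip,
                })

        n_aneu = int(rng.poisson(profile.aneuploidy_rate * divisions))
        n_rearr = int(rng.poisson(profile.rearrangement_rate * divisions))
        for _ in range(n_aneu):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            rec["cnvs"].append({"chrom": chrom, "start": 0,
                                "end": chrom_sizes[chrom], "state": 2,
                                "kind": "aneuploidy"})
        for _ in range(n_rearr):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            size = chrom_sizes[chrom]
            span = int(size * rng.uniform(0.05, 0.3))
            if rng.random() < 0.5:  # terminal
                start = 0 if rng.random() < 0.5 else size - span
            else:
                start = int(rng.integers(1, max(2, size - span)))
            rec["cnvs"].append({"chrom": chrom, "start": start,
                                "end": start + span,
                                "state": 2 if rng.random() < 0.5 else 0,
                                "kind": "rearrangement"})

        lines.append(LineRecord(line_id, profile.label, n_cycles, variants))
    return lines, truth


def _place_indel(genome: Genome, line_id: str, length: int, is_del: bool,
                 slippage: bool, runs, used: set, rng: np.random.Generator,
                 min_copies: int, max_tries: int = 200) -> Variant | None:
    """One indel placement; slippage events go inside mononucleotide runs,
    others are rejection-sampled into non-repeat sites."""
    chrom_names = list(genome.sequences)
    for _ in range(max_tries):
        if slippage:
            name, s, e, base = runs[int(rng.integers(len(runs)))]
            if is_del and (e - s) < length + 1:
                continue  # keep >= 1 copy so the locus stays a run
            if not is_del and (e - s) < max(min_copies, 1):
                continue
            pos = s  # left-aligned representation anchors at the run start
            if pos == 0:
                continue
            if is_del:
                ref = genome.sequences[name][pos - 1: pos + length]
                alt = genome.sequences[name][pos - 1]
            else:
                ref = genome.sequences[name][pos - 1]
                alt = ref + base * length
        else:
            name = chrom_names[int(rng.integers(len(chrom_names)))]
            seq = genome.sequences[name]
            pos = int(rng.integers(1, len(seq) - length - 1))
            if is_del:
                ref = seq[pos - 1: pos + length]
                alt = seq[pos - 1]
            else:
                ref = seq[pos - 1]
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
                alt = ref + ins
        if "N" in ref or "N" in alt:
            continue
        npos, nref, nalt = normalize_variant(name, pos - 1, ref, alt, genome)
        key = (name, npos)
        if key in used:
            continue
        v = Variant(line_id, name, npos, nref, nalt)
        ann = repeat_context(genome, v, min_copies=min_copies)
        if ann.in_tandem_repeat != slippage:
            continue
        used.add(key)
        return v
    return None


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------

def simulate_depth(genome: Genome, cnv_truth: Sequence[dict],
                   mean_depth: float = 40.0, window: int = 1000,
                   seed: int = 0) -> list[DepthTrack]:
    """Per-window Poisson depth with copy state taken from CNV truth.

    ``cnv_truth`` entries are dicts with chrom/start/end/state (as produced
    by :func:`simulate_lines`); unaffected windows have copy state 1.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    tracks = []
    for name, seq in genome.sequences.items():
        n_win = max(1, len(seq) // window)
        state = np.ones(n_win)
        for cnv in cnv_truth:
            if cnv["chrom"] != name:
                continue
            w0 = cnv["start"] // window
            w1 = max(w0 + 1, -(-cnv["end"] // window))
            state[w0:min(w1, n_win)] = cnv["state"]
        depths = rng.poisson(mean_depth * state).astype(float)
        tracks.append(DepthTrack(name, window, depths))
    return tracks


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str | Path, genome: Genome,
                  genes: Sequence[GeneModel], lines: Sequence[LineRecord],
                  truth: TruthSet, mean_depth: float = 40.0,
                  window: int = 1000, seed: int = 0) -> None:
    """Emit FASTA, GFF3, per-line VCFs, depth TSVs, and truth JSON."""
    from .genome_io import write_genome, write_genes, write_variants
    from .structural import write_depth_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(genome, out / "genome.fa")
    write_genes(genes, out / "genes.gff3")
    truth.to_json(out / "truth.json")
    with open(out / "metadata.tsv", "w") as fh:
        fh.write("line_id\tcondition\tn_cycles\tvariants_path\n")
        for line in lines:
            fh.write(f"{line.line_id}\t{line.condition}\t{line.n_cycles}\t"
                     f"{out / (line.line_id + '.vcf')}\n")
    for i, line in enumerate(lines):
        write_variants(line.variants, out / f"{line.line_id}.vcf", genome)
        tracks = simulate_depth(
            genome, truth.lines[line.line_id]["cnvs"],
            mean_depth=mean_depth, window=window, seed=seed + 7919 * (i + 1))
        write_depth_table(tracks, out / f"{line.line_id}.depth.tsv")
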