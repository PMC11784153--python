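"""InDel classification, tandem-repeat (slippage) context, and
mononucleotide-repeat census.

Small insertions and deletions in mutation-accumulation data are heavily
enriched in tandem repeats, the footprint of template slippage during
replication.  An indel is annotated as "in a tandem repeat" when its
inserted/deleted sequence is a whole number of copies of some unit u and
the reference around the event carries at least ``min_copies`` tandem
copies of u.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, Variant

DEFAULT_MIN_COPIES = 2
DEFAULT_SEARCH_WINDOW = 50
DEFAULT_MAX_INDEL_LEN = 50

SIZE_BINS = ("1 bp", "2 bp", ">=3 bp")
INDEL_CLASSES = tuple(f"{b} {d}" for b in SIZE_BINS
                      for d in ("deletions", "insertions"))


@dataclass(frozen=True)
class IndelClass:
    direction: str  # "insertion" | "deletion"
    size_bin: str   # "1 bp" | "2 bp" | ">=3 bp"
    length: int

    @property
    def label(self) -> str:
        return f"{self.size_bin} {self.direction}s"


def classify_indel(v: Variant) -> IndelClass:
    """Direction x size bin (1 / 2 / >=3 bp) of a left-aligned indel."""
    if not v.is_indel:
        raise ValueError(f"not an indel: {v.ref}>{v.alt}")
    length = v.indel_length
    size_bin = "1 bp" if length == 1 else "2 bp" if length == 2 else ">=3 bp"
    return IndelClass(v.vclass, size_bin, length)


@dataclass
class RepeatAnnotation:
    in_tandem_repeat: bool
    unit: str | None
    unit_length: int
    ref_copies: int
    repeat_type: str  # "mononucleotide" | "multinucleotide" | "none"
    truncated_at_window: bool = False


def _tandem_copies(seq: str, anchor: int, unit: str, window: int) -> tuple[int, bool]:
    """Maximal tandem run of ``unit`` in ``seq`` through position ``anchor``.

    Counts whole-unit matches extending right from ``anchor`` and left of
    it, bounded by ``window`` bases each side. Returns (copies, truncated).
    """
    d = len(unit)
    copies = 0
    right_limit = min(len(seq), anchor + window + d)
    j = anchor
    while j + d <= right_limit and seq[j:j + d] == unit:
        copies += 1
        j += d
    truncated_r = j + d <= len(seq) and j >= anchor + window
    left_limit = max(0, anchor - window)
    j = anchor
    while j - d >= left_limit and seq[j - d:j] == unit:
        copies += 1
        j -= d
    truncated_l = j - d >= 0 and j <= anchor - window
    return copies, bool(truncated_r or truncated_l)


def repeat_context(genome: Genome, v: Variant,
                   min_copies: int = DEFAULT_MIN_COPIES,
                   window: int = DEFAULT_SEARCH_WINDOW) -> RepeatAnnotation:
    """Slippage annotation of a left-aligned indel.

    The inserted/deleted sequence is tested as k copies of a unit u for
    every divisor of the indel length, shortest qualifying unit first;
    the locus is in a tandem repeat when the reference carries at least
    ``min_copies`` tandem copies of u at/adjacent to the event site.
    """
    if not v.is_indel:
        raise ValueError("repeat context is defined for indels only")
    seq = genome.sequences[v.chrom]
    event = v.indel_seq
    length = len(event)
    anchor = v.pos + min(len(v.ref), len(v.alt))  # first affected base
    best: RepeatAnnotation | None = None
    for d in range(1, length + 1):
        if length % d:
            continue
        unit = event[:d]
        if unit * (length // d) != event:
            continue
        copies, truncated = _tandem_copies(seq, anchor, unit, window)
        ann = RepeatAnnotation(
            in_tandem_repeat=copies >= min_copies,
            unit=unit,
            unit_length=d,
            ref_copies=copies,
            repeat_type="mononucleotide" if d == 1 else "multinucleotide",
            truncated_at_window=truncated,
        )
        if ann.in_tandem_repeat:
            return ann
        if best is None:
            best = ann
    assert best is not None
    if not best.in_tandem_repeat:
        best = RepeatAnnotation(False, best.unit, best.unit_length,
                                best.ref_copies, "none",
                                best.truncated_at_window)
    return best


@dataclass
class RepeatFractionResult:
    n_in_repeat: int
    n_total: int
    fraction: float
    per_class: pd.DataFrame  # index: class label; columns: in_repeat, total, fraction


def repeat_fraction(variants: Iterable[Variant], genome: Genome,
                    min_copies: int = DEFAULT_MIN_COPIES,
                    window: int = DEFAULT_SEARCH_WINDOW) -> RepeatFractionResult:
    """Fraction of indels inside tandem repeats, overall and per class."""
    indels = [v for v in variants if v.is_indel]
    if not indels:
        raise ValueError("no indels to annotate")
    rows = []
    for v in indels:
        cls = classify_indel(v)
        ann = repeat_context(genome, v, min_copies, window)
        rows.append((cls.label, ann.in_tandem_repeat, ann.repeat_type))
    df = pd.DataFrame(rows, columns=["class", "in_repeat", "repeat_type"])
    per_class = df.groupby("class")["in_repeat"].agg(
        in_repeat="sum", total="count"
    ).reindex(INDEL_CLASSES, fill_value=0)
    per_class["fraction"] = np.where(per_class["total"] > 0,
                                     per_class["in_repeat"] / per_class["total"],
                                     np.nan)
    n_in = int(df["in_repeat"].sum())
    return RepeatFractionResult(n_in, len(indels), n_in / len(indels), per_class)


@dataclass
class RepeatCensus:
    """Counts of maximal mononucleotide runs, by base and run length."""

    table: pd.DataFrame  # index: run length; columns: A C G T
    min_run: int

    @property
    def total_runs(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def total_bases(self) -> int:
        return int((self.table.to_numpy().sum(axis=1)
                    * self.table.index.to_numpy()).sum())

    def length_histogram(self) -> pd.Series:
        return self.table.sum(axis=1).astype(int)


def mononucleotide_census(genome: Genome, min_run: int = 2) -> RepeatCensus:
    """Tabulate every maximal single-base run of length >= ``min_run``.

    Runs are maximal (flanked by a different base or a chromosome end) and
    counted once — mononucleotide runs are identical on both strands. N
    runs are ignored.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    counts: dict[tuple[int, str], int] = {}
    for seq in genome.sequences.values():
        if not seq:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        boundaries = np.flatnonzero(np.diff(arr) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [len(arr)]))
        lengths = ends - starts
        for s, ln in zip(starts, lengths):
            if ln >= min_run:
                base = seq[s]
                if base != "N":
                    counts[(int(ln), base)] = counts.get((int(ln), base), 0) + 1
    if counts:
        max_len = max(l for l, _ in counts)
        table = pd.DataFrame(0, index=range(min_run, max_len + 1),
                             columns=list("ACGT"), dtype=int)
        for (ln, base), n in counts.items():
            table.loc[ln, base] = n
    else:
        table = pd.DataFrame(columns=list("ACGT"), dtype=int)
    return RepeatCensus(table, min_run)


def split_small_and_large(variants: Sequence[Variant],
                          max_indel_len: int = DEFAULT_MAX_INDEL_LEN
                          ) -> tuple[list[Variant], list[Variant]]:
    """Route indels longer than ``max_indel_len`` to the structural side."""
    small, large = [], []
    for v in variants:
        (large if v.is_indel and v.indel_length > max_indel_len
         else small).append(v)
    return small, large
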