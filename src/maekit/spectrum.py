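"""SNV spectrum analysis: pyrimidine-normalized substitution classes,
SBS96 trinucleotide categories, context enrichment, and flank matrices.

Every substitution is referred to its pyrimidine strand (the COSMIC SBS
convention): a G>A call reflects C>T on the complementary strand and is
counted as C>T, with its context reverse-complemented so the mutated
pyrimidine sits at the center.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Genome, Variant, revcomp

log = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})

#: COSMIC-ordered SBS96 labels: classes in lexical order, 5' x 3' in ACGT order.
SBS96_LABELS = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)


@dataclass(frozen=True)
class SubstitutionClass:
    """Pyrimidine-referenced class plus the strand of the original call."""

    label: str  # one of SUBSTITUTION_CLASSES
    purine_original: bool  # True if the called ref base was A or G

    @property
    def is_transition(self) -> bool:
        return self.label in TRANSITIONS


def classify_snv(v: Variant) -> SubstitutionClass:
    """Map an SNV to its pyrimidine-normalized substitution class."""
    if not v.is_snv:
        raise ValueError(f"not an SNV: {v.ref}>{v.alt}")
    ref, alt = v.ref, v.alt
    if ref in PURINES:
        return SubstitutionClass(f"{_COMP[ref]}>{_COMP[alt]}", True)
    return SubstitutionClass(f"{ref}>{alt}", False)


def snv_context(genome: Genome, v: Variant, k: int = 1) -> str | None:
    """Oriented (2k+1)-mer around an SNV, pyrimidine at the center.

    Reverse-complemented when the reference base is a purine. Returns
    ``None`` (to be counted as an exclusion by callers) when the site is
    within ``k`` of a chromosome end or the window contains N.
    """
    if not v.is_snv:
        raise ValueError("context extraction requires an SNV")
    seq = genome.sequences[v.chrom]
    if v.pos - k < 0 or v.pos + k + 1 > len(seq):
        return None
    window = seq[v.pos - k: v.pos + k + 1]
    if "N" in window:
        return None
    return revcomp(window) if v.ref in PURINES else window


def sbs96_label(context: str, cls: SubstitutionClass) -> str:
    """SBS96 label from an oriented trinucleotide and a class."""
    assert len(context) == 3
    return f"{context[0]}[{cls.label}]{context[2]}"


def sbs96_counts(variants: Iterable[Variant], genome: Genome) -> pd.Series:
    """96-category count vector over SNVs; end/N contexts excluded.

    Returns a Series indexed by :data:`SBS96_LABELS` with an
    ``attrs['n_excluded']`` count of SNVs without a full trinucleotide.
    """
    counts = pd.Series(0, index=list(SBS96_LABELS), dtype=int)
    excluded = 0
    for v in variants:
        if not v.is_snv:
            continue
        ctx = snv_context(genome, v, k=1)
        if ctx is None:
            excluded += 1
            continue
        counts[sbs96_label(ctx, classify_snv(v))] += 1
    counts.attrs["n_excluded"] = excluded
    return counts


def six_class_counts(variants: Iterable[Variant]) -> pd.Series:
    """Direct six-class substitution counts (no context needed)."""
    counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    for v in variants:
        if v.is_snv:
            counts[classify_snv(v).label] += 1
    return counts


def collapse_to_six(sbs96: pd.Series) -> pd.Series:
    """Sum the 96-vector down to the six substitution classes."""
    out = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    for label, n in sbs96.items():
        out[label[2:5]] += n
    return out


# ---------------------------------------------------------------------------
# Genome context expectation
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _kmer_code_counts(seq: str, k: int) -> np.ndarray:
    """Counts of all k-mers (base-4 coded) in one sequence; N windows skipped."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = arr[j: j + n]
        code = code * 4 + np.maximum(window, 0)
        valid &= window >= 0
    return np.bincount(code[valid], minlength=4 ** k)


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def genome_context_expectation(genome: Genome, k: int = 1) -> pd.Series:
    """Expected frequency of each pyrimidine-normalized (2k+1)-mer,
    conditioned on its center base.

    Every genome position with a full window contributes once: positions
    whose center is a purine contribute the reverse complement of their
    window, so both strands are represented through normalization. For
    each center base (C or T) the frequencies sum to 1.
    """
    width = 2 * k + 1
    total = np.zeros(4 ** width, dtype=np.int64)
    for seq in genome.sequences.values():
        total += _kmer_code_counts(seq, width)
    merged: dict[str, int] = {}
    for code, n in enumerate(total):
        if n == 0:
            continue
        kmer = _code_to_kmer(code, width)
        if kmer[k] in PURINES:
            kmer = revcomp(kmer)
        merged[kmer] = merged.get(kmer, 0) + int(n)
    ser = pd.Series(merged, dtype=float)
    for center in "CT":
        mask = ser.index.str[k] == center
        tot = ser.loc[mask].sum()
        if tot > 0:
            ser.loc[mask] = ser.loc[mask] / tot
    return ser.sort_index()


# ---------------------------------------------------------------------------
# Context enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    family: str  # substitution class
    trinucleotide: str
    observed: int
    expected: float
    statistic: float
    pvalue: float
    adjusted_p: float
    test: str  # "chi2" or "binom"


def _adjust(pvals: Sequence[float], method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(np.asarray(pvals) * len(pvals), 1.0)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests
        return multipletests(pvals, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def context_enrichment(observed: pd.Series,
                       expectation: pd.Series,
                       min_class_count: int = 10,
                       adjust: str = "bonferroni",
                       min_expected_chi2: float = 5.0) -> list[EnrichmentResult]:
    """Per-trinucleotide enrichment tests within each substitution class.

    ``observed`` is an SBS96 count Series; ``expectation`` the conditioned
    genome frequencies from :func:`genome_context_expectation`. For each
    class with at least ``min_class_count`` SNVs, each of its 16
    trinucleotides gets a 1-df chi-squared goodness-of-fit against its
    complement (exact binomial when the expected count falls below
    ``min_expected_chi2``); p-values are adjusted within the class family.
    """
    results: list[EnrichmentResult] = []
    for cls in SUBSTITUTION_CLASSES:
        labels = [l for l in observed.index if l[2:5] == cls]
        counts = observed[labels]
        n_cls = int(counts.sum())
        if n_cls < min_class_count:
            log.warning("class %s has %d SNVs (< %d): enrichment family skipped",
                        cls, n_cls, min_class_count)
            continue
        fam: list[EnrichmentResult] = []
        for label in labels:
            tri = label[0] + label[2] + label[6]  # 5' + ref + 3'
            p_exp = float(expectation.get(tri, 0.0))
            obs = int(counts[label])
            exp = n_cls * p_exp
            if exp < min_expected_chi2 or (n_cls - exp) < min_expected_chi2:
                test = "binom"
                pv = stats.binomtest(obs, n_cls, p_exp).pvalue if 0 < p_exp < 1 \
                    else (1.0 if obs == exp else 0.0)
                stat = float("nan")
            else:
                test = "chi2"
                stat = (obs - exp) ** 2 / exp + \
                       ((n_cls - obs) - (n_cls - exp)) ** 2 / (n_cls - exp)
                pv = float(stats.chi2.sf(stat, df=1))
            fam.append(EnrichmentResult(cls, tri, obs, exp, stat, pv, pv, test))
        adj = _adjust([r.pvalue for r in fam], adjust)
        for r, a in zip(fam, adj):
            r.adjusted_p = float(a)
        results.extend(fam)
    return results


# ---------------------------------------------------------------------------
# Flanking-sequence matrices (sequence-logo data)
# ---------------------------------------------------------------------------

@dataclass
class FlankMatrix:
    """Per-position base frequencies around SNVs of one class.

    Positions run -window..-1, +1..+window relative to the mutated base on
    the pyrimidine-normalized strand.  ``information`` is 2 - H(bits) per
    position (no small-sample correction).
    """

    substitution_class: str
    frequencies: pd.DataFrame  # index: positions, columns: A C G T
    n_variants: int
    n_excluded: int = 0

    @property
    def information(self) -> pd.Series:
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=1)
        return pd.Series(2.0 - h, index=self.frequencies.index)


def flank_matrix(variants: Sequence[Variant], genome: Genome,
                 window: int = 4) -> FlankMatrix:
    """Base-frequency matrix of the ``window`` bases each side of SNVs.

    All variants must belong to the same substitution class; contexts are
    taken on the pyrimidine-normalized strand.
    """
    snvs = [v for v in variants if v.is_snv]
    if not snvs:
        raise ValueError("empty variant class")
    cls_labels = {classify_snv(v).label for v in snvs}
    if len(cls_labels) > 1:
        raise ValueError(f"variants span multiple classes: {sorted(cls_labels)}")
    positions = [p for p in range(-window, window + 1) if p != 0]
    counts = pd.DataFrame(0, index=positions, columns=list("ACGT"), dtype=float)
    used = excluded = 0
    for v in snvs:
        ctx = snv_context(genome, v, k=window)
        if ctx is None:
            excluded += 1
            continue
        used += 1
        for p in positions:
            counts.loc[p, ctx[window + p]] += 1
    if used == 0:
        raise ValueError("no variant had a full flanking window")
    freq = counts / used
    return FlankMatrix(cls_labels.pop(), freq, used, excluded)


# ---------------------------------------------------------------------------
# G/C site composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionTest:
    n_gc: int
    n_total: int
    fraction_gc: float
    expected_gc: float
    pvalue: float


def site_composition_test(variants: Sequence[Variant],
                          genome_gc: float) -> CompositionTest:
    """Are SNVs over-represented at G/C sites relative to genome GC?

    Two-sided exact binomial test of the number of SNVs whose (original)
    reference base is G or C against the genome GC fraction.
    """
    snvs = [v for v in variants if v.is_snv]
    if not snvs:
        raise ValueError("no SNVs to test")
    n_gc = sum(1 for v in snvs if v.ref in "GC")
    res = stats.binomtest(n_gc, len(snvs), genome_gc)
    return CompositionTest(n_gc, len(snvs), n_gc / len(snvs),
                           genome_gc, float(res.pvalue))
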