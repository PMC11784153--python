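"""Mutation-rate estimation for mutation-accumulation experiments.

The denominator model: each subculture cycle transfers a single colony, and
a colony on a plate grows from one cell through approximately ``t`` cell
divisions (default 25).  A line streaked for ``g`` cycles therefore
accumulates mutations over ``g * t`` divisions, and an experiment of many
lines over ``sum(g_i) * t`` divisions in total.  Per-base rates divide the
event count additionally by the genome size ``N``:

    mu_bp  = n_events / (N * gen_tot * t)      [per base per cell division]
    mu_lar = n_events / (gen_tot * t)          [per cell division]

Confidence intervals default to a nonparametric bootstrap over whole lines
(percentile method); an exact Poisson interval is available as an
alternative.  Between-condition comparisons use the two-sided Wilcoxon
rank-sum test on per-line rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .genome_io import Variant

DEFAULT_DIVISIONS_PER_COLONY = 25
DEFAULT_N_BOOT = 10_000


@dataclass
class LineRecord:
    """One subcultured isolate: its condition, cycle count, and variants."""

    line_id: str
    condition: str
    n_cycles: int
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")


@dataclass
class ExperimentDesign:
    """Lines plus the two denominator constants t and N."""

    lines: list[LineRecord]
    t: int = DEFAULT_DIVISIONS_PER_COLONY
    genome_size: int = 0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t}")
        if self.genome_size < 0:
            raise ValueError("genome_size must be positive")


@dataclass
class RateEstimate:
    """Point rate with CI, event count, and denominator bookkeeping.

    ``ci_low <= ci_high`` always holds; for the percentile bootstrap the
    point is not guaranteed to lie inside the interval (it usually does).
    """

    point: float
    ci_low: float
    ci_high: float
    n_events: int
    n_divisions: int
    genome_size: int | None  # None for structural (per-division) rates
    ci_method: str = "none"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")

    def __format__(self, spec: str) -> str:
        return format(self.point, spec or ".3g")


def total_divisions(lines: Sequence[LineRecord], t: int = DEFAULT_DIVISIONS_PER_COLONY) -> int:
    """Total cell divisions across lines: (sum of cycle counts) * t."""
    if not lines:
        raise ValueError("no lines given")
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    return sum(line.n_cycles for line in lines) * t


def per_base_rate(n_events: int, design: ExperimentDesign,
                  ci: tuple[float, float] | None = None,
                  ci_method: str = "none") -> RateEstimate:
    """Per-base per-division mutation rate: n / (N * gen_tot * t)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if design.genome_size <= 0:
        raise ValueError("genome_size must be positive for per-base rates")
    divisions = total_divisions(design.lines, design.t)
    denom = design.genome_size * divisions
    point = n_events / denom
    flags = []
    if n_events == 0:
        flags.append("no events observed")
    lo, hi = ci if ci is not None else (point, point)
    return RateEstimate(point, lo, hi, n_events, divisions,
                        design.genome_size, ci_method, flags)


def structural_rate(n_events: int, design: ExperimentDesign,
                    ci: tuple[float, float] | None = None,
                    ci_method: str = "none") -> RateEstimate:
    """Per-cell-division rate for aneuploidy/rearrangement events."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    divisions = total_divisions(design.lines, design.t)
    point = n_events / divisions
    flags = ["no events observed"] if n_events == 0 else []
    lo, hi = ci if ci is not None else (point, point)
    return RateEstimate(point, lo, hi, n_events, divisions, None,
                        ci_method, flags)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def poisson_ci(n_events: int, denominator: float,
               alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for a count divided by a denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    lo = 0.0 if n_events == 0 else stats.chi2.ppf(alpha / 2, 2 * n_events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n_events + 2) / 2
    return lo / denominator, hi / denominator


def bootstrap_ci(lines: Sequence[LineRecord],
                 event_selector: Callable[[Variant], bool],
                 design: ExperimentDesign,
                 n_boot: int = DEFAULT_N_BOOT,
                 seed: int = 0,
                 per_base: bool = True,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for a rate, resampling whole lines.

    Lines are resampled with replacement; both the event count and the
    division denominator are recomputed per resample, so lines with more
    cycles carry proportionally more weight. Deterministic given ``seed``.
    """
    lines = list(lines)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    counts = np.array([sum(1 for v in ln.variants if event_selector(v))
                       for ln in lines], dtype=float)
    cycles = np.array([ln.n_cycles for ln in lines], dtype=float)
    scale = design.genome_size if per_base else 1
    if per_base and scale <= 0:
        raise ValueError("genome_size must be positive for per-base rates")
    if len(lines) < 2:
        warnings.warn("fewer than 2 lines: bootstrap CI undefined, "
                      "returning the point estimate for both bounds")
        point = counts.sum() / (cycles.sum() * design.t * scale)
        return point, point
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(lines), size=(n_boot, len(lines)))
    boot_rates = counts[idx].sum(axis=1) / (cycles[idx].sum(axis=1)
                                            * design.t * scale)
    lo, hi = np.quantile(boot_rates, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def estimate_rate(lines: Sequence[LineRecord],
                  event_selector: Callable[[Variant], bool],
                  design: ExperimentDesign,
                  per_base: bool = True,
                  ci_method: str = "bootstrap",
                  n_boot: int = DEFAULT_N_BOOT,
                  seed: int = 0) -> RateEstimate:
    """Full estimate for the events a predicate selects: point + CI."""
    n = sum(1 for ln in lines for v in ln.variants if event_selector(v))
    sub_design = ExperimentDesign(list(lines), design.t, design.genome_size)
    divisions = total_divisions(lines, design.t)
    if ci_method == "bootstrap":
        ci = bootstrap_ci(lines, event_selector, sub_design,
                          n_boot=n_boot, seed=seed, per_base=per_base)
    elif ci_method == "poisson":
        denom = divisions * (design.genome_size if per_base else 1)
        ci = poisson_ci(n, denom)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if per_base:
        return per_base_rate(n, sub_design, ci=ci, ci_method=ci_method)
    return structural_rate(n, sub_design, ci=ci, ci_method=ci_method)


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def fold_change(numerator: RateEstimate, denominator: RateEstimate) -> float:
    """Ratio of point rates; infinite (with a warning) on a zero denominator."""
    if denominator.point == 0:
        warnings.warn(
            f"zero denominator rate ({denominator.n_events} events over "
            f"{denominator.n_divisions} divisions): fold change is infinite"
        )
        return float("inf")
    return numerator.point / denominator.point


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    method: str
    rates_a: list[float] = field(default_factory=list)
    rates_b: list[float] = field(default_factory=list)


def per_line_rates(lines: Sequence[LineRecord],
                   event_selector: Callable[[Variant], bool],
                   design: ExperimentDesign,
                   per_base: bool = True) -> list[float]:
    """Each line's own rate: count / (cycles * t [* N])."""
    scale = design.genome_size if per_base else 1
    return [sum(1 for v in ln.variants if event_selector(v))
            / (ln.n_cycles * design.t * scale) for ln in lines]


def compare_line_rates(group_a: Sequence[LineRecord],
                       group_b: Sequence[LineRecord],
                       event_selector: Callable[[Variant], bool],
                       design: ExperimentDesign,
                       per_base: bool = True) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on per-line rates.

    Exact null for small tie-free samples; normal approximation with tie
    correction otherwise.  All-constant data is degenerate: p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 lines per group")
    ra = per_line_rates(group_a, event_selector, design, per_base)
    rb = per_line_rates(group_b, event_selector, design, per_base)
    if len(set(ra) | set(rb)) == 1:
        warnings.warn("all per-line rates identical: degenerate comparison, p = 1")
        return RankSumResult(statistic=len(ra) * len(rb) / 2, pvalue=1.0,
                             method="degenerate", rates_a=ra, rates_b=rb)
    if sorted(ra) == sorted(rb):
        # identical rate multisets: exactly null, no ties broken
        return RankSumResult(statistic=len(ra) * len(rb) / 2, pvalue=1.0,
                             method="identical-groups", rates_a=ra, rates_b=rb)
    has_ties = len(set(ra + rb)) < len(ra) + len(rb)
    small = len(ra) <= 8 and len(rb) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(ra, rb, alternative="two-sided", method=method)
    return RankSumResult(statistic=float(res.statistic),
                         pvalue=float(res.pvalue), method=method,
                         rates_a=ra, rates_b=rb)
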