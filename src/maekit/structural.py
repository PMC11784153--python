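"""Coverage-based aneuploidy and segmental CNV detection.

Read depth is summarized per fixed-size window, normalized by the
genome-wide median to a relative coverage (RC) track where 0, 1, and 2
correspond to 0, 1, and 2 copies of DNA in a haploid, and thresholded
runs of windows become CNV calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rates import ExperimentDesign, RateEstimate, structural_rate

DEFAULT_LOW_THR = 0.5
DEFAULT_HIGH_THR = 1.5
DEFAULT_MIN_WINDOWS = 10
DEFAULT_WINDOW = 1000
DEFAULT_WHOLE_CHR_FRACTION = 0.9


@dataclass
class DepthTrack:
    """Mean read depth per non-overlapping window tiling one chromosome."""

    chrom: str
    window: int
    depths: np.ndarray  # one value per window, >= 0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("negative depth")


@dataclass
class RelativeCoverageTrack:
    chrom: str
    window: int
    rc: np.ndarray


@dataclass
class CnvCall:
    """Contiguous copy-number call; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    copy_state: int  # 0 (deletion) or 2 (duplication), haploid frame
    scope: str       # "whole-chromosome" | "terminal" | "interstitial"
    mean_rc: float
    line_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def read_depth_table(path: str | Path) -> list[DepthTrack]:
    """Read a depth table: TSV/BED columns chrom, start, end, mean depth."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "depth"])
    tracks = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        widths = (grp["end"] - grp["start"]).to_numpy()
        window = int(widths.max())
        if (grp["start"].to_numpy()[1:] != grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"windows on {chrom} do not tile without gaps")
        tracks.append(DepthTrack(str(chrom), window, grp["depth"].to_numpy()))
    return tracks


def write_depth_table(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depths):
                fh.write(f"{t.chrom}\t{i * t.window}\t{(i + 1) * t.window}\t{d:g}\n")


def relative_coverage(tracks: Sequence[DepthTrack]) -> list[RelativeCoverageTrack]:
    """Normalize depth tracks by the genome-wide median window depth.

    The median is robust to CNVs occupying less than half the genome; an
    all-zero (or zero-median) depth collection is an error.
    """
    if not tracks:
        raise ValueError("no depth windows")
    alldepths = np.concatenate([t.depths for t in tracks])
    med = float(np.median(alldepths))
    if med <= 0:
        raise ValueError("median window depth is zero; cannot normalize")
    return [RelativeCoverageTrack(t.chrom, t.window, t.depths / med)
            for t in tracks]


def call_cnvs(rc_tracks: Sequence[RelativeCoverageTrack],
              low_thr: float = DEFAULT_LOW_THR,
              high_thr: float = DEFAULT_HIGH_THR,
              min_windows: int = DEFAULT_MIN_WINDOWS,
              whole_chr_fraction: float = DEFAULT_WHOLE_CHR_FRACTION,
              line_id: str = "") -> list[CnvCall]:
    """Call maximal runs of low/high relative coverage as CNVs.

    A run of >= ``min_windows`` consecutive windows with RC <= ``low_thr``
    becomes a deletion (state 0); RC >= ``high_thr`` a duplication
    (state 2). Runs touching a chromosome end are terminal; runs covering
    >= ``whole_chr_fraction`` of the chromosome are whole-chromosome.
    """
    if not (0 < low_thr < 1 < high_thr):
        raise ValueError("need 0 < low_thr < 1 < high_thr")
    calls: list[CnvCall] = []
    for track in rc_tracks:
        state = np.zeros(len(track.rc), dtype=int)
        state[track.rc <= low_thr] = -1
        state[track.rc >= high_thr] = 1
        n = len(state)
        i = 0
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < n and state[j] == state[i]:
                j += 1
            if j - i >= min_windows:
                start, end = i * track.window, j * track.window
                if (j - i) / n >= whole_chr_fraction:
                    scope = "whole-chromosome"
                elif i == 0 or j == n:
                    scope = "terminal"
                else:
                    scope = "interstitial"
                calls.append(CnvCall(
                    chrom=track.chrom, start=start, end=end,
                    copy_state=0 if state[i] == -1 else 2, scope=scope,
                    mean_rc=float(track.rc[i:j].mean()), line_id=line_id,
                ))
            i = j
    return calls


def write_cnv_bed(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Emit calls as BED3+ (name=state/scope, score=mean RC x 100)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t"
                     f"CN{c.copy_state}:{c.scope}\t{c.mean_rc * 100:.0f}\t"
                     f"{c.line_id}\n")


@dataclass
class StructuralSummary:
    n_aneuploidies: int
    n_rearrangements: int
    aneuploidy_rate: RateEstimate
    rearrangement_rate: RateEstimate
    calls: list[CnvCall] = field(default_factory=list)


def structural_event_summary(calls_per_line: dict[str, Sequence[CnvCall]],
                             design: ExperimentDesign) -> StructuralSummary:
    """Count aneuploidies vs segmental rearrangements and rate them.

    Whole-chromosome calls count as aneuploidies; terminal and interstitial
    calls as rearrangements. Calls are assumed deduplicated per line.
    """
    flat = [c for calls in calls_per_line.values() for c in calls]
    n_aneu = sum(1 for c in flat if c.scope == "whole-chromosome")
    n_rearr = len(flat) - n_aneu
    return StructuralSummary(
        n_aneuploidies=n_aneu,
        n_rearrangements=n_rearr,
        aneuploidy_rate=structural_rate(n_aneu, design),
        rearrangement_rate=structural_rate(n_rearr, design),
        calls=flat,
    )
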