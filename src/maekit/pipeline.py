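"""End-to-end orchestration: config validation, stage execution, and a
report bundle mirroring the rate / indel-class / spectrum table layout."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consequence, genome_io, indels, rates, spectrum, structural

log = logging.getLogger(__name__)


@dataclass
class LineSpec:
    line_id: str
    condition: str
    n_cycles: int
    variants_path: str
    depth_path: str | None = None


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML on disk)."""

    genome: str
    output_dir: str
    lines: list[LineSpec] = field(default_factory=list)
    gff: str | None = None
    t: int = rates.DEFAULT_DIVISIONS_PER_COLONY
    genome_size_override: int | None = None
    n_boot: int = rates.DEFAULT_N_BOOT
    ci_method: str = "bootstrap"
    seed: int = 0
    flank_window: int = 4
    adjust: str = "bonferroni"
    min_class_count: int = 10
    min_copies: int = indels.DEFAULT_MIN_COPIES
    max_indel_len: int = indels.DEFAULT_MAX_INDEL_LEN
    min_run: int = 2
    cnv_low_thr: float = structural.DEFAULT_LOW_THR
    cnv_high_thr: float = structural.DEFAULT_HIGH_THR
    cnv_min_windows: int = structural.DEFAULT_MIN_WINDOWS

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    lines = [LineSpec(**ln) for ln in data.pop("lines", [])]
    return PipelineConfig(lines=lines, **data)


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Load a config and return it with an exhaustive error list."""
    errors: list[str] = []
    try:
        cfg = load_config(path)
    except (OSError, TypeError, yaml.YAMLError) as exc:
        return None, [f"cannot parse config: {exc}"]
    if not cfg.genome:
        errors.append("genome: path missing")
    elif not Path(cfg.genome).exists():
        errors.append(f"genome: path does not exist: {cfg.genome}")
    if cfg.gff and not Path(cfg.gff).exists():
        errors.append(f"gff: path does not exist: {cfg.gff}")
    if cfg.t < 1:
        errors.append(f"t: must be >= 1, got {cfg.t}")
    if cfg.n_boot < 100:
        errors.append(f"n_boot: must be >= 100, got {cfg.n_boot}")
    if cfg.ci_method not in ("bootstrap", "poisson"):
        errors.append(f"ci_method: unknown method {cfg.ci_method!r}")
    if not (0 < cfg.cnv_low_thr < 1 < cfg.cnv_high_thr):
        errors.append("cnv thresholds: need 0 < low < 1 < high")
    for ln in cfg.lines:
        if ln.n_cycles < 1:
            errors.append(f"line {ln.line_id}: n_cycles must be >= 1")
        if not Path(ln.variants_path).exists():
            errors.append(f"line {ln.line_id}: variants path missing: "
                          f"{ln.variants_path}")
        if ln.depth_path and not Path(ln.depth_path).exists():
            errors.append(f"line {ln.line_id}: depth path missing: "
                          f"{ln.depth_path}")
    return (cfg if not errors else None), errors


def _rate_json(est: rates.RateEstimate) -> dict:
    return {
        "point": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
        "n_events": est.n_events, "n_divisions": est.n_divisions,
        "genome_size": est.genome_size, "ci_method": est.ci_method,
        "flags": est.flags,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to the output dir.

    Produces per-condition rate tables (SNV / indel / structural), the
    per-indel-class rate table, 6- and 96-class spectrum tables, context
    enrichment, repeat fractions, coding/non-coding summary, and CNV
    calls, each stamped with the config hash and seed. Any stage failure
    removes partial outputs and re-raises with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.content_hash(), "seed": config.seed}
    report: dict = {"stamp": stamp}
    stage = "load"
    try:
        genome = genome_io.read_genome(config.genome)
        genes = genome_io.read_genes(config.gff) if config.gff else []
        N = config.genome_size_override or genome.total_length
        lines_by_cond: dict[str, list[rates.LineRecord]] = {}
        depth_by_line: dict[str, list[structural.DepthTrack]] = {}
        for spec_line in config.lines:
            vs = genome_io.read_variants(spec_line.variants_path, genome,
                                         spec_line.line_id)
            small, _large = indels.split_small_and_large(vs, config.max_indel_len)
            rec = rates.LineRecord(spec_line.line_id, spec_line.condition,
                                   spec_line.n_cycles, small)
            lines_by_cond.setdefault(spec_line.condition, []).append(rec)
            if spec_line.depth_path:
                depth_by_line[spec_line.line_id] = \
                    structural.read_depth_table(spec_line.depth_path)

        stage = "rates"
        rate_table: dict = {}
        indel_table: dict = {}
        for cond, lns in lines_by_cond.items():
            design = rates.ExperimentDesign(lns, config.t, N)
            kw = dict(ci_method=config.ci_method, n_boot=config.n_boot,
                      seed=config.seed)
            rate_table[cond] = {
                "snv": _rate_json(rates.estimate_rate(
                    lns, lambda v: v.is_snv, design, **kw)),
                "indel": _rate_json(rates.estimate_rate(
                    lns, lambda v: v.is_indel, design, **kw)),
                "n_divisions": rates.total_divisions(lns, config.t),
            }
            per_class = {}
            for label in indels.INDEL_CLASSES:
                sel = _indel_class_selector(label)
                per_class[label] = _rate_json(rates.estimate_rate(
                    lns, sel, design, **kw))
            indel_table[cond] = per_class

        stage = "spectrum"
        expectation = spectrum.genome_context_expectation(genome)
        spectra: dict = {}
        for cond, lns in lines_by_cond.items():
            all_vs = [v for ln in lns for v in ln.variants]
            snvs = [v for v in all_vs if v.is_snv]
            six = spectrum.six_class_counts(snvs)
            sbs = spectrum.sbs96_counts(snvs, genome)
            enr = spectrum.context_enrichment(
                sbs, expectation, min_class_count=config.min_class_count,
                adjust=config.adjust)
            comp = (spectrum.site_composition_test(snvs, genome_io.gc_content(genome))
                    if snvs else None)
            spectra[cond] = {
                "six_class": six.to_dict(),
                "sbs96": sbs.to_dict(),
                "n_excluded": sbs.attrs.get("n_excluded", 0),
                "enrichment": [asdict(r) for r in enr],
                "gc_site_test": asdict(comp) if comp else None,
            }

        stage = "indels"
        repeat_summary: dict = {}
        for cond, lns in lines_by_cond.items():
            ind = [v for ln in lns for v in ln.variants if v.is_indel]
            if ind:
                rf = indels.repeat_fraction(ind, genome,
                                            min_copies=config.min_copies)
                repeat_summary[cond] = {
                    "n_in_repeat": rf.n_in_repeat, "n_total": rf.n_total,
                    "fraction": rf.fraction,
                    "per_class": rf.per_class.reset_index()
                                   .to_dict(orient="records"),
                }
            else:
                repeat_summary[cond] = {"n_in_repeat": 0, "n_total": 0,
                                        "fraction": None, "per_class": []}
        census = indels.mononucleotide_census(genome, config.min_run)
        report["mononucleotide_census"] = {
            "total_runs": census.total_runs,
            "total_bases": census.total_bases,
            "length_histogram": {int(k): int(v) for k, v
                                 in census.length_histogram().items()},
        }

        stage = "cnv"
        calls_by_cond: dict[str, dict[str, list]] = {}
        for cond, lns in lines_by_cond.items():
            per_line = {}
            for ln in lns:
                tracks = depth_by_line.get(ln.line_id)
                if not tracks:
                    continue
                rc = structural.relative_coverage(tracks)
                per_line[ln.line_id] = structural.call_cnvs(
                    rc, config.cnv_low_thr, config.cnv_high_thr,
                    config.cnv_min_windows, line_id=ln.line_id)
            calls_by_cond[cond] = per_line
        cnv_report: dict = {}
        all_calls: list[structural.CnvCall] = []
        for cond, per_line in calls_by_cond.items():
            design = rates.ExperimentDesign(lines_by_cond[cond], config.t, N)
            summ = structural.structural_event_summary(per_line, design)
            all_calls.extend(summ.calls)
            cnv_report[cond] = {
                "n_aneuploidies": summ.n_aneuploidies,
                "n_rearrangements": summ.n_rearrangements,
                "aneuploidy_rate": _rate_json(summ.aneuploidy_rate),
                "rearrangement_rate": _rate_json(summ.rearrangement_rate),
            }
        structural.write_cnv_bed(all_calls, out / "cnv_calls.bed")

        stage = "consequence"
        consequence_report: dict = {}
        if genes:
            index = consequence.GeneIndex(genes)
            for cond, lns in lines_by_cond.items():
                all_vs = [v for ln in lns for v in ln.variants]
                anns = [consequence.annotate(v, index, genome) for v in all_vs]
                counts: dict[str, int] = {}
                for a in anns:
                    counts[a.consequence] = counts.get(a.consequence, 0) + 1
                snvs = [v for v in all_vs if v.is_snv]
                test = (asdict(consequence.coding_fraction_test(
                            snvs, genes, genome)) if snvs else None)
                consequence_report[cond] = {"counts": counts,
                                            "coding_test": test}

        report.update({
            "rate_table": rate_table,
            "indel_class_table": indel_table,
            "spectra": spectra,
            "repeat_fraction": repeat_summary,
            "cnv": cnv_report,
            "consequence": consequence_report,
        })
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
        _write_tsv_tables(report, out)
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _indel_class_selector(label: str):
    size_bin, direction = label.rsplit(" ", 1)
    direction = direction.rstrip("s")

    def sel(v):
        if not v.is_indel:
            return False
        c = indels.classify_indel(v)
        return c.direction == direction and c.size_bin == size_bin
    return sel


def _write_tsv_tables(report: dict, out: Path) -> None:
    rows = []
    for cond, tab in report["rate_table"].items():
        for kind in ("snv", "indel"):
            r = tab[kind]
            rows.append({"condition": cond, "class": kind, **{
                k: r[k] for k in ("point", "ci_low", "ci_high", "n_events")}})
    pd.DataFrame(rows).to_csv(out / "rates.tsv", sep="\t", index=False)
    rows = []
    for cond, spec_tab in report["spectra"].items():
        for label, n in spec_tab["sbs96"].items():
            rows.append({"condition": cond, "category": label, "count": n})
    pd.DataFrame(rows).to_csv(out / "sbs96.tsv", sep="\t", index=False)
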