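"""Synthetic MAE generator: composition, determinism, event statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from maekit import gc_content, synthetic
from maekit.genome_io import read_genes, read_genome
from maekit.indels import mononucleotide_census
from maekit.spectrum import classify_snv


class TestGenerateGenome:
    def test_gc_within_sampling_error(self):
        genome, _ = synthetic.generate_genome(100_000, gc=0.5, n_genes=0,
                                              seed=41)
        sigma = (0.5 * 0.5 / 100_000) ** 0.5
        assert abs(gc_content(genome) - 0.5) < 3 * sigma + 0.01

    def test_high_gc_respected(self):
        genome, _ = synthetic.generate_genome(50_000, gc=0.65, n_genes=0,
                                              seed=42)
        assert abs(gc_content(genome) - 0.65) < 0.02

    def test_iid_run_lengths_geometric(self):
        """With no homopolymer boost, the run-length distribution matches
        the i.i.d. geometric expectation for a uniform alphabet."""
        genome, _ = synthetic.generate_genome(200_000, gc=0.5, n_genes=0,
                                              seed=43, homopolymer_boost=1.0)
        census = mononucleotide_census(genome, min_run=2)
        hist = census.length_histogram()
        # P(run length = L) proportional to (1/4)^(L-1) * 3/4; ratio of
        # consecutive counts should be ~1/4
        n2, n3 = hist.get(2, 0), hist.get(3, 0)
        assert n2 > 1000
        assert n3 / n2 == pytest.approx(0.25, abs=0.05)

    def test_determinism_byte_identical(self, tmp_path):
        from maekit.genome_io import write_genome, write_genes
        a = synthetic.generate_genome(20_000, n_genes=5, seed=44)
        b = synthetic.generate_genome(20_000, n_genes=5, seed=44)
        for (g, genes), name in ((a, "a"), (b, "b")):
            write_genome(g, tmp_path / f"{name}.fa")
            write_genes(genes, tmp_path / f"{name}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == \
               (tmp_path / "b.gff3").read_bytes()

    def test_genes_are_valid_orfs(self, small_genome):
        genome, genes = small_genome
        assert len(genes) == 10
        for g in genes:
            cds = g.spliced_cds(genome)
            assert cds[:3] == "ATG" and cds[-3:] == "TAA"
            assert len(cds) % 3 == 0

    def test_gene_packing_error(self):
        with pytest.raises(ValueError, match="packing"):
            synthetic.generate_genome(10_000, n_genes=50, seed=1)

    def test_files_round_trip(self, tmp_path, small_genome):
        from maekit.genome_io import write_genome, write_genes
        genome, genes = small_genome
        write_genome(genome, tmp_path / "g.fa")
        write_genes(genes, tmp_path / "g.gff3")
        back = read_genome(tmp_path / "g.fa")
        assert back.sequences == genome.sequences
        gback = read_genes(tmp_path / "g.gff3")
        assert sorted(g.cds[0] for g in gback) == sorted(g.cds[0] for g in genes)


class TestSimulateLines:
    def test_poisson_event_count_scale(self, small_genome):
        """Total SNV rate 1e-7 over 1.25e8 site-divisions per line gives
        Poisson(12.5) counts per line."""
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(
            label="x", snv_rates={"C>T": 1e-7}, indel_rates={})
        lines, _ = synthetic.simulate_lines(genome, None, prof, 40, 100, 25,
                                            seed=45)
        counts = [len(ln.variants) for ln in lines]
        mean = np.mean(counts)
        expected = 1e-7 * genome.total_length * 100 * 25
        assert abs(mean - expected) < 3 * (expected / 40) ** 0.5

    def test_zero_rates_empty(self, small_genome):
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(label="null", snv_rates={},
                                          indel_rates={})
        lines, truth = synthetic.simulate_lines(genome, None, prof, 3, 100,
                                                25, seed=46)
        assert all(not ln.variants for ln in lines)
        assert all(not rec["snvs"] and not rec["indels"]
                   for rec in truth.lines.values())

    def test_classes_match_request(self, small_genome):
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(
            label="x", snv_rates={"T>G": 2e-7}, indel_rates={})
        lines, _ = synthetic.simulate_lines(genome, None, prof, 3, 100, 25,
                                            seed=47)
        for ln in lines:
            for v in ln.variants:
                assert classify_snv(v).label == "T>G"

    def test_ref_alleles_match_genome(self, small_genome):
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(
            label="x", snv_rates={"C>A": 1e-7},
            indel_rates={"del1": 5e-8, "ins2": 3e-8, "del3+": 3e-8})
        lines, _ = synthetic.simulate_lines(genome, None, prof, 5, 100, 25,
                                            seed=48)
        for ln in lines:
            for v in ln.variants:
                assert genome.fetch(v.chrom, v.pos, v.pos + len(v.ref)) == v.ref

    def test_determinism(self, small_genome):
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(
            label="x", snv_rates={"C>T": 1e-7}, indel_rates={"del1": 5e-8})
        a, _ = synthetic.simulate_lines(genome, None, prof, 3, 100, 25, seed=49)
        b, _ = synthetic.simulate_lines(genome, None, prof, 3, 100, 25, seed=49)
        assert [(v.chrom, v.pos, v.ref, v.alt) for ln in a for v in ln.variants] \
            == [(v.chrom, v.pos, v.ref, v.alt) for ln in b for v in ln.variants]

    def test_truth_matches_variants_record_for_record(self, small_genome):
        genome, _ = small_genome
        prof = synthetic.ConditionProfile(
            label="x", snv_rates={"C>T": 1e-7}, indel_rates={"del1": 1e-7})
        lines, truth = synthetic.simulate_lines(genome, None, prof, 4, 100,
                                                25, seed=50)
        for ln in lines:
            rec = truth.lines[ln.line_id]
            emitted = sorted((v.chrom, v.pos, v.ref, v.alt) for v in ln.variants)
            recorded = sorted(
                [(s["chrom"], s["pos"], s["ref"], s["alt"]) for s in rec["snvs"]]
                + [(i["chrom"], i["pos"], i["ref"], i["alt"])
                   for i in rec["indels"]])
            assert emitted == recorded

    def test_zeocin_context_bias_visible(self, small_genome):
        """Zeocin-preset T-centered SNVs carry a 5' G more often than the
        genomic background at T sites."""
        genome, _ = small_genome
        prof = dataclasses.replace(
            synthetic.PRESETS["zeocin"],
            snv_rates={k: v * 500 for k, v in
                       synthetic.PRESETS["zeocin"].snv_rates.items()},
            indel_rates={})
        lines, _ = synthetic.simulate_lines(genome, None, prof, 5, 100, 25,
                                            seed=51)
        from maekit.spectrum import snv_context
        t_contexts = []
        for ln in lines:
            for v in ln.variants:
                cls = classify_snv(v)
                if cls.label.startswith("T"):
                    ctx = snv_context(genome, v, k=1)
                    if ctx:
                        t_contexts.append(ctx)
        assert len(t_contexts) > 200
        frac_g5 = np.mean([c[0] == "G" for c in t_contexts])
        # background: fraction of T-centered trinucleotides with 5' G
        from maekit.spectrum import genome_context_expectation
        exp = genome_context_expectation(genome)
        bg = sum(f for tri, f in exp.items()
                 if tri[1] == "T" and tri[0] == "G")
        assert frac_g5 > bg + 0.1


class TestSimulateDepth:
    def test_mean_depth_without_cnvs(self, small_genome):
        genome, _ = small_genome
        tracks = synthetic.simulate_depth(genome, [], mean_depth=40,
                                          window=500, seed=52)
        depths = np.concatenate([t.depths for t in tracks])
        se = 40 ** 0.5 / len(depths) ** 0.5
        assert abs(depths.mean() - 40) < 4 * se

    def test_duplicated_chromosome_doubles(self, small_genome):
        genome, _ = small_genome
        truth = [{"chrom": "chr1", "start": 0,
                  "end": genome.total_length, "state": 2,
                  "kind": "aneuploidy"}]
        tracks = synthetic.simulate_depth(genome, truth, mean_depth=40,
                                          window=500, seed=53)
        assert tracks[0].depths.mean() == pytest.approx(80, rel=0.05)

    def test_bad_depth_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            synthetic.simulate_depth(genome, [], mean_depth=0)


def test_end_to_end_rate_recovery(small_genome):
    """Full pipeline on simulated lines recovers the generating total SNV
    rate within 20% when at least 50 events are expected."""
    from maekit.rates import ExperimentDesign, estimate_rate
    genome, _ = small_genome
    prof = synthetic.ConditionProfile(
        label="x",
        snv_rates={"C>T": 3e-8, "C>A": 1e-8, "T>A": 1e-8},
        indel_rates={})
    true_rate = prof.total_snv_rate
    lines, _ = synthetic.simulate_lines(genome, None, prof, 20, 100, 25,
                                        seed=54)
    design = ExperimentDesign(lines, 25, genome.total_length)
    est = estimate_rate(lines, lambda v: v.is_snv, design, n_boot=500, seed=1)
    assert est.n_events >= 50
    assert abs(est.point - true_rate) / true_rate < 0.2
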