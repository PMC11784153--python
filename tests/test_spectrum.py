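"""Substitution spectra: class mapping, SBS96, enrichment, flank matrices."""

import collections
import itertools
import random

import numpy as np
import pytest
from scipy import stats

from maekit import Genome, Variant, synthetic
from maekit.genome_io import revcomp
from maekit.spectrum import (SBS96_LABELS, SUBSTITUTION_CLASSES,
                             classify_snv, collapse_to_six,
                             context_enrichment, flank_matrix,
                             genome_context_expectation, sbs96_counts,
                             site_composition_test, six_class_counts,
                             snv_context)


def snv(pos, ref, alt, chrom="c1"):
    return Variant("l", chrom, pos, ref, alt)


class TestClassifySnv:
    @pytest.mark.parametrize("ref,alt,label,transition", [
        ("C", "T", "C>T", True),
        ("G", "A", "C>T", True),   # purine call folded onto pyrimidine strand
        ("A", "C", "T>G", False),
        ("T", "C", "T>C", True),
        ("G", "C", "C>G", False),
        ("A", "T", "T>A", False),
    ])
    def test_pyrimidine_normalization(self, ref, alt, label, transition):
        cls = classify_snv(snv(0, ref, alt))
        assert cls.label == label
        assert cls.is_transition is transition
        assert cls.purine_original == (ref in "AG")

    def test_rejects_indel(self):
        with pytest.raises(ValueError):
            classify_snv(Variant("l", "c", 0, "AT", "A"))

    def test_double_reverse_complement_identity(self):
        for ref, alt in itertools.permutations("ACGT", 2):
            label = classify_snv(snv(0, ref, alt)).label
            back = classify_snv(snv(0, revcomp(ref), revcomp(alt))).label
            assert label == back


class TestSnvContext:
    def test_purine_center_reverse_complemented(self):
        # genome AAGTA, G>A at pos 2: plus-strand window "AGT",
        # reverse complement "ACT", center C, class C>T
        g = Genome({"c1": "AAGTA"})
        assert snv_context(g, snv(2, "G", "A"), k=1) == "ACT"

    def test_pyrimidine_center_unmodified(self):
        g = Genome({"c1": "AACTA"})
        assert snv_context(g, snv(2, "C", "T"), k=1) == "ACT"

    def test_chromosome_end_excluded(self):
        g = Genome({"c1": "CGTA"})
        assert snv_context(g, snv(0, "C", "T"), k=1) is None
        assert snv_context(g, snv(3, "A", "G"), k=1) is None

    def test_n_context_excluded(self):
        g = Genome({"c1": "ANCTA"})
        assert snv_context(g, snv(2, "C", "T"), k=1) is None


class TestSbs96:
    def test_one_hot(self):
        g = Genome({"c1": "AACTA"})
        counts = sbs96_counts([snv(2, "C", "T")], g)
        assert counts.sum() == 1
        assert counts["A[C>T]T"] == 1

    def test_sum_equals_snvs_minus_exclusions(self, small_genome):
        genome, _ = small_genome
        seq = genome.sequences["chr1"]
        rng = random.Random(0)
        variants = []
        for _ in range(400):
            p = rng.randrange(len(seq))
            ref = seq[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(snv(p, ref, alt, "chr1"))
        counts = sbs96_counts(variants, genome)
        assert counts.sum() + counts.attrs["n_excluded"] == 400

    def test_matches_brute_force_recount(self, small_genome):
        genome, _ = small_genome
        seq = genome.sequences["chr1"]
        rng = random.Random(1)
        variants = []
        for _ in range(500):
            p = rng.randrange(1, len(seq) - 1)
            ref = seq[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(snv(p, ref, alt, "chr1"))
        counts = sbs96_counts(variants, genome)
        # independent brute-force tally with plain string ops
        brute = collections.Counter()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for v in variants:
            tri = seq[v.pos - 1:v.pos + 2]
            ref, alt = v.ref, v.alt
            if ref in "AG":
                tri = "".join(comp[b] for b in reversed(tri))
                ref, alt = comp[ref], comp[alt]
            brute[f"{tri[0]}[{ref}>{alt}]{tri[2]}"] += 1
        for label in SBS96_LABELS:
            assert counts[label] == brute.get(label, 0)

    def test_six_class_collapse_matches_direct_counts(self, small_genome):
        genome, _ = small_genome
        seq = genome.sequences["chr1"]
        rng = random.Random(2)
        variants = [snv(p, seq[p], rng.choice([b for b in "ACGT" if b != seq[p]]),
                        "chr1")
                    for p in rng.sample(range(1, len(seq) - 1), 300)]
        collapsed = collapse_to_six(sbs96_counts(variants, genome))
        direct = six_class_counts(variants)
        assert (collapsed == direct).all()


class TestGenomeContextExpectation:
    def test_all_c_genome(self):
        g = Genome({"c1": "C" * 50})
        exp = genome_context_expectation(g)
        assert exp["CCC"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one_per_center(self, small_genome):
        genome, _ = small_genome
        exp = genome_context_expectation(genome)
        for center in "CT":
            assert exp[exp.index.str[1] == center].sum() == pytest.approx(1.0)

    def test_periodic_genome_matches_hand_enumeration(self):
        g = Genome({"c1": "ACGT" * 25})
        exp = genome_context_expectation(g)
        # windows: ACG, CGT, GTA, TAC repeating; centered on C: ACG and
        # GTA (revcomp TAC); centered on T: CGT->ACG? no: CGT center G ->
        # revcomp ACG (center C); GTA center T stays; TAC center A ->
        # revcomp GTA (center T).
        # Counts of 98 windows: ACG x25, CGT x25, GTA x25, TAC x23.
        # C-centered: ACG(25) + ACG(from CGT, 25) = 50 -> freq 1.
        # T-centered: GTA(25) + GTA(from TAC, 23) = 48 -> freq 1.
        assert exp["ACG"] == pytest.approx(1.0)
        assert exp["GTA"] == pytest.approx(1.0)

    def test_matches_sliding_window_tally(self):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(5_000))
        g = Genome({"c1": seq})
        exp = genome_context_expectation(g)
        tally = collections.Counter()
        for i in range(len(seq) - 2):
            tri = seq[i:i + 3]
            if tri[1] in "AG":
                tri = revcomp(tri)
            tally[tri] += 1
        for center in "CT":
            total = sum(n for t, n in tally.items() if t[1] == center)
            for tri, n in tally.items():
                if tri[1] == center:
                    assert exp[tri] == pytest.approx(n / total)


class TestContextEnrichment:
    def _uniform_expectation(self):
        import pandas as pd
        idx = [f"{a}{c}{b}" for c in "CT" for a in "ACGT" for b in "ACGT"]
        return pd.Series(1 / 16, index=idx)

    def test_proportional_counts_not_flagged(self):
        import pandas as pd
        counts = pd.Series(0, index=list(SBS96_LABELS), dtype=int)
        for label in SBS96_LABELS:
            if label[2:5] == "C>T":
                counts[label] = 10  # exactly uniform = expectation
        res = context_enrichment(counts, self._uniform_expectation())
        assert res and all(r.adjusted_p > 0.01 for r in res)

    def test_toy_chi_squared_formula(self):
        """30 of 40 SNVs in a context expected at frequency 0.25."""
        import pandas as pd
        counts = pd.Series(0, index=list(SBS96_LABELS), dtype=int)
        counts["A[C>T]A"] = 30
        counts["G[C>T]G"] = 10
        exp = self._uniform_expectation() * 0  # start at zero
        exp["ACA"] = 0.25
        exp["GCG"] = 0.75
        res = context_enrichment(counts, exp, min_class_count=10)
        by_tri = {r.trinucleotide: r for r in res if r.family == "C>T"}
        o, e = 30, 40 * 0.25
        expected_stat = (o - e) ** 2 / e + ((40 - o) - (40 - e)) ** 2 / (40 - e)
        assert by_tri["ACA"].statistic == pytest.approx(expected_stat)
        assert by_tri["ACA"].pvalue == pytest.approx(
            float(stats.chi2.sf(expected_stat, 1)))

    def test_small_class_skipped_with_warning(self, caplog):
        import pandas as pd
        counts = pd.Series(0, index=list(SBS96_LABELS), dtype=int)
        counts["A[C>G]A"] = 3
        with caplog.at_level("WARNING"):
            res = context_enrichment(counts, self._uniform_expectation(),
                                     min_class_count=10)
        assert res == []
        assert "skipped" in caplog.text

    def test_injected_bias_detected(self, small_genome):
        """SNVs drawn 5x more often from 5'-GT*-3' contexts flag that
        trinucleotide while an unbiased draw flags nothing."""
        genome, _ = small_genome
        exp = genome_context_expectation(genome)
        prof = synthetic.ConditionProfile(
            label="biased",
            snv_rates={"T>A": 4e-7},
            indel_rates={},
            context_bias={"T>A": {f"GT{b}": 5.0 for b in "ACGT"}},
        )
        lines, _ = synthetic.simulate_lines(genome, None, prof, 4, 100, 25,
                                            seed=9)
        snvs = [v for ln in lines for v in ln.variants]
        assert len(snvs) > 100
        res = context_enrichment(sbs96_counts(snvs, genome), exp)
        flagged = {r.trinucleotide for r in res
                   if r.adjusted_p < 0.01 and r.observed > r.expected}
        assert flagged & {f"GT{b}" for b in "ACGT"}


class TestFlankMatrix:
    def test_identical_flanks_two_bits(self):
        g = Genome({"c1": "ACGTACGTACGT" * 3})
        # every C at positions 1, 5, 9... has identical context
        vs = [snv(p, "C", "T") for p in range(5, 25, 4)]
        fm = flank_matrix(vs, g, window=4)
        assert np.allclose(fm.information.to_numpy(), 2.0)
        assert np.allclose(fm.frequencies.sum(axis=1).to_numpy(), 1.0)

    def test_uniform_flanks_near_zero_bits(self):
        rng = random.Random(6)
        seq = "".join(rng.choice("ACGT") for _ in range(20_000))
        g = Genome({"c1": seq})
        vs = [snv(p, seq[p], "T" if seq[p] != "T" else "A")
              for p in range(10, 19_000, 10) if seq[p] == "C"]
        fm = flank_matrix(vs, g, window=4)
        assert fm.information.abs().max() < 0.05

    def test_constructed_five_prime_t(self):
        """C>T SNVs placed only after a 5' T: that position is all T."""
        seq = ("AG" + "TC" + "GA") * 60  # every C preceded by T
        g = Genome({"c1": seq})
        vs = [snv(p, "C", "T") for p in range(3, len(seq) - 4, 6)]
        fm = flank_matrix(vs, g, window=1)
        assert fm.frequencies.loc[-1, "T"] == pytest.approx(1.0)

    def test_empty_class_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            flank_matrix([], genome)

    def test_mixed_classes_rejected(self):
        g = Genome({"c1": "AACTAACTAA"})
        with pytest.raises(ValueError, match="classes"):
            flank_matrix([snv(2, "C", "T"), snv(3, "T", "G")], g)


class TestSiteComposition:
    def test_extreme_case(self):
        vs = [snv(i, "C", "T") for i in range(100)]
        res = site_composition_test(vs, 0.5)
        assert res.fraction_gc == 1.0 and res.pvalue < 1e-20

    def test_fraction_conservation(self):
        vs = [snv(0, "C", "T"), snv(1, "A", "G"), snv(2, "G", "T")]
        res = site_composition_test(vs, 0.5)
        assert res.fraction_gc == pytest.approx(2 / 3)

    def test_matches_exact_binomial_sum(self):
        """160 of 247 SNVs at G/C vs genome GC 0.494, against a direct
        tail-probability summation."""
        vs = [snv(i, "C", "T") for i in range(160)] + \
             [snv(i, "A", "G") for i in range(160, 247)]
        res = site_composition_test(vs, 0.494)
        n, p = 247, 0.494
        probs = [stats.binom.pmf(k, n, p) for k in range(n + 1)]
        cutoff = probs[160] * (1 + 1e-7)
        expected = sum(pr for pr in probs if pr <= cutoff)
        assert res.pvalue == pytest.approx(expected, rel=1e-6)

    def test_no_snvs_rejected(self):
        with pytest.raises(ValueError):
            site_composition_test([], 0.5)


def test_spectrum_recovers_generator_weights(small_genome):
    """Simulated spectra match the generating class weights (chi-squared
    goodness-of-fit not rejected at 0.01)."""
    genome, _ = small_genome
    prof = synthetic.PRESETS["spontaneous"]
    weights = np.array([prof.snv_rates[c] for c in SUBSTITUTION_CLASSES])
    weights = weights / weights.sum()
    boosted = synthetic.ConditionProfile(
        label="boosted",
        snv_rates={k: v * 2000 for k, v in prof.snv_rates.items()},
        indel_rates={},
    )
    lines, _ = synthetic.simulate_lines(genome, None, boosted, 10, 100, 25,
                                        seed=13)
    counts = six_class_counts([v for ln in lines for v in ln.variants])
    assert counts.sum() >= 500
    stat, p = stats.chisquare(counts.to_numpy(),
                              counts.sum() * weights)
    assert p > 0.01
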