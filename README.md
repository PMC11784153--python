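# maekit

Analysis toolkit for **mutation-accumulation experiments** (MAEs) in
haploid microbes: estimate spontaneous and mutagen-induced mutation
rates from per-line variant calls, characterize substitution spectra and
sequence-context biases, annotate indels by tandem-repeat (slippage)
context, and detect aneuploidy and segmental copy-number variants from
read-depth tracks. A built-in synthetic-experiment generator produces
complete datasets with ground truth, so every analysis stage is testable
without any sequencing data.

It is written for microbial genomicists who already have per-line
variant calls (VCF or TSV), a reference genome (FASTA), and an
annotation (GFF3) — typically from a serial single-colony passaging
experiment — and want publication-grade rates, spectra, and tables.

## The model

In an MAE, each line passes through repeated single-colony bottlenecks;
a colony grows from one cell through ≈ *t* divisions (default *t* = 25),
so a line streaked for *g* cycles accumulates mutations over *g·t*
divisions. For an experiment with total cycle count gen<sub>tot</sub>
across lines, a genome of *N* bp, and *n* observed events:

    μ_bp  = n / (N · gen_tot · t)      (per base per cell division)
    μ_lar = n / (gen_tot · t)          (per cell division; aneuploidy,
                                        rearrangements)

Confidence intervals come from a seeded percentile bootstrap over whole
lines (denominators recomputed per resample); an exact Poisson interval
is available. Spectra use the COSMIC SBS convention — every substitution
referred to its pyrimidine strand, 6 classes × 16 flanking dinucleotides
= 96 categories — with per-class chi-squared context-enrichment tests
against genome-composition expectations. Indels are left-aligned,
binned by size (1 / 2 / ≥3 bp × direction), and annotated for tandem
repeats (the footprint of replication slippage). Coverage is normalized
to relative coverage (RC ≈ 0/1/2 for 0/1/2 copies in a haploid) and
thresholded runs of windows become CNV calls. See `docs/methods.md` for
assumptions, defaults, and limitations.

## Worked example

Point rates from an experiment layout and its event counts — here the
layout of a published *Yarrowia lipolytica* MAE (21 lines: 11 × 103 and
10 × 120 cycles, *t* = 25, *N* = 20.5 Mb) with its 247 SNVs and 192
indels:

```python
from maekit import (ExperimentDesign, LineRecord, per_base_rate,
                    structural_rate, total_divisions)

lines = ([LineRecord(f"WY{i+1}", "spontaneous", 103) for i in range(11)]
         + [LineRecord(f"WY{i+12}", "spontaneous", 120) for i in range(10)])
design = ExperimentDesign(lines, t=25, genome_size=20_500_000)

print("total divisions:", total_divisions(lines, design.t))
snv = per_base_rate(247, design)
indel = per_base_rate(192, design)
print(f"SNV rate:   {snv.point:.3g} per bp per division")
print(f"InDel rate: {indel.point:.3g} per bp per division")
print(f"aneuploidy: {structural_rate(1, design).point:.3g} per division")
print(f"1 SNV anywhere in the genome every "
      f"{1/(snv.point*20_500_000):.0f} divisions")
```

prints

```
total divisions: 58325
SNV rate:   2.07e-10 per bp per division
InDel rate: 1.61e-10 per bp per division
aneuploidy: 1.71e-05 per division
1 SNV anywhere in the genome every 236 divisions
```

i.e. one base substitution per 4.8 Tb of replicated genome, and roughly
one SNV somewhere in the genome every 236 cell divisions — the scale at
which spontaneous mutation supplies variation in this yeast.

A full synthetic round trip — generate an experiment, analyze it back —
is one command:

```sh
maekit simulate --profile zeocin --lines 8 --cycles 22 --out-dir ds/
maekit rates --genome ds/genome.fa --metadata ds/metadata.tsv
```

or programmatically via `maekit.synthetic.generate_genome` /
`simulate_lines` and `maekit.pipeline.run_all` (see
`tests/test_pipeline.py` for a complete, runnable configuration).

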