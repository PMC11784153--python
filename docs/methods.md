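# Methods

`maekit` analyzes mutation-accumulation experiments (MAEs): many
independent lines of a haploid microbe are passaged through repeated
single-colony bottlenecks so that mutations accumulate with minimal
selection, then sequenced once at the end. The package takes the
*products* of variant calling (VCF/TSV per line, a reference FASTA, a
GFF3 annotation, optional per-window depth tables) and produces rates,
spectra, indel repeat annotations, CNV calls, and consequence summaries.
Read alignment and variant calling themselves are out of scope.

## Rate model

Each subculture cycle transfers one colony, and a colony grows from a
single cell through approximately `t` cell divisions. A line streaked
for `g` cycles therefore experiences `g * t` divisions; an experiment
accumulates `gen_tot * t = (sum of g_i) * t` divisions in total. Rates
are

    mu_bp  = n / (N * gen_tot * t)     per base per cell division,
    mu_lar = n / (gen_tot * t)         per cell division,

where `n` is the event count and `N` the genome length. `t` defaults to
25 (a typical yeast colony) but is a configuration field, since it is an
approximation, not a measurement. `N` is taken from the loaded FASTA by
default and can be overridden by a constant (e.g. 20,500,000 bp for the
*Yarrowia lipolytica* reference) to reproduce published arithmetic
digit-for-digit.

This estimator assumes (i) negligible selection during passaging,
(ii) complete detection of accumulated variants, and (iii) independence
of lines. No correction for detection power or for fluctuation-assay
style jackpot effects is attempted.

### Confidence intervals

Published MAE intervals are typically asymmetric and wider than a naive
Poisson interval because between-line variance exceeds Poisson
expectation. The default CI is therefore a nonparametric bootstrap over
whole lines: lines are resampled with replacement, and both the event
count and the division denominator are recomputed per resample
(percentile method, `n_boot = 10,000`, seeded and fully deterministic).
With the percentile method the point estimate is not mathematically
guaranteed to lie inside the interval, though it does in practice;
`ci_low <= ci_high` always holds. An exact (Garwood) Poisson interval is
available as `ci_method="poisson"`. A single-line experiment has no
between-line variance to resample; it returns a degenerate flagged
interval rather than crashing.

### Comparisons

Between-condition comparisons use the two-sided Wilcoxon rank-sum test
on per-line rates, each line carrying its own denominator. The exact
null is used for small tie-free samples (both groups <= 8), the normal
approximation with tie correction otherwise. Two degenerate inputs are
special-cased to p = 1: all rates identical, and identical rate
multisets in the two groups (exactly null, no ties broken). Rate classes
with no events are reported as rate 0 with an explicit
"no events observed" flag rather than omitted.

## Substitution spectra

Every SNV is referred to its pyrimidine strand (COSMIC SBS convention):
a G>A call is counted as C>T with its context reverse-complemented so
the mutated pyrimidine sits at the center. Six substitution classes x 16
flanking-dinucleotide combinations give the 96 SBS categories.

Genome context expectations are conditioned on the center base: for each
pyrimidine-normalized trinucleotide, its frequency among genome
positions whose normalized center matches (C-centered and T-centered
frequencies each sum to 1). Both strands enter through the
normalization, each position counted once. Conditioning on the center
base (rather than on all trinucleotides) is the package's choice; it
makes the expectation independent of the genome's GC split between C-
and T-centered sites.

Enrichment is tested per substitution class: each of the class's 16
trinucleotides gets a 1-df chi-squared goodness-of-fit against its
complement, with expected count = class total x conditioned genome
frequency. Expected counts below 5 fall back to an exact binomial test
(logged). The multiple-comparison family is one substitution class (16
tests); the default adjustment is Bonferroni — conservative, matching a
generic "adjusted for multiple comparisons" — with Benjamini–Hochberg
selectable. Classes with fewer than `min_class_count` (default 10) SNVs
are skipped with a warning: a goodness-of-fit over 16 cells is
meaningless below that.

Flank matrices (sequence-logo data) record per-position base frequencies
over a +-4 bp window on the normalized strand; information content is
`2 - H` bits per position with no small-sample correction (the
correction matters only for tens of sites, and the uncorrected value is
what a logo displays). SNVs within the window of a chromosome end, or
with an N in the window, are excluded and counted, never silently
dropped. Trinucleotide analyses use k = 1, logos k = 4.

The G/C-site composition test is a two-sided exact binomial test of the
number of SNVs whose original reference base is G or C against the
genome GC fraction.

## Indels and repeat context

Indels are left-aligned and parsimony-trimmed against the reference (the
standard VCF normalization) before any classification; size bins are
1 bp / 2 bp / >= 3 bp by direction. Events longer than 50 bp (config
`max_indel_len`) are excluded from indel statistics and routed to the
structural side — published analyses rarely state this cutoff, so it is
explicit here.

Slippage annotation: the inserted/deleted sequence is tested as `k`
copies of a unit `u` for every divisor of the indel length (shortest
qualifying unit wins, so an AA deletion inside an A-run reports unit A);
the locus is "in a tandem repeat" when the reference carries at least
`min_copies` tandem copies of `u` at or adjacent to the event
(default 2, i.e. a >= 2-mer homopolymer qualifies for a 1 bp event; the
literature does not pin this threshold down, so it is exposed rather
than guessed). The search window is 50 bp each side of the event;
longer repeats are truncated at the window edge and flagged.

The mononucleotide census tabulates every maximal single-base run of
length >= `min_run` by base and length. Runs are maximal — flanked by a
different base or a chromosome end — and strand-symmetric, so they are
counted once.

## Coverage-based CNV calling

Per-window depth is normalized by the genome-wide **median** window
depth, giving relative coverage (RC) where 0/1/2 ≈ 0/1/2 copies in a
haploid. The median is robust as long as CNVs occupy well under half
the genome; the acceptance simulations respect that regime. Calls are
maximal runs of >= `min_windows` (default 10) consecutive windows with
RC <= 0.5 (deletion) or RC >= 1.5 (duplication); runs touching a
chromosome end are terminal, runs covering >= 90% of a chromosome are
whole-chromosome (counted as aneuploidy in rate summaries), the rest
interstitial. All thresholds are configuration. No GC-bias correction
is applied by default — the synthetic depth model is unbiased — but the
depth tables pass through a single normalization point where a
correction hook can be inserted.

## Consequence annotation

"Coding" means the CDS footprint only; introns and UTRs count as
non-coding, and the genomic coding fraction used by the chi-squared
coding/non-coding test is always computed from the provided GFF3, never
assumed. SNV consequences come from codon comparison on the gene strand
(standard nuclear code): start_lost (codon 1 ATG abolished) outranks
missense; stop_lost / stop_gained by stop-codon comparison. CDS indels
are frameshift when length % 3 != 0, in-frame otherwise; indels
spanning a CDS boundary are flagged and counted coding. Variants in
multiple genes report the most severe consequence with the full list
retained. Genes with inconsistent CDS structure (overlapping segments,
length not a multiple of 3 after phase) are flagged at load and their
variants marked unannotatable rather than mis-translated.

## Synthetic experiment generator

The generator's defaults are the study conditions the analysis targets,
not tuning knobs.

* **Genome**: first-order Markov chain at the requested GC fraction;
  `homopolymer_boost` multiplies the self-transition probability,
  inflating run lengths (boost 1 = i.i.d., geometric run lengths).
  Genes are complete ORFs (ATG ... TAA, no internal stops) written into
  the sequence on random strands, non-overlapping.
* **Per-line events**: counts per class are Poisson with mean
  `rate * N * cycles * t` — independent divisions, no selection, the
  MAE design assumption. SNV positions are importance-sampled over
  precomputed eligible-site indices with per-class trinucleotide
  weights; a biased class samples its preferred contexts in proportion
  to the weight.
* **Indels**: with probability `slippage_fraction` an event
  expands/contracts a mononucleotide run by whole units (deletions keep
  at least one copy so the locus remains a run); the remainder is
  rejection-sampled into sites the repeat annotator classifies as
  non-repeat, so the generating slippage flag and the analyzer's
  in-repeat call coincide by construction and the recovered fraction is
  a clean binomial estimate of the parameter.
* **CNVs**: per-line Poisson counts at per-division rates; aneuploidies
  duplicate a whole chromosome, rearrangements take 5–30% of one.
  Depth is Poisson(`mean_depth * copy_state`) per window.

The built-in presets (`spontaneous`, `uv`, `mms`, `zeocin`) carry the
per-class rate magnitudes reported for *Y. lipolytica* (total SNV rates
2.07e-10 / 1.104e-8 / 6.91e-9 / 5.32e-9 per bp per division; the
published indel-class rate table; structural rates of order 1e-5–1e-4
per division) and the qualitative context signatures: UV C>T at 5'
pyrimidines, MMS T>A/T>G with 5'-GTC / 5'-NTG preferences, Zeocin
T>A/T>G at 5'-G (the bleomycin 5'-G-Py rule) with T>A about twice T>G.
Where only class percentages were published (e.g. spontaneous C>T 43%,
C>A 19%), the remaining mass is split plausibly across the minor
classes; the presets are config data, not hard-coded truth, and any
profile can be built from scratch.

What the generator does **not** emulate: alignment/calling artifacts,
mapping bias, GC-coverage bias, clustered mutations (MMBIR-like),
selection, and real indel length distributions beyond the three bins
(a geometric tail above 3 bp stands in). Passing tests therefore
demonstrate the statistical machinery is correct under the stated
model, not that the upstream calling pipeline is artifact-free.

## Numerical and scale choices

* Left-alignment extends through the reference; an indel whose run
  touches position 0 of a chromosome cannot take anchor-base form and
  is an error (the synthetic generator never produces one).
* Multi-nucleotide substitutions are rejected with a warning, not split
  into SNVs — how upstream callers represent them is ambiguous.
* Bootstrap resampling is vectorized (an `(n_boot, n_lines)` index
  matrix), so the default 10,000 resamples cost milliseconds.
* Test and acceptance simulations use 50–200 kb genomes with per-class
  rates scaled so expected event counts land in the tens-to-thousands;
  the estimators are invariant to this joint scaling of rate x genome
  size, so small genomes exercise exactly the arithmetic used at 20 Mb.
* Rates print with 3 significant figures, matching the convention of
  the tables they reproduce.

## Known limitations

* Coverage-based CNV calling has no breakpoint resolution beyond the
  window size and cannot see copy-neutral rearrangements.
* The coding/non-coding test treats all CDS bases as one class; it does
  not model per-gene mutability.
* The Wilcoxon exact path requires tie-free data; heavily tied
  small-sample comparisons fall back to the tie-corrected normal
  approximation.
* The repeat annotator's `min_copies = 2` default counts a 1 bp
  deletion next to a single identical base as "in a repeat"; analyses
  sensitive to this should sweep the threshold.
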