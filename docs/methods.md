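# Methods

## The screen

`mfscreen` implements a two-gate screen for the dominant male-determining
factor (M factor) of a culicine mosquito, starting from a de novo transcript
assembly, male and female whole-genome alignment counts against it, and a
stage-resolved embryonic expression matrix.

**Gate 1 — chromosome quotient (CQ).** For each transcript with male
alignment count M, female count F and library totals N_M, N_F,

    CQ = (F / N_F) / (M / N_M)

A hemizygous, male-limited sequence attracts essentially no female genomic
reads, so its CQ sits near 0; autosomal sequences sit near 1; sequences with
female dosage bias near 2. The gate keeps transcripts with **CQ < 0.2,
male count > 20 and female count < 20**, all comparisons strict: boundary
values fail. Conventions chosen here:

* *Orientation* is female-over-male, so male-specific sequences score near 0,
  consistent with the `CQ < 0.2` threshold.
* *Depth normalization* is on by default. With near-equal library sizes it is
  immaterial, but it makes the statistic invariant to depth: multiplying one
  sex's library total and all its counts by a constant leaves CQ unchanged.
  `normalize=False` gives the raw ratio F/M.
* *M = 0* leaves CQ undefined (NaN) rather than infinite; such records can
  never pass (they also fail the male-count clause) and are reported with
  reason `no male coverage`.
* *Counting unit* is one SAM alignment line = one count (not read pairs), at
  `mapq_min=0` and `primary_only=True` by default; unmapped records are
  always skipped. Whether the original screen counted pairs or single-end
  alignments is not recoverable, so the convention is documented rather than
  guessed.

**Gate 2 — staged expression filter.** An M factor must be transcribed by
the zygote at the time of sex determination, but not be maternally deposited
and not be expressed in females. On TMM-scale abundances the gate requires
**E4–8 h > 0, E8–12 h > 0, E0–1 h = 0, adult female = 0**. Replicates are
aggregated by their mean by default (for zero/nonzero conditions the mean
criterion equals "all replicates zero" / "any replicate positive"); an
`all_replicates` mode requires the condition in every replicate. Because
normalization maps zeros to zeros exactly, "TMM > 0" is exact positivity with
no epsilon floor, and the gate's verdicts are identical on raw and normalized
matrices.

**TE exclusion.** Transposase- or reverse-transcriptase-derived transcripts
pass both gates easily (repetitive, often Y/M-enriched) but are not M-factor
candidates; they are removed by a precomputed boolean annotation flag.
Running the homology search itself is out of scope (database-version
dependent); a case-insensitive keyword helper
(`transposase`, `reverse transcriptase`) builds the flag from product
strings when only free text is available.

A transcript is a **final candidate** iff it passes both gates and is not
TE-flagged. The report retains every clause verdict, orders candidates by
ascending CQ then id, and is byte-stable on identical input.

## TMM normalization

TMM (trimmed mean of M-values) is implemented from its definition rather
than wrapped, since the zero-preservation property of the full
normalize-then-filter path is load-bearing here. For library f against a
reference library r, over genes with nonzero counts in both:

    M_g = log2((y_gf/N_f) / (y_gr/N_r))
    A_g = [log2(y_gf/N_f) + log2(y_gr/N_r)] / 2
    w_g = 1 / [ (N_f−y_gf)/(N_f·y_gf) + (N_r−y_gr)/(N_r·y_gr) ]

The top and bottom 30% of M_g and 5% of A_g are discarded (average ranks;
cutoffs `floor(n·trim)+1 … n−floor(n·trim)`), the factor is
`2^(Σ w M / Σ w)` over survivors, and factors are rescaled to geometric
mean 1. The weights are the delta-method (binomial) asymptotic variance of
M_g. The reference library is auto-selected as the sample whose upper
quartile of nonzero library-size-scaled counts is closest to the mean upper
quartile, and can be pinned explicitly. If `max|M_g| < 1e-6` the factor is 1
(identical libraries); a sample sharing no expressed gene with the reference
gets factor 1 with a warning. Normalized values are counts per million of
the effective library size `N_f · factor_f`.

The test suite checks this implementation two independent ways: against a
naive pure-Python re-implementation of the doubly-trimmed weighted mean
(relative error < 1e-9 on random 50×4 Poisson matrices), and against the
reference Bioconductor implementation via `Rscript` with the same reference
column pinned (agreement to < 1e-6).

## The synthetic-data generator

The simulator provides a known-truth world in which the full screen is
testable without any sequence download. It emulates:

* **Three linkage classes** with copy numbers (male, female): hemizygous
  male-specific (1, 0) — the planted M-factor class; autosomal (2, 2);
  female-dosage-biased (1, 2). Defaults: 10 / 200 / 20 contigs, uniform
  random sequence, lengths uniform on 500–2000 nt (spanning typical
  full-length mRNA isoforms).
* **DNA alignment counts** per contig and sex:
  `count ~ Poisson(depth · copy/2 · length_factor)`, with
  `mean = leakage · depth` for a sex with copy number 0. The default
  scenario uses a unit length factor, so `depth` (default 100) is exactly
  the expected count of every autosomal contig and planted M-linked contigs
  sit at depth/2 = 50 expected male alignments — comfortably clear of the
  strict `male > 20` threshold; length-proportional counts are available by
  passing contig lengths. Poisson (not negative-binomial) dispersion is
  adequate for exercising threshold logic; real WGS coverage is
  overdispersed, so a green recovery test does not certify performance on
  real data. `leakage` (default 0) models mismapping into the absent sex:
  at 0 the female count of an M-linked contig is exactly 0.
* **Expression design**: seven stages (0–1, 2–4, 4–8, 8–12 h embryos,
  pupae, adult male, adult female) × 3 replicates. Zygotic genome activation
  defaults to 6.5 h post-oviposition, so the 0–1 h and 2–4 h windows fall
  entirely before activation (M-linked rows exactly zero there and in adult
  females) and the 4–8 h window onward is expressed. Expressed entries are
  rounded log-normal draws (scale 50, log-sd 0.6) floored at 1, mimicking
  quantifier output; autosomal rows are positive everywhere (maternal
  deposition covers pre-activation embryos), and female-biased rows are
  2× elevated in adult females. The generator does not emulate isoform
  structure, positional coverage, GC bias or batch effects.

One global seed feeds `numpy.random.SeedSequence.spawn` substreams per step
(reference set, DNA counts, expression), so the scenario is reproducible
bit-for-bit and enlarging one component does not perturb the others.
Library totals are column sums plus a constant off-target mass (10^6), so
totals always exceed any per-contig count.

With these defaults the screen's recovery of the planted M-linked set is
exact (sensitivity 1.0, zero false positives) for every seed we exercise;
the acceptance tests pin seeds 101, 202 and 303. Female-biased contigs
concentrate near CQ 2 and never approach the CQ gate.

## Candidate characterization

* **ORF finding** scans the forward strand only (inputs are mRNA isoforms),
  all three frames, requiring an ATG start and an in-frame stop within the
  sequence; the longest ORF wins, ties to the 5'-most start. ORFs without a
  stop are not reported — a truncated isoform with a premature stop is
  represented by its short ORF, never by open-ended extension.
* **Translation** uses the standard genetic code with `*` for stops;
  ambiguity codes translate to `X` unless every resolution agrees; trailing
  partial codons are dropped; non-IUPAC characters are hard errors.
* **In-silico PCR** is exact-match (no mismatches, no degenerate-base
  expansion): every forward-primer site paired with every downstream
  reverse-primer site (reverse complement on the forward strand), product
  length spanning both primer footprints, capped by `max_product`.

## Phenotype and qPCR summaries

Per-tissue feminization percentages are reported over all individuals of a
group as `P% (n/total)` with integer half-up rounding; injection tables use
one decimal for hatch rate and two decimals for adult sex ratios (half-up),
so female% + male% prints as 100.00 for any non-degenerate input. Fold
changes use 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference). The bundled
`mosaic_phenotypes_synthetic.csv` is a clearly-labelled reconstruction: its
tallies reproduce published per-tissue totals, but individual-level
co-occurrence of phenotypes is invented.

## Numerical and degenerate-input choices

* Strict inequalities everywhere in the CQ gate; exact zero tests in the
  expression gate (justified by exact zero preservation).
* Coordinates 0-based half-open; TSVs are tab-separated with header, UTF-8,
  `#` comments ignored.
* Empty count table → empty report, not an error. References missing from
  the expression matrix → all-zero expression with a logged warning.
* Depth-invariance of CQ holds to 1e-12; TMM factor geometric mean to 1e-12.

## Known limitations

* The screen operates at transcript granularity; collapsing isoforms to
  genes is out of scope.
* Poisson coverage and the absence of repeat structure make the simulator
  friendlier than real WGS data; thresholds validated here may need
  re-tuning for heavily repetitive genomes.
* BAM/CRAM input is not parsed; convert to SAM text or supply a count TSV.
* The in-silico PCR helper does not model primer thermodynamics or
  tolerate mismatches.
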