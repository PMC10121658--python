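# mfscreen

A reusable implementation of the chromosome-quotient (CQ) screen used to
identify dominant male-determining factors (M factors) in culicine
mosquitoes with homomorphic sex chromosomes — where the male-determining
locus is a small hemizygous region invisible to karyotyping.

**Who it is for.** Researchers with (a) a de novo transcript assembly,
(b) male and female whole-genome resequencing aligned to it, and (c) a
stage-resolved embryonic RNA-seq series, who want to shortlist
male-specific, zygotically-activated transcripts as M-factor candidates —
plus the downstream bits: ORF calling, in-silico PCR for sex-diagnostic
amplicons, and knockout-phenotype summary statistics.

## The statistic and the screen

For each transcript with male/female genomic alignment counts M, F and
library totals N_M, N_F:

```
CQ = (F / N_F) / (M / N_M)
```

CQ ≈ 0 for male-limited (hemizygous M-linked) sequences, ≈ 1 for autosomal,
≈ 2 for female-dosage-biased. A transcript is a final candidate iff:

1. **CQ gate** — CQ < 0.2, male count > 20, female count < 20 (strict);
2. **expression gate** — on TMM-normalized abundances: E4–8 h > 0,
   E8–12 h > 0, E0–1 h = 0, adult female = 0 (zygotic activation, no
   maternal deposition, male-limited);
3. **not transposase/reverse-transcriptase-derived** (annotation flag).

TMM (trimmed mean of M-values) normalization is implemented from its
definition — doubly trimmed (30% on log-ratios M, 5% on abundances A),
inverse-variance-weighted, factors rescaled to geometric mean 1 — and
cross-checked in the tests against both a brute-force oracle and the
Bioconductor reference implementation. See `docs/methods.md` for the full
model and conventions.

## Worked example

Generate a synthetic scenario with a known planted truth (10 hemizygous
M-linked, 200 autosomal, 20 female-biased contigs; depth 100) and screen it:

```
$ mfscreen simulate --seed 11 --out demo
$ mfscreen screen --counts demo/counts.tsv \
    --male-total 1021573 --female-total 1021925 \
    --matrix demo/expression.tsv --samples demo/samples.tsv \
    --out demo/report.tsv
10 final candidate(s)

$ head -4 demo/report.tsv
id        male_count  female_count  cq  cq_pass  expression_pass  te_excluded  final_candidate  fail_reasons
mlk_0001  57          0             0   True     True             False        True
mlk_0002  51          0             0   True     True             False        True
mlk_0003  45          0             0   True     True             False        True

$ tail -5 demo/report.tsv
# summary
# n_references            230
# n_cq_pass               10
# n_cq_and_expression_pass 10
# n_final_candidates      10
```

The library totals come from `demo/manifest.json`. All ten planted
M-linked contigs (ids `mlk_*`, per `demo/truth.tsv`) — and only those —
pass both gates: male counts near 50 (half the autosomal male depth, as
expected for a single-copy locus), zero female counts, CQ = 0.

Phenotype summaries of mosaic knockout males, from a per-individual score
table (here the bundled synthetic reconstruction):

```
$ mfscreen pheno --table src/mfscreen/data/mosaic_phenotypes_synthetic.csv
antennae            54% (21/39)   feminized=21 malformed=0 normal=18
maxillary_palps     90% (35/39)   feminized=35 malformed=0 normal=4
external_genitalia  92% (36/39)   feminized=36 malformed=0 normal=3
gonads              85% (33/39)   feminized=33 malformed=0 normal=6
```

Each line is one sexually dimorphic tissue: the percentage of the 39 mosaic
males scored feminized in that tissue.

Other subcommands: `cq`, `tmm`, `exprfilter` (the individual pipeline
stages), `orf` and `ispcr` (candidate characterization), `injection` and
`ddct` (knockout experiment statistics). `mfscreen --help` lists them all.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default scenario from the given seed, runs the complete
screen end-to-end (TMM normalization included), and reports the recovery of
the planted M-linked truth (sensitivity and false-positive count) on
stderr, writing the JSON result object to `--out`.
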