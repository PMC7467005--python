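# Methods

This note documents the statistical procedures `karyotag` implements, the
choices made where the procedure admitted more than one reading, and what
the synthetic-data generator does and does not emulate.

## Locus genotyping from amplicon reads

A locus is genotyped from the counts of reads containing the
reference-allele probe (`n_ref`) versus the alternate-allele probe
(`n_alt`), both exact substring matches on the read as delivered (the
amplicon orientation is fixed by the library design, so no
reverse-complement search is attempted; base qualities are ignored by
default, matching occurrence-counting pipelines). Reads matching both
probes of a locus are ambiguous and counted as `count_other`, as are reads
assigned to a locus by its forward primer that match neither probe; neither
contributes to depth.

With depth d = n_ref + n_alt and ratio r = n_ref/n_alt (r = ∞ when
n_alt = 0 — no pseudocount, which keeps the call deterministic):

| condition            | call        |
|----------------------|-------------|
| d ≤ 10               | no call     |
| r ≥ 10               | 0 (hom ref) |
| 0.2 ≤ r ≤ 5          | 1 (het)     |
| r ≤ 0.1              | 2 (hom alt) |
| otherwise (dead zone)| no call     |

The depth rule is strict (> 10). The ratio cut-offs are the conventional
values of the multiplexed-amplicon genotyper this caller follows; they are
exposed in `CallThresholds` rather than hard-coded, and the dead zones
(0.1–0.2 and 5–10) deliberately leave borderline loci uncalled.

## Call-rate filtering

Per-tag call rate = called specimens / specimens the tag applies to; per
specimen, rate = called tags / tags applicable to its species. Computing
specimen rates over applicable tags only matters: otherwise every
*An. coluzzii* specimen would be penalised for the *gambiae*-only 2Rj/2Rd
tags it can never score. Both thresholds default to 0.80.

Tags are filtered first, then specimens, with specimen rates recomputed on
the surviving tags. Because removing specimens can in turn drop a tag's
rate below threshold, `filter_matrix` repeats the two passes until nothing
changes; this makes the operation idempotent on any input while leaving the
first pass — the common case on well-behaved data — identical to the
single-pass procedure. The filter report records every dropped tag and
specimen with the rate that condemned it.

## Multilocus karyotype call

For each specimen × applicable inversion, the mean alternate-allele count is
taken over the inversion's non-missing tags and binned into three equal
intervals of [0, 2]:

mean ≤ 2/3 → 0, 2/3 < mean ≤ 4/3 → 1, mean > 4/3 → 2.

The boundaries are exact thirds with lower-bin-inclusive membership; the
familiar two-decimal rendering (0–0.67 / 0.68–1.33 / 1.34–2) is the printed
form of the same edges. Binning is total on [0, 2] and monotone.

Specimens that survive the 80% filter but are missing some of one
inversion's tags are averaged over the tags they do have;
`min_tags_per_inversion` (default 1) sets how few is too few, in which case
the karyotype is missing rather than guessed. Tags are unweighted — no
per-tag concordance weighting is applied. `mean_alt` is written to 4
decimals; the bin is computed on the unrounded value.

## Tag ascertainment

`evaluate_candidate` scores a candidate SNP against specimens of known
inversion genotype: within each class g ∈ {0,1,2}, c_g = (specimens whose
SNP genotype equals g) / (specimens in class g). Missing SNP calls stay in
the denominator and count as mismatches — the conservative choice, and
switchable (`missing_as_mismatch=False`). The minimum c_g over non-empty
classes is the conservative genotypic concordance; empty classes are
flagged (`class_incomplete`) instead of forcing the minimum to zero, which
preserves auditability when a rare homokaryotype is absent from training
data. Under the simulator's haplotype model the class-0 concordance has the
closed form q² with q = (1−p_std)(1−ε) + p_std·ε, which the tests verify
empirically.

Selection filters:

* **Concordance floors** per inversion, with two presets — an array preset
  (0.7 for 2Rb/2Rc/2Ru, 0.75 for 2Rd, 0.9 for 2Rj, 0.9925 for 2La) and a
  sequencing preset (0.8 for 2Rc, 0.85 for 2Rd, 0.9 for 2Rb/2Rj/2Ru, 0.995
  for 2La). Retention is inclusive (min_concordance ≥ floor). The two 2Rc
  tag sets share the 2Rc floor.
* **Flanking-variant screen**: fail if any variant within ±25 bp of the tag
  exceeds 5% frequency in ≥ 1 inversion-genotype class or in ≥ 2 population
  samples — such variants disrupt allele-specific probe annealing.
* **Complexity screen**: fail on homopolymer runs > 5 or windowed
  dinucleotide Shannon entropy < 1.5 bits. These two defaults are this
  tool's own stand-in for external primer-design rejection rules and are
  labelled as tool defaults, not empirical constants.
* **Positional pruning** for over-abundant candidates: keep every k-th
  (default 3rd) candidate of a position-sorted list, anchored at the first
  element (the phase is a convention; the list order is validated).

Population-partition handling (excluding confounded subgroups before
evaluation) is done by the caller through ordinary row selection, not
hard-coded taxonomy.

## Concordance analysis

Complete cytogenetic/array/sequencing triples are classified into five
categories (all agree; molecular pair vs cytogenetics; each single-method
disagreement; all differ); any missing call makes the triple INCOMPLETE and
drops it from the complete-case denominators. Percentages are rounded
half-up to 2 decimals. The per-inversion 3×3 contingency (cytogenetic class
× shared molecular class) is restricted to triples where the two molecular
methods agree, so its diagonal equals the three-way-agreement count and its
off-diagonal the cytogenetic-vs-molecular discordance count — an identity
the tests assert on arbitrary inputs.

The parity test builds a 2×2 of specimen-code parity (odd/even) against
membership in a chosen category (default: molecular pair vs cytogenetics)
and reports chi-square with and without Yates continuity correction plus
the two-sided Fisher exact p. The default unit is the specimen × inversion
observation, because discordances are naturally pooled across inversions; a
specimen-level mode (a specimen is discordant if any selected inversion is)
is provided since either accounting is defensible.

`fisher_exact_2x2` uses the point-probability definition of the two-sided
test: with margins fixed, p sums the hypergeometric probabilities of all
tables whose point probability is ≤ the observed one, with a 1e-7 relative
tolerance for ties (floating-point equality would otherwise split ties
arbitrarily). Degenerate margins give p = 1. The implementation enumerates
the hypergeometric support via `scipy.stats.hypergeom`; tests check it
against an independent full-enumeration oracle on all tables with total
≤ 30 and against `scipy.stats.fisher_exact`.

## The synthetic cohort generator

The generator works at the level of chromosome copies. For each specimen
and inversion, each of the two copies is inverted independently with the
arrangement frequency f, so karyotypes follow Hardy-Weinberg proportions in
expectation. A tag SNP carries the alternate allele with probability
`p_inv` on an inverted copy and `p_std` on a standard copy; each allele is
flipped with error ε; the SNP genotype is the alt-allele count, masked
missing with probability μ. This haplotype-level model was chosen over a
direct per-genotype concordance model because it yields closed-form class
concordances for oracle tests, and because it reproduces, rather than
postulates, the downward bias of misapplied tags: when `p_inv = p_std` is
small (alternate alleles rare regardless of orientation), heterozygous and
inverted specimens are systematically called standard homozygotes.

Read depths are negative-binomial (mean 200, size 5 by default — amplicon
counts are overdispersed relative to Poisson) with binomial allele sampling
at success probability (1−g/2)(1−e) + (g/2)e for genotype g and per-base
error e. Cytogenetic calls equal the truth except with a configurable error
rate that moves the call to a uniformly chosen different class; an
even-code bias flag confines errors to even-numbered specimens, emulating
one of two karyotyping teams mis-scoring. Specimen numeric codes are
assigned sequentially 1..n so odd/even stratification is exercisable by
construction.

Defaults (960 specimens, 45:55 species split, arrangement frequencies
spanning rare 2Rj/2Rd to near-fixed 2La, p_inv = 0.95, p_std = 0.02,
ε = 0.005, μ = 0.02) were chosen once to resemble a West-African
field-cohort genotyping experiment and are the conditions under which the
end-to-end tests run. What the generator does **not** emulate: linkage
disequilibrium decay with distance from breakpoints (all tags of an
inversion are conditionally independent given orientation), recombination
and inversion breakpoint structure, index mis-assignment between specimens,
and locus-specific amplification bias. Passing tests therefore demonstrate
the pipeline's correctness and its statistical behaviour under the stated
model, not the field performance of any particular tag panel.

Problem sizes used by the test suite and the acceptance script (500–5000
specimens, 1–10 tags per inversion) are chosen so Monte-Carlo standard
errors are small relative to the tolerances being checked (3-SE bounds for
distributional checks).

## Shipped reference tables

`karyotag.cohort_data` carries the published summary tables of the
960-mosquito Burkina Faso cohort on which the tag panels were validated:
per-inversion genotype-class contingency blocks (for the six inversions
with published blocks; the low-polymorphism 2Rj block was not published),
complete-case totals, the odd/even parity margins, and the per-platform tag
counts. `calls_from_class_tables` expands the blocks into per-record calls
so the tabulation code paths, not copied constants, produce the summary
quantities; records in the molecular-disagreement categories are padded
from the complete-case totals without attributing their split, which is
exactly the information the blocks carry.

## Degenerate inputs and numerical notes

* Empty genotype matrices are errors for rate computation; an all-dropped
  filter result is an error, not an empty matrix.
* `mean_alt` is undefined (not 0) below `min_tags_per_inversion`;
  `bin_genotype` rejects values outside [0, 2] and NaN.
* Ratio ∞ (n_alt = 0) is an ordinary homozygous-reference call provided
  depth passes.
* Species labels are validated against the inversion registry, which is a
  plain JSON file — adding species or inversions requires no code change.
* All simulation randomness flows through `numpy.random.default_rng` seeds;
  a fixed seed makes every written file byte-identical.
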