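# Methods

## The PMC index model

A policy is evaluated against a two-level framework: primary variables
(dimensions) each holding an ordered list of binary sub-variables
(criteria). Coding assigns each (policy, sub-variable) cell 1 if the
policy text satisfies the criterion, else 0; all sub-variables carry
equal weight. The first-level value of dimension *i* is the mean of its
flags, `X_i = (1/T_i) Σ_j X_ij`, and the PMC index is `Σ_i X_i`, ranging
from 0 to the number of dimensions. The model assumes the criteria are
meaningful yes/no judgements, the framework is complete (no missing
cells — the reader rejects blanks rather than imputing, because the
averages assume full columns), and dimensions are comparable enough
that an unweighted sum is informative.

The default framework has nine dimensions and 41 sub-variables with
per-dimension counts (6, 3, 4, 4, 6, 6, 3, 4, 5). It is package data,
not code: any two-level framework loads from the same YAML format, and
every formula is parameterised by the framework (the divisor `T_i`
always comes from the framework's sub-variable counts).

## Rounding conventions

Published score tables in this literature print first-level values to
two decimals and print a PMC column equal to the sum of the *printed*
values, not of the exact fractions (e.g. exact thirds 2/3 print as 0.67
and contribute 0.67 to the printed sum). The package therefore offers
two summation modes:

- **report-parity** (default): round each first-level value half-up to
  `decimals` places (default 2), then sum. Reproduces printed tables.
- **full-precision**: sum the exact fractions.

Rounding is decimal half-up (0.125 → 0.13), not banker's rounding,
because that is how printed tables behave. The two modes differ by at
most `n · 10^(−decimals)/2`. Percentages in corpus summaries are
rounded half-up to one decimal.

The packaged published table is stored verbatim, typographical quirks
included: a handful of printed first-level values are not expressible
with the default framework's sub-variable counts (e.g. an X8 of 0.67
where X8 has four sub-variables). `ReferenceScoreTable.parity_mismatches`
reports — never corrects — rows whose printed PMC disagrees with the
two-decimal row sum; for the packaged table the report is empty. A
SHA-256 checksum over the packaged file is pinned and verified at load.

## Grading

The default 0–9 scale is partitioned Bad [0, 4), Good [4, 6),
Excellent [6, 8), Perfect [8, 9]. Interval notation in the literature
is half-open on the left; the top interval is closed at the maximum so
a perfect score is classifiable. "Acceptable" in prose is the Good
band. Frameworks with a different dimension count must supply their own
cut-points (`grade(pmc, cutpoints=...)`); the defaults apply only to
nine-dimension frameworks.

## The PMC surface

For nine-dimension frameworks the first-level values fill a 3×3 matrix
row-major — (X1, X2, X3) on the first row — so the flattened matrix
reproduces the score vector and `mean(cells) × 9` equals the
full-precision PMC. Smooth rendering upsamples the grid with an
interpolating tensor-product spline of degree 2 per axis (the highest
interpolating degree a three-knot axis supports), factor 25 per cell
edge by default. The spline reproduces the nine anchor heights exactly;
off-knot values are clipped to [0, 1] to tame overshoot, which cannot
move the anchors since they already lie in [0, 1]. Rendering is
qualitative: grid density and colour map are visual choices, and the
tested contract is only that anchors are never altered.

## Keyword-rule coding

Real studies code matrices by human reading. For reproducible pipelines
the package includes a transparent rule coder: one rule per
sub-variable, each a list of literal keyword patterns with `any`/`all`
matching. Matching is substring containment after NFKC normalisation,
whitespace stripping and case folding — no stemming or fuzzy matching,
by design: a rule either plainly matches or it does not, and the rule
file documents the coding. Sub-variables without a rule code to 0.
Mutually exclusive groups (such as the four issuer flags) are *not*
enforced by the reader — the matrix format stays general — but
`lint_exclusive_blocks` warns when a configured block's row sum is not 1.

## Text mining

Segmentation is a pluggable strategy: `whitespace` (Latin or
pre-tokenized text), `ngram` (overlapping character n-grams, a
dictionary-free baseline for unsegmented Chinese), and `dictionary`
(greedy forward maximum matching against a user-supplied lexicon —
deterministic and fully inspectable). Sentences are split on Chinese
and Latin sentence-final punctuation (。！？.!?) before segmentation;
stopwords are removed after. The packaged stopword list is a small
editable text file, not a canonical resource.

Co-occurrence counting uses per-window pair counting: a pair counts
once per window containing both terms, regardless of repeats — the
standard convention for semantic maps. Windows are sentences (default),
whole documents, or sliding token windows of size k ≥ 2. Edges below
`min_edge_weight` (default 2) are dropped, then isolated nodes. Degree
and weighted degree separate core terms from those at the periphery of
the semantic map.

## Synthetic data

The matrix generator draws independent Bernoulli(p) columns with
per-sub-variable satisfaction probabilities, plus *exclusive blocks*:
groups of flags of which exactly one is set per policy, drawn from
categorical weights. Blocks emulate structurally constrained dimensions
— a corpus whose policies are all nationally issued sets exactly one of
four issuer flags, pinning that dimension's first-level value to 1/4.
The closed-form expected full-precision PMC under a sampling plan is
`Σ_i (Σ_j p_ij)/T_i`, used in tests for end-to-end consistency.

The corpus generator draws i.i.d. tokens from a weighted vocabulary and
plants term pairs that co-occur per document with a configured
probability (implemented by overwriting two distinct token positions,
so a planted pair is guaranteed to share its document). It emits both
pre-tokenized streams and raw text that round-trips exactly through the
whitespace tokenizer, so text-mining tests need no segmentation
dictionary.

What the generators do *not* emulate: realistic legal prose, correlated
sub-variables beyond exclusive blocks, Zipfian long tails, or the
manual-coding process itself. Passing tests therefore demonstrate the
arithmetic, counting and recovery machinery, not coding validity on
real documents.

All randomness flows through one `numpy.random.Generator` per call,
seeded from a single integer in the config; no global state.

## Problem sizes and numerical choices

Parameter-recovery tests use 10,000 synthetic policies (binomial
standard errors ≈ 0.005, so 3-SE bands are tight but stable) and the
statistical assertions use 3 standard errors for individual parameters
and 4 for the derived mean-PMC check, a conventional
false-failure/power balance for seeded tests. Example scripts use
2,000 policies and 25 documents — enough for visibly tight agreement
while running in seconds. Exact comparisons (report parity, grade
counts, extremes) use no tolerance beyond ±0.01 inherited from
two-decimal printing. Ties in term ranking break lexicographically so
output order is total and deterministic.

## Known limitations

- Sub-variable-level assignments behind a published first-level table
  are not recoverable (only the per-dimension averages are printed), so
  published corpora can be re-aggregated but not re-coded.
- The rule coder is intentionally literal; it is a reproducibility tool,
  not a text classifier.
- Grade cut-points are fixed convention, not fitted; applying them to a
  non-default dimension count is refused rather than rescaled.
- Surface plots are qualitative; only anchor fidelity is guaranteed.
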