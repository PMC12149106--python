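# pmceval

Quantitative policy evaluation with the **Policy Modeling Consistency
(PMC) index model**, built around the corpus of Chinese traditional
medicine (TCM) new-drug registration policies but generalising to any
two-level binary evaluation framework.

Policy studies often need to compare dozens or hundreds of regulatory
documents on a common scale. The PMC approach codes every policy
against a framework of binary criteria ("sub-variables") grouped under
evaluation dimensions ("primary variables"), averages the flags within
each dimension, and sums the dimensions into a single consistency
score. `pmceval` implements the whole pipeline for analysts doing this
kind of quantitative policy content analysis: framework definition,
strict binary-matrix ingestion, scoring and grading, corpus aggregates,
3-D surface visualisation of a policy's strengths and weaknesses, and
the accompanying text-mining stage (high-frequency terms and term
co-occurrence networks).

## The model

A framework has primary variables $X_1,\dots,X_n$; dimension $i$ owns
$T_i$ binary sub-variables $X_{ij}\in\{0,1\}$ ($X_{ij}=1$ when the
policy text satisfies criterion $j$). Then

$$X_i = \frac{1}{T_i}\sum_{j=1}^{T_i} X_{ij}, \qquad
  \mathrm{PMC} = \sum_{i=1}^{n} X_i \in [0, n].$$

For the default nine-dimension framework (nature, timeliness, issuing
institution, policy object, function, content, approach, incentive
method, scientificity — 41 sub-variables in total) the score is graded
Bad $[0,4)$, Good (acceptable) $[4,6)$, Excellent $[6,8)$, Perfect
$[8,9]$. The nine first-level values arranged row-major into a
$3\times 3$ matrix form the *PMC surface*, whose concavity shows at a
glance which dimensions a policy neglects.

Published score tables print first-level values to two decimals and sum
the *printed* values; `pmceval`'s default **report-parity** rounding
mode (round half-up to two decimals, then sum) reproduces those printed
PMC columns exactly, while full-precision summation is always available.

## Worked example

`examples/score_published_corpus.py` scores the packaged table of 165
published TCM registration policy evaluations (first-level values
stored verbatim) and prints:

```
policies scored: 165
mean PMC index:  5.858
  Perfect     0  (0.0%)
  Excellent  39  (23.6%)
  Good      119  (72.1%)
  Bad         7  (4.2%)
weakest policy:  P3 (PMC 3.9)
strongest policy: P156 (PMC 7.91)
variable means:  {'X1': 0.661, 'X2': 0.942, 'X3': 0.25, 'X4': 0.964, 'X5': 0.558, 'X6': 0.643, 'X7': 0.678, 'X8': 0.548, 'X9': 0.615}
```

The corpus mean of 5.858 sits in the acceptable band; no policy is
perfect; the issuing-institution mean of exactly 0.25 reflects that
every policy sets exactly one of the four issuer flags (all are issued
nationally). The other examples generate a synthetic coded corpus and
check its mean PMC against the closed-form expectation
(`synthetic_scoring.py`), recover planted term frequencies and
co-occurrences from raw text (`text_mining.py`), and render smooth PMC
surfaces for the weakest and strongest policies (`surface_plot.py`).

A thin CLI wraps the library for shell pipelines:

```sh
pmceval simulate matrix --n-policies 100 --seed 1 --out matrix.csv
pmceval score matrix.csv --out scores.csv
pmceval summarize scores.csv
pmceval surface scores.csv --policy S1 --out s1.png
pmceval mine network --texts docs/ --window sentence --min-weight 2 --out net.graphml
```

## Layout

- `src/pmceval/schema.py` — evaluation frameworks (YAML-defined; the
  default nine-dimension framework ships as package data)
- `src/pmceval/coding.py` — the policies × sub-variables binary matrix:
  strict CSV reader, keyword-rule coder, column statistics
- `src/pmceval/pmc.py` — first-level values, PMC index, grades, corpus
  summaries
- `src/pmceval/surface.py` — 3×3 surface matrices and their rendering
- `src/pmceval/textmining.py` — segmentation (whitespace, character
  n-gram, dictionary forward-maximum-matching), term ranking,
  co-occurrence networks
- `src/pmceval/synthetic.py` — synthetic matrix/corpus generators with
  ground truth, and the packaged published score table
- `docs/methods.md` — modelling choices, conventions, limitations
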