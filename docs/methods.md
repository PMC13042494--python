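# Methods

## The statistic

`cscore` quantifies, per feature, how concordantly two case-vs-control
comparisons moved that feature.  Inputs are the per-feature effect `E`
(log2 fold change from a DE model, or a normalized enrichment score when
scoring pathways) and its BH-adjusted FDR `q` in each comparison.  The
statistic multiplies two parts:

- **Magnitude** `|E1|·wFDR(q1) + |E2|·wFDR(q2)` — the total amount of
  (significance-weighted) change.  The weight `wFDR` is 1 for q < 0.05
  and `log10(q)/log10(0.05)` otherwise: it is continuous at the 0.05
  threshold, decreases monotonically to 0 at q = 1, and so soft-thresholds
  effects rather than hard-filtering them.  Absolute values are used so
  that a gene strongly *down* in both comparisons contributes as much
  magnitude as one strongly up in both.
- **Ratio** — direction and agreement.  When the effects share a sign
  (`E1·E2 > 0`) it is `max(|E1|,|E2|)/(|E1−E2|+1)`: large when the effects
  are big and close.  Otherwise it is `−|E1−E2|/(max(|E1|,|E2|)+1)`:
  increasingly negative as the effects diverge.  The `+1` in each
  denominator keeps the ratio finite and tempers small-effect noise.

The C-score is their product; its sign classifies the gene (positive =
shared response, negative = different response) and its size ranks genes
continuously, replacing threshold-based DEG-overlap bookkeeping.

**Zero rule.** A feature whose fold change is exactly 0 in either
comparison is scored exactly 0: a zero effect has no direction, so
neither branch of the ratio is meaningful.  The alternative reading —
zero only when *both* effects vanish — is available as
`zero_rule="both"`; under it a (0, e) gene falls in the discordant
branch.  On continuous data exact zeros essentially never occur and the
two readings coincide.

**Algebraic properties** (all property-tested): symmetry under swapping
the two contrasts; invariance under flipping the signs of both effects;
`sign(C) = sign(E1·E2)` whenever the magnitude is positive and both
effects are nonzero; `|Ratio| ≤ max(|E1|,|E2|)` in the concordant branch
and `≤ 2·max(|E1|,|E2|)` overall (the discordant numerator `|E1−E2|` can
reach twice the larger effect, so the one-sided bound without the factor
2 does not hold there).

## Permutation significance

The null model destroys the gene-level pairing between the two
comparisons while preserving each comparison's joint (effect, FDR)
distribution: one permutation shuffles the rows of contrast 1 and,
independently, the rows of contrast 2, then recomputes every C-score.
All permuted scores — across genes and permutations — are pooled into a
single null distribution.  Equivalently, the null is the distribution of
`C(E1_i, q1_i, E2_j, q2_j)` over ordered cross-pairs `(i, j)`, and with
`exact_mode=True` all n² cross-pairs are enumerated directly, which is
what the n²-permutation small-sample rule converges to.  The pooled
construction is what makes that n² rule natural; a per-gene null
(`pooled=False`) is available for comparison and has the same marginal
support.

Permutation counts follow the gene count: 40 000 permutations when a
cell type has more than 200 genes, n² otherwise (`PermutationConfig`).
For each gene the one-sided p-value is the fraction of null scores at or
beyond the observed score *on its own side*: above it for positive
scores, below it for negative scores; zero-scored genes get p = 1.
Calls use one-sided p < 0.05.

**Ties.** By default null scores exactly equal to the observed score
count as extreme (`tie_policy="inclusive"`), the standard permutation
convention: p can never be 0, and in the fully degenerate case (all rows
identical) every gene correctly gets p = 1.  The literal strict
inequality is available as `tie_policy="strict"`.  On continuous data
ties have probability ~0 and the policies coincide.

**p correction.** The default reported p is `(count+1)/(N+1)`
(`add_one`), which accounts for the observed arrangement being one of
the admissible ones and cannot return 0 from finite sampling;
`raw_frequency` gives the plain tail frequency.

**A calibration property worth knowing.** Because the tested tail is
chosen from the observed score's *sign*, a pure-noise gene is called at
p < α when it lands in the overall α-tail of its own sign's half of the
pool — so the expected null call rate is ~2α, not α (≈10% of null genes
at α = 0.05; the test suite pins this at 0.10 ± 3 binomial SEs on the
all-null benchmark).  This is a property of the sign-conditional
one-sided rule itself, inherited by any analysis using it; interpret the
0.05 cut as a ranking device, not a strict false-positive guarantee, and
note that no multiple-testing correction is applied across genes.

## Alignment of contrasts

C-scores require both comparisons to report the gene.  Two contrast
tables are inner-joined on feature id, in lexicographic order so results
do not depend on input row order; genes present on only one side are
dropped and counted (`missing_as_zero=True` instead imputes E = 0,
q = 1, which the zero rule scores 0 — a conservative way to keep them
visible in outputs).

## Communication network

Given per-cell-type score tables and a ligand–receptor resource
(CSV/TSV with `pair_name`, `ligand`, `receptor`; complex subunits joined
by `_`), every ordered cell-type pair and resource entry yields a
candidate edge.  Ligand subunit C-scores come from the sender's table,
receptor subunit scores from the receiver's; the edge weight sums them
and the edge's `mean_p` averages the same genes' permutation p-values.
Choices the resource format forces, and their defaults:

- an edge is emitted when at least one subunit on each side is found
  (`require_all_subunits=True` for the strict rule); found-gene counts
  are recorded per edge and missing lookups logged;
- subunit aggregation within each side is `sum` (default; matches
  "sum of C-scores over the corresponding genes"), with `mean` and `min`
  exposed because consensus resources differ in subunit conventions;
- self-edges (sender = receiver) are excluded by default — the network
  maps signaling *between* cell types;
- no significance filter is applied by default; `max_mean_p` enables one.

Positive-weight edges form the shared-response network, negative ones
the different-response network; zero-weight edges belong to neither and
are dropped with a count.  Degrees use **absolute** weights within each
subnetwork — `out_degree(c) = Σ|w|` over edges sent by `c`, likewise
in-degree — so the "different" network's degrees are positive magnitudes
comparable with the shared network's, and the conservation law
Σ out = Σ in = Σ|w| holds exactly.  Gene rankings aggregate `|w|` over
the edges a gene participates in, per role (ligand = sender side,
receptor = receiver side), ties broken by gene id.

## Surrounding statistics

- **Hypergeometric overlap** (`hypergeom_overlap`): P(X ≥ k) for the
  overlap of two gene sets in a declared universe (enrichment
  alternative), computed through scipy's log-gamma machinery so a
  ~10⁴-gene universe stays finite.
- **Exact Mann–Whitney U** (`mannwhitney_exact`): exact two-sided p for
  small untied samples, `2·min(P(U≤u), P(U≥u))` capped at 1.  The
  "sum of both tails" definition is exposed but coincides with the
  doubled tail because the untied U null is symmetric.  Tied values are
  rejected rather than approximated.
- **BH adjustment** (`bh_adjust`): standard step-up, used by the
  synthetic generator to turn z-test p-values into FDRs.

## Synthetic benchmark

The generator plants a known regulation class per gene — shared-up,
shared-down, different, or null, drawn from configurable proportions —
and emits the two aligned contrast tables the scorer consumes.  True
effects are drawn on the log2 scale directly: |θ| ~ Normal(μ_eff, σ_eff)
truncated at zero, independently per contrast, with a common random sign
for shared genes and opposite signs for different genes; null genes have
θ = 0.  Observed effects add Normal(0, se) estimation noise; per-gene
p-values are the corresponding two-sided z-tests and FDRs are BH within
each contrast.  Defaults — 2 000 genes, 5/5/5/85% class proportions,
μ_eff = 1.5, σ_eff = 0.3, se = 0.25 — describe a sparse, well-powered
DE setting: clear but not extreme log2 fold changes of about 1.5 with
per-gene standard errors a moderately sized pseudobulk comparison would
give.  Everything is deterministic given the seed; cell type *i* of a
multi-cell-type fixture uses seed + i and the toy ligand–receptor
resource seed + 10000.

What the generator does *not* emulate: count-level noise models
(negative-binomial dispersion, library-size effects), correlated genes,
effect-size/FDR dependence beyond the z-model, or compositional effects
between cell types.  Passing recovery tests therefore show the scorer
and network machinery are correct and well calibrated under the model's
own assumptions — not that any particular biological dataset will
separate as cleanly.

On the default benchmark (20 pilot seeds) shared and different calls
both exceed 0.99 precision and 0.94 recall; the test suite asserts the
looser pre-registered bounds (precision ≥ 0.8, recall ≥ 0.5 per class).

## Numerical and engineering choices

- Scores are computed vectorized in float64; `c_score = magnitude ×
  ratio` holds to ~1e−12 in outputs, and score TSVs are written with
  `%.17g` so write→read round-trips are exact.
- Sampled permutations are generated in fixed-size blocks of 256 from a
  single `numpy` Generator (contrast-1 block then contrast-2 block per
  chunk), so results are bit-reproducible given the seed; tail counts
  are accumulated by binary search against the sorted pool, never
  materializing the full 40 000 × n null.
- Degenerate inputs: fewer than 2 genes cannot be permutation-tested;
  empty feature intersections, duplicate ids, FDRs outside [0, 1] and
  non-finite effects are rejected at construction with the offending ids
  named; rows with missing values are dropped at read time with their
  row numbers logged.
- The pipeline echoes its effective config, logs every dropped gene and
  edge to `dropped_records.tsv`, and writes byte-identical outputs on
  rerun with the same config.

## Limitations

- The C-score consumes point estimates and FDRs only; it ignores
  effect-size uncertainty beyond the FDR weight, and genes tested in
  only one comparison are invisible to it (by default).
- The pooled null assumes genes are exchangeable within a contrast;
  strong gene–gene correlation (co-regulated modules) makes the null
  narrower than reality and the permutation p anti-conservative, on top
  of the ~2α sign-conditioning effect described above.
- Network weights inherit every upstream bias of the ligand–receptor
  resource (coverage, complex annotation) and say nothing about
  expression level or spatial adjacency — edges measure concordance of
  *regulation*, not communication probability.
- Exact cross-pair enumeration materializes an n×n score matrix; beyond
  ~5 000 genes use sampled mode.
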