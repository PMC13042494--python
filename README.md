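# cscore — dual-contrast concordance analysis

When a study compares two related conditions against the same control —
say, two flavors of maternal obesity (with appropriate- vs
large-for-gestational-age infants) against normal-BMI placentas, one cell
type at a time — the question is rarely just "which genes moved?" but
"which genes moved *the same way* in both comparisons, and which moved
*differently*?"  Binary overlap of DEG lists answers this with arbitrary
thresholds; `cscore` answers it with a continuous statistic.

For each gene with effect sizes `E1, E2` (log2 fold changes, or GSEA
normalized enrichment scores in pathway mode) and BH-adjusted FDRs
`q1, q2` in the two comparisons:

```
C = Magnitude × Ratio

wFDR(q)   = 1                      if q < 0.05
            log10(q) / log10(0.05) if q ≥ 0.05

Magnitude = |E1|·wFDR(q1) + |E2|·wFDR(q2)

Ratio     =  max(|E1|,|E2|) / (|E1−E2| + 1)   if E1·E2 > 0   (concordant)
            −|E1−E2| / (max(|E1|,|E2|) + 1)   if E1·E2 ≤ 0   (discordant)
```

Positive C: the gene goes up in both comparisons or down in both (a
*shared* response).  Negative C: up in one, down in the other
(*different*).  Genes with a zero fold change score exactly 0.
Significance comes from a permutation test whose null pools C-scores of
randomly cross-paired rows of the two contrasts (40 000 permutations, or
n² when a cell type has ≤ 200 genes), with a one-sided p < 0.05 call.

On top of the per-gene scores the package builds a **cell–cell
communication network**: every (sender cell type, receiver cell type,
ligand, receptor) tetramer from a LIANA-style consensus resource becomes
a directed edge weighted by the sum of the C-scores of its ligand genes
(in the sender) and receptor genes (in the receiver), carrying the mean
permutation p of those genes.  Splitting edges by sign yields the shared
and different regulatory networks; weighted in/out-degrees rank receiver
and sender cell types, and per-gene aggregation ranks ligands and
receptors.

Also included: exact small-sample Mann–Whitney U and one-sided
hypergeometric overlap tests (the study-level statistics around the
core), a synthetic dual-contrast generator with planted ground truth for
end-to-end validation, and a YAML-driven pipeline CLI.

## Worked example

```python
from cscore import ConcordanceModel, SyntheticConfig
from cscore.synthetic import generate_dual_contrast

cfg = SyntheticConfig(n_genes=300, seed=1)   # 15% planted signal
dual, truth = generate_dual_contrast(cfg)
res = ConcordanceModel(dual).fit(seed=1)
print(res.summary())
```

```
Dual-contrast concordance (C-score) results
===============================================
cell type:        synthetic
contrasts:        sim_contrast1 / sim_contrast2
genes scored:     300
permutations:     40000
alpha (one-sided):   0.05

pattern counts:
  shared_up            16
  shared_down          15
  different            17
  zero                  0
  not_significant     252

top 5 concordant (highest C):
  gene094        C=+7.818  p=0.0001097
  gene112        C=+6.120  p=0.000862
  ...
top 5 discordant (lowest C):
  gene280        C=-4.823  p=0.0006322
  gene228        C=-4.737  p=0.0008598
  ...
```

48 of 300 genes are called (16 shared-up, 15 shared-down, 17 different);
every call agrees with the planted truth class in this run.  `res.frame`
holds the full per-gene table (components, C-score, permutation p,
pattern), `res.plot()` draws the rank-ordered score scatter, and
`cscore.build_network` consumes a dict of such results per cell type.

From a shell, the same analysis runs as
`cscore run config.yaml`, with `cscore score`, `cscore network`,
`cscore simulate` and `cscore stats` covering the individual stages.

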