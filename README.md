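# marbling

Contamination-aware comparison of bovine fat-depot transcriptomes.

Dissected intramuscular ("marbling") fat — the commercially prized IMF depot —
unavoidably carries fragments of the surrounding *longissimus dorsi* (LD)
muscle, so a bulk IMF expression profile is a mixture of marbling-adipocyte
and muscle RNA. Naively ranking IMF-vs-SC (subcutaneous fat) differential
expression then fills the "up in IMF" list with muscle genes. This package is
for transcriptomics researchers who need to separate the adipocyte signal
from that contamination without a deconvolution model, using the
threshold-filter strategy the problem's scale actually supports:

- **PIF ranking** — the Phenotypic Impact Factor `PIF = M · A`, where
  `M = x̄_A − x̄_B` and `A = (x̄_A + x̄_B)/2` on log2 depot means,
  z-scored over the table with one-tailed normal p-values, plus a classical
  pooled-variance t-test on replicates, MA coordinates and signed fold
  changes, max-|PIF| probe-to-gene collapse, and percent-extreme selection.
- **Multi-criteria contamination filters** — strict AND-combined log2
  threshold queries (e.g. *IMF > 2-fold SC AND IMF > LD*) that retain only
  genes whose IMF expression cannot be explained by the muscle admixture,
  with probe/gene counts and fold enrichment/depletion versus independence
  (`expected = nA·nB/N`), and a continuous IMF-minus-LD colour score for MA
  overlays.
- **Enrichment verification** — exact log-space hypergeometric upper tails
  with Benjamini–Hochberg q-values over user-supplied GMT gene sets: a
  contaminated list lights up a "muscle system process" set, a clean one
  does not.
- **Mitoproteome skew** — the exact Binomial(n, ½) lower tail on the sign
  split of mitoproteome genes around M = 0, a proxy for relative
  mitochondrial content.
- **Clustering** — UPGMA on 1 − Pearson r for depot columns, gene panels and
  correlation profiles, with seeded gene subsampling and Newick export.
- **Metabolite–phenotype correlations** — Pearson r with exact two-sided p
  over small animal panels (|r| > 0.707 flags at n = 8, α = 0.05) and
  correlation-of-correlations clustering.
- **A fully labelled synthetic study generator** — 6 tissues × 3 breeds × 4
  replicates, gene classes, linear-intensity muscle admixture of the IMF
  samples at fraction α, a planted mitoproteome shift, and an 8-animal
  phenotype/metabolite panel with a latent marbling factor, so every stage is
  testable against ground truth.

See `docs/methods.md` for the statistical details and the generator's
calibration.

## Worked example

```python
import marbling as m

ds = m.generate(seed=42)                       # synthetic study, alpha = 0.1
table = m.score_table(ds.matrix, "IMF", "SC", ds.probe_map)
genes = m.collapse_probes(table)               # one max-|PIF| row per gene

naive = m.select_extreme(genes, 0.01, "up")    # top 1% PIF "up in IMF"
print(m.enrich(list(naive["gene"]), list(genes["gene"]), ds.gene_sets).head(1))

report = m.run_named_queries(m.depot_mean_table(ds.matrix), ds.probe_map)
q4 = report.set_index("query").loc["q4_IMF_adipocyte_vs_SC"]
print(q4["probe_count"], q4["unique_gene_count"])
print(m.enrich(q4["genes"], list(genes["gene"]), ds.gene_sets).query("set == 'MUSCLE_SYSTEM_PROCESS'"))

print(m.skew_test(genes, ds.mito_genes))
```

prints (abbreviated):

```
                  set   k   K   n     N             p             q
MUSCLE_SYSTEM_PROCESS  34  70  50  5000  2.721698e-55  1.633019e-54
177 76
                  set  k   K   n     N    p    q
MUSCLE_SYSTEM_PROCESS  0  70  76  5000  1.0  1.0
SkewResult(n_matched=800, n_above=734, n_below=66, n_ties=0, p=7.71e-144)
```

Reading: the naive top-1% PIF list (50 genes) overlaps the muscle set 34
times — overwhelming contamination signal (q ≈ 2e-54). The AND-filtered
IMF-vs-SC query returns 76 unique genes with **zero** muscle-set overlap
(q = 1): the filter removed the muscle-attributable signal while keeping the
planted adipocyte genes. The mitoproteome tilts 734 up vs 66 down, an upward
skew the binomial tail calls at p ≈ 8e-144.

A `marbling` console command exposes the same stages
(`simulate`, `de`, `filter`, `enrich`, `mitoskew`, `cluster`, `correlate`);
try `marbling --help`.

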