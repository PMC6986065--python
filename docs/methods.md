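# Methods

## The problem

Dissected intramuscular ("marbling") fat is never a pure adipocyte sample:
fragments of the surrounding longissimus dorsi (LD) muscle come with it, so a
bulk IMF transcriptome is a mixture of marbling-adipocyte RNA and muscle RNA.
Genes that are merely abundant in muscle then masquerade as "up in IMF" when
IMF is compared with a clean depot such as subcutaneous (SC) fat. This package
implements a contamination-aware comparison: abundance-weighted
differential-expression ranking, strict multi-criteria threshold filters that
remove the muscle-attributable signal, enrichment-based verification that the
removal worked, a mitoproteome sign-skew test, depot clustering, and a
metabolite-phenotype correlation stage.

## Statistics

**MA coordinates and fold change.** For depot means `x̄_A`, `x̄_B` (log2),
`M = x̄_A − x̄_B` and `A = (x̄_A + x̄_B)/2`. Fold changes use the signed table
convention `+2^M` (M ≥ 0) / `−2^(−M)` (M < 0), so −2.20 means 2.2-fold lower
in the first depot.

**PIF.** The Phenotypic Impact Factor is `PIF = M · A`: differential
expression weighted by average abundance, de-emphasising low-abundance probes
near the platform's detection limit. PIF values are z-scored over the whole
probe-level table (sample mean/SD, ddof 1) and referred to the standard-normal
upper tail of |z| for a one-tailed p — extremeness regardless of sign, since
both strongly up- and down-regulated genes are of interest. Probe-to-gene
collapse keeps the max-|PIF| probe per gene, ties broken by probe id.
Percent-extreme selection takes round-half-up(fraction · N) records from the
PIF ranking (1% of 14,476 = 145; 5% = 724).

**t-test.** Classical pooled-variance two-sample t with nA + nB − 2 df,
two-sided. Degenerate zero-pooled-variance rows return p = 1 (equal means) or
p = 0 (unequal) by convention. p-values are reported raw, uncorrected.

**Threshold queries.** Every criterion is a strict inequality on log2 depot
means; "k-fold" thresholds are primary in log2 (4-fold = 2.0, 2-fold = 1.0,
1.68-fold = 0.75, 1.32-fold = 0.4), "by any amount" is threshold 0. "Average
of the other fat depots" is the unweighted mean of the four non-IMF depot
means. AND-combinations intersect probe sets; reports carry probe-level and
deduplicated gene-level counts. The independence ratio compares the observed
intersection with `expected = nA·nB/N` on probe-level counts against the full
probe background, reported as observed/expected (enrichment) or
expected/observed (depletion).

**Enrichment.** Exact hypergeometric upper tail, summed in log space
(gammaln + logsumexp), at gene level; annotation sets are intersected with the
supplied background first, and the BH step-up denominator is the number of
sets with nonzero background intersection. GO-DAG structure is out of scope —
annotations are user-supplied GMT files.

**Mitoproteome skew.** Genes matched to the mitoproteome list are partitioned
by the sign of M; the smaller sign count k out of all n matched genes
(including ties — with the reference counts only n = 886 reproduces the
printed 2.29e-26, 595 + 287 = 882 does not) is referred to the exact
Binomial(n, ½) lower tail, computed in log space with no normal approximation.

**Clustering.** Distance is 1 − Pearson r (so anti-correlated profiles are
maximally distant — "positive relationships only"), linkage is UPGMA. Tissue
dendrograms cluster breed-by-tissue mean columns; the correlation-profile tree
clusters rows of the joint metabolite/phenotype correlation matrix by the
correlation of those rows (correlations of correlations). Subsampling for
genome-scale column clustering is uniform without replacement, seeded.

**Correlations.** Pearson r with two-sided p from `t = r√((n−2)/(1−r²))`,
flagged at raw α = 0.05 with no multiplicity correction, matching the
reference analysis; at n = 8 the flag threshold is |r| > 0.707.

## The synthetic study

The generator emulates the reference design: 6 tissues (IMF, SC, Inter, Kid,
Omen, LD), 3 breeds × 4 replicates per tissue (12 samples per depot, 72
columns), gene-level log2 baselines ~ N(10, 2) clipped to [4, 17], replicate
noise SD 0.5, small breed offsets (SD 0.1) so depot structure dominates, and
1–4 probes per gene (mean ≈ 2.35, matching ~34k probes for ~14.5k genes at
paper scale) with constant per-probe affinity offsets that cancel in M.

Gene-class conditions are calibrated to the study's own censuses:

- **muscle-specific** (1.5% of genes, +U(2, 9) log2 in LD): the study's
  LD > 4-fold SC screen returns ~1.2% of genes, and muscle structural
  transcripts (myosins, actins) span a very large dynamic range — which is
  exactly why modest admixture produces the "protuberance" of spuriously
  IMF-up genes;
- **IMF-adipocyte-specific** (2%, +U(0.8, 2.5) in clean IMF): the study's
  adipocyte-credible AND lists hold ~0.3–0.5% of genes with ~1–1.5 log2
  effects;
- **SC-specific** (4.5%, +U(0.8, 2.5) in SC), sized to the ~4–6% down-list;
- **shared-adipocyte** (15%, +U(0.5, 1.5) in all five fat depots);
- **background** (77%), flat.

Contamination mixes linear intensities per matched sample:
`observed = log2((1−α)·2^clean_IMF + α·2^LD)`, pairing IMF replicate k of a
breed with LD replicate k of the same breed; α = 0.1 is the default study
condition. 16% of background/shared genes form the mitoproteome list and get
a +0.3 log2 shift in clean IMF. The 8-animal panel has 7 marbling phenotypes
and 1 planted metabolite loaded √0.9 each on a latent marbling factor
(population r = 0.9 for planted pairs), 8 noise phenotypes and 9 noise
metabolites.

What the generator does **not** emulate: probe-level microarray artifacts
(dye/spatial effects), heavy-tailed or correlated gene noise, breed-by-depot
interactions, and any real gene identity. Passing tests therefore demonstrate
the pipeline's behaviour under the assumed mixture model and study geometry,
not performance on arbitrary real data.

## Numerical choices and degenerate inputs

Tail probabilities are exact log-space summations (no approximations); BH is
the standard step-up with mergesort-stable ordering; zero-spread PIF vectors
and zero-variance correlation profiles are errors, not NaNs; missing matrix
cells are rejected rather than imputed (the upstream normalized matrices are
complete); probe-collapse ties and extreme-selection ties break on probe id
for determinism. The discrete binomial null is calibration-tested through the
randomized probability integral transform, which is exactly Uniform(0, 1)
when the sign counts are truly Binomial(n, ½).

## Problem sizes

The default synthetic profile uses 5,000 genes, which keeps multi-seed
property suites (20 seeds per contamination level, 2,000-seed null
calibrations at reduced gene counts) comfortable on a single CPU; the
paper-scale profile (14,476 genes, ~34k probes) runs the full pipeline —
generation, scoring, collapse, queries, enrichment, skew — in about a second
and is exercised in the acceptance tests.

## Known limitations

- Threshold values are the study's pragmatic, empirically chosen cut-offs;
  the package makes no claim of optimality and does not estimate α (the
  method is deliberately not a deconvolution).
- Printed independence ratios in the reference multi-criteria census other
  than the 6.41 row are not reproducible from their printed marginals; the
  package reports the recomputed arithmetic.
- Enrichment results depend entirely on the supplied annotation files;
  reproducing any specific published q-value requires the same annotation
  release.
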