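# Methods

## Design and model

The package targets a 2×2 perturbation design — control, A, B, A+B —
with replicated bulk RNA-seq gene counts. Counts for gene *g* in sample
*s* are modelled as negative binomial with mean
μ_gs = q_g(condition(s)) · f_s and variance μ + αμ², where q_g is the
condition-level expected expression, f_s a sample size factor and α the
dispersion (α = 0 recovers Poisson). The quantity of interest is
epistatic *reversion*: whether genes moved by A return toward control
when B is co-applied.

## Synthetic data generator

`synthdata.generate` draws a complete experiment from a `SimConfig`.
What it emulates, and the defaults:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 17,108 | annotated gene count of the emulated chick neural-tube study |
| `n_reps` | 2 | biological replicates per condition in that design |
| `class_proportions` | 85% null, 5.4% up-reversed, 5.4% down-reversed, 0.6% up-not-reversed, 0.6% down-not-reversed, 3% B-only | ~12% of genes A-responsive with 90% of them reverting, matching the reported scale of the deregulated set and its ~90% inverse-correlation |
| `effect_log2fc` | 2.0 | a strong but realistic bulk effect; the source data report no effect-size distribution, so this is a free parameter |
| `dispersion` α | 0.05 | typical bulk biological-replicate dispersion; yields replicate log-expression correlations ≈ 0.98, near the >0.99 reported for the real data |
| `base_mean_range` | (10, 1000), log-uniform | spans low to well-covered genes, geometric mean 100 |
| `length_range` | (200, 20000) bp, log-uniform | plausible transcript lengths so TPM is non-trivial |
| `reversion` | 1.0 | reversed genes return exactly to baseline in A+B; values in (0,1) give partial reversion |

Class labels are apportioned by largest remainder and shuffled with the
seeded generator, so identical configs are bit-identical. B-only genes
carry their effect in both B and A+B (B is present in both).

What the generator does **not** emulate: gene–gene correlation,
mean-dependent dispersion trends, library-size imbalance (unless
`libsize_factors` is set), GC/length biases, and partially-reverting or
*concordantly amplified* genes (deregulated in the same direction in
both A-vs-control and A+B-vs-A). Passing tests therefore demonstrate
correct behaviour under an idealised NB world, not performance on any
particular real dataset.

## Expression units and QC

TPM divides counts by gene length in kb and rescales each sample to sum
to 1e6. QC (replicate Pearson correlation, sample PCA) runs on
log2(TPM+1); the pseudocount 1 keeps zeros at zero and the transform is
stated here because the emulated study does not report its own. Row
z-scores use the sample standard deviation (n−1), which matters at
these sample sizes (2–8 columns); constant rows become zero vectors and
are flagged rather than dropped.

## Differential expression

The two-condition test is deliberately self-contained and desk-scale:

1. **Normalisation** — median-of-ratios to the per-gene geometric mean
   over genes expressed in every sample, rescaled to geometric mean 1;
   total-count fallback (with a warning) if no gene is fully observed.
2. **Dispersion** — per-gene method of moments within each group,
   α_g = (s² − m)/m² pooled by residual df, shrunk toward a common
   dispersion with weight prior_df/(prior_df + df_g), prior_df = 20. At
   two replicates per group (1 residual df per group) the per-gene
   estimate is nearly uninformative and the common value dominates, as
   intended. The common dispersion is the pooled ratio
   Σ(s² − m)/Σm² over genes and groups rather than a (trimmed) mean of
   per-gene estimates: the per-gene moment estimates are extremely
   right-skewed at 1–2 df, so trimmed means are biased low (measured
   ≈0.039 for a true α = 0.05 on 10,000 genes), which in turn inflates
   the Wald type-I rate; the ratio form measures ≈0.049 on the same data
   and keeps the null p-value distribution close to uniform
   (fraction p < 0.05 ≈ 0.055 at n = 2 per group).
3. **Wald test** — log2FC = log2((m̄_num + c)/(m̄_den + c)) with
   pseudocount c = 0.5 guarding zero-count groups; delta-method standard
   error from Var(ln m̄) ≈ (μ + αμ²)/(n(μ + c)²) per group; two-sided
   normal p. Genes with zero counts across the whole contrast are
   untested (missing p/FDR).
4. **FDR** — Benjamini–Hochberg step-up within each contrast, because
   contrasts are reported separately.

Known limitations: the normal reference slightly understates small-n
tail uncertainty, and with a large one-sided planted fraction the
median-of-ratios factors absorb part of the shift (≈ −0.05 log2 bias at
5% planted all-up genes; ≈ −0.10 at 10%). The recovery experiments use
a 10,000-gene background with ≤5% planted genes for this reason.

## Reversal classification

"Inversely correlated" is operationalised as strict sign opposition of
the two contrasts' log2 fold changes on the FDR-significant overlap; no
magnitude criterion is imposed. Genes whose fold-change product is
exactly zero (possible under pseudocount symmetry) cannot carry a sign
comparison; to preserve the identity reversed + concordant = overlap
they are counted as concordant and flagged `zero_lfc`. The reversed
fraction is reported as undefined (JSON null), not 0, on an empty
overlap.

An important property, verified by simulation: the overlap conditions on
detection in the A+B-vs-A contrast. Genes that are truly *not* reversed
have a zero effect there and enter the overlap only as false
discoveries, so the overlap's reversed fraction is an estimate of the
composition of the *jointly significant* set (the analogue of a reported
"689 of 759 common genes inverted"), not of the reversed share among all
A-responsive genes. The clustering route below does not condition on
C-significance and recovers the planted class mix instead; the two views
are complementary and both are reported.

The three-contrast category labels follow the field's reading:
up in A and significantly down in A+B-vs-A ⇒ putative oncogene; the
mirror ⇒ putative suppressor; significant in A but absent from the
A+B-vs-A set ⇒ not reversed ("absence from the set", not a sign test,
because the defining feature is *no detectable change*). The B contrast
is attached as a regulated-by-B-alone flag, separating reversion that
requires the A context from genes B moves on its own.

## Dynamics clustering

k-means (k-means++ seeding, Lloyd iterations, best of 10 restarts,
deterministic under the seed; backed by scikit-learn behind the package
surface) on row-z-scored log2(TPM+1) profiles of the genes deregulated
by A at FDR ≤ 0.05. Clustering uses replicate-level columns by default —
condition means (4 columns) are available via a switch — since replicate
spread is itself informative about cluster tightness. k defaults to 12
but is an exploratory knob: the emulated study chose 12 subjectively,
and cluster identity is not a stable, testable surface. What *is* tested
is the category map: centroid condition deltas Δ1 = A − control and
Δ2 = AB − A with a dead-band ε (default 0.25 z-units, about half the
within-class noise s.d. of the default simulation) assign each cluster
to putative-oncogene / putative-suppressor / not-reversed / other.

## Over-representation

Upper-tail hypergeometric p per gene set (P[X ≥ n_hit]), BH across the
collection, fold enrichment (n_hit/n_query)/(n_set/n_universe). The
universe is the set of genes actually tested in the DGE — the only
defensible background for sorted cell populations — and query members
outside it are dropped with a warning. Under-representation is available
behind a flag. No ontology database is bundled; collections are GMT
files.

## Pipeline and determinism

`run_all` chains QC → DGE (three contrasts) → reversal → clustering →
enrichment, writing TSV/JSON artifacts plus a run report (stage status,
input SHA-256 hashes, seed, package version). Reports contain no
timestamps, floats are written with a fixed format, and every random
stage is seeded, so reruns on identical inputs are byte-identical — this
is tested.

## Problem sizes used in tests

The test-suite and acceptance experiments run at 1,500–10,000 genes and
2–6 replicates per condition: large enough for stable Monte-Carlo bands
(binomial s.e. on a 0.05 rate at 10,000 genes ≈ 0.002), small enough to
execute in seconds. The full-scale default of 17,108 genes behaves
identically (all operations are vectorised in the gene dimension).
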