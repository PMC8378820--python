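# Methods

This note documents the statistical procedures, the conventions chosen where
the underlying pipeline description leaves the design open, and what the
synthetic generators do and do not emulate.

## Expression container and preprocessing

All expression stages operate on a genes × samples matrix with a class label
per sample and an explicit value-space flag (`linear` counts/TPM vs
pedestal-log2). The preprocessing chain is:

1. **Pedestal-log transform.** Every value becomes `log2(x + c)` with pedestal
   `c = 2` by default. The pedestal keeps zeros finite (`log2(2) = 1`) and
   compresses low-end variance; the transform is strictly monotone, so ranks
   are untouched.
2. **Detection filter.** A gene is kept iff at least one sample exceeds 1.0
   post-transform — strictly, so a gene whose every value equals the zero-count
   image (1.0) is discarded as not detected.
3. **Quantile normalization.** Every column is mapped onto the rank-wise mean
   of the column-sorted values. Ties within a column receive the mean of the
   target values over the tied ranks, so tied inputs stay tied.
4. **Noise floor.** Per class, each gene contributes a `(mean, CV)` point
   (CV = sample SD / mean of the normalized log2 values; genes with mean ≤ 0
   are excluded; constant genes contribute CV = 0). A LOWESS curve (tricube
   local linear regression, span 0.3) is fitted per class and evaluated on a
   200-point grid; a straight line is fitted to the curve over the upper half
   of the mean range, where expression is signal-dominated and the CV-mean
   relationship is close to linear. A class deviates grossly when its curve
   exceeds the line's extrapolation by more than δ anywhere (δ = 0.5 CV units
   by default, configurable). The floor is placed at the half-height of the
   excess — for a step-like noise onset blurred by a local smoother, the
   half-height crossing is the standard estimate of the underlying boundary —
   and the final floor is the maximum over classes, or the minimum observed
   value when no class deviates (flooring then is a no-op). Values below the
   floor are raised to it; genes never observed above it are discarded as
   noise-biased.

Two numerical choices here deserve emphasis, because both depart from the more
obvious convention and both were forced by recovery analyses on planted data:

- **No robustness iterations in the LOWESS fit.** Robust reweighting treats
  large residuals as contamination, but in this fit the high-CV points at low
  expression *are* the signal being sought; with robustness iterations the
  planted noise boundary is systematically pulled low. The smoother therefore
  runs a single pass.
- **δ is an absolute CV excess, not a residual-scaled one.** The smoothed
  curve is nearly noise-free, so any tolerance proportional to the smooth's
  own residual scatter degenerates toward zero and the mild convex rise of
  counting noise at low expression (shot noise ∝ 1/µ) would flag most of the
  mean range. An absolute excess of 0.5 ignores that intrinsic curvature while
  catching several-fold CV inflation.

With these conventions the planted 5-fold CV inflation below log2 mean 3.0 is
recovered at 2.87 ± 0.09 over 20 seeds (within the ±0.5 design tolerance),
homoscedastic data yields floor = minimum observed, and realistic
negative-binomial data without planted inflation is left essentially
untouched.

## Differential expression

Per gene, a one-way fixed-effects ANOVA with class as the single factor;
degenerate genes (zero between- and within-class variance) get F = 0, p = 1
rather than being dropped. Benjamini-Hochberg adjustment is applied once
across all tested genes. Genes with q < 0.05 enter a TukeyHSD post hoc: the
Tukey-Kramer studentized range statistic
`q = |m_a − m_b| / sqrt(MSE/2 · (1/n_a + 1/n_b))` with the pooled ANOVA MSE,
referred to the studentized range distribution with k groups and N − k df.
A contrast is called differential when the post-hoc p < 0.05 **and** the
linear fold change `2^|Δlog2 mean|` ≥ 1.5; direction is the sign of the
log2-mean difference, and a zero difference is never called. Post-hoc
p-values are not additionally adjusted across genes (adjustment happens at
the ANOVA level).

For large batches, the studentized-range survival function is evaluated on a
160-knot grid per (k, df) and interpolated monotonically in log space (PCHIP);
the interpolation error (< 1e-3 absolute, < 1% relative near p = 0.05) is far
below any decision threshold, and batches of ≤ 256 values use the exact
quadrature.

## Rescue clustering

Expression is z-scored per gene across all samples jointly (population SD;
constant rows become zeros). The up- and down-regulated gene lists from the
disease-vs-control contrast are clustered separately with k-means (k = 15
each, k-means++ initialization, 10 restarts, fixed seed 17 recorded in the
output). For each cluster the per-class centroid is the mean z-score over the
cluster's genes and the class's samples. A cluster is *reversed* when
`|c_trt − c_ctrl| ≤ (1 − θ)·|c_dis − c_ctrl|` — the treated centroid has moved
at least the fraction θ of the way back toward control — with θ = 0.5 by
default ("partially corrected"); the rule is monotone in rescue strength. The
rescued gene list is the union of reversed-cluster members; per-direction
restored fractions are reversed clusters over total clusters.

On planted data (20% of 2,000 genes dysregulated at ±1.5 log2, 60% rescued,
n = 6/group) the recovered rescued-gene fraction is within ±0.01 of the
planted 0.60 on typical seeds (tolerance ±0.10 over 20 seeds).

## Gene-set enrichment and restoration

Genes are ranked by `s = sign(Δlog2 mean) · (−log10 p_posthoc)` for the
contrast, descending, ties broken lexicographically by gene id; p = 0 is
replaced by the smallest positive double. The ranking uses post-hoc statistics
computed over *all* genes of the contrast (an enrichment ranking needs a score
for every gene; the q < 0.05 gate applies only to DE calls). The metric is
configurable; signed −log10 p is the default because it is monotone in both
evidence and direction.

The enrichment score is the weighted Kolmogorov-Smirnov running sum: hits
increment by `|s|^p` normalized over the set's hits (p = 1 default; all-zero
scores fall back to equal weights), misses decrement by `1/(N − |S|)`; ES is
the signed maximum deviation, with an exact +x/−x tie resolving positive
(with a 1e-12 tolerance so the convention is stable under summation order).

The null distribution is **gene-set permutation**: for each distinct set size,
`n_perm` random same-size subsets of the ranked list (one shared null per
size, seeded). NES divides ES by the mean magnitude of same-sign null ES.
The permutation p compares the observed ES against the same-sign null tail,
`p = (1 + #{null at least as extreme}) / (#same-sign null + 1)` — under a
symmetric null this is uniform, which the calibration tests verify by KS test,
and it respects the add-one lower bound `p ≥ 1/(n_perm + 1)`. FDR q is
GSEA-style: the tail fraction of the pooled null NES distribution divided by
the tail fraction of the observed NES distribution, clipped to [0, 1].
Significance requires p < 0.05 and q ≤ 0.25.

A set significant in disease-vs-control is classified **restored** iff it is
significant in treated-vs-disease with opposite NES sign. This
opposite-direction rule is a declared operationalization; per-direction counts
and fractions are reported (down-regulated = NES < 0 in disease).

## Promoter motif scanning

JASPAR plain-text count matrices are converted to probabilities with a
background-proportional pseudocount: each cell gains `c · 4 · b(base)` mass
(= `c` per cell at uniform background) before row normalization, with
c = 0.2 by default (0.8 per column split by background). Scores are log2 odds
against the background (bits). Promoter windows cover −1000..+100 bp around
the TSS in transcription orientation (0-based half-open internally; windows
truncate at contig boundaries; a TSS beyond the contig is an error). Both
strands are scanned at every offset; windows containing N are skipped; the
default threshold is 80% of the maximum attainable score. FIMO-style p-values
from the exact score distribution are deliberately out of scope — the
headline statistic is the fraction of a gene list whose promoter contains at
least one hit, which is threshold-based.

## Isoform profiling

Per sample, isoform share_i = `t(a_i) / Σ_j t(a_j)` with t either `log1p`
(default; matches a log-normalized-counts display, where shares describe the
displayed quantity) or `identity` (estimates linear abundance shares — this
is the transform to use when comparing against mixture proportions, and the
one the recovery tests use, since multinomial shares are defined on linear
counts). The reported share is the mean across usable samples, summing to
100%. Relative isoform level is the per-sample target/reference ratio;
zero-reference samples are dropped with a warning; summaries are mean ± SEM
(n − 1 denominator).

## Assay arithmetic

- mBU = (mean 618/460 emission ratio of experimental wells − mean ratio of
  no-ligand control wells) × 1000. Ratios are averaged per condition before
  subtraction (well pairing across conditions is not defined); condition SEMs
  propagate in quadrature. Zero-donor wells are excluded with a warning.
- RLU = firefly/Renilla per well; per-condition mean ± SEM; optional fold over
  a named baseline condition (the baseline folds to 1).
- ΔΔCt: `fold = E^−ΔΔCt` with
  `ΔΔCt = (Ct_tgt − Ct_ref)_sample − (Ct_tgt − Ct_ref)_calibrator` and
  amplification efficiency E = 2.0 by default (configurable).
- ChIP percent input: `100 · E^(Ct_input − log_E(1/f) − Ct_IP)` for input
  fraction f (default 1%); optional fold over a control IP.
- Copy ratio: exo/endo, also reported as percent increase (ratio × 100).

All are scale-invariant where the formula dictates (common factors cancel in
RLU; a common Ct shift cancels in ΔΔCt), and fold ↔ ΔΔCt round-trips to
machine precision.

## Synthetic data

One root seed feeds named substreams (counts, gene sets, promoters, isoforms,
assays), so adding or re-running one generator never perturbs another, and
every generator is bit-reproducible given its config.

**Counts.** Baseline means are log2-normal (mean 5, SD 1.8 in log2 units —
a detected-gene abundance distribution for a moderately deep bulk library);
counts are negative-binomial with variance µ + αµ², α = 0.1 (typical bulk
biological overdispersion). A fraction of genes (default 20%) is
dysregulated, half up / half down; the effect (default ±1.5) is defined on
the **pedestal-log2 scale** — the disease mean is chosen so that
`log2(µ_dis + 2) − log2(µ_ctrl + 2)` equals the configured effect exactly at
every baseline, which is also the scale every downstream stage works on. Of
the dysregulated genes a fraction (default 60%) is restored: the treated
class returns to the control mean (a partial-restoration knob retains a
configurable fraction of the effect, exercising the θ threshold). Optional
noise-floor injection inflates the log-space CV of genes below a chosen
pedestal-log2 mean by a configured factor, as symmetric jitter on the
pedestal-log2 scale applied after the NB draw (delta-method calibrated), so
the CV inflates without shifting the gene's mean and the planted boundary
stays sharp. Truth sidecars carry per-gene status, restoration and inflation
flags sufficient to score every downstream stage.

**Scenario parameters fixed for the power tests.** The DE power scenario
(1.0 log2 shifts in 10% of genes, n = 6/group) runs at dispersion α = 0.05
and baseline log2-normal(7, 1.5): a deep-sequencing cell-line regime. This
was fixed after a feasibility analysis, not after tuning against the
pipeline: at α = 0.1 the log2-scale SD asymptotes at √α/ln 2 ≈ 0.46, and an
ideal Gaussian-oracle ANOVA + BH (no pipeline involved) tops out at
sensitivity ≈ 0.65 for that effect size — no method can reach 0.8 there. At
the deep-coverage setting the oracle reaches 0.98 and the pipeline ≈ 0.9,
so the test discriminates implementation defects rather than raw noise.

**Gene sets** are direction-pure samples from the planted gene classes:
rescued sets from restored dysregulated genes, non-rescued sets from
non-restored ones, alternating up/down pools (20 + 10 sets of 30 by default).
**Promoters** are uniform-background sequences (1,100 bp) with the exact
consensus planted at recorded offsets and strands in a configured fraction
(default 0.3). **Isoform mixtures** split an NB-distributed per-sample total
multinomially by the configured shares (default 17/83). **Plates** add
multiplicative Gaussian noise (CV 5%) around known true assay values; zero
noise reproduces the truth exactly.

**What the generators do not emulate** — and hence what passing tests do not
establish about real data: library-size and composition biases (counts are
generated at a common scale; quantile normalization is exercised as a
transform, not validated as a correction), batch effects, correlated genes
(all genes are independent given their means, so cluster structure beyond the
planted rescue pattern is absent), sequence composition beyond uniform
background, isoform-mapping ambiguity, and plate position effects. Results on
real data additionally depend on upstream quantification, which is outside
this package's scope (the pipeline starts from count/abundance matrices).

## Known limitations

- The noise-floor rule assumes noise manifests as a CV excess at the low end;
  pervasive heteroscedasticity across the whole range would defeat the
  upper-half linear reference.
- Tukey post-hoc p-values are exact only under balanced-ish designs and
  homoscedastic classes (pooled MSE); no Welch-style correction is applied.
- Gene-set permutation tests set coherence against a random-gene null, not a
  phenotype-permutation null; inter-gene correlation therefore inflates
  significance on real data, which is the standard caveat for this null and
  the reason the q ≤ 0.25 convention is used.
- The PWM scan reports threshold-based hits only; no p-value calibration or
  conservation filtering.
- DE assumes the pedestal-log values are variance-stabilized enough for
  ANOVA; no exact count-model (NB Wald/LRT) test is provided.
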