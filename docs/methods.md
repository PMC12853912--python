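# Methods

## The system being modelled

A miRNA family (miR-200) and a pair of transcription factors (ZEB1/2)
repress each other: the miRNA degrades the TF transcripts through 3'UTR
sites, and the TF represses the miRNA locus together with a broad
epithelial gene program. The experimental design the pipeline models
breaks the loop in defined places: parental mesenchymal cells, cells
with a dox-inducible 3'UTR-less ZEB transgene held at endogenous level
(endogZEB), and cells over-expressing it (oexZEB), each treated with a
control or miR-200c mimic. Because the transgene lacks the 3'UTR, the
miRNA can no longer remove the TF, so any miR effect that disappears in
the endogZEB/oexZEB backgrounds must flow through the TF.

## Synthetic data: what it emulates

`synthetic.simulate_counts` assigns each sample a ZEB activity
Z ∈ {0, 1, 2} and a miR activity M ∈ {0, 1} (parental+miR has Z = 0; the
transgene backgrounds keep Z at 1 or 2 regardless of miR). Gene classes
respond as:

| class | transcriptional (ΔI) | post-transcriptional (ΔPT) |
|---|---|---|
| direct_miR_PT | 0 | `pt · M` (default −1) |
| ZEB_repressed | `−tr · (Z − 1)` (default tr = 2) | 0 |
| ZEB_activated | `+tr · (Z − 1)` (tr = 1.5) | 0 |
| coherent_FFL | `+tr · (Z − 1)` (tr = 1) | `pt · M` (−1) |
| incoherent_FFL | `−tr · (Z − 1)` (tr = 1) | `pt · M` (−1) |
| indirect | ±½ of the TF effect, random sign | 0 |
| null | 0 | 0 |

Default class proportions are 10/10/5/5/5/15/50 percent. Counts are
negative binomial with variance μ + φμ² (φ = 0.05 by default); φ = 0
degenerates to the rounded mean so that noise-free oracles are exact.
Exonic means follow ΔI + ΔPT; intronic means follow ΔI only, scaled by
an intron fraction of 0.3 — the identifying assumption of exon–intron
split analysis is therefore true by construction. A batch effect adds a
0.3 log2 shift to a random 30% of genes in batch-2 samples (emulating a
small replicate effect of a few percent of variance). Library sizes are
drawn from 15–25 million reads, the depth of the kind of bulk
experiment being emulated; at this depth biological dispersion, not
shot noise, limits recovery. Gene base abundances span 2⁶–2¹⁰ relative
units.

What the generator does **not** emulate: gene length and GC effects,
isoform switching, overlapping genes, intronless genes (beyond genes
falling under the detection filter), correlated noise between exonic
and intronic layers, and outlier samples. Passing the recovery
benchmarks therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to everything real data
contains.

`simulate_panel` builds a CCLE-like screen input: planted pairs receive
prediction scores in the extreme negative tail (uniform on
[−1.2, −0.6] against a background exponential tail clipped at −0.55)
and target expression `−s·m + (1−s)·ε` where s is the anti-correlation
strength, so s = 1 gives Spearman exactly −1 and s = 0 is the null.
`simulate_chip` plants noisy peak sets around the transcriptionally
ZEB-bound classes with configurable sensitivity and false-positive
rate; true targets get stochastically higher peak scores (gamma(4,2)
vs gamma(2,1.5)). `simulate_ring` places modules at equal angles on the
circle spanned by the orthonormalised Z and M activity profiles, with
angular jitter sd 0.1 — the planted version of the circular regulatory
continuum.

Every generator draws from its own seeded stream
(`default_rng([seed, tag])`), so changing one operation's parameters
never perturbs another's output at the same seed.

## Normalisation and models

TMM follows the standard recipe: reference sample by upper-quartile
closest to the mean, gene-wise M and A values on library-scaled
proportions, double trimming (30% of M, 5% of A), inverse
delta-method-variance weights, factors rescaled to geometric mean 1.
Log-CPM uses the library-size-scaled prior convention
`log2((y + pc_s) / (L_s + 2pc_s) · 1e6)` with `pc_s = 0.5·L_s/mean(L)`.
Both are verified against the Bioconductor implementations in the test
suite. Filtering CPM is computed on raw library sizes (before TMM), a
choice documented here because either order is defensible.

Known limitation: with the generator's default 50% regulated genes and
asymmetric effect sizes, trimming cannot fully separate the null
distribution and TMM retains a residual ~0.1 log2 composition bias in
absolute coefficients. This is inherent to composition-based scaling
under heavy regulation, affects real experiments of this kind equally,
and cancels in the interaction contrasts that carry the biology.

Precision weights re-implement the mean–variance-trend idea: per-gene
OLS on log2-CPM, lowess (span 0.5) of √σ̂ against average log2 count,
trend evaluated at each observation's fitted log2 count and raised to
the −4th power; the trend is clamped at its boundary values outside the
fitted range. Moderation matches the scaled-inverse-χ² empirical-Bayes
estimator to 8 decimal places of the reference implementation,
including the prior-parameter recovery (a planted d₀ = 4, s₀² = 2 prior
over 5000 genes is recovered within ±1 and 10%); when the
log-variances are under-dispersed the prior df is infinite and all
variances pool to the mean. Tests are two-sided with d + d₀ degrees of
freedom; BH is applied within each contrast.

The two design parameterizations (cell-means + batch vs intercept,
main effects and interactions + batch) span the same column space, and
a dox offset column is added only when no-dox control samples are
present, keeping both full rank.

## EISA

Both count layers are filtered jointly (≥ 5 reads in ≥ 2 samples in
*both* layers — the intron floor is a package default; the exonic-only
thresholds of the expression filter do not apply here), then normalised
independently (own TMM factors and library sizes). ΔE and ΔI are the
same linear-model contrast applied to each layer; a group-mean mode
exists for noise-free verification. "Exact" recovery at dispersion 0 is
limited only by count rounding and the log prior (~0.01 log2 at the
default depth). The classifier (|Δ| ≥ 0.585, i.e. 1.5-fold, with a
2:1 dominance ratio between components) is a display convenience over
the continuous components, not a calibrated test.

## Network

Signed adjacency `((1 + r)/2)^β` with β = 16; TOM
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; average linkage on
1 − TOM. Branch cutting is a simplified form of hybrid dynamic cutting:
a static cut at the 99th percentile of merge heights deliberately
over-fragments, fragments below the minimum size (10) are dissolved and
their genes reassigned to the module of highest kME when kME ≥ 0.3
(else unassigned), and eigengene merging (dissimilarity < 0.25)
consolidates the fragments. The full published dynamic-hybrid recursion
(deep split levels > 0) is not implemented and raises. Modules under 50
genes can be discarded afterwards, the usual guard against reporting
tiny unstable modules. Gene selection uses the robust range (second-highest minus
second-lowest) rather than the plain range so that a single outlier
sample cannot promote a gene, with name-prefix exclusion of noisy
noncoding classes (SNOR/SCARN/RNU/MIR) and a ≥ 4 CPM in ≥ 2 samples
floor before taking the top 3000.

Eigengenes are unit-norm leading singular vectors of the z-scored
module submatrix, sign-oriented along the module mean profile. The
circular-structure check runs PCA twice: on gene profiles (z-scored
expression) to read each gene's angle `atan2(PC2, PC1)`, and on the
network matrix at β = 16 vs β = 1 to compare the PC1+PC2 variance
shares (the un-powered matrix concentrates > 99% of variance in two
components; the soft-powered one spreads it). Angle agreement is scored
by the mean resultant of pairwise angle differences, maximised over
reflection — moment-based circular correlations that subtract circular
means are undefined for ring-uniform marginals, which is precisely the
planted geometry.

## Screen and integration

REC scores default to Spearman correlation (the panel's scale is then
irrelevant); Pearson is available. Tail selection uses ≤-quantile
thresholds so ties are included, and percentiles are computed over
pairs with a defined REC. TF enrichment deduplicates genes first and
uses the conventional one-sided exact binomial tail P(X ≥ k) against
the background proportion, so an empty TF overlap yields p = 1 exactly.
The prediction-strength bins are cumulative (score < −0.1 … < −0.9),
matching how targeting-strength axes are usually drawn; counts are
therefore nested, not partitioned.

Module enrichment uses two-sided Fisher's exact tests (verified against
exhaustive hypergeometric enumeration for every 2×2 table with total
≤ 40) with BH across modules; unassigned genes stay in the universe.
The "top 50% of peak scores" rule is interpreted as ≥ the within-source
median, since peak-score scales are not comparable across sources. The
heatmap ring order is computed from the angular order of module
eigengenes in their PC1/PC2 plane (a manual order can be supplied);
within a module genes lean toward the adjacent ring module with the
larger kME and rise in own-kME toward the centre, with gene-id
tie-breaks making the layout a stable bijection.

## Benchmark problem sizes

The recovery benchmarks run at: 600 planted genes (300 transcriptional
vs 300 post-transcriptional) among 6000, matching a realistic ~10%
regulated fraction; 200 planted |log2FC| = 2 among 5000 genes for the
differential-expression check; 50 planted pairs among 10,000 (500-sample
panel) for the screen, with 200 null replicates at moderate quantiles
for the p-value uniformity check; and 3000 genes in 8 ring modules for
module recovery. All use the 12-sample study design and NB dispersion
0.05.

## Numerical choices and degenerate inputs

- Sample (n−1) standard deviations everywhere.
- dispersion = 0 means deterministic rounded means, not Poisson.
- Zero-variance genes: error in adjacency construction; zero rows with
  a warning in midpoint scaling; missing REC (excluded downstream) in
  the screen.
- Trigamma inversion by Newton iteration from `x₀ = 0.5 + 1/y` with
  closed-form guards at both extremes.
- BH uses a stable mergesort so tied p-values keep input order.
- Per-stage pipeline seeds are SHA-256-derived from the master seed and
  stage name, keeping every stage's stream independent.
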