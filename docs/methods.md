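# Methods

This note documents the models, numerical choices and design decisions
behind `mirtally`, and what the synthetic-data generator does and does not
emulate.

## Analysis model

### Preprocessing

Probe-level intensities pass through the canonical robust multi-array
average (RMA) order: optional background correction → quantile
normalization across arrays → log₂ → Tukey median-polish summarization of
each probe set.

**Detection calls.** The miRNA 3.0-class chips carry no mismatch probes,
so the classic MAS5 present/absent call (a Wilcoxon rank test of
discrimination scores) is realized here as a one-sided Wilcoxon rank-sum
of a probe set's intensities against the array's background probes,
shifted by a small offset τ (default 0.015) so a set must exceed
background by a margin. This preserves the MAS5 contract — a rank test
against background with an offset — on a PM-only platform; the exact tail
is used whenever SciPy can enumerate it. The default expression filter
retains features detected (p < 0.05) on at least 6 arrays. Because the
background draw is shared by all probe sets of an array, detection
p-values are exchangeable and marginally calibrated but correlated within
an array; the filter's "≥ k arrays" form is robust to that.

**Quantile normalization** maps each column onto the mean of the
column-sorted vectors; ties within a column receive the mean of the
reference values at their rank positions, so the defining property (all
columns share one sorted vector) holds exactly in the tie-free case and
rank order is always preserved.

**Median polish** alternates row- and column-median sweeps on the additive
model `value ≈ overall + probe + array`, stopping when no sweep moves a
residual median by `tol` (default 0.01) or after `max_iter` (default 10,
the convention for RMA summarization). The returned per-array expression
is `overall + array effect`; it is invariant to adding a constant to any
probe row.

**Background correction** (exponential signal ⊕ Gaussian noise
convolution) is implemented but off by default: the synthetic fixtures are
generated on the normalized scale, and the acceptance surface of the
pipeline is the normalization/summarization contract, not the background
model. Parameter estimation uses the kernel-density mode, the sub-mode
spread, and the mean excess above the mode — adequate for screening, not a
reimplementation of any vendor's exact estimator.

**Annotation funnel.** Features are filtered to a controlled species set
(human, apes, Old World monkeys — the lineages with conserved miRNA
complements relevant to a vervet study), grouped by identical mature
sequence (U/T-insensitive), and reduced to one representative per group
named by the human miRBase name when present, else the lexicographically
smallest name (a deterministic, documented tie-break). Funnel counts are
reported per step and are non-increasing by construction. Outlier arrays
are *reported* (per-array mean, five-number summary, first two PC
coordinates), never dropped automatically; exclusion is a configuration
decision.

### Differential expression

Each feature is fit by least squares to the full-factorial 2×2 model
(age × exposure, interaction included) under sum-to-zero coding.
Main-effect and interaction F statistics come from model comparison —
Type III sums of squares — the standard convention for unbalanced
factorials such as the 6/6/5/6 design that results when one array of a
6/6/6/6 study is discarded. The interaction stays in the model when
testing main effects because the analysis reports the interaction as a
first-class result. Fold changes are contrasts of *unweighted* cell means
(PAE − control; 2 yr − 5 mo with 5 months as baseline), so imbalance does
not bias them — matching the Type III philosophy. Features with zero
residual variance receive the limiting p (0 with any effect, else 1) and
are flagged.

Every cell must hold ≥ 2 samples (residual degrees of freedom); the fit is
vectorized across features with one QR factorization per model.

**q-values.** p-values are converted to q-values with the smoothing
estimator of the null proportion: π̂₀(λ) = #{p > λ}/(m(1−λ)) on
λ = 0, 0.05, …, 0.90, smoothed by a cubic smoothing spline (generalized
cross-validation choice of smoothing parameter) and evaluated at the
largest λ, clamped to (0, 1]. Setting π₀ = 1 reproduces Benjamini–Hochberg
exactly, which is the frozen oracle in the test suite. DE selection uses
the printed rule — p < 0.05 *and* |log₂FC| > 1, both strict — with
q-values reported alongside as descriptive output.

**Control list.** The k (default 24) non-DE miRNAs with main-effect
p-values nearest 1, after excluding features with a strong interaction
effect. "Strong" is not quantified in the source analyses; the default
interaction screen is p < 0.05. Ties in p break by feature id, so the
list is deterministic.

### Integration

Target-prediction files are parsed into a deduplicated relation
miRNA → {genes}: per-site rows collapse to one edge, and gene symbols are
harmonized by uppercase exact match only (unmatched genes are logged,
never fuzzily matched). Three dialects are supported: TargetScan-7.2-style
tab files, miRWalk-3.0-style CSV, and a generic two-column TSV that covers
any other engine's output.

The DE list used throughout integration is the *upregulated* miRNAs only;
downregulated miRNAs play no role in the suppression analysis. Pair
correlations are Pearson, with the exact t-transform p-value
(t = r·√((n−2)/(1−r²)), n−2 df, two-sided) — the default behaviour of the
standard correlation test. Histograms use 20 half-open bins of width 0.05
over [0,1] (last bin closed), with a fine mode of 20 bins over
[0, 0.0025) for the most significant sliver; counts are split by
correlation sign.

Counts are *independent target counts* — distinct miRNAs, never binding
sites — and genes with fold-change data but no predicted edge stay in the
table at count 0. Per-category summaries report n, mean fold change, and
the standard error of the mean (sd/√n), plus Pearson and Spearman tests on
the per-gene vectors. Residuals are DE-category mean minus control-category
mean over the categories populated on both sides; the ≥ min-hits comparison
(default 4) is a two-sided Welch t-test — the unequal-variance form, since
nothing guarantees equal spread — with the groups allowed to overlap (a
gene heavily targeted by both lists appears in both), which is the
conservative reading of the analysis and is documented here as such.

### Co-expression

The DE list's correlation matrix is ordered by loading on the first
eigenvector of the correlation matrix, with the sign fixed so the
largest-magnitude entry is positive and loading ties broken by feature id —
PCA signs are arbitrary and must be pinned for reproducible orderings.
Genomic-cluster membership comes from annotation coordinates (chromosome
plus optional window), never from re-alignment, keeping genome-scale data
out of the package; the report carries the members, span, and mean
pairwise Pearson r over all unordered pairs.

## Synthetic data generator

The generator emulates the study conditions end to end: 613 expressed
unique miRNAs on 23 arrays (cells 6/6/5/6), 24 planted upregulated and 3
downregulated miRNAs at a ±1.5 log₂ exposure shift against residual noise
of sd 0.25 (log₂ scale, independent Gaussian — the simplest model
consistent with RMA-scale data), a 5-member genomic cluster, a 16,000-gene
mRNA universe with ~2,000 predicted targets per miRNA (mean independent
count 3, counts spanning ≈ 0–16, the range seen in transcriptome-scale
target tallies), and per-hit mRNA depression β = 0.02.

**Target maps.** A latent *true* target relation drives the suppression:
each planted miRNA draws its true targets from a weighted gene
distribution (lognormal targetability, σ = 0.5 — some genes are hubs for
many miRNAs). The two emitted maps are symmetric noisy observers of that
relation: each keeps a true edge with sensitivity √overlap (so the
probability that one map's edge appears in the other is the configured
`map_overlap`, default 0.7) and fills to its nominal out-degree with fresh
weighted draws. Non-planted miRNAs copy a fixed random planted miRNA's
edges within each map with probability `map_overlap`, plus fresh draws —
the single knob that sets the DE-versus-control target-count correlation
(≈ 0.73 at the default). The symmetric-observer design was chosen over
deriving the second map from the first because a derived map carries
systematically less signal than the map that defines the truth, which
would make the replication analysis fail for reasons that have nothing to
do with the method.

Each gene's mRNA log₂ fold change is −β × (distinct true planted-miRNA
hits) + N(0, noise_sd), and an mRNA expression matrix consistent with
those fold changes over the same 23 samples is emitted so the
pair-correlation stage can run end to end.

**Cluster.** The planted cluster shares a latent locus factor with
amplitude 3× the residual sd — a co-transcribed locus with its own
expression variability, which is what makes a cluster stand out as a tight
block against the exposure-driven background correlation. The factor is
drawn orthogonal to the 2×2 design space (locus variability independent of
the experimental factors), so it perturbs neither cell means nor fold
changes, and the member-specific noise is calibrated so that the raw
pairwise correlation — exposure shift included — lands at `cluster_rho`
(default 0.97). A by-product matching real data: cluster–non-cluster
correlations sit near 0.56 and non-cluster pairs near 0.90, so the DE
list's correlations span roughly 0.5–0.99 rather than being uniform.

**Probe-level fixture.** Background probes are lognormal; absent probe
sets are draws from exactly the background distribution (so null detection
p-values are calibrated), present sets are scaled by `signal_fold` with
per-probe affinity effects. Truth labels are recorded.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: hybridization chemistry and spatial
artifacts, heavy-tailed or correlated array noise, cross-hybridization
between related miRNAs, sequence-driven target prediction (edges are
sampled, not predicted from seeds), secondary mRNA regulation
(transcription-factor cascades), and any real genome's coordinates. The
generator demonstrates that the pipeline recovers the structures it is
designed to detect at realistic sizes and noise levels — not that those
structures are present in any particular dataset.

## Problem sizes and numerical choices

- The acceptance checks run the full chain at the default study size
  (613 × 23 miRNA matrix, 16,000-gene universe) over 20 seeds, and null
  calibration on a 4,000-feature global-null dataset — chosen so the
  binomial resolution of the type-I band is adequate at a single seed.
- Bit-level determinism: all randomness flows from one
  `numpy.random.Generator` seeded by the configuration; pipeline outputs
  avoid wall-clock state, and fixture round-trips use round-trip float
  parsing.
- Degenerate inputs are first-class: empty gene universes produce valid
  empty files; an empty DE list downgrades the integration t-test to a
  notice; zero-variance features are rejected (correlation matrix) or
  flagged (pair correlations) by the operation that cannot define them.
- `mannwhitneyu`'s exact mode is used automatically for small, tie-free
  detection samples; elsewhere the normal approximation with tie
  correction applies.
- The π̂₀ spline falls back to the raw estimate at the largest λ when the
  grid is degenerate, and to 1 whenever the estimate exceeds 1.

## Known limitations

- The detection offset τ and the background-probe variant of the
  detection call are documented stand-ins; vendor tools may differ in
  detail, though the rank-test contract is the same.
- Type III tests assume the full factorial model; a main-effects-only
  analysis would give different p-values on unbalanced data.
- Gene-symbol harmonization is exact-match by design; cross-platform
  symbol drift must be resolved upstream.
- The ≥ min-hits groups may share genes; a disjoint-group variant would
  need an explicit tie-break rule that the overlap-permitting reading
  avoids.
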