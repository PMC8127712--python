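# Methods

## Model overview and assumptions

The pipeline models the association between population allele
frequencies and the environment at the sampling sites, and projects that
association onto a future climate. Its central assumptions are the
standard ones of the genomic-offset family: the fitted
genotype–environment relationship is in (or near) equilibrium and
remains valid under the future scenario; all modelled loci contribute
equally; loci are under direct environmental selection or tightly
linked to such loci; and gene flow does not reorganize the spatial
pattern between now and the projection horizon. Violations (rapid
demographic change, plasticity, polygenic redundancy) bias the offset
as an *index* of required change, not its sign; the offset should be
read comparatively across a landscape rather than as an absolute
evolutionary rate.

## Per-SNP forests

Each SNP's frequency is regressed on the predictors with a bootstrap
CART forest (500 trees, `mtry = ⌈p/3⌉`, minimum leaf 2, unlimited
depth; all configurable via `GradientForestParams`). The forest is a
compact numba-compiled implementation specialized for very small n
(sites are typically 10–20): variance-reduction splits with thresholds
at midpoints of adjacent sorted values, per-tree bootstrap, and
out-of-bag R². The test suite cross-validates its predictions and OOB
behaviour against scikit-learn's RandomForestRegressor; at n = 15 both
give systematically *negative* OOB R² on noise responses
(mean ≈ −0.30) — an expected property of out-of-bag validation at tiny
n, not a defect — which is why significance calibration (below) cannot
simply threshold R² at zero.

## Turnover functions

Split improvements are credited to (predictor, threshold) pairs. Per
SNP they are normalized to sum to one and weighted by max(OOB R², 0),
so each SNP distributes exactly its explainable variance and
uninformative SNPs contribute nothing; the pool is divided by the SNP
count so totals are mean-R² decompositions. Along each predictor the
pooled mass is binned into 50 equal-width bins over the observed range
and, under density standardization (default), divided by the local
density of split *opportunities* (midpoints of adjacent distinct
observed values, floored at the smallest positive density) and rescaled
to preserve the predictor's total — standardization reshapes the
turnover function along the gradient without changing its total rise.
The cumulative sum gives the monotone step function F_p with F(min) = 0;
evaluation clamps to endpoint values outside the training range, which
deliberately prevents invented turnover where future climates exceed
observed support. A predictor's overall importance is F_p's total rise;
ties in the ranking break lexicographically.

## Significant SNPs

The per-SNP statistic is OOB R². Because its null distribution at small
n is shifted and skewed, the default criterion is an empirical-null
calibration in the large-scale-inference tradition: location and scale
of the null are estimated robustly (median and MAD) from the observed
R² distribution across all SNPs — valid when the adaptive fraction is
modest, as in the simulated architecture (10%) — and one-sided normal
p-values on the resulting z-scores are controlled with
Benjamini–Hochberg at q = 0.05, intersected with R² > 0. Two
alternatives are available: plain `r2_positive` (the permissive
gradient-forest convention; at n = 15 it admits ~10% of null SNPs) and
`permutation_fdr` (pooled permutation null; more expensive and its tail
is inflated by permutations of near-binary adaptive responses, so it is
not the default).

## Landscape transform, PCA and RGB

Raster stacks are pushed through F_p cell-wise (nodata propagates). The
PCA is fitted once on the pooled current ∪ future unmasked cells,
centred but not variance-scaled — the transformed layers already share
cumulative-importance units, and rescaling would erase relative
importance. Both time points are projected with the same rotation so
scores are comparable; component signs are fixed (largest-magnitude
loading positive) for determinism. RGB rendering scales each channel by
the joint min/max over both time points, so identical compositions get
identical colours in both panels; the default "2pc" mode maps PC1→R,
PC2→G with blue fixed at 128 (two components capture the modelled
variation; a "3pc" mode is offered as the common three-channel
convention). A channel whose component is constant (relative spread
≤ 1e-12) renders as 128 with a warning. Scaling records are kept for
legends.

## Turnover and vulnerability surfaces

Adaptive turnover is the focal moving-window range: per band, max − min
over a (2r+1)² window intersected with valid cells (truncated at edges;
all-nodata windows yield nodata), composited across bands by the mean.
The default radius is 1 (3×3), configurable and recorded in output
metadata. The implementation (separable min/max filters with ±∞
padding) is tested for exact equality against a double-loop oracle.

Genomic vulnerability is computed in transformed-predictor space, not
PC space (PC truncation discards signal); the Euclidean metric is the
default and the Manhattan metric — which coincides with it when a
single predictor changes — is available, as is the PC-space distance as
a diagnostic via the exported score rasters. The per-SNP allele shift
is a deliberately separate, explicit construction: each retained forest
predicts the SNP's frequency under the current and future predictor
vectors of every cell; the relative shift |p_fut − p_cur|/max(p_cur, ε)
uses ε = 0.01 to guard division near zero, and cells are summarized
over the significant set by mean (default) or max. Classes use
upper-inclusive half-open intervals: low ≤ 0.25 < medium ≤ 0.50 < high,
configurable.

## Overlays and tests

Polygons are rasterized by cell-centre containment (boundary-inclusive),
which matches per-km² counting semantics and is exactly testable;
richness counts distinct species ids per cell and endemism is a
feature-level flag supplied with the data. The two-sample comparison is
a pooled-variance Student t with df = n₁+n₂−2, one-tailed by default
(testing mean(a) > mean(b)), with Cohen's d = Δmean/pooled SD; the
regional grouping is user-supplied (the bundled analysis uses a 3×3
block partition, two south-western regions vs the other seven). The
composite priority is intentionally weight-explicit —
w₁·rank(low vulnerability) + w₂·rank(high turnover) − w₃·threat, with
per-cell percentile ranks in [0,1] and protected cells flagged rather
than scored — and records its formula and weights in metadata.

## Synthetic data generator

The generator emulates the study design, not any particular geography:
4 environmental layers (tmin °C, precipitation mm, precipitation
seasonality, cloud cover %) as Gaussian random fields (white noise
convolved with a Gaussian kernel of bandwidth `autocorr_length`,
default 6 cells) blended with rotating deterministic gradients and
rescaled to stated ranges on a 60×60 grid of 0.01° (≈1 km) cells;
15 sites placed by equal-count quantile stratification along the driver
so the gradient is spanned (identifiability at small n); 500 SNPs of
which 50 are adaptive logistic clines on the driver,
p = clamp(logistic(a + b·E) + ε, 0, 1) with b = ±8 per env-unit,
site noise ε ~ N(0, 0.02), and neutral SNPs p̄ ~ U[0.01, 0.99] plus the
same noise (the p̄ spectrum straddles the 2% MAF threshold); the future
scenario adds a delta to the driver ramping linearly from 0 on the
eastern edge to 2.0 env-units on the western "coastal" edge (other
layers unchanged by default). Cline centres are drawn within the
central 60% (20–80th percentile) of the site-sampled driver range so
every cline is flanked by populations on both sides — a cline with a
single population on one flank cannot be validated out of bag at any
significance criterion. Clamping (not resampling) keeps the generator
monotone in the driver. Ground truth (class, slope, intercept) is
recorded per SNP.

What the generator does *not* emulate: linkage between SNPs, drift and
demographic history, spatially autocorrelated sampling noise,
covariance between environmental layers beyond chance, and nodata
structure. Passing tests therefore demonstrate correctness of the
machinery and identifiability under the stated architecture, not
robustness to demographic confounding in real data.

## Determinism and numerics

Every stochastic component takes an explicit seed: the generator splits
its seed into independent streams (fields, sites, frequencies); each
SNP's forest seed derives deterministically from the model seed and
column index; the forest uses an internal splitmix64 stream, so results
are identical across platforms and runs. Frequencies are stored as
float64 and round-trip CSV/GeoTIFF exactly (17-significant-digit CSVs,
round-trip float parsing); RGB and class rasters are bytes with legend
metadata. Pipeline manifests record the seed, a config hash and
per-artifact SHA-256; reruns with identical configs produce identical
manifests (timings go to the log). Geographic convention, used
everywhere: row-major 0-based grids, top-left origin, northern row
first, square cells in degrees (WGS84).

## Problem sizes

Default test and analysis sizes — 60×60 cells, 500 SNPs, 15 sites,
500 trees — were chosen so a full fit takes ~2 s and the complete
multi-seed property checks (20-fit parameter recovery, 10-seed
monotone-warming) finish in a few minutes on one CPU, while remaining
at the study's actual population and panel scale in the dimensions that
matter statistically (sites and adaptive fraction).

## Known limitations

* GeoTIFFs are read/written with square-pixel, WGS84 geographics only;
  no reprojection or resampling is provided.
* Polygon input is GeoJSON; shapefiles must be converted upstream.
* The empirical-null significance calibration assumes a modest adaptive
  fraction; panels where most SNPs are environment-associated would
  need the permutation criterion with an external null.
* The offset is reported in cumulative-importance units, which are
  comparable within one fitted model but not across models.
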