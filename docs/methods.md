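# Methods

This note records the models, estimators and numerical choices behind
`depmix`, what the synthetic screens do and do not emulate, and the
known limits of both.

## Score model and imputation

Dependency scores are taken as produced by the upstream CERES (CRISPR)
and DEMETER2 (shRNA) pipelines; no further normalisation is applied.
The two screens are aligned to a shared genes × cell-lines frame: genes
match on Entrez id when both files carry one (falling back to symbol),
and shRNA columns (CCLE names) are translated to DepMap ids through the
cell-line metadata table.  The canonical orientation is genes × lines
everywhere because every per-gene statistic indexes gene-then-line.

A condition measured by exactly one technology is imputed from the
other before mixing.  The imputation model is a single global smooth
curve per direction — CRISPR as a function of shRNA and the converse —
fitted by locally weighted linear regression (lowess, span 0.3, two
robustifying iterations) on the doubly-measured conditions.  For speed
the fit uses a seeded random subsample of at most 200,000 pairs; with
millions of near-collinear points the subsampling changes predictions
negligibly.  Predictions outside the fitted range are extrapolated
linearly from the terminal curve segment.  Observed values are never
modified, and conditions measured by neither method stay missing
through every later stage.  The model is deliberately simple: it
captures the monotone mean relation between the two technologies and
nothing else (no per-lineage or per-gene structure).

The combined score is the elementwise mix
`S^θ = θ·S^C + (1−θ)·S^R`, exactly affine in θ; θ = 0.6 is the default,
and θ is global — there are no gene- or lineage-specific mixes.

## Essentiality threshold

The pooled combined scores form a near-normal background plus a heavy
left tail of true essential effects.  The background is recovered from
the side the tail cannot reach:

1. A Gaussian-kernel density estimate (Silverman bandwidth, FFT-binned
   on a 512-point grid) locates the dominant mode.  The raw grid argmax
   is noisy where the density is flat, so the mode is refined by a
   quadratic fit to the log-density over the contiguous region above
   60% of the peak — exact for a normal peak, and insensitive to the
   left tail because the window is contiguous around the maximum.  If a
   second peak exceeds half the primary's height a warning is raised
   and the global maximum is used.
2. Scores at or above the mode are reflected about it; the folded
   sample's mean and standard deviation estimate Normal(μ, σ).
3. `T = μ + σ·Φ⁻¹(0.001)`, so a background condition is flagged at rate
   0.001.

On 10⁶ standard-normal draws this recovers T within ±0.03 of the exact
−3.0902, and 1% contamination at −6 moves it by well under 0.1 (the
contamination sits entirely below the mode).  The estimator is
location-equivariant up to KDE grid tolerance.  Conditions still
missing after imputation are excluded from the fit and never called
essential.

## Efficacy, selectivity and the essential set

Per-gene percentiles use linear interpolation between order statistics
(continuous in X; X defaults to 1, the grid {1, 2.5, 5, 10, 25} is what
the interactive tooling exposes).  Genes with fewer than 20 observed
scores get undefined efficacy and are flagged rather than scored.

The dispersion regression `E_{100−X} ~ E_X` across genes uses Huber
M-estimation (tuning 1.345, ≤50 IRLS iterations, tolerance 1e-8) so
that the selective minority does not drag the line fitted to the
commonly essential majority.  When the relation is numerically exact
the robust scale degenerates to zero and the fit falls back to ordinary
least squares, which makes "genes on the line have selectivity zero"
hold to machine precision.  Genes whose expected dispersion `D̂` is not
positive sit in a pathological fit region; their selectivity is
undefined (NaN) and flagged, not clamped.

Essential genes are `{G : E_X < T^θ}`.  Method-exclusive essentiality
is tested per gene and direction with a one-tailed Fisher's exact test
of that gene's conditions against all other genes' conditions
(2×2 of {this gene, rest} × {in area, not}), at the fixed α = 1e-3;
areas A and B are CRISPR-essential-only and shRNA-essential-only
conditions under per-method thresholds fitted on the raw (unimputed)
matrices.  Gene-set overrepresentation uses the same hypergeometric
upper tail with Benjamini–Hochberg adjustment across sets.  Both
operations share one kernel that is verified against exact
rational-arithmetic enumeration in the test suite.

## ECHODOTS

Clustering operates on the essential genes' pairwise Spearman distance
(1 − ρ, pairwise-complete lines; a constant profile has undefined ρ and
is placed at distance 1 with a warning).  Each ensemble member embeds
the distance matrix with t-SNE (precomputed metric, random
initialisation, perplexity 30 — auto-reduced to (n−1)/3 for small
inputs — 1000 gradient iterations by default) and partitions the layout
with DBSCAN at ε = L/d, where L is the larger of the two per-axis
coordinate ranges.  `min_pts = 2`, so two-gene clusters are possible
and singletons are noise.

The consensus links every gene pair co-clustered in more than half of
the runs (noise counts as co-clustered with nothing) and takes
connected components; components of size ≥ 2 are the consensus
clusters, ordered by decreasing size for stable ids.  A gene's
membership probability is the mean co-association with its consensus
co-members — equivalently the average fraction of co-members it was
actually clustered with per run; noise genes report the support of
their best component.  This realises the "majority vote" of the
ensemble verifiably; the cited ensemble-clustering literature admits
several constructions and this co-association one was chosen for being
auditable.

The granularity lower bound d₀ is the smallest d in a grid whose
consensus keeps the largest-to-second-largest cluster size ratio at or
below 5 (noise excluded) — below d₀ most genes merge into one cluster.
One distance matrix and one set of seeded embeddings are shared across
all granularities; only DBSCAN and the consensus are re-run per d.
Ascending d maps to L/M/S prefixes; each finer cluster is linked to the
coarser cluster holding the plurality of its genes, and links where the
finer cluster is not a clean subset are flagged as hierarchy
violations, not repaired.  The full run is bit-reproducible given the
base seed (run i uses seed base+i).

Default granularities are {65, 100, 141} (appropriate for thousands of
genes); the planted benchmark below uses {16, 24, 48} — the coarse
level sits at the d₀ scale validated by the ratio rule on that data,
and the fine level at 3× coarse, where genes without a genuine partner
fall out as noise.

Connectivity graphs join cluster genes at Spearman ρ strictly greater
than 0.1 (one-sided: negative correlations never create edges),
weighted by ρ, with pairwise-complete correlations; GraphML export
preserves weights and small-cluster membership.

## Synthetic screens

The generator plants known structure so every stage is testable
offline.  Per condition, truth = biological background + essential
effect; each screen observes truth plus its own measurement noise.
Background variance splits evenly between the shared biological part
and per-method noise, so paired background scores correlate at 0.5 and
cross-method imputation has signal.  Essential effects are iid
Normal(−1.2, 0.2) shifts (six background standard deviations,
`background_sd = 0.2`): on all lines for commonly essential genes and
method-exclusive artifacts (the latter in one matrix only), on a
penetrance-sized line subset (default 10%) for selective genes.
Planted modules draw their members from the selective class, share one
dependent-line set, and mix a shared per-line latent factor into their
biological background at the requested correlation — together these
make module profiles strongly rank-correlated, the property the
clustering exploits.  Missingness is assigned per condition
independently at rates (0.20, 0.0028, 0.0007) for
CRISPR-only-tested / shRNA-only-tested / untested, matching the
aggregate rates of paired DepMap releases.

The default spec (2,000 genes × 100 lines) keeps every stage fast with
stable threshold fits; the clustering benchmark uses 423 lines — the
width of a real release — because rank correlations over few lines are
noisy.  What the generator does *not* emulate: copy-number artifacts,
reagent-level variability, lineage-correlated background, off-target
structure, non-normal background shapes.  Passing tests therefore show
the estimators recover the structure they model, not that real screens
contain only such structure.

## Numerical and design notes

- Percentile convention: linear interpolation (numpy default), chosen
  for continuity in X.
- Fisher tests return p = 1 for zero-margin tables.
- Binomial significance of a dependent-line count is the exact upper
  tail P(K ≥ k); no tail convention is hard-coded beyond that.
- The PC1 mixing ratio is the leading covariance eigenvector of the
  pooled doubly-observed (S^C, S^R) cloud, sign-fixed into the positive
  quadrant, reported as v_C/(v_C+v_R).
- The pipeline expands one global seed into per-stage seeds through
  `SeedSequence`, so a config file fully determines every output byte.

## Known limitations

- The consensus stage materialises an n×n co-association matrix; fine
  above ~5,000 essential genes is untested territory for memory.
- The d₀ rule inherits the grid's quantisation: neighbouring data seeds
  can select adjacent grid points.
- On the planted benchmark the fraction of uncorrelated filler left as
  noise at the fine granularity varies roughly between 0.6 and 0.8
  across generator seeds — finite-sample rank correlations give some
  filler pairs consistent mutual nearest neighbours, which the ensemble
  (correctly, given its inputs) treats as weak clusters.
- Selectivity is undefined for genes in the D̂ ≤ 0 region and for genes
  with fewer than 20 observed lines; they are flagged, not ranked.
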