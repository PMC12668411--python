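# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Synthetic data model

The generator emulates a circular bead array read out through a droplet
snRNA-seq library, for two species at once.

**Geometry.** Beads and cells are placed uniformly in a disc of radius
`array_radius` (default 1,000 length units, 5,000 beads). Latent
differentiation pseudotime is tied to geometry: `t = 1 − r/R`, increasing
from the tissue periphery to the center, the concentric-maturation
arrangement the spatial-field stage is designed to reveal.

**Bead oligos and reads.** Each bead carries a unique 15-nt spatial
barcode split 8 + 7 around an 18-nt universal-primer (UP) linker,
mirroring the bead design. A simulated read pair is R1 = 16-nt cell
barcode + 12-nt library UMI, R2 = bc1(8) + UP(18) + bc2(7) + 9-nt bead
UMI. Per droplet, `Poisson(reads_per_cell_mean)` molecules are emitted
(default 60); each molecule's bead is drawn with probability proportional
to a Gaussian kernel of its distance to the cell (`diffusion_sigma`,
default 25 units ≈ 2 bead spacings). The physical barcode-diffusion
process is not modeled; any monotone-decaying kernel would serve, and the
Gaussian is chosen for analyzability. Each molecule is sequenced
1 + Poisson(0.5) times so that chimeric reads can create multi-bead
(cell, UMI) groups — without duplication the chimera filter would have
nothing to reject. Corruptions are injected independently per read:
an `N` substituted into the UMI (rate 0.02), 1–3 UP substitutions (0.05),
a single UP deletion (0.02), 1–2 barcode substitutions (0.05), and
chimeric reassignment of the bead barcode keeping (cell, UMI) (0.02).
A per-read truth log records every injection, so filter behavior can be
audited read by read.

**Expression.** Counts are negative binomial (gamma–Poisson, dispersion
θ = 2) with mean depth 2,000 UMIs/cell and lognormal per-cell size
factors (σ = 0.25). A fraction of genes (default 10%) respond to
pseudotime through a Gaussian bump on the log scale,

    μ_g(t) = b_g · exp(a_g · exp(−(t − c_g)² / 2w_g²)),

with centers c_g ~ U(0.15, 0.85), widths w_g ~ U(0.10, 0.25), and
amplitudes a_g = 2 · LogNormal(0, 0.5). The lognormal amplitude spread
makes effect sizes long-tailed, so the "top program" (the upper decile by
mutual information) is a well-separated set rather than a threshold
artifact — the property real trajectory panels show. Mitochondrial genes
(5% of the panel, `mt-`/`MT-` prefixes) are ordinary flat genes whose
summed fraction exercises the QC cap.

**Two species and orthology.** The two species get independent cell
populations but linked gene panels: 90% of non-mitochondrial genes form
one-to-one ortholog pairs, exported in the three-column MGI HOM report
layout together with decoy one-to-many and many-to-one classes that the
strict filter must reject. `shared_ortholog_frac` of the responsive genes
are responsive *through their ortholog pair in both species*, and a
shared pair inherits a single (c, w, a, baseline) parameter set — a
conserved program conserves its dynamics and expression level. The
remaining responsive genes are species-specific, with their partner (if
any) kept flat. Setting `shared_ortholog_frac = 0` produces independent
programs, the null of the cross-species test.

**Doublets** are sums of two distinct real cells' count vectors appended
as extra droplets (rate 5%); their spatial reads alternate between both
parents' positions, so placement sees two clouds.

**What is not emulated:** ambient RNA (delegated to external tools on
real data), batch structure, UMI collisions beyond the birthday rate of a
random 12-mer, optical bead-calling artifacts, and segmentation of
non-fibroblast lineages. Passing tests therefore demonstrate method
correctness and statistical calibration under a clean generative model,
not robustness to those real-data pathologies.

## Spatial positioning

UP detection scans offsets ±2 nt around the expected start, accepting the
best ≤2-substitution alignment (ties toward the expected offset) or, if
none, an exact single-deletion match (prefix + suffix check). Whitelist
matching tries exact, then a unique 1-substitution neighbor, then a
unique 1-deletion match; any ambiguity (two candidate beads) rejects the
read, because a wrong rescue corrupts placement silently. The chimera
rule keeps a (cell, UMI) group's dominant bead if it holds ≥80% of the
group's reads, else drops the group.

DBSCAN treats a bead's UMI count as a sample weight, so nUMI enters the
minPts density condition multiplicatively. The (ε, minPts) pair is chosen
from candidate grids — ε defaults to 1.5/2.5/4/6× the median
nearest-bead spacing, minPts ∈ {3, 5, 10} — by the placement score: the
fraction of cells with exactly one signal cluster holding ≥50% of the
cell's UMIs, ties toward smaller ε. Cells with zero or several signal
clusters stay unplaced. Coordinates are continuous, origin at the array
center.

On the default 5,000-bead / 300-cell simulation the pipeline places ~95%
of droplets with a median error of ~0.6 bead spacings.

## Quality control

The MAD filters operate on log1p totals and log1p detected-gene counts
(natural log; the MAD z-score is base-invariant). They are iterated to a
fixed point — medians recomputed over retained cells until no removal —
which makes the filter idempotent; a single pass is not, because removing
the tails shifts the median enough to expose borderline cells. The UMI
floor (<500, strict) and mitochondrial cap (>8%, strict) are single-pass
and inherently idempotent. An all-zero cell is caught by the floor and
the mito fraction uses a guarded denominator.

Doublet detection builds synthetic doublets as count-vector sums of two
random real cells (sums preserve the library-size signal the enrichment
relies on), co-embeds them with the real cells (log-normalize, HVGs, PCA,
k=15 neighbors, Leiden), and tests each cluster's synthetic count with an
upper-tail hypergeometric (population = augmented set, successes =
synthetics, draws = cluster size). Clusters with p strictly below 1e-7
mark their real members; after 40 iterations a cell flagged in ≥50% of
iterations is a doublet. The per-iteration flag-count series is returned
for convergence inspection rather than gated automatically.

## Trajectory

HVG ranking follows the variance-stabilizing scheme: a lowess trend of
log10 variance on log10 mean fit on raw counts, counts standardized by
the trend's predicted standard deviation, clipped at √n, and genes ranked
by the variance of the clipped values. Mitochondrial and ribosomal
(`RPS/RPL/MRPS/MRPL`) genes are excluded.

The embedding is a centered PCA of the HVG-subset log-normalized matrix
with a deterministic sign convention (each component's largest-magnitude
loading positive). It deliberately stands in for a learned batch-aware
embedding: single-sample synthetic data has no batch structure, and every
downstream statistic consumes the embedding only through neighbor
distances. The `Embedding.method` tag records `"pca"`.

Diffusion pseudotime uses the standard adaptive-bandwidth Gaussian-kernel
diffusion map over a k=15 neighbor graph (10 components, single-branch),
with connectivity verified (a disconnected graph raises, listing
component sizes) and the result rescaled so t(root)=0, max t=1. The root
is supplied by the caller; the pipeline's synthetic runs root at the most
peripheral (least-differentiated) cell, as a biologically chosen root
would be on real data. Recovery on a 2,000-cell, 20-gene monotone
trajectory: Spearman ρ ≈ 0.92 against the latent time; two roots chosen
in the same terminal region agree at ρ ≥ 0.95.

## Pseudotime-associated genes

Mutual information uses the Kraskov k-nearest-neighbor estimator (k=3)
with the standard preprocessing: each variable scaled to unit variance,
~1e-10 noise to break ties, Chebyshev joint neighborhoods,
strict-inequality marginal counts, and the digamma formula, clipped at 0.
The neighbor search runs in a compiled (numba) kernel that exploits the
one-dimensional marginals (outward scan in sorted order plus binary
search); it reproduces the reference implementation to <1e-3 nats on
continuous data and makes 10⁵–10⁶ gene×permutation evaluations tractable
on one CPU. Genes constant across cells score exactly 0. Accuracy against
the Gaussian closed form −½ln(1−ρ²) at ρ=0.9, n=2,000: error ≈ 0.03
nats.

The permutation null shuffles the pseudotime vector globally, once per
permutation, reusing the shuffle for all genes — cheaper than per-gene
shuffles and preserving inter-gene dependence under the null. The
empirical p-value is the literal proportion of permutations with MI ≥
observed (no +1 correction; p = 0 is possible and documented).
Benjamini–Hochberg adjustment runs over all scored genes; a
min-expression pre-filter (detected in ≥1% of cells, configurable)
excludes genes whose MI is undefined noise. Top hits are significant
genes with MI strictly above the linear-interpolation 90th percentile of
significant-gene MI. Production default is B=1,000 permutations; test
suites use B=40–200 with the calibration property (mean q<0.05 fraction
≤ 5% under a global null over 20 seeds at B=200) checked explicitly.

## Cross-species overlap

Strict one-to-one filtering keeps homology classes with exactly one gene
per organism and additionally drops any symbol appearing in more than one
class (an ambiguous symbol cannot anchor a pair). The background keeps
pairs detected (count > 0) in ≥1% of cells and MI-significant in both
species; "expressed" is interpreted as detection since no other
definition is workable across depths. Top sets are intersected with the
background before forming K and n.

The upper-tail hypergeometric sum is computed in log space (log-gamma
binomial coefficients combined with log-sum-exp): the printed-scale
result p ≈ 3.2×10⁻⁶³ is far above double underflow, but naive pmf
summation loses precision and smaller tails would underflow outright.
The scipy implementation serves as an independent cross-check in tests.

Calibration and power, verified by the test suite: with top sets drawn
uniformly from a synthetic background the p-values are approximately
uniform (KS p > 0.01 over 500 replicates); running the full
expression → pseudotime → MI → top-hits → orthologs → overlap chain on
400-gene / 400-cell two-species simulations, a half-shared conserved
program rejects at p < 0.01 in every tested seed, and fully independent
programs never do. These problem sizes are the package's scaled test
conditions; the statistic itself is size-agnostic.

## Trend heatmap

Each gene's log-normalized expression is regressed on pseudotime with a
cubic B-spline basis of 20 functions; the smoothing penalty is selected
by a deterministic generalized-cross-validation grid search over 25
log-spaced values (GCV = n·RSS/(n−edf)²), replacing the library's
stochastic penalty optimizer which broke byte-identical reruns.
Predictions on an 800-point uniform grid over [min t, max t] are
quantile-normalized: subtract the 1st percentile, divide by the 99th
percentile *of the shifted values* (the grammatical antecedent of the
normalization description; dividing by the raw 99th percentile is the
documented alternative), guard the division for flat curves, clip to
[0, 1]. Genes are ordered by the grid index of their maximum, ties broken
by gene id, so the heatmap reads as successive waves of activation.

## Spatial field

Outlier removal computes, per cell, the mean distance to its 5 spatial
nearest neighbors and the mean absolute pseudotime difference to them;
cells above the 98th percentile of the former AND the 95th percentile of
the latter (percentiles over the full point set) are dropped — isolated
cells are kept unless they also disagree with their neighborhood, and at
most ~2% of cells can be removed.

The surface is a Gaussian-process posterior mean with an RBF (initial
length scale 1.0) plus white-noise (initial variance 1e-3) kernel,
hyperparameters optimized by marginal likelihood with a fallback to the
initial values on optimizer failure. Coordinates are standardized with a
single isotropic scale factor before fitting, so the stated initial
hyperparameters are meaningful whatever the physical units; the 200×200
evaluation grid spans the data bounding box with a 2% margin and is
mapped back to data units (rows index y, columns x).

The surface is blurred first (Gaussian, σ = 10 grid pixels, reflective
boundary) and then differentiated with central differences — the order
that yields smooth streamlines; `blur_before_gradient=False` selects the
alternative reading (differentiate, then blur the components). The field
is masked to the convex hull of the input cells, with hull membership
given a half-grid-cell tolerance so every input point's nearest node
stays unmasked. On the radial synthetic tissue the gradient points inward
with a mean angular error of ~1°, versus a 20° acceptance bound; the
field is rotation-equivariant to within 5° and line-integrates back to
surface differences within 2%.

## Pipeline

One global seed fans out to per-stage seeds via a CRC32 hash of the stage
name, so stages re-run in isolation reproduce exactly. The YAML config is
validated strictly (unknown keys, types, ranges) before any stage runs;
an empty config is the full-default configuration with every
protocol-stated value (500 / 3 MAD / 8% / 40 / 0.5 / 1e-7 / 10,000 /
3,000 / 30 / 15 / 10 / 3 / 1,000 / 0.05 / 90 / 1% / 20 / 800 / 1–99 /
5 / 98 / 95 / 1.0 / 1e-3 / 200×200 / 10). Logging is structured to
stderr; data go only to declared paths; the run report records per-stage
counts, parameters, wall time and warnings.

## Known limitations

- The embedding is linear; strongly nonlinear manifolds would benefit
  from the learned embeddings used on real data.
- The chimera rule and UP-detection procedure are reasonable but
  non-canonical readings of tersely specified filters; both are isolated
  behind small functions with exhaustive unit tests.
- The doublet detector assumes discrete population structure; doublets of
  adjacent states on a continuum are largely undetectable by cluster
  enrichment (true of the approach generally, not this implementation).
- GPR is exact (O(n³)); thousands of placed cells per sample are fine,
  hundreds of thousands would need an approximate solver.
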