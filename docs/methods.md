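# Methods

This note documents the models, conventions and numerical choices behind
`clsmverse`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Coordinate conventions and geometry

Voxel indices are 0-based; the affine maps voxel centres to world mm. A
world point belongs to the voxel whose centre is nearest, with the tie at a
`+0.5` boundary broken toward the higher index (half-open cells). This
single rule is used everywhere — point lookup, endpoint assignment and
streamline traversal — so no boundary case is ambiguous.

Streamline-voxel traversal uses the Amanatides-Woo incremental grid walk
(3-D DDA) on the half-open cells, which is *exact*: a voxel is reported iff
the segment geometrically intersects its cell. The test suite verifies this
against an independent slab-method segment/box intersection oracle on 1000
random segments in an anisotropic grid. A point-sampling oracle (points
every voxel/20 along the segment) is additionally checked to be a subset of
the traversal; sampling alone can miss voxels clipped by chords shorter than
the sampling step, which is why the exact oracle is the equality reference.

Streamlines are stored in world mm. The plain-text `jsonl-polyline` dialect
round-trips at full double precision; TRK/TCK (via nibabel) store float32
and round-trip to about 1e-4 mm at brain-scale coordinates.

## Tract metrics

Eight metrics per tract per participant. Indirect metrics need only the
lesion mask: lesion percentage (share of tract voxels inside the lesion) and
disconnection percentage (share of the tract's streamlines whose traversal
contains a lesioned voxel — a binary pass criterion, no partial-volume
weighting). Direct metrics (volume, streamline count, mean FA/MD/AD/RD) are
computed on the *post-lesion* bundle: severed streamlines are removed and
the mask is rebuilt from the survivors, emulating per-participant
tractography; a config switch computes them on the intact atlas bundle
instead. When every streamline of a tract is severed, the tract is treated
as unreconstructable and its direct metrics are missing — missingness is
explicit (NaN), never coded as zero, because downstream models analyse each
metric on its own complete cases. The denominator of the disconnection
percentage is the atlas bundle's streamline count (configurable); percentages
are always on the 0-100 scale.

## Parcel connectomes

Streamlines are assigned to parcels by the label at their endpoint voxels
only (*end* criterion, strict — no dilation); a streamline contributes to an
edge iff both endpoints land in distinct nonzero parcels. The indirect
connectome counts the streamlines preserved after lesion filtering. The
direct connectome optionally corrects counts for parcel distance and volume;
because the exact correction used by common probabilistic-tractography
post-processing is not standardised, three variants are exposed (`off`,
`volume` = n/√(v_i v_j), `full` = n·d/√(v_i v_j)) with `full` as default —
transparency was preferred over fidelity to an unstated formula. A
percent-loss matrix is offered as a convenience, but preserved counts are
the primary indirect output.

## Graph metrics

All metrics run on `W' = W / max(W)` (so every metric is invariant to a
positive rescaling of the connectome), with edge lengths `1/w'` and
Dijkstra shortest paths. Characteristic path length averages the *finite*
off-diagonal distances; unreachable pairs are excluded and counted in the
log, which keeps the metric defined on fragmented (heavily lesioned)
networks. Weighted transitivity uses geometric-mean triangle intensities
over wedges (binary degrees in the denominator). Modularity is Louvain with
resolution γ = 1, 20 seeded restarts, best Q kept — chosen for
reproducibility; exhaustive-partition tests confirm the optimum is reached
on small graphs in ≥95% of cases. The rich-club curve uses binary degree
levels k = 1..k_max−1 and normalises the weight inside each >k subgraph by
the sum of the equally many largest weights in the whole graph; levels whose
subgraph has no edge are skipped and the remaining levels are averaged.

Small-worldness is the σ ratio `(C/⟨C_null⟩)/(L/⟨L_null⟩)` with C =
weighted transitivity and L = characteristic path length, against an
ensemble (default 100, seed-controlled) of nulls built by degree-preserving
double-edge swaps followed by a random reassignment of the original weight
multiset; when a graph is too small or dense to swap, the weight shuffle
alone forms the null. The σ form was chosen over Muldoon-style small-world
propensity: with only a global clustering and path-length pair in hand, σ is
the more widely comparable quantity, and the choice is encapsulated in one
function. Metrics that are undefined on a given graph (e.g. an empty
connectome after a massive lesion) are reported as NaN, never dropped.

## Statistical models

Every brain-behaviour cell compares two nested OLS models on identical
rows: `outcome ~ 1 + lesion_cc + scanner` (dummy coding, reference level
dropped) versus the same plus one candidate metric. Rows where the metric
is missing are removed from *both* models, so the per-metric N varies the
way it does when tractography fails for some participants. The cell records
ΔR², the F-test p of the added term, and a class at uncorrected thresholds
(significant < 0.05, marginal < 0.1): multiverse grids are about the pattern
across cells, so no familywise correction is applied. A metric collinear
with the base covariates yields ΔR² = 0 and class `ns` with a warning.

Sparse CCA uses the rank-1 penalized-matrix-decomposition estimator: with a
univariate response, the X-side weight vector is the soft-thresholded,
renormalised covariance vector `X'y`, with the threshold solved by bisection
so that ‖w‖₁ ≤ c and ‖w‖₂ = 1, where `c = 1 + sparsity·(√p − 1)` and
`sparsity ∈ (0, 1]` (default 0.3; no internal sparsity search is claimed).
Model fit is the Pearson correlation between observed scores and held-out
predictions pooled over 4 CV folds (pooling is more stable than per-fold
correlations at n = 50). Significance is a permutation test: the outcome
vector is permuted and the full cross-validation re-run per permutation
(499 by default, batched, two-sided on |r|). A parametric p-value on the
pooled predictions was measured to be anticonservative — the null standard
deviation of the pooled r is ≈0.20 rather than the 1/√(n−3) ≈ 0.14 a
Pearson test assumes, because predictions in different folds share training
data — so the permutation null, which accounts for that dependence exactly,
is the default.

## The synthetic cohort

The generator produces, from a single seed, a parcel atlas, tract bundles,
lesions, diffusion scalar maps and behaviour:

* **Grid**: 40×48×40 voxels at 2.5 mm isotropic (a 100×120×100 mm field of
  view), origin at the volume centre; "left hemisphere" is x < 0.
* **Atlas**: spherical parcels (radius 2 voxels) packed on a lattice; the 14
  slots nearest a left perisylvian anchor form the "language" ROI. 166
  parcels fit the same grid for whole-brain-scale checks.
* **Bundles**: six tight streamline tubes (25 streamlines each) between
  designated language-parcel pairs, arched quadratic curves with 1.5 mm
  jitter, plus 260 background streamlines between random parcel pairs so
  whole-brain connectomes are non-trivial. Tract masks are the union of
  member traversals.
* **Lesions**: sphere-union blobs (main radius ~N(25, 10) mm clipped to
  7-38 mm, up to two satellites) centred on the perisylvian territory with
  generous scatter, clipped to the grid. The defaults target volumes of
  roughly 2-260 cc with a mean near 70-90 cc, and produce the qualitative
  phenomena the pipeline must handle: disconnection percentages that pile up
  near 0 and 100 (most lesions either miss a tight bundle or engulf it) and
  occasional complete disconnection, which makes direct metrics missing for
  30-45% of tract×participant combinations. Lesion shapes are deliberately
  not anatomically realistic — only the overlap/severance topology matters
  to the methods under test.
* **Scalar maps**: per-voxel Gaussian fields around healthy means (FA
  0.45 ± 0.06; MD/AD/RD 0.80/1.20/0.60 ×10⁻³ mm²/s) with additive lesion
  shifts (FA −0.18, diffusivities up), clipped to physical ranges. This
  degradation model is a configurable stand-in; its parameters are not
  claims about tissue biophysics.
* **Behaviour**: naming (0-60) and Token (0-45) scores are linear in lesion
  volume (negative slope), scanner offsets (three levels, 50/36/14%), an
  optional planted metric effect, and Gaussian noise, then clipped to the
  test ranges (a warning fires if more than 10% of scores clip). Defaults
  give a lesion-size/behaviour correlation around −0.5 to −0.6. The default
  planted effect is β = −5 naming points per reference-SD of AF
  disconnection percentage.
* **Determinism**: every generator is a pure function of (spec, seed);
  cohorts regenerate bit-identically, and ground truth (planted β, true
  metric values, latent scores, fully-disconnected tracts) is stored with
  every cohort.

The per-participant **direct** connectome is emulated from the atlas
tractogram by removing severed streamlines, dropping a further 20% at
random, and resampling each edge count through lognormal-Poisson noise
(sd 0.7 on the log rate) before the distance/volume correction —
probabilistic tractography's edge counts are highly variable, and without
this term direct and indirect connectomes would be implausibly similar.

For statistical calibration and power work a lighter regression-level
generator (`simulate_behavior_table`) draws lesion sizes from a clipped
lognormal and plants a candidate metric with a configurable partial R².
With `exact_orthogonal=True` the metric is residualised against the base
design in-sample and scaled to unit variance, so the planted noncentrality
`n·pr/(1−pr)` holds exactly in every replicate (at partial R² = 0.15 and
n = 50 the add-one F-test power is 0.83 analytically, ~0.82 empirically).
Scores in this table are left unclipped: it calibrates the regression
machinery, not the score distributions.

## What the synthetic validation shows — and does not

Passing tests establish that the geometry, counting, graph and regression
machinery compute their definitions correctly, that the statistical tests
are calibrated under the null, and that planted effects of known size are
recovered with the expected power. They do not establish anything about
real diffusion data: the generator has no crossing fibres, no registration
error, no atlas mismatch, no spatially correlated noise and no realistic
lesion shapes, and the direct-vs-indirect divergence it produces is driven
by an explicit noise model rather than by the physics of tractography.
Quantities that depend on those real-data properties (e.g. the typical size
of direct/indirect correlations) should not be read off the synthetic runs.

## Problem sizes

Default analyses use the 50-participant cohort on the 40×48×40 grid, with
24 parcels (14 in the ROI), 150 bundle + 260 background streamlines.
Calibration simulations use 1000-2000 null replicates and 500 planted
replicates at n = 50; sparse-CCA nulls use 100-200 replicates with 499
permutations each; small-worldness inside cohort-level tables uses 25 nulls
per network (100 when called standalone). These sizes were chosen so a full
validation run completes in a few minutes on a single core.
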