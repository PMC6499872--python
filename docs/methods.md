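# Methods

This note records the models, defaults and design choices behind
`tractoica`, and what the synthetic benchmarks do and do not demonstrate.

## Data model

The pipeline's input is a seeds × targets matrix of streamline visitation
counts: entry (s, t) is the number of streamlines, out of a fixed budget
initiated at cortical seed vertex s, that visited brain voxel t.  Group
matrices are arithmetic means over subjects, so entries may be fractional.
Internally matrices are dense float64 (the synthetic scale, ≤ ~2,000 ×
~50,000, is comfortably in memory); on disk they use a whitespace triplet
dialect (`row col value`, 0-based, `#` headers carrying shape, dialect and
streamline budget) with streaming, line-number-reporting parsing and an
explicit `one_based` flag for FSL-style 1-based files.  Voxel convention:
(i, j, k) indices, C order, first axis left–right with the mirror plane
between i = dim/2 − 1 and dim/2 (so voxel i reflects to dim − 1 − i).

## Synthetic generator

The generator emulates the *statistical* structure the decomposition
assumes, not anatomy:

* **Geometry** — two exact mirror hemispheres: left seeds uniform in the
  left half-volume, right seeds their reflections; all voxels are targets;
  seed and target mirror maps are involutions by construction.
* **Ground truth** — k planted components.  Grey maps: seeds are sorted
  along the longest in-hemisphere coordinate axis and each component gets
  a contiguous window carrying a half-sine bump; window stride is chosen
  so adjacent supports share a requested Jaccard overlap (0 ⇒ an exact
  partition, hence disjoint supports).  White maps: a jittered voxel path
  between two endpoint regions, dilated and Gaussian-smoothed — a
  connected "tract" blob.  Symmetric truths plant mirror pairs that are
  exact by construction, giving a known symmetry ceiling of r = 1.
* **Counts** — Poisson with rate c·(baseline + Σₖ aₖ·jₖ·gₖ(s)·wₖ(t)).
  Per-subject log-normal jitter jₖ (unit mean, spread `noise_scale`)
  models between-subject variability; the global scale c fixes the largest
  expected row total at `n_samples_per_seed` (each seed emits a fixed
  streamline budget, as in probtrackx-style tracking), and counts are
  clipped there.  Defaults: 10,000 samples/seed; baseline_rate = 0.01
  (visitation matrices are dominated by tract cores, with weak diffuse
  background); amplitudes drawn U(0.8, 1.2).

The standard benchmark phantom is 2 × 100 seeds on a 20 × 16 × 16 volume
(5,120 targets), 8 mirror-symmetric components with disjoint supports,
10 subjects.  Disjoint supports satisfy ICA's independence assumption, so
this benchmark tests pipeline correctness; the `overlap` parameter exists
to study degradation when components genuinely share territory (sources
become spatially correlated and unmixing quality falls — report recovery
as a function of `overlap` and `noise_scale`, not at a single value).
What passing these benchmarks does **not** show: robustness to real
tractography artefacts (distance bias, gyral bias, crossing-fibre
failures), to imperfect interhemispheric vertex correspondence, or to
non-Poisson overdispersion.

## Reduction (MIGP)

Chunks are a partition of one random permutation of all target columns
(sampling without replacement until the whole volume is covered).  Each
iteration concatenates the running U·S basis (left singular vectors
weighted by singular values — the carry that preserves second moments)
with the next chunk and truncates to the top n_pca directions.
Numerically zero directions (singular value < 10⁻¹⁰ × largest) are
dropped so rank deficiency stays visible; `effective_rank` records what
remains.  Column centering is off by default — counts are nonnegative and
the decomposition operates on raw visitation structure — and exposed as a
flag.  Full-scale defaults: chunk_size 10,000, n_pca 4,000; synthetic runs
use 512 / 30.

## ICA and back-projection

scikit-learn's FastICA (symmetric parallel updates, logcosh contrast by
default, tol 10⁻⁶, max_iter 1,000, seeded init) performs the unmixing;
whitening projects to the K requested sources, the standard fastICA
construction (a square unmixing matrix is required, so "keep all n_pca
dimensions" is not realisable in this family).  Sources are re-scaled to
exactly unit population variance with the mixing matrix scaled inversely.
Non-convergence is recorded and warned, never raised.  Sign alignment
operationalises "longest tail positive" as |max| vs |min| of each grey
column, negating grey, white and mixing columns together; it is idempotent.
Back-projection solves one joint least-squares regression of every target
voxel's seed profile onto all K unit-variance grey maps (minimum-norm with
a warning if the design is rank deficient).  Variance explained is
1 − ‖M − G Wᵀ‖²F / ‖M − column-means‖²F; it is monotone in K for nested
component sets.  K is always a required, user-fixed argument (the
full-scale convention is K = 50); no selection criterion is implemented.
The pipeline never reorders components — permutation/sign ambiguity is
resolved only in evaluation, by optimal assignment on absolute
correlations.

## Gaussian/gamma mixture

Each component map (grey and white separately — the fit report records
domain per row) is fitted to π₀·N(μ₀, σ₀²) + π₁·Γ(x − δ; shape, scale),
gamma supported above its location δ, which is constrained to δ ≥ μ₀.  δ
is a *fitted* parameter rather than being pinned to the null mean: signal
excursions sit genuinely offset from the null, and anchoring the gamma at
μ₀ forces the fit to smear the density down to the null mean,
systematically inflating the recovered shape.  EM details:

* E-step exact; M-step closed-form for weights and Gaussian, and an
  improve-only L-BFGS-B step (warm-started, bounded, ≤ 30 inner
  iterations) for the gamma triple — a generalized EM, so the observed
  log-likelihood is non-decreasing (asserted to 10⁻⁷ slack).
* Convergence uses an **absolute** log-likelihood tolerance (default
  10⁻⁶): the location creep of the gamma class makes slow-but-real
  progress that a relative criterion (scaled by |loglik| ~ 10⁴) would cut
  short at a poor local optimum.
* The likelihood is multimodal in δ, so the fit runs EM from two
  deterministic inits — gamma anchored one robust SD above the median,
  and at the 90th percentile — and keeps the mode with the higher final
  log-likelihood.  Initialization is from robust moments (median/MAD
  null, upper-tail moments for the gamma); everything is deterministic.
* A fit with π₁ < 0.05 (or a collapsed gamma class) is flagged
  `null_only`; thresholding such a fit returns an empty mask with a
  warning.  Thresholding keeps locations with posterior signal
  probability > p (default 0.5); masks shrink monotonically as p grows.

Winner-take-all uses per-row argmax with the documented lowest-index tie
rule; all-zero (or all-non-finite) rows get the sentinel −1, and rows
mixing finite with non-finite values raise (an upstream bug, not data).

## Symmetry and evaluation

Symmetry correlates whole-surface grey maps (both hemispheres jointly)
against whole-surface flipped maps; constant maps yield undefined
correlations, recorded as NaN and excluded from maxima.  Grouped means
average each group's best correlations; groupings are always user input.
In synthetic runs the mirror correspondence is exact by construction; for
real data any user-supplied vertex correspondence table is accepted.
Truth matching solves the optimal injective assignment (Hungarian) on
absolute grey-map correlations — greedy matching can misattribute
correlated components, and optimality is cheap at K ≤ 50.

## Pipeline and provenance

Per-stage seeds derive from one master seed via SHA-256 of
`"{master_seed}:{stage}"` (platform-stable, < 2³¹), so stages can be rerun
in isolation; subject i uses the subjects-stage seed plus i.  The manifest
records every config field (no silent defaults), per-stage wall time,
convergence flags and array checksums; replaying a manifest's config
reproduces all numeric artifacts bit-for-bit (verified in tests; the only
rerun-to-rerun differences are wall times).  Artifact formats: triplet
matrix text, `.npy` scores, TSV tables, NIfTI-1 volumes, GIFTI metric
files, JSON manifest.

## Numerical and testing choices

* Benchmark sizes (200 × 5,120 phantom, n = 5,000 mixture fits, ≤ 200 ×
  2,000 MIGP oracles) are the package's validation scale: large enough
  for stable statistics, small enough to run the whole suite in minutes.
* The Poisson-mean convergence check is aggregate: with ~10³ cells, ~0.3%
  legitimately exceed 3 standard errors, so the test requires ≥ 99% of
  cells within 3 SE and a standardized RMS deviation ≤ 1.2, with
  zero-rate cells exactly zero.
* MIGP–SVD equivalence is asserted via principal angles (< 10⁻⁶ below
  rank capacity); above capacity the reconstruction error must be within
  10% of the optimal truncated SVD.
* The symmetry-attenuation law r ≈ SNR²/(SNR²+1) is checked at SNR ∈
  {1, 2, 5, 10} within ±0.05 over ≥ 20 replicates.

## Known limitations

* The generator's subject-to-subject variability (log-normal amplitude
  jitter) is a stand-in; real between-subject variation also moves
  component *shapes*, not just amplitudes.
* Back-projection and variance explained operate on the group-average
  matrix only; per-subject decompositions are out of scope.
* The mixture model is two-class; maps with a genuine negative signal
  tail (rare after sign alignment) would need a negative-gamma extension.
* No out-of-core path: full-scale (≥ 10⁵-voxel) matrices must fit in
  memory, although the triplet reader streams at parse time.
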