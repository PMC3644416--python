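# Methods

This note documents the models, algorithms and numerical choices behind
`splinodule`: a three-stage pipeline — undecimated-wavelet denoising,
biorthogonal spline-wavelet compression, and multi-scale B-spline-wavelet
nodule detection — built on a from-scratch spline-wavelet core and validated
entirely on synthetic phantoms with exact ground truth.

## Spline-wavelet core

**Causal B-splines.** The degree-`n` basis function is the (n+1)-fold
convolution of the indicator of `[0, 1)`: compactly supported on `[0, n+1)`,
non-negative, unit integral, with integer shifts forming a partition of unity.
Evaluation uses the exact truncated-power formula

    phi_n(x) = 1/n! * sum_{k=0}^{n+1} (-1)^k C(n+1,k) (x-k)_+^n

(with `t_+^0 := 1{t >= 0}` so the degree-0 case is the half-open box), not
grid interpolation; this lets identities such as the two-scale relation
`phi_n(x/2) = sqrt(2) * sum_k h_n(k) phi_n(x-k)` with the binomial filter
`h_n(k) = sqrt(2) C(n+1,k)/2^(n+1)` be verified to ~1e-13.  The alternating
sum loses precision for large degrees; up to the degrees used here (n <= ~10)
the cancellation error is far below every tolerance in the test suite.

**Riesz bounds.** The frame bounds of the shifted B-splines are the extrema
over `[0, pi]` of the periodized spectral autocorrelation
`A(w) = sum_k |phihat_n(w + 2 pi k)|^2`.  By Poisson summation this equals the
finite cosine polynomial with coefficients `phi_{2n+1}(n+1+k)`, `k = -n..n`,
so the `2 pi k` sum is evaluated exactly rather than truncated; only the
frequency grid (default 1024 points) is a numerical parameter.  Known values
(`(1,1)` for the box, `(1/3, 1)` for the hat via `A(w) = (2 + cos w)/3`) are
reproduced to 1e-6 at grid size 4096.

**Filter quadruples.** All families carry explicit integer support offsets
and use the alternating-sign highpass convention `g(k) = (-1)^k htilde(1-k)`,
`gtilde(k) = (-1)^k h(1-k)`, which converts lowpass duality into full
quadruple biorthogonality.

* *Haar*: degree-0, self-dual.
* *Biorthogonal spline (CDF)*: synthesis lowpass is the binomial filter of
  the requested degree; the analysis lowpass is the shortest symmetric dual
  (length `N + 2*Ntilde - 1`, `N = degree+1`), obtained by solving the stacked
  linear system of (i) duality `sum_k h(k) htilde(k-2m) = delta_m`, (ii)
  `Ntilde` vanishing moments, (iii) DC gain `sqrt(2)` by least squares; a
  residual above 1e-9 (e.g. when `N + Ntilde` is odd, where no symmetric
  solution exists) is reported as a configuration error.  The recovered taps
  match the classical 5/3 and longer published pairs to 1e-10 (cross-checked
  against PyWavelets in the tests).
* *Semi-orthogonal B-spline*: the dual lowpass is IIR,
  `Htilde(w) = H(w) A(w)/A(2w)` with `A` the exact autocorrelation cosine
  polynomial above; taps are recovered on a 4096-point FFT grid and trimmed
  below 1e-10 of the peak.  The truncation, not arithmetic, limits the duality
  residual (~1e-10) and downstream reconstruction error (~1e-9).

Orthogonal (Battle-Lemarie) and shift-orthogonal spline families are
catalogued with their properties but are not constructible — the pipeline
never uses them.

## 2D transforms

Both transforms are separable, use correlation with the analysis filters and
convolution with the synthesis filters, and are exact inverses of each other.

**Decimated (`dwt2`/`idwt2`).** In `periodic` mode the transform is the
non-expansive bijection (odd extents are edge-padded by one sample and cropped
on inversion), so subbands halve exactly and total coefficient count equals
the pixel count.  In `symmetric`/`zero` modes the transform is expansive: a
subband keeps every coefficient whose *synthesis* filter support meets the
signal — exactly the set the inverse needs — so perfect reconstruction holds
at 1e-8 for any image size and filter length, at the cost of a constant number
of extra boundary coefficients per side and level.  The mirror extension is
sized so that every kept coefficient reads only properly extended samples,
which preserves vanishing moments (and hence constant-image annihilation) up
to the boundary.

**Undecimated (`swt2`/`iswt2`).** The a-trous scheme upsamples the filters by
`2^(level-1)`; no downsampling, every subband input-shaped.  `periodic` mode
is exactly shift-equivariant.  `symmetric` mode mirror-extends the image by
the total filter reach, runs the periodic machinery on the extended domain and
crops; the pyramid keeps the extended arrays internally so the inverse (the
standard dual-frame average, a factor 1/2 per 1D stage) is exact for every
bank, including even-length filters whose half-sample symmetry otherwise
breaks naive reflective boundary handling.

## Denoising

Stationary-transform shrinkage: decompose, shrink the detail subbands, leave
the approximation untouched, invert.  Four operators: hard, soft,
semisoft/firm (upper threshold defaulting to `2T`), and *stein*, implemented
as the nonnegative garrote `x (1 - T^2/x^2)_+` — the standard concrete reading
of "Stein thresholding" in the shrinkage literature.  All four are
non-expansive in magnitude and satisfy `|hard| >= |stein| >= |soft|` beyond
the threshold.

Threshold selection defaults to the universal threshold
`sigma * sqrt(2 ln N_pixels)` with `sigma` estimated per subband as
`median(|coefficients|)/0.6745` (`per_level` policy).  A `global` policy
instead propagates the level-1 diagonal estimate through the equivalent
a-trous filter norms, which is the white-noise-correct scaling when the noise
is known to be i.i.d.  Quality metrics are plain MSE and
`PSNR = 10 log10(max^2/MSE)` (infinite for identical inputs).

## Compression

The decimated pyramid (periodic mode, so the transform is a bijection and the
coefficient count equals the pixel count) is sparsified to a retained budget
of `floor(total/target_ratio)` coefficients: the approximation band is always
kept in full, detail coefficients are ranked by magnitude, and ties at the
cutoff break by `(level, subband, row, col)` order for bit-determinism.  The
reported "compression ratio" is the coefficient-count proxy
`total/retained` — there is no entropy coder, and byte-level ratios are out of
scope.  Because the budget uses the floor, the achieved ratio is always at
least the target.  Decompress-then-recompress with identical settings is
exactly idempotent (a consequence of the bijectivity of the periodic
transform).  An optional uniform dead-zone quantizer exists for
experimentation and is off by default.

## Detection

The paper-level idea — round lesions respond isotropically in spline-wavelet
detail subbands, at a level matching their size — is made concrete as:

1. **Response**: per level of the undecimated transform, the isotropic detail
   magnitude `sqrt(H^2 + V^2 + 2 D^2)`, normalized by the map's robust scale
   (MAD/0.6745) so one threshold works across levels.  Default 4 levels,
   covering lesion radii of roughly 2-16 px.
2. **Candidates**: 8-neighborhood local maxima above
   `response_threshold_k = 3.5` times the robust scale, merged across levels
   within the match radius.  Candidates closer than `field_margin = 8` px to
   the Otsu-segmented bright-field boundary are discarded: they are
   juxta-pleural artifacts, typically a vessel entering the field at the rim,
   whose position barely moves from slice to slice and which would otherwise
   survive the persistence rule.
3. **Segmentation**: Otsu's threshold inside a window of side `4 * 2^level`;
   the 8-connected component containing the center, holes filled.  If the
   component is clipped by the window the window is doubled (twice at most).
   Rim tapers can fuse a nodule with a nearby vessel into one component; the
   component is then bridge-cut by morphological openings of growing radius
   (2, 3, 4 px) and, failing that, split at its narrowest neck by a
   distance-transform watershed.  A region produced by a split is accepted
   only if it is not a fragment of a longer structure: it must adjoin at most
   one other bright region, or be simultaneously clearly brighter than its
   surrounding ring and strongly disc-shaped (the vessel-junction rescue).
   Masks still touching the window edge mark elongated structures and are
   rejected by default.
4. **Shape gates**: circularity `4 pi A / P^2 >= 0.6`, aspect ratio (from
   second-order moments) `<= 2.5`, solidity/convexity `>= 0.8`, area in
   `[20, 2000]` px.  Perimeter uses the diagonal-weighted boundary estimate of
   scikit-image's `regionprops`.
5. **Coherence gate**: structure-tensor coherence `(l1 - l2)/(l1 + l2)`
   averaged over the (slightly dilated) candidate mask must not exceed 0.3.
   Gradients around a round lesion point everywhere (coherence near 0); along
   a vessel they stay perpendicular to the ridge (near 1).  On phantom data
   the two populations separate by more than a factor of two, making this the
   single most effective vessel rejector.
6. **Deduplication**: candidates are recentered on their mask centroid; any
   candidate within another's equivalent radius is a duplicate of the same
   lesion and the strongest response wins.
7. **Slice persistence (stacks)**: greedy nearest-neighbor tracking across
   consecutive slices within the match radius; a track must span at least
   `min_persistence = 2` slices, and each surviving track is reported once at
   its maximum-response slice.  Nodules are 3D-compact and persist; vessels
   drift 1-3 px per slice and drop out.  The 2D-plus-persistence design is
   deliberately preferred over full 3D multi-scale filtering for speed.

All detector constants are package-defined defaults chosen on development
phantoms (seeds disjoint from the ones used in the acceptance tests) and are
overridable through `DetectionConfig`; none of them comes from published
operating characteristics, which do not exist for this pipeline.

## Synthetic phantoms

A phantom slice is: dark background (60), brighter elliptical lung field
(110) — an inverted-attenuation convention so the structures of interest are
bright — nodules as radially flat discs whose cosine-taper rim (half-width
1.5 px) crosses half contrast exactly at the nominal radius, and vessels as
curved quadratic-Bezier polylines of constant width with the same rim taper.
Overlapping structure profiles combine by maximum, not sum: distinct vessels
occupy disjoint tissue in a true axial slice, so attenuation does not add
where two drawn centerlines cross.  Gaussian noise is added last and values
clip to [0, 255].  Levels were chosen so that the default noise levels
(sigma 10-20) leave clipping negligible (worst tail below ~0.2%).

Defaults mirror the pipeline's study conditions: 256x256 slices, 3 nodules
with radii 4-12 px and contrast 40-80, 4 vessels of width 2-5 px and contrast
45, noise sigma 10.  Placement is rejection sampling (100 attempts per
structure, radius redrawn per attempt): nodules stay inside the field with a
radius-dependent margin, at least twice their radius away from every vessel
centerline, and pairwise separated; impossible layouts raise a generation
error rather than silently overlapping.  Stacks extend this with a
spherical-cap radius profile over `nodule_z_extent` consecutive slices for
each nodule, per-slice cumulative vessel drift of 1-3 px, and independent
per-slice noise.  One seeded generator drives all randomness, so a seed fixes
the output bit-for-bit.

What the phantoms do *not* emulate: Hounsfield-unit calibration, beam
hardening and reconstruction artifacts, lobar anatomy and fissures,
juxta-pleural and ground-glass nodules, bronchial walls, and the partial
volume effects of thick slices.  Passing the acceptance suite therefore shows
that the pipeline implements its stated mathematics and separates compact
from elongated structures under controlled conditions — not that it meets any
clinical operating point.

## Evaluation

Segmentation comparison implements the published manual-vs-automatic area
statistics verbatim: `M_d = |M_a - A_a|` and the percentage
`100 * M_d / (M_a + A_a)`.  Note the latter *decreases* with agreement; the
package also provides the complementary, clearly repo-defined
`area_agreement_pct = 100 - accuracy_pct` for anyone wanting a number that
grows with agreement.  Detection scoring matches detections to truth greedily
by ascending distance, one-to-one, inside a configurable radius (5 px
default); greedy matching is deterministic and permutation-invariant, and at
these object densities differs from optimal assignment only in contrived
ties.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 256x256
slices, 10-slice stacks, and 5-20 phantoms per property — sizes at which every
stage (a-trous transforms at 4 levels, per-candidate segmentation) completes
in a few seconds per slice while still exercising all code paths at the
pipeline's native slice resolution.

## Known limitations

* The semi-orthogonal dual filter is a truncated FIR approximation; duality
  holds to ~1e-10, not machine precision.
* Expansive decimated subbands are slightly larger than half the input;
  consumers that require exact halving should use periodic mode.
* The detector's vessel rejection is tuned for bright-structure phantoms; on
  real CT the field-margin heuristic (global Otsu) would need a proper lung
  segmentation.
* Vessel junctions that are compact, bright and slow-moving across slices are
  the residual false-positive mode; the persistence rule cannot remove a
  stationary artifact.
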