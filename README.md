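# splinodule

Spline-wavelet denoising, compression and lung-nodule detection for CT-like
slices and slice stacks — with a synthetic phantom generator so the whole
pipeline is testable end to end without any real CT data.

## Who this is for

Researchers and students in medical image analysis who want a small,
self-contained, fully tested reference implementation of the classic
spline-wavelet pipeline for pulmonary nodule detection: shift-invariant
wavelet shrinkage for noise removal, sparsifying wavelet compression for
storage, and multi-scale blob detection with shape-based rejection of the
vessels and bronchi that mimic nodules in size, shape and density.

## The mathematics at the core

Everything is built on the **causal B-spline** of degree *n*, the (n+1)-fold
convolution of the indicator of `[0, 1)`:

- exact evaluation via the truncated-power formula
  `phi_n(x) = 1/n! * sum_k (-1)^k C(n+1,k) (x-k)_+^n`;
- the **two-scale relation** `phi_n(x/2) = sqrt(2) * sum_k h_n(k) phi_n(x-k)`
  with the binomial filter `h_n(k) = sqrt(2) C(n+1,k) / 2^(n+1)`;
- **Riesz bounds** `0 < A_n <= B_n < inf` of the shifted splines, computed
  exactly from the sampled autocorrelation;
- three constructible **filter-bank families**: Haar, semi-orthogonal
  B-spline (FIR synthesis, truncated-IIR dual), and biorthogonal spline
  (Cohen–Daubechies–Feauveau), whose dual filters are derived by solving the
  perfect-reconstruction linear system rather than looked up;
- separable 2D **decimated** and **undecimated (a trous)** transforms with
  exact inverses (reconstruction error below 1e-8 for every shipped bank, any
  image size).

The pipeline stages:

1. **Denoise** — undecimated transform + shrinkage (hard / soft / semisoft /
   Stein-garrote), universal threshold by default; shift-invariant by
   construction.
2. **Compress** — keep the largest-magnitude coefficients of the decimated
   biorthogonal pyramid to a target coefficient-count ratio (the
   approximation band is always kept).
3. **Detect** — normalized multi-scale detail magnitude, local maxima,
   Otsu-window segmentation, shape gates (circularity, aspect ratio,
   convexity, area), a structure-tensor coherence gate, and — for stacks —
   logical-AND slice persistence that removes detections that do not recur at
   a consistent position in consecutive slices.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Generate a phantom slice (3 nodules, 4 vessels, noise sigma 10), run the full
pipeline with 10:1 compression, and score against the ground truth:

```bash
splinodule phantom --out ph --seed 7 --config spec.yaml   # spec: 256x256, 3 nodules, 4 vessels, sigma 10
splinodule pipeline --in ph/slice_0000.png --ratio 10 --out det.json
splinodule evaluate --det det.json --truth ph/truth.json --out score.json
```

The detection report lists each final nodule with its position, responding
scale, and shape features, e.g.:

```json
{
 "slice": -1, "row": 130, "col": 216, "scale_level": 2,
 "response": 7.528,
 "features": {"area": 176.0, "circularity": 1.017, "aspect_ratio": 1.014,
              "convexity": 0.962, "extent": 0.782, "...": "..."}
}
```

Here the generator seeded nodules at (176, 51), (130, 216) and (171, 77); all
three are found (the high circularity and near-unit aspect ratio are what
separate them from the vessel responses), and the score file reports:

```json
{"true_positives": 3, "false_positives": 0, "false_negatives": 0,
 "precision": 1.0, "recall": 1.0, "match_radius": 5.0}
```

The same stages are available as library functions (`denoise_image`,
`compress`/`decompress`, `detect_pipeline`, `detection_metrics`, ...) — the
CLI is a thin wrapper.

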