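# Methods

This document describes every stage of the inclination pipeline, the
parameter defaults, and the numerical design decisions.

## 1. Signal model and map extraction (`signal.py`)

A 3D-PLI measurement records one image per polariser rotation angle
`rho` (default: 18 angles, 10° apart). Per pixel,

```
I(rho) = T/2 * (1 + sin(delta) * sin(2 (rho - phi)))
```

with transmittance `T`, retardation phase `delta`, and in-plane direction
`phi`. For uniform sampling of `[0, 180)` the three maps follow exactly
from discrete Fourier analysis of harmonic orders 0 and 2:

* `T` = twice the mean intensity,
* `R = |sin delta|` = second-harmonic amplitude / mean (clipped to [0, 1]),
* `phi` = second-harmonic phase, mapped to `[0, 180)` degrees.

Pixels with zero mean intensity return `T = R = phi = 0` by convention.
On noise-free data the inversion is exact to machine precision.

## 2. Attenuation model

Tissue is modelled as two compartments along each light path: myelin of
thickness `d_m` (attenuation `mu_m`) and non-birefringent tissue filling
the remainder of a reference thickness `d_M` (attenuation `mu_c`):

```
T(d_m) = I0~ * exp(-mu_m d_m - mu_c (d_M - d_m)),   I0~ = I0 exp(-mu_c (d - d_M))
```

With `T_M = T(d_M)` and `T_c = T(0)` this gives the exact identity

```
ln(T_c / T) / ln(T_c / T_M) = d_m / d_M,
```

which is the bridge from the measured transmittance to the relative
myelin content. Any pure scaling of `T` cancels in the log ratios, so
the pipeline normalises transmittance by the image maximum only
(`scale_transmittance`); an affine min–max normalisation would destroy
the identity. (`normalise_transmittance` provides the affine variant for
display purposes.)

## 3. Median filtering (`filters.py`)

Before any histogram is taken, the scaled transmittance is smoothed with
a circular median filter (radius 5). The footprint is truncated at the
image borders — no padding values are invented. After classification the
filter is re-applied **region-masked**: each pixel's footprint only sees
pixels of its own region label, and background pixels are excluded
entirely (they pass through unchanged). This keeps HM/LM borders sharp
instead of smearing dark white matter into the cortex.

`chunked_apply` tiles any local operator over a large image with
overlapping halos (halo ≥ footprint radius) and reproduces the
whole-image result bit-for-bit; it exists purely as a memory tactic.
Global stages (histograms, bootstrap, parameter estimation) always see
the full pixel multiset.

## 4. Threshold estimation (`segmentation.py`)

Regions: **HM** (high myelination: `R > R_thres` or `T < T_thres`),
**LM** (low myelination: `R ≤ R_thres` and `T_thres ≤ T ≤ T_back`),
**BG** (background: `R ≤ R_thres` and `T > T_back`).

All thresholds are read from histograms as **points of maximum
curvature** of the count polyline,

```
kappa = y'' / (1 + y'^2)^(3/2),
```

with counts rescaled to [0, 1] *within the search window* (so a dominant
peak outside the window cannot flatten the elbow inside it) and the
signed maximum taken (an elbow seen from above is convex; a peak top is
concave).

* `R_thres`: a 64-bin histogram locates the dominant retardation peak
  and its FWHM; the maximum-curvature point is searched within
  `20 × FWHM` *behind* the peak, then refined at 128 and 256 bins within
  the window `[2 (b − 1), 2 (b + 1)]` of the previous result. The final
  value is the 256-bin centre.
* `T_back`: same cascade on the transmittance histogram, searching
  `10 × FWHM` *before* the (background) peak.
* `T_ref`: the mean filtered transmittance over the connected region of
  highest retardation covering 0.009–0.011 % of the image (binary search
  on a retardation cut-off; 8-connected components). This region is the
  densest in-plane fibre bundle; its transmittance estimates `T_M`.
* `T_thres`: the maximum-curvature point of the 256-bin transmittance
  histogram restricted to `(T_ref, T_back)` — the foot of the
  white-matter transmittance peak.

Threshold estimation runs in two passes: a preliminary pass locates
`R_thres` and `T_back` on the raw histograms, background pixels are then
collapsed onto the histogram extremes (`mask_background_for_histograms`),
and the final thresholds are read from the masked histograms. All
subsequent resampling draws from exactly that masked pixel multiset.

## 5. Transition-width bootstrap (`bootstrap.py`)

The thresholds are histogram statistics, so they carry sampling
uncertainty. Per bootstrap iteration, `ceil(f · n)` pixels (default
`f = 0.25`) are drawn with replacement — one joint index stream for both
maps — and the thresholds are recomputed: `R_thres` with the full
64 → 128 → 256 cascade, `T_thres` as the restricted curvature search
between the *full-sample* `T_ref` and `T_back` (these anchors are
spatial quantities and are held fixed on resamples). After `n = 200`
iterations, the mean of the resampled values **above** the full-sample
threshold is the positive mean `R_thres+` (likewise `R_thres−`,
`T_thres±`), and the distances `w± = |R_thres± − R_thres|` are the
transition-zone widths. A side with no resampled values defaults to the
original threshold — a zero width on that side. The defaults (200
iterations, 25 % sample) come from the convergence criterion that the
running means move by less than one 256-bin width (0.0039) between
iterations 200 and 500; `convergence_trace` reproduces that study.

The whole procedure is deterministic for a fixed seed (one seeded
generator; spawned sub-streams per repeat in the trace).

## 6. HM-probability map (`probability.py`)

Deviations from the threshold point are scaled by the one-sided widths,

```
dR = (R - R_thres) / w,   w = w+ if R > R_thres else w-,
```

(analogously `dT`), and blended into a probability by a directional
error-function sigmoid:

```
P_HM = 0.5 - 0.5 * erf( cos(3 pi/4 - atan2(dT, dR)) * sqrt(dR^2 + dT^2) )
```

The direction term selects the HM corner (high `R`, low `T` → `P → 1`)
against the LM corner (`P → 0`); at the threshold point `P = 0.5`
exactly. Pixels with `P > 0.95` count as HM, `P < 0.05` as LM, the band
in between as transition zone. Background pixels carry `P = 0`.

**Zero-width semantics.** If a side has zero width, a deviation to that
side is infinite; it is represented by a large saturation constant and
the pixel short-circuits to the hard binary rule
`P = 1 iff (dR > 0 or dT < 0)`, with no numeric overflow. This makes the
probability map converge pointwise to the binary classification as all
widths go to zero (in which case the combined model reduces exactly to
the hard-split model). Feeding the saturated value through the angle
formula instead would let a collapsed axis override the other one and
contradict that limit.

At finite widths the 0.5-contour of the sigmoid is the diagonal
`dT = dR`, so pixels deviating into the same corner on both axes can
differ from the binary OR rule; agreement is exact for axis-pure
deviations.

## 7. Model-parameter estimation (`inclination.py`)

On the region-masked filtered transmittance:

* `R_ref,LM`: maximum-curvature elbow (full cascade) of the retardation
  histogram over LM pixels (`P < 0.05`, tissue only).
* `R_ref,HM`: mean of the top 10 % retardation values inside the
  connected highest-retardation region of the HM pixels (`P ≥ 0.95`),
  sized 0.009–0.011 % of the HM area.
* `T_M`: mean transmittance of that same reference region.
* `T_c`: the 256-bin mode of the LM transmittance values.

The label map restricts both LM references to tissue — background
carries `P = 0` by definition and would otherwise flood the LM
histograms. Before the weighted model is applied, the transmittance is
clipped from below to `T_M`: steep fibres scatter more light and appear
darker than in-plane fibres of equal myelin content, and the clip
prevents the weight from over-correcting them.

## 8. Inclination models

* **Unweighted**: `alpha = arccos( sqrt( arcsin R / arcsin R_ref ) )`,
  with the ratio clamped to [0, 1] (`R > R_ref` saturates to 0°,
  flagged).
* **Weighted**: multiplies the ratio by `ln(T_c/T_M) / ln(T_c/T)`
  (= `d_M / d_m` under the attenuation model), correcting for myelin
  content; uses `R_ref,HM`. Pixels with `T ≥ T_c` (no detectable myelin
  attenuation; the weight diverges) fall back to the unweighted formula
  and are flagged.
* **Combined**: `alpha = P · alpha_HM + (1 − P) · alpha_LM`, where
  `alpha_HM` is the weighted model and `alpha_LM` the unweighted model
  with the interpolated reference
  `R_ref* = P · R_ref,HM + (1 − P) · R_ref,LM`.

Four scenarios for comparison: (i) unweighted with one section-wide
reference (the mean of the top 10 % retardations of the global reference
region) — over-estimates LM inclinations; (ii) weighted everywhere;
(iii) hard HM/LM split; (iv) the combined model (default). Background is
NaN in every scenario.

## 9. Phantom design (`phantom.py`)

The generator builds a brain-like layout — steep-fibre band (alpha
45–68°), dense in-plane band with a radial gradient (the reference
region), a fan where myelin thins towards the cortex (planted transition
zone), heterogeneous cortex with fibre-bundle blobs, and a background
margin — and evaluates the forward models per pixel. Default optics:
`lambda = 550 nm`, section 60 µm, `d_M = 10 µm`, `dn = lambda/(4 d_M)`
(so `delta ≤ pi/2` and the retardation is invertible),
`mu_m = 0.0907 /µm`, `mu_c = 0.00594 /µm` → `T_M ≈ 0.30`, `T_c ≈ 0.70`.

The estimators assume specific histogram shapes, and the layout plants
them with explicit margins:

* the background margin (~7 % of the minimum dimension) makes the BG
  spike the biggest 64-bin transmittance peak (anchor for `T_back`);
* the steep band's narrow thickness spread forms a tall transmittance
  lump just above `T_M` whose upper foot is the sharpest bend between
  `T_ref` and `T_back` (that foot is `T_thres`);
* ~13 % of the cortex consists of contiguous, exactly unmyelinated
  patches (wide enough to survive the median filter), putting the mode
  of the LM transmittance exactly at `T_c` without out-curving the HM
  foot (an isolated histogram atom of count `A` in a window with maximum
  `M` contributes curvature ≈ `A/(4M)` through its neighbours);
* cortex myelin thickness and inclination are coupled
  (`cos^2 alpha = f · min(1, d_LM/d_m)`), capping the cortex retardation
  well below the white-matter range and leaving a sharp, data-rich elbow
  for `R_thres` and `R_ref,LM`.

On the noise-free default phantom the histograms are so data-rich that
every bootstrap resample reproduces the elbows bit-exactly: all four
transition widths are zero and the probability map is binary (the
degenerate limit of §6). The finite-width sigmoid path is exercised by
the unit tests with synthetic widths and by noisy phantoms
(`noise_sigma > 0` adds Gaussian noise to the rotation series).

## 10. Defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| median radius | 5 px | circular median filter footprint |
| bootstrap fraction | 0.25 | resample size as a fraction of tissue pixels |
| bootstrap iterations | 200 | fixed by the convergence criterion |
| probability band | (0.05, 0.95) | LM / transition / HM partition of `P_HM` |
| reference-region size | 0.009–0.011 % | of the eligible pixels |
| histogram bins | 64 → 128 → 256 | refinement cascade |
| scenario | iv | combined model |
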