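"""Histogram-based estimation of the myelination thresholds and the HM/LM/BG labels.

Brain sections imaged with 3D-PLI separate into regions of high myelination
(HM: high retardation and/or low transmittance), low myelination (LM) and
background (BG: very high transmittance, no tissue).  The separating
thresholds are read off the retardation and transmittance histograms as
points of maximum curvature next to the dominant peaks, refined through a
64 -> 128 -> 256 bin cascade, and anchored by the mean transmittance of the
small connected region with the highest retardation (densely packed
in-plane fibres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signal import PLIMaps

__all__ = [
    "BG",
    "LM",
    "HM",
    "ThresholdSet",
    "RegionLabelMap",
    "normalise_transmittance",
    "scale_transmittance",
    "mask_background_for_histograms",
    "max_curvature_point",
    "histogram_peak_fwhm",
    "refine_threshold",
    "find_reference_region",
    "estimate_thresholds",
    "classify_regions",
]

# Label codes (also the values written to the 8-bit label TIFF).
BG: int = 0
LM: int = 1
HM: int = 2

#: 8-connectivity structuring element used for all connected-component work.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdSet:
    """The four threshold parameters of the HM/LM/BG classification.

    ``r_thres`` splits the retardation histogram behind its dominant peak,
    ``t_back`` separates tissue from background in the transmittance
    histogram, ``t_ref`` is the mean transmittance of the densest in-plane
    fibre region, and ``t_thres`` the maximum-curvature point between
    ``t_ref`` and ``t_back``.
    """

    r_thres: float
    t_thres: float
    t_back: float
    t_ref: float

    def __post_init__(self) -> None:
        if not (0 < self.r_thres < 1):
            raise ValueError("r_thres must lie in (0, 1)")
        if not (0 < self.t_thres < 1):
            raise ValueError("t_thres must lie in (0, 1)")
        if not (0 < self.t_back <= 1):
            raise ValueError("t_back must lie in (0, 1]")
        if self.t_thres > self.t_back:
            raise ValueError("t_thres must not exceed t_back")
        if self.t_ref > self.t_back:
            raise ValueError("t_ref must not exceed t_back")


@dataclass
class RegionLabelMap:
    """Per-pixel HM/LM/BG labels (values ``HM``, ``LM``, ``BG``)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (BG, LM, HM)).all():
            raise ValueError("labels must be one of BG, LM, HM")


def normalise_transmittance(t_raw: np.ndarray) -> np.ndarray:
    """Affine rescaling of a transmittance raster so min -> 0 and max -> 1."""
    t_raw = np.asarray(t_raw, dtype=float)
    if not np.all(np.isfinite(t_raw)) or np.any(t_raw < 0):
        raise ValueError("transmittance must be finite and non-negative")
    lo, hi = t_raw.min(), t_raw.max()
    if hi == lo:
        raise ValueError("constant transmittance image: normalisation undefined")
    return (t_raw - lo) / (hi - lo)


def scale_transmittance(t_raw: np.ndarray) -> np.ndarray:
    """Scale a transmittance raster by its maximum so values lie in [0, 1].

    The pipeline uses this pure scaling (rather than an affine min-max map)
    because an additive offset would not cancel in the Lambert-Beer log
    ratios ln(T_c/T) that the transmittance-weighted inclination model is
    built on, whereas a common scale factor cancels exactly.
    """
    t_raw = np.asarray(t_raw, dtype=float)
    if not np.all(np.isfinite(t_raw)) or np.any(t_raw < 0):
        raise ValueError("transmittance must be finite and non-negative")
    hi = t_raw.max()
    if hi <= 0:
        raise ValueError("transmittance image has no positive values")
    return t_raw / hi


def mask_background_for_histograms(
    maps: PLIMaps, t_back: float, r_thres: float
) -> PLIMaps:
    """Collapse background pixels before histogram analysis.

    Pixels satisfying the BG rule (R <= r_thres and T > t_back) are set to
    the image-minimum retardation and image-maximum transmittance so they
    cannot distort the peaks that the tissue thresholds are read from.
    """
    out = maps.copy()
    bg = (out.retardation <= r_thres) & (out.transmittance > t_back)
    if bg.any():
        out.retardation[bg] = maps.retardation.min()
        out.transmittance[bg] = maps.transmittance.max()
    return out


def _curvature(counts: np.ndarray) -> np.ndarray:
    """Discrete plane-curve curvature of the normalised count polyline.

    Counts are rescaled to [0, 1] and treated as ordinates on a unit-spaced
    bin grid; derivatives are central finite differences (one-sided at the
    array ends).
    """
    y = np.asarray(counts, dtype=float)
    lo, hi = y.min(), y.max()
    if hi > lo:
        y = (y - lo) / (hi - lo)
    else:
        y = np.zeros_like(y)
    d1 = np.gradient(y)
    d2 = np.gradient(d1)
    return d2 / (1.0 + d1**2) ** 1.5


def max_curvature_point(
    counts: np.ndarray, search_range: tuple[int, int]
) -> int:
    """Bin index of maximum curvature within ``search_range`` (inclusive).

    The curvature is evaluated on the count polyline restricted to the
    search window (normalised within it), so a dominant peak outside the
    window cannot mask the elbow structure inside it -- next to a
    near-delta background or reference peak the relevant bend is in the
    tail, not at the peak's own foot.  Ties are broken towards the lower
    bin index.
    """
    counts = np.asarray(counts, dtype=float)
    lo, hi = int(search_range[0]), int(search_range[1])
    lo = max(lo, 0)
    hi = min(hi, counts.size - 1)
    if hi - lo + 1 < 3:
        raise ValueError("search range must span at least 3 bins")
    kappa = _curvature(counts[lo : hi + 1])
    return lo + int(np.argmax(kappa))  # argmax returns the first maximum


def histogram_peak_fwhm(counts: np.ndarray) -> tuple[int, float]:
    """Locate the biggest histogram peak and its FWHM in bin units.

    The peak is the bin with the globally maximal count; the full width at
    half maximum is measured by linear interpolation of the half-maximum
    crossings of the count polyline, clipped at the histogram ends.
    """
    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0

    left = 0.0
    for i in range(peak, 0, -1):
        if counts[i - 1] < half:
            # linear interpolation between bins i-1 and i
            frac = (half - counts[i - 1]) / (counts[i] - counts[i - 1])
            left = (i - 1) + frac
            break
    else:
        left = 0.0

    right = float(counts.size - 1)
    for i in range(peak, counts.size - 1):
        if counts[i + 1] < half:
            frac = (counts[i] - half) / (counts[i] - counts[i + 1])
            right = i + frac
            break
    else:
        right = float(counts.size - 1)

    return peak, max(right - left, 1.0)


def _clamp_window(lo: int, hi: int, nbins: int) -> tuple[int, int]:
    """Clip a bin window to the histogram and widen it to >= 3 bins."""
    lo = max(int(lo), 0)
    hi = min(int(hi), nbins - 1)
    while hi - lo + 1 < 3:
        if lo > 0:
            lo -= 1
        elif hi < nbins - 1:
            hi += 1
        else:
            raise ValueError("histogram too small for curvature analysis")
    return lo, hi


def _threshold_at_resolution(
    values: np.ndarray, nbins: int, peak_side: str, window: tuple[int, int] | None
) -> int:
    """One resolution step of the refinement cascade; returns a bin index."""
    counts, _ = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")
    if window is None:
        peak, fwhm = histogram_peak_fwhm(counts)
        if peak_side == "behind_retardation_peak":
            lo, hi = peak + 1, peak + int(round(20.0 * fwhm))
        elif peak_side == "before_transmittance_peak":
            lo, hi = peak - int(round(10.0 * fwhm)), peak - 1
        else:
            raise ValueError(f"unknown peak_side {peak_side!r}")
    else:
        lo, hi = window
    lo, hi = _clamp_window(lo, hi, nbins)
    return max_curvature_point(counts, (lo, hi))


def refine_threshold(values: np.ndarray, peak_side: str) -> float:
    """Multi-resolution maximum-curvature threshold of a [0, 1] sample.

    A 64-bin histogram locates the biggest peak and searches for the point
    of maximum curvature within 20 x FWHM behind it (retardation) or
    10 x FWHM before it (transmittance); the search is then repeated at 128
    and 256 bins within the window [2*(result - 1), 2*(result + 1)] of the
    previous result.  Returns the bin-centre value at 256-bin resolution.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    b64 = _threshold_at_resolution(values, 64, peak_side, None)
    b128 = _threshold_at_resolution(
        values, 128, peak_side, (2 * (b64 - 1), 2 * (b64 + 1))
    )
    b256 = _threshold_at_resolution(
        values, 256, peak_side, (2 * (b128 - 1), 2 * (b128 + 1))
    )
    return (b256 + 0.5) / 256.0


def restricted_curvature_threshold(
    values: np.ndarray, lower: float, upper: float, nbins: int = 256
) -> float:
    """Maximum-curvature point of a histogram restricted to (lower, upper).

    Used for T_thres, which lives between T_ref and T_back.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    centres = 0.5 * (edges[:-1] + edges[1:])
    inside = np.nonzero((centres > lower) & (centres < upper))[0]
    if inside.size < 3:
        raise ValueError(
            f"fewer than 3 histogram bins between {lower:.4f} and {upper:.4f}"
        )
    idx = max_curvature_point(counts, (int(inside[0]), int(inside[-1])))
    return float(centres[idx])


def find_reference_region(
    retardation: np.ndarray,
    valid_mask: np.ndarray | None = None,
    target_fraction_range: tuple[float, float] = (0.00009, 0.00011),
    max_iterations: int = 64,
) -> np.ndarray:
    """Connected set of highest-retardation pixels of a prescribed size.

    Binary search on a retardation cut-off: pixels above the cut-off (within
    ``valid_mask``) are labelled into 8-connected components and the
    component with the highest mean retardation is kept.  The cut-off is
    adjusted until the component covers a fraction of the eligible pixels
    inside ``target_fraction_range`` (default 0.009-0.011 %).  If no cut-off
    reaches the window (tiny images), the smallest component found above the
    window is returned with a warning.

    Returns a boolean mask of the selected pixels.
    """
    retardation = np.asarray(retardation, dtype=float)
    if valid_mask is None:
        valid_mask = np.ones_like(retardation, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n_eligible = int(valid_mask.sum())
    if n_eligible == 0:
        raise ValueError("no eligible pixels for the reference region")

    vals = retardation[valid_mask]
    lo_cut, hi_cut = float(vals.min()), float(vals.max())
    frac_lo, frac_hi = target_fraction_range

    def component_at(cut: float) -> tuple[np.ndarray | None, float]:
        above = valid_mask & (retardation > cut)
        if not above.any():
            return None, 0.0
        lab, n = ndimage.label(above, structure=_STRUCT8)
        if n == 0:
            return None, 0.0
        means = ndimage.mean(retardation, lab, index=np.arange(1, n + 1))
        best = int(np.argmax(means)) + 1
        comp = lab == best
        return comp, comp.sum() / n_eligible

    best_above: tuple[np.ndarray, float] | None = None
    lo, hi = lo_cut, hi_cut
    for _ in range(max_iterations):
        cut = 0.5 * (lo + hi)
        comp, frac = component_at(cut)
        if comp is None or frac < frac_lo:
            hi = cut  # component too small (or empty): lower the cut-off
            continue
        if frac > frac_hi:
            if best_above is None or frac < best_above[1]:
                best_above = (comp, frac)
            lo = cut  # component too big: raise the cut-off
            continue
        return comp

    if best_above is not None:
        warnings.warn(
            "no retardation cut-off yields a component inside the target size "
            f"window; falling back to the smallest component above it "
            f"(fraction {best_above[1]:.2e})",
            stacklevel=2,
        )
        return best_above[0]
    raise ValueError("could not locate a reference region above the size window")


def estimate_thresholds(
    maps: PLIMaps, return_masked: bool = False
) -> ThresholdSet | tuple[ThresholdSet, PLIMaps]:
    """Estimate (R_thres, T_thres, T_back, T_ref) from normalised maps.

    Expects the transmittance already normalised to [0, 1] and median
    filtered.  A preliminary pass locates R_thres and T_back so the
    background can be collapsed (``mask_background_for_histograms``); the
    final thresholds are then read from the masked histograms.

    With ``return_masked`` the background-collapsed maps are returned as
    well, so resampling procedures (the transition-width bootstrap) can
    draw from exactly the pixel multiset the thresholds were read from.
    """
    r = maps.retardation.ravel()
    t = maps.transmittance.ravel()
    if t.min() < 0 or t.max() > 1:
        raise ValueError("transmittance must be normalised to [0, 1]")

    # Pass 1 (raw maps): preliminary thresholds for the BG rule.
    r_thres0 = refine_threshold(r, "behind_retardation_peak")
    t_back0 = refine_threshold(t, "before_transmittance_peak")

    masked = mask_background_for_histograms(maps, t_back=t_back0, r_thres=r_thres0)
    rm = masked.retardation.ravel()
    tm = masked.transmittance.ravel()

    # Pass 2 (background collapsed): final histogram thresholds.
    r_thres = refine_threshold(rm, "behind_retardation_peak")
    t_back = refine_threshold(tm, "before_transmittance_peak")

    # T_ref: mean (median-filtered) transmittance over the connected region
    # with the highest retardation values, searched on the raw retardation.
    ref_region = find_reference_region(maps.retardation)
    t_ref = float(maps.transmittance[ref_region].mean())
    if t_ref >= t_back:
        raise ValueError(
            "reference transmittance is not below the background threshold; "
            "the histograms lack a broad variety of tissue components"
        )

    t_thres = restricted_curvature_threshold(tm, t_ref, t_back)
    thresholds = ThresholdSet(
        r_thres=r_thres, t_thres=t_thres, t_back=t_back, t_ref=t_ref
    )
    if return_masked:
        return thresholds, masked
    return thresholds


def classify_regions(maps: PLIMaps, thresholds: ThresholdSet) -> RegionLabelMap:
    """Binary HM/LM/BG classification from the threshold parameters.

    HM: (R > R_thres) or (T < T_thres);
    LM: (R <= R_thres) and (T_thres <= T <= T_back);
    BG: (R <= R_thres) and (T > T_back).
    """
    r, t = maps.retardation, maps.transmittance
    labels = np.full(maps.shape, LM, dtype=np.uint8)
    hm = (r > thresholds.r_thres) | (t < thresholds.t_thres)
    bg = ~hm & (t > thresholds.t_back)
    labels[hm] = HM
    labels[bg] = BG
    return RegionLabelMap(labels)
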