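"""Unit tests for histogram thresholding and the HM/LM/BG classification."""

import numpy as np
import pytest

from pli_incline import (
    BG,
    HM,
    LM,
    PLIMaps,
    ThresholdSet,
    classify_regions,
    find_reference_region,
    mask_background_for_histograms,
    max_curvature_point,
    normalise_transmittance,
    refine_threshold,
    scale_transmittance,
)
from pli_incline.segmentation import (
    estimate_thresholds,
    histogram_peak_fwhm,
    restricted_curvature_threshold,
)


def test_normalise_transmittance_affine():
    t = np.array([[2.0, 4.0], [6.0, 10.0]])
    out = normalise_transmittance(t)
    assert out.min() == 0.0 and out.max() == 1.0
    np.testing.assert_allclose(out, (t - 2.0) / 8.0)
    with pytest.raises(ValueError):
        normalise_transmittance(np.full((2, 2), 3.0))  # constant image


def test_scale_transmittance_preserves_log_ratios():
    t = np.array([[0.3, 0.6], [0.9, 1.2]])
    out = scale_transmittance(t)
    assert out.max() == 1.0
    # A pure scale cancels in every Lambert-Beer log ratio.
    np.testing.assert_allclose(
        np.log(out[0, 1] / out[0, 0]), np.log(t[0, 1] / t[0, 0]), rtol=1e-12
    )
    with pytest.raises(ValueError):
        scale_transmittance(np.zeros((2, 2)))


def test_max_curvature_point_finds_elbow():
    # A polyline with a sharp bend: steep drop then flat tail.
    counts = np.concatenate([np.linspace(100, 10, 10), np.full(30, 10.0)])
    idx = max_curvature_point(counts, (0, counts.size - 1))
    assert 8 <= idx <= 11  # the elbow where the drop meets the tail
    with pytest.raises(ValueError):
        max_curvature_point(counts, (5, 6))  # window too narrow


def test_max_curvature_point_window_local_normalisation():
    # A huge peak outside the window must not flatten the elbow inside it.
    counts = np.concatenate(
        [np.array([1e6]), np.linspace(100, 10, 10), np.full(20, 10.0)]
    )
    idx = max_curvature_point(counts, (1, counts.size - 1))
    assert 9 <= idx <= 12


def test_histogram_peak_fwhm_triangle():
    counts = np.array([0.0, 2.0, 4.0, 8.0, 4.0, 2.0, 0.0])
    peak, fwhm = histogram_peak_fwhm(counts)
    assert peak == 3
    assert fwhm == pytest.approx(2.0)  # half-max crossings at bins 2 and 4


def test_refine_threshold_bimodal(rng):
    # Dominant low peak with a sparse high tail: the elbow sits at the
    # upper edge of the low population.
    low = rng.beta(2.0, 8.0, 200_000) * 0.3
    high = rng.uniform(0.6, 0.9, 2_000)
    thr = refine_threshold(np.concatenate([low, high]), "behind_retardation_peak")
    assert 0.1 < thr < 0.45


def test_restricted_curvature_threshold_window():
    vals = np.concatenate([np.full(1000, 0.31), np.linspace(0.3, 0.5, 5000)])
    thr = restricted_curvature_threshold(vals, 0.30, 0.50)
    assert 0.30 < thr < 0.50
    with pytest.raises(ValueError):
        restricted_curvature_threshold(vals, 0.300, 0.305)  # < 3 bins inside


def test_find_reference_region_hotspot(rng):
    r = rng.uniform(0.0, 0.3, (256, 256))
    r[100:108, 50:58] = np.linspace(0.9, 1.0, 64).reshape(8, 8)  # planted hotspot
    region = find_reference_region(r, target_fraction_range=(0.00005, 0.0002))
    ys, xs = np.nonzero(region)
    assert region.sum() > 0
    assert ys.min() >= 100 and ys.max() < 108 and xs.min() >= 50 and xs.max() < 58


def test_mask_background_collapses_bg_pixels():
    t = np.array([[0.95, 0.5], [0.3, 0.99]])
    r = np.array([[0.01, 0.6], [0.02, 0.05]])
    maps = PLIMaps(t, np.zeros_like(t), r)
    masked = mask_background_for_histograms(maps, t_back=0.9, r_thres=0.1)
    # BG pixels (low R, high T) collapse onto the histogram extremes.
    assert masked.retardation[0, 0] == r.min()
    assert masked.transmittance[0, 0] == t.max()
    assert masked.transmittance[1, 1] == t.max()
    # Tissue pixels are untouched.
    assert masked.retardation[0, 1] == 0.6
    assert masked.transmittance[1, 0] == 0.3


def test_classify_regions_rules():
    thresholds = ThresholdSet(r_thres=0.1, t_thres=0.3, t_back=0.8, t_ref=0.25)
    r = np.array([[0.2, 0.05, 0.05, 0.05]])
    t = np.array([[0.9, 0.2, 0.5, 0.9]])
    labels = classify_regions(PLIMaps(t, np.zeros_like(t), r), thresholds).labels
    assert labels[0, 0] == HM  # high R wins even at background-like T
    assert labels[0, 1] == HM  # low T
    assert labels[0, 2] == LM
    assert labels[0, 3] == BG


def test_threshold_set_validation():
    with pytest.raises(ValueError):
        ThresholdSet(r_thres=0.0, t_thres=0.3, t_back=0.8, t_ref=0.25)
    with pytest.raises(ValueError):
        ThresholdSet(r_thres=0.1, t_thres=0.9, t_back=0.8, t_ref=0.25)
    with pytest.raises(ValueError):
        ThresholdSet(r_thres=0.1, t_thres=0.3, t_back=0.8, t_ref=0.85)


def test_estimate_thresholds_on_phantom(default_phantom):
    from pli_incline.filters import median_filter_disk

    t = median_filter_disk(scale_transmittance(default_phantom.maps.transmittance))
    maps = PLIMaps(t, default_phantom.maps.direction, default_phantom.maps.retardation)
    thresholds, masked = estimate_thresholds(maps, return_masked=True)
    # The ordering the classification relies on.
    assert 0.0 < thresholds.r_thres < 0.5
    assert thresholds.t_ref < thresholds.t_thres < thresholds.t_back
    # The cortex retardation cap lies below r_thres; white matter above it.
    spec = default_phantom.spec
    r_cap = np.sin(spec.delta_max * 0.88 * spec.lm_thickness_fraction)
    assert thresholds.r_thres >= r_cap
    # The masked maps collapse the background onto the extremes.
    bg = default_phantom.labels_truth == BG
    assert np.all(masked.transmittance[bg] == masked.transmittance.max())


def test_estimate_thresholds_rejects_unnormalised():
    t = np.full((8, 8), 2.0)
    maps = PLIMaps(t, np.zeros_like(t), np.zeros_like(t))
    with pytest.raises(ValueError):
        estimate_thresholds(maps)
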