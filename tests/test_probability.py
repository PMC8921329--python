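"""Unit tests for the HM-probability map."""

import numpy as np
import pytest

from pli_incline import (
    BG,
    PLIMaps,
    ThresholdSet,
    TransitionWidths,
    classify_regions,
    compute_pmap,
    probability,
    scaled_deviations,
)

THRESHOLDS = ThresholdSet(r_thres=0.1, t_thres=0.3, t_back=0.8, t_ref=0.25)
WIDTHS = TransitionWidths(
    r_plus=0.12, r_minus=0.08, t_plus=0.33, t_minus=0.27,
    n_iterations=200, sample_fraction=0.25,
)


def test_scaled_deviations_signs_and_scale():
    r = np.array([0.12, 0.08, 0.1])
    t = np.array([0.33, 0.27, 0.3])
    dr, dt = scaled_deviations(r, t, THRESHOLDS, WIDTHS)
    np.testing.assert_allclose(dr, [1.0, -1.0, 0.0])
    np.testing.assert_allclose(dt, [1.0, -1.0, 0.0])


def test_scaled_deviations_rejects_non_bracketing():
    bad = TransitionWidths(
        r_plus=0.09, r_minus=0.08, t_plus=0.33, t_minus=0.27,
        n_iterations=1, sample_fraction=0.25,
    )  # r_plus below r_thres
    with pytest.raises(ValueError):
        scaled_deviations(np.array([0.1]), np.array([0.3]), THRESHOLDS, bad)


def test_probability_limits_and_monotonicity():
    assert probability(np.array(0.0), np.array(0.0)) == pytest.approx(0.5)
    # Deep in the HM corner (high R, low T) the probability approaches 1.
    assert probability(np.array(8.0), np.array(-8.0)) > 0.999
    # Deep in the LM corner it approaches 0.
    assert probability(np.array(-8.0), np.array(8.0)) < 0.001
    # Monotone increasing along the R axis.
    dr = np.linspace(-4.0, 4.0, 41)
    p = probability(dr, np.zeros_like(dr))
    assert np.all(np.diff(p) > 0)
    # Monotone decreasing along the T axis.
    dt = np.linspace(-4.0, 4.0, 41)
    p = probability(np.zeros_like(dt), dt)
    assert np.all(np.diff(p) < 0)


def test_zero_width_side_hard_binary():
    """A collapsed transition side assigns the hard binary classification."""
    zero = TransitionWidths(
        r_plus=THRESHOLDS.r_thres, r_minus=THRESHOLDS.r_thres,
        t_plus=0.33, t_minus=0.27, n_iterations=1, sample_fraction=0.25,
    )
    # R above threshold with zero R-width -> hard HM, regardless of a small
    # T deviation to the LM side.
    r = np.array([0.2, 0.05])
    t = np.array([0.31, 0.31])
    dr, dt = scaled_deviations(r, t, THRESHOLDS, zero)
    p = probability(dr, dt)
    assert p[0] == 1.0
    # R below threshold: the saturated axis alone does not force HM; the
    # binary OR rule decides (T above T_thres -> LM).
    assert p[1] == 0.0


def test_all_widths_zero_matches_binary_classification(rng):
    """As all widths -> 0 the map converges pointwise to classify_regions."""
    degenerate = TransitionWidths(
        r_plus=THRESHOLDS.r_thres, r_minus=THRESHOLDS.r_thres,
        t_plus=THRESHOLDS.t_thres, t_minus=THRESHOLDS.t_thres,
        n_iterations=1, sample_fraction=0.25,
    )
    r = rng.uniform(0.0, 1.0, (40, 40))
    t = rng.uniform(0.0, 0.8, (40, 40))  # keep off the BG branch
    maps = PLIMaps(t, np.zeros_like(t), r)
    pmap = compute_pmap(maps, THRESHOLDS, degenerate)
    binary = classify_regions(maps, THRESHOLDS).labels
    assert set(np.unique(pmap.p_hm)) <= {0.0, 1.0}
    from pli_incline import HM
    assert np.array_equal(pmap.p_hm == 1.0, binary == HM)


def test_compute_pmap_background_zero():
    r = np.array([[0.05, 0.5]])
    t = np.array([[0.95, 0.3]])
    maps = PLIMaps(t, np.zeros_like(t), r)
    pmap = compute_pmap(maps, THRESHOLDS, WIDTHS)
    assert pmap.p_hm[0, 0] == 0.0  # background pixel
    assert pmap.p_hm[0, 1] > 0.95


def test_pmap_masks_partition():
    r = np.array([[0.05, 0.101, 0.5]])
    t = np.array([[0.5, 0.299, 0.2]])
    maps = PLIMaps(t, np.zeros_like(t), r)
    pmap = compute_pmap(maps, THRESHOLDS, WIDTHS)
    union = pmap.hm_mask | pmap.lm_mask | pmap.transition_mask
    assert union.all()
    assert not (pmap.hm_mask & pmap.lm_mask).any()
    assert pmap.transition_mask[0, 1]  # just past both thresholds
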