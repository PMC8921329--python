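"""Unit tests for the synthetic phantom generator."""

import numpy as np
import pytest

from pli_incline import (
    BG,
    HM,
    LM,
    PhantomSpec,
    extract_maps,
    forward_retardation,
    forward_series,
    forward_transmittance,
    generate_phantom,
)
from pli_incline.phantom import TRANSITION


def test_spec_optical_defaults():
    spec = PhantomSpec()
    assert spec.delta_max == pytest.approx(np.pi / 2)
    assert spec.t_myelin == pytest.approx(0.29999, abs=1e-4)
    assert spec.t_cell == pytest.approx(0.70019, abs=1e-4)
    assert spec.t_myelin < spec.t_cell < spec.i0_tilde <= 1.0


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(mu_myelin=0.001, mu_cell=0.01)
    with pytest.raises(ValueError):
        PhantomSpec(d_max_um=100.0, section_thickness_um=60.0)
    with pytest.raises(ValueError):
        PhantomSpec(shape=(16, 16), border=10)
    with pytest.raises(ValueError):
        PhantomSpec(lm_thickness_fraction=1.5)


def test_deterministic_for_seed():
    a = generate_phantom(PhantomSpec(shape=(96, 96), seed=7))
    b = generate_phantom(PhantomSpec(shape=(96, 96), seed=7))
    assert np.array_equal(a.maps.retardation, b.maps.retardation)
    assert np.array_equal(a.maps.transmittance, b.maps.transmittance)
    c = generate_phantom(PhantomSpec(shape=(96, 96), seed=8))
    assert not np.array_equal(a.maps.retardation, c.maps.retardation)


def test_maps_consistent_with_ground_truth(default_phantom):
    """The emitted maps are exactly the forward models of the ground truth."""
    ph = default_phantom
    tissue = ph.tissue_mask
    r_expect = forward_retardation(
        ph.dm_truth[tissue],
        np.nan_to_num(ph.alpha_truth[tissue]),
        ph.spec.birefringence,
        ph.spec.wavelength_nm,
    )
    t_expect = forward_transmittance(ph.dm_truth[tissue], ph.spec)
    np.testing.assert_allclose(ph.maps.retardation[tissue], r_expect, atol=1e-12)
    np.testing.assert_allclose(ph.maps.transmittance[tissue], t_expect, atol=1e-12)
    # Background: full incident intensity, zero retardation.
    assert np.all(ph.maps.transmittance[~tissue] == ph.spec.incident_intensity)
    assert np.all(ph.maps.retardation[~tissue] == 0.0)


def test_invertible_regime(default_phantom):
    """delta <= pi/2 everywhere: |sin| never folds over."""
    ph = default_phantom
    cos2 = np.cos(np.deg2rad(np.nan_to_num(ph.alpha_truth))) ** 2
    delta = ph.spec.delta_max * (ph.dm_truth / ph.spec.d_max_um) * cos2
    assert np.nanmax(delta) <= np.pi / 2 + 1e-9


def test_all_regions_present(default_phantom):
    labels = default_phantom.labels_truth
    for code in (BG, LM, HM, TRANSITION):
        assert (labels == code).any()
    # Unmyelinated cortex patches exist (the T_c mode population).
    lm = labels == LM
    assert (default_phantom.dm_truth[lm] == 0.0).any()
    assert np.isnan(default_phantom.alpha_truth[lm]).any()


def test_series_round_trip(small_phantom):
    ph = generate_phantom(PhantomSpec(shape=(64, 64), seed=1), with_series=True)
    maps = extract_maps(ph.series)
    np.testing.assert_allclose(maps.transmittance, ph.maps.transmittance, atol=1e-12)
    np.testing.assert_allclose(maps.retardation, ph.maps.retardation, atol=1e-10)


def test_forward_series_noise_deterministic():
    t = np.full((4, 4), 0.5)
    r = np.full((4, 4), 0.3)
    phi = np.zeros((4, 4))
    s1 = forward_series(t, r, phi, noise_sigma=0.01, seed=9)
    s2 = forward_series(t, r, phi, noise_sigma=0.01, seed=9)
    assert np.array_equal(s1.intensities, s2.intensities)
    assert np.all(s1.intensities >= 0.0)
    assert not np.array_equal(
        s1.intensities, forward_series(t, r, phi, noise_sigma=0.01, seed=10).intensities
    )


def test_forward_transmittance_validation():
    spec = PhantomSpec()
    with pytest.raises(ValueError):
        forward_transmittance(np.array([-1.0]), spec)
    with pytest.raises(ValueError):
        forward_transmittance(np.array([spec.d_max_um + 1.0]), spec)


def test_wrapped_regime_flag():
    spec = PhantomSpec(wrapped_regime=True)
    assert spec.delta_max == pytest.approx(np.pi)
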