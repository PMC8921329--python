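"""Unit tests for the inclination models and parameter estimation."""

import numpy as np
import pytest

from pli_incline import (
    BG,
    HM,
    LM,
    ModelParams,
    PLIMaps,
    clip_transmittance,
    inclination_combined,
    inclination_unweighted,
    inclination_weighted,
    run_scenario,
)
from pli_incline.segmentation import RegionLabelMap

PARAMS = ModelParams(r_ref_hm=0.9, r_ref_lm=0.3, t_m=0.3, t_c=0.7)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(r_ref_hm=0.2, r_ref_lm=0.3, t_m=0.3, t_c=0.7)  # lm > hm
    with pytest.raises(ValueError):
        ModelParams(r_ref_hm=0.9, r_ref_lm=0.3, t_m=0.8, t_c=0.7)  # t_m >= t_c
    with pytest.raises(ValueError):
        ModelParams(r_ref_hm=0.9, r_ref_lm=0.0, t_m=0.3, t_c=0.7)  # zero ref
    with pytest.raises(ValueError):
        ModelParams(r_ref_hm=1.2, r_ref_lm=0.3, t_m=0.3, t_c=0.7)  # > 1


def test_r_ref_star_interpolation():
    p = np.array([0.0, 0.5, 1.0])
    np.testing.assert_allclose(PARAMS.r_ref_star(p), [0.3, 0.6, 0.9])


def test_unweighted_endpoints():
    # R = R_ref -> in-plane (0 degrees); R -> 0 -> out-of-plane (90 degrees).
    assert inclination_unweighted(0.9, 0.9) == pytest.approx(0.0, abs=1e-9)
    assert inclination_unweighted(0.0, 0.9) == pytest.approx(90.0)
    # R above R_ref saturates to 0 degrees instead of going complex.
    assert inclination_unweighted(0.99, 0.9) == 0.0
    with pytest.raises(ValueError):
        inclination_unweighted(np.array([0.5]), 0.0)


def test_unweighted_inverts_forward_model():
    """alpha -> R via the retardation model -> alpha, exactly."""
    delta_max = np.pi / 2
    alpha = np.linspace(0.0, 85.0, 50)
    r = np.sin(delta_max * np.cos(np.deg2rad(alpha)) ** 2)
    r_ref = np.sin(delta_max)
    np.testing.assert_allclose(inclination_unweighted(r, r_ref), alpha, atol=1e-9)


def test_weighted_inverts_forward_model():
    """Thickness-varying forward data is recovered exactly by the weighted model."""
    rng = np.random.default_rng(0)
    delta_max = np.pi / 2
    mu_m, mu_c, d_max = 0.0907, 0.00594, 10.0
    alpha = rng.uniform(0.0, 80.0, 1000)
    d_m = rng.uniform(2.0, 10.0, 1000)
    r = np.sin(delta_max * (d_m / d_max) * np.cos(np.deg2rad(alpha)) ** 2)
    t = np.exp(-mu_m * d_m - mu_c * (d_max - d_m))
    t_m = np.exp(-mu_m * d_max)
    t_c = np.exp(-mu_c * d_max)
    params = ModelParams(r_ref_hm=np.sin(delta_max), r_ref_lm=0.1, t_m=t_m, t_c=t_c)
    got = inclination_weighted(r, t, params)
    np.testing.assert_allclose(got, alpha, atol=1e-8)


def test_weighted_invalid_fallback():
    """T >= T_c diverges; the pixel falls back to the unweighted model."""
    r = np.array([0.5, 0.5])
    t = np.array([0.5, 0.75])  # second pixel above t_c = 0.7
    alpha, saturated, invalid = inclination_weighted(r, t, PARAMS, return_masks=True)
    assert not invalid[0] and invalid[1]
    assert alpha[1] == pytest.approx(inclination_unweighted(0.5, PARAMS.r_ref_hm))
    assert np.isfinite(alpha).all()


def test_combined_reduces_to_branches():
    r = np.array([0.4])
    t = np.array([0.5])
    a1 = inclination_combined(r, t, np.array([1.0]), PARAMS)
    a0 = inclination_combined(r, t, np.array([0.0]), PARAMS)
    np.testing.assert_allclose(a1, inclination_weighted(r, t, PARAMS))
    np.testing.assert_allclose(a0, inclination_unweighted(r, PARAMS.r_ref_lm))
    with pytest.raises(ValueError):
        inclination_combined(r, t, np.array([1.5]), PARAMS)


def test_clip_transmittance():
    out = clip_transmittance(np.array([0.1, 0.3, 0.5]), 0.3)
    np.testing.assert_allclose(out, [0.3, 0.3, 0.5])


def test_run_scenario_background_nan_and_split():
    r = np.array([[0.05, 0.8, 0.2]])
    t = np.array([[0.95, 0.35, 0.6]])
    maps = PLIMaps(t, np.zeros_like(t), r)
    labels = RegionLabelMap(np.array([[BG, HM, LM]], dtype=np.uint8))
    out = run_scenario(maps, "iii", PARAMS, labels)
    assert np.isnan(out.alpha[0, 0])
    # The HM pixel uses the weighted model, the LM pixel the unweighted one.
    assert out.alpha[0, 1] == pytest.approx(
        float(inclination_weighted(np.array([0.8]), np.array([0.35]), PARAMS)[0])
    )
    assert out.alpha[0, 2] == pytest.approx(
        float(inclination_unweighted(np.array([0.2]), PARAMS.r_ref_lm)[0])
    )
    with pytest.raises(ValueError):
        run_scenario(maps, "v", PARAMS, labels)
    with pytest.raises(ValueError):
        run_scenario(maps, "iv", PARAMS, labels)  # needs the probability map


def test_scenario_i_section_reference():
    r = np.array([[0.5]])
    t = np.array([[0.5]])
    maps = PLIMaps(t, np.zeros_like(t), r)
    labels = RegionLabelMap(np.array([[LM]], dtype=np.uint8))
    out = run_scenario(maps, "i", PARAMS, labels, r_ref_section=0.95)
    assert out.alpha[0, 0] == pytest.approx(
        float(inclination_unweighted(np.array([0.5]), 0.95)[0])
    )


def test_compute_model_params_on_phantom(pipeline_iv, default_phantom):
    """End-to-end estimated parameters land near the phantom's optical truth."""
    params = pipeline_iv.params
    spec = default_phantom.spec
    scale = default_phantom.maps.transmittance.max()
    # T_M and T_c within a few histogram bins of the forward-model values.
    assert params.t_m == pytest.approx(spec.t_myelin / scale, abs=0.02)
    assert params.t_c == pytest.approx(spec.t_cell / scale, abs=0.02)
    # The HM reference is near the maximum retardation of the dense band.
    assert params.r_ref_hm > 0.95
    # The LM reference is the elbow of the LM-restricted retardation
    # histogram: within a couple of 256-bin widths of R_thres.
    assert params.r_ref_lm == pytest.approx(
        pipeline_iv.thresholds.r_thres, abs=2.5 / 256.0
    )
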