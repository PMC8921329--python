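"""Fibre-inclination models: unweighted, transmittance-weighted, and combined.

The out-of-plane inclination alpha of a nerve-fibre bundle relates to the
measured retardation through

    R = |sin(2 pi / lambda * dn * d_m * cos^2 alpha)|,

so with a reference retardation R_ref of densely packed in-plane fibres the
unweighted model inverts this as

    alpha = arccos( sqrt( arcsin(R) / arcsin(R_ref) ) ).

Where the amount of myelin d_m varies, the Lambert-Beer attenuation of the
transmittance provides the correction factor ln(T_c/T_M) / ln(T_c/T)
(equal to d_M / d_m under the two-compartment attenuation model), giving
the transmittance-weighted model.  The combined model blends the two with
the per-pixel HM-probability, interpolating the reference retardation in
the transition zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import masked_median_filter
from .probability import HMProbabilityMap
from .segmentation import BG, HM, RegionLabelMap, find_reference_region, refine_threshold
from .signal import PLIMaps

__all__ = [
    "ModelParams",
    "InclinationMap",
    "masked_median_filter",
    "compute_model_params",
    "clip_transmittance",
    "inclination_unweighted",
    "inclination_weighted",
    "inclination_combined",
    "run_scenario",
]


@dataclass(frozen=True)
class ModelParams:
    """Estimated parameters of the inclination formulas.

    ``r_ref_hm`` / ``r_ref_lm`` are the reference retardations of in-plane
    fibres in HM / LM regions; ``t_m`` is the transmittance of the region
    with maximum myelin thickness and ``t_c`` the transmittance of purely
    non-birefringent tissue.  All live on the normalised [0, 1] scales.
    """

    r_ref_hm: float
    r_ref_lm: float
    t_m: float
    t_c: float

    def __post_init__(self) -> None:
        if not (0 < self.r_ref_hm <= 1 and 0 < self.r_ref_lm <= 1):
            raise ValueError("reference retardations must lie in (0, 1]")
        if self.r_ref_lm > self.r_ref_hm:
            raise ValueError("r_ref_lm must not exceed r_ref_hm")
        if not (0 < self.t_m < 1):
            raise ValueError("t_m must lie in (0, 1)")
        if not (self.t_m < self.t_c <= 1):
            raise ValueError(
                "t_m must be below t_c (myelin-rich tissue must be darker "
                "than non-birefringent tissue)"
            )

    def r_ref_star(self, p_hm: np.ndarray) -> np.ndarray:
        """Reference retardation interpolated across the transition zone."""
        p = np.asarray(p_hm, dtype=float)
        return p * self.r_ref_hm + (1.0 - p) * self.r_ref_lm


@dataclass
class InclinationMap:
    """Out-of-plane inclination raster in degrees with quality masks.

    ``alpha`` is in [0, 90] degrees (NaN on background); ``saturated``
    flags pixels whose arccos argument had to be clamped; ``weight_invalid``
    flags pixels where T >= T_c made the log weight diverge and the
    unweighted branch was used instead.
    """

    alpha: np.ndarray
    scenario: str
    saturated: np.ndarray
    weight_invalid: np.ndarray


def compute_model_params(
    maps: PLIMaps,
    pmap: HMProbabilityMap,
    region_size_fraction: tuple[float, float] = (0.00009, 0.00011),
    labels: RegionLabelMap | None = None,
) -> ModelParams:
    """Estimate {R_ref,HM, R_ref,LM, T_M, T_c} from the maps and P_HM.

    Expects the transmittance median-filtered per region.  R_ref,LM is the
    maximum-curvature point of the retardation histogram over LM pixels
    (P_HM < 0.05).  R_ref,HM is the mean of the top 10 % retardation values
    inside the connected highest-retardation region of the HM pixels
    (P_HM >= 0.95, region size 0.009-0.011 % of the HM area); T_M is the
    mean transmittance of that same region.  T_c is the mode (256-bin) of
    the LM transmittance values.

    Background pixels carry P_HM = 0 and would otherwise flood the LM
    reference histograms, so pass ``labels`` to restrict both references to
    tissue.
    """
    tissue = np.ones(maps.shape, dtype=bool) if labels is None else labels.labels != BG
    lm = (pmap.p_hm < pmap.band[0]) & tissue
    hm = (pmap.p_hm >= pmap.band[1]) & tissue
    if not lm.any():
        raise ValueError(
            "no LM pixels: the histograms lack a broad variety of tissue "
            "components and the LM reference cannot be estimated"
        )
    if not hm.any():
        raise ValueError("no HM pixels: the HM reference cannot be estimated")

    r_ref_lm = refine_threshold(maps.retardation[lm], "behind_retardation_peak")

    ref_region = find_reference_region(
        maps.retardation, valid_mask=hm, target_fraction_range=region_size_fraction
    )
    ref_vals = np.sort(maps.retardation[ref_region])
    top = ref_vals[int(np.floor(0.9 * ref_vals.size)) :]
    r_ref_hm = float(top.mean())
    t_m = float(maps.transmittance[ref_region].mean())

    counts, edges = np.histogram(maps.transmittance[lm], bins=256, range=(0.0, 1.0))
    t_c = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))

    return ModelParams(r_ref_hm=r_ref_hm, r_ref_lm=r_ref_lm, t_m=t_m, t_c=t_c)


def clip_transmittance(transmittance: np.ndarray, t_m: float) -> np.ndarray:
    """Clip transmittance from below to T_M.

    Out-of-plane fibres scatter more and appear darker than in-plane fibres
    of the same myelin content; raising their transmittance to T_M prevents
    the weighted model from over-correcting them.
    """
    return np.maximum(np.asarray(transmittance, dtype=float), t_m)


def _arccos_sqrt(argument: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """arccos(sqrt(arg)) in degrees with the argument clamped to [0, 1]."""
    arg = np.asarray(argument, dtype=float)
    saturated = (arg > 1.0) | (arg < 0.0)
    alpha = np.degrees(np.arccos(np.sqrt(np.clip(arg, 0.0, 1.0))))
    return alpha, saturated


def inclination_unweighted(
    retardation: np.ndarray, r_ref: np.ndarray | float
) -> np.ndarray:
    """Unweighted inclination alpha = arccos(sqrt(arcsin R / arcsin R_ref)).

    The ratio is clamped to [0, 1] before the square root, so R > R_ref
    saturates to alpha = 0 degrees.  Returns degrees.
    """
    r_ref = np.asarray(r_ref, dtype=float)
    if np.any(r_ref <= 0):
        raise ValueError("r_ref must be positive")
    ratio = np.arcsin(np.clip(retardation, 0.0, 1.0)) / np.arcsin(np.clip(r_ref, 0.0, 1.0))
    alpha, _ = _arccos_sqrt(ratio)
    return alpha


def inclination_weighted(
    retardation: np.ndarray,
    transmittance: np.ndarray,
    params: ModelParams,
    return_masks: bool = False,
):
    """Transmittance-weighted inclination.

        alpha = arccos( sqrt( arcsin(R)/arcsin(R_ref,HM)
                              * ln(T_c/T_M) / ln(T_c/T) ) )

    Expects T already clipped so T >= T_M.  Pixels with T >= T_c (no
    detectable myelin attenuation, diverging weight) fall back to the
    unweighted formula with R_ref,HM and are flagged.  Returns degrees,
    optionally with (saturated, weight_invalid) boolean masks.
    """
    r = np.asarray(retardation, dtype=float)
    t = np.asarray(transmittance, dtype=float)
    ratio = np.arcsin(np.clip(r, 0.0, 1.0)) / np.arcsin(params.r_ref_hm)
    log_ref = np.log(params.t_c / params.t_m)
    invalid = t >= params.t_c
    t_safe = np.where(invalid, params.t_m, t)
    weight = log_ref / np.log(params.t_c / t_safe)
    alpha, saturated = _arccos_sqrt(ratio * weight)
    if invalid.any():
        alpha = np.where(invalid, inclination_unweighted(r, params.r_ref_hm), alpha)
        saturated = saturated & ~invalid
    if return_masks:
        return alpha, saturated, invalid
    return alpha


def inclination_combined(
    retardation: np.ndarray,
    transmittance: np.ndarray,
    p_hm: np.ndarray,
    params: ModelParams,
    return_masks: bool = False,
):
    """P_HM-weighted blend of the transmittance-weighted and unweighted models.

        alpha = P_HM * alpha_HM + (1 - P_HM) * alpha_LM,

    where alpha_HM uses R_ref,HM with the transmittance weight and alpha_LM
    uses the interpolated reference R_ref* = P_HM R_ref,HM + (1-P_HM) R_ref,LM.
    """
    p = np.asarray(p_hm, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_hm must lie in [0, 1]")
    alpha_hm, saturated, invalid = inclination_weighted(
        retardation, transmittance, params, return_masks=True
    )
    alpha_lm = inclination_unweighted(retardation, params.r_ref_star(p))
    alpha = p * alpha_hm + (1.0 - p) * alpha_lm
    if return_masks:
        return alpha, saturated, invalid
    return alpha


def run_scenario(
    maps: PLIMaps,
    scenario: str,
    params: ModelParams,
    labels: RegionLabelMap,
    pmap: HMProbabilityMap | None = None,
    r_ref_section: float | None = None,
) -> InclinationMap:
    """Compute an inclination map under one of four model scenarios.

    (i)   unweighted model on the whole section with the section-wide
          reference retardation;
    (ii)  transmittance-weighted model on the whole section;
    (iii) both models hard-split by the binary HM/LM labels;
    (iv)  combined model blended by the HM-probability map.

    ``maps`` must carry the median-filtered, T_M-clipped transmittance.
    Background pixels are set to NaN.
    """
    r, t = maps.retardation, maps.transmittance
    shape = maps.shape
    saturated = np.zeros(shape, dtype=bool)
    invalid = np.zeros(shape, dtype=bool)

    if scenario == "i":
        ref = params.r_ref_hm if r_ref_section is None else r_ref_section
        ratio = np.arcsin(np.clip(r, 0, 1)) / np.arcsin(ref)
        alpha, saturated = _arccos_sqrt(ratio)
    elif scenario == "ii":
        alpha, saturated, invalid = inclination_weighted(r, t, params, return_masks=True)
    elif scenario == "iii":
        alpha_hm, sat_hm, invalid = inclination_weighted(r, t, params, return_masks=True)
        alpha_lm = inclination_unweighted(r, params.r_ref_lm)
        hm = labels.labels == HM
        alpha = np.where(hm, alpha_hm, alpha_lm)
        saturated = sat_hm & hm
        invalid = invalid & hm
    elif scenario == "iv":
        if pmap is None:
            raise ValueError("scenario iv requires the HM-probability map")
        alpha, saturated, invalid = inclination_combined(
            r, t, pmap.p_hm, params, return_masks=True
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected i, ii, iii or iv")

    bg = labels.labels == BG
    alpha = np.where(bg, np.nan, alpha)
    saturated &= ~bg
    invalid &= ~bg
    return InclinationMap(
        alpha=alpha, scenario=scenario, saturated=saturated, weight_invalid=invalid
    )
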