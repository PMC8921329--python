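"""The HM-probability map: a smooth sigmoid blend between LM and HM regions.

Each pixel's retardation/transmittance pair is expressed as a signed
deviation from (R_thres, T_thres), scaled by the bootstrap transition
widths.  An error-function sigmoid of the deviation radius, steered by the
deviation direction, turns the hard binary classification into a
probability P_HM in [0, 1]: deep on the HM side (high R and/or low T)
P_HM -> 1, deep on the LM side P_HM -> 0, and P_HM = 0.5 exactly at the
threshold point.  Pixels with P_HM > 0.95 count as HM, < 0.05 as LM, and
everything in between as transition zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .bootstrap import TransitionWidths
from .segmentation import BG, RegionLabelMap, ThresholdSet, classify_regions
from .signal import PLIMaps

__all__ = ["HMProbabilityMap", "scaled_deviations", "probability", "compute_pmap"]

#: Saturation magnitude standing in for an infinite deviation on a
#: zero-width side (large enough that the erf sigmoid is exactly 0 or 1).
_SATURATED = 1e8

#: Default transition-zone band: P_HM < 0.05 is LM, > 0.95 is HM.
DEFAULT_BAND = (0.05, 0.95)


@dataclass
class HMProbabilityMap:
    """Per-pixel probability of high myelination with its intermediates."""

    p_hm: np.ndarray
    delta_r: np.ndarray
    delta_t: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND

    @property
    def hm_mask(self) -> np.ndarray:
        return self.p_hm > self.band[1]

    @property
    def lm_mask(self) -> np.ndarray:
        return self.p_hm < self.band[0]

    @property
    def transition_mask(self) -> np.ndarray:
        return ~(self.hm_mask | self.lm_mask)


def _signed_deviation(
    value: np.ndarray, threshold: float, width_plus: float, width_minus: float
) -> np.ndarray:
    """Deviation from a threshold in units of the one-sided transition width.

    The sign of (value - threshold) is retained; a zero-width side with a
    non-zero deviation saturates to +/- a large constant instead of
    overflowing.
    """
    num = np.asarray(value, dtype=float) - threshold
    width = np.where(num > 0, width_plus, width_minus)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(width > 0, num / np.where(width > 0, width, 1.0), 0.0)
    dev = np.where((width <= 0) & (num != 0), np.sign(num) * _SATURATED, dev)
    return dev


def scaled_deviations(
    retardation: np.ndarray,
    transmittance: np.ndarray,
    thresholds: ThresholdSet,
    widths: TransitionWidths,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed, width-scaled deviations (Delta R, Delta T) of every pixel.

    Delta R = (R - R_thres) / w with w = (R_thres+ - R_thres) above the
    threshold and (R_thres - R_thres-) below it; analogous for Delta T.
    The deviations carry the sign of the numerator so the direction term of
    the probability formula can distinguish HM-wards from LM-wards
    deviations.
    """
    wr_plus = widths.r_plus - thresholds.r_thres
    wr_minus = thresholds.r_thres - widths.r_minus
    wt_plus = widths.t_plus - thresholds.t_thres
    wt_minus = thresholds.t_thres - widths.t_minus
    if min(wr_plus, wr_minus, wt_plus, wt_minus) < 0:
        raise ValueError("bootstrap means must bracket the original thresholds")
    delta_r = _signed_deviation(retardation, thresholds.r_thres, wr_plus, wr_minus)
    delta_t = _signed_deviation(transmittance, thresholds.t_thres, wt_plus, wt_minus)
    return delta_r, delta_t


def probability(delta_r: np.ndarray, delta_t: np.ndarray) -> np.ndarray:
    """Sigmoid HM-probability of scaled deviations (Delta R, Delta T).

        P_HM = 0.5 - 0.5 * erf( cos(3 pi/4 - atan2(Delta T, Delta R))
                                 * sqrt(Delta R^2 + Delta T^2) )

    The direction term selects the HM corner (positive Delta R, negative
    Delta T -> P_HM -> 1) against the LM corner (negative Delta R, positive
    Delta T -> P_HM -> 0); at zero deviation the radius vanishes and
    P_HM = 0.5 exactly.

    A saturated deviation (a zero-width side, see ``scaled_deviations``)
    means the transition zone has collapsed on that axis, so the pixel is
    assigned the hard binary classification instead of the sigmoid value:
    P_HM = 1 if Delta R > 0 or Delta T < 0 (the HM rule), else 0.  Feeding
    the saturated value through the angle formula would let the collapsed
    axis override the other one, contradicting the binary OR-rule in the
    zero-width limit.
    """
    delta_r = np.asarray(delta_r, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    theta = np.arctan2(delta_t, delta_r)
    radius = np.hypot(delta_r, delta_t)
    p = 0.5 - 0.5 * erf(np.cos(0.75 * np.pi - theta) * radius)
    saturated = (np.abs(delta_r) >= _SATURATED) | (np.abs(delta_t) >= _SATURATED)
    if np.any(saturated):
        hard = np.where((delta_r > 0) | (delta_t < 0), 1.0, 0.0)
        p = np.where(saturated, hard, p)
    return p


def compute_pmap(
    maps: PLIMaps,
    thresholds: ThresholdSet,
    widths: TransitionWidths,
    labels: RegionLabelMap | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> HMProbabilityMap:
    """HM-probability map of a section; background pixels carry P_HM = 0."""
    delta_r, delta_t = scaled_deviations(
        maps.retardation, maps.transmittance, thresholds, widths
    )
    p = np.clip(probability(delta_r, delta_t), 0.0, 1.0)
    if labels is None:
        labels = classify_regions(maps, thresholds)
    if labels.labels.shape != p.shape:
        raise ValueError("label map shape does not match the maps")
    p[labels.labels == BG] = 0.0
    return HMProbabilityMap(p_hm=p, delta_r=delta_r, delta_t=delta_t, band=band)
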