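"""End-to-end pipeline: maps (or series) in, inclination and probability maps out.

The stages follow the measurement's analysis chain: harmonic signal
extraction (if a rotation series is given), transmittance scaling, circular
median filtering, histogram-threshold estimation, bootstrap of the
transition widths, HM-probability map, model-parameter estimation on the
region-masked filtered transmittance, T_M clipping, and finally the
inclination scenario.  Histogram and bootstrap stages always see the full
pixel multiset; only pointwise/local-window stages may be chunked.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as plio
from .bootstrap import TransitionWidths, bootstrap_thresholds
from .filters import chunked_apply, masked_median_filter, median_filter_disk
from .inclination import (
    InclinationMap,
    ModelParams,
    clip_transmittance,
    compute_model_params,
    run_scenario,
)
from .probability import HMProbabilityMap, compute_pmap
from .segmentation import (
    BG,
    RegionLabelMap,
    ThresholdSet,
    classify_regions,
    estimate_thresholds,
    find_reference_region,
    scale_transmittance,
)
from .signal import PLIMaps, RotationSeries, extract_maps

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("pli_incline")


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run (defaults as published)."""

    scenario: str = "iv"
    sample_fraction: float = 0.25
    iterations: int = 200
    median_radius: int = 5
    region_size_fraction: tuple[float, float] = (0.00009, 0.00011)
    p_hm_band: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chunk_shape: tuple[int, int] | None = None  # None: filter the whole image at once

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Artefact bundle of one run."""

    maps: PLIMaps  # scaled raw maps
    filtered_transmittance: np.ndarray  # region-masked median-filtered, T_M-clipped
    thresholds: ThresholdSet
    widths: TransitionWidths
    labels: RegionLabelMap
    pmap: HMProbabilityMap
    params: ModelParams
    inclination: InclinationMap
    config: PipelineConfig

    def report(self) -> dict:
        """JSON-serialisable parameter report of the run."""
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "widths": dataclasses.asdict(self.widths),
            "model_params": dataclasses.asdict(self.params),
            "config": self.config.to_dict(),
            "scenario": self.inclination.scenario,
        }


def _median_filter(image, labels, radius, chunk_shape, exclude=None):
    if chunk_shape is None:
        return masked_median_filter(image, labels, radius=radius, exclude=exclude)
    if labels is None:
        return chunked_apply(
            lambda img: masked_median_filter(img, None, radius=radius),
            [image],
            chunk_shape,
            halo=radius,
            footprint_radius=radius,
        )
    return chunked_apply(
        lambda img, lab: masked_median_filter(img, lab, radius=radius, exclude=exclude),
        [image, labels],
        chunk_shape,
        halo=radius,
        footprint_radius=radius,
    )


def run_pipeline(
    maps: PLIMaps | None = None,
    series: RotationSeries | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis chain on precomputed maps or a rotation series."""
    config = config or PipelineConfig()
    if maps is None:
        if series is None:
            raise ValueError("either maps or a rotation series must be given")
        logger.info("extracting maps from a %d-angle rotation series", series.n_angles)
        maps = extract_maps(series)

    # Transmittance is brought to [0, 1] by a pure scale so the Lambert-Beer
    # log ratios of the weighted model are unaffected.
    t_scaled = scale_transmittance(maps.transmittance)
    maps = PLIMaps(t_scaled, maps.direction, np.clip(maps.retardation, 0.0, 1.0))

    t_filtered = _median_filter(
        maps.transmittance, None, config.median_radius, config.chunk_shape
    )
    hist_maps = PLIMaps(t_filtered, maps.direction, maps.retardation)

    thresholds, masked_maps = estimate_thresholds(hist_maps, return_masked=True)
    logger.info(
        "thresholds: r_thres=%.4f t_thres=%.4f t_back=%.4f t_ref=%.4f",
        thresholds.r_thres,
        thresholds.t_thres,
        thresholds.t_back,
        thresholds.t_ref,
    )

    labels = classify_regions(hist_maps, thresholds)

    # Resample from the background-collapsed maps: the bootstrap must see
    # the same pixel multiset the full-sample thresholds were read from.
    widths = bootstrap_thresholds(
        masked_maps,
        thresholds,
        sample_fraction=config.sample_fraction,
        n_iterations=config.iterations,
        seed=config.seed,
    )
    logger.info(
        "transition widths: r+=%.4f r-=%.4f t+=%.4f t-=%.4f",
        widths.r_plus,
        widths.r_minus,
        widths.t_plus,
        widths.t_minus,
    )

    pmap = compute_pmap(hist_maps, thresholds, widths, labels=labels, band=config.p_hm_band)

    # Region-masked median filter for the model parameters and the
    # weighted inclination (keeps HM/LM borders sharp, ignores background).
    t_masked = _median_filter(
        maps.transmittance,
        labels.labels,
        config.median_radius,
        config.chunk_shape,
        exclude=BG,
    )
    model_maps = PLIMaps(t_masked, maps.direction, maps.retardation)
    params = compute_model_params(
        model_maps, pmap, region_size_fraction=config.region_size_fraction, labels=labels
    )
    logger.info(
        "model params: r_ref_hm=%.4f r_ref_lm=%.4f t_m=%.4f t_c=%.4f",
        params.r_ref_hm,
        params.r_ref_lm,
        params.t_m,
        params.t_c,
    )

    t_clipped = clip_transmittance(t_masked, params.t_m)
    incl_maps = PLIMaps(t_clipped, maps.direction, maps.retardation)

    r_ref_section = None
    if config.scenario == "i":
        tissue = labels.labels != BG
        region = find_reference_region(
            maps.retardation,
            valid_mask=tissue,
            target_fraction_range=config.region_size_fraction,
        )
        vals = np.sort(maps.retardation[region])
        r_ref_section = float(vals[int(np.floor(0.9 * vals.size)) :].mean())
        logger.info("section-wide reference retardation: %.4f", r_ref_section)

    inclination = run_scenario(
        incl_maps,
        config.scenario,
        params,
        labels,
        pmap=pmap,
        r_ref_section=r_ref_section,
    )

    return PipelineResult(
        maps=maps,
        filtered_transmittance=t_clipped,
        thresholds=thresholds,
        widths=widths,
        labels=labels,
        pmap=pmap,
        params=params,
        inclination=inclination,
        config=config,
    )


def write_result(outdir: str | Path, result: PipelineResult) -> None:
    """Write all rasters, masks and the JSON report of a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plio.write_raster(outdir / "p_hm.tif", result.pmap.p_hm)
    plio.write_raster(outdir / "inclination.tif", result.inclination.alpha)
    plio.write_raster(
        outdir / "transmittance_filtered.tif", result.filtered_transmittance
    )
    import tifffile

    tifffile.imwrite(outdir / "labels.tif", result.labels.labels.astype(np.uint8))
    quality = (
        result.inclination.saturated.astype(np.uint8)
        + 2 * result.inclination.weight_invalid.astype(np.uint8)
    )
    tifffile.imwrite(outdir / "quality_mask.tif", quality)
    (outdir / "report.json").write_text(json.dumps(result.report(), indent=2))
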