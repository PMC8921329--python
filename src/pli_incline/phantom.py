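"""Synthetic 3D-PLI phantoms with per-pixel ground truth.

The generator builds a brain-like section layout and evaluates the forward
models of the measurement per pixel:

* retardation  R = |sin(2 pi / lambda * dn * d_m * cos^2 alpha)|,
* transmittance (two-compartment Lambert-Beer)
      T = I0~ * exp(-mu_m d_m - mu_c (d_M - d_m)),
      I0~ = I0 * exp(-mu_c (d - d_M)),
* the rotation series  I(rho) = T/2 (1 + sin delta sin 2(rho - phi)).

The default optical regime sets 2 pi dn d_M / lambda = pi / 2 so the peak
phase delta never exceeds pi/2 and the retardation is invertible (no
|sin| fold-over); a flag enables the wrapped regime for stress tests.

The layout emulates the features the analysis relies on: a dense in-plane
fibre band (the corpus-callosum-like reference, with a gentle radial
inclination gradient so the highest-retardation region is a unique small
disk), a steep fibre band, a fan where fibres thin out from white matter
into cortex (ground-truth transition zone), a wide low-myelination cortex,
fibre-bundle blobs in the cortex (putamen-like), and background margins.

All tissue fields are spatially smooth random textures, so the histograms
the threshold estimators read carry the structure the estimators assume:
the transmittance histogram is trimodal with the background spike as its
biggest peak (the margin is sized for that), a tall narrow high-myelination
lump just above T_M whose upper foot is the sharpest bend between T_ref and
T_back, and a broad smooth cortex lump.  A small population of contiguous,
exactly unmyelinated cortex patches puts the mode of the cortex
transmittance exactly at T_c (the patches are wide enough to survive the
median filter) while staying well below the high-myelination peak, so it
wins the mode contest without winning the curvature contest.  The
retardation histogram has a dominant low peak ending in a sharp, data-rich
elbow at the upper edge of the cortex retardation, followed by a gap and
the white-matter tail.  In the cortex the myelin thickness and the
inclination are coupled (thicker myelinated bundles dive more steeply), so
the cortex transmittance spreads widely while its retardation stays below
the white-matter range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import BG, HM, LM
from .signal import PLIMaps, RotationSeries

__all__ = [
    "TRANSITION",
    "PhantomSpec",
    "Phantom",
    "forward_retardation",
    "forward_transmittance",
    "forward_series",
    "generate_phantom",
]

#: Ground-truth label for planted transition (fan) zones; BG/LM/HM match
#: the classifier's codes.
TRANSITION: int = 3


@dataclass
class PhantomSpec:
    """Geometry, optics and noise of a synthetic section.

    Optical defaults: wavelength 550 nm, section thickness 60 um, maximum
    myelin thickness 10 um with birefringence dn = lambda / (4 d_M) so the
    peak retardation phase is exactly pi/2.  Attenuation coefficients are
    chosen so a fully myelinated column transmits ~30 % and purely
    non-birefringent tissue ~70 % of the incident light.
    """

    shape: tuple[int, int] = (512, 512)
    wavelength_nm: float = 550.0
    section_thickness_um: float = 60.0
    d_max_um: float = 10.0
    birefringence: float | None = None  # default: quarter-wave at d_max
    mu_myelin: float = 0.0907  # 1/um
    mu_cell: float = 0.00594  # 1/um
    incident_intensity: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    wrapped_regime: bool = False  # if True, dn doubles and delta exceeds pi/2
    dark_steep_factor: float | None = None  # optional T multiplier where alpha > 60 deg
    # layout fractions of the interior width (steep band, dense band, fan;
    # the remainder is cortex)
    layout: tuple[float, float, float] = (0.22, 0.10, 0.16)
    border: int | None = None  # BG margin in px; default ~7 % of min dimension
    lm_thickness_fraction: float = 0.1  # LM reference d_m as a fraction of d_M
    n_blobs: int = 6
    blob_radius_fraction: float = 0.035

    def __post_init__(self) -> None:
        if self.birefringence is None:
            factor = 2.0 if self.wrapped_regime else 1.0
            # 2 pi dn d_M / lambda = pi/2  =>  dn = lambda / (4 d_M)
            self.birefringence = factor * (self.wavelength_nm * 1e-3) / (
                4.0 * self.d_max_um
            )
        if self.border is None:
            # The margin is sized so the background spike is always the
            # biggest peak of the 64-bin transmittance histogram, as the
            # threshold cascade assumes for T_back.
            self.border = max(4, int(round(0.07 * min(self.shape))))
        if not (0 <= self.lm_thickness_fraction < 1):
            raise ValueError("lm_thickness_fraction must lie in [0, 1)")
        if self.mu_myelin <= self.mu_cell or self.mu_cell < 0:
            raise ValueError("attenuation must satisfy mu_myelin > mu_cell >= 0")
        if self.d_max_um > self.section_thickness_um:
            raise ValueError("d_M must not exceed the section thickness")
        if 2 * self.border >= min(self.shape):
            raise ValueError("background border exceeds the image size")

    @property
    def delta_max(self) -> float:
        """Peak retardation phase 2 pi dn d_M / lambda (radians)."""
        return 2.0 * np.pi * self.birefringence * self.d_max_um / (
            self.wavelength_nm * 1e-3
        )

    @property
    def i0_tilde(self) -> float:
        return self.incident_intensity * np.exp(
            -self.mu_cell * (self.section_thickness_um - self.d_max_um)
        )

    @property
    def t_myelin(self) -> float:
        """Transmittance of a fully myelinated column (d_m = d_M)."""
        return self.i0_tilde * np.exp(-self.mu_myelin * self.d_max_um)

    @property
    def t_cell(self) -> float:
        """Transmittance of a purely non-birefringent column (d_m = 0)."""
        return self.i0_tilde * np.exp(-self.mu_cell * self.d_max_um)


@dataclass
class Phantom:
    """Generated maps plus the ground truth they were computed from."""

    spec: PhantomSpec
    maps: PLIMaps
    alpha_truth: np.ndarray  # degrees; NaN where no fibres exist
    dm_truth: np.ndarray  # myelin thickness in um
    labels_truth: np.ndarray  # BG / LM / HM / TRANSITION
    series: RotationSeries | None = None

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels_truth != BG


def forward_retardation(
    d_m_um: np.ndarray, alpha_deg: np.ndarray, birefringence: float, wavelength_nm: float
) -> np.ndarray:
    """R = |sin(2 pi / lambda * dn * d_m * cos^2 alpha)|."""
    delta = (
        2.0
        * np.pi
        / (wavelength_nm * 1e-3)
        * birefringence
        * np.asarray(d_m_um, dtype=float)
        * np.cos(np.deg2rad(alpha_deg)) ** 2
    )
    return np.abs(np.sin(delta))


def forward_transmittance(d_m_um: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Two-compartment Lambert-Beer transmittance of a tissue column."""
    d_m = np.asarray(d_m_um, dtype=float)
    if np.any(d_m < 0) or np.any(d_m > spec.d_max_um):
        raise ValueError("d_m must lie in [0, d_M]")
    return spec.i0_tilde * np.exp(
        -spec.mu_myelin * d_m - spec.mu_cell * (spec.d_max_um - d_m)
    )


def forward_series(
    transmittance: np.ndarray,
    retardation: np.ndarray,
    direction_deg: np.ndarray,
    angles_deg: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RotationSeries:
    """Evaluate the polarimetric sinusoid at every rotation angle.

    Gaussian noise of standard deviation ``noise_sigma`` is added and the
    intensities floored at zero; deterministic for a fixed seed.
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 10.0)
    angles_deg = np.asarray(angles_deg, dtype=float)
    t = np.asarray(transmittance, dtype=float)
    r = np.asarray(retardation, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("retardation must lie in [0, 1]")
    phi = np.deg2rad(direction_deg)
    rho = np.deg2rad(angles_deg)[:, None, None]
    intens = 0.5 * t * (1.0 + r * np.sin(2.0 * (rho - phi)))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sigma, size=intens.shape)
    return RotationSeries(np.maximum(intens, 0.0), angles_deg)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Spatially smooth random texture with zero mean and unit variance."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    std = field.std()
    if std == 0:
        return np.zeros(shape)
    return (field - field.mean()) / std


def generate_phantom(spec: PhantomSpec, with_series: bool = False) -> Phantom:
    """Build the brain-like layout and run the forward models.

    Deterministic for a fixed ``spec.seed`` (the seed drives the tissue
    textures, blob placement, the direction texture and the optional series
    noise).
    """
    h, w = spec.shape
    b = spec.border
    ih, iw = h - 2 * b, w - 2 * b
    if ih <= 0 or iw <= 0:
        raise ValueError("layout regions exceed the image bounds")
    rng = np.random.default_rng(spec.seed)
    sigma = max(2.0, 0.016 * min(spec.shape))  # texture correlation length

    d_m = np.zeros((h, w))
    alpha = np.full((h, w), np.nan)
    labels = np.full((h, w), BG, dtype=np.uint8)
    phi = (
        np.linspace(0.0, 160.0, h)[:, None] + np.linspace(0.0, 15.0, w)[None, :]
    ) % 180.0

    f_steep, f_dense, f_fan = spec.layout
    x0 = b
    x_steep = x0 + int(round(f_steep * iw))
    x_dense = x_steep + int(round(f_dense * iw))
    x_fan = x_dense + int(round(f_fan * iw))
    x_end = b + iw
    if x_fan >= x_end:
        raise ValueError("layout regions exceed the image bounds")

    rows = np.arange(b, b + ih)
    row_frac = (rows - b) / max(ih - 1, 1)
    d_lm = spec.lm_thickness_fraction * spec.d_max_um

    # Steep-fibre band: near-full myelin thickness with a smooth texture,
    # alpha 45 -> 68 degrees across columns (kept below ~70 degrees so its
    # retardation stays clearly above the cortex range).  The thickness
    # spread is narrow, so the band forms a tall transmittance peak just
    # above T_M whose upper foot is the sharpest bend between T_ref and
    # T_back.
    cols = np.arange(x0, x_steep)
    cfrac = (cols - x0) / max(cols.size - 1, 1)
    tex = _smooth_field(rng, (ih, cols.size), sigma)
    d_m[b : b + ih, x0:x_steep] = spec.d_max_um * (0.952 + 0.016 * np.tanh(tex))
    alpha[b : b + ih, x0:x_steep] = 45.0 + 23.0 * cfrac[None, :]
    labels[b : b + ih, x0:x_steep] = HM

    # Dense in-plane band (corpus-callosum-like reference): myelin thickness
    # and inclination both vary radially from an off-lattice centre (exactly
    # d_M and 0 degrees at the centre), so the retardation decreases
    # strictly with radius: the highest-retardation region is a unique small
    # disk, pixels join it one at a time (no grid-symmetric ties), and the
    # reference-disk transmittance equals T_M to high accuracy.
    cy, cx = b + ih / 2.0 + 0.237, (x_steep + x_dense) / 2.0 + 0.611
    yy, xx = np.mgrid[b : b + ih, x_steep:x_dense]
    s_rad = np.hypot(yy - cy, xx - cx)
    s_rad = s_rad / s_rad.max()
    d_m[b : b + ih, x_steep:x_dense] = spec.d_max_um * (1.0 - 0.35 * s_rad**2)
    alpha[b : b + ih, x_steep:x_dense] = 8.0 * s_rad
    labels[b : b + ih, x_steep:x_dense] = HM

    # Fan (transition zone): myelin thins from white matter towards the LM
    # reference thickness while the fibres flatten towards 8 degrees.
    cols = np.arange(x_dense, x_fan)
    s = (cols - x_dense + 1.0) / (cols.size + 1.0)  # in (0, 1)
    alpha_wm = 25.0 * row_frac  # fan root inclination varies across rows
    d_m[b : b + ih, x_dense:x_fan] = 0.85 * spec.d_max_um + s[None, :] * (
        d_lm - 0.85 * spec.d_max_um
    )
    alpha[b : b + ih, x_dense:x_fan] = (
        alpha_wm[:, None] * (1.0 - s[None, :]) + 8.0 * s[None, :]
    )
    labels[b : b + ih, x_dense:x_fan] = TRANSITION

    # Cortex: smooth heterogeneous myelin content with two populations.
    # A sparse set of contiguous patches (a deep sub-level set of a coarse
    # smooth field) is exactly unmyelinated, so the mode of the cortex
    # transmittance sits exactly at T_c and survives the median filter; the
    # patch fraction (~13 %) keeps that histogram bin well below the
    # high-myelination transmittance peak, so it cannot win the
    # maximum-curvature contest for T_thres.  The myelinated rest follows
    # d_m = d_LM (0.42 + 1.2 sqrt|g|), whose density vanishes smoothly at
    # both edges of its transmittance range (no delta atoms, a clear gap
    # below T_c).  The retardation is capped by coupling thickness and
    # inclination, cos^2(alpha) = f * min(1, d_LM / d_m) for a smooth
    # in-plane fraction field f (thick cortical bundles dive steeply), so
    # the cortex retardation stays below sin(0.88 * delta_max * d_LM / d_M)
    # and leaves a sharp, data-rich elbow against the white-matter tail.
    csl = np.s_[b : b + ih, x_fan:x_end]
    nc = x_end - x_fan
    g1 = np.abs(_smooth_field(rng, (ih, nc), sigma))
    dm_c = d_lm * (0.42 + 1.2 * np.sqrt(g1))
    dm_c = np.minimum(dm_c, 4.0 * d_lm)
    frac_c = np.clip(0.62 + 0.2 * _smooth_field(rng, (ih, nc), sigma), 0.05, 0.88)
    cos2 = frac_c * np.minimum(1.0, d_lm / np.maximum(dm_c, 1e-12))
    alpha_c = np.degrees(np.arccos(np.sqrt(cos2)))
    none = _smooth_field(rng, (ih, nc), 1.5 * sigma) < -1.10  # unmyelinated patches
    dm_c[none] = 0.0
    alpha_c[none] = np.nan
    d_m[csl] = dm_c
    alpha[csl] = alpha_c
    labels[csl] = LM

    # Putamen-like fibre-bundle blobs in the cortex.
    blob_r = max(2, int(round(spec.blob_radius_fraction * min(ih, iw))))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_blobs):
        if x_end - x_fan <= 2 * (blob_r + 2):
            break
        by = rng.integers(b + blob_r + 1, b + ih - blob_r - 1)
        bx = rng.integers(x_fan + blob_r + 1, x_end - blob_r - 1)
        mask = (yy - by) ** 2 + (xx - bx) ** 2 <= blob_r**2
        d_m[mask] = 0.8 * spec.d_max_um
        alpha[mask] = float(rng.uniform(5.0, 30.0))
        labels[mask] = HM

    tissue = labels != BG
    retardation = np.zeros((h, w))
    retardation[tissue] = forward_retardation(
        d_m[tissue],
        np.nan_to_num(alpha[tissue]),
        spec.birefringence,
        spec.wavelength_nm,
    )
    transmittance = np.full((h, w), spec.incident_intensity)
    transmittance[tissue] = forward_transmittance(d_m[tissue], spec)

    if spec.dark_steep_factor is not None:
        steep = tissue & (np.nan_to_num(alpha, nan=0.0) > 60.0)
        transmittance[steep] *= spec.dark_steep_factor

    maps = PLIMaps(
        transmittance=transmittance,
        direction=phi,
        retardation=np.clip(retardation, 0.0, 1.0),
    )
    series = None
    if with_series or spec.noise_sigma > 0:
        series = forward_series(
            transmittance,
            np.clip(retardation, 0.0, 1.0),
            phi,
            noise_sigma=spec.noise_sigma,
            seed=spec.seed + 1,
        )
    return Phantom(
        spec=spec,
        maps=maps,
        alpha_truth=alpha,
        dm_truth=d_m,
        labels_truth=labels,
        series=series,
    )
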