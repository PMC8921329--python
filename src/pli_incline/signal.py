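"""Extraction of transmittance, direction and retardation from a 3D-PLI rotation series.

A 3D-PLI measurement records one intensity image per rotation angle of the
polariser.  Per pixel the intensities follow a second-harmonic sinusoid

    I(rho) = T/2 * (1 + sin(delta) * sin(2*(rho - phi)))

whose mean, normalised amplitude and phase carry the transmittance ``T``,
the retardation ``R = |sin delta|`` and the in-plane fibre direction
``phi``.  For uniformly sampled angles the three quantities are obtained
exactly by discrete Fourier analysis of orders 0 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RotationSeries", "PLIMaps", "extract_maps"]


@dataclass
class RotationSeries:
    """A stack of polarimetric images, one per polariser rotation angle.

    Parameters
    ----------
    intensities : ndarray, shape (n_angles, height, width)
        Non-negative intensity images in camera units.
    angles : ndarray, shape (n_angles,)
        Polariser rotation angles in degrees, strictly increasing and
        equally spaced within [0, 180).  The default acquisition uses
        18 angles in 10 degree steps.
    """

    intensities: np.ndarray
    angles: np.ndarray = field(default_factory=lambda: np.arange(0.0, 180.0, 10.0))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a (n_angles, height, width) stack")
        n = self.intensities.shape[0]
        if self.angles.ndim != 1 or self.angles.size != n:
            raise ValueError(
                f"angle count ({self.angles.size}) does not match stack depth ({n})"
            )
        if n < 3:
            raise ValueError("at least 3 rotation angles are required")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")
        steps = np.diff(self.angles)
        if np.any(steps <= 0):
            raise ValueError("angles must be strictly increasing")
        # Harmonic extraction assumes uniform sampling of [0, 180).
        if not np.allclose(steps, 180.0 / n, rtol=0, atol=1e-8):
            raise ValueError(
                "angles must be equally spaced with step 180/n_angles degrees"
            )
        if self.angles[0] < 0 or self.angles[-1] >= 180.0:
            raise ValueError("angles must lie in [0, 180) degrees")

    @property
    def n_angles(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass
class PLIMaps:
    """Transmittance, direction and retardation rasters of one section.

    ``transmittance`` is in camera units (or [0, 1] after normalisation),
    ``direction`` in degrees within [0, 180), and ``retardation`` is the
    dimensionless |sin delta| in [0, 1].
    """

    transmittance: np.ndarray
    direction: np.ndarray
    retardation: np.ndarray

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.retardation = np.asarray(self.retardation, dtype=float)
        if not (
            self.transmittance.shape
            == self.direction.shape
            == self.retardation.shape
        ):
            raise ValueError("transmittance, direction and retardation must share one shape")
        if np.any(self.retardation < -1e-12) or np.any(self.retardation > 1 + 1e-12):
            raise ValueError("retardation must lie in [0, 1]")
        if np.any(self.transmittance < 0):
            raise ValueError("transmittance must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmittance.shape

    def copy(self) -> "PLIMaps":
        return PLIMaps(
            self.transmittance.copy(), self.direction.copy(), self.retardation.copy()
        )


def extract_maps(series: RotationSeries) -> PLIMaps:
    """Fit the second-harmonic sinusoid per pixel and return the three maps.

    The transmittance is twice the signal mean, the retardation the
    second-harmonic amplitude divided by the mean (clipped to [0, 1]) and
    the direction the second-harmonic phase mapped to [0, 180) degrees.
    Pixels with zero mean intensity yield T = R = phi = 0 by convention.
    """
    rho = np.deg2rad(series.angles)[:, None, None]
    intens = series.intensities
    n = series.n_angles

    mean = intens.mean(axis=0)
    # Fourier coefficients of the 2nd harmonic in 2*rho:
    #   I = T/2 + (T/2) sin(delta) [sin(2 rho) cos(2 phi) - cos(2 rho) sin(2 phi)]
    a = (2.0 / n) * np.sum(intens * np.sin(2.0 * rho), axis=0)
    b = (2.0 / n) * np.sum(intens * np.cos(2.0 * rho), axis=0)
    amplitude = np.hypot(a, b)

    transmittance = 2.0 * mean
    with np.errstate(divide="ignore", invalid="ignore"):
        retardation = np.where(mean > 0, amplitude / np.where(mean > 0, mean, 1.0), 0.0)
    retardation = np.clip(retardation, 0.0, 1.0)

    # phase: a = A cos(2 phi), b = -A sin(2 phi)  =>  2 phi = atan2(-b, a)
    phi = 0.5 * np.arctan2(-b, a)
    phi = np.rad2deg(phi) % 180.0
    # Undefined phase (zero amplitude) resolves to phi = 0.
    phi = np.where((amplitude <= 1e-14 * np.maximum(mean, 1e-300)) | (mean <= 0), 0.0, phi)
    transmittance = np.where(mean > 0, transmittance, 0.0)

    return PLIMaps(transmittance=transmittance, direction=phi, retardation=retardation)
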