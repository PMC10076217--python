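"""Surrogate panoramic scenes with elevation-dependent power.

In the mouse visual environment, stimulus power falls gradually with
elevation and drops abruptly near the horizon.  This module generates
spatially correlated (approximately 1/f) surrogate panoramas carrying
that structure, concatenates upper/lower-field images at a simulated
horizon, and computes the per-elevation power, SNR and vertical SNR
asymmetry profiles the efficient-coding model consumes.

Conventions: ``intensity[row, col]`` with row 0 at the *top* of the
visual field; elevation decreases with increasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PanoramicImage",
    "SceneParams",
    "ElevationProfile",
    "generate_panorama",
    "simulate_horizon_concat",
    "compute_power_profile",
    "compute_snr_asymmetry",
]


@dataclass
class PanoramicImage:
    """Elevation-indexed intensity field (row 0 = top of visual field)."""

    intensity: np.ndarray  # (rows, cols), linear light units, >= 0
    deg_per_row: float = 1.0
    top_elevation_deg: float | None = None  # elevation of row 0; None -> centred
    channel: str = "UV"  # {"UV", "green", "joint"}

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        if self.top_elevation_deg is None:
            self.top_elevation_deg = self.deg_per_row * (self.intensity.shape[0] - 1) / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def elevations(self) -> np.ndarray:
        """Per-row elevation in degrees (strictly decreasing with row)."""
        n = self.intensity.shape[0]
        return self.top_elevation_deg - self.deg_per_row * np.arange(n)


def _default_luminance(elev_deg: np.ndarray) -> np.ndarray:
    # brighter sky: mean intensity rises with elevation
    return 2.0 + 1.5 / (1.0 + np.exp(-elev_deg / 15.0))


def _default_contrast(elev_deg: np.ndarray) -> np.ndarray:
    # contrast (s.d. of fluctuations) also increases with elevation
    return 0.3 + 0.7 / (1.0 + np.exp(-elev_deg / 15.0))


@dataclass
class SceneParams:
    """Parameters of the surrogate-panorama generator.

    ``horizon_step`` multiplies intensity below the horizon (elevation
    < 0), producing the abrupt power drop at the simulated horizon on
    top of the smooth gradients.
    """

    spectral_exponent: float = 2.0  # spatial power-spectrum slope (power ~ 1/f^2)
    luminance_gradient: Callable[[np.ndarray], np.ndarray] = field(
        default=_default_luminance
    )
    contrast_gradient: Callable[[np.ndarray], np.ndarray] = field(
        default=_default_contrast
    )
    horizon_step: float = 0.4
    image_shape: tuple[int, int] = (64, 128)
    deg_per_row: float = 1.0
    channel: str = "UV"
    channel_correlation: float = 0.8  # UV/green shared-component fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.horizon_step <= 1.0):
            raise ValueError("horizon_step must lie in (0, 1]")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")

    @staticmethod
    def homogeneous(seed: int = 0, image_shape: tuple[int, int] = (64, 128),
                    mean: float = 3.0, sd: float = 1.0,
                    spectral_exponent: float = 2.0) -> "SceneParams":
        """Statistically homogeneous 1/f surrogate (no gradients, no
        horizon step) — the texture the RF-optimization sweeps consume,
        where SNR and its vertical asymmetry are imposed patch-wise."""
        return SceneParams(
            spectral_exponent=spectral_exponent,
            luminance_gradient=lambda e: np.full(np.shape(e), mean, dtype=float),
            contrast_gradient=lambda e: np.full(np.shape(e), sd, dtype=float),
            horizon_step=1.0,
            image_shape=image_shape,
            seed=seed,
        )


def _powerlaw_field(shape: tuple[int, int], exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance field with power spectrum ~ 1/f^exponent."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC
    amp = f ** (-exponent / 2.0)
    phase = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    field_ = np.real(np.fft.ifft2(amp * phase))
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def generate_panorama(params: SceneParams) -> PanoramicImage:
    """Draw one surrogate panorama.

    The image is a 1/f-correlated texture modulated row-wise: row mean
    follows ``luminance_gradient(elevation)``, row s.d. follows
    ``contrast_gradient(elevation)``, and all rows below the horizon
    (elevation < 0) are multiplied by ``horizon_step``.  With a zero
    contrast gradient the image degenerates to the deterministic
    luminance profile.  Negative values are clipped to zero (light
    intensities are non-negative).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    top_elev = params.deg_per_row * (h - 1) / 2.0
    elev = top_elev - params.deg_per_row * np.arange(h)

    if params.channel == "joint":
        shared = _powerlaw_field((h, w), params.spectral_exponent, rng)
        tex_uv = _mix_channels(shared, params, rng)
        tex_gr = _mix_channels(shared, params, rng)
        texture = 0.5 * (tex_uv + tex_gr)
    elif params.channel in ("UV", "green"):
        shared = _powerlaw_field((h, w), params.spectral_exponent, rng)
        # draw both channels from the shared component so that UV/green of the
        # same seed are correlated; keep the requested one
        tex_uv = _mix_channels(shared, params, rng)
        tex_gr = _mix_channels(shared, params, rng)
        texture = tex_uv if params.channel == "UV" else tex_gr
    else:
        raise ValueError(f"unknown channel {params.channel!r}")

    mean = np.asarray(params.luminance_gradient(elev), dtype=float)
    sd = np.asarray(params.contrast_gradient(elev), dtype=float)
    if np.any(mean < 0) or np.any(sd < 0):
        raise ValueError("gradients must be non-negative")

    img = mean[:, None] + sd[:, None] * texture
    img[elev < 0, :] *= params.horizon_step
    np.clip(img, 0.0, None, out=img)
    return PanoramicImage(
        intensity=img,
        deg_per_row=params.deg_per_row,
        top_elevation_deg=top_elev,
        channel=params.channel,
    )


def _mix_channels(shared: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    rho = params.channel_correlation
    indep = _powerlaw_field(shared.shape, params.spectral_exponent, rng)
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def simulate_horizon_concat(upper: PanoramicImage, lower: PanoramicImage) -> PanoramicImage:
    """Stack an upper-field image on top of a lower-field image.

    The seam plays the role of the horizon: the output's elevation axis
    places 0 deg at the junction between the two blocks.
    """
    if upper.intensity.shape[1] != lower.intensity.shape[1]:
        raise ValueError("widths must match")
    if upper.channel != lower.channel:
        raise ValueError("channels must match")
    stacked = np.vstack([upper.intensity, lower.intensity])
    deg = upper.deg_per_row
    # horizon (elevation 0) sits between the last upper row and first lower row
    top_elev = deg * (upper.intensity.shape[0] - 0.5)
    return PanoramicImage(stacked, deg_per_row=deg, top_elevation_deg=top_elev,
                          channel=upper.channel)


@dataclass
class ElevationProfile:
    """Per-row scene statistics: luminance, power (contrast), SNR."""

    elevation: np.ndarray  # degrees, one entry per row
    mean_intensity: np.ndarray
    mean_power: np.ndarray  # per-row variance of intensity (contrast power)
    snr: np.ndarray
    noise_power: float


def compute_power_profile(images: Sequence[PanoramicImage], noise_power: float) -> ElevationProfile:
    """Per-elevation luminance/contrast/SNR over a set of panoramas.

    For each row, the mean and variance of intensity are taken over all
    images and all columns; ``snr(row) = variance(row) / noise_power``.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    if noise_power <= 0:
        raise ValueError("noise_power must be > 0")
    shape = images[0].intensity.shape
    for im in images:
        if im.intensity.shape != shape:
            raise ValueError("all images must share a shape")
    stack = np.stack([im.intensity for im in images])  # (n, rows, cols)
    mean = stack.mean(axis=(0, 2))
    power = stack.var(axis=(0, 2))
    return ElevationProfile(
        elevation=images[0].elevations(),
        mean_intensity=mean,
        mean_power=power,
        snr=power / noise_power,
        noise_power=float(noise_power),
    )


def compute_snr_asymmetry(profile: ElevationProfile, window_height: int, y: int) -> float:
    """Vertical SNR asymmetry of a window centred on row ``y``.

    asym(y) = (m_up - m_down) / (m_up + m_down), where m_up and m_down
    are the sums of the SNR profile above and below the window midline.
    For even window heights the midline lies between the two central
    rows, so both halves receive ``window_height // 2`` rows; for odd
    heights the central row is excluded from both halves.
    """
    n = len(profile.snr)
    half = window_height // 2
    top = y - (window_height - 1) // 2
    bottom = top + window_height  # exclusive
    if top < 0 or bottom > n:
        raise ValueError("window does not fit inside the profile")
    rows = profile.snr[top:bottom]
    m_up = rows[:half].sum()
    m_down = rows[window_height - half:].sum()
    total = m_up + m_down
    if total <= 0:
        raise ValueError("zero total SNR in window; asymmetry undefined")
    return float((m_up - m_down) / total)
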