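"""Retina-wide population statistics.

Aligns cells to a common retinal frame (optic nerve at the origin,
+y ventral, +x nasal, left retinas mirrored), bins RF metrics in 1D
and 2D, tests dorsoventral trends (two-sample Kolmogorov-Smirnov on
binned values, joint linear regression on standardized position),
clusters temporal RFs with a diagonal-covariance Gaussian mixture
selected at the BIC elbow, computes the mosaic tiling index, and
extracts saccades and their orientation-tuning statistic from eye
traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.signal import medfilt
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .dogfit import Gaussian2D
from .simulate import EyeTrace

__all__ = [
    "BinnedMap",
    "TrendStats",
    "GMMResult",
    "SaccadeStats",
    "align_retina",
    "flip_on_center_rfs",
    "bin_metric_2d",
    "bin_metric_1d",
    "ks_dorsoventral",
    "regression_weights",
    "cluster_temporal_rfs",
    "tiling_index",
    "detect_saccades",
    "saccade_orientation_tuning",
]


def align_retina(
    cells: pd.DataFrame,
    optic_nerve_xy: tuple[float, float],
    ventral_direction_deg: float,
    side: str = "right",
    rf_stacks: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, list[np.ndarray]]:
    """Rigidly map recorded coordinates onto the common retinal frame.

    Cells (columns ``x_um``, ``y_um``) are translated so the optic
    nerve sits at the origin and rotated so the direction given by
    ``ventral_direction_deg`` (angle of the ventral axis in the
    recording frame, degrees CCW from +x) maps onto +y.  Left retinas
    are mirrored in x so +x is nasal for every retina.  Attached RF
    crops, if given, are rotated/mirrored consistently (nearest-
    neighbour resampling about the crop centre).
    """
    if optic_nerve_xy is None:
        raise ValueError("optic nerve position is required")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    out = cells.copy()
    x = out["x_um"].to_numpy(dtype=float) - optic_nerve_xy[0]
    y = out["y_um"].to_numpy(dtype=float) - optic_nerve_xy[1]
    # rotate so that the ventral direction maps to +y
    phi = np.deg2rad(90.0 - ventral_direction_deg)
    ct, st = np.cos(phi), np.sin(phi)
    xr = ct * x - st * y
    yr = st * x + ct * y
    if side == "left":
        xr = -xr
    out["x_um"], out["y_um"] = xr, yr
    out["side"] = side
    out["mirrored"] = side == "left"
    if rf_stacks is None:
        return out
    rotated = [_transform_rf(a, phi, mirror=(side == "left")) for a in rf_stacks]
    return out, rotated


def _transform_rf(rf: np.ndarray, phi: float, mirror: bool) -> np.ndarray:
    """Rotate a (H, W[, L]) RF crop about its centre by ``phi`` and
    optionally mirror the x axis (nearest-neighbour)."""
    from scipy.ndimage import rotate
    out = rotate(rf, np.rad2deg(phi), axes=(1, 0), reshape=False, order=0,
                 mode="constant", cval=0.0)
    if mirror:
        out = out[:, ::-1].copy()
    return out


def flip_on_center_rfs(cells: pd.DataFrame,
                       rf2d_values: Sequence[np.ndarray] | None = None
                       ) -> pd.DataFrame | tuple[pd.DataFrame, list[np.ndarray]]:
    """Unify polarity: flip ON-center RFs so all centers are negative.

    Cells with positive fitted center amplitude (``g1_amp``) have their
    amplitudes (and attached RF maps) negated; sign-symmetric summary
    metrics are untouched.
    """
    out = cells.copy()
    flip = out["g1_amp"].to_numpy(dtype=float) > 0
    out.loc[flip, "g1_amp"] = -out.loc[flip, "g1_amp"]
    if "g2_amp" in out.columns:
        out.loc[flip, "g2_amp"] = -out.loc[flip, "g2_amp"]
    out["flipped"] = flip
    if rf2d_values is None:
        return out
    flipped_maps = [(-a if f else a) for a, f in zip(rf2d_values, flip)]
    return out, flipped_maps


@dataclass
class BinnedMap:
    bin_edges: tuple[np.ndarray, ...]  # one array per axis
    mean: np.ndarray  # per-bin mean metric (NaN where below min_count)
    count: np.ndarray
    min_count: int

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.bin_edges)


def bin_metric_2d(cells: pd.DataFrame, metric: str, bin_um: float = 50.0,
                  min_count: int = 5, extent_um: float = 1500.0) -> BinnedMap:
    """Mean of ``metric`` on a square grid over +/-``extent_um``;
    bins with fewer than ``min_count`` cells carry NaN."""
    if bin_um <= 0:
        raise ValueError("bin size must be positive")
    edges = np.arange(-extent_um, extent_um + bin_um / 2, bin_um)
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    v = cells[metric].to_numpy(dtype=float)
    count, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    total, _, _ = np.histogram2d(x, y, bins=(edges, edges), weights=v)
    with np.errstate(invalid="ignore"):
        mean = total / count
    mean[count < min_count] = np.nan
    return BinnedMap(bin_edges=(edges, edges), mean=mean, count=count.astype(int),
                     min_count=min_count)


def bin_metric_1d(cells: pd.DataFrame, metric: str, axis: str = "y_um",
                  n_bins: int = 6) -> BinnedMap:
    """Mean of ``metric`` in ``n_bins`` equal-width bins spanning the
    group's coordinate range along ``axis``."""
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    pos = cells[axis].to_numpy(dtype=float)
    lo, hi = pos.min(), pos.max()
    if hi <= lo:
        raise ValueError("degenerate coordinate range")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
    v = cells[metric].to_numpy(dtype=float)
    count = np.bincount(idx, minlength=n_bins)
    total = np.bincount(idx, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = total / count
    mean[count == 0] = np.nan
    return BinnedMap(bin_edges=(edges,), mean=mean, count=count, min_count=1)


@dataclass
class TrendStats:
    ks_statistic: float
    ks_p: float
    beta_elevation: float
    beta_azimuth: float


def ks_dorsoventral(ventral: np.ndarray, dorsal: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (exact for small n)."""
    ventral = np.asarray(ventral, dtype=float)
    dorsal = np.asarray(dorsal, dtype=float)
    ventral = ventral[np.isfinite(ventral)]
    dorsal = dorsal[np.isfinite(dorsal)]
    if len(ventral) < 2 or len(dorsal) < 2:
        raise ValueError("each sample needs at least two values")
    method = "exact" if max(len(ventral), len(dorsal)) <= 25 else "asymp"
    res = stats.ks_2samp(ventral, dorsal, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def regression_weights(cells: pd.DataFrame, metric: str) -> tuple[float, float]:
    """Joint OLS weights of the metric on standardized elevation (y) and
    azimuth (x) coordinates: (beta_elevation, beta_azimuth)."""
    if len(cells) < 3:
        raise ValueError("need at least three cells")
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate positions")
    X = np.column_stack([(y - y.mean()) / y.std(), (x - x.mean()) / x.std()])
    X = sm.add_constant(X)
    v = cells[metric].to_numpy(dtype=float)
    fit = sm.OLS(v, X).fit()
    return float(fit.params[1]), float(fit.params[2])


@dataclass
class GMMResult:
    n_components_grid: np.ndarray
    bic_curve: np.ndarray
    chosen_k: int
    memberships: np.ndarray
    responsibilities: np.ndarray
    pca_dims: int


def cluster_temporal_rfs(profiles: np.ndarray, pca_dims: int = 10,
                         k_grid: Sequence[int] = range(1, 11),
                         seed: int = 0, n_init: int = 10,
                         chosen_k: int | None = None) -> GMMResult:
    """PCA + diagonal-covariance GMM over a grid of cluster counts.

    Profiles (n_cells, n_samples) are reduced to ``pca_dims`` principal
    components; for each k a diagonal-covariance mixture is EM-fitted
    (k-means++ init, ``n_init`` restarts, 1e-6 variance floor).  The
    cluster count is chosen at the BIC-curve elbow (maximum discrete
    second difference; interior grid points only), unless ``chosen_k``
    overrides it.
    """
    profiles = np.asarray(profiles, dtype=float)
    k_grid = np.asarray(list(k_grid), dtype=int)
    if k_grid.max() > profiles.shape[0]:
        raise ValueError("k exceeds the number of profiles")
    dims = min(pca_dims, profiles.shape[1], profiles.shape[0])
    Z = PCA(n_components=dims, random_state=seed).fit_transform(profiles)
    models, bics = [], []
    for k in k_grid:
        gm = GaussianMixture(n_components=int(k), covariance_type="diag",
                             reg_covar=1e-6, n_init=n_init,
                             init_params="k-means++", random_state=seed)
        gm.fit(Z)
        models.append(gm)
        bics.append(gm.bic(Z))
    bics = np.asarray(bics)
    if chosen_k is None:
        if len(k_grid) >= 3:
            d2 = bics[2:] - 2 * bics[1:-1] + bics[:-2]
            chosen_k = int(k_grid[1 + int(np.argmax(d2))])
        else:
            chosen_k = int(k_grid[int(np.argmin(bics))])
    best = models[int(np.nonzero(k_grid == chosen_k)[0][0])]
    resp = best.predict_proba(Z)
    return GMMResult(n_components_grid=k_grid, bic_curve=bics,
                     chosen_k=int(chosen_k), memberships=resp.argmax(axis=1),
                     responsibilities=resp, pca_dims=dims)


def tiling_index(ellipses: Sequence[Gaussian2D], pitch_um: float = 1.0,
                 n_sd: float = 2.0) -> float:
    """TI = Area(union of RF centers) / sum of individual areas.

    RF centers are the ``n_sd``-s.d. contours of the fitted center
    Gaussians; areas are measured by rasterizing all ellipses on a
    common grid at ``pitch_um`` resolution, so identical ellipses give
    exactly 1/K and disjoint ones exactly 1.
    """
    if len(ellipses) == 0:
        raise ValueError("need at least one ellipse")
    for g in ellipses:
        if g.sigma_x <= 0 or g.sigma_y <= 0:
            raise ValueError("zero-area ellipse")
    pad = n_sd * max(max(g.sigma_x, g.sigma_y) for g in ellipses) + 2 * pitch_um
    xs = [g.m_x for g in ellipses]
    ys = [g.m_y for g in ellipses]
    gx = np.arange(min(xs) - pad, max(xs) + pad, pitch_um)
    gy = np.arange(min(ys) - pad, max(ys) + pad, pitch_um)
    X, Y = np.meshgrid(gx + pitch_um / 2, gy + pitch_um / 2)
    union = np.zeros(X.shape, dtype=bool)
    total = 0.0
    for g in ellipses:
        inside = g.quadratic_form(X, Y) <= n_sd ** 2
        union |= inside
        total += inside.sum()
    if total == 0:
        raise ValueError("ellipses cover no raster pixels; decrease pitch")
    return float(union.sum() / total)


@dataclass
class SaccadeStats:
    times: np.ndarray
    amplitudes_deg: np.ndarray  # r_t
    directions_deg: np.ndarray  # alpha_t
    preferred_orientation_deg: float  # alpha_bar
    tuning: float  # r_bar in [0, 1]


def detect_saccades(eye: EyeTrace, median_window_s: float = 0.7,
                    min_speed_deg_s: float = 45.0, min_amp_deg: float = 3.0,
                    min_interval_s: float = 0.25) -> pd.DataFrame:
    """Detect saccades on a median-filtered eye-position trace.

    Fast-position-change events are taken where the 2D speed of the
    median-filtered trace exceeds ``min_speed_deg_s``; contiguous
    supra-threshold samples form one event whose amplitude/direction
    are measured from the positions just before and after it.  Events
    below ``min_amp_deg`` or closer than ``min_interval_s`` to the
    previous accepted event are rejected.
    """
    fs = eye.sample_hz
    if min_speed_deg_s * (1.0 / fs) > 30.0:
        raise ValueError("sampling rate too low for the speed threshold")
    win = int(round(median_window_s * fs))
    if win % 2 == 0:
        win += 1
    az = medfilt(eye.azimuth, win)
    el = medfilt(eye.elevation, win)
    speed = np.hypot(np.diff(az), np.diff(el)) * fs
    fast = speed > min_speed_deg_s
    events = []
    i = 0
    n = len(fast)
    guard = max(int(round(0.05 * fs)), 1)  # samples flanking the fast segment
    last_t = -np.inf
    while i < n:
        if fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            pre = max(i - guard, 0)
            post = min(j + 1 + guard, len(az) - 1)
            dx = az[post] - az[pre]
            dy = el[post] - el[pre]
            amp = float(np.hypot(dx, dy))
            t = float(eye.time[i])
            if amp >= min_amp_deg and t - last_t >= min_interval_s:
                events.append({
                    "time": t,
                    "amplitude_deg": amp,
                    "direction_deg": float(np.degrees(np.arctan2(dy, dx)) % 360.0),
                })
                last_t = t
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(events, columns=["time", "amplitude_deg", "direction_deg"])


def saccade_orientation_tuning(saccades: pd.DataFrame) -> SaccadeStats:
    """Amplitude-weighted circular orientation statistics on doubled angles.

    alpha_bar = 0.5 * arg[sum_t r_t exp(2 i alpha_t)];
    r_bar = |sum_t r_t exp(2 i alpha_t)| / sum_t r_t.
    Doubling the angles makes opposite directions count as one
    orientation, so purely horizontal saccades give r_bar = 1.
    """
    r = saccades["amplitude_deg"].to_numpy(dtype=float)
    a = np.deg2rad(saccades["direction_deg"].to_numpy(dtype=float))
    if len(r) == 0 or r.sum() <= 0:
        raise ValueError("need at least one saccade with positive amplitude")
    z = np.sum(r * np.exp(2j * a))
    alpha_bar = float(np.degrees(0.5 * np.angle(z)) % 180.0)
    r_bar = float(np.abs(z) / r.sum())
    return SaccadeStats(times=saccades["time"].to_numpy(dtype=float),
                        amplitudes_deg=r, directions_deg=np.degrees(a) % 360.0,
                        preferred_orientation_deg=alpha_bar, tuning=r_bar)
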