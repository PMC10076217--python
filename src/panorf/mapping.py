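"""Receptive-field estimation from deconvolved traces and shifting
white noise: calcium-triggered average with population subtraction,
normalization, localization, 1-mm crop and SNR-based quality control.

The estimator for neuron i at latency tau and pixel (x, y) is

    RF(i,x,y,tau) = sum_t s(x,y,t-tau) * r(i,t)
                  - sum_t s(x,y,t-tau) * pop(t)

where pop(t) is the population-mean response (optionally the raw sum);
the second term removes the residual stimulus distribution and any
slow drift common to all neurons.  The stimulus is evaluated by
zero-order hold (the last frame before t-tau) and the latency grid
advances in 0.025 s steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from .simulate import ShiftingNoiseStimulus

__all__ = [
    "SpatiotemporalRF",
    "TraceSet",
    "default_latency_grid",
    "compute_dff",
    "estimate_rf",
    "normalize_rf",
    "locate_rf",
    "crop_rf",
    "compute_rf_snr",
    "filter_rfs",
]

LATENCY_STEP_S = 0.025  # 40 Hz latency grid
SNR_CAP_DB = 300.0


def default_latency_grid(t_min: float = -0.5, t_max: float = 1.5) -> np.ndarray:
    """Latency grid in 0.025 s increments covering [t_min, t_max]."""
    n0 = int(np.round(t_min / LATENCY_STEP_S))
    n1 = int(np.round(t_max / LATENCY_STEP_S))
    return np.arange(n0, n1 + 1) * LATENCY_STEP_S


@dataclass
class TraceSet:
    traces: np.ndarray  # (N, T) nonnegative deconvolved responses
    sample_hz: float

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if self.traces.shape[0] < 1:
            raise ValueError("need at least one trace")


@dataclass
class SpatiotemporalRF:
    """Estimated RF(x, y, tau) for one neuron, plus location/quality state."""

    values: np.ndarray  # (H, W, L)
    latencies: np.ndarray  # (L,) seconds
    px_um: float
    cell_id: int = 0
    mask: np.ndarray | None = None  # (H, W) True where valid
    normalized: bool = False
    p_var: tuple[int, int] | None = None  # (row, col)
    t_var: int | None = None  # latency index
    snr_db: float | None = None
    snr_capped: bool = False

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.values.shape[:2], dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def compute_dff(F: np.ndarray, sample_hz: float, window_s: float = 20.0,
                percentile: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """dF/F with a sliding-percentile baseline.

    The baseline at each time point is the ``percentile``-th percentile
    of F in a ``window_s`` window centred on it (window clipped at the
    trace edges).  Returns (dff, degenerate) where ``degenerate`` flags
    samples whose baseline is non-positive (dff set to 0 there).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    win = int(round(window_s * sample_hz))
    if win >= F.shape[1]:
        raise ValueError("window must be shorter than the trace")
    win = max(win, 1)
    baseline = percentile_filter(F, percentile, size=(1, win), mode="nearest")
    degenerate = baseline <= 0
    safe = np.where(degenerate, 1.0, baseline)
    dff = (F - baseline) / safe
    dff[degenerate] = 0.0
    return dff, degenerate


def estimate_rf(
    traces: TraceSet,
    stimulus: ShiftingNoiseStimulus,
    latencies: np.ndarray | None = None,
    population_term: str = "mean",
    cell_ids: Sequence[int] | None = None,
) -> list[SpatiotemporalRF]:
    """Calcium-triggered average with population subtraction.

    ``population_term``: "mean" (default) couples the stimulus with the
    population-mean response (including neuron i itself); "sum" uses the
    raw sum over neurons as printed; "none" disables the correction.
    """
    if latencies is None:
        latencies = default_latency_grid()
    latencies = np.asarray(latencies, dtype=float)
    R = traces.traces  # (N, T)
    N, T = R.shape
    t_samples = np.arange(T) / traces.sample_hz
    if np.max(np.abs(latencies)) >= t_samples[-1]:
        raise ValueError("latency grid exceeds the recording span")
    if population_term == "mean":
        pop = R.mean(axis=0)
    elif population_term == "sum":
        pop = R.sum(axis=0)
    elif population_term == "none":
        pop = np.zeros(T)
    else:
        raise ValueError("population_term must be 'mean', 'sum' or 'none'")
    Rc = R - pop[None, :]

    H, W = stimulus.field_shape
    F = stimulus.n_frames
    frames_flat = stimulus.frames.reshape(F, -1).astype(np.float64)
    out = np.empty((N, H * W, len(latencies)))
    duration = stimulus.duration_s
    # the stimulus is constant within a frame, so the sum over samples
    # collapses to per-frame accumulated weights followed by one matrix
    # product per latency
    for li, tau in enumerate(latencies):
        t_shift = t_samples - tau
        valid = (t_shift >= 0) & (t_shift < duration)
        Wf = np.zeros((N, F))
        if np.any(valid):
            idx = stimulus.frame_index_at(t_shift[valid])  # non-decreasing
            uniq, first = np.unique(idx, return_index=True)
            Wf[:, uniq] = np.add.reduceat(Rc[:, valid], first, axis=1)
        out[:, :, li] = Wf @ frames_flat
    ids = list(cell_ids) if cell_ids is not None else list(range(N))
    return [
        SpatiotemporalRF(values=out[i].reshape(H, W, len(latencies)),
                         latencies=latencies.copy(), px_um=stimulus.px_um,
                         cell_id=ids[i])
        for i in range(N)
    ]


def normalize_rf(rf: SpatiotemporalRF,
                 baseline_before: float = 0.0) -> SpatiotemporalRF:
    """Normalize to [-1, 1]: subtract the mean over latencies tau < 0,
    divide by the maximum absolute value of the entire RF.

    ``baseline_before`` tightens the baseline window to tau <
    ``baseline_before``.  With a zero-order-hold stimulus, latencies
    less negative than one stimulus frame period still index the frame
    the response was driven by, so a baseline over all tau < 0 is
    contaminated by the RF itself; passing e.g. -0.175 (one 6-Hz frame)
    restricts the mean to genuinely pre-stimulus lags.
    """
    pre = rf.latencies < baseline_before
    if not np.any(pre):
        raise ValueError("latency grid must contain baseline samples")
    vals = rf.values[rf.mask]
    baseline = float(vals[:, pre].mean())
    shifted = rf.values - baseline
    m = float(np.abs(shifted[rf.mask]).max())
    if m == 0:
        raise ValueError("all-zero RF cannot be normalized")
    return SpatiotemporalRF(values=shifted / m, latencies=rf.latencies.copy(),
                            px_um=rf.px_um, cell_id=rf.cell_id,
                            mask=rf.mask.copy(), normalized=True,
                            p_var=rf.p_var, t_var=rf.t_var, snr_db=rf.snr_db,
                            snr_capped=rf.snr_capped)


def locate_rf(rf: SpatiotemporalRF) -> tuple[tuple[int, int], int]:
    """P_var (pixel of peak temporal variance) and T_var (latency of
    peak spatial variance); argmax ties break at the lowest flat index."""
    var_t = rf.values.var(axis=2)  # (H, W)
    var_t[~rf.mask] = -np.inf
    if np.all(~np.isfinite(var_t)) or np.nanmax(var_t) <= 0:
        raise ValueError("constant RF has no variance to locate")
    p_flat = int(np.argmax(var_t))
    p_var = tuple(int(v) for v in divmod(p_flat, rf.values.shape[1]))
    sp = rf.values[rf.mask]  # (n_valid, L)
    var_xy = sp.var(axis=0)
    t_var = int(np.argmax(var_xy))
    rf.p_var, rf.t_var = p_var, t_var
    return p_var, t_var


def crop_rf(rf: SpatiotemporalRF, p_var: tuple[int, int] | None = None,
            edge_um: float = 1000.0, pad: bool = True) -> SpatiotemporalRF:
    """Square crop of edge ``edge_um`` centred on P_var.

    Out-of-field regions are zero-padded and excluded via the validity
    mask; with ``pad=False`` an out-of-bounds crop raises.
    """
    if p_var is None:
        if rf.p_var is None:
            locate_rf(rf)
        p_var = rf.p_var
    H, W, L = rf.values.shape
    e = int(round(edge_um / rf.px_um))
    half = e // 2
    r0, c0 = p_var[0] - half, p_var[1] - half
    r1, c1 = r0 + e, c0 + e
    if (r0 < 0 or c0 < 0 or r1 > H or c1 > W) and not pad:
        raise ValueError("crop exceeds the field and padding is disabled")
    vals = np.zeros((e, e, L), dtype=rf.values.dtype)
    mask = np.zeros((e, e), dtype=bool)
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, H), min(c1, W)
    vals[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = rf.values[sr0:sr1, sc0:sc1]
    mask[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = rf.mask[sr0:sr1, sc0:sc1]
    out = SpatiotemporalRF(values=vals, latencies=rf.latencies.copy(),
                           px_um=rf.px_um, cell_id=rf.cell_id, mask=mask,
                           normalized=rf.normalized, t_var=rf.t_var,
                           snr_db=rf.snr_db, snr_capped=rf.snr_capped)
    out.p_var = (p_var[0] - r0, p_var[1] - c0)
    return out


def compute_rf_snr(rf: SpatiotemporalRF, p_var: tuple[int, int] | None = None,
                   exclusion_radius_um: float = 500.0) -> float:
    """Peak-to-noise ratio in dB.

    peak = max |RF|; noise power = mean squared RF value over pixels
    farther than ``exclusion_radius_um`` from P_var, across all
    latencies.  Zero noise power is capped at 300 dB and flagged.
    """
    if p_var is None:
        if rf.p_var is None:
            locate_rf(rf)
        p_var = rf.p_var
    H, W, _ = rf.values.shape
    rows, cols = np.indices((H, W))
    dist_um = np.hypot(rows - p_var[0], cols - p_var[1]) * rf.px_um
    far = (dist_um > exclusion_radius_um) & rf.mask
    if not np.any(far):
        raise ValueError("no pixels beyond the exclusion radius")
    noise_power = float(np.mean(rf.values[far] ** 2))
    peak = float(np.abs(rf.values[rf.mask]).max())
    if noise_power == 0:
        rf.snr_db = SNR_CAP_DB
        rf.snr_capped = True
        return rf.snr_db
    snr = 10.0 * np.log10(peak ** 2 / noise_power)
    rf.snr_db = float(min(snr, SNR_CAP_DB))
    rf.snr_capped = snr >= SNR_CAP_DB
    return rf.snr_db


def filter_rfs(rfs: Sequence[SpatiotemporalRF], threshold_db: float = 15.0
               ) -> tuple[list[SpatiotemporalRF], pd.DataFrame]:
    """Keep RFs with SNR strictly above ``threshold_db``; report all."""
    kept = []
    rows = []
    for rf in rfs:
        if rf.snr_db is None:
            compute_rf_snr(rf)
        keep = rf.snr_db > threshold_db
        if keep:
            kept.append(rf)
        rows.append({
            "cell_id": rf.cell_id,
            "p_var_row": None if rf.p_var is None else rf.p_var[0],
            "p_var_col": None if rf.p_var is None else rf.p_var[1],
            "t_var": rf.t_var,
            "snr_db": rf.snr_db,
            "kept": keep,
        })
    report = pd.DataFrame(rows)
    report.attrs["n_kept"] = len(kept)
    report.attrs["n_total"] = len(rfs)
    return kept, report
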