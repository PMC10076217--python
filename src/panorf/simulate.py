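"""Synthetic retina: shifting white-noise stimulus, ground-truth RGC
population with dorsoventral RF gradients, and noisy deconvolved-like
responses plus eye-position traces.

The stimulus is a binary checkerboard (100 um checkers) whose whole
grid is offset by random multiples of 10 um on both axes at every
6 Hz frame; the working pixel grid is 10 um/px so checkers are 10 px
and the shift quantum is exactly 1 px.  Cells are linear-nonlinear
units: a space-time separable filter (difference-of-Gaussians spatial
profile times a biphasic temporal kernel), half-wave rectification,
truncated-Gaussian additive noise, boxcar resampling to the 10 Hz
imaging rate.  Every generator is seed-deterministic so downstream
stages can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ShiftingNoiseStimulus",
    "GroundTruthCell",
    "GradientSpec",
    "SimulatedRecording",
    "EyeTrace",
    "make_stimulus",
    "make_population",
    "render_true_rf",
    "simulate_responses",
    "simulate_eye_trace",
]

STIM_HZ = 6.0
CHECKER_UM = 100.0
SHIFT_QUANTUM_UM = 10.0
DEFAULT_PX_UM = 10.0  # working grid: 10 um per pixel


@dataclass
class ShiftingNoiseStimulus:
    frames: np.ndarray  # (T, H, W) int8 in {-1, +1}
    shifts_px: np.ndarray  # (T, 2): (dy, dx) integer pixel offsets
    px_um: float = DEFAULT_PX_UM
    checker_um: float = CHECKER_UM
    shift_quantum_um: float = SHIFT_QUANTUM_UM
    update_hz: float = STIM_HZ
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.update_hz

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_index_at(self, t: float | np.ndarray) -> np.ndarray:
        """Zero-order hold: index of the last frame starting before time t."""
        idx = np.floor(np.asarray(t) * self.update_hz).astype(int)
        return np.clip(idx, 0, self.n_frames - 1)


def make_stimulus(
    duration_s: float,
    seed: int = 0,
    field_um: tuple[float, float] = (1000.0, 1000.0),
    px_um: float = DEFAULT_PX_UM,
    checker_um: float = CHECKER_UM,
    shift_quantum_um: float = SHIFT_QUANTUM_UM,
    shifting: bool = True,
) -> ShiftingNoiseStimulus:
    """Binary shifting-checkerboard stimulus at a 6 Hz update.

    Each frame draws i.i.d. fair-coin checkers and a uniform offset in
    {0, q, 2q, ...} up to one checker period per axis (q = 10 um).
    ``shifting=False`` pins all offsets to zero (static-checker control).
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if (checker_um / px_um) % 1 or (shift_quantum_um / px_um) % 1:
        raise ValueError("pixel grid must divide checker size and shift quantum")
    rng = np.random.default_rng(seed)
    T = round(duration_s * STIM_HZ)
    H = int(round(field_um[0] / px_um))
    W = int(round(field_um[1] / px_um))
    cpx = int(checker_um / px_um)  # checker edge in px
    qpx = int(shift_quantum_um / px_um)
    n_offsets = cpx // qpx  # offsets spanning one checker period
    nby, nbx = H // cpx + 2, W // cpx + 2  # checker lattice with margin for shifts
    frames = np.empty((T, H, W), dtype=np.int8)
    shifts = np.zeros((T, 2), dtype=int)
    for t in range(T):
        lattice = rng.integers(0, 2, size=(nby, nbx)).astype(np.int8) * 2 - 1
        big = np.repeat(np.repeat(lattice, cpx, axis=0), cpx, axis=1)
        if shifting:
            dy = int(rng.integers(0, n_offsets)) * qpx
            dx = int(rng.integers(0, n_offsets)) * qpx
        else:
            dy = dx = 0
        shifts[t] = (dy, dx)
        frames[t] = big[dy:dy + H, dx:dx + W]
    return ShiftingNoiseStimulus(frames=frames, shifts_px=shifts, px_um=px_um,
                                 checker_um=checker_um,
                                 shift_quantum_um=shift_quantum_um, seed=seed)


def default_temporal_kernel(n_taps: int = 4) -> np.ndarray:
    """Biphasic kernel on the stimulus frame grid (most recent tap first)."""
    k = np.zeros(n_taps)
    k[0] = 1.0
    if n_taps > 1:
        k[1] = -0.35
    return k


@dataclass
class GroundTruthCell:
    """True DoG receptive field of one simulated RGC.

    ``surround_offset_um`` displaces the surround Gaussian along the
    dorsoventral (y) axis, creating a vertically asymmetric surround.
    Amplitude signs follow the measurement convention: an OFF cell has a
    negative center and positive surround; ON is the mirror image.
    """

    cell_id: int
    position_um: tuple[float, float]  # (x, y); +y = ventral
    polarity: int  # +1 ON, -1 OFF
    center_amp: float
    surround_amp: float
    center_sigma_um: float
    surround_sigma_um: float
    surround_offset_um: float
    temporal_kernel: np.ndarray
    noise_level: float

    def __post_init__(self) -> None:
        if self.center_sigma_um <= 0 or self.surround_sigma_um <= 0:
            raise ValueError("sigmas must be > 0")
        if self.center_amp * self.surround_amp >= 0:
            raise ValueError("center and surround amplitudes must have opposite sign")

    # analytic summary metrics used as recovery ground truth
    def true_relative_surround(self) -> float:
        # ratio of integrated |surround| to integrated |center|
        cs = abs(self.center_amp) * 2 * np.pi * self.center_sigma_um ** 2
        ss = abs(self.surround_amp) * 2 * np.pi * self.surround_sigma_um ** 2
        return ss / cs

    def true_vertical_asymmetry(self) -> float:
        # (u - l)/(u + l) of the surround mass above/below the center row;
        # for a Gaussian surround displaced by delta along y the split is
        # Phi-based: u - l = erf-type asymmetry. "up" = dorsal = -y.
        from scipy.stats import norm
        delta = self.surround_offset_um
        # mass of surround Gaussian above the center row (y < 0 side)
        frac_up = norm.cdf(0.0, loc=delta, scale=self.surround_sigma_um)
        return float(2.0 * frac_up - 1.0)


@dataclass
class GradientSpec:
    """Maps dorsoventral position y (um) to true RF parameters.

    Defaults impose the measured-trend geometry: relative surround
    strength rising from dorsal to ventral, center size falling, and a
    ventrally increasing (dorsal-shifted) surround offset.  Setting all
    slopes to zero gives a homogeneous (null) retina.
    """

    surround_gain: Callable[[float], float] = lambda y: 0.35 + 0.25 * (y / 500.0)
    center_sigma_um: Callable[[float], float] = lambda y: 55.0 - 15.0 * (y / 500.0)
    surround_offset_um: Callable[[float], float] = lambda y: -60.0 * (y / 500.0)

    @staticmethod
    def null() -> "GradientSpec":
        return GradientSpec(
            surround_gain=lambda y: 0.35,
            center_sigma_um=lambda y: 55.0,
            surround_offset_um=lambda y: 0.0,
        )


def make_population(
    n_cells: int,
    gradient_spec: GradientSpec | None = None,
    seed: int = 0,
    extent_um: tuple[float, float] = (700.0, 700.0),
    on_fraction: float = 0.5,
    surround_sigma_factor: float = 2.2,
    center_amp: float = 1.0,
    noise_level: float = 0.5,
    kernel_taps: int = 4,
) -> list[GroundTruthCell]:
    """Scatter ``n_cells`` RGCs uniformly over a rectangle centred on the
    optic nerve, with DoG parameters given by the dorsoventral gradient."""
    if extent_um[0] <= 0 or extent_um[1] <= 0:
        raise ValueError("empty retinal extent")
    spec = gradient_spec or GradientSpec()
    rng = np.random.default_rng(seed)
    xs = rng.uniform(-extent_um[0] / 2, extent_um[0] / 2, size=n_cells)
    ys = rng.uniform(-extent_um[1] / 2, extent_um[1] / 2, size=n_cells)
    pols = np.where(rng.random(n_cells) < on_fraction, 1, -1)
    kernel = default_temporal_kernel(kernel_taps)
    cells = []
    for i in range(n_cells):
        y = float(ys[i])
        csig = float(spec.center_sigma_um(y))
        gain = float(spec.surround_gain(y))
        ssig = csig * surround_sigma_factor
        # surround_gain is the target relative surround strength (integrated
        # mass ratio); convert to a peak amplitude
        samp = gain * center_amp * csig ** 2 / ssig ** 2
        # measurement convention: OFF center negative, ON positive
        c_amp = center_amp * (1.0 if pols[i] > 0 else -1.0)
        s_amp = -samp * np.sign(c_amp)
        cells.append(GroundTruthCell(
            cell_id=i,
            position_um=(float(xs[i]), y),
            polarity=int(pols[i]),
            center_amp=c_amp,
            surround_amp=s_amp,
            center_sigma_um=csig,
            surround_sigma_um=ssig,
            surround_offset_um=float(spec.surround_offset_um(y)),
            temporal_kernel=kernel.copy(),
            noise_level=noise_level,
        ))
    return cells


def render_true_rf(cell: GroundTruthCell, stimulus: ShiftingNoiseStimulus,
                   origin_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Rasterize the cell's spatial DoG on the stimulus pixel grid.

    ``origin_um`` is the retinal coordinate of stimulus pixel (0, 0)
    (top-left); +y (ventral) increases with the stimulus row index.
    """
    H, W = stimulus.field_shape
    px = stimulus.px_um
    ys = origin_um[1] + px * (np.arange(H) + 0.5)
    xs = origin_um[0] + px * (np.arange(W) + 0.5)
    X, Y = np.meshgrid(xs, ys)
    cx, cy = cell.position_um
    dc2 = (X - cx) ** 2 + (Y - cy) ** 2
    ds2 = (X - cx) ** 2 + (Y - (cy + cell.surround_offset_um)) ** 2
    rf = (cell.center_amp * np.exp(-dc2 / (2 * cell.center_sigma_um ** 2))
          + cell.surround_amp * np.exp(-ds2 / (2 * cell.surround_sigma_um ** 2)))
    return rf


@dataclass
class SimulatedRecording:
    stimulus: ShiftingNoiseStimulus
    traces: np.ndarray  # (N, T_rec) nonnegative event-rate traces
    imaging_hz: float
    cells: list[GroundTruthCell]
    origin_um: tuple[float, float]
    seed: int

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]


def _boxcar_weights(n_frames: int, update_hz: float, imaging_hz: float,
                    n_out: int) -> np.ndarray:
    """(n_out, n_frames) overlap matrix averaging a zero-order-hold
    frame-rate signal over imaging bins [n/fs, (n+1)/fs)."""
    W = np.zeros((n_out, n_frames))
    frame_edges = np.arange(n_frames + 1) / update_hz
    for n in range(n_out):
        t0, t1 = n / imaging_hz, (n + 1) / imaging_hz
        f0 = max(int(np.floor(t0 * update_hz)), 0)
        f1 = min(int(np.ceil(t1 * update_hz)), n_frames)
        for f in range(f0, f1):
            lo = max(t0, frame_edges[f])
            hi = min(t1, frame_edges[f + 1])
            if hi > lo:
                W[n, f] = (hi - lo) * imaging_hz
    return W


def _boxcar_resample(frame_signal: np.ndarray, update_hz: float,
                     imaging_hz: float, n_out: int) -> np.ndarray:
    """Time-average a zero-order-hold frame-rate signal over imaging bins."""
    W = _boxcar_weights(frame_signal.shape[-1], update_hz, imaging_hz, n_out)
    return frame_signal @ W.T


def simulate_responses(
    cells: Sequence[GroundTruthCell],
    stimulus: ShiftingNoiseStimulus,
    imaging_hz: float = 10.0,
    seed: int = 0,
    origin_um: tuple[float, float] | None = None,
    rectify: bool = True,
    pre_noise: float = 0.75,
) -> SimulatedRecording:
    """Linear-nonlinear forward model producing deconvolved-like traces.

    Per cell: project each stimulus frame onto the rendered spatial RF,
    convolve the frame-rate projection with the cell's temporal kernel,
    add membrane-like Gaussian noise of s.d. ``pre_noise`` times the
    drive s.d., half-wave rectify, boxcar-resample to the imaging rate,
    then add truncated-Gaussian noise (``noise_level``, emulating
    deconvolution residuals) and clip at zero, so traces are nonnegative
    like deconvolved calcium events.  The pre-rectification noise
    dithers the nonlinearity: with a binary stimulus the few checkers
    under a small RF center make the drive coarsely discrete, and
    without dithering the rectified response's stimulus average is a
    visibly distorted version of the filter.  Set ``pre_noise=0`` and
    ``noise_level=0`` for the deterministic model the forward-model
    oracle checks.
    """
    H, W = stimulus.field_shape
    px = stimulus.px_um
    if origin_um is None:
        origin_um = (-W * px / 2.0, -H * px / 2.0)
    # footprint check
    for c in cells:
        x, y = c.position_um
        r = 2.0 * c.surround_sigma_um
        if (x - r < origin_um[0] or x + r > origin_um[0] + W * px
                or y - r < origin_um[1] or y + r > origin_um[1] + H * px):
            raise ValueError(f"cell {c.cell_id} RF footprint outside stimulus")
    rng = np.random.default_rng(seed)
    T = stimulus.n_frames
    n_out = int(np.floor(stimulus.duration_s * imaging_hz))
    frames_flat = stimulus.frames.reshape(T, -1).astype(np.float64)
    rf_mat = np.stack([render_true_rf(c, stimulus, origin_um).ravel()
                       for c in cells])
    proj = rf_mat @ frames_flat.T  # (N, T) frame-rate drive
    W = _boxcar_weights(T, stimulus.update_hz, imaging_hz, n_out)
    traces = np.empty((len(cells), n_out))
    for i, c in enumerate(cells):
        k = c.temporal_kernel
        drive = np.convolve(proj[i], k)[:T]  # causal: most recent tap first
        if pre_noise > 0:
            drive = drive + rng.normal(0.0, pre_noise * max(np.std(drive), 1e-12),
                                       size=T)
        rate = np.maximum(drive, 0.0) if rectify else drive
        resampled = rate @ W.T
        if c.noise_level > 0:
            scale = max(np.std(resampled), 1e-12)
            noise = rng.normal(0.0, c.noise_level * scale, size=n_out)
            resampled = resampled + noise
        traces[i] = np.maximum(resampled, 0.0) if rectify else resampled
    return SimulatedRecording(stimulus=stimulus, traces=traces,
                              imaging_hz=imaging_hz, cells=list(cells),
                              origin_um=origin_um, seed=seed)


@dataclass
class EyeTrace:
    time: np.ndarray  # s
    azimuth: np.ndarray  # deg, median-zeroed
    elevation: np.ndarray  # deg, median-zeroed
    true_saccades: list[tuple[float, float, float]]  # (time, amplitude, direction deg)
    sample_hz: float


def simulate_eye_trace(
    duration_s: float,
    saccade_rate_hz: float = 0.2,
    preferred_orientation_deg: float = 0.0,
    orientation_jitter_deg: float = 10.0,
    drift_sd_deg: float = 0.15,
    amplitude_range_deg: tuple[float, float] = (4.0, 15.0),
    sample_hz: float = 50.0,
    seed: int = 0,
) -> EyeTrace:
    """Drift plus step-like saccades with known times/amplitudes/directions.

    Saccades occur at Poisson times (>=1 s apart), alternate direction
    along the preferred orientation (with Gaussian orientation jitter),
    and complete within one sample so their peak speed far exceeds the
    detection threshold.  Position slowly relaxes back toward the origin
    between saccades, and the median position is re-zeroed at the end.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_hz))
    t = np.arange(n) / sample_hz
    drift = np.cumsum(rng.normal(0.0, drift_sd_deg / np.sqrt(sample_hz), size=(2, n)), axis=1)
    pos = drift.copy()

    true_saccades: list[tuple[float, float, float]] = []
    if saccade_rate_hz > 0:
        times = []
        tt = rng.exponential(1.0 / saccade_rate_hz)
        while tt < duration_s - 1.0:
            if not times or tt - times[-1] >= 1.0:
                times.append(tt)
                tt += rng.exponential(1.0 / saccade_rate_hz)
            else:
                tt = times[-1] + 1.0 + rng.exponential(1.0 / saccade_rate_hz)
        flip = 1.0
        for ts in times:
            amp = rng.uniform(*amplitude_range_deg)
            ori = preferred_orientation_deg + rng.normal(0.0, orientation_jitter_deg)
            direction = ori if flip > 0 else ori + 180.0
            flip = -flip
            idx = int(ts * sample_hz)
            step = amp * np.array([np.cos(np.deg2rad(direction)),
                                   np.sin(np.deg2rad(direction))])
            # instantaneous step, relaxing back with a 4-s time constant
            decay = np.exp(-(t[idx:] - t[idx]) / 4.0)
            pos[0, idx:] += step[0] * decay
            pos[1, idx:] += step[1] * decay
            true_saccades.append((float(t[idx]), float(amp), float(direction % 360.0)))
    pos[0] -= np.median(pos[0])
    pos[1] -= np.median(pos[1])
    return EyeTrace(time=t, azimuth=pos[0], elevation=pos[1],
                    true_saccades=true_saccades, sample_hz=sample_hz)
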