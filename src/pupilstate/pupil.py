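"""Pupil trace construction and conditioning.

Landmark-to-diameter conversion, eye-size normalization, TR binning,
variance normalization, a double-gamma HRF kernel family and causal
convolution, and Welch power spectral density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy.special import gammaln

__all__ = [
    "LandmarkSeries",
    "PupilTrace",
    "HRFKernel",
    "PSD",
    "diameter_from_landmarks",
    "bin_to_tr",
    "normalize_variance",
    "hrf_kernel",
    "hrf_peak_time",
    "hrf_shape_for_peak",
    "convolve_pupil",
    "welch_psd",
]

#: weight and fixed shape of the undershoot term of the HRF
UNDERSHOOT_WEIGHT = 0.3
UNDERSHOOT_SHAPE = 12.0


@dataclass(frozen=True)
class LandmarkSeries:
    """Per-frame coordinates of four pupil-edge points.

    ``points`` has shape ``(n_frames, 4, 2)``: points 1-2 span one chord,
    points 3-4 the other.
    """

    points: np.ndarray
    fps: float
    eye_size: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 3 or pts.shape[1:] != (4, 2):
            raise ValueError(f"points must be (n_frames, 4, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.eye_size <= 0:
            raise ValueError("eye_size must be positive")


@dataclass
class PupilTrace:
    """A sampled pupil diameter trace.

    ``normalized`` flags eye-size normalization (values then lie in [0, 1]).
    """

    values: np.ndarray
    dt: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.normalized and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("normalized trace must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class HRFKernel:
    """A unit-peak double-gamma hemodynamic response kernel on t >= 0."""

    a: float
    dt: float
    length: float
    values: np.ndarray


@dataclass(frozen=True)
class PSD:
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs[0] != 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must start at 0 and be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def peak_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.power))])


def diameter_from_landmarks(series: LandmarkSeries) -> PupilTrace:
    """Mean of the two chord lengths, divided by eye size.

    d = ( |p2 - p1| + |p4 - p3| ) / 2 / eye_size
    """
    pts = series.points
    if pts.shape[0] < 1:
        raise ValueError("need at least one frame")
    chord12 = np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
    chord34 = np.linalg.norm(pts[:, 3] - pts[:, 2], axis=1)
    d = (chord12 + chord34) / 2.0 / series.eye_size
    return PupilTrace(values=d, dt=1.0 / series.fps, normalized=bool(np.all(d <= 1)))


def bin_to_tr(trace: PupilTrace, tr: float) -> PupilTrace:
    """Average non-overlapping windows of ``round(tr/dt)`` samples.

    The trailing partial window is dropped; the output has dt = tr.
    """
    if tr < trace.dt:
        raise ValueError(f"tr {tr} must be >= trace dt {trace.dt}")
    win = int(round(tr / trace.dt))
    n_out = len(trace) // win
    if n_out == 0:
        raise ValueError("trace shorter than one binning window")
    binned = trace.values[: n_out * win].reshape(n_out, win).mean(axis=1)
    return PupilTrace(values=binned, dt=float(tr), normalized=trace.normalized)


def normalize_variance(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, variance 1 (population variance)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = values.std()
    if sd == 0:
        raise ValueError("zero-variance input cannot be variance normalized")
    return (values - values.mean()) / sd


def _hrf_closed_form(t: np.ndarray, a: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    main = np.exp((a - 1) * np.log(tp) - tp - gammaln(a))
    under = UNDERSHOOT_WEIGHT * np.exp(
        (UNDERSHOOT_SHAPE - 1) * np.log(tp) - tp - gammaln(UNDERSHOOT_SHAPE)
    )
    out[pos] = main - under
    return out


def hrf_kernel(a: float, dt: float = 1.0, length: float = 30.0) -> HRFKernel:
    """Double-gamma kernel f(t) = t^(a-1) e^-t / G(a) - 0.3 t^11 e^-t / G(12).

    Sampled at t = 0, dt, ..., length and rescaled to unit peak.  Requires
    a > 1 so the peak sits strictly inside t > 0.
    """
    if a <= 1:
        raise ValueError("a must be > 1 (peak would sit at the t=0 boundary)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if length < 20:
        raise ValueError("length must be >= 20 s to cover the undershoot")
    t = np.arange(0.0, length + dt / 2, dt)
    vals = _hrf_closed_form(t, a)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("kernel has no positive peak on the sampling grid")
    return HRFKernel(a=float(a), dt=float(dt), length=float(length), values=vals / peak)


def hrf_peak_time(a: float) -> float:
    """Numeric peak time of the closed-form kernel (dense grid + refinement)."""
    grid = np.linspace(1e-4, 25.0, 2501)
    t0 = grid[int(np.argmax(_hrf_closed_form(grid, a)))]
    res = optimize.minimize_scalar(
        lambda t: -_hrf_closed_form(np.array([t]), a)[0],
        bounds=(max(t0 - 0.02, 1e-6), t0 + 0.02),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def hrf_shape_for_peak(peak_s: float, a_max: float = 40.0) -> float:
    """Invert ``hrf_peak_time``: find a with the requested peak time (seconds)."""
    if peak_s <= 0:
        raise ValueError("peak time must be positive")
    lo, hi = 1.0 + 1e-6, a_max
    if hrf_peak_time(hi) < peak_s:
        raise ValueError(f"peak {peak_s}s not reachable with a <= {a_max}")
    return float(optimize.brentq(lambda a: hrf_peak_time(a) - peak_s, lo, hi))


def convolve_pupil(trace: PupilTrace, kernel: HRFKernel) -> PupilTrace:
    """Causal convolution truncated to the input length, then re-standardized."""
    if abs(kernel.dt - trace.dt) > 1e-12:
        raise ValueError(f"kernel dt {kernel.dt} != trace dt {trace.dt}")
    full = np.convolve(trace.values, kernel.values)[: len(trace)]
    return PupilTrace(values=normalize_variance(full), dt=trace.dt, normalized=False)


def welch_psd(values: np.ndarray, dt: float = 1.0, nfft: int = 512) -> PSD:
    """Welch estimate: 512-point DFT, Hann window, 50% overlap.

    Inputs shorter than the DFT length are handled as a single zero-padded
    segment.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 64:
        raise ValueError("need at least 64 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    fs = 1.0 / dt
    n = values.shape[0]
    if n < nfft:
        freqs, power = signal.welch(
            values, fs=fs, window="hann", nperseg=n, noverlap=0, nfft=nfft,
            detrend="constant",
        )
    else:
        freqs, power = signal.welch(
            values, fs=fs, window="hann", nperseg=nfft, noverlap=nfft // 2,
            nfft=nfft, detrend="constant",
        )
    return PSD(freqs=freqs, power=power)
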