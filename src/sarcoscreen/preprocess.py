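"""Signal conditioning and descriptive analyses for sEMG / strain recordings.

Covers per-trace normalization, active-window segmentation of MVC trials,
signal-to-noise ratio, median frequency (Welch PSD based) and an STFT
magnitude spectrogram.  All operations work on plain numpy arrays plus a
sampling rate; the :class:`Window` container carries enough metadata to
trace a value back to its recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Window",
    "Spectrogram",
    "normalize_trace",
    "moving_rms",
    "segment_active_windows",
    "compute_snr",
    "median_frequency",
    "stft_spectrogram",
    "bandpass_filter",
]


@dataclass
class Window:
    """A contiguous analysis window cut from one channel of a recording."""

    samples: np.ndarray
    sampling_rate: float
    source_channel: str = ""
    t1: float = 0.0
    t2: float = 0.0
    subject_id: str = ""
    trial: int = -1
    kind: str = "active"  # "active" (hold phase), "trial", "rest", ...

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a window needs at least 2 samples")
        if self.t2 <= self.t1:
            self.t1 = 0.0
            self.t2 = self.samples.size / self.sampling_rate

    @property
    def n(self) -> int:
        return int(self.samples.size)


@dataclass
class Spectrogram:
    time_bins: np.ndarray      # s
    frequency_bins: np.ndarray  # Hz
    magnitude: np.ndarray       # (time, frequency), linear units


def normalize_trace(series: np.ndarray) -> np.ndarray:
    """Min–max normalize a trace into [-1, 1], symmetric about its mean.

    The series is centred on its mean and divided by the maximum absolute
    deviation, so ``[-2, 0, 2] -> [-1, 0, 1]``.  A constant series maps to
    all zeros.  The map is idempotent on non-constant input.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    centred = x - x.mean()
    peak = np.max(np.abs(centred))
    if peak == 0:
        return np.zeros_like(x)
    return centred / peak


def moving_rms(x: np.ndarray, sampling_rate: float, width_s: float = 0.1) -> np.ndarray:
    """RMS envelope with a centred moving window (default 100 ms)."""
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(width_s * sampling_rate)))
    kernel = np.ones(w) / w
    power = np.convolve(x * x, kernel, mode="same")
    return np.sqrt(np.maximum(power, 0.0))


def segment_active_windows(
    recording,
    channel: str,
    threshold_factor: float = 3.0,
    envelope_width_s: float = 0.1,
    hold_fraction: float = 0.5,
    max_duration_s: float = 4.0,
) -> list[Window]:
    """Cut one active (contraction) window per MVC trial of a recording.

    The moving-RMS envelope of the chosen channel is compared against
    ``threshold_factor`` times its rest baseline (envelope level outside
    the trial intervals).  To clip the window to the hold phase — the
    ramps of a trapezoidal contraction also clear a noise-level baseline
    almost immediately — the threshold is additionally floored at
    ``hold_fraction`` of the trial's peak (95th-percentile) envelope, an
    envelope half-maximum estimate of the hold.  Inside each trial the
    region spanning the first to the last supra-threshold sample (robust
    to brief envelope dips mid-contraction) becomes the active window,
    centre-cropped to ``max_duration_s`` (the protocol hold length) so
    window duration — and with it the length-dependent features iEMG, WL,
    ZC and SSC — is comparable across trials and subjects; if
    the envelope never crosses the threshold a warning is emitted and the
    central 80 % of the trial is used as a fallback.
    """
    x = np.asarray(recording.channels[channel], dtype=float)
    fs = float(recording.sampling_rate)
    env = moving_rms(x, fs, envelope_width_s)

    rest_mask = np.ones(x.size, dtype=bool)
    for start, stop in recording.trial_boundaries:
        rest_mask[start:stop] = False
    baseline = np.median(env[rest_mask]) if rest_mask.any() else np.median(env)

    windows: list[Window] = []
    for trial_idx, (start, stop) in enumerate(recording.trial_boundaries):
        trial_env = env[start:stop]
        threshold = max(
            threshold_factor * baseline,
            hold_fraction * np.percentile(trial_env, 95),
        )
        above = trial_env > threshold
        run = _crossing_span(above)
        if run is None:
            warnings.warn(
                f"channel {channel!r} trial {trial_idx}: envelope never "
                f"exceeded {threshold_factor}x baseline; falling back to "
                "the central 80% of the trial",
                stacklevel=2,
            )
            margin = (stop - start) // 10
            lo, hi = start + margin, stop - margin
        else:
            lo, hi = start + run[0], start + run[1]
        max_len = int(round(max_duration_s * fs))
        if hi - lo > max_len:
            centre = (lo + hi) // 2
            lo = centre - max_len // 2
            hi = lo + max_len
        windows.append(
            Window(
                samples=x[lo:hi],
                sampling_rate=fs,
                source_channel=channel,
                t1=lo / fs,
                t2=hi / fs,
                subject_id=getattr(recording, "subject_id", ""),
                trial=trial_idx,
                kind="active",
            )
        )
    return windows


def _crossing_span(mask: np.ndarray) -> tuple[int, int] | None:
    """Half-open span from the first to the last True sample."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1]) + 1


def compute_snr(signal_window: np.ndarray, noise_window: np.ndarray) -> float:
    """Signal-to-noise ratio in dB: 20*log10(RMS_signal / RMS_noise)."""
    s = np.asarray(getattr(signal_window, "samples", signal_window), dtype=float)
    n = np.asarray(getattr(noise_window, "samples", noise_window), dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("signal and noise windows must be non-empty")
    rms_n = np.sqrt(np.mean(n * n))
    if rms_n == 0:
        raise ValueError("noise window has zero RMS; SNR undefined")
    rms_s = np.sqrt(np.mean(s * s))
    return float(20.0 * np.log10(rms_s / rms_n))


def welch_psd(
    x: np.ndarray, sampling_rate: float, segment_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann segments (default 1 s) and 50 % overlap."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, int(round(segment_s * sampling_rate)))
    return sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )


def median_frequency(
    window: Window | np.ndarray,
    sampling_rate: float | None = None,
    segment_s: float = 1.0,
) -> float:
    """Median frequency of a window's power spectrum, in Hz.

    The frequency f* at which the cumulative Welch PSD reaches half the
    total power, with linear interpolation between frequency bins.  This
    is the classic sEMG fatigue / fibre-composition statistic: slower
    motor-unit action potentials shift power downward and lower f*.
    """
    if isinstance(window, Window):
        x, fs = window.samples, window.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        x, fs = np.asarray(window, dtype=float), float(sampling_rate)
    if x.size < 64:
        raise ValueError("median frequency needs at least 64 samples")

    freqs, psd = welch_psd(x, fs, segment_s)
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        raise ValueError("zero total power; median frequency undefined")
    # cumulative power via trapezoids, then linear interpolation to 1/2
    cum = np.concatenate(
        ([0.0], np.cumsum(0.5 * (psd[1:] + psd[:-1]) * np.diff(freqs)))
    )
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half))
    if idx == 0:
        return float(freqs[0])
    f_lo, f_hi = freqs[idx - 1], freqs[idx]
    c_lo, c_hi = cum[idx - 1], cum[idx]
    frac = 0.0 if c_hi == c_lo else (half - c_lo) / (c_hi - c_lo)
    return float(f_lo + frac * (f_hi - f_lo))


def stft_spectrogram(
    series: np.ndarray,
    sampling_rate: float,
    window_s: float = 0.5,
    overlap: float = 0.75,
) -> Spectrogram:
    """Magnitude spectrogram via the short-time Fourier transform.

    Hann window of ``window_s`` seconds (default 0.5 s) with fractional
    ``overlap`` (default 75 %).  Magnitudes are linear units; the squared
    spectrogram is Parseval-consistent with windowed signal energy up to
    the window correction factor.
    """
    x = np.asarray(series, dtype=float)
    nperseg = int(round(window_s * sampling_rate))
    if nperseg < 32:
        raise ValueError("STFT window must span at least 32 samples")
    if x.size < nperseg:
        raise ValueError("series shorter than one STFT window")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, times, zxx = sps.stft(
        x, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), boundary=None, padded=False,
    )
    return Spectrogram(
        time_bins=times, frequency_bins=freqs, magnitude=np.abs(zxx).T
    )


def spectral_centroid(spec: Spectrogram) -> np.ndarray:
    """Per-frame power-weighted mean frequency of a spectrogram (Hz)."""
    power = spec.magnitude**2
    denom = power.sum(axis=1)
    denom[denom == 0] = np.nan
    return (power * spec.frequency_bins).sum(axis=1) / denom


def bandpass_filter(
    x: np.ndarray,
    sampling_rate: float,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> np.ndarray:
    """Optional zero-phase Butterworth band-pass (off by default upstream)."""
    nyq = sampling_rate / 2.0
    high_hz = min(high_hz, 0.99 * nyq)
    sos = sps.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
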