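"""Whitened Welch spectra, Morlet spectrograms, coherence, triggered spectrograms.

Whitening removes the 1/f trend by multiplying each power value by its
frequency; the frequency grid is set to 0.1 Hz by zero-padding (nfft = 10
x fs).  Event-triggered spectrograms use 40 ms Hann windows with 82%
overlap, are whitened per trial and averaged across anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .session import SignalTrace, extract_windows

MORLET_W0 = 6.0  # Morlet center parameter; cmor bandwidth/center below


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray
    params: dict

    def peak_freq(self) -> float:
        return float(self.freqs[np.argmax(self.power)])


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # time x freq
    params: dict


def welch_whitened_psd(
    trace: SignalTrace | np.ndarray,
    fs: float | None = None,
    window_s: float = 1.0,
    grid_hz: float = 0.1,
    whiten: bool = True,
) -> Spectrum:
    """Welch periodogram (1 s Hann segments, 50% overlap) times frequency.

    The raw Welch power is multiplied pointwise by frequency ("whitening"),
    which flattens a 1/f background and makes band-limited oscillations
    stand out.  Requires at least two segments of data.
    """
    x, fs = _as_array(trace, fs)
    nperseg = int(round(window_s * fs))
    if x.size < 2 * nperseg:
        raise ValueError(
            f"trace too short for Welch PSD: need >= {2 * nperseg} samples "
            f"({2 * window_s:g} s), got {x.size}"
        )
    nfft = int(round(fs / grid_hz))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, nfft=nfft)
    power = p * f if whiten else p
    return Spectrum(f, power, {
        "window_s": window_s, "overlap": 0.5, "nfft": nfft, "whitened": whiten,
    })


def coherence(
    x: SignalTrace | np.ndarray,
    y: SignalTrace | np.ndarray,
    fs: float | None = None,
    window_s: float = 1.0,
    grid_hz: float = 0.1,
) -> Spectrum:
    """Magnitude-squared coherence with the Welch segmentation above."""
    xa, fsx = _as_array(x, fs)
    ya, fsy = _as_array(y, fs)
    if xa.size != ya.size or fsx != fsy:
        raise ValueError("x and y must share fs and length")
    nperseg = int(round(window_s * fsx))
    nfft = int(round(fsx / grid_hz))
    f, c = sps.coherence(xa, ya, fs=fsx, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2, nfft=nfft)
    return Spectrum(f, c, {"window_s": window_s, "kind": "coherence"})


def wavelet_spectrogram(
    trace: SignalTrace | np.ndarray,
    freqs: np.ndarray,
    fs: float | None = None,
    w0: float = MORLET_W0,
) -> Spectrogram:
    """Complex Morlet wavelet transform magnitude per frequency.

    ``w0`` is the Morlet center parameter (time-frequency trade-off);
    implemented with PyWavelets' ``cmor`` wavelet using bandwidth fb = 2
    and center frequency fc = w0 / (2 pi).
    """
    x, fs = _as_array(trace, fs)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2) or np.any(freqs <= 0):
        raise ValueError("freqs must lie in (0, fs/2)")
    fc = w0 / (2 * np.pi)
    wavelet = f"cmor2.0-{fc:.6f}"
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    mag = np.abs(coefs).T  # time x freq
    return Spectrogram(np.arange(x.size) / fs, freqs, mag, {"w0": w0})


def triggered_spectrogram(
    trace: SignalTrace | np.ndarray,
    anchors: np.ndarray,
    fs: float | None = None,
    span_s: float = 0.5,
    window_s: float = 0.04,
    overlap: float = 0.82,
    grid_hz: float = 0.1,
    max_freq: float | None = 130.0,
) -> Spectrogram:
    """Anchor-averaged whitened short-time spectrogram.

    For each usable anchor the ``span_s`` window following it is cut out
    and a Hann STFT (``window_s`` segments, ``overlap`` fractional
    overlap, 0.1 Hz zero-padded grid) is computed; individual spectrograms
    are whitened (x f) and averaged.  ``max_freq`` truncates the stored
    frequency axis (None keeps everything up to Nyquist).
    """
    x, fs = _as_array(trace, fs)
    windows, kept = extract_windows(x, np.asarray(anchors), (0.0, span_s), fs=fs)
    if windows.shape[0] == 0:
        raise ValueError("no usable anchors (all too close to the edges)")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    nfft = int(round(fs / grid_hz))
    f, tt, _ = sps.spectrogram(windows[0], fs=fs, window="hann", nperseg=nperseg,
                               noverlap=noverlap, nfft=nfft)
    fsel = slice(None) if max_freq is None else f <= max_freq
    acc = None
    for w in windows:
        _, _, p = sps.spectrogram(w, fs=fs, window="hann", nperseg=nperseg,
                                  noverlap=noverlap, nfft=nfft)
        p = (p[fsel, :].T) * f[fsel]
        acc = p if acc is None else acc + p
    return Spectrogram(tt, f[fsel], acc / windows.shape[0], {
        "window_s": window_s, "overlap": overlap, "n_anchors": int(windows.shape[0]),
        "dropped": int((~kept).sum()),
    })


def _as_array(trace, fs):
    if isinstance(trace, SignalTrace):
        return trace.samples, trace.fs
    if fs is None:
        raise ValueError("fs required for bare arrays")
    return np.asarray(trace, dtype=float), fs
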