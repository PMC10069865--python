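"""Laminar gamma-triggered averages, current source density, and the
induced/evoked amplitude decomposition with the phase-resetting index.

CSD at interior site B with neighbours A and C is the second spatial
difference ``-A + 2B - C``; the outermost sites are reported as NaN.

For a band and a set of trial anchors:

* *induced* amplitude = average over trials of each trial's Hilbert
  envelope (survives trial-to-trial carrier-phase jitter);
* *evoked* amplitude = Hilbert envelope of the average filtered trial
  (survives only if the carrier phase is reset at each trial);
* the phase-resetting index is the inter-trial coherence (ITC): the
  per-timepoint magnitude of the mean unit phasor of the band phase
  across trials, in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .coupling import band_phase_amplitude
from .session import Session, extract_windows


@dataclass
class LaminarAverage:
    """Channels x time gamma-triggered mean LFP around envelope peaks."""

    lfp_avg: np.ndarray      # channels x time
    csd: np.ndarray          # channels x time; edge channels NaN
    lags_s: np.ndarray
    trigger_count: int
    band: tuple
    depths_um: np.ndarray | None = None


@dataclass
class TriggeredAmplitude:
    band: tuple
    lags_s: np.ndarray
    induced: np.ndarray
    evoked: np.ndarray
    itc: np.ndarray
    n_trials: int


def csd_operator(profile: np.ndarray) -> np.ndarray:
    """-A + 2B - C along the channel axis; outer channels NaN."""
    out = np.full_like(profile, np.nan, dtype=float)
    out[1:-1] = -profile[:-2] + 2.0 * profile[1:-1] - profile[2:]
    return out


def gamma_peak_triggers(
    session: Session,
    band: tuple[float, float] = (30.0, 50.0),
    ref_channel: int = 0,
    threshold_pct: float = 90.0,
    refractory_s: float = 0.05,
) -> np.ndarray:
    """Times of gamma-amplitude peaks on the reference channel.

    Local maxima of the band envelope above its ``threshold_pct``-th
    percentile, at least ``refractory_s`` apart.
    """
    bs = band_phase_amplitude(session.lfp[ref_channel], band)
    env = bs.amplitude.copy()
    env[~bs.valid_mask] = 0.0
    height = np.percentile(env[bs.valid_mask], threshold_pct)
    peaks, _ = sps.find_peaks(env, height=height,
                              distance=int(refractory_s * session.fs))
    return peaks / session.fs


def csd_profile(
    session: Session,
    band: tuple[float, float] = (30.0, 50.0),
    ref_channel: int = 0,
    epoch_s: float = 0.05,
    threshold_pct: float = 90.0,
) -> LaminarAverage:
    """Gamma-triggered laminar LFP average and its CSD.

    Epochs of +-``epoch_s`` around each envelope peak of the reference
    channel are averaged on every channel; the CSD is the second spatial
    difference of the average.
    """
    if len(session.lfp) < 3:
        raise ValueError("CSD needs at least 3 laminar channels")
    triggers = gamma_peak_triggers(session, band, ref_channel, threshold_pct)
    if triggers.size == 0:
        raise ValueError("no gamma-amplitude peaks found")
    span = (-epoch_s, epoch_s)
    rows = []
    count = None
    for tr in session.lfp:
        w, kept = extract_windows(tr.samples, triggers, span, fs=session.fs)
        rows.append(w.mean(axis=0))
        count = int(w.shape[0])
    lfp_avg = np.stack(rows)
    lags = span[0] + np.arange(lfp_avg.shape[1]) / session.fs
    depths = np.asarray([tr.depth_um for tr in session.lfp], dtype=float)
    return LaminarAverage(lfp_avg, csd_operator(lfp_avg), lags, count, band, depths)


def amplitude_decomposition(
    trace,
    band: tuple[float, float],
    anchors: np.ndarray,
    fs: float | None = None,
    span_s: float = 0.5,
) -> TriggeredAmplitude:
    """Induced and evoked amplitude plus ITC for anchored trials.

    The whole trace is band-filtered once (zero-phase FIR + Hilbert) and
    the per-trial phase/amplitude windows are cut from the result, so no
    per-trial filter edges contaminate the curves.
    """
    from .session import SignalTrace

    if isinstance(trace, SignalTrace):
        fs = trace.fs
    if fs is None:
        raise ValueError("fs required for bare arrays")
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    if anchors.size == 0:
        raise ValueError("no anchors given")
    if anchors.size < 10:
        warnings.warn("fewer than 10 anchors; induced/evoked estimates will be noisy")
    bs = band_phase_amplitude(trace, band, fs=fs)
    filtered = bs.amplitude * np.cos(bs.phase)
    span = (0.0, span_s)
    amp_w, _ = extract_windows(bs.amplitude, anchors, span, fs=fs)
    filt_w, _ = extract_windows(filtered, anchors, span, fs=fs)
    ph_w, _ = extract_windows(bs.phase, anchors, span, fs=fs)
    if amp_w.shape[0] == 0:
        raise ValueError("no usable anchors")
    induced = amp_w.mean(axis=0)
    mean_trace = filt_w.mean(axis=0)
    evoked = np.abs(sps.hilbert(mean_trace))
    itc = np.abs(np.mean(np.exp(1j * ph_w), axis=0))
    lags = np.arange(amp_w.shape[1]) / fs
    return TriggeredAmplitude(band, lags, induced, evoked, itc, int(amp_w.shape[0]))


def phase_resetting_index(
    trace,
    band: tuple[float, float],
    anchors: np.ndarray,
    fs: float | None = None,
    span_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-trial coherence curve; returns (lags_s, itc)."""
    anchors = np.atleast_1d(anchors)
    if anchors.size < 2:
        raise ValueError("need >= 2 anchors for an ITC estimate")
    res = amplitude_decomposition(trace, band, anchors, fs=fs, span_s=span_s)
    return res.lags_s, res.itc
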