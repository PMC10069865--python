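"""Band filtering, analytic phase/amplitude, and phase-amplitude coupling.

The coupling estimator is the entropy-based modulation index: the phase
series of a slow band is cut into 18 equal bins, the mean amplitude of a
fast band is computed per bin and normalized to a distribution ``p``, and

    MI = (Hmax - H) / Hmax,      Hmax = log(18),  H = -sum p log p.

MI is 0 for a phase-uniform amplitude and 1 when all amplitude falls in a
single phase bin.

Filtering follows the eegfilt convention: least-squares FIR with order
``3 * round(fs / lo)`` (capped at a third of the signal length), applied
forward and backward for zero phase.  Phase and amplitude come from the
Hilbert analytic signal; the cosine convention is used (phase 0 at the
band-signal peak).  The first and last filter-order samples are flagged
as edge-contaminated and excluded from coupling estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import SignalTrace, Session

N_PHASE_BINS = 18


@dataclass
class BandSignal:
    """Phase and amplitude of one band-filtered signal."""

    band: tuple
    phase: np.ndarray       # radians in (-pi, pi], cosine convention
    amplitude: np.ndarray   # Hilbert envelope, input units
    fs: float
    n_edge: int             # edge-contaminated samples at each end
    source: str = ""

    @property
    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.phase.size, dtype=bool)
        if self.n_edge > 0:
            m[: self.n_edge] = False
            m[-self.n_edge:] = False
        return m


@dataclass
class PhaseAmplitudeDistribution:
    """18-bin amplitude-by-phase distribution with its entropy and MI."""

    bin_edges: np.ndarray
    mean_amp: np.ndarray
    p: np.ndarray
    H: float
    Hmax: float
    MI: float

    @property
    def n_bins(self) -> int:
        return self.mean_amp.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class Comodulogram:
    phase_freqs: np.ndarray   # band centers, Hz
    amp_freqs: np.ndarray     # band centers, Hz
    mi: np.ndarray            # phase x amp matrix
    phase_source: str

    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_fir_bandpass(
    fs: float, lo: float, hi: float, n_samples: int, order: int | None = None
) -> np.ndarray:
    """Least-squares FIR band-pass taps (eegfilt order rule)."""
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi < fs/2")
    tw = 0.15  # fractional transition width, each side
    if order is None:
        # eegfilt rule, lengthened so the filter resolution fs/order also
        # covers narrow bands (10 Hz bands at 120 Hz) and the transition
        # regions (tw*lo can be well below fs/order at kHz rates,
        # which would leave large least-squares passband ripple)
        order = max(3 * int(round(fs / lo)),
                    int(round(fs / (hi - lo))),
                    int(round(fs / (tw * lo))))
    # the least-squares design solves a dense (order/2)^2 system; cap the
    # order so design stays tractable (sub-Hz bands hit this)
    order = min(order, (n_samples - 1) // 3, 12000)
    if order < 6:
        raise ValueError("signal too short for the requested band filter")
    # least-squares FIR tolerates bands somewhat below its frequency
    # resolution (the 1 Hz comodulogram phase bands sit in this regime);
    # reject only bands narrower than a quarter of the resolution
    min_width = 0.25 * fs / order
    if hi - lo < min_width:
        raise ValueError(
            f"band ({lo}, {hi}) too narrow for filter order {order}; "
            f"minimum width {min_width:.2f} Hz"
        )
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1
    edges = [0.0, lo * (1 - tw), lo, hi, min(hi * (1 + tw), 0.999 * nyq), nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    # passband weighted up to limit ripple (the two-pass application
    # squares it); then normalized so the mean two-pass passband gain is 1
    b = sps.firls(numtaps, edges, desired, weight=[1.0, 20.0, 1.0], fs=fs)
    probe = np.linspace(lo, hi, 25)
    _, h = sps.freqz(b, worN=probe, fs=fs)
    return b / np.sqrt(np.sqrt(np.mean(np.abs(h) ** 4)))


def filtfilt_fir(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase two-pass FIR filtering with reflect padding."""
    pad = b.size
    xp = np.concatenate([x[pad:0:-1], x, x[-2: -pad - 2: -1]])
    y = sps.fftconvolve(xp, b, mode="same")
    y = sps.fftconvolve(y[::-1], b, mode="same")[::-1]
    return y[pad: pad + x.size]


def band_phase_amplitude(
    trace: SignalTrace | np.ndarray,
    band: tuple[float, float],
    fs: float | None = None,
    order: int | None = None,
    source: str = "",
) -> BandSignal:
    """Band-pass filter and extract analytic phase and amplitude."""
    if isinstance(trace, SignalTrace):
        fs = trace.fs
        source = source or trace.channel_id
        x = trace.samples
    else:
        x = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required for bare arrays")
    lo, hi = band
    b = design_fir_bandpass(fs, lo, hi, x.size, order)
    y = filtfilt_fir(b, x)
    analytic = sps.hilbert(y)
    return BandSignal(
        band=(lo, hi),
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        fs=fs,
        n_edge=b.size,
        source=source,
    )


# ---------------------------------------------------------------------------
# modulation index
# ---------------------------------------------------------------------------

def phase_bin_indices(phase: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Equal bins over (-pi, pi]; returns the bin index of each sample."""
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def mi_from_binned_amplitude(mean_amp: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """(p, H, Hmax, MI) from a per-bin mean-amplitude vector."""
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("amplitude distribution sums to zero")
    p = mean_amp / total
    nz = p[p > 0]
    H = float(-np.sum(nz * np.log(nz)))
    Hmax = float(np.log(mean_amp.size))
    # clamp: roundoff can leave H marginally above Hmax for uniform p
    mi = min(1.0, max(0.0, (Hmax - H) / Hmax))
    return p, H, Hmax, mi


def modulation_index(
    phase: BandSignal | np.ndarray,
    amplitude: BandSignal | np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = N_PHASE_BINS,
    empty_bin: str = "error",
) -> PhaseAmplitudeDistribution:
    """Phase-amplitude distribution and modulation index.

    ``mask`` selects analysis samples (e.g. odorless cycles); when
    BandSignals are supplied their edge-contaminated samples are excluded
    automatically.  ``empty_bin`` is ``"error"`` (default: raise, advising
    longer data) or ``"smooth"`` (Laplace-smooth the distribution with
    eps=1e-12).
    """
    ph, valid_p = _series_of(phase, "phase")
    am, valid_a = _series_of(amplitude, "amplitude")
    if ph.size != am.size:
        raise ValueError("phase and amplitude series must have equal length")
    m = valid_p & valid_a
    if mask is not None:
        m &= np.asarray(mask, dtype=bool)
    ph, am = ph[m], am[m]
    if ph.size == 0:
        raise ValueError("no valid samples after masking")
    idx = phase_bin_indices(ph, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        if empty_bin == "smooth":
            sums = np.bincount(idx, weights=am, minlength=n_bins)
            mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0) + 1e-12
        else:
            raise ValueError(
                f"{int((counts == 0).sum())} empty phase bins; record longer data "
                "or pass empty_bin='smooth'"
            )
    else:
        mean_amp = np.bincount(idx, weights=am, minlength=n_bins) / counts
    p, H, Hmax, mi = mi_from_binned_amplitude(mean_amp)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return PhaseAmplitudeDistribution(edges, mean_amp, p, H, Hmax, mi)


# ---------------------------------------------------------------------------
# comodulogram
# ---------------------------------------------------------------------------

DEFAULT_PHASE_CENTERS = np.arange(1.0, 9.0)          # 1-8 Hz, 1 Hz steps
DEFAULT_AMP_CENTERS = np.arange(20.0, 131.0, 10.0)   # 20-130 Hz, 10 Hz steps


def band_set(
    x: np.ndarray,
    fs: float,
    centers: np.ndarray,
    width: float,
    kind: str,
    source: str = "",
) -> list[BandSignal]:
    """Filter ``x`` in consecutive bands centered on ``centers``."""
    out = []
    for c in centers:
        lo, hi = c - width / 2.0, c + width / 2.0
        if lo <= 0:
            lo = 0.25 * c
        bs = band_phase_amplitude(x, (lo, hi), fs=fs, source=source)
        out.append(bs)
    return out


def comodulogram_from_bands(
    phase_bands: list[BandSignal],
    amp_bands: list[BandSignal],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    mi = np.zeros((len(phase_bands), len(amp_bands)))
    for i, pb in enumerate(phase_bands):
        m = pb.valid_mask
        if mask is not None:
            m = m & mask
        for j, ab in enumerate(amp_bands):
            mm = m & ab.valid_mask
            idx = phase_bin_indices(pb.phase[mm])
            counts = np.bincount(idx, minlength=N_PHASE_BINS)
            sums = np.bincount(idx, weights=ab.amplitude[mm], minlength=N_PHASE_BINS)
            mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            mean_amp = mean_amp + 1e-12 * mean_amp.max()
            mi[i, j] = mi_from_binned_amplitude(mean_amp)[3]
    return mi


def comodulogram(
    session: Session,
    phase_source: str = "resp",
    channel: int = 0,
    mask: np.ndarray | None = None,
    phase_centers: np.ndarray = DEFAULT_PHASE_CENTERS,
    amp_centers: np.ndarray = DEFAULT_AMP_CENTERS,
    phase_width: float = 1.0,
    amp_width: float = 10.0,
) -> Comodulogram:
    """Phase-amplitude comodulogram of a session.

    ``phase_source`` is ``"resp"`` (respiration phase) or ``"lfp"``; the
    amplitude signal is always the LFP channel ``channel``.
    """
    fs = session.fs
    amp_x = session.lfp[channel].samples
    phase_x = session.resp.samples if phase_source == "resp" else amp_x
    pb = band_set(phase_x, fs, np.asarray(phase_centers), phase_width, "phase",
                  source=phase_source.upper())
    ab = band_set(amp_x, fs, np.asarray(amp_centers), amp_width, "amp",
                  source=f"LFP{channel}")
    mi = comodulogram_from_bands(pb, ab, mask)
    return Comodulogram(np.asarray(phase_centers), np.asarray(amp_centers), mi,
                        phase_source.upper())


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

def mi_surrogates(
    phase: BandSignal | np.ndarray,
    amplitude: BandSignal | np.ndarray,
    n_surrogates: int = 200,
    rng: np.random.Generator | int | None = None,
    min_shift_s: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Null MI distribution from circular time-shifts of the amplitude.

    Each surrogate circularly shifts the amplitude series by a random
    offset of at least ``min_shift_s`` and recomputes the MI against the
    unshifted phase.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ph, valid_p = _series_of(phase, "phase")
    am, valid_a = _series_of(amplitude, "amplitude")
    fs = phase.fs if isinstance(phase, BandSignal) else None
    min_shift = int(min_shift_s * fs) if fs else max(1, ph.size // 100)
    m = valid_p & valid_a
    if mask is not None:
        m &= np.asarray(mask, dtype=bool)
    idx = phase_bin_indices(ph)
    out = np.empty(n_surrogates)
    n = ph.size
    for s in range(n_surrogates):
        shift = int(rng.integers(min_shift, n - min_shift))
        am_s = np.roll(am, shift)
        mm = m & np.roll(valid_a, shift)
        counts = np.bincount(idx[mm], minlength=N_PHASE_BINS)
        sums = np.bincount(idx[mm], weights=am_s[mm], minlength=N_PHASE_BINS)
        mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        mean_amp = mean_amp + 1e-12 * max(mean_amp.max(), 1e-300)
        out[s] = mi_from_binned_amplitude(mean_amp)[3]
    return out


def comodulogram_surrogate_max(
    phase_bands: list[BandSignal],
    amp_bands: list[BandSignal],
    n_surrogates: int = 200,
    rng: np.random.Generator | int | None = None,
    min_shift_s: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Family-wise null: per surrogate, the MAX MI over the whole grid.

    Every (phase, amplitude) pair gets an independent circular shift of
    its amplitude series; the surrogate statistic is the grid maximum, so
    comparing each observed cell against the 95th percentile of this
    distribution controls the family-wise error over the grid.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fs = phase_bands[0].fs
    min_shift = int(min_shift_s * fs)
    n = phase_bands[0].phase.size
    pre = []
    for pb in phase_bands:
        m = pb.valid_mask
        if mask is not None:
            m = m & mask
        pre.append((phase_bin_indices(pb.phase), m))
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        best = 0.0
        for idx, m in pre:
            for ab in amp_bands:
                shift = int(rng.integers(min_shift, n - min_shift))
                am_s = np.roll(ab.amplitude, shift)
                mm = m & np.roll(ab.valid_mask, shift)
                counts = np.bincount(idx[mm], minlength=N_PHASE_BINS)
                sums = np.bincount(idx[mm], weights=am_s[mm], minlength=N_PHASE_BINS)
                mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
                mean_amp = mean_amp + 1e-12 * max(mean_amp.max(), 1e-300)
                best = max(best, mi_from_binned_amplitude(mean_amp)[3])
        out[s] = best
    return out


def _series_of(x, which: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, BandSignal):
        return (x.phase if which == "phase" else x.amplitude), x.valid_mask
    arr = np.asarray(x, dtype=float)
    return arr, np.ones(arr.size, dtype=bool)


def align_phase_to_inhalation(band: BandSignal, inhalation_times: np.ndarray) -> BandSignal:
    """Rotate a phase series so the mean inhalation onset maps to 0 rad.

    Used for respiration phase axes: after alignment, 0 degrees
    corresponds to the start of inhalation.
    """
    idx = np.clip((np.asarray(inhalation_times) * band.fs).astype(int), 0, band.phase.size - 1)
    mean_angle = np.angle(np.mean(np.exp(1j * band.phase[idx])))
    shifted = np.angle(np.exp(1j * (band.phase - mean_angle)))
    return BandSignal(band.band, shifted, band.amplitude, band.fs, band.n_edge, band.source)
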