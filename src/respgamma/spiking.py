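"""Single-unit spiking analyses.

Rate smoothing (10 ms Gaussian kernel), optogenetic unit classification
(rank-sum laser test + laminar FFI/FBI split), spike-phase coupling to
respiration or gamma (mean vector length and preferred angle, with a
session-thirds stability check), spike-triggered gamma envelopes, and the
odor specificity index

    SI = max(F_x) / (F_a + ... + F_f)

which is 1/n_odors for untuned and 1 for fully selective units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .coupling import BandSignal
from .session import SpikeTrain


@dataclass
class RateMatrix:
    """Units x time smoothed firing rates (Hz)."""

    rates: np.ndarray
    fs: float
    unit_ids: list
    kernel_sd_ms: float
    normalization: str = "none"

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    def row(self, unit_id: str) -> np.ndarray:
        return self.rates[self.unit_ids.index(unit_id)]


@dataclass
class SpikePhaseCoupling:
    """Circular statistics of one unit's spike phases."""

    unit_id: str
    phases: np.ndarray
    mvl: float
    preferred_phase: float
    n_spikes: int
    reference: str = ""

    @property
    def flagged(self) -> bool:
        return self.n_spikes == 0


@dataclass
class SpecificityResult:
    window_centers: np.ndarray
    si: np.ndarray              # units x windows, NaN where undefined
    population: np.ndarray      # mean over units per window
    n_undefined: int
    unit_ids: list


def smooth_normalize_rates(
    spikes: list[SpikeTrain],
    duration_s: float,
    fs_out: float = 1000.0,
    kernel_sd_ms: float = 10.0,
    normalize: str = "none",
) -> RateMatrix:
    """Gaussian-smoothed firing rates on a common time grid.

    The kernel preserves spike count (rates integrate to the number of
    spikes).  ``normalize``: ``none``, ``mean`` (divide each unit by its
    time-averaged rate) or ``zscore``.
    """
    if not spikes:
        raise ValueError("empty spike list")
    n = int(round(duration_s * fs_out))
    sigma = kernel_sd_ms * 1e-3 * fs_out
    rows = []
    for st in spikes:
        counts = np.zeros(n)
        if st.n_spikes:
            idx = np.minimum((st.spike_times * fs_out).astype(int), n - 1)
            np.add.at(counts, idx, 1.0)
        else:
            warnings.warn(f"unit {st.unit_id!r} has no spikes; zero rate row")
        rate = ndimage.gaussian_filter1d(counts, sigma) * fs_out
        rows.append(rate)
    rates = np.stack(rows)
    if normalize == "mean":
        means = rates.mean(axis=1, keepdims=True)
        rates = np.divide(rates, means, out=np.zeros_like(rates), where=means > 0)
    elif normalize == "zscore":
        mu = rates.mean(axis=1, keepdims=True)
        sd = rates.std(axis=1, keepdims=True)
        rates = np.divide(rates - mu, sd, out=np.zeros_like(rates), where=sd > 0)
    elif normalize != "none":
        raise ValueError("normalize must be 'none', 'mean' or 'zscore'")
    return RateMatrix(rates, fs_out, [s.unit_id for s in spikes], kernel_sd_ms, normalize)


# ---------------------------------------------------------------------------
# optogenetic classification
# ---------------------------------------------------------------------------

def opto_classify_units(
    spikes: list[SpikeTrain],
    laser_epochs: np.ndarray,
    layer_boundary_um: float,
    alpha: float = 1e-3,
) -> dict[str, str]:
    """Classify units as EXC / FFI / FBI from laser responsiveness.

    Per-epoch spike counts during the laser are compared against
    equal-duration immediately-preceding baselines with a two-sided
    Wilcoxon rank-sum test; p < ``alpha`` marks a unit VGAT+ (inhibitory).
    VGAT+ units shallower than ``layer_boundary_um`` are feedforward
    (FFI), the rest feedback (FBI); everything else is EXC.
    """
    if laser_epochs is None or len(laser_epochs) == 0:
        raise ValueError("no laser epochs; opto classification impossible")
    epochs = np.asarray(laser_epochs, dtype=float).reshape(-1, 3)
    labels: dict[str, str] = {}
    for st in spikes:
        laser_counts, base_counts = [], []
        for start, stop, _ in epochs:
            dur = stop - start
            laser_counts.append(np.count_nonzero(
                (st.spike_times >= start) & (st.spike_times < stop)))
            base_counts.append(np.count_nonzero(
                (st.spike_times >= start - dur) & (st.spike_times < start)))
        stat = stats.ranksums(laser_counts, base_counts)
        if stat.pvalue < alpha:
            depth = st.depth_um if st.depth_um is not None else layer_boundary_um
            labels[st.unit_id] = "FFI" if depth < layer_boundary_um else "FBI"
        else:
            labels[st.unit_id] = "EXC"
    return labels


# ---------------------------------------------------------------------------
# spike-phase coupling
# ---------------------------------------------------------------------------

def spike_phases(spike_times: np.ndarray, reference: BandSignal) -> np.ndarray:
    """Band phase at each spike (nearest sample), excluding edge samples."""
    idx = np.round(np.asarray(spike_times) * reference.fs).astype(int)
    idx = idx[(idx >= 0) & (idx < reference.phase.size)]
    idx = idx[reference.valid_mask[idx]]
    return reference.phase[idx]


def mvl(phases: np.ndarray) -> float:
    """Mean vector length of a set of angles (0 = uniform, 1 = point mass)."""
    phases = np.asarray(phases)
    if phases.size == 0:
        return float("nan")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def preferred_phase(phases: np.ndarray) -> float:
    """Circular mean angle in (-pi, pi]."""
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def spike_phase_coupling(
    spike_times: np.ndarray | SpikeTrain,
    reference: BandSignal,
    unit_id: str = "",
) -> SpikePhaseCoupling:
    if isinstance(spike_times, SpikeTrain):
        unit_id = unit_id or spike_times.unit_id
        spike_times = spike_times.spike_times
    ph = spike_phases(spike_times, reference)
    if ph.size == 0:
        return SpikePhaseCoupling(unit_id, ph, float("nan"), float("nan"), 0,
                                  reference.source)
    return SpikePhaseCoupling(unit_id, ph, mvl(ph), preferred_phase(ph),
                              int(ph.size), reference.source)


def phase_stability(
    spike_times: np.ndarray,
    reference: BandSignal,
    duration_s: float,
) -> float:
    """|circular difference| of the preferred phase, first vs last third.

    Returns the absolute angular difference in radians (NaN when either
    third has no spikes).
    """
    spike_times = np.asarray(spike_times)
    first = spike_times[spike_times < duration_s / 3.0]
    last = spike_times[spike_times >= 2.0 * duration_s / 3.0]
    p1 = spike_phases(first, reference)
    p2 = spike_phases(last, reference)
    if p1.size == 0 or p2.size == 0:
        return float("nan")
    d = preferred_phase(p1) - preferred_phase(p2)
    return float(np.abs(np.angle(np.exp(1j * d))))


def spike_triggered_envelope(
    spike_times: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    window: tuple[float, float] = (-0.15, 0.3),
    norm_pre_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Spike-aligned amplitude envelope, normalized per spike.

    Each spike's triggered window is divided by that spike's mean envelope
    over the ``norm_pre_s`` seconds preceding it, so a flat output of 1
    means spiking unrelated to the envelope.  Returns ``(lags_s, curve,
    n_used, n_dropped)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = envelope.size
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    npre = int(round(norm_pre_s * fs))
    centers = np.round(spike_times * fs).astype(int)
    ok = (centers + w0 >= 0) & (centers + w1 <= n) & (centers - npre >= 0)
    used = centers[ok]
    if used.size == 0:
        raise ValueError("no spikes with a full triggered window")
    acc = np.zeros(w1 - w0)
    kept = 0
    for c in used:
        base = envelope[c - npre: c].mean()
        if base <= 0:
            continue
        acc += envelope[c + w0: c + w1] / base
        kept += 1
    lags = np.arange(w0, w1) / fs
    return lags, acc / max(kept, 1), kept, int((~ok).sum())


# ---------------------------------------------------------------------------
# odor specificity
# ---------------------------------------------------------------------------

def specificity_index(
    rates: RateMatrix,
    trials: list[tuple[float, int]],
    window_s: float = 0.1,
    overlap: float = 0.625,
    t_max: float = 1.0,
) -> SpecificityResult:
    """Sliding-window odor specificity index per unit plus population mean.

    ``trials`` are (anchor_s, odor_id) pairs (inhalation onsets during
    odor delivery).  Windows of ``window_s`` slide from the anchor with
    62.5% overlap (37.5 ms hop at the default).  Windows with zero summed
    rate are flagged undefined and excluded from the population mean.
    """
    odors = sorted({o for _, o in trials})
    if len(odors) < 2:
        raise ValueError("need >= 2 odors with trials")
    hop = window_s * (1.0 - overlap)
    starts = np.arange(0.0, t_max - window_s + 1e-9, hop)
    centers = starts + window_s / 2.0
    n_units = rates.n_units
    si = np.full((n_units, starts.size), np.nan)
    n_undef = 0
    fs = rates.fs
    n_time = rates.rates.shape[1]
    for w, t0 in enumerate(starts):
        f_per_odor = np.zeros((n_units, len(odors)))
        for k, o in enumerate(odors):
            anchors = [a for a, oo in trials if oo == o]
            cols = []
            for a in anchors:
                i0 = int(round((a + t0) * fs))
                i1 = int(round((a + t0 + window_s) * fs))
                if i0 < 0 or i1 > n_time:
                    continue
                cols.append(rates.rates[:, i0:i1].mean(axis=1))
            if cols:
                f_per_odor[:, k] = np.mean(cols, axis=0)
        total = f_per_odor.sum(axis=1)
        ok = total > 0
        si[ok, w] = f_per_odor[ok].max(axis=1) / total[ok]
        n_undef += int((~ok).sum())
    population = np.nanmean(si, axis=0)
    return SpecificityResult(centers, si, population, n_undef, list(rates.unit_ids))
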