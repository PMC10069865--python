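"""Synthetic piriform-cortex sessions with planted, recoverable structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every downstream quantity has a known planted truth:

* a quasi-periodic 2–3 Hz airflow signal whose negative deflections mark
  inhalations (ground-truth onsets are returned);
* multichannel LFP = pink (1/f) noise + a respiration-coherent slow wave
  + an *evoked* beta transient (fixed carrier phase ~100 ms after
  inhalation) + an *induced* low-gamma burst (Gaussian amplitude envelope
  peaking ~200 ms after inhalation, carrier phase re-drawn every cycle),
  with a laminar sign reversal of the gamma component;
* excitatory (EXC), feedback-inhibitory (FBI) and feedforward-inhibitory
  (FFI) spike trains: EXC/FFI fire early in the cycle with heterogeneous
  per-cell respiratory tuning, FBI rate tracks the gamma envelope;
* odor trials in which a sparse odor-specific "winner" subset escapes a
  gamma-envelope-gated suppression of the remaining "loser" cells, whose
  residual burst spikes are von-Mises phase-locked to the gamma carrier;
* an ablation mode (TeLC-like: recurrent excitation silenced) that
  collapses the gamma burst, the suppression, and the FBI-envelope
  coupling while leaving everything else untouched.

The odor response of a principal cell is modelled as a *nonspecific*
envelope-gated afferent drive shared by all cells, on top of which the
odor's winners receive an extra gain with trial-to-trial (assembly
activation) variability; the winner-take-all suppression then multiplies
the non-winners.  In control sessions the suppression nearly cancels the
nonspecific drive, leaving the winners as the dominant coherent mode; in
ablated sessions the unsuppressed nonspecific drive becomes a broad mode
shared across cells and odors.  This is exactly the circuit account the
analysis is meant to expose (skewed weights, orthogonal assemblies and
high gamma-window decoding in control; all degraded under ablation).

Spike trains are drawn by thinning an inhomogeneous Poisson process, so
generation is exact and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np
from scipy import special

from .session import EventSeries, Session, SignalTrace, SpikeTrain


@dataclass
class SynthConfig:
    """All generator knobs.  Defaults are the study conditions emulated."""

    duration_s: float = 120.0
    fs: float = 2000.0
    seed: int = 0

    # respiration: cycle rate drawn per cycle, inhalation = negative lobe
    resp_rate_hz: float = 2.5
    resp_rate_sd: float = 0.5
    resp_noise: float = 0.05
    inhale_fraction: float = 0.4

    # LFP composition
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    slow_amp: float = 1.5
    beta_freq: float = 15.0
    beta_band: tuple = (10.0, 20.0)
    beta_latency_s: float = 0.1
    beta_sd_s: float = 0.03
    beta_amp: float = 1.5
    beta_odor_factor: float = 1.5
    gamma_freq: float = 40.0
    gamma_band: tuple = (30.0, 60.0)
    gamma_latency_s: float = 0.2
    gamma_sd_s: float = 0.05
    gamma_amp: float = 2.0
    gamma_phase_jitter_sd: float = 2.0 * np.pi  # wrapped-normal sd; 2*pi ~ uniform
    odor_gamma_width_factor: float = 2.0

    # laminar geometry
    n_channels: int = 8
    reversal_channel: int = 4
    channel_spacing_um: float = 50.0
    smooth_reversal: bool = False
    layer_boundary_um: float = 150.0

    # populations
    n_exc: int = 200
    n_fbi: int = 10
    n_ffi: int = 5
    exc_rate_hz: float = 1.5
    fbi_rate_hz: float = 3.0
    ffi_rate_hz: float = 4.0
    fbi_env_gain: float = 4.0
    early_latency_range_s: tuple = (0.03, 0.09)
    early_sd_s: float = 0.03
    early_depth_range: tuple = (0.5, 2.0)

    # odors and the winner-take-all structure
    n_odors: int = 6
    first_odor_s: float = 15.0
    odor_interval_s: float = 10.0
    odor_duration_s: float = 1.0
    winners_per_odor: int = 10
    winners_overlap: bool = False
    winner_gain: float = 8.0
    winner_trial_sd: float = 0.4
    winner_participation: float = 0.85
    nonspecific_odor_drive: float = 2.0
    loser_suppression: float = 0.85
    loser_gamma_locking: float = 2.0
    winner_phase_gate_kappa: float = 0.0

    # optogenetic tagging
    n_laser_epochs: int = 0
    laser_epoch_s: float = 0.5
    laser_gain: float = 3.0

    ablated: bool = False

    def validate(self) -> None:
        if self.resp_rate_sd >= self.resp_rate_hz:
            raise ValueError("resp_rate_sd must be < resp_rate_hz (cycle length could be non-positive)")
        for name in ("duration_s", "fs", "noise_amp", "beta_amp", "gamma_amp",
                     "winner_gain", "exc_rate_hz", "fbi_rate_hz", "ffi_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.loser_suppression <= 1.0:
            raise ValueError("loser_suppression must lie in [0, 1]")
        if self.winners_per_odor > self.n_exc:
            raise ValueError("winners_per_odor cannot exceed n_exc")
        if not self.winners_overlap and self.n_odors * self.winners_per_odor > self.n_exc:
            raise ValueError("disjoint winner sets need n_odors*winners_per_odor <= n_exc")
        if not 0 <= self.reversal_channel <= self.n_channels:
            raise ValueError("reversal_channel out of range")


@dataclass
class GroundTruth:
    """Planted quantities recorded beside a generated session."""

    inhalation_times: np.ndarray
    cycle_periods: np.ndarray
    cycle_odor: np.ndarray            # odor index per cycle, -1 = odorless
    odor_onsets: np.ndarray
    odor_ids: np.ndarray
    gamma_envelope: np.ndarray        # normalized [0, 1], LFP timebase
    gamma_phase: np.ndarray           # carrier phase (rad), LFP timebase
    winner_sets: Dict[int, np.ndarray]  # odor -> EXC unit indices
    config: SynthConfig = field(repr=False, default=None)

    def to_jsonable(self) -> dict:
        return {
            "inhalation_times": self.inhalation_times.tolist(),
            "cycle_odor": self.cycle_odor.tolist(),
            "odor_onsets": self.odor_onsets.tolist(),
            "odor_ids": self.odor_ids.tolist(),
            "winner_sets": {str(k): v.tolist() for k, v in self.winner_sets.items()},
        }


def ablate_recurrence(cfg: SynthConfig) -> SynthConfig:
    """TeLC-like ablation of recurrent excitation (idempotent).

    Scales the gamma burst amplitude down (x0.2), reduces the loser
    suppression to a small residual (0.1), removes the FBI rate-envelope
    coupling, and scales the winner gain down (x0.35) — the winners'
    extra drive rides on the recurrent collaterals whose output the
    toxin blocks.  Everything else is unchanged.
    """
    if cfg.ablated:
        return replace(cfg)
    return replace(
        cfg,
        ablated=True,
        gamma_amp=cfg.gamma_amp * 0.2,
        loser_suppression=min(cfg.loser_suppression, 0.1),
        fbi_env_gain=0.0,
        winner_gain=cfg.winner_gain * 0.35,
    )


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def generate_respiration(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[SignalTrace, np.ndarray]:
    """Quasi-periodic airflow trace plus ground-truth inhalation onsets.

    Each cycle's rate is drawn from N(resp_rate_hz, resp_rate_sd); the
    waveform is a negative half-sine (inhalation) followed by a smaller
    positive half-sine (exhalation), plus white sensor noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    onsets, periods = _draw_cycles(cfg, rng)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    clean = np.zeros(n)
    for on, per in zip(onsets, periods):
        i0 = int(round(on * cfg.fs))
        i1 = min(n, int(round((on + per) * cfg.fs)))
        tau = t[i0:i1] - on
        t_inh = cfg.inhale_fraction * per
        w = np.where(
            tau < t_inh,
            -np.sin(np.pi * tau / t_inh),
            0.6 * np.sin(np.pi * (tau - t_inh) / (per - t_inh)),
        )
        clean[i0:i1] = w
    noisy = clean + cfg.resp_noise * rng.standard_normal(n)
    trace = SignalTrace(noisy, cfg.fs, "RESP")
    trace._clean = clean  # stashed for the LFP's respiration-coherent term
    return trace, onsets


def _draw_cycles(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    onsets, periods = [], []
    t = 0.0
    floor = max(0.2, cfg.resp_rate_hz - 3.0 * cfg.resp_rate_sd)
    while t < cfg.duration_s - 0.05:
        rate = max(floor, rng.normal(cfg.resp_rate_hz, cfg.resp_rate_sd))
        per = 1.0 / rate
        if t + 0.5 * per > cfg.duration_s:
            break
        onsets.append(t)
        periods.append(min(per, cfg.duration_s - t))
        t += per
    return np.asarray(onsets), np.asarray(periods)


# ---------------------------------------------------------------------------
# odor schedule
# ---------------------------------------------------------------------------

def _odor_schedule(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    onsets = []
    t = cfg.first_odor_s
    while t + cfg.odor_duration_s < cfg.duration_s - 1.0:
        onsets.append(t)
        t += cfg.odor_interval_s
    onsets = np.asarray(onsets)
    ids = np.empty(onsets.size, dtype=int)
    for b in range(0, onsets.size, cfg.n_odors):
        block = rng.permutation(cfg.n_odors)
        ids[b: b + cfg.n_odors] = block[: onsets.size - b]
    return onsets, ids


def _tag_cycles(
    onsets: np.ndarray, odor_onsets: np.ndarray, odor_ids: np.ndarray, window_s: float
) -> np.ndarray:
    """Odor index per respiratory cycle (-1 = odorless).

    A cycle is an odor cycle when its inhalation falls within ``window_s``
    following an odor onset.
    """
    tag = np.full(onsets.size, -1, dtype=int)
    for on, oid in zip(odor_onsets, odor_ids):
        hit = (onsets >= on) & (onsets < on + window_s)
        tag[hit] = oid
    return tag


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _burst_fields(
    cfg: SynthConfig,
    onsets: np.ndarray,
    periods: np.ndarray,
    cycle_odor: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample gamma envelope (normalized), gamma carrier phase, and the
    beta and gamma LFP components (single-channel, unsigned)."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    env = np.zeros(n)
    phase = np.zeros(n)
    beta = np.zeros(n)
    gamma = np.zeros(n)
    psis = np.mod(rng.normal(0.0, cfg.gamma_phase_jitter_sd, size=onsets.size), 2 * np.pi)
    for k, (on, per) in enumerate(zip(onsets, periods)):
        i0 = int(round(on * cfg.fs))
        i1 = min(n, int(round((on + per) * cfg.fs)))
        tau = t[i0:i1] - on
        is_odor = cycle_odor[k] >= 0
        # odors prolong the gamma epoch: the burst rises at the same
        # latency but decays more slowly (duration, not amplitude, grows)
        sd_rise = cfg.gamma_sd_s
        sd_fall = cfg.gamma_sd_s * (cfg.odor_gamma_width_factor if is_odor else 1.0)
        dt_lat = tau - cfg.gamma_latency_s
        e = np.exp(-0.5 * (dt_lat / np.where(dt_lat < 0, sd_rise, sd_fall)) ** 2)
        th = 2 * np.pi * cfg.gamma_freq * tau + psis[k]
        env[i0:i1] = e
        phase[i0:i1] = np.mod(th + np.pi, 2 * np.pi) - np.pi
        gamma[i0:i1] = cfg.gamma_amp * e * np.cos(th)
        b_amp = cfg.beta_amp * (cfg.beta_odor_factor if is_odor else 1.0)
        eb = np.exp(-0.5 * ((tau - cfg.beta_latency_s) / cfg.beta_sd_s) ** 2)
        beta[i0:i1] = b_amp * eb * np.cos(2 * np.pi * cfg.beta_freq * tau)
    return env, phase, beta, gamma


def _reversal_profile(cfg: SynthConfig) -> np.ndarray:
    if cfg.smooth_reversal:
        # linear dipole-like taper from +1 to -1 across the stack
        return np.linspace(1.0, -1.0, cfg.n_channels)
    sign = np.ones(cfg.n_channels)
    sign[cfg.reversal_channel:] = -1.0
    return sign


def generate_lfp_stack(
    cfg: SynthConfig,
    onsets: np.ndarray,
    periods: np.ndarray,
    cycle_odor: np.ndarray,
    resp_clean: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[SignalTrace], np.ndarray, np.ndarray]:
    """Laminar LFP stack; returns (traces, gamma_envelope, gamma_phase)."""
    env, phase, beta, gamma = _burst_fields(cfg, onsets, periods, cycle_odor, rng)
    slow = cfg.slow_amp * resp_clean
    profile = _reversal_profile(cfg)
    n = env.size
    traces = []
    for ch in range(cfg.n_channels):
        noise = _pink_noise(n, cfg.noise_exponent, cfg.noise_amp, rng)
        x = noise + slow + beta + profile[ch] * gamma
        traces.append(
            SignalTrace(x, cfg.fs, f"ch{ch:02d}", depth_um=ch * cfg.channel_spacing_um)
        )
    return traces, env, phase


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _thin_poisson(
    rate: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact inhomogeneous-Poisson sampling by thinning."""
    lam_max = float(rate.max())
    duration = rate.size / fs
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    tt = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((tt * fs).astype(int), rate.size - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate[idx] / lam_max
    return tt[keep]


def _cycle_slices(onsets: np.ndarray, periods: np.ndarray, fs: float, n: int):
    for on, per in zip(onsets, periods):
        i0 = int(round(on * fs))
        i1 = min(n, int(round((on + per) * fs)))
        yield slice(i0, i1)


def generate_spiketrains(
    cfg: SynthConfig,
    onsets: np.ndarray,
    periods: np.ndarray,
    cycle_odor: np.ndarray,
    env: np.ndarray,
    phase: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[SpikeTrain], Dict[int, np.ndarray], np.ndarray | None]:
    """EXC/FBI/FFI spike trains with the planted winner-take-all structure."""
    n = env.size
    fs = cfg.fs
    t_early = _early_kernel_positions(cfg, onsets, fs, n, rng)

    # winner sets
    if cfg.winners_overlap:
        winner_sets = {
            o: np.sort(rng.choice(cfg.n_exc, cfg.winners_per_odor, replace=False))
            for o in range(cfg.n_odors)
        }
    else:
        perm = rng.permutation(cfg.n_exc)[: cfg.n_odors * cfg.winners_per_odor]
        winner_sets = {
            o: np.sort(perm[o * cfg.winners_per_odor: (o + 1) * cfg.winners_per_odor])
            for o in range(cfg.n_odors)
        }

    # gamma-phase factors (mean-one von Mises densities)
    vm_lock = _vm_factor(phase, cfg.loser_gamma_locking)
    vm_gate = (
        _vm_factor(phase, cfg.winner_phase_gate_kappa)
        if cfg.winner_phase_gate_kappa > 0
        else None
    )

    slices = list(_cycle_slices(onsets, periods, fs, n))
    # per-cycle winner activation strength (shared by that odor's winners)
    g_cycle = cfg.winner_gain * np.exp(rng.normal(0.0, cfg.winner_trial_sd, size=len(slices)))
    spont_sup = 0.5 * cfg.loser_suppression

    spikes: list[SpikeTrain] = []
    laser = _laser_epochs(cfg)
    for i in range(cfg.n_exc):
        b = cfg.exc_rate_hz * np.exp(rng.normal(0.0, 0.3))
        rate = b * (1.0 + t_early[i])
        mod = np.ones(n)
        for k, sl in enumerate(slices):
            o = cycle_odor[k]
            e = env[sl]
            if o >= 0:
                if i in winner_sets[o] and rng.uniform() < cfg.winner_participation:
                    gate = vm_gate[sl] if vm_gate is not None else 1.0
                    mod[sl] = 1.0 + (cfg.nonspecific_odor_drive + g_cycle[k] * gate) * e
                else:
                    s_ik = cfg.loser_suppression * (0.75 + 0.5 * rng.uniform())
                    lock = 1.0 + e * (vm_lock[sl] - 1.0)
                    mod[sl] = (
                        (1.0 + cfg.nonspecific_odor_drive * e)
                        * np.clip(1.0 - s_ik * e, 0.0, None)
                        * lock
                    )
            else:
                mod[sl] = np.clip(1.0 - spont_sup * rng.uniform() * e, 0.0, None)
        rate = rate * mod
        tt = _thin_poisson(rate, fs, rng)
        depth = float(np.clip(rng.normal(250.0, 30.0), cfg.layer_boundary_um + 10, None))
        spikes.append(SpikeTrain(f"exc{i:03d}", tt, "EXC", depth))

    for i in range(cfg.n_fbi):
        b = cfg.fbi_rate_hz * np.exp(rng.normal(0.0, 0.2))
        rate = b * (1.0 + cfg.fbi_env_gain * env)
        rate = _apply_laser(rate, laser, cfg, fs)
        tt = _thin_poisson(rate, fs, rng)
        depth = float(np.clip(rng.normal(280.0, 40.0), cfg.layer_boundary_um + 10, None))
        spikes.append(SpikeTrain(f"fbi{i:02d}", tt, "FBI", depth))

    for i in range(cfg.n_ffi):
        b = cfg.ffi_rate_hz * np.exp(rng.normal(0.0, 0.2))
        rate = b * (1.0 + t_early[cfg.n_exc + i])
        rate = _apply_laser(rate, laser, cfg, fs)
        tt = _thin_poisson(rate, fs, rng)
        depth = float(np.clip(rng.normal(80.0, 30.0), None, cfg.layer_boundary_um - 10))
        spikes.append(SpikeTrain(f"ffi{i:02d}", tt, "FFI", depth))

    return spikes, winner_sets, laser


def _vm_factor(phase: np.ndarray, kappa: float) -> np.ndarray:
    if kappa <= 0:
        return np.ones_like(phase)
    return np.exp(kappa * np.cos(phase)) / special.i0(kappa)


def _early_kernel_positions(cfg, onsets, fs, n, rng) -> list[np.ndarray]:
    """Per-unit early-cycle rate modulation a_i * sum_k N(onset_k + l_i, sd)."""
    n_units = cfg.n_exc + cfg.n_ffi
    half = int(round(4 * cfg.early_sd_s * fs))
    sup = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (sup / (cfg.early_sd_s * fs)) ** 2)
    out = []
    lo, hi = cfg.early_latency_range_s
    d_lo, d_hi = cfg.early_depth_range
    for _ in range(n_units):
        lat = rng.uniform(lo, hi)
        depth = rng.uniform(d_lo, d_hi)
        mod = np.zeros(n)
        centers = np.round((onsets + lat) * fs).astype(int)
        for c in centers:
            a = max(0, c - half)
            b = min(n, c + half + 1)
            mod[a:b] += kern[a - (c - half): kern.size - ((c + half + 1) - b)]
        out.append(depth * mod)
    return out


def _laser_epochs(cfg: SynthConfig) -> np.ndarray | None:
    if cfg.n_laser_epochs <= 0:
        return None
    starts = np.linspace(2.0, cfg.duration_s - 2.0, cfg.n_laser_epochs)
    return np.column_stack([starts, starts + cfg.laser_epoch_s, np.ones(starts.size)])


def _apply_laser(rate: np.ndarray, laser: np.ndarray | None, cfg: SynthConfig, fs: float):
    if laser is None:
        return rate
    rate = rate.copy()
    for start, stop, _ in laser:
        rate[int(start * fs): int(stop * fs)] *= cfg.laser_gain
    return rate


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def generate_session(cfg: SynthConfig) -> tuple[Session, GroundTruth]:
    """Assemble a full synthetic session and its planted ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    resp, onsets = generate_respiration(cfg, rng)
    n = resp.samples.size
    periods = np.diff(np.append(onsets, cfg.duration_s))
    odor_onsets, odor_ids = _odor_schedule(cfg, rng)
    cycle_odor = _tag_cycles(onsets, odor_onsets, odor_ids, 1.0)
    lfp, env, phase = generate_lfp_stack(
        cfg, onsets, periods, cycle_odor, resp._clean, rng
    )
    spikes, winner_sets, laser = generate_spiketrains(
        cfg, onsets, periods, cycle_odor, env, phase, rng
    )
    events = EventSeries(onsets, odor_onsets, odor_ids, laser)
    meta = {
        "generator": "respgamma.synth",
        "seed": int(cfg.seed),
        "ablated": bool(cfg.ablated),
        "layer_boundary_um": float(cfg.layer_boundary_um),
        "reversal_channel": int(cfg.reversal_channel),
        "n_odors": int(cfg.n_odors),
    }
    session = Session(lfp, resp, spikes, events, meta)
    session.validate()
    truth = GroundTruth(
        inhalation_times=onsets,
        cycle_periods=periods,
        cycle_odor=cycle_odor,
        odor_onsets=odor_onsets,
        odor_ids=odor_ids,
        gamma_envelope=env,
        gamma_phase=phase,
        winner_sets=winner_sets,
        config=cfg,
    )
    return session, truth
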