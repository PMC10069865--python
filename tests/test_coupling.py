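"""Band filtering conventions and the entropy-based modulation index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respgamma import coupling
from respgamma.coupling import (
    band_phase_amplitude,
    mi_from_binned_amplitude,
    modulation_index,
)

FS = 2000.0


def _tone(freq, duration=10.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t), t


class TestBandSignal:
    def test_amplitude_and_phase_rate(self):
        x, t = _tone(40.0, amp=2.0)
        bs = band_phase_amplitude(x, (30.0, 60.0), fs=FS)
        core = slice(bs.n_edge, -bs.n_edge)
        assert np.allclose(bs.amplitude[core], 2.0, rtol=0.02)
        dphi = np.unwrap(bs.phase[core])
        rate = np.polyfit(t[core], dphi, 1)[0]
        assert rate == pytest.approx(2 * np.pi * 40.0, rel=1e-3)

    def test_out_of_band_rejection(self):
        x, _ = _tone(5.0)
        bs = band_phase_amplitude(x, (30.0, 60.0), fs=FS)
        core = slice(bs.n_edge, -bs.n_edge)
        assert bs.amplitude[core].max() < 0.05

    def test_cosine_phase_convention(self):
        x, _ = _tone(40.0)
        bs = band_phase_amplitude(x, (30.0, 60.0), fs=FS)
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        peaks = peaks[(peaks > bs.n_edge) & (peaks < x.size - bs.n_edge)]
        assert np.abs(bs.phase[peaks]).max() < 0.2

    def test_band_too_narrow_error(self):
        with pytest.raises(ValueError, match="minimum width"):
            band_phase_amplitude(np.zeros(4000), (40.0, 40.01), fs=FS)


class TestModulationIndex:
    def test_uniform_amplitude_zero(self):
        p, H, Hmax, mi = mi_from_binned_amplitude(np.full(18, 3.7))
        assert mi == 0.0
        assert H == pytest.approx(Hmax)

    def test_single_bin_mass_one(self):
        amp = np.zeros(18)
        amp[7] = 5.0
        assert mi_from_binned_amplitude(amp)[3] == 1.0

    def test_matches_entropy_oracle(self):
        """MI on 1 + cos(bin center) amplitudes equals a direct entropy
        evaluation of the same 18-bin distribution."""
        centers = -np.pi + (np.arange(18) + 0.5) * (2 * np.pi / 18)
        amp = 1.0 + np.cos(centers)
        # independent oracle: direct entropy computation
        p = amp / amp.sum()
        H = -(p[p > 0] * np.log(p[p > 0])).sum()
        expected = (np.log(18) - H) / np.log(18)
        # pipeline path: phase samples distributed over bins with this
        # amplitude profile
        phases = np.repeat(centers, 500)
        amps = np.repeat(amp, 500)
        pad = modulation_index(phases, amps)
        assert pad.MI == pytest.approx(expected, abs=1e-12)

    def test_empty_bin_policy(self):
        phases = np.full(1000, 0.1)
        amps = np.ones(1000)
        with pytest.raises(ValueError, match="empty phase bins"):
            modulation_index(phases, amps)
        pad = modulation_index(phases, amps, empty_bin="smooth")
        assert pad.MI == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           rot=st.integers(min_value=0, max_value=17))
    def test_invariance_scale_and_bin_rotation(self, scale, rot):
        """MI is invariant to amplitude rescaling and to phase rotation by
        whole bin widths."""
        rng = np.random.default_rng(7)
        phases = rng.uniform(-np.pi, np.pi, 20000)
        amps = 1.0 + 0.5 * np.cos(phases) + 0.1 * rng.uniform(size=20000)
        base = modulation_index(phases, amps).MI
        scaled = modulation_index(phases, amps * scale).MI
        shift = rot * (2 * np.pi / 18)
        rotated = np.angle(np.exp(1j * (phases + shift)))
        rot_mi = modulation_index(rotated, amps).MI
        assert scaled == pytest.approx(base, abs=1e-9)
        assert rot_mi == pytest.approx(base, abs=1e-9)

    def test_monotone_in_coupling_depth(self, rng):
        """MI grows with the planted modulation depth (5 depths)."""
        t = np.arange(int(60 * FS)) / FS
        from scipy import signal as sps

        slow = sps.fftconvolve(
            rng.standard_normal(t.size),
            sps.firwin(4001, [3.5, 4.5], pass_zero=False, fs=FS), mode="same")
        slow /= np.abs(slow).max()
        mis = []
        for depth in (0.0, 0.2, 0.4, 0.6, 0.8):
            sig = (1 + depth * slow) * np.cos(2 * np.pi * 40 * t)
            ph = band_phase_amplitude(slow, (3.5, 4.5), fs=FS)
            am = band_phase_amplitude(sig, (35.0, 45.0), fs=FS)
            mis.append(modulation_index(ph, am, empty_bin="smooth").MI)
        assert np.all(np.diff(mis) > 0)


class TestComodulogram:
    def test_argmax_at_planted_cell(self, rng):
        """4 Hz quasi-periodic phase modulating 40 Hz amplitude."""
        from scipy import signal as sps

        t = np.arange(int(60 * FS)) / FS
        slow = sps.fftconvolve(
            rng.standard_normal(t.size),
            sps.firwin(4001, [3.5, 4.5], pass_zero=False, fs=FS), mode="same")
        slow /= slow.std()
        sig = (slow + 0.5 * (1 + 0.8 * np.tanh(slow)) * np.cos(2 * np.pi * 40 * t)
               + 0.5 * rng.standard_normal(t.size))
        pb = coupling.band_set(sig, FS, coupling.DEFAULT_PHASE_CENTERS, 1.0, "phase")
        ab = coupling.band_set(sig, FS, coupling.DEFAULT_AMP_CENTERS, 10.0, "amp")
        mi = coupling.comodulogram_from_bands(pb, ab)
        i, j = np.unravel_index(np.argmax(mi), mi.shape)
        assert coupling.DEFAULT_PHASE_CENTERS[i] == 4.0
        assert coupling.DEFAULT_AMP_CENTERS[j] == 40.0

    def test_session_comodulogram_grid(self, spont):
        session, _ = spont
        com = coupling.comodulogram(session, phase_source="resp")
        assert com.mi.shape == (8, 12)
        assert np.all((com.mi >= 0) & (com.mi <= 1))

    def test_ablated_resp_gamma_cells_reduced(self):
        from respgamma import pipeline
        from respgamma.synth import ablate_recurrence, generate_session

        cfg = pipeline.spontaneous_config(21, duration_s=60.0)
        ctrl, _ = generate_session(cfg)
        abl, _ = generate_session(ablate_recurrence(cfg))
        assert pipeline.resp_gamma_mi(abl) < 0.3 * pipeline.resp_gamma_mi(ctrl)


def test_phase_alignment_to_inhalation(spont):
    session, truth = spont
    ph = band_phase_amplitude(session.resp, (1.0, 4.0))
    aligned = coupling.align_phase_to_inhalation(ph, truth.inhalation_times)
    idx = (truth.inhalation_times * session.fs).astype(int)
    mean_angle = np.angle(np.mean(np.exp(1j * aligned.phase[idx])))
    assert abs(mean_angle) < 1e-6
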