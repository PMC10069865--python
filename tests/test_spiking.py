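"""Rate smoothing, opto-tagging, spike-phase coupling, specificity index."""

import numpy as np
import pytest
from scipy import special, stats

from respgamma.session import SpikeTrain
from respgamma.spiking import (
    RateMatrix,
    mvl,
    opto_classify_units,
    phase_stability,
    preferred_phase,
    smooth_normalize_rates,
    specificity_index,
    spike_phase_coupling,
    spike_triggered_envelope,
)
from respgamma.coupling import BandSignal


def _bandsig(phase, fs=1000.0):
    return BandSignal((30.0, 60.0), phase, np.ones_like(phase), fs, 0, "GAMMA")


class TestRates:
    def test_kernel_preserves_spike_count(self):
        st_ = SpikeTrain("u", [5.0])
        rm = smooth_normalize_rates([st_], 10.0, fs_out=1000.0)
        assert rm.rates[0].sum() / 1000.0 == pytest.approx(1.0, rel=0.01)

    def test_poisson_rate_recovered(self, rng):
        tt = np.sort(rng.uniform(0, 100.0, 1000))
        rm = smooth_normalize_rates([SpikeTrain("u", tt)], 100.0)
        assert rm.rates[0].mean() == pytest.approx(10.0, abs=0.2)

    def test_mean_normalization_constant_unit(self, rng):
        tt = np.sort(rng.uniform(0, 50.0, 500))
        rm = smooth_normalize_rates([SpikeTrain("u", tt)], 50.0, normalize="mean")
        assert rm.rates[0].mean() == pytest.approx(1.0, rel=1e-6)

    def test_silent_unit_warns_zero_row(self):
        with pytest.warns(UserWarning, match="no spikes"):
            rm = smooth_normalize_rates(
                [SpikeTrain("a", [1.0]), SpikeTrain("b", [])], 5.0)
        assert rm.rates[1].sum() == 0.0


class TestOptoClassification:
    @staticmethod
    def _unit(uid, base_hz, laser_hz, epochs, depth, duration=120.0, seed=0):
        rng = np.random.default_rng(seed)
        tt = np.sort(rng.uniform(0, duration, rng.poisson(base_hz * duration)))
        extra = []
        for start, stop, _ in epochs:
            extra.append(rng.uniform(start, stop,
                                     rng.poisson((laser_hz - base_hz) * (stop - start))))
        tt = np.sort(np.concatenate([tt] + extra)) if laser_hz > base_hz else tt
        return SpikeTrain(uid, tt, "UNKNOWN", depth)

    def test_rule_application(self):
        starts = np.linspace(2.0, 115.0, 50)
        epochs = np.column_stack([starts, starts + 0.5, np.ones(50)])
        units = [
            self._unit("driven_deep", 5.0, 15.0, epochs, depth=300.0, seed=1),
            self._unit("driven_shallow", 5.0, 15.0, epochs, depth=80.0, seed=2),
            self._unit("unresponsive", 5.0, 5.0, epochs, depth=250.0, seed=3),
        ]
        labels = opto_classify_units(units, epochs, layer_boundary_um=150.0)
        assert labels == {"driven_deep": "FBI", "driven_shallow": "FFI",
                          "unresponsive": "EXC"}

    def test_generator_units_recovered(self):
        from dataclasses import replace

        from respgamma import pipeline
        from respgamma.synth import generate_session

        cfg = replace(pipeline.spontaneous_config(55, duration_s=90.0),
                      n_laser_epochs=50, n_exc=30, winners_per_odor=5)
        sess, _ = generate_session(cfg)
        labels = opto_classify_units(sess.spikes, sess.events.laser_epochs,
                                     cfg.layer_boundary_um)
        true = {u.unit_id: u.unit_class for u in sess.spikes}
        agreement = np.mean([labels[k] == true[k] for k in labels])
        assert agreement >= 0.95

    def test_no_laser_error(self):
        with pytest.raises(ValueError, match="laser"):
            opto_classify_units([SpikeTrain("u", [1.0])], None, 150.0)


class TestSpikePhase:
    def test_point_mass(self):
        phases = np.full(100, np.pi / 2)
        assert mvl(phases) == pytest.approx(1.0)
        assert preferred_phase(phases) == pytest.approx(np.pi / 2)

    def test_four_point_symmetry(self):
        phases = np.tile([0.0, np.pi / 2, np.pi, -np.pi / 2], 25)
        assert mvl(phases) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_bessel_calibration(self, rng):
        """MVL of von Mises(kappa=2) samples matches I1(2)/I0(2)."""
        phases = stats.vonmises.rvs(2.0, size=10000, random_state=rng)
        expected = special.i1(2.0) / special.i0(2.0)
        assert mvl(phases) == pytest.approx(expected, abs=0.02)

    def test_rotation_invariance(self, rng):
        phases = rng.vonmises(0.5, 1.5, size=5000)
        rot = np.angle(np.exp(1j * (phases + 1.1)))
        assert mvl(rot) == pytest.approx(mvl(phases), abs=1e-12)
        d = preferred_phase(rot) - preferred_phase(phases)
        assert np.angle(np.exp(1j * (d - 1.1))) == pytest.approx(0.0, abs=1e-9)

    def test_no_valid_spikes_flagged(self):
        ref = _bandsig(np.zeros(1000))
        res = spike_phase_coupling(np.asarray([]), ref, "u")
        assert res.flagged and np.isnan(res.mvl)

    def test_stability_of_stationary_locked_unit(self, rng):
        """A stationary, strongly locked unit keeps its preferred phase
        between the first and last session thirds (< 20 degrees)."""
        fs = 1000.0
        duration = 600.0
        t = np.arange(int(duration * fs)) / fs
        phase = np.angle(np.exp(1j * 2 * np.pi * 5.0 * t))
        ref = _bandsig(phase, fs)
        deltas = []
        for s in range(10):
            r = np.random.default_rng(s)
            spike_phases = r.vonmises(1.0, 2.0, size=3000)
            k = r.integers(0, int(5.0 * duration), size=3000)
            tt = np.sort((k + (spike_phases + np.pi) / (2 * np.pi)) / 5.0)
            tt = tt[tt < duration]
            deltas.append(phase_stability(tt, ref, duration))
        assert np.degrees(np.nanmean(deltas)) < 20.0


class TestSpikeTriggeredEnvelope:
    def test_spikes_at_peaks(self):
        fs = 1000.0
        env = 1.0 + np.cos(2 * np.pi * 1.0 * np.arange(int(60 * fs)) / fs)
        spikes = np.arange(2.0, 58.0)  # at envelope peaks
        lags, curve, n, _ = spike_triggered_envelope(spikes, env, fs)
        assert curve[np.argmin(np.abs(lags))] == curve.max()
        assert curve.max() > 1.0

    def test_independent_spikes_flat(self, rng):
        fs = 1000.0
        env = 1.0 + 0.5 * rng.standard_normal(int(120 * fs)) ** 2
        spikes = np.sort(rng.uniform(1.0, 119.0, 2000))
        _, curve, _, _ = spike_triggered_envelope(spikes, env, fs)
        assert abs(curve.mean() - 1.0) < 0.05
        assert curve.std() / curve.mean() < 0.05

    def test_fbi_units_elevated(self, spont, spont_gamma):
        session, _ = spont
        tt = np.sort(np.concatenate(
            [u.spike_times for u in session.units("FBI")]))
        lags, curve, _, _ = spike_triggered_envelope(
            tt, spont_gamma.amplitude, session.fs)
        assert curve[np.argmin(np.abs(lags))] > 1.2


class TestSpecificityIndex:
    @staticmethod
    def _rates_for(per_odor_hz, n_trials=4, fs=100.0):
        """One unit firing at a constant odor-dependent rate."""
        n_odors = len(per_odor_hz)
        trial_len = 1.5
        duration = n_odors * n_trials * trial_len + 1.0
        n = int(duration * fs)
        rates = np.zeros((1, n))
        trials = []
        k = 0
        for o, hz in enumerate(per_odor_hz):
            for _ in range(n_trials):
                a = 0.5 + k * trial_len
                rates[0, int(a * fs): int((a + 1.0) * fs)] = hz
                trials.append((a, o))
                k += 1
        rm = RateMatrix(rates, fs, ["u"], 10.0)
        return rm, trials

    @pytest.mark.parametrize("per_odor,expected", [
        ((4.0, 4.0, 4.0, 4.0, 4.0, 4.0), 1.0 / 6.0),
        ((5.0, 0.0, 0.0, 0.0, 0.0, 0.0), 1.0),
        ((10.0, 2.0, 2.0, 2.0, 2.0, 2.0), 0.5),
    ])
    def test_si_formula(self, per_odor, expected):
        rm, trials = self._rates_for(per_odor)
        res = specificity_index(rm, trials)
        np.testing.assert_allclose(res.si[0], expected, atol=1e-9)

    def test_all_zero_window_flagged(self):
        rm, trials = self._rates_for((0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
        res = specificity_index(rm, trials)
        assert np.all(np.isnan(res.si))
        assert res.n_undefined > 0

    def test_population_curve_tracks_envelope(self, odor_pair, odor_rates):
        from respgamma import pipeline

        (ctrl, truth), _ = odor_pair
        rates_c, _ = odor_rates
        out = pipeline.specificity_summary(ctrl, rates_c,
                                           truth.gamma_envelope, ctrl.fs)
        assert out["envelope_corr_r"] > 0.5
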