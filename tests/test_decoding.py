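"""Population vectors, odor decoding, phase-resolved decoding."""

import numpy as np
import pytest
from scipy import stats

from respgamma.decoding import (
    DecodingResult,
    PopulationVectors,
    accuracy_gamma_correlation,
    decode_odors,
    phase_resolved_decoding,
    popvec_correlations,
    population_vectors,
    profile_shift_surrogates,
)
from respgamma.spiking import RateMatrix


def _toy_rates(seed=0, n_cells=30, n_trials_per_odor=8, n_odors=4,
               odor_gain=None, fs=100.0):
    """Rates with (optional) odor-specific cell gains in 0.15-0.25 s."""
    rng = np.random.default_rng(seed)
    trial_len = 1.5
    n_trials = n_trials_per_odor * n_odors
    duration = n_trials * trial_len + 1.0
    n = int(duration * fs)
    rates = 3.0 + np.abs(rng.normal(0, 1.0, size=(n_cells, n)))
    trials = []
    order = rng.permutation(np.repeat(np.arange(n_odors), n_trials_per_odor))
    t = np.arange(n) / fs
    for k, o in enumerate(order):
        a = 0.5 + k * trial_len
        trials.append((a, int(o)))
        if odor_gain:
            cells = np.arange(o * 5, o * 5 + 5)
            bump = np.exp(-0.5 * ((t - a - 0.2) / 0.04) ** 2)
            rates[cells] += odor_gain * bump[None, :]
    rm = RateMatrix(rates, fs, [f"c{i}" for i in range(n_cells)], 10.0)
    return rm, trials


class TestPopulationVectors:
    def test_sliding_window_count(self):
        rm, trials = _toy_rates()
        pv = population_vectors(rm, trials)
        # (1000 - 100) / 37.5 + 1 = 25 sliding windows
        assert pv.window_centers.size == 25
        assert set(pv.fixed) == {"pre", "gamma", "post"}

    def test_constant_rates_identical_vectors(self):
        rm, trials = _toy_rates()
        rm.rates[:] = np.arange(rm.n_units)[:, None] * 1.0
        pv = population_vectors(rm, trials)
        assert np.allclose(pv.X.std(axis=0), 0.0)

    def test_planted_gain_separates_odors(self):
        rm, trials = _toy_rates(odor_gain=20.0)
        pv = population_vectors(rm, trials)
        g = pv.fixed["gamma"]
        odors = np.unique(pv.labels)
        means = np.stack([g[pv.labels == o].mean(axis=0) for o in odors])
        within = np.mean([np.linalg.norm(g[pv.labels == o] - means[i], axis=1).mean()
                          for i, o in enumerate(odors)])
        between = np.mean([np.linalg.norm(means[i] - means[j])
                           for i in range(len(odors)) for j in range(i + 1, len(odors))])
        assert between > within


class TestPopvecCorrelations:
    def test_identical_responses_r_one(self):
        rm, trials = _toy_rates()
        rm.rates[:] = np.arange(rm.n_units)[:, None] + 1.0
        out = popvec_correlations(population_vectors(rm, trials))
        np.testing.assert_allclose(out["curve"], 1.0)

    def test_anticorrelated_patterns(self):
        base = np.asarray([5.0, 1.0, 5.0, 1.0, 5.0, 1.0])
        X = np.stack([np.tile(base, (4, 1)), np.tile(base[::-1], (4, 1))])
        X = np.concatenate(X)  # 8 trials x 6 cells
        labels = np.repeat([0, 1], 4)
        pv = PopulationVectors(X[:, None, :], np.asarray([0.2]), labels,
                               {"gamma": X}, 0.1)
        out = popvec_correlations(pv)
        assert out["fixed"]["gamma"] == pytest.approx(-1.0)

    def test_gamma_window_decorrelates_on_fixture(self, odor_pair, odor_rates):
        from respgamma import pipeline

        (ctrl, _), _ = odor_pair
        rates_c, _ = odor_rates
        out = pipeline.decoding_summary(ctrl, rates=rates_c, repeats=5,
                                        seed=0, windows="fixed")["popvec"]
        assert out["fixed"]["gamma"] < out["fixed"]["pre"]
        assert out["fixed"]["gamma"] < out["fixed"]["post"]


class TestDecodeOdors:
    def test_shuffled_labels_at_chance(self):
        rm, trials = _toy_rates(odor_gain=20.0)
        rng = np.random.default_rng(3)
        shuffled = [(a, int(o)) for (a, _), o in
                    zip(trials, rng.permutation([o for _, o in trials]))]
        pv = population_vectors(rm, shuffled)
        res = decode_odors(pv, repeats=30, windows="fixed", seed=1)
        n_test = int(np.ceil(len(trials) / 3))
        ci = 1.96 * np.sqrt(res.chance * (1 - res.chance) / n_test)
        assert np.all(np.abs(res.mean_accuracy - res.chance) < ci)

    def test_planted_signal_decoded_in_gamma_window(self):
        rm, trials = _toy_rates(odor_gain=20.0)
        pv = population_vectors(rm, trials)
        res = decode_odors(pv, repeats=30, windows="fixed", seed=1)
        accs = dict(zip(res.window_names, res.mean_accuracy))
        assert accs["gamma"] > 3 * res.chance
        assert accs["pre"] < accs["gamma"]

    def test_identical_trials_chance_all_classifiers(self):
        rm, trials = _toy_rates()
        rm.rates[:] = 2.0
        rm.rates += np.random.default_rng(0).normal(0, 0.01, rm.rates.shape)
        pv = population_vectors(rm, trials)
        n_test = int(np.ceil(len(trials) / 3))
        ci = 1.96 * np.sqrt((1 / 4) * (3 / 4) / n_test)
        for clf in ("sgd-svm", "lda", "knn"):
            res = decode_odors(pv, classifier=clf, repeats=20,
                               windows="fixed", seed=2)
            assert np.all(res.mean_accuracy < 0.25 + ci + 0.05)

    def test_repeat_structure_and_determinism(self):
        rm, trials = _toy_rates(odor_gain=10.0)
        pv = population_vectors(rm, trials)
        a = decode_odors(pv, repeats=10, windows="fixed", seed=7)
        b = decode_odors(pv, repeats=10, windows="fixed", seed=7)
        assert a.accuracy.shape[0] == 10
        np.testing.assert_array_equal(a.accuracy, b.accuracy)


class TestAccuracyGammaCorrelation:
    def test_affine_relation_r_one(self):
        centers = np.linspace(0.05, 0.95, 20)
        env = np.exp(-0.5 * ((np.linspace(0, 1, 200) - 0.2) / 0.1) ** 2)
        acc_curve = 0.2 + 0.6 * np.interp(centers, np.linspace(0, 1, 200), env)
        res = DecodingResult(centers, np.tile(acc_curve, (5, 1)), "sgd-svm", 1 / 6)
        r, _ = accuracy_gamma_correlation(res, np.linspace(0, 1, 200), env)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_constant_accuracy_flagged(self):
        centers = np.linspace(0.05, 0.95, 10)
        res = DecodingResult(centers, np.full((3, 10), 0.5), "sgd-svm", 1 / 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = accuracy_gamma_correlation(res, centers, np.sin(centers))
        assert np.isnan(r)

    def test_too_few_windows_error(self):
        res = DecodingResult(np.asarray([0.1, 0.2]), np.full((3, 2), 0.5),
                             "sgd-svm", 1 / 6)
        with pytest.raises(ValueError, match=">= 3"):
            accuracy_gamma_correlation(res, np.asarray([0.1, 0.2]),
                                       np.asarray([0.0, 1.0]))


class TestPhaseResolved:
    def test_single_bin_error(self, flat_session):
        from respgamma import pipeline

        session, _ = flat_session
        with pytest.raises(ValueError, match="phase bins"):
            phase_resolved_decoding(
                pipeline.principal_units(session),
                pipeline.gamma_signal(session),
                pipeline.odor_trials(session), n_bins=1)

    def test_surrogate_distribution_seed_invariant(self):
        """At n=10,000 the surrogate MI distribution is stable across RNG
        seeds (KS distance < 0.05)."""
        rng = np.random.default_rng(0)
        profiles = 0.4 + 0.2 * rng.random((4, 8))
        a = profile_shift_surrogates(profiles, 10000, rng=1)
        b = profile_shift_surrogates(profiles, 10000, rng=2)
        assert stats.ks_2samp(a, b).statistic < 0.05

    def test_gated_fixture_exceeds_surrogates(self, gated_session):
        from respgamma import pipeline

        session, _ = gated_session
        res = phase_resolved_decoding(
            pipeline.principal_units(session), pipeline.gamma_signal(session),
            pipeline.odor_trials(session), repeats=10, n_surrogates=10000,
            seed=23)
        assert res.percentile > 95.0

    def test_flat_fixture_inside_surrogates(self, flat_session):
        from respgamma import pipeline

        session, _ = flat_session
        res = phase_resolved_decoding(
            pipeline.principal_units(session), pipeline.gamma_signal(session),
            pipeline.odor_trials(session), repeats=10, n_surrogates=10000,
            seed=23)
        assert 2.5 <= res.percentile <= 97.5
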