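"""End-to-end analyses composed from the module-level operations.

These helpers encode the canonical parameter choices (bands, windows,
masks) so the CLI, the test-suite fixtures and the acceptance script all
run the identical pipeline.
"""

from __future__ import annotations

import numpy as np

from . import assemblies, coupling, csd, decoding, directionality, spiking
from .session import Session, SpikeTrain
from .spiking import RateMatrix
from .synth import SynthConfig

LOW_GAMMA = (30.0, 60.0)
BETA = (10.0, 20.0)
RESP_BAND = (1.0, 4.0)


# ---------------------------------------------------------------------------
# canonical synthetic configurations
# ---------------------------------------------------------------------------

def spontaneous_config(seed: int, duration_s: float = 120.0) -> SynthConfig:
    """Odorless session for the respiration/gamma mechanism analyses."""
    return SynthConfig(duration_s=duration_s, seed=seed, first_odor_s=1e9)


def odor_config(seed: int, duration_s: float = 720.0) -> SynthConfig:
    """Odor-rich session for specificity/assembly/decoding analyses."""
    return SynthConfig(duration_s=duration_s, seed=seed,
                       n_channels=4, reversal_channel=4)


def phase_gated_config(seed: int, duration_s: float = 420.0,
                       kappa: float = 3.0) -> SynthConfig:
    """Odor session whose winner gain is gated to one gamma phase."""
    return SynthConfig(duration_s=duration_s, seed=seed,
                       n_channels=2, reversal_channel=2,
                       winner_phase_gate_kappa=kappa)


def phase_flat_config(seed: int, duration_s: float = 420.0) -> SynthConfig:
    """Null fixture for phase-resolved decoding: no phase-gated winner
    gain and no loser phase locking, so the accuracy-by-phase profile has
    no planted structure."""
    return SynthConfig(duration_s=duration_s, seed=seed,
                       n_channels=2, reversal_channel=2,
                       winner_phase_gate_kappa=0.0, loser_gamma_locking=0.0)


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------

def odor_trials(session: Session, window_s: float = 1.0) -> list[tuple[float, int]]:
    """(inhalation time, odor id) for inhalations within ``window_s`` of
    an odor onset."""
    ev = session.events
    out = []
    for on, oid in zip(ev.odor_onsets, ev.odor_ids):
        hit = ev.inhalation_times[
            (ev.inhalation_times >= on) & (ev.inhalation_times < on + window_s)
        ]
        out += [(float(t), int(oid)) for t in hit]
    return sorted(out)


def principal_units(session: Session, use_all: bool = False) -> list[SpikeTrain]:
    """EXC units; with ``use_all`` (no opto labels, e.g. ablation
    experiments) every unit is used."""
    if use_all:
        return list(session.spikes)
    exc = session.units("EXC")
    return exc if exc else list(session.spikes)


def gamma_signal(session: Session, band=LOW_GAMMA, channel: int = 0) -> coupling.BandSignal:
    return coupling.band_phase_amplitude(session.lfp[channel], band)


def session_rates(session: Session, fs_out: float = 200.0,
                  normalize: str = "none") -> RateMatrix:
    return spiking.smooth_normalize_rates(session.spikes, session.duration,
                                          fs_out=fs_out, normalize=normalize)


# ---------------------------------------------------------------------------
# mechanism analyses (respiration -> gamma)
# ---------------------------------------------------------------------------

def resp_gamma_mi(session: Session, channel: int = 0) -> float:
    """Modulation index of low-gamma amplitude by respiration phase."""
    ph = coupling.band_phase_amplitude(session.resp, RESP_BAND)
    am = gamma_signal(session, channel=channel)
    return coupling.modulation_index(ph, am, empty_bin="smooth").MI


def rhythm_summary(session: Session, channel: int = 0,
                   n_surrogates: int = 200, seed: int = 0) -> dict:
    """Respiration-phase comodulogram peak and Resp->low-gamma MI with a
    circular-shift surrogate threshold."""
    com = coupling.comodulogram(session, phase_source="resp", channel=channel)
    peak_phase, peak_amp = com.argmax_cell()
    ph = coupling.band_phase_amplitude(session.resp, RESP_BAND)
    am = gamma_signal(session, channel=channel)
    mi = coupling.modulation_index(ph, am, empty_bin="smooth").MI
    surr = coupling.mi_surrogates(ph, am, n_surrogates=n_surrogates, rng=seed)
    return {
        "comodulogram": com,
        "peak_phase_hz": peak_phase,
        "peak_amp_hz": peak_amp,
        "resp_gamma_mi": mi,
        "surrogate_p95": float(np.percentile(surr, 95.0)),
    }


def directionality_summary(session: Session, channel: int = 0) -> dict:
    env = gamma_signal(session, channel=channel).amplitude
    fs = session.fs
    anchors = session.events.inhalation_times
    lags, mean, sem, n = directionality.triggered_envelope(env, fs, anchors)
    post = lags >= 0
    peak_latency = float(lags[post][np.argmax(mean[post])])
    xl, xr = directionality.envelope_crosscorr(env, session.resp.samples, fs)
    g = directionality.granger_logF(session.resp.samples, env, fs)
    return {
        "triggered_lags": lags, "triggered_mean": mean, "triggered_sem": sem,
        "peak_latency_s": peak_latency,
        "xcorr_peak_lag_s": float(xl[np.argmax(xr)]),
        "logF_resp_to_gamma": g.logF_x_to_y,
        "logF_gamma_to_resp": g.logF_y_to_x,
    }


def evoked_induced_summary(session: Session, channel: int = 0) -> dict:
    anchors = session.events.inhalation_times
    tr = session.lfp[channel]
    out = {}
    for name, band in (("beta", BETA), ("gamma", LOW_GAMMA)):
        dec = csd.amplitude_decomposition(tr, band, anchors)
        k = int(np.argmax(dec.induced))
        out[name] = dec
        out[f"{name}_itc_peak"] = float(dec.itc.max())
        out[f"{name}_itc_peak_latency_s"] = float(dec.lags_s[np.argmax(dec.itc)])
        out[f"{name}_evoked_induced_ratio"] = float(dec.evoked[k] / dec.induced[k])
    return out


def csd_summary(session: Session, reversal_channel: int | None = None) -> dict:
    lam = csd.csd_profile(session)
    rev = reversal_channel
    if rev is None:
        rev = int(session.meta.get("reversal_channel", len(session.lfp) // 2))
    flip = np.nan
    if 1 <= rev <= len(session.lfp) - 2:
        a = lam.csd[rev - 1]
        b = lam.csd[rev]
        t = int(np.nanargmax(np.abs(a)))
        flip = float(a[t] * b[t])
    return {"laminar": lam, "reversal_product": flip}


# ---------------------------------------------------------------------------
# spiking / odor analyses
# ---------------------------------------------------------------------------

def fbi_envelope_correlation(session: Session, envelope: np.ndarray,
                             env_fs: float, rates: RateMatrix | None = None) -> float:
    """Pearson r between the inhalation-triggered mean FBI rate and the
    triggered gamma envelope."""
    from scipy import stats

    fbi = session.units("FBI")
    if not fbi:
        raise ValueError("no FBI units")
    rm = rates if rates is not None else spiking.smooth_normalize_rates(
        fbi, session.duration, fs_out=200.0)
    rows = [rm.unit_ids.index(u.unit_id) for u in fbi if u.unit_id in rm.unit_ids]
    mean_rate = rm.rates[rows].mean(axis=0)
    anchors = session.events.inhalation_times
    _, rate_curve, _, _ = directionality.triggered_envelope(
        mean_rate, rm.fs, anchors, span=(0.0, 0.4))
    lags, env_curve, _, _ = directionality.triggered_envelope(
        envelope, env_fs, anchors, span=(0.0, 0.4))
    env_i = np.interp(np.arange(rate_curve.size) / rm.fs,
                      lags - lags[0], env_curve)
    return float(stats.pearsonr(rate_curve, env_i)[0])


def specificity_summary(session: Session, rates: RateMatrix,
                        envelope: np.ndarray, env_fs: float) -> dict:
    """Population SI curve and its correlation with the triggered
    envelope."""
    from scipy import stats

    trials = odor_trials(session)
    pr_ids = {u.unit_id for u in principal_units(session)}
    rows = [i for i, uid in enumerate(rates.unit_ids) if uid in pr_ids]
    sub = RateMatrix(rates.rates[rows], rates.fs,
                     [rates.unit_ids[i] for i in rows],
                     rates.kernel_sd_ms, rates.normalization)
    res = spiking.specificity_index(sub, trials)
    anchors = np.asarray([a for a, _ in trials])
    lags, env_curve, _, _ = directionality.triggered_envelope(
        envelope, env_fs, anchors, span=(0.0, 1.0))
    env_i = np.interp(res.window_centers, lags - lags[0], env_curve)
    r = float(stats.pearsonr(res.population, env_i)[0])
    return {"specificity": res, "envelope_corr_r": r}


def assembly_analysis(session: Session, rates: RateMatrix | None = None,
                      use_all_cells: bool = False, seed: int = 0,
                      envelope: np.ndarray | None = None,
                      env_fs: float | None = None) -> dict:
    """Per-odor assembly weights, cross-odor similarity and time courses.

    Returns the dict consumed by
    :func:`respgamma.assemblies.winner_take_all_report`.
    """
    rates = rates if rates is not None else session_rates(session)
    trials = odor_trials(session)
    pr = principal_units(session, use_all=use_all_cells)
    pr_ids = [u.unit_id for u in pr]
    rows = [rates.unit_ids.index(uid) for uid in pr_ids]
    sub = RateMatrix(rates.rates[rows], rates.fs, pr_ids,
                     rates.kernel_sd_ms, rates.normalization)
    odors = sorted({o for _, o in trials})
    weights = []
    for o in odors:
        anchors = np.asarray([a for a, oo in trials if oo == o])
        weights.append(assemblies.assembly_weights(sub, anchors, o, seed=seed))
    sim = assemblies.cross_odor_similarity(weights)
    if envelope is None:
        bs = gamma_signal(session)
        envelope, env_fs = bs.amplitude, session.fs
    # per-odor winner/loser curves (odor-specific anchors), averaged across
    # odors — each odor contributes its own winner-odor / loser-odor pairs
    fbi_rows = np.asarray([i for i, u in enumerate(session.spikes)
                           if u.unit_class == "FBI"], dtype=int)
    fbi_ids = [session.spikes[i].unit_id for i in fbi_rows]
    fbi_in_rates = np.asarray([rates.unit_ids.index(uid) for uid in fbi_ids
                               if uid in rates.unit_ids], dtype=int)
    curves: dict[str, list[np.ndarray]] = {"winners": [], "losers": [],
                                           "fbi": [], "envelope": []}
    lags = None
    for w in weights:
        anchors = np.asarray([a for a, oo in trials if oo == w.odor_id])
        tc = assemblies.assembly_timecourses(
            sub, w.winners, w.losers, np.empty(0, dtype=int),
            envelope, env_fs, anchors)
        lags = tc["lags_s"]
        for key in ("winners", "losers", "envelope"):
            if key in tc:
                curves[key].append(tc[key])
    if fbi_in_rates.size:
        all_anchors = np.asarray([a for a, _ in trials])
        tc_fbi = assemblies.assembly_timecourses(
            rates, np.empty(0, dtype=int), np.empty(0, dtype=int),
            fbi_in_rates, envelope, env_fs, all_anchors)
        if "fbi" in tc_fbi:
            curves["fbi"].append(tc_fbi["fbi"])
    tc_out: dict = {"lags_s": lags}
    for key, lst in curves.items():
        if lst:
            tc_out[key] = np.mean(lst, axis=0)
    return {"weights": weights, "similarity": sim, "timecourses": tc_out,
            "unit_ids": pr_ids}


def decoding_summary(session: Session, rates: RateMatrix | None = None,
                     classifiers=("sgd-svm",), repeats: int = 100,
                     seed: int = 0, windows: str = "fixed") -> dict:
    rates = rates if rates is not None else session_rates(session)
    trials = odor_trials(session)
    pr_ids = {u.unit_id for u in principal_units(session)}
    rows = [i for i, uid in enumerate(rates.unit_ids) if uid in pr_ids]
    sub = RateMatrix(rates.rates[rows], rates.fs,
                     [rates.unit_ids[i] for i in rows],
                     rates.kernel_sd_ms, rates.normalization)
    pv = decoding.population_vectors(sub, trials)
    out = {"pv": pv}
    for clf in classifiers:
        out[clf] = decoding.decode_odors(pv, classifier=clf, repeats=repeats,
                                         seed=seed, windows=windows)
    out["popvec"] = decoding.popvec_correlations(pv)
    return out


# ---------------------------------------------------------------------------
# full pipeline run (summary numbers)
# ---------------------------------------------------------------------------

def run_full_analysis(seed: int, fast: bool = False) -> dict:
    """Run the whole pipeline on freshly generated sessions.

    Returns ``{name: {"value": float, "n": int}}`` where ``n`` is the
    problem size behind each number.  ``fast`` halves the session
    durations and repeat counts (used for determinism checks).
    """
    from scipy import stats as sstats

    from . import decoding as dec
    from .session import detect_inhalations
    from .spiking import mvl as _mvl
    from .synth import ablate_recurrence, generate_session

    ss = np.random.SeedSequence(seed)
    sd = [int(s) % (2**31 - 1) for s in ss.generate_state(8)]
    out: dict = {}

    def put(name, value, n):
        out[name] = {"value": float(value), "n": int(n)}

    # --- mechanism analyses on a spontaneous (odorless) session ---
    spont_dur = 60.0 if fast else 120.0
    sess, truth = generate_session(spontaneous_config(sd[0], spont_dur))

    det = detect_inhalations(sess.resp)
    gt = truth.inhalation_times
    hits = np.mean([np.min(np.abs(det - g)) <= 0.025 for g in gt]) if det.size else 0.0
    put("inhalation_detection_hit_rate_pct", 100.0 * hits, gt.size)

    rs = rhythm_summary(sess, n_surrogates=100 if fast else 200, seed=sd[5])
    put("comod_peak_phase_freq_hz", rs["peak_phase_hz"], gt.size)
    put("comod_peak_amp_freq_hz", rs["peak_amp_hz"], gt.size)
    put("resp_gamma_mi", rs["resp_gamma_mi"], gt.size)
    put("resp_gamma_mi_surrogate_p95", rs["surrogate_p95"], 100 if fast else 200)

    ds = directionality_summary(sess)
    put("triggered_gamma_peak_latency_ms", ds["peak_latency_s"] * 1e3, gt.size)
    put("xcorr_peak_lag_ms", ds["xcorr_peak_lag_s"] * 1e3, gt.size)
    put("granger_logF_resp_to_gamma", ds["logF_resp_to_gamma"], gt.size)
    put("granger_logF_gamma_to_resp", ds["logF_gamma_to_resp"], gt.size)

    ei = evoked_induced_summary(sess)
    put("beta_itc_peak", ei["beta_itc_peak"], gt.size)
    put("beta_itc_peak_latency_ms", ei["beta_itc_peak_latency_s"] * 1e3, gt.size)
    put("beta_evoked_induced_ratio", ei["beta_evoked_induced_ratio"], gt.size)
    put("gamma_itc_max", float(ei["gamma"].itc.max()), gt.size)
    put("gamma_evoked_induced_ratio", ei["gamma_evoked_induced_ratio"], gt.size)

    cs = csd_summary(sess)
    put("csd_reversal_product", cs["reversal_product"], cs["laminar"].trigger_count)
    put("fbi_rate_envelope_corr_r",
        fbi_envelope_correlation(sess, truth.gamma_envelope, sess.fs), gt.size)

    # MVL calibration against the von Mises closed form I1(k)/I0(k)
    rng = np.random.default_rng(sd[6])
    phases = sstats.vonmises.rvs(2.0, size=10000, random_state=rng)
    put("mvl_vonmises_kappa2", _mvl(phases), 10000)

    # --- ablated spontaneous session: gamma power and coupling loss ---
    from .spectral import welch_whitened_psd

    sess_a, _ = generate_session(ablate_recurrence(spontaneous_config(sd[0], spont_dur)))
    psd_c = welch_whitened_psd(sess.lfp[0])
    psd_a = welch_whitened_psd(sess_a.lfp[0])
    band = (psd_c.freqs >= 30) & (psd_c.freqs <= 60)
    put("gamma_power_ablated_over_control_pct",
        100.0 * psd_a.power[band].mean() / psd_c.power[band].mean(), int(band.sum()))
    put("resp_gamma_mi_ablated", resp_gamma_mi(sess_a), gt.size)

    # --- odor sessions: specificity, assemblies, decoding ---
    odor_dur = 300.0 if fast else 600.0
    repeats = 40 if fast else 100
    cfg_o = odor_config(sd[1], odor_dur)
    so, to = generate_session(cfg_o)
    sa, ta = generate_session(ablate_recurrence(cfg_o))
    rates_o = session_rates(so)
    rates_a = session_rates(sa)
    trials = odor_trials(so)

    si = specificity_summary(so, rates_o, to.gamma_envelope, so.fs)
    put("si_envelope_corr_r", si["envelope_corr_r"], len(trials))

    res_c = assembly_analysis(so, rates=rates_o, seed=sd[5],
                              envelope=to.gamma_envelope, env_fs=so.fs)
    res_a = assembly_analysis(sa, rates=rates_a, use_all_cells=True, seed=sd[5],
                              envelope=ta.gamma_envelope, env_fs=sa.fs)
    recalls = []
    for w in res_c["weights"]:
        planted = set(int(i) for i in to.winner_sets[w.odor_id])
        found = set(int(res_c["unit_ids"][i][3:]) for i in w.winners
                    if str(res_c["unit_ids"][i]).startswith("exc"))
        recalls.append(len(planted & found) / len(planted))
    put("winner_recall_mean_pct", 100.0 * np.mean(recalls), len(recalls))
    from .assemblies import winner_take_all_report

    rep = winner_take_all_report(res_c, res_a)
    put("assembly_skewness_control", rep.skewness["control"], len(res_c["weights"]))
    put("assembly_skewness_ablated", rep.skewness["ablated"], len(res_a["weights"]))
    put("loser_fraction_control_pct", 100 * rep.loser_fraction["control"], 200)
    put("loser_fraction_ablated_pct", 100 * rep.loser_fraction["ablated"], 215)
    put("loser_inhibition_depth_control_z",
        rep.loser_inhibition_depth["control"], len(trials))
    put("loser_inhibition_depth_ablated_z",
        rep.loser_inhibition_depth["ablated"], len(odor_trials(sa)))
    put("cross_odor_mean_r_control", rep.cross_odor_mean_r["control"], 15)
    put("cross_odor_mean_r_ablated", rep.cross_odor_mean_r["ablated"], 15)
    put("cross_odor_significant_pairs_control",
        int(res_c["similarity"].significant.sum() // 2), 15)

    dec_c = decoding_summary(so, rates=rates_o, repeats=repeats, seed=sd[5],
                             windows="fixed")
    dr = dec_c["sgd-svm"]
    accs = dict(zip(dr.window_names, dr.mean_accuracy))
    n_tr = len(trials)
    put("decoding_accuracy_pre_pct", 100 * accs["pre"], n_tr)
    put("decoding_accuracy_gamma_pct", 100 * accs["gamma"], n_tr)
    put("decoding_accuracy_post_pct", 100 * accs["post"], n_tr)
    put("decoding_chance_pct", 100 * dr.chance, n_tr)
    pvr = dec_c["popvec"]["fixed"]
    put("popvec_corr_pre", pvr["pre"], n_tr)
    put("popvec_corr_gamma", pvr["gamma"], n_tr)
    put("popvec_corr_post", pvr["post"], n_tr)
    dec_a = decoding_summary(sa, rates=rates_a, repeats=repeats, seed=sd[5],
                             windows="fixed")
    put("decoding_accuracy_gamma_ablated_pct",
        100 * dict(zip(dec_a["sgd-svm"].window_names,
                       dec_a["sgd-svm"].mean_accuracy))["gamma"],
        len(odor_trials(sa)))

    # sliding-window accuracy vs the triggered gamma envelope
    slide = decoding_summary(so, rates=rates_o, repeats=max(20, repeats // 2),
                             seed=sd[5], windows="sliding")["sgd-svm"]
    anchors = np.asarray([a for a, _ in trials])
    env = gamma_signal(so).amplitude
    lags, env_curve, _, _ = directionality.triggered_envelope(
        env, so.fs, anchors, span=(0.0, 1.0))
    r, _ = dec.accuracy_gamma_correlation(slide, lags - lags[0], env_curve)
    put("accuracy_gamma_corr_r", r, slide.window_centers.size)

    # --- phase-resolved decoding with circular-shift surrogates ---
    ph_dur = 240.0 if fast else 420.0
    n_surr = 2000 if fast else 10000
    sg, _ = generate_session(phase_gated_config(sd[2], ph_dur))
    n_blocks = 2 if fast else 4
    res_g = dec.phase_resolved_decoding(
        principal_units(sg), gamma_signal(sg), odor_trials(sg),
        n_blocks=n_blocks, repeats=10 if fast else 15,
        n_surrogates=n_surr, seed=sd[5])
    put("phase_decoding_real_mi", res_g.mi_real, n_surr)
    put("phase_decoding_real_mi_percentile", res_g.percentile, n_surr)
    sf, _ = generate_session(phase_flat_config(sd[3], ph_dur))
    res_f = dec.phase_resolved_decoding(
        principal_units(sf), gamma_signal(sf), odor_trials(sf),
        n_blocks=n_blocks, repeats=10 if fast else 15,
        n_surrogates=n_surr, seed=sd[5])
    put("phase_decoding_null_percentile", res_f.percentile, n_surr)
    return out
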