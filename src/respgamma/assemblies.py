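"""Per-odor ICA assembly weights and the winner-take-all quantification.

For each odor, the smoothed principal-cell rates inside all 1000 ms
windows following inhalation start (during that odor's delivery) are
concatenated in time and a single independent component is extracted.
The component sign is fixed so the weight skewness is non-negative;
cells with weights above the 95th percentile are *winners*, cells with
weights below the component mean are *losers*.  Cross-odor similarity is
the Pearson correlation of weight vectors, Bonferroni-corrected over the
odor pairs; winner-take-all degradation (ablated vs control) is
summarized by weight skewness, loser fraction, loser-inhibition depth,
and the mean cross-odor correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .spiking import RateMatrix


@dataclass
class AssemblyWeights:
    odor_id: int
    weights: np.ndarray
    winners: np.ndarray          # cell indices
    losers: np.ndarray           # cell indices
    skewness: float
    n_components_used: int = 1
    unit_ids: list | None = None


@dataclass
class CrossOdorSimilarity:
    odor_ids: list
    r: np.ndarray                # symmetric, diag 1
    p: np.ndarray
    significant: np.ndarray      # Bonferroni-corrected flags
    n_pairs: int


@dataclass
class WinnerTakeAllReport:
    skewness: dict
    loser_fraction: dict
    loser_inhibition_depth: dict
    cross_odor_mean_r: dict

    def differences(self) -> dict:
        return {
            k: self.__dict__[k]["control"] - self.__dict__[k]["ablated"]
            for k in ("skewness", "loser_fraction", "loser_inhibition_depth",
                      "cross_odor_mean_r")
        }


def _odor_window_matrix(
    rates: RateMatrix,
    anchors: np.ndarray,
    window_s: float = 1.0,
) -> np.ndarray:
    """time x cells matrix of concatenated per-window rate segments."""
    fs = rates.fs
    nwin = int(round(window_s * fs))
    segs = []
    for a in np.atleast_1d(anchors):
        i0 = int(round(a * fs))
        if i0 < 0 or i0 + nwin > rates.rates.shape[1]:
            continue
        segs.append(rates.rates[:, i0: i0 + nwin])
    if len(segs) < 2:
        raise ValueError("need >= 2 usable windows for ICA")
    return np.concatenate(segs, axis=1).T


def assembly_weights(
    rates: RateMatrix,
    anchors: np.ndarray,
    odor_id: int,
    window_s: float = 1.0,
    n_components: int = 1,
    seed: int = 0,
    max_iter: int = 500,
) -> AssemblyWeights:
    """First-IC assembly weights with winner/loser labels for one odor.

    ``anchors`` are the inhalation onsets during this odor's delivery.
    ICA is seeded; on non-convergence the fit is retried with up to 3
    seeds before raising.  Multi-component mode (``n_components`` > 1)
    returns the component with the largest absolute skewness, which
    reduces to the single-component path at k = 1.
    """
    if rates.n_units < 2:
        raise ValueError("need >= 2 cells")
    X = _odor_window_matrix(rates, anchors, window_s)
    sd = X.std(axis=0)
    if np.count_nonzero(sd > 0) < 2:
        raise ValueError("rank-deficient input: fewer than 2 active cells")
    # center only: weights keep the cells' absolute (Hz) response scale,
    # as when ICA runs directly on smoothed spiking activity
    Xz = X - X.mean(axis=0)
    comp = _fit_ica(Xz, n_components, seed, max_iter)
    if n_components > 1:
        skews = np.abs(stats.skew(comp @ Xz.T, axis=1))
        weights = comp[np.argmax(skews)]
    else:
        weights = comp[0]
    sk = float(stats.skew(weights))
    if sk < 0:
        weights = -weights
        sk = -sk
    winners = np.flatnonzero(weights > np.percentile(weights, 95.0))
    losers = np.flatnonzero(weights < weights.mean())
    return AssemblyWeights(odor_id, weights, winners, losers, sk,
                           n_components, list(rates.unit_ids))


def _fit_ica(Xz: np.ndarray, n_components: int, seed: int, max_iter: int) -> np.ndarray:
    last_err = None
    for attempt in range(3):
        ica = FastICA(n_components=n_components, random_state=seed + attempt,
                      max_iter=max_iter, whiten="unit-variance", tol=1e-4)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ica.fit(Xz)
            converged = not any("did not converge" in str(w.message) for w in caught)
        if converged or attempt == 2:
            return ica.components_
        last_err = "FastICA did not converge"
    raise RuntimeError(last_err)


def cross_odor_similarity(per_odor: list[AssemblyWeights]) -> CrossOdorSimilarity:
    """Pairwise Pearson correlation of weight vectors across odors."""
    n = len(per_odor)
    rosters = {tuple(w.unit_ids) if w.unit_ids else None for w in per_odor}
    if len(rosters) > 1:
        raise ValueError("all odors must share the same cell roster")
    r = np.eye(n)
    p = np.zeros((n, n))
    n_pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            ri, pi = stats.pearsonr(per_odor[i].weights, per_odor[j].weights)
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    significant = (p * n_pairs < 0.05) & ~np.eye(n, dtype=bool)
    return CrossOdorSimilarity([w.odor_id for w in per_odor], r, p, significant, n_pairs)


def assembly_timecourses(
    rates: RateMatrix,
    winners: np.ndarray,
    losers: np.ndarray,
    fbi_rows: np.ndarray,
    envelope: np.ndarray,
    env_fs: float,
    anchors: np.ndarray,
    span: tuple[float, float] = (-0.1, 0.7),
) -> dict:
    """Inhalation-aligned z-scored mean rate curves per cell group.

    Returns a dict with ``lags_s`` plus z-scored curves for ``winners``,
    ``losers``, ``fbi`` and the gamma ``envelope`` on a common timebase.
    An empty loser (or FBI) set omits that curve with a warning.
    """
    from .session import extract_windows

    out: dict = {}
    fs = rates.fs
    n0 = int(round(span[0] * fs))
    n1 = int(round(span[1] * fs))
    lags = np.arange(n0, n1) / fs
    out["lags_s"] = lags

    def _curve(rows: np.ndarray) -> np.ndarray | None:
        if rows.size == 0:
            return None
        mean_rate = rates.rates[rows].mean(axis=0)
        w, _ = extract_windows(mean_rate, np.atleast_1d(anchors), span, fs=fs)
        curve = w.mean(axis=0)
        sd = curve.std()
        return (curve - curve.mean()) / sd if sd > 0 else curve * 0.0

    for name, rows in (("winners", np.asarray(winners)),
                       ("losers", np.asarray(losers)),
                       ("fbi", np.asarray(fbi_rows))):
        c = _curve(rows)
        if c is None:
            warnings.warn(f"empty {name} set; curve omitted")
        else:
            out[name] = c
    env_w, _ = extract_windows(envelope, np.atleast_1d(anchors), span, fs=env_fs)
    env_curve = env_w.mean(axis=0)
    sd = env_curve.std()
    out["envelope"] = (env_curve - env_curve.mean()) / sd if sd > 0 else env_curve * 0
    # envelope may be on a different fs; resample to the rate timebase
    if env_w.shape[1] != lags.size:
        out["envelope"] = np.interp(
            lags, span[0] + np.arange(env_w.shape[1]) / env_fs, out["envelope"]
        )
    return out


def loser_inhibition_depth(timecourses: dict) -> float:
    """Depth of the loser dip (positive = below their mean) around the
    envelope peak."""
    if "losers" not in timecourses:
        return float("nan")
    env = timecourses["envelope"]
    peak = int(np.argmax(env))
    half = max(1, int(0.1 * env.size))
    lo = max(0, peak - half)
    hi = min(env.size, peak + half)
    return float(-np.min(timecourses["losers"][lo:hi]))


def winner_take_all_report(
    control: dict,
    ablated: dict,
) -> WinnerTakeAllReport:
    """Compare winner-take-all signatures between two analyzed sessions.

    Each argument packs the per-odor ``AssemblyWeights`` list, the
    ``CrossOdorSimilarity``, and the assembly ``timecourses`` dict of one
    session, all computed with identical thresholds.
    """
    def summarize(d: dict) -> tuple[float, float, float, float]:
        weights: list[AssemblyWeights] = d["weights"]
        sk = float(np.mean([w.skewness for w in weights]))
        frac = float(np.mean([w.losers.size / w.weights.size for w in weights]))
        depth = loser_inhibition_depth(d["timecourses"])
        sim: CrossOdorSimilarity = d["similarity"]
        off = ~np.eye(sim.r.shape[0], dtype=bool)
        mean_r = float(sim.r[off].mean())
        return sk, frac, depth, mean_r

    c = summarize(control)
    a = summarize(ablated)
    keys = ("skewness", "loser_fraction", "loser_inhibition_depth", "cross_odor_mean_r")
    packed = {k: {"control": c[i], "ablated": a[i]} for i, k in enumerate(keys)}
    return WinnerTakeAllReport(packed["skewness"], packed["loser_fraction"],
                               packed["loser_inhibition_depth"],
                               packed["cross_odor_mean_r"])
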