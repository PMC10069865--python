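"""Population-vector correlations and odor decoding.

Trials are inhalation onsets during odor delivery, labelled by odor.
Population vectors are per-trial mean principal-cell rates in 100 ms
windows sliding at a 37.5 ms hop, plus the three fixed windows used for
statistics: Pre = 0-100 ms, Gamma = 150-250 ms, Post = 525-625 ms after
inhalation start.  The decoder is a linear SVM trained by stochastic
gradient descent (hinge loss, L2) on stratified random 2/3-1/3 splits
repeated 100 times; LDA and kNN run through the same harness as
robustness checks.  Phase-resolved decoding pools spikes by the gamma
phase at which they occur and compares the modulation index of the
accuracy-by-phase profile against circular-shift surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .coupling import BandSignal, mi_from_binned_amplitude
from .session import SpikeTrain
from .spiking import RateMatrix

FIXED_WINDOWS = {"pre": (0.0, 0.1), "gamma": (0.15, 0.25), "post": (0.525, 0.625)}
CLASSIFIERS = ("sgd-svm", "lda", "knn")


@dataclass
class PopulationVectors:
    X: np.ndarray                # trials x windows x cells
    window_centers: np.ndarray
    labels: np.ndarray           # odor id per trial
    fixed: dict                  # name -> trials x cells
    window_s: float
    n_dropped: int = 0


@dataclass
class DecodingResult:
    window_centers: np.ndarray
    accuracy: np.ndarray         # repeats x windows
    classifier: str
    chance: float
    window_names: list | None = None

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def n_repeats(self) -> int:
        return self.accuracy.shape[0]


@dataclass
class PhaseDecodingMI:
    bin_centers: np.ndarray
    profile: np.ndarray              # mean accuracy per phase bin
    normalized_profile: np.ndarray   # profile - mean
    block_profiles: np.ndarray       # blocks x bins
    mi_real: float
    surrogate_mi: np.ndarray
    percentile: float
    chance: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# population vectors
# ---------------------------------------------------------------------------

def population_vectors(
    rates: RateMatrix,
    trials: list[tuple[float, int]],
    window_s: float = 0.1,
    overlap: float = 0.625,
    t_max: float = 1.0,
    fixed_windows: dict = None,
) -> PopulationVectors:
    """Per-trial mean-rate vectors in sliding and fixed windows."""
    odors = {o for _, o in trials}
    if len(odors) < 2:
        raise ValueError("need >= 2 odors")
    fixed_windows = FIXED_WINDOWS if fixed_windows is None else fixed_windows
    hop = window_s * (1.0 - overlap)
    starts = np.arange(0.0, t_max - window_s + 1e-9, hop)
    fs = rates.fs
    n_time = rates.rates.shape[1]
    need = max([t_max] + [w[1] for w in fixed_windows.values()])
    usable = [(a, o) for a, o in trials
              if a >= 0 and int(round((a + need) * fs)) <= n_time]
    n_dropped = len(trials) - len(usable)
    if len(usable) < 4:
        raise ValueError("too few usable trials")
    labels = np.asarray([o for _, o in usable])
    anchors = np.asarray([a for a, _ in usable])
    cum = np.concatenate([np.zeros((rates.n_units, 1)),
                          np.cumsum(rates.rates, axis=1)], axis=1) / fs

    def window_mean(t0: float, t1: float) -> np.ndarray:
        i0 = np.round((anchors + t0) * fs).astype(int)
        i1 = np.round((anchors + t1) * fs).astype(int)
        return np.stack([(cum[:, b] - cum[:, a]) / ((b - a) / fs)
                         for a, b in zip(i0, i1)])

    X = np.stack([window_mean(t0, t0 + window_s) for t0 in starts], axis=1)
    fixed = {name: window_mean(t0, t1) for name, (t0, t1) in fixed_windows.items()}
    return PopulationVectors(X, starts + window_s / 2.0, labels, fixed,
                             window_s, n_dropped)


def popvec_correlations(pv: PopulationVectors) -> dict:
    """Mean between-odor Pearson correlation per window.

    For each window the trial vectors are averaged per odor and every
    odor pair's Pearson r is computed; pairs involving a zero-variance
    vector are skipped (counted).  Returns a dict with the sliding curve
    and the fixed-window values.
    """
    odors = np.unique(pv.labels)

    def mean_r(mat_per_odor: np.ndarray) -> tuple[float, int]:
        rs, skipped = [], 0
        for i in range(len(odors)):
            for j in range(i + 1, len(odors)):
                a, b = mat_per_odor[i], mat_per_odor[j]
                if a.std() == 0 or b.std() == 0:
                    skipped += 1
                    continue
                rs.append(stats.pearsonr(a, b)[0])
        return (float(np.mean(rs)) if rs else float("nan")), skipped

    curve = np.empty(pv.window_centers.size)
    skipped_total = 0
    for w in range(pv.window_centers.size):
        per_odor = np.stack([pv.X[pv.labels == o, w].mean(axis=0) for o in odors])
        curve[w], sk = mean_r(per_odor)
        skipped_total += sk
    fixed = {}
    for name, mat in pv.fixed.items():
        per_odor = np.stack([mat[pv.labels == o].mean(axis=0) for o in odors])
        fixed[name], sk = mean_r(per_odor)
        skipped_total += sk
    return {"window_centers": pv.window_centers, "curve": curve,
            "fixed": fixed, "n_skipped_pairs": skipped_total}


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _make_classifier(name: str, seed: int):
    if name == "sgd-svm":
        return make_pipeline(
            StandardScaler(),
            SGDClassifier(loss="hinge", penalty="l2", alpha=1e-4,
                          random_state=seed, tol=1e-3),
        )
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _accuracy(X: np.ndarray, y: np.ndarray, classifier: str, rs: int,
              train_frac: float) -> float:
    for attempt in range(10):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_frac, random_state=rs + 1000 * attempt,
            stratify=y)
        if np.unique(ytr).size == np.unique(y).size:
            break
    else:
        raise RuntimeError("could not build a split containing every odor")
    clf = _make_classifier(classifier, rs)
    clf.fit(Xtr, ytr)
    return float(np.mean(clf.predict(Xte) == yte))


def decode_odors(
    pv: PopulationVectors,
    classifier: str = "sgd-svm",
    repeats: int = 100,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
    windows: str = "sliding",
) -> DecodingResult:
    """Windowed odor decoding with repeated stratified splits.

    ``windows`` selects ``"sliding"`` (the hop grid), ``"fixed"``
    (Pre/Gamma/Post) or ``"all"``.
    """
    mats, centers, names = [], [], None
    if windows in ("sliding", "all"):
        mats += [pv.X[:, w] for w in range(pv.window_centers.size)]
        centers += list(pv.window_centers)
    if windows in ("fixed", "all"):
        names = list(pv.fixed)
        mats += [pv.fixed[n] for n in names]
        centers += [np.mean(FIXED_WINDOWS.get(n, (np.nan, np.nan))) for n in names]
        if windows == "fixed":
            names = names
        else:
            names = [None] * (len(mats) - len(names)) + names
    y = pv.labels
    counts = np.bincount(np.searchsorted(np.unique(y), y))
    if counts.min() < 2:
        raise ValueError("need >= 2 trials per odor")
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(repeats)]
    acc = np.empty((repeats, len(mats)))
    for r, rs in enumerate(repeat_seeds):
        for w, X in enumerate(mats):
            acc[r, w] = _accuracy(X, y, classifier, rs, train_frac)
    chance = 1.0 / np.unique(y).size
    return DecodingResult(np.asarray(centers), acc, classifier, chance,
                          names if windows == "fixed" else None)


def accuracy_gamma_correlation(
    result: DecodingResult,
    env_lags_s: np.ndarray,
    env_curve: np.ndarray,
) -> tuple[float, float]:
    """Pearson r between the accuracy time course and the triggered gamma
    envelope (interpolated to the window centers)."""
    if result.window_centers.size < 3:
        raise ValueError("need >= 3 windows")
    acc = result.mean_accuracy
    env = np.interp(result.window_centers, env_lags_s, env_curve)
    if acc.std() == 0 or env.std() == 0:
        warnings.warn("zero-variance input; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(acc, env)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# phase-resolved decoding
# ---------------------------------------------------------------------------

def phase_binned_counts(
    spikes: list[SpikeTrain],
    phase: np.ndarray,
    fs: float,
    trials: list[tuple[float, int]],
    n_bins: int = 8,
    window: tuple[float, float] = (0.1, 0.35),
) -> tuple[np.ndarray, np.ndarray]:
    """bins x trials x cells spike counts, pooled by gamma phase of spike.

    Spikes inside ``window`` after each trial anchor are assigned to the
    phase bin containing the gamma phase at the spike sample.
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    labels = np.asarray([o for _, o in trials])
    counts = np.zeros((n_bins, len(trials), len(spikes)))
    for c, st in enumerate(spikes):
        tt = st.spike_times
        for ti, (a, _) in enumerate(trials):
            sel = tt[(tt >= a + window[0]) & (tt < a + window[1])]
            if sel.size == 0:
                continue
            idx = np.minimum((sel * fs).astype(int), phase.size - 1)
            b = np.clip(np.searchsorted(edges, phase[idx], side="right") - 1,
                        0, n_bins - 1)
            np.add.at(counts[:, ti, c], b, 1.0)
    return counts, labels


def phase_resolved_decoding(
    spikes: list[SpikeTrain],
    gamma_phase: BandSignal | np.ndarray,
    trials: list[tuple[float, int]],
    fs: float | None = None,
    n_bins: int = 8,
    window: tuple[float, float] = (0.1, 0.35),
    n_blocks: int = 4,
    classifier: str = "sgd-svm",
    repeats: int = 20,
    train_frac: float = 2.0 / 3.0,
    n_surrogates: int = 10000,
    seed: int = 0,
) -> PhaseDecodingMI:
    """Odor decoding accuracy as a function of gamma phase, with a
    circular-shift surrogate test.

    The session's trials are split into ``n_blocks`` balanced blocks
    (pseudo-sessions).  Decoding runs once per (block, phase bin); the
    real accuracy-by-phase profile is the block average and its
    modulation index (entropy-based, same form as for amplitude
    distributions) is compared against ``n_surrogates`` surrogates in
    which each block's profile is circularly shifted by an independent
    random number of bins before averaging — the profile-level
    realization of circularly shifting each session's gamma phases.
    """
    if n_bins < 2:
        raise ValueError("need >= 2 gamma phase bins")
    if isinstance(gamma_phase, BandSignal):
        fs = gamma_phase.fs
        phase = gamma_phase.phase
    else:
        phase = np.asarray(gamma_phase)
        if fs is None:
            raise ValueError("fs required for bare phase arrays")
    counts, labels = phase_binned_counts(spikes, phase, fs, trials, n_bins, window)
    empty = np.flatnonzero(counts.sum(axis=(1, 2)) == 0)
    if empty.size:
        warnings.warn(f"{empty.size} empty phase bins merged with neighbours")
        for b in empty:
            counts[(b + 1) % n_bins] += counts[b]
    blocks = _balanced_blocks(labels, n_blocks)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(repeats)]
    block_profiles = np.zeros((n_blocks, n_bins))
    for bi, sel in enumerate(blocks):
        y = labels[sel]
        for k in range(n_bins):
            X = counts[k][sel]
            accs = [_accuracy(X, y, classifier, rs, train_frac)
                    for rs in repeat_seeds]
            block_profiles[bi, k] = np.mean(accs)
    profile = block_profiles.mean(axis=0)
    mi_real = mi_from_binned_amplitude(np.maximum(profile, 1e-12))[3]
    surr_mi = profile_shift_surrogates(block_profiles, n_surrogates,
                                       rng=np.random.default_rng(ss.spawn(1)[0]))
    percentile = float(100.0 * np.mean(surr_mi < mi_real))
    centers = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (centers[:-1] + centers[1:])
    return PhaseDecodingMI(centers, profile, profile - profile.mean(),
                           block_profiles, float(mi_real), surr_mi, percentile,
                           chance=1.0 / np.unique(labels).size)


def profile_shift_surrogates(
    block_profiles: np.ndarray,
    n_surrogates: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null MI distribution from per-block circular profile rotations.

    Each surrogate rotates every block's accuracy-by-phase profile by an
    independent random integer number of bins, averages across blocks and
    recomputes the entropy-based MI.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_blocks, n_bins = block_profiles.shape
    shifts = rng.integers(0, n_bins, size=(n_surrogates, n_blocks))
    rolled = np.stack([np.stack([np.roll(block_profiles[b], s)
                                 for s in range(n_bins)])
                       for b in range(n_blocks)])  # blocks x shifts x bins
    surr_profiles = rolled[np.arange(n_blocks)[None, :], shifts].mean(axis=1)
    return _mi_rows(np.maximum(surr_profiles, 1e-12))


def _balanced_blocks(labels: np.ndarray, n_blocks: int) -> list[np.ndarray]:
    """Round-robin assignment of each odor's trials across blocks."""
    blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    for o in np.unique(labels):
        idx = np.flatnonzero(labels == o)
        for j, t in enumerate(idx):
            blocks[j % n_blocks].append(t)
    out = [np.asarray(sorted(b)) for b in blocks]
    if any(len(b) < 4 for b in out):
        raise ValueError("too few trials per block; reduce n_blocks")
    return out


def _mi_rows(profiles: np.ndarray) -> np.ndarray:
    p = profiles / profiles.sum(axis=1, keepdims=True)
    h = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    hmax = np.log(profiles.shape[1])
    return (hmax - h) / hmax
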