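"""Directionality between respiration and the low-gamma amplitude envelope.

Three complementary strategies (the third is the only inferential one):

1. inhalation-triggered average of the 30-60 Hz amplitude envelope —
   if respiration drives gamma the envelope peaks at a fixed latency
   (~200 ms) after inhalation start;
2. the normalized cross-correlogram between envelope and respiration —
   a positive-lag peak means respiration leads;
3. time-domain Granger causality from a bivariate VAR(10): for each
   direction the log of the restricted-vs-unrestricted F statistic.

Both series are z-scored before the VAR and, by default, decimated to
200 Hz so that the 10 lags span 50 ms of history rather than 5 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from statsmodels.tsa.stattools import grangercausalitytests

from .session import extract_windows


@dataclass
class GrangerResult:
    order: int
    logF_x_to_y: float
    logF_y_to_x: float
    fs_used: float


def triggered_envelope(
    envelope: np.ndarray,
    fs: float,
    anchors: np.ndarray,
    span: tuple[float, float] = (-0.2, 0.6),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Anchor-aligned mean and SEM of an amplitude envelope.

    Returns ``(lags_s, mean, sem, n_used)``.
    """
    anchors = np.atleast_1d(anchors)
    if anchors.size < 2:
        raise ValueError("need >= 2 anchors for a triggered average")
    windows, kept = extract_windows(envelope, anchors, span, fs=fs)
    n = windows.shape[0]
    lags = span[0] + np.arange(windows.shape[1]) / fs
    mean = windows.mean(axis=0)
    sem = windows.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return lags, mean, sem, n


def envelope_crosscorr(
    envelope: np.ndarray,
    resp: np.ndarray,
    fs: float,
    max_lag_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation over +-``max_lag_s``.

    Both inputs are z-scored internally.  Positive lag means respiration
    leads the envelope.
    """
    if envelope.size != resp.size:
        raise ValueError("inputs must have equal length")
    ze = _zscore(envelope)
    zr = _zscore(resp)
    n = ze.size
    full = sps.correlate(ze, zr, mode="full") / n
    lags_all = np.arange(-n + 1, n) / fs
    keep = np.abs(lags_all) <= max_lag_s
    return lags_all[keep], full[keep]


def granger_logF(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    order: int = 10,
    decimate_to: float | None = 200.0,
) -> GrangerResult:
    """log(F) Granger causality in both directions from a VAR(order).

    ``x -> y`` asks whether x's past improves the prediction of y beyond
    y's own past (restricted vs unrestricted residual-variance F-test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    fs_used = fs
    if decimate_to is not None and decimate_to < fs:
        q = int(round(fs / decimate_to))
        x = sps.decimate(x, q, ftype="fir", zero_phase=True)
        y = sps.decimate(y, q, ftype="fir", zero_phase=True)
        fs_used = fs / q
    if x.size < 20 * order:
        raise ValueError("series too short for the requested VAR order")
    x = _zscore(x)
    y = _zscore(y)
    resid = y - x * float(np.dot(x, y) / np.dot(x, x))
    if np.var(resid) < 1e-10:
        raise ValueError("signals are (nearly) identical; VAR regression is singular")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_xy = _granger_f(np.column_stack([y, x]), order)  # x -> y
        f_yx = _granger_f(np.column_stack([x, y]), order)  # y -> x
    return GrangerResult(order, float(np.log(f_xy)), float(np.log(f_yx)), fs_used)


def _granger_f(data: np.ndarray, order: int) -> float:
    import contextlib
    import io

    with contextlib.redirect_stdout(io.StringIO()):
        res = grangercausalitytests(data, maxlag=[order])
    return res[order][0]["ssr_ftest"][0]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd < 1e-12:
        raise ValueError("zero-variance input")
    return (x - np.mean(x)) / sd
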