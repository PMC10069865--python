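"""Session data model, container I/O, and signal preprocessing.

A :class:`Session` bundles everything one piriform-cortex recording provides:
a laminar stack of LFP traces, the respiration airflow trace, per-unit spike
trains with class/depth metadata, and the event streams (inhalation onsets,
odor onsets with identities, optional laser epochs).  All times are in
seconds with t = 0 at recording start; analysis windows are half-open
``[anchor + pre, anchor + post)``.

Containers are HDF5 files (``/lfp``, ``/resp``, ``/spikes``, ``/events``,
``/meta`` groups).  A plain CSV+JSON directory layout is supported as a
text-only fallback for small fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

UNIT_CLASSES = ("EXC", "FBI", "FFI", "UNKNOWN")


class MalformedContainerError(ValueError):
    """A session container is missing a required group or field."""


@dataclass
class SignalTrace:
    """A uniformly sampled continuous signal (LFP channel or respiration).

    Parameters
    ----------
    samples : ndarray
        Signal values (µV for LFP, arbitrary airflow units for respiration).
    fs : float
        Sampling rate in Hz.
    channel_id : str
        Label for provenance.
    depth_um : float, optional
        Electrode depth in µm (laminar position).
    """

    samples: np.ndarray
    fs: float
    channel_id: str = ""
    depth_um: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a nonempty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit with class and depth metadata."""

    unit_id: str
    spike_times: np.ndarray
    unit_class: str = "UNKNOWN"
    depth_um: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(
                f"unit_class must be one of {UNIT_CLASSES}, got {self.unit_class!r}"
            )
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"spike_times of unit {self.unit_id!r} are not sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be >= 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class EventSeries:
    """Event streams: inhalation onsets, odor onsets/identities, laser epochs."""

    inhalation_times: np.ndarray
    odor_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    odor_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    laser_epochs: np.ndarray | None = None  # (n, 3): start, stop, intensity

    def __post_init__(self) -> None:
        self.inhalation_times = np.asarray(self.inhalation_times, dtype=float)
        self.odor_onsets = np.asarray(self.odor_onsets, dtype=float)
        self.odor_ids = np.asarray(self.odor_ids)
        if self.inhalation_times.size > 1 and np.any(np.diff(self.inhalation_times) <= 0):
            raise ValueError("inhalation_times must be strictly increasing")
        if self.odor_onsets.size != self.odor_ids.size:
            raise ValueError("every odor_onset needs an odor_id")
        if self.laser_epochs is not None:
            self.laser_epochs = np.asarray(self.laser_epochs, dtype=float).reshape(-1, 3)


@dataclass
class Session:
    """One recording: laminar LFP stack, respiration, spikes, and events."""

    lfp: list[SignalTrace]
    resp: SignalTrace
    spikes: list[SpikeTrain]
    events: EventSeries
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check cross-field invariants; raise ValueError on violation."""
        if not self.lfp:
            raise ValueError("session needs at least one LFP channel")
        n = self.lfp[0].samples.size
        fs = self.lfp[0].fs
        for tr in self.lfp:
            if tr.samples.size != n or tr.fs != fs:
                raise ValueError("all LFP channels must share fs and length")
        if self.resp.fs != fs or self.resp.samples.size != n:
            raise ValueError("resp and lfp must share fs and length after preprocessing")
        depths = [tr.depth_um for tr in self.lfp]
        if all(d is not None for d in depths) and len(depths) > 1:
            if np.any(np.diff(depths) < 0):
                raise ValueError("laminar order must be monotone in depth")
        dur = self.duration
        for st in self.spikes:
            if st.spike_times.size and (st.spike_times[0] < 0 or st.spike_times[-1] > dur):
                raise ValueError(f"unit {st.unit_id!r} has spikes outside [0, duration]")
        if self.events.inhalation_times.size and self.events.inhalation_times[-1] > dur:
            raise ValueError("inhalation times exceed session duration")

    @property
    def fs(self) -> float:
        return self.lfp[0].fs

    @property
    def duration(self) -> float:
        return self.lfp[0].duration

    def units(self, unit_class: str | None = None) -> list[SpikeTrain]:
        """Spike trains, optionally restricted to one unit class."""
        if unit_class is None:
            return list(self.spikes)
        return [s for s in self.spikes if s.unit_class == unit_class]


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_session(session: Session, path: str | Path, force: bool = False) -> Path:
    """Write ``session`` to an HDF5 container (or CSV+JSON directory).

    Refuses to overwrite an existing path unless ``force`` is given.
    ``path`` ending in ``.h5``/``.hdf5`` selects HDF5; anything else is
    written as a directory of CSV/JSON text files.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    session.validate()
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(session, path)
    else:
        _save_csvdir(session, path)
    return path


def load_session(path: str | Path) -> Session:
    """Read a session container written by :func:`save_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        sess = _load_csvdir(path)
    else:
        sess = _load_h5(path)
    sess.validate()
    return sess


def _save_h5(session: Session, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=np.stack([t.samples for t in session.lfp]))
        g.create_dataset("fs", data=session.lfp[0].fs)
        depths = [t.depth_um if t.depth_um is not None else np.nan for t in session.lfp]
        g.create_dataset("depth_um", data=np.asarray(depths, dtype=float))
        g.create_dataset(
            "channel_id", data=np.array([t.channel_id for t in session.lfp], dtype="S")
        )
        g = f.create_group("resp")
        g.create_dataset("data", data=session.resp.samples)
        g.create_dataset("fs", data=session.resp.fs)
        g = f.create_group("spikes")
        for st in session.spikes:
            u = g.create_group(st.unit_id)
            u.create_dataset("times", data=st.spike_times)
            u.attrs["class"] = st.unit_class
            u.attrs["depth_um"] = np.nan if st.depth_um is None else st.depth_um
        g = f.create_group("events")
        g.create_dataset("inhalations", data=session.events.inhalation_times)
        g.create_dataset("odor_onsets", data=session.events.odor_onsets)
        g.create_dataset("odor_ids", data=np.asarray(session.events.odor_ids, dtype=int))
        if session.events.laser_epochs is not None:
            g.create_dataset("laser", data=session.events.laser_epochs)
        g = f.create_group("meta")
        g.attrs["json"] = json.dumps(session.meta)


def _require(h5: h5py.File, key: str):
    if key not in h5:
        raise MalformedContainerError(f"malformed container: {key.strip('/')}")
    return h5[key]


def _load_h5(path: Path) -> Session:
    with h5py.File(path, "r") as f:
        lg = _require(f, "lfp")
        data = _require(lg, "data")[...]
        fs = float(_require(lg, "fs")[()])
        depths = lg["depth_um"][...] if "depth_um" in lg else np.full(len(data), np.nan)
        chans = (
            [c.decode() for c in lg["channel_id"][...]]
            if "channel_id" in lg
            else [f"ch{i}" for i in range(len(data))]
        )
        lfp = [
            SignalTrace(row, fs, chans[i], None if np.isnan(depths[i]) else float(depths[i]))
            for i, row in enumerate(data)
        ]
        rg = _require(f, "resp")
        resp = SignalTrace(_require(rg, "data")[...], float(_require(rg, "fs")[()]), "RESP")
        spikes = []
        if "spikes" in f:
            for uid in sorted(f["spikes"]):
                u = f["spikes"][uid]
                d = u.attrs.get("depth_um", np.nan)
                spikes.append(
                    SpikeTrain(
                        uid,
                        u["times"][...],
                        str(u.attrs.get("class", "UNKNOWN")),
                        None if np.isnan(d) else float(d),
                    )
                )
        eg = _require(f, "events")
        events = EventSeries(
            _require(eg, "inhalations")[...],
            eg["odor_onsets"][...] if "odor_onsets" in eg else np.empty(0),
            eg["odor_ids"][...] if "odor_ids" in eg else np.empty(0, dtype=int),
            eg["laser"][...] if "laser" in eg else None,
        )
        mg = f["meta"] if "meta" in f else None
        meta = json.loads(mg.attrs["json"]) if mg is not None and "json" in mg.attrs else {}
    return Session(lfp, resp, spikes, events, meta)


def _save_csvdir(session: Session, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "lfp_data.csv", np.stack([t.samples for t in session.lfp]).T, delimiter=",")
    np.savetxt(path / "resp_data.csv", session.resp.samples, delimiter=",")
    spikes = {
        st.unit_id: {
            "times": st.spike_times.tolist(),
            "class": st.unit_class,
            "depth_um": st.depth_um,
        }
        for st in session.spikes
    }
    ev = session.events
    header = {
        "fs": session.lfp[0].fs,
        "depth_um": [t.depth_um for t in session.lfp],
        "channel_id": [t.channel_id for t in session.lfp],
        "events": {
            "inhalations": ev.inhalation_times.tolist(),
            "odor_onsets": ev.odor_onsets.tolist(),
            "odor_ids": np.asarray(ev.odor_ids, dtype=int).tolist(),
            "laser": None if ev.laser_epochs is None else ev.laser_epochs.tolist(),
        },
        "meta": session.meta,
    }
    (path / "session.json").write_text(json.dumps(header))
    (path / "spikes.json").write_text(json.dumps(spikes))


def _load_csvdir(path: Path) -> Session:
    hdr_path = path / "session.json"
    if not hdr_path.exists():
        raise MalformedContainerError("malformed container: session.json")
    hdr = json.loads(hdr_path.read_text())
    if not (path / "resp_data.csv").exists():
        raise MalformedContainerError("malformed container: resp")
    fs = float(hdr["fs"])
    data = np.loadtxt(path / "lfp_data.csv", delimiter=",", ndmin=2).T
    lfp = [
        SignalTrace(row, fs, hdr["channel_id"][i], hdr["depth_um"][i])
        for i, row in enumerate(data)
    ]
    resp = SignalTrace(np.loadtxt(path / "resp_data.csv", delimiter=","), fs, "RESP")
    spikes = []
    sp = json.loads((path / "spikes.json").read_text()) if (path / "spikes.json").exists() else {}
    for uid in sorted(sp):
        d = sp[uid]
        spikes.append(SpikeTrain(uid, np.asarray(d["times"]), d["class"], d["depth_um"]))
    ev = hdr["events"]
    events = EventSeries(
        np.asarray(ev["inhalations"]),
        np.asarray(ev["odor_onsets"]),
        np.asarray(ev["odor_ids"], dtype=int),
        None if ev["laser"] is None else np.asarray(ev["laser"]),
    )
    return Session(lfp, resp, spikes, events, hdr.get("meta", {}))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def decimate_trace(trace: SignalTrace, target_fs: float) -> SignalTrace:
    """Anti-aliased decimation of a trace to ``target_fs``.

    The downsampling factor must be an integer; an FIR anti-aliasing filter
    is applied zero-phase before subsampling (large factors are cascaded in
    stages <= 10 to keep the FIR well conditioned).
    """
    if target_fs >= trace.fs:
        raise ValueError(f"target_fs must be < trace.fs ({trace.fs})")
    q = trace.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        near = trace.fs / round(q)
        raise ValueError(
            f"fs={trace.fs} is not an integer multiple of target_fs={target_fs}; "
            f"nearest valid target is {near:g} Hz"
        )
    q = int(round(q))
    x = trace.samples
    for factor in _stage_factors(q):
        x = signal.decimate(x, factor, ftype="fir", zero_phase=True)
    return SignalTrace(x, target_fs, trace.channel_id, trace.depth_um)


def _stage_factors(q: int, max_stage: int = 10) -> list[int]:
    factors: list[int] = []
    while q > max_stage:
        for p in range(max_stage, 1, -1):
            if q % p == 0:
                factors.append(p)
                q //= p
                break
        else:  # prime > max_stage: fall back to one big stage
            break
    factors.append(q)
    return [f for f in factors if f > 1]


def detect_inhalations(
    resp: SignalTrace,
    smooth_ms: float = 25.0,
    refractory_ms: float = 100.0,
    polarity: int = -1,
    threshold_frac: float = 0.1,
) -> np.ndarray:
    """Detect inhalation onset times from the airflow trace.

    Inhalation produces negative airflow, so onsets are downward
    zero-crossings of the (moving-average smoothed) signal.  To reject
    noise crossings, a candidate must descend through ``-threshold_frac *
    std`` and is then back-dated to the preceding zero-crossing.  A
    refractory period of ``refractory_ms`` is enforced.

    Returns an array of onset times in seconds (empty, with a warning, for
    a flat signal).
    """
    # polarity=-1: inhalation is negative airflow (sensor convention);
    # polarity=+1 analyses a sign-flipped trace.
    x = resp.samples if polarity < 0 else -resp.samples
    if np.std(x) < 1e-12:
        warnings.warn("respiration trace is flat; no inhalations detected")
        return np.empty(0)
    n_smooth = max(1, int(round(smooth_ms * 1e-3 * resp.fs)))
    kernel = np.ones(n_smooth) / n_smooth
    s = np.convolve(x, kernel, mode="same")
    sd = np.std(s)
    thr = -threshold_frac * sd
    below = s < thr
    cand = np.flatnonzero(~below[:-1] & below[1:]) + 1
    refractory = int(round(refractory_ms * 1e-3 * resp.fs))
    onsets = []
    last = -refractory - 1
    nonneg = s >= 0
    for i in cand:
        # back-date to the zero-crossing preceding the threshold crossing
        prev = np.flatnonzero(nonneg[max(0, i - refractory): i])
        j = (max(0, i - refractory) + prev[-1] + 1) if prev.size else i
        if j - last <= refractory:
            continue
        onsets.append(j)
        last = j
    return np.asarray(onsets) / resp.fs


def extract_windows(
    x: np.ndarray | SignalTrace,
    anchors: np.ndarray,
    span: tuple[float, float],
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut equal-length windows ``[anchor+pre, anchor+post)`` from a signal.

    Parameters
    ----------
    x : array or SignalTrace
        Source signal (1-D).
    anchors : array
        Anchor times in seconds.
    span : (pre_s, post_s)
        Signed window offsets; e.g. ``(-0.2, 0.5)`` spans 200 ms before to
        500 ms after each anchor.
    fs : float
        Sampling rate, required when ``x`` is a bare array.

    Returns
    -------
    windows : (n_kept, n_samples) array
    kept : boolean mask over ``anchors`` (False = dropped at an edge).
    """
    if isinstance(x, SignalTrace):
        fs = x.fs
        x = x.samples
    if fs is None:
        raise ValueError("fs required when x is a bare array")
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    if anchors.size == 0:
        raise ValueError("anchors is empty")
    pre, post = span
    if post <= pre:
        raise ValueError("span must satisfy post > pre")
    n = int(round((post - pre) * fs))
    starts = np.round((anchors + pre) * fs).astype(int)
    kept = (starts >= 0) & (starts + n <= x.size)
    windows = np.stack([x[s: s + n] for s in starts[kept]]) if kept.any() else np.empty((0, n))
    return windows, kept
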