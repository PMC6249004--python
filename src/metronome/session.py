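"""Session container: trials, continuous LFP, spike trains, geometry.

A session holds one continuous multi-channel LFP matrix (channels x
samples, 1000 Hz after down-sampling) with a trial-onset index into the
session clock, rather than per-trial fragments — mirroring continuous
acquisition.  Spike times are per sorted unit, in session-clock
milliseconds.  The on-disk form is a single HDF5 file with a schema
version::

    /trials     column datasets (trial_id, tempo_ms, ...) + ragged switch times
    /lfp        float32 matrix, attrs: sampling_rate_hz
    /spikes     unit_000, unit_001, ... float64 vectors
    /geometry   channels x 2 electrode coordinates (micrometres)
    /meta       attrs: schema_version, and free-form metadata
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

SCHEMA_VERSION = "1"

#: epoch names in storage order: (baseline_on, entrain_on, maint_on, maint_off)
_EPOCH_COLS = ("baseline_on_ms", "entrain_on_ms", "maint_on_ms", "maint_off_ms")


class FormatError(IOError):
    """Raised when a session container does not match the expected schema."""


@dataclass
class TrialRecord:
    """One task trial.

    Times are trial-relative milliseconds, zero at the first entrainment
    stimulus onset.  ``switch_times_ms`` lists every side alternation
    (visible and virtual) at multiples of the tempo; ``go_cue_ms`` falls at
    ``maintenance onset + (n_maintenance - 0.5) * tempo_ms``.
    """

    trial_id: int
    tempo_ms: float
    start_side: str                      # "left" | "right"
    n_maintenance: int                   # maintenance interval holding the go-cue
    switch_times_ms: np.ndarray
    go_cue_ms: float
    epoch_bounds: dict                   # baseline/entrainment/maintenance -> (on, off)
    response_side: str = "none"          # "left" | "right" | "none"
    correct: bool | None = None
    rt_ms: float = np.nan
    internal_period_ms: float = np.nan   # generator ground truth when synthetic

    @property
    def maintenance_onset_ms(self) -> float:
        return self.epoch_bounds["maintenance"][0]

    @property
    def t_go_ms(self) -> float:
        """Elapsed time from maintenance onset to the go-cue."""
        return self.go_cue_ms - self.maintenance_onset_ms

    def validate(self) -> None:
        st = np.asarray(self.switch_times_ms, float)
        if st.size > 1:
            d = np.diff(st)
            if not (np.all(d > 0) and np.allclose(d, self.tempo_ms)):
                raise ValueError(f"trial {self.trial_id}: switch times must "
                                 "increase by one tempo")
        expected_go = (self.epoch_bounds["maintenance"][0]
                       + (self.n_maintenance - 0.5) * self.tempo_ms)
        if not np.isclose(self.go_cue_ms, expected_go):
            raise ValueError(f"trial {self.trial_id}: go_cue_ms inconsistent "
                             "with n_maintenance")


def true_side_at_go(trial: TrialRecord, n_entrainment: int = 3) -> str:
    """Side of the (virtual) stimulus at the go-cue, from interval parity."""
    flips = n_entrainment + trial.n_maintenance - 1
    if flips % 2 == 0:
        return trial.start_side
    return "right" if trial.start_side == "left" else "left"


@dataclass
class SessionData:
    """Aligned container of trials, LFP, spike trains and geometry."""

    trials: list[TrialRecord]
    lfp: np.ndarray                      # channels x samples
    sampling_rate_hz: float
    spike_trains: list[np.ndarray]       # per-unit session-clock spike times (ms)
    electrode_xy: np.ndarray             # channels x 2, micrometres
    trial_onsets_ms: dict[int, float]    # trial_id -> session-clock time of t=0
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.lfp.shape[1] / self.sampling_rate_hz * 1000.0

    def validate(self) -> None:
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be channels x samples")
        if self.electrode_xy.shape != (self.n_channels, 2):
            raise ValueError("electrode_xy must be channels x 2")
        if not np.all(np.isfinite(self.electrode_xy)):
            raise ValueError("electrode_xy must be finite")
        span = self.duration_ms
        for k, st in enumerate(self.spike_trains):
            st = np.asarray(st, float)
            if st.size and (st.min() < 0 or st.max() > span):
                raise ValueError(f"unit {k}: spike time outside recording span")
        for tr in self.trials:
            tr.validate()
            if tr.trial_id not in self.trial_onsets_ms:
                raise ValueError(f"trial {tr.trial_id} missing from onset index")

    def trial_slice(self, trial_id: int, t_start_ms: float, t_stop_ms: float,
                    channel: int = 0) -> np.ndarray:
        """LFP samples of one channel over a trial-relative time range."""
        onset = self.trial_onsets_ms[trial_id]
        fs = self.sampling_rate_hz
        i0 = int(round((onset + t_start_ms) * fs / 1000.0))
        i1 = int(round((onset + t_stop_ms) * fs / 1000.0))
        i0 = max(i0, 0)
        i1 = min(i1, self.lfp.shape[1])
        return self.lfp[channel, i0:i1]


_SIDE_DTYPE = h5py.string_dtype("utf-8")


def write_session(session: SessionData, path) -> None:
    """Write the session container; deterministic byte layout (no timestamps)."""
    session.validate()
    path = Path(path)
    trials = session.trials
    n = len(trials)

    def col(getter, dtype=np.float64):
        return np.array([getter(t) for t in trials], dtype=dtype)

    switch_flat = (np.concatenate([np.asarray(t.switch_times_ms, float)
                                   for t in trials])
                   if n else np.empty(0))
    switch_len = col(lambda t: len(np.asarray(t.switch_times_ms)), np.int64)

    with h5py.File(path, "w", track_order=True) as f:
        def dset(group, name, data, **kw):
            group.create_dataset(name, data=data, track_times=False, **kw)

        g = f.create_group("trials")
        dset(g, "trial_id", col(lambda t: t.trial_id, np.int64))
        dset(g, "tempo_ms", col(lambda t: t.tempo_ms))
        dset(g, "start_side", col(lambda t: t.start_side, object),
             dtype=_SIDE_DTYPE)
        dset(g, "n_maintenance", col(lambda t: t.n_maintenance, np.int64))
        dset(g, "go_cue_ms", col(lambda t: t.go_cue_ms))
        dset(g, "response_side", col(lambda t: t.response_side, object),
             dtype=_SIDE_DTYPE)
        dset(g, "correct", col(lambda t: -1 if t.correct is None
                               else int(t.correct), np.int8))
        dset(g, "rt_ms", col(lambda t: t.rt_ms))
        dset(g, "internal_period_ms", col(lambda t: t.internal_period_ms))
        for i, name in enumerate(_EPOCH_COLS):
            epoch, idx = (("baseline", 0), ("entrainment", 0),
                          ("maintenance", 0), ("maintenance", 1))[i]
            dset(g, name, col(lambda t, e=epoch, j=idx: t.epoch_bounds[e][j]))
        dset(g, "switch_times_flat", switch_flat)
        dset(g, "switch_times_len", switch_len)
        dset(g, "onset_ms", col(lambda t: session.trial_onsets_ms[t.trial_id]))

        dset(f, "lfp", session.lfp.astype(np.float32))
        f["lfp"].attrs["sampling_rate_hz"] = float(session.sampling_rate_hz)

        sp = f.create_group("spikes")
        for k, st in enumerate(session.spike_trains):
            dset(sp, f"unit_{k:03d}", np.asarray(st, np.float64))

        dset(f, "geometry", session.electrode_xy.astype(np.float64))

        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in sorted(session.meta.items()):
            meta.attrs[k] = v


def read_session(path) -> SessionData:
    """Read a container written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for group in ("trials", "lfp", "spikes", "geometry", "meta"):
            if group not in f:
                raise FormatError(f"container missing required group '{group}'")
        version = f["meta"].attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise FormatError(f"schema version mismatch in /meta: "
                              f"{version!r} != {SCHEMA_VERSION!r}")
        g = f["trials"]
        n = g["trial_id"].shape[0]
        switch_flat = g["switch_times_flat"][:]
        switch_len = g["switch_times_len"][:]
        offsets = np.concatenate([[0], np.cumsum(switch_len)])
        decode = np.vectorize(lambda b: b.decode() if isinstance(b, bytes) else b,
                              otypes=[object])
        start_side = decode(g["start_side"][:]) if n else np.empty(0, object)
        resp_side = decode(g["response_side"][:]) if n else np.empty(0, object)
        trials, onsets = [], {}
        for i in range(n):
            bounds = {
                "baseline": (float(g["baseline_on_ms"][i]),
                             float(g["entrain_on_ms"][i])),
                "entrainment": (float(g["entrain_on_ms"][i]),
                                float(g["maint_on_ms"][i])),
                "maintenance": (float(g["maint_on_ms"][i]),
                                float(g["maint_off_ms"][i])),
            }
            corr = int(g["correct"][i])
            tr = TrialRecord(
                trial_id=int(g["trial_id"][i]),
                tempo_ms=float(g["tempo_ms"][i]),
                start_side=str(start_side[i]),
                n_maintenance=int(g["n_maintenance"][i]),
                switch_times_ms=switch_flat[offsets[i]:offsets[i + 1]].copy(),
                go_cue_ms=float(g["go_cue_ms"][i]),
                epoch_bounds=bounds,
                response_side=str(resp_side[i]),
                correct=None if corr < 0 else bool(corr),
                rt_ms=float(g["rt_ms"][i]),
                internal_period_ms=float(g["internal_period_ms"][i]),
            )
            trials.append(tr)
            onsets[tr.trial_id] = float(g["onset_ms"][i])
        units = sorted(f["spikes"].keys())
        spikes = [f["spikes"][u][:] for u in units]
        session = SessionData(
            trials=trials,
            lfp=f["lfp"][:].astype(np.float64),
            sampling_rate_hz=float(f["lfp"].attrs["sampling_rate_hz"]),
            spike_trains=spikes,
            electrode_xy=f["geometry"][:],
            trial_onsets_ms=onsets,
            meta={k: f["meta"].attrs[k] for k in f["meta"].attrs
                  if k != "schema_version"},
        )
    session.validate()
    return session
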