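"""In-memory and on-disk containers: epoched data and the trial table.

The trial table is a plain :class:`pandas.DataFrame` (one row per trial)
written as TSV with missing reaction times encoded as empty fields.  The
epoch container stores a trials x channels x time float array together with
the sampling rate, time axis (ms relative to the lock event) and channel
labels; on disk it is a ``.npy`` array plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Epoched multichannel time series, one epoch per trial-table row."""

    data: np.ndarray  # (n_trials, n_channels, n_times)
    sfreq: float  # samples per second
    times: np.ndarray  # ms relative to the lock event, strictly increasing
    lock: str = "stimulus"  # "stimulus" | "response"
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock {self.lock!r}")
        if not self.channels:
            self.channels = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel label count mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials (boolean mask or index array), keeping metadata."""
        return EpochSet(self.data[mask], self.sfreq, self.times, self.lock, list(self.channels))

    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` plus ``<path>.json`` sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "sfreq": self.sfreq,
            "times": self.times.tolist(),
            "lock": self.lock,
            "channels": self.channels,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        try:
            meta = json.loads(path.with_suffix(".json").read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed sidecar JSON for {path}: {e}") from e
        return cls(
            data=data,
            sfreq=meta["sfreq"],
            times=np.asarray(meta["times"], dtype=float),
            lock=meta["lock"],
            channels=list(meta["channels"]),
        )


#: Columns a full trial table carries, in canonical output order.
TRIAL_COLUMNS = [
    "subject_id",
    "phase",
    "miniblock",
    "trial",
    "word",
    "color",
    "set",
    "congruency",
    "ispc",
    "condition_id",
    "sc_class",
    "most_likely_response",
    "sr_class",
    "frequency",
    "correct_response",
    "rt",
    "accuracy",
    "latent_gain",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as TSV; missing RT becomes an empty field."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    return trials


def to_response_locked(
    epochs: EpochSet,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = (-800.0, 200.0),
) -> tuple[EpochSet, pd.DataFrame]:
    """Re-epoch stimulus-locked data around each trial's response.

    Samples are taken at ``rt + t`` for every ``t`` on the response-locked
    grid (same sampling rate), by nearest-sample lookup on the stimulus
    grid.  Trials without a response or whose shifted window is not fully
    covered by the stimulus epoch are dropped; the matching trial subset is
    returned alongside.
    """
    if epochs.lock != "stimulus":
        raise ValueError("input must be stimulus-locked")
    step = 1000.0 / epochs.sfreq
    new_times = np.arange(window_ms[0], window_ms[1] + 0.5 * step, step)
    rt = trials["rt"].to_numpy(dtype=float)
    lo, hi = epochs.times[0], epochs.times[-1]
    ok = np.isfinite(rt) & (rt + new_times[0] >= lo - 0.5 * step) & (rt + new_times[-1] <= hi + 0.5 * step)
    idx_ok = np.flatnonzero(ok)
    out = np.empty((idx_ok.size, epochs.data.shape[1], new_times.size))
    for row, i in enumerate(idx_ok):
        sample_times = rt[i] + new_times
        cols = np.clip(
            np.searchsorted(epochs.times, sample_times - 0.5 * step), 0, epochs.times.size - 1
        )
        out[row] = epochs.data[i][:, cols]
    resp = EpochSet(out, epochs.sfreq, new_times, "response", list(epochs.channels))
    return resp, trials.iloc[idx_ok].reset_index(drop=True)
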