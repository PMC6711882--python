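"""Epoched-EEG container and its on-disk format.

The pipeline's central object is an :class:`EpochSet`: a ``trials x channels x
samples`` float32 array with a millisecond time axis and a per-trial metadata
table. Epochs are stimulus-locked windows from -400 ms to +1200 ms at 256 Hz.

On disk an EpochSet is a directory with two files:

``meta.json``
    sampling rate, channel names, time axis, and the trial table as records.
``epochs.f32``
    the raw samples as little-endian 32-bit floats, trial-major, then
    channel-major, then sample order (C order of the in-memory array).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical channel order used throughout the package (Biosemi 128 labels;
#: approximately PO7, Pz, PO8, Fz in the 10-20 system)
CHANNELS = ("A10", "A19", "B7", "C21")

#: default epoch geometry: -400..+1200 ms at 256 Hz
FS = 256.0
EPOCH_PRE_MS = 400.0
EPOCH_POST_MS = 1200.0


def default_time_axis(fs: float = FS, pre_ms: float = EPOCH_PRE_MS,
                      post_ms: float = EPOCH_POST_MS) -> np.ndarray:
    """Sample times in ms, stimulus onset at 0 (sample ``round(pre_ms*fs/1000)``)."""
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_total = int(round((pre_ms + post_ms) * fs / 1000.0))
    return (np.arange(n_total) - n_pre) * 1000.0 / fs


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial metadata.

    Parameters
    ----------
    data : float32 array, shape (n_trials, n_channels, n_samples)
        Epoch samples in microvolts.
    channels : list of str
        Channel names, one per data row; order matches ``data`` axis 1.
    fs : float
        Sampling rate in Hz.
    time_ms : array, shape (n_samples,)
        Time of each sample relative to stimulus onset, in ms.
    trials : DataFrame
        One row per trial. Must contain a ``trial_id`` column; the synthetic
        generator adds task/block/state/probe linkage and behavior columns.
    """

    data: np.ndarray
    channels: list[str]
    fs: float
    time_ms: np.ndarray
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length mismatch")
        if len(self.trials) == 0:
            self.trials = pd.DataFrame({"trial_id": np.arange(self.data.shape[0])})
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table length mismatch")

    # -- basic introspection ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None

    def get_channel(self, name: str) -> np.ndarray:
        """All trials for one channel, shape (n_trials, n_samples)."""
        return self.data[:, self.channel_index(name), :]

    def sample_slice(self, lo_ms: float, hi_ms: float) -> slice:
        """Slice of the sample axis covering ``lo_ms <= t < hi_ms``."""
        idx = np.nonzero((self.time_ms >= lo_ms) & (self.time_ms < hi_ms))[0]
        if idx.size == 0:
            raise ValueError(f"period [{lo_ms}, {hi_ms}) ms outside epoch")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def select_trials(self, mask_or_ids) -> "EpochSet":
        """Subset by boolean mask or by trial_id values."""
        mask = np.asarray(mask_or_ids)
        if mask.dtype != bool:
            mask = self.trials["trial_id"].isin(mask).to_numpy()
        return EpochSet(self.data[mask], list(self.channels), self.fs,
                        self.time_ms, self.trials.loc[mask].reset_index(drop=True))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "fs": self.fs,
            "channels": list(self.channels),
            "time_ms": self.time_ms.tolist(),
            "shape": list(self.data.shape),
            "trials": json.loads(self.trials.to_json(orient="records")),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        self.data.astype("<f4").tofile(path / "epochs.f32")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        shape = tuple(meta["shape"])
        data = np.fromfile(path / "epochs.f32", dtype="<f4").reshape(shape)
        trials = pd.DataFrame(meta["trials"])
        return cls(data, list(meta["channels"]), float(meta["fs"]),
                   np.asarray(meta["time_ms"]), trials)

    def export_trials_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.trials.to_csv(path, index=False)
        return path


def concatenate(sets: list[EpochSet]) -> EpochSet:
    """Stack EpochSets that share geometry (channels, fs, time axis)."""
    first = sets[0]
    for s in sets[1:]:
        if s.channels != first.channels or s.fs != first.fs \
                or not np.array_equal(s.time_ms, first.time_ms):
            raise ValueError("cannot concatenate EpochSets with different geometry")
    data = np.concatenate([s.data for s in sets], axis=0)
    trials = pd.concat([s.trials for s in sets], ignore_index=True)
    return EpochSet(data, list(first.channels), first.fs, first.time_ms, trials)
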