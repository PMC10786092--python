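"""Epoched multichannel EEG container and plain-text serialization.

One :class:`EpochedEEG` holds a single participant's epochs as a
``(n_trials, n_channels, n_times)`` array in microvolts, together with the
per-trial (race, pain, gender) condition labels and the timepoint grid.
Serialization is deliberately plain text: a wide CSV of samples, a CSV
sidecar of condition labels, and a JSON header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CATEGORIES, CONDITIONS
from .errors import ConfigError


@dataclass
class EpochedEEG:
    """Trials x channels x timepoints for one participant."""

    data: np.ndarray
    condition_labels: np.ndarray  # (n_trials, 3) of str
    times_ms: np.ndarray
    channel_ids: list[str] = field(default_factory=list)
    participant_id: str = "p000"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels, dtype=object)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError("data must be trials x channels x timepoints")
        n_trials, n_channels, n_times = self.data.shape
        if not self.channel_ids:
            self.channel_ids = [f"ch{i + 1:02d}" for i in range(n_channels)]
        if len(self.channel_ids) != n_channels:
            raise ConfigError("channel_ids length must match data channels")
        if self.condition_labels.shape != (n_trials, 3):
            raise ConfigError("condition_labels must be (n_trials, 3)")
        if self.times_ms.shape != (n_times,):
            raise ConfigError("times_ms length must match data timepoints")
        if n_times > 1:
            steps = np.diff(self.times_ms)
            if not np.all(steps > 0):
                raise ConfigError("times_ms must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
                raise ConfigError("times_ms must be uniformly spaced")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("data must be finite")
        for j, dim in enumerate(("race", "pain", "gender")):
            valid = set(CATEGORIES[dim])
            seen = set(self.condition_labels[:, j].tolist())
            if not seen <= valid:
                raise ConfigError(
                    f"condition_labels column '{dim}' has labels outside {valid}"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / float(self.times_ms[1] - self.times_ms[0])

    def condition_index(self) -> np.ndarray:
        """Index of each trial's condition in the canonical 8-condition order."""
        lookup = {cond: i for i, cond in enumerate(CONDITIONS)}
        return np.array(
            [lookup[tuple(row)] for row in self.condition_labels], dtype=int
        )

    def select_trials(self, mask: np.ndarray) -> "EpochedEEG":
        mask = np.asarray(mask)
        return EpochedEEG(
            data=self.data[mask],
            condition_labels=self.condition_labels[mask],
            times_ms=self.times_ms,
            channel_ids=list(self.channel_ids),
            participant_id=self.participant_id,
        )

    def crop(self, t_lo_ms: float, t_hi_ms: float) -> "EpochedEEG":
        """Restrict the epoch to timepoints within [t_lo_ms, t_hi_ms].

        Exact for per-timepoint analyses (each timepoint is processed
        independently downstream).
        """
        mask = (self.times_ms >= t_lo_ms - 1e-9) & (self.times_ms <= t_hi_ms + 1e-9)
        if not mask.any():
            raise ConfigError("crop window contains no timepoints")
        return EpochedEEG(
            data=self.data[:, :, mask],
            condition_labels=self.condition_labels,
            times_ms=self.times_ms[mask],
            channel_ids=list(self.channel_ids),
            participant_id=self.participant_id,
        )

    def time_index(self, t_ms: float) -> int:
        """Index of the grid point equal to ``t_ms`` (within numerical slack)."""
        idx = int(np.argmin(np.abs(self.times_ms - t_ms)))
        if abs(self.times_ms[idx] - t_ms) > 1e-6:
            raise ConfigError(f"time {t_ms} ms is not on the epoch grid")
        return idx

    # -- plain-text serialization -----------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        n_trials, _, n_times = self.data.shape
        flat = self.data.transpose(0, 2, 1).reshape(n_trials * n_times, -1)
        frame = pd.DataFrame(flat, columns=self.channel_ids)
        frame.insert(0, "time_ms", np.tile(self.times_ms, n_trials))
        frame.insert(0, "trial", np.repeat(np.arange(n_trials), n_times))
        frame.to_csv(directory / "data.csv", index=False)
        labels = pd.DataFrame(
            self.condition_labels, columns=["race", "pain", "gender"]
        )
        labels.insert(0, "trial", np.arange(n_trials))
        labels.to_csv(directory / "labels.csv", index=False)
        header = {
            "participant_id": self.participant_id,
            "channel_ids": list(self.channel_ids),
            "sampling_rate_hz": self.sampling_rate_hz if n_times > 1 else None,
            "n_trials": int(n_trials),
            "n_times": int(n_times),
        }
        (directory / "meta.json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EpochedEEG":
        directory = Path(directory)
        header = json.loads((directory / "meta.json").read_text())
        frame = pd.read_csv(directory / "data.csv")
        labels = pd.read_csv(directory / "labels.csv")
        channel_ids = header["channel_ids"]
        n_trials = header["n_trials"]
        n_times = header["n_times"]
        times = frame["time_ms"].to_numpy()[:n_times]
        data = (
            frame[channel_ids]
            .to_numpy()
            .reshape(n_trials, n_times, len(channel_ids))
            .transpose(0, 2, 1)
        )
        return cls(
            data=data,
            condition_labels=labels[["race", "pain", "gender"]].to_numpy(dtype=object),
            times_ms=times,
            channel_ids=channel_ids,
            participant_id=header["participant_id"],
        )
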