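"""Desk-reproducible preprocessing: artifact rejection, downsampling, exclusion.

The rules implemented here are the ones that can be reproduced without the
recording chain: trials with any sample exceeding an absolute amplitude
threshold are rejected, epochs are decimated to a lower rate, and
participants left with too few trials are excluded.  Decimation is plain
sample selection; the generator's signals are smooth, so no anti-alias
filter is applied by default (a low-pass hook is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sosfiltfilt, butter

from .epochs import EpochedEEG
from .errors import ConfigError, EmptyResultError

__all__ = [
    "PreprocessReport",
    "reject_artifact_trials",
    "downsample",
    "exclude_low_trial_participants",
    "lowpass",
]


@dataclass
class PreprocessReport:
    trials_in: int = 0
    trials_rejected: int = 0
    participants_excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trials_rejected > self.trials_in or min(self.trials_in, self.trials_rejected) < 0:
            raise ConfigError("rejected count must be within [0, trials_in]")


def reject_artifact_trials(
    epochs: EpochedEEG, threshold_uv: float = 100.0
) -> tuple[EpochedEEG, PreprocessReport]:
    """Drop trials whose absolute amplitude exceeds ``threshold_uv`` anywhere.

    Trial order is preserved.  Raises :class:`EmptyResultError` if every
    trial is rejected.
    """
    if threshold_uv <= 0:
        raise ConfigError("threshold_uv must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    report = PreprocessReport(
        trials_in=epochs.n_trials, trials_rejected=int((~keep).sum())
    )
    if not keep.any():
        raise EmptyResultError(
            f"all {epochs.n_trials} trials exceed +/-{threshold_uv} uV "
            f"for participant {epochs.participant_id}"
        )
    return epochs.select_trials(keep), report


def downsample(epochs: EpochedEEG, target_rate_hz: float = 100.0) -> EpochedEEG:
    """Decimate to ``target_rate_hz`` by sample selection.

    The original rate must be an integer multiple of the target; epoch
    endpoints are preserved when they sit on the coarser grid.
    """
    rate = epochs.sampling_rate_hz
    factor = rate / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigError(
            f"original rate {rate:g} Hz is not an integer multiple of "
            f"target {target_rate_hz:g} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return epochs
    return EpochedEEG(
        data=epochs.data[:, :, ::factor],
        condition_labels=epochs.condition_labels,
        times_ms=epochs.times_ms[::factor],
        channel_ids=list(epochs.channel_ids),
        participant_id=epochs.participant_id,
    )


def lowpass(epochs: EpochedEEG, cutoff_hz: float, order: int = 4) -> EpochedEEG:
    """Optional zero-phase Butterworth low-pass (off by default in the pipeline)."""
    sos = butter(order, cutoff_hz, fs=epochs.sampling_rate_hz, output="sos")
    return EpochedEEG(
        data=sosfiltfilt(sos, epochs.data, axis=2),
        condition_labels=epochs.condition_labels,
        times_ms=epochs.times_ms,
        channel_ids=list(epochs.channel_ids),
        participant_id=epochs.participant_id,
    )


def exclude_low_trial_participants(
    cohort: list[EpochedEEG], min_trials: int = 10
) -> tuple[list[EpochedEEG], PreprocessReport]:
    """Drop participants with fewer than ``min_trials`` retained trials.

    The rule is a strict ``<``: a participant with exactly ``min_trials``
    trials is retained.
    """
    if min_trials < 1:
        raise ConfigError("min_trials must be >= 1")
    kept, excluded = [], []
    for ep in cohort:
        if ep.n_trials < min_trials:
            excluded.append((ep.participant_id, f"trial number {ep.n_trials} < {min_trials}"))
        else:
            kept.append(ep)
    report = PreprocessReport(
        trials_in=sum(ep.n_trials for ep in cohort),
        trials_rejected=0,
        participants_excluded=excluded,
    )
    if not kept:
        raise EmptyResultError("no participants remain after low-trial exclusion")
    return kept, report
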