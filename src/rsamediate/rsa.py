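"""RSA regression: neural dissimilarity as a combination of model RDMs.

At each timepoint the z-scored 28-pair neural dissimilarity vector is
regressed (OLS with intercept) on the z-scored race, pain and gender model
vectors, yielding one beta per dimension per timepoint — the unique-variance
contribution of that dimension to the neural geometry.  Windowed means of
the beta time courses provide per-participant neural indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DIMENSIONS
from .epochs import EpochedEEG
from .errors import ConfigError, DegenerateDataError
from .rdm import (
    ModelRDMSet,
    build_model_rdms,
    neural_rdm_series,
    vectorize_and_zscore,
)

__all__ = [
    "BetaTimecourse",
    "NeuralIndicator",
    "fit_rdm_regression",
    "beta_timecourse",
    "window_average",
]


@dataclass
class BetaTimecourse:
    """Per-timepoint regression weights (race, pain, gender) for one participant."""

    betas: np.ndarray  # (n_times, 3)
    times_ms: np.ndarray
    participant_id: str = "p000"
    dimensions: tuple = DIMENSIONS

    def __post_init__(self) -> None:
        if self.betas.shape != (self.times_ms.size, len(self.dimensions)):
            raise ConfigError("betas must be (n_times, n_dimensions)")
        if not np.all(np.isfinite(self.betas)):
            raise ConfigError("betas must be finite")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (participant, time, dimension, beta) table."""
        records = [
            {
                "participant_id": self.participant_id,
                "time_ms": t,
                "dimension": d,
                "beta": self.betas[i, j],
            }
            for i, t in enumerate(self.times_ms)
            for j, d in enumerate(self.dimensions)
        ]
        return pd.DataFrame.from_records(records)

    def peak_latency_ms(self, dimension: str, window_ms=(0.0, 600.0)) -> float:
        """Latency of the maximum beta inside ``window_ms``."""
        j = self.dimensions.index(dimension)
        mask = (self.times_ms >= window_ms[0]) & (self.times_ms <= window_ms[1])
        t = self.times_ms[mask]
        return float(t[np.argmax(self.betas[mask, j])])


@dataclass
class NeuralIndicator:
    """Window-averaged betas (one scalar per dimension)."""

    participant_id: str
    window_ms: tuple[float, float]
    mean_beta: dict[str, float]


def fit_rdm_regression(neural_vec: np.ndarray, model_vecs: np.ndarray) -> np.ndarray:
    """OLS betas of a 28-pair neural vector on stacked model vectors.

    ``model_vecs`` is (k, 28).  An intercept is included; inputs are assumed
    z-scored.  Exactly collinear models are rejected.
    """
    y = np.asarray(neural_vec, dtype=float)
    M = np.atleast_2d(np.asarray(model_vecs, dtype=float))
    if M.shape[1] != y.size:
        raise ConfigError("model vectors and neural vector lengths differ")
    X = np.column_stack([np.ones(y.size), M.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateDataError(
            f"model vectors are collinear (design rank {rank} < {X.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef[1:]


def beta_timecourse(
    epochs: EpochedEEG,
    models: ModelRDMSet | None = None,
    cov_mode: str = "per_timepoint",
) -> BetaTimecourse:
    """Beta time course for one participant across the full epoch.

    The analysis window (0–600 ms) is applied downstream; the full epoch is
    retained here so baselines remain inspectable.
    """
    if models is None:
        models = build_model_rdms()
    series = neural_rdm_series(epochs, cov_mode=cov_mode)
    model_mat = models.vectors(zscore=True)  # (3, 28)
    T = series.times_ms.size
    betas = np.empty((T, model_mat.shape[0]))
    for t in range(T):
        neural = vectorize_and_zscore(series.rdms[t])
        betas[t] = fit_rdm_regression(neural, model_mat)
    return BetaTimecourse(
        betas=betas, times_ms=series.times_ms, participant_id=epochs.participant_id
    )


def subset_beta_timecourse(
    epochs: EpochedEEG, race_category: str, cov_mode: str = "per_timepoint"
) -> BetaTimecourse:
    """RSA restricted to one race's 4 conditions (pain + gender models only).

    Mirrors the separate per-race analysis: trials of the other race are
    dropped, 4x4 binary model RDMs for pain and gender are built over the
    remaining conditions, and the 6 unique pairs are regressed per timepoint.
    """
    from .config import CATEGORIES, CONDITIONS
    from .rdm import _condition_means, _ledoit_wolf_stack, _mahalanobis_from_means

    if race_category not in CATEGORIES["race"]:
        raise ConfigError(f"race_category must be one of {CATEGORIES['race']}")
    keep = np.array([row[0] == race_category for row in epochs.condition_labels])
    sub = epochs.select_trials(keep)
    conds = [c for c in CONDITIONS if c[0] == race_category]
    lookup = {c: i for i, c in enumerate(conds)}
    idx = np.array([lookup[tuple(row)] for row in sub.condition_labels])
    counts = np.bincount(idx, minlength=4)
    if (counts == 0).any():
        from .errors import MissingConditionError

        raise MissingConditionError(
            f"missing {race_category}-race conditions for {epochs.participant_id}"
        )
    means = np.zeros((4,) + sub.data.shape[1:])
    np.add.at(means, idx, sub.data)
    means /= counts[:, None, None]
    demeaned = sub.data - means[idx]
    if cov_mode == "per_timepoint":
        covs, _ = _ledoit_wolf_stack(demeaned.transpose(2, 0, 1))
    else:
        pooled = demeaned.transpose(0, 2, 1).reshape(-1, sub.n_channels)
        covs = np.repeat(_ledoit_wolf_stack(pooled[None])[0], sub.n_times, axis=0)

    i, j = np.triu_indices(4, 1)
    dims = ("pain", "gender")
    model_rows = []
    for axis, dim in ((1, "pain"), (2, "gender")):
        cats = np.array([c[axis] for c in conds])
        v = (cats[i] != cats[j]).astype(float)
        model_rows.append((v - v.mean()) / v.std())
    model_mat = np.vstack(model_rows)

    betas = np.empty((sub.n_times, 2))
    for t in range(sub.n_times):
        md = _mahalanobis_from_means(means[:, :, t], covs[t])[i, j]
        sd = md.std()
        if sd == 0:
            raise DegenerateDataError("constant subset RDM: z-score undefined")
        betas[t] = fit_rdm_regression((md - md.mean()) / sd, model_mat)
    return BetaTimecourse(
        betas=betas,
        times_ms=sub.times_ms,
        participant_id=epochs.participant_id,
        dimensions=dims,
    )


def window_average(
    betas: BetaTimecourse, window_ms: tuple[float, float] = (120.0, 160.0)
) -> NeuralIndicator:
    """Mean beta per dimension over ``window_ms`` (inclusive endpoints)."""
    lo, hi = window_ms
    if lo > hi:
        raise ConfigError("window start must not exceed end")
    mask = (betas.times_ms >= lo - 1e-9) & (betas.times_ms <= hi + 1e-9)
    if not mask.any():
        raise ConfigError(f"window {window_ms} contains no grid samples")
    mean = betas.betas[mask].mean(axis=0)
    return NeuralIndicator(
        participant_id=betas.participant_id,
        window_ms=(lo, hi),
        mean_beta={d: float(mean[j]) for j, d in enumerate(betas.dimensions)},
    )
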