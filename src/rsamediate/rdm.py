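"""Representational dissimilarity matrices from Mahalanobis distances.

The neural dissimilarity between two conditions at a timepoint is the
Mahalanobis distance between their trial-averaged topographies,

    MD_AB = sqrt((a - b)^T C^{-1} (a - b)),

where ``C`` is a Ledoit–Wolf shrinkage estimate of the channel covariance
computed from condition-demeaned single trials.  Binary model RDMs code each
stimulus dimension: entry 1 for condition pairs that differ on the
dimension's category, 0 otherwise.

The shrinkage estimator here is an analytic re-implementation of the
Ledoit–Wolf formula (shrinking toward the scaled identity), vectorized over
timepoints so that per-timepoint covariances stay cheap; tests assert exact
agreement with ``sklearn.covariance.LedoitWolf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .config import CONDITIONS, DIMENSIONS
from .epochs import EpochedEEG
from .errors import ConfigError, DegenerateDataError, MissingConditionError

__all__ = [
    "ModelRDMSet",
    "NeuralRDMSeries",
    "ShrunkCovariance",
    "build_model_rdms",
    "condition_mean_topographies",
    "shrinkage_covariance",
    "mahalanobis_rdm",
    "neural_rdm_series",
    "vectorize_and_zscore",
    "pair_indices",
]

N_CONDITIONS = 8
#: canonical ordering of the 28 unique off-diagonal pairs (row-major upper triangle)
_TRIU = np.triu_indices(N_CONDITIONS, k=1)


def pair_indices() -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the 28 unique condition pairs, canonical order."""
    return _TRIU


@dataclass(frozen=True)
class ModelRDMSet:
    """Binary 8x8 model RDMs for the race, pain and gender dimensions."""

    race: np.ndarray
    pain: np.ndarray
    gender: np.ndarray
    condition_order: tuple = CONDITIONS

    def __getitem__(self, dim: str) -> np.ndarray:
        return getattr(self, dim)

    def vectors(self, zscore: bool = True) -> np.ndarray:
        """(3, 28) stacked pair vectors, z-scored by default."""
        rows = []
        for d in DIMENSIONS:
            v = self[d][_TRIU]
            rows.append(vectorize_and_zscore(self[d]) if zscore else v)
        return np.vstack(rows)


@dataclass
class NeuralRDMSeries:
    """Per-timepoint 8x8 Mahalanobis-distance RDMs."""

    rdms: np.ndarray  # (n_times, 8, 8)
    times_ms: np.ndarray
    participant_id: str = "p000"

    def __post_init__(self) -> None:
        if self.rdms.ndim != 3 or self.rdms.shape[1:] != (8, 8):
            raise ConfigError("rdms must be (n_times, 8, 8)")
        if not np.all(np.isfinite(self.rdms)) or (self.rdms < -1e-12).any():
            raise ConfigError("RDM entries must be finite and non-negative")


@dataclass
class ShrunkCovariance:
    """Channels x channels shrinkage covariance estimate."""

    matrix: np.ndarray
    shrinkage_intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrinkage_intensity <= 1.0:
            raise ConfigError("shrinkage_intensity must be in [0, 1]")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ConfigError("covariance must be symmetric")


def build_model_rdms(condition_order=CONDITIONS) -> ModelRDMSet:
    """Binary between/within model RDMs for the 2x2x2 design."""
    conds = list(condition_order)
    if len(conds) != 8 or len(set(map(tuple, conds))) != 8:
        raise ConfigError("condition_order must contain the 8 distinct conditions")
    if set(map(tuple, conds)) != set(CONDITIONS):
        raise ConfigError("condition_order must cover the 2x2x2 design")
    mats = {}
    for j, dim in enumerate(DIMENSIONS):
        cats = np.array([c[j] for c in conds])
        mats[dim] = (cats[:, None] != cats[None, :]).astype(float)
    return ModelRDMSet(
        race=mats["race"],
        pain=mats["pain"],
        gender=mats["gender"],
        condition_order=tuple(map(tuple, conds)),
    )


def condition_mean_topographies(epochs: EpochedEEG, t_ms: float) -> np.ndarray:
    """(8, n_channels) trial-averaged topographies at one timepoint."""
    ti = epochs.time_index(t_ms)
    return _condition_means(epochs)[:, :, ti]


def _condition_means(epochs: EpochedEEG) -> np.ndarray:
    """(8, ch, T) condition means; raises if any condition is empty."""
    idx = epochs.condition_index()
    counts = np.bincount(idx, minlength=N_CONDITIONS)
    if (counts == 0).any():
        missing = [CONDITIONS[i] for i in np.flatnonzero(counts == 0)]
        raise MissingConditionError(
            f"participant {epochs.participant_id} has no trials for {missing}"
        )
    means = np.zeros((N_CONDITIONS,) + epochs.data.shape[1:])
    np.add.at(means, idx, epochs.data)
    return means / counts[:, None, None]


def _ledoit_wolf_stack(demeaned: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ledoit–Wolf shrinkage for a stack of centered samples.

    ``demeaned`` is (T, n, p): T independent estimation problems with n
    centered observations of p variables.  Returns (T, p, p) shrunk
    covariances and (T,) shrinkage intensities.  Matches
    sklearn.covariance.ledoit_wolf(assume_centered=True) exactly.
    """
    T, n, p = demeaned.shape
    if n < 2:
        raise DegenerateDataError("need at least 2 trials for covariance")
    if p < 2:
        raise DegenerateDataError("need at least 2 channels for covariance")
    dt = demeaned.transpose(0, 2, 1)
    emp = np.matmul(dt, demeaned) / n
    mu = np.trace(emp, axis1=1, axis2=2) / p
    eye = np.eye(p)
    delta = ((emp - mu[:, None, None] * eye) ** 2).sum(axis=(1, 2)) / p
    x2 = demeaned**2
    beta_raw = (
        np.matmul(x2.transpose(0, 2, 1), x2) / n - emp**2
    ).sum(axis=(1, 2)) / (p * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta > 0, np.minimum(beta_raw, delta) / np.where(delta > 0, delta, 1.0), 0.0)
    shrunk = (1.0 - shrink)[:, None, None] * emp + (shrink * mu)[:, None, None] * eye
    return shrunk, shrink


def shrinkage_covariance(condition_demeaned_trials: np.ndarray) -> ShrunkCovariance:
    """Ledoit–Wolf shrinkage covariance from condition-demeaned trials.

    ``condition_demeaned_trials`` is (n_trials, n_channels): each trial minus
    its own condition's mean response.  The estimate shrinks the sample
    covariance toward the scaled identity with an analytically chosen
    intensity in [0, 1].
    """
    x = np.asarray(condition_demeaned_trials, dtype=float)
    if x.ndim != 2:
        raise ConfigError("expected a trials x channels matrix")
    if not np.any(np.abs(x) > 0):
        raise DegenerateDataError(
            "demeaned trials are identically zero (duplicate trials?)"
        )
    shrunk, shrink = _ledoit_wolf_stack(x[None])
    return ShrunkCovariance(matrix=shrunk[0], shrinkage_intensity=float(shrink[0]))


def _mahalanobis_from_means(means_t: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """k x k MD matrix from (k, ch) means and a covariance matrix."""
    try:
        chol = cho_factor(cov, lower=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise DegenerateDataError(f"covariance not positive definite: {exc}") from exc
    # cheap conditioning diagnostic: squared ratio of Cholesky diagonal extremes
    # lower-bounds the condition number of cov
    diag = np.abs(np.diag(chol[0]))
    if diag.min() == 0 or (diag.max() / diag.min()) ** 2 > 1e12:
        raise DegenerateDataError(
            "covariance is numerically singular "
            f"(conditioning diagnostic {(diag.max() / max(diag.min(), 1e-300)) ** 2:.3g})"
        )
    k = means_t.shape[0]
    i, j = np.triu_indices(k, 1)
    diffs = means_t[i] - means_t[j]  # (n_pairs, ch)
    solved = cho_solve(chol, diffs.T).T
    d2 = np.einsum("pc,pc->p", diffs, solved)
    md = np.sqrt(np.maximum(d2, 0.0))
    out = np.zeros((k, k))
    out[i, j] = md
    out[j, i] = md
    return out


def mahalanobis_rdm(
    epochs: EpochedEEG, t_ms: float, cov: ShrunkCovariance
) -> np.ndarray:
    """8x8 Mahalanobis-distance RDM at one timepoint."""
    means_t = condition_mean_topographies(epochs, t_ms)
    return _mahalanobis_from_means(means_t, cov.matrix)


def neural_rdm_series(
    epochs: EpochedEEG, cov_mode: str = "per_timepoint"
) -> NeuralRDMSeries:
    """Mahalanobis RDMs over all timepoints.

    ``cov_mode`` selects whether the channel covariance is estimated per
    timepoint from that timepoint's condition-demeaned trials (default) or
    once per epoch from all timepoints pooled.
    """
    if cov_mode not in ("per_timepoint", "per_epoch"):
        raise ConfigError("cov_mode must be 'per_timepoint' or 'per_epoch'")
    means = _condition_means(epochs)  # (8, ch, T)
    idx = epochs.condition_index()
    demeaned = epochs.data - means[idx]  # (n, ch, T)
    T = epochs.n_times
    if cov_mode == "per_timepoint":
        stack = demeaned.transpose(2, 0, 1)  # (T, n, ch)
        covs, _ = _ledoit_wolf_stack(stack)
    else:
        pooled = demeaned.transpose(0, 2, 1).reshape(-1, epochs.n_channels)
        covs = np.repeat(
            _ledoit_wolf_stack(pooled[None])[0], T, axis=0
        )
    rdms = np.empty((T, N_CONDITIONS, N_CONDITIONS))
    for t in range(T):
        rdms[t] = _mahalanobis_from_means(means[:, :, t], covs[t])
    return NeuralRDMSeries(
        rdms=rdms, times_ms=epochs.times_ms, participant_id=epochs.participant_id
    )


def vectorize_and_zscore(rdm: np.ndarray) -> np.ndarray:
    """Extract the 28 unique pairs in canonical order and z-score them.

    Z-scoring uses the population SD (divide by n).  A constant RDM has no
    dissimilarity structure and raises :class:`DegenerateDataError`.
    """
    rdm = np.asarray(rdm, dtype=float)
    if rdm.shape != (N_CONDITIONS, N_CONDITIONS):
        raise ConfigError("expected an 8x8 matrix")
    if not np.allclose(rdm, rdm.T, atol=1e-10):
        raise ConfigError("RDM must be symmetric")
    v = rdm[_TRIU]
    sd = v.std()
    if sd == 0:
        raise DegenerateDataError("constant RDM: z-score undefined")
    return (v - v.mean()) / sd


def devectorize(vec: np.ndarray) -> np.ndarray:
    """Inverse of pair extraction: rebuild a symmetric zero-diagonal 8x8 matrix."""
    out = np.zeros((N_CONDITIONS, N_CONDITIONS))
    i, j = _TRIU
    out[i, j] = vec
    out[j, i] = vec
    return out
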