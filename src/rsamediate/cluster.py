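"""Cluster-based permutation test of group beta time courses against zero.

At each timepoint a one-sample t statistic is computed across participants.
Contiguous runs of timepoints whose |t| exceeds the two-tailed critical
value at ``threshold_p`` form clusters, separately for positive and
negative t.  The cluster statistic is the summed t ("mass"); observed
|mass| is compared against a permutation null built by randomly flipping
the sign of each participant's whole time course (the one-sample analogue
of reassigning condition membership) and recording the maximum |mass| per
iteration.  The p-value uses the +1 correction, so it is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError

__all__ = ["Cluster", "ClusterResult", "cluster_test"]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    threshold_p: float = 0.05
    n_permutations: int = 10000
    analysis_window_ms: tuple[float, float] = (0.0, 600.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        return {
            "threshold_p": self.threshold_p,
            "n_permutations": self.n_permutations,
            "analysis_window_ms": list(self.analysis_window_ms),
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "sign": c.sign,
                }
                for c in self.clusters
            ],
        }


def _tstat(data: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 for each column."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    return mean / (sd / np.sqrt(n))


def _clusters_from_t(tvals: np.ndarray, t_crit: float) -> list[tuple[int, int, float]]:
    """(start_idx, end_idx, mass) for suprathreshold runs, split by sign."""
    out = []
    for sign in (1, -1):
        above = (sign * tvals) > t_crit
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            out.append((int(start), int(stop - 1), float(tvals[start:stop].sum())))
    return out


def _max_cluster_mass(tvals: np.ndarray, t_crit: float) -> float:
    masses = [abs(m) for *_, m in _clusters_from_t(tvals, t_crit)]
    return max(masses, default=0.0)


def cluster_test(
    group_betas: np.ndarray,
    times_ms: np.ndarray | None = None,
    threshold_p: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
    analysis_window_ms: tuple[float, float] = (0.0, 600.0),
) -> ClusterResult:
    """Two-sided cluster permutation test of mean beta = 0.

    ``group_betas`` is participants x timepoints.  If ``times_ms`` is given,
    timepoints are restricted to ``analysis_window_ms`` first.  With a fixed
    seed the Monte-Carlo null is reproducible.
    """
    data = np.asarray(group_betas, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ConfigError("group_betas must be participants x timepoints, n >= 2")
    if not 0 < threshold_p < 1:
        raise ConfigError("threshold_p must be in (0, 1)")
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives a very coarse null", stacklevel=2)

    if times_ms is not None:
        times_ms = np.asarray(times_ms, dtype=float)
        lo, hi = analysis_window_ms
        mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
        data = data[:, mask]
        times_ms = times_ms[mask]
    n, T = data.shape
    if times_ms is None:
        times_ms = np.arange(T, dtype=float)

    zero_var = data.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} timepoints have zero variance across "
            "participants; their t statistics are set to 0",
            stacklevel=2,
        )

    t_crit = stats.t.ppf(1.0 - threshold_p / 2.0, df=n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed_t = _tstat(data)
    observed_t = np.nan_to_num(observed_t, nan=0.0, posinf=0.0, neginf=0.0)
    observed = _clusters_from_t(observed_t, t_crit)

    rng = np.random.default_rng(seed)
    # vectorized sign-flip t statistics: sum of squares is flip-invariant
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    sum_sq = (data**2).sum(axis=0)  # (T,)
    means = (flips @ data) / n  # (P, T)
    var = (sum_sq / n - means**2) * (n / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_t = means / np.sqrt(var / n)
    null_t = np.nan_to_num(null_t, nan=0.0, posinf=0.0, neginf=0.0)
    null_max = np.fromiter(
        (_max_cluster_mass(row, t_crit) for row in null_t),
        dtype=float,
        count=n_permutations,
    )

    clusters = []
    for start, stop, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_permutations)
        clusters.append(
            Cluster(
                start_ms=float(times_ms[start]),
                end_ms=float(times_ms[stop]),
                mass=mass,
                p_value=float(p),
                sign=1 if mass > 0 else -1,
            )
        )
    clusters.sort(key=lambda c: c.start_ms)
    return ClusterResult(
        clusters=clusters,
        threshold_p=threshold_p,
        n_permutations=n_permutations,
        analysis_window_ms=tuple(analysis_window_ms),
    )
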