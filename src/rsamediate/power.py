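"""Sampling-variability curves and the SEM minimum-sample-size bound.

``sampling_variability`` quantifies how much a brain–behavior correlation
fluctuates at small n: participants are resampled with replacement at a
grid of sample sizes and the spread of the resulting Pearson correlations
(min–max range, 95% and 99% quantile intervals) is reported per size.  The
"confidence intervals" follow the resampling usage: they are quantiles of
the resampling distribution, not analytic CIs.

``westland_min_n`` is an a-priori lower bound on SEM sample size combining
an effect-detection bound with a structural bound driven by the ratio of
observed to latent variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError

__all__ = ["SamplingCurve", "log_spaced_sizes", "sampling_variability", "westland_min_n"]


def log_spaced_sizes(n_min: int = 25, n_max: int = 676, n_intervals: int = 20) -> list[int]:
    """Logarithmically spaced sample sizes from ``n_min`` to ``n_max``.

    The grid is uniform in log2, anchored at ``n_max`` and descending in
    steps of ``h`` doublings, where ``h = log2(n_max/n_min)/(n_intervals-1)``
    snapped to the nearest quarter when that is an adequate fit (within
    0.01); each size is the floor of ``n_max * 2**(-k*h)``.  The
    quarter-doubling snap makes the default grid a "halve every four steps"
    ladder; with (25, 676, 20) it yields 25, 29, 35, ..., 568, 676.
    """
    if n_intervals < 2:
        raise ConfigError("n_intervals must be >= 2")
    if n_min < 3:
        raise ConfigError("n_min must be >= 3")
    if n_min >= n_max:
        raise ConfigError("n_min must be below n_max")
    h = math.log2(n_max / n_min) / (n_intervals - 1)
    snapped = round(h * 4) / 4
    if snapped > 0 and abs(snapped - h) < 0.01:
        h = snapped
    sizes = [int(math.floor(n_max * 2.0 ** (-k * h))) for k in range(n_intervals)]
    sizes = sizes[::-1]
    if sizes != sorted(set(sizes)):
        raise DegenerateDataError("size grid is not strictly increasing; widen the range")
    return sizes


@dataclass
class SamplingCurve:
    sizes: list[int]
    mean_r: np.ndarray
    min_r: np.ndarray
    max_r: np.ndarray
    q95: np.ndarray  # (n_sizes, 2): 2.5 / 97.5 percentiles
    q99: np.ndarray  # (n_sizes, 2): 0.5 / 99.5 percentiles
    n_resamples: int
    n_redrawn: int = 0

    def width(self, level: int = 99) -> np.ndarray:
        q = self.q99 if level == 99 else self.q95
        return q[:, 1] - q[:, 0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (size, statistic, value) table."""
        rows = []
        for i, s in enumerate(self.sizes):
            rows += [
                {"size": s, "statistic": "mean_r", "value": self.mean_r[i]},
                {"size": s, "statistic": "min_r", "value": self.min_r[i]},
                {"size": s, "statistic": "max_r", "value": self.max_r[i]},
                {"size": s, "statistic": "q2.5", "value": self.q95[i, 0]},
                {"size": s, "statistic": "q97.5", "value": self.q95[i, 1]},
                {"size": s, "statistic": "q0.5", "value": self.q99[i, 0]},
                {"size": s, "statistic": "q99.5", "value": self.q99[i, 1]},
            ]
        return pd.DataFrame(rows)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (R, n) arrays; NaN when degenerate."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.einsum("rn,rn->r", xc, yc)
    den = np.sqrt(
        np.einsum("rn,rn->r", xc, xc) * np.einsum("rn,rn->r", yc, yc)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def sampling_variability(
    x,
    y,
    sizes: list[int] | None = None,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> SamplingCurve:
    """Resampling distribution of corr(x, y) at each sample size.

    Participants are drawn with replacement, so sizes may exceed the number
    of available participants.  Zero-variance resamples (undefined
    correlation) are redrawn and counted.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ConfigError("x and y must have equal lengths")
    if x.size < 3:
        raise ConfigError("need at least 3 participants")
    if sizes is None:
        sizes = log_spaced_sizes(25, x.size, 20)
    rng = np.random.default_rng(seed)
    n = x.size
    n_sizes = len(sizes)
    mean_r = np.empty(n_sizes)
    min_r = np.empty(n_sizes)
    max_r = np.empty(n_sizes)
    q95 = np.empty((n_sizes, 2))
    q99 = np.empty((n_sizes, 2))
    n_redrawn = 0
    for i, s in enumerate(sizes):
        rs = np.empty(n_resamples)
        filled = 0
        while filled < n_resamples:
            chunk = n_resamples - filled
            idx = rng.integers(0, n, size=(chunk, s))
            r = _pearson_rows(x[idx], y[idx])
            good = np.isfinite(r)
            n_redrawn += int((~good).sum())
            r = r[good]
            rs[filled : filled + r.size] = r
            filled += r.size
        mean_r[i] = rs.mean()
        min_r[i] = rs.min()
        max_r[i] = rs.max()
        q95[i] = np.quantile(rs, [0.025, 0.975])
        q99[i] = np.quantile(rs, [0.005, 0.995])
    return SamplingCurve(
        sizes=list(sizes),
        mean_r=mean_r,
        min_r=min_r,
        max_r=max_r,
        q95=q95,
        q99=q99,
        n_resamples=n_resamples,
        n_redrawn=n_redrawn,
    )


def westland_min_n(
    effect: float,
    power: float = 0.95,
    alpha: float = 0.05,
    n_latent: int = 2,
    n_observed: int = 11,
) -> int:
    """A-priori minimum SEM sample size (lower bound).

    Returns the larger of two bounds, each rounded up:

    * an effect-detection bound for a standardized association ``effect``
      between latent variables at the requested power and two-sided alpha,
      based on detecting the corresponding Kendall concordance
      tau = (2/pi)*asin(effect) with a conservative variance constant of
      12/25 (this operationalization reproduces the published calculator's
      worked values, e.g. 679 for effect 0.15, power 0.95, alpha 0.05);
    * a structural bound driven by the ratio r of observed to latent
      variables: 50*r**2 - 450*r + 1100.
    """
    from scipy import stats

    if not 0.0 < effect < 1.0:
        raise ConfigError("effect must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ConfigError("power must be in (0, 1)")
    if n_latent < 1 or n_observed < n_latent:
        raise ConfigError("need n_observed >= n_latent >= 1")

    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    tau = (2.0 / math.pi) * math.asin(effect)
    n_effect = math.ceil(0.48 * z**2 / tau**2)

    r = n_observed / n_latent
    n_struct = math.ceil(50.0 * r**2 - 450.0 * r + 1100.0)
    return max(n_effect, n_struct)
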