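"""Trait scoring, orthogonalization, and the extreme-group contrast.

Esteem-for-group (EG) and relational-interdependence (RI) composites are
config-driven item means over 1–7 Likert ratings (a deliberate approximation
to latent factor scores; see docs/methods.md).  Each composite is then
standardized and the companion trait regressed out, giving orthogonalized
scores whose correlation with the other raw trait is exactly zero.  The
extreme-group contrast compares an outcome between the bottom- and
top-quartile participants with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "score_subcomponents",
    "orthogonalize",
    "extreme_group_compare",
    "punishment_outcome",
    "ExtremeGroupResult",
]


def score_subcomponents(
    item_ratings: pd.DataFrame, mapping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-factor composites as means of assigned item columns.

    ``mapping`` assigns each factor a list of at least two item columns.
    Ratings must lie in [1, 7]; rows with missing items are flagged via a
    boolean ``complete`` column and their composites set to NaN.
    """
    if not mapping:
        raise ConfigError("mapping must assign items to at least one factor")
    out = pd.DataFrame(index=item_ratings.index)
    complete = pd.Series(True, index=item_ratings.index)
    for factor, items in mapping.items():
        items = list(items)
        if len(items) < 2:
            raise ConfigError(f"factor '{factor}' must have >= 2 items")
        missing_cols = [c for c in items if c not in item_ratings.columns]
        if missing_cols:
            raise ConfigError(f"item columns not found: {missing_cols}")
        block = item_ratings[items]
        valid = block.notna()
        vals = block.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 1) | (finite > 7)).any():
            raise ConfigError(f"ratings for factor '{factor}' outside [1, 7]")
        complete &= valid.all(axis=1)
        out[f"{factor}_raw"] = block.mean(axis=1).where(valid.all(axis=1))
    out["complete"] = complete
    if "participant_id" in item_ratings.columns:
        out.insert(0, "participant_id", item_ratings["participant_id"])
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DegenerateDataError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def orthogonalize(
    scores: pd.DataFrame, factors: tuple[str, str] = ("EG", "RI")
) -> pd.DataFrame:
    """Add standardized residual scores with the companion trait regressed out.

    For factors (A, B): ``A_orth`` is the standardized OLS residual of
    standardized A on standardized B (and symmetrically), so
    corr(A_orth, B_raw) = 0 exactly.
    """
    a, b = factors
    out = scores.copy()
    xa = scores[f"{a}_raw"].to_numpy(dtype=float)
    xb = scores[f"{b}_raw"].to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ConfigError("orthogonalize requires complete trait scores")
    if xa.size < 3:
        raise ConfigError("need at least 3 participants")
    za, zb = _standardize(xa), _standardize(xb)
    r = float(np.mean(za * zb))
    if abs(r) >= 1.0 - 1e-12:
        raise DegenerateDataError("traits are perfectly collinear")
    out[f"{a}_orth"] = _standardize(za - r * zb)
    out[f"{b}_orth"] = _standardize(zb - r * za)
    return out


def punishment_outcome(cohort: pd.DataFrame) -> pd.Series:
    """High-minus-low conflict shock intensity (mA) per participant."""
    return cohort["punishment_high"] - cohort["punishment_low"]


@dataclass(frozen=True)
class ExtremeGroupResult:
    median_low: float
    median_high: float
    statistic: float
    p_value: float
    n_low: int
    n_high: int


def extreme_group_compare(
    scores: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
) -> ExtremeGroupResult:
    """Rank-sum contrast of the outcome between score quartile extremes.

    Groups are participants with scores at or below the ``lower_q`` quantile
    and at or above the ``upper_q`` quantile (linear-interpolation quantiles,
    boundary inclusive).  The two-sided Wilcoxon rank-sum test is computed
    via the Mann–Whitney U statistic (exact for small untied samples).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.size != y.size:
        raise ConfigError("scores and outcome lengths differ")
    if s.size < 8:
        raise ConfigError("need at least 8 participants for quartile groups")
    q_lo, q_hi = np.quantile(s, [lower_q, upper_q])
    low = y[s <= q_lo]
    high = y[s >= q_hi]
    if low.size == 0 or high.size == 0:
        raise DegenerateDataError(
            "tied percentile boundary produced an empty extreme group"
        )
    if np.ptp(np.concatenate([low, high])) == 0:
        # outcome identical everywhere: no discriminability
        return ExtremeGroupResult(
            median_low=float(np.median(low)),
            median_high=float(np.median(high)),
            statistic=float(low.size * high.size / 2.0),
            p_value=1.0,
            n_low=int(low.size),
            n_high=int(high.size),
        )
    res = stats.mannwhitneyu(high, low, alternative="two-sided")
    return ExtremeGroupResult(
        median_low=float(np.median(low)),
        median_high=float(np.median(high)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_low=int(low.size),
        n_high=int(high.size),
    )
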