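"""Single-mediator regression mediation with bias-corrected bootstrap CIs.

The model mirrors the classic "model 4" layout: the a-path regresses the
mediator M on the predictor X, the b and c' paths come from the joint
regression of the outcome Y on X and M, and the total effect c from Y on X
alone.  The indirect effect is the product a*b; its confidence interval is a
bias-corrected (BC, no acceleration) percentile bootstrap over row
resamples.  Path p-values come from classical OLS t tests (statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = ["MediationResult", "mediate", "regress_outcome_on_indicators"]


@dataclass(frozen=True)
class PathEstimate:
    coef: float
    se: float
    t: float
    p: float


@dataclass
class MediationResult:
    a_path: PathEstimate
    b_path: PathEstimate
    c_total: PathEstimate
    c_prime_direct: PathEstimate
    indirect: float
    ci: tuple[float, float]
    ci_level: float
    n_boot: int
    n_obs: int
    n_redrawn: int = 0
    covariates: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        """CI excludes zero."""
        lo, hi = self.ci
        return lo > 0 or hi < 0

    def to_dict(self) -> dict:
        def path(p: PathEstimate) -> dict:
            return {"coef": p.coef, "se": p.se, "t": p.t, "p": p.p}

        return {
            "a_path": path(self.a_path),
            "b_path": path(self.b_path),
            "c_total": path(self.c_total),
            "c_prime_direct": path(self.c_prime_direct),
            "indirect": self.indirect,
            "ci": list(self.ci),
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "n_obs": self.n_obs,
            "n_redrawn": self.n_redrawn,
            "covariates": self.covariates,
            "significant": self.significant,
        }


def _ols_path(y: np.ndarray, X: np.ndarray, col: int) -> PathEstimate:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return PathEstimate(
        coef=float(model.params[col + 1]),
        se=float(model.bse[col + 1]),
        t=float(model.tvalues[col + 1]),
        p=float(model.pvalues[col + 1]),
    )


def _ab_paths(X: np.ndarray, M: np.ndarray, Y: np.ndarray, C: np.ndarray | None):
    """Point estimates of (a, b) by plain least squares (bootstrap hot path)."""
    ones = np.ones_like(X)
    if C is None:
        Xa = np.column_stack([ones, X])
        Xb = np.column_stack([ones, X, M])
    else:
        Xa = np.column_stack([ones, X, C])
        Xb = np.column_stack([ones, X, M, C])
    a = np.linalg.lstsq(Xa, M, rcond=None)[0][1]
    b_idx = 2
    b = np.linalg.lstsq(Xb, Y, rcond=None)[0][b_idx]
    return a, b


def _ab_paths_vectorized(Xb, Mb, Yb):
    """(a, b) per bootstrap row for the no-covariate case.

    Inputs are (B, n) arrays of resampled columns; closed-form OLS.
    """
    n = Xb.shape[1]
    xm = Xb.mean(axis=1)
    mm = Mb.mean(axis=1)
    ym = Yb.mean(axis=1)
    xc = Xb - xm[:, None]
    mc = Mb - mm[:, None]
    yc = Yb - ym[:, None]
    sxx = np.einsum("bn,bn->b", xc, xc)
    smm = np.einsum("bn,bn->b", mc, mc)
    sxm = np.einsum("bn,bn->b", xc, mc)
    sxy = np.einsum("bn,bn->b", xc, yc)
    smy = np.einsum("bn,bn->b", mc, yc)
    a = sxm / sxx
    det = sxx * smm - sxm**2
    b = (sxx * smy - sxm * sxy) / det
    bad = (sxx <= 0) | (smm <= 0) | (det <= 0)
    return a, b, bad


def mediate(
    X,
    M,
    Y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 10000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator mediation with a bias-corrected bootstrap CI.

    Rows with missing values are dropped (complete-case).  Bootstrap
    resamples whose X or M column is degenerate are redrawn and counted in
    ``n_redrawn``.  The BC interval shifts the percentile endpoints by
    ``2*z0`` where ``z0`` is the normal quantile of the fraction of
    bootstrap indirect effects below the point estimate.
    """
    X = np.asarray(X, dtype=float).ravel()
    M = np.asarray(M, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if not (X.size == M.size == Y.size):
        raise ConfigError("X, M, Y must have equal lengths")
    cov_names: list[str] = []
    C = None
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != X.size:
                C = C.T
            cov_names = [f"cov{i}" for i in range(C.shape[1])]

    mask = np.isfinite(X) & np.isfinite(M) & np.isfinite(Y)
    if C is not None:
        mask &= np.isfinite(C).all(axis=1)
    X, M, Y = X[mask], M[mask], Y[mask]
    if C is not None:
        C = C[mask]
    n = X.size
    if n < 5:
        raise ConfigError("need at least 5 complete cases")
    if X.std() == 0 or M.std() == 0:
        raise DegenerateDataError("X or M has zero variance")

    # path estimates with OLS t tests
    if C is None:
        Xa, Xbc, Xc = X[:, None], np.column_stack([X, M]), X[:, None]
    else:
        Xa = np.column_stack([X, C])
        Xbc = np.column_stack([X, M, C])
        Xc = np.column_stack([X, C])
    a_path = _ols_path(M, Xa, 0)
    b_path = _ols_path(Y, Xbc, 1)
    c_prime = _ols_path(Y, Xbc, 0)
    c_total = _ols_path(Y, Xc, 0)
    point = a_path.coef * b_path.coef

    rng = np.random.default_rng(seed)
    n_redrawn = 0
    boots = np.empty(n_boot)
    if C is None:
        filled = 0
        while filled < n_boot:
            chunk = min(n_boot - filled, 4096)
            idx = rng.integers(0, n, size=(chunk, n))
            a, b, bad = _ab_paths_vectorized(X[idx], M[idx], Y[idx])
            good = ~bad
            keep = a[good] * b[good]
            boots[filled : filled + keep.size] = keep
            filled += keep.size
            n_redrawn += int(bad.sum())
    else:
        filled = 0
        while filled < n_boot:
            idx = rng.integers(0, n, size=n)
            if X[idx].std() == 0 or M[idx].std() == 0:
                n_redrawn += 1
                continue
            a, b = _ab_paths(X[idx], M[idx], Y[idx], C[idx])
            boots[filled] = a * b
            filled += 1

    # bias-corrected percentile interval
    frac = np.mean(boots < point)
    frac = min(max(frac, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(frac)
    alpha = 1.0 - ci_level
    z_lo, z_hi = stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)
    p_lo = stats.norm.cdf(2.0 * z0 + z_lo)
    p_hi = stats.norm.cdf(2.0 * z0 + z_hi)
    lo, hi = np.quantile(boots, [p_lo, p_hi])

    return MediationResult(
        a_path=a_path,
        b_path=b_path,
        c_total=c_total,
        c_prime_direct=c_prime,
        indirect=float(point),
        ci=(float(lo), float(hi)),
        ci_level=ci_level,
        n_boot=n_boot,
        n_obs=n,
        n_redrawn=n_redrawn,
        covariates=cov_names,
    )


def regress_outcome_on_indicators(
    outcome,
    indicators: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Multiple OLS of an outcome on neural indicators, standardized.

    Returns a coefficient table (one row per indicator) with standardized
    betas, t statistics and two-sided p-values.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if isinstance(indicators, pd.DataFrame):
        names = names or list(indicators.columns)
        Z = indicators.to_numpy(dtype=float)
    else:
        Z = np.atleast_2d(np.asarray(indicators, dtype=float))
        if Z.shape[0] != y.size:
            Z = Z.T
        names = names or [f"x{i}" for i in range(Z.shape[1])]
    if y.size <= 10:
        raise ConfigError("need more than 10 observations")
    if not np.all(np.isfinite(Z)) or not np.all(np.isfinite(y)):
        raise ConfigError("indicators and outcome must be finite")
    sds = Z.std(axis=0)
    if (sds == 0).any() or y.std() == 0:
        raise DegenerateDataError("zero-variance column")
    Zs = (Z - Z.mean(axis=0)) / sds
    ys = (y - y.mean()) / y.std()
    if np.linalg.matrix_rank(Zs) < Zs.shape[1]:
        raise DegenerateDataError("indicators are rank deficient")
    model = sm.OLS(ys, sm.add_constant(Zs)).fit()
    raw = sm.OLS(y, sm.add_constant(Z)).fit()
    return pd.DataFrame(
        {
            "coef": raw.params[1:],
            "beta": model.params[1:],
            "t": model.tvalues[1:],
            "p": model.pvalues[1:],
        },
        index=pd.Index(names, name="indicator"),
    )
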