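"""Relative importance of climate drivers for community trait axes.

The variance of a community PC score explained by the five climate
variables (MAT, MAP, Summer_T, Summer_P, AI) is decomposed with the LMG
method: each regressor's share is its average sequential increment to R^2
over all p! orderings in which regressors can enter the model — a Shapley
value.  Shares are nonnegative and sum exactly to the full-model R^2.

The p! average is computed through the equivalent subset-weighted sum

    share_j = sum_{S not containing j} w(|S|) * (R2(S + j) - R2(S)),
    w(k) = k! (p - 1 - k)! / p!,

which needs 2^p subset R^2 values instead of p! orderings; with
standardised regressors each subset R^2 comes from one small solve against
the regressor correlation matrix.  Uncertainty is quantified by a
nonparametric bootstrap over communities with percentile intervals.
"""

from __future__ import annotations

import logging
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import CLIMATE_VARS, ImportanceResult

__all__ = [
    "aggregate_climate",
    "ols_fit",
    "lmg_importance",
    "lmg_importance_enumerated",
    "LMGImportance",
    "bootstrap_importance",
    "univariate_regressions",
    "aridity_divergence",
]

logger = logging.getLogger(__name__)


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix (or a subset model) is rank deficient."""


def aggregate_climate(climate: pd.DataFrame, resolution: float = 0.25) -> pd.DataFrame:
    """Mean per-plot climate within each grid cell.

    ``climate`` holds one row per plot (``plot_id, lon, lat`` + the climate
    variables); returns a cell-indexed DataFrame of cell means.
    """
    from .community import assign_grid

    c = climate.copy()
    c["cell_id"] = assign_grid(c, resolution)
    return c.groupby("cell_id")[list(CLIMATE_VARS)].mean()


def _collinear_columns(X: np.ndarray, names) -> list:
    """Identify columns beyond the numerical rank via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def ols_fit(X: pd.DataFrame | np.ndarray, y) -> tuple[np.ndarray, float]:
    """Least squares with intercept via SVD; returns (coefficients, R^2).

    Coefficients are ordered ``[intercept, b_1, ..., b_p]``.  Raises
    :class:`RankDeficiencyError` listing the collinear columns when the
    design matrix is rank deficient.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    design = np.column_stack([np.ones(n), Xa])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise RankDeficiencyError(
            f"rank-deficient design; collinear columns: "
            f"{_collinear_columns(design, ['intercept'] + names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(design, ya, rcond=None)
    resid = ya - design @ beta
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return beta, r2


def _subset_r2_table(C: np.ndarray, r_y: np.ndarray) -> np.ndarray:
    """R^2 of every regressor subset, indexed by bitmask.

    ``C`` is the regressor correlation matrix, ``r_y`` the regressor-response
    correlations; for a subset S, R2(S) = r_yS' C_SS^{-1} r_yS.
    """
    p = C.shape[0]
    table = np.empty(1 << p)
    table[0] = 0.0
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        sub = C[np.ix_(idx, idx)]
        try:
            sol = np.linalg.solve(sub, r_y[idx])
        except np.linalg.LinAlgError as e:
            raise RankDeficiencyError(
                f"singular regressor subset {idx}"
            ) from e
        table[mask] = float(r_y[idx] @ sol)
    return table


def _standardise(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    return Xs, ys


def _lmg_from_moments(C: np.ndarray, r_y: np.ndarray) -> tuple[np.ndarray, float]:
    p = C.shape[0]
    table = _subset_r2_table(C, r_y)
    weights = np.array(
        [factorial(k) * factorial(p - 1 - k) / factorial(p) for k in range(p)]
    )
    shares = np.zeros(p)
    for mask in range(1 << p):
        k = bin(mask).count("1")
        for j in range(p):
            if not mask >> j & 1:
                shares[j] += weights[k] * (table[mask | 1 << j] - table[mask])
    return shares, float(table[(1 << p) - 1])


def lmg_importance(X: pd.DataFrame | np.ndarray, y) -> pd.Series:
    """LMG (Shapley) R^2 shares via the subset-weighted identity.

    Regressors are standardised first (LMG itself is scale-invariant; this
    only conditions the solves).  Limited to p <= 12 regressors (2^p subset
    models).  The returned shares sum to the full-model R^2.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    p = Xa.shape[1]
    if p > 12:
        raise ValueError(f"exhaustive subset enumeration limited to p<=12, got {p}")
    ya = np.asarray(y, dtype=float).ravel()
    Xs, ys = _standardise(Xa, ya)
    n = len(ys)
    C = (Xs.T @ Xs) / (n - 1)
    r_y = (Xs.T @ ys) / (n - 1)
    shares, _ = _lmg_from_moments(C, r_y)
    return pd.Series(shares, index=names, name="lmg_share")


def lmg_importance_enumerated(X, y) -> pd.Series:
    """Naive p! all-orderings LMG (oracle; exponential, tiny p only)."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    p = Xa.shape[1]

    def r2_of(idx: tuple[int, ...]) -> float:
        if not idx:
            return 0.0
        _, r2 = ols_fit(Xa[:, list(idx)], ya)
        return r2

    cache: dict[tuple[int, ...], float] = {}

    def r2_cached(idx) -> float:
        key = tuple(sorted(idx))
        if key not in cache:
            cache[key] = r2_of(key)
        return cache[key]

    shares = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        before: list[int] = []
        for j in order:
            shares[j] += r2_cached(before + [j]) - r2_cached(before)
            before.append(j)
    return pd.Series(shares / len(orders), index=names, name="lmg_share")


class LMGImportance(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the LMG R^2 decomposition.

    After ``fit(X, y)``: ``shares_`` (Series, sums to ``r_squared_``),
    ``r_squared_``, ``coef_``/``intercept_`` of the full OLS model.
    """

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
        beta, r2 = ols_fit(X, y)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.shares_ = lmg_importance(X, y)
        self.r_squared_ = r2
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


def bootstrap_importance(
    X: pd.DataFrame,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    response: str = "y",
    max_retries: int = 100,
) -> ImportanceResult:
    """Bootstrapped LMG shares with percentile confidence intervals.

    Communities are resampled with replacement ``n_boot`` times; degenerate
    draws (rank-deficient regressor sample) are redrawn up to
    ``max_retries`` times in total and logged.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)

    point = lmg_importance(Xa, ya)
    point.index = names
    _, full_r2 = ols_fit(Xa, ya)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(names)))
    retries = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        if Xa[idx].std(axis=0).min() == 0.0 or ya[idx].std() == 0.0:
            retries += 1
            if retries > max_retries:
                raise RankDeficiencyError(
                    f"exceeded {max_retries} redraws of degenerate bootstrap "
                    "samples"
                )
            continue
        try:
            Xs, ys = _standardise(Xa[idx], ya[idx])
            C = (Xs.T @ Xs) / (n - 1)
            r_y = (Xs.T @ ys) / (n - 1)
            shares, _ = _lmg_from_moments(C, r_y)
        except (RankDeficiencyError, FloatingPointError):
            retries += 1
            if retries > max_retries:
                raise RankDeficiencyError(
                    f"exceeded {max_retries} redraws of degenerate bootstrap "
                    "samples"
                )
            continue
        draws[b] = shares
        b += 1
    if retries:
        logger.info("bootstrap_importance: %d degenerate draws redrawn", retries)

    draws_df = pd.DataFrame(draws, columns=names)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return ImportanceResult(
        response=response,
        shares=point,
        r_squared=full_r2,
        boot_mean=pd.Series(draws.mean(axis=0), index=names),
        ci_low=pd.Series(lo, index=names),
        ci_high=pd.Series(hi, index=names),
        draws=draws_df,
        n_obs=n,
        n_boot=n_boot,
    )


def univariate_regressions(
    climate: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Simple OLS of each PC score on each climate variable.

    Returns a tidy frame with columns ``response, variable, slope,
    stderr, r2, p`` (two-sided p from the t test on the slope).
    """
    rows = []
    joined = climate.join(scores, how="inner")
    for pc in scores.columns:
        for var in climate.columns:
            res = stats.linregress(joined[var], joined[pc])
            rows.append(
                {
                    "response": pc,
                    "variable": var,
                    "slope": res.slope,
                    "stderr": res.stderr,
                    "r2": res.rvalue**2,
                    "p": res.pvalue,
                    "n": len(joined),
                }
            )
    return pd.DataFrame(rows)


def aridity_divergence(
    scores: pd.DataFrame,
    ai: pd.Series,
    n_bins: int = 5,
    min_per_bin: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divergence of trait-axis scores toward the arid end of the gradient.

    Communities are split into ``n_bins`` equal-count aridity-index bins;
    per bin and PC the score variance is computed, and the monotone trend of
    variance against bin median AI is measured by Spearman rank correlation
    (a planted widening of strategies at low AI shows up as a negative
    correlation).

    Returns ``(per_bin, trend)`` where ``per_bin`` has columns ``bin,
    ai_median, n`` plus one variance column per PC, and ``trend`` has
    ``response, rho, p``.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 aridity bins")
    joined = scores.join(ai.rename("AI"), how="inner").dropna()
    labels = pd.qcut(joined["AI"], q=n_bins, labels=False, duplicates="drop")
    counts = labels.value_counts()
    if labels.nunique() < n_bins or (counts < min_per_bin).any():
        raise ValueError(
            f"too few communities per bin (minimum {min_per_bin}); "
            f"bin sizes {sorted(counts.to_dict().items())}"
        )
    per_bin = joined.groupby(labels).agg(
        ai_median=("AI", "median"), n=("AI", "size"),
        **{f"var_{pc}": (pc, lambda s: s.var(ddof=1)) for pc in scores.columns},
    ).rename_axis("bin").reset_index()

    rows = []
    for pc in scores.columns:
        rho, p = stats.spearmanr(per_bin["ai_median"], per_bin[f"var_{pc}"])
        rows.append({"response": pc, "rho": float(rho), "p": float(p)})
    return per_bin, pd.DataFrame(rows)
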