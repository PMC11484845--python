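"""Scaled/centred PCA of the CWM matrix, with Procrustes congruence tests.

The ordination is a correlation-matrix PCA computed from first principles:
columns are z-scored (ddof=1) and the decomposition is taken from the
singular values of the standardised matrix, which is algebraically the
eigendecomposition of the Pearson correlation matrix.  Because PCA signs
are arbitrary, each component is flipped so that the trait with the largest
absolute loading has a positive loading; this fixed convention makes
loadings, scores and downstream Procrustes comparisons reproducible.

Loading *contributions* follow the usual convention: the squared loading of
a trait on an axis as a percentage of the axis' total squared loadings.

:func:`procrustes_compare` measures the congruence of two loading
configurations by symmetric Procrustes superimposition (centre, unit-norm,
optimal rotation, optional dilation); the residual statistic
``m2 = 1 - (sum of singular values of X'Y)^2`` lies in [0, 1] and is tested
by permuting the rows (traits) of the second configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import OrdinationSummary, ProcrustesResult

__all__ = [
    "ScaledPCA",
    "pca",
    "contributions",
    "correlation_matrix",
    "procrustes_compare",
]


class ScaledPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA with a deterministic sign convention.

    Parameters
    ----------
    n_components : int
        Number of leading components to retain for scores/loadings (the
        explained-variance denominator always uses all components).

    Attributes
    ----------
    means_, sds_ : Series
        Column standardisation parameters (sd with ddof=1).
    loadings_ : DataFrame, traits x components
        Unit-norm eigenvectors of the correlation matrix, sign-fixed.
    eigenvalues_ : ndarray
        All eigenvalues, descending.
    explained_pct_ : ndarray
        Percent of total variance per retained component.
    sign_flips_ : ndarray
        The +-1 applied to each retained component.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 observations")
        if X.isna().any().any():
            bad = [c for c in X.columns if X[c].isna().any()]
            raise ValueError(f"missing values in columns {bad}")
        sds = X.std(ddof=1)
        zero = [c for c, s in sds.items() if s == 0]
        if zero:
            raise ValueError(f"zero-variance columns: {zero}")

        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.means_ = X.mean()
        self.sds_ = sds
        Z = ((X - self.means_) / self.sds_).to_numpy()
        n = Z.shape[0]

        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        eigvals = s**2 / (n - 1)
        k = min(self.n_components, X.shape[1])
        vecs = vt[:k].T  # traits x k

        flips = np.ones(k)
        for j in range(k):
            i_max = int(np.argmax(np.abs(vecs[:, j])))
            if vecs[i_max, j] < 0:
                vecs[:, j] = -vecs[:, j]
                flips[j] = -1.0

        self.eigenvalues_ = eigvals
        self.explained_pct_ = 100.0 * eigvals[:k] / eigvals.sum()
        self.loadings_ = pd.DataFrame(
            vecs, index=X.columns, columns=[f"PC{j + 1}" for j in range(k)]
        )
        self.sign_flips_ = flips
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project rows onto the retained components (z-row . loadings)."""
        X = pd.DataFrame(X).reindex(columns=self.loadings_.index)
        if X.isna().any().any():
            raise ValueError("cannot project rows with missing traits")
        Z = (X - self.means_) / self.sds_
        scores = Z.to_numpy() @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=X.index,
                            columns=self.loadings_.columns)

    def contributions_(self) -> pd.DataFrame:
        """Per-trait contribution (%) to each retained axis; columns sum to 100."""
        L2 = self.loadings_ ** 2
        return 100.0 * L2 / L2.sum(axis=0)

    def summary(self, X: pd.DataFrame) -> OrdinationSummary:
        return OrdinationSummary(
            loadings=self.loadings_.copy(),
            eigenvalues=self.eigenvalues_.copy(),
            explained_pct=self.explained_pct_.copy(),
            contributions=self.contributions_(),
            scores=self.transform(X),
            means=self.means_.copy(),
            sds=self.sds_.copy(),
            sign_flips=self.sign_flips_.copy(),
        )


def pca(cwm: pd.DataFrame, n_components: int = 2) -> OrdinationSummary:
    """Fit :class:`ScaledPCA` and return its full summary."""
    return ScaledPCA(n_components=n_components).fit(cwm).summary(cwm)


def contributions(result: OrdinationSummary, axis: int) -> pd.Series:
    """Per-trait contribution (%) to one axis (1-based)."""
    cols = result.contributions.columns
    if not 1 <= axis <= len(cols):
        raise ValueError(f"axis must be in 1..{len(cols)}")
    return result.contributions[cols[axis - 1]]


def correlation_matrix(
    cwm: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    p-values use the exact t transform ``t = r sqrt((n-2)/(1-r^2))`` on
    n - 2 degrees of freedom; the diagonal is r = 1, p = 0.
    """
    if len(cwm) < 3:
        raise ValueError("need at least 3 observations")
    sds = cwm.std(ddof=1)
    zero = [c for c, s in sds.items() if s == 0]
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    n = len(cwm)
    r = np.corrcoef(cwm.to_numpy(), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    cols = cwm.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Normalised symmetric Procrustes statistic for centred unit-norm configs."""
    u, s, vt = np.linalg.svd(X.T @ Y)
    rotation = (u @ vt).T  # applied as Y @ rotation -> aligned with X
    scale = float(s.sum())
    m2 = 1.0 - scale**2
    return max(m2, 0.0), rotation, scale


def _centre_norm(A: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(A)
    if norm == 0:
        raise ValueError("degenerate configuration (zero norm)")
    return A / norm


def procrustes_compare(
    loadings_a: pd.DataFrame | np.ndarray,
    loadings_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    scaling: bool = True,
) -> ProcrustesResult:
    """Symmetric Procrustes test between two loading configurations.

    Rows are traits (must match in count and order), columns the first two
    (or more) axes.  Both configurations are centred and scaled to unit
    Frobenius norm; ``m2 = 1 - (trace Sigma)^2`` where Sigma are the
    singular values of ``X'Y``.  Significance is assessed by permuting the
    rows of the second configuration ``n_perm`` times;
    ``p = (1 + #{m2_perm <= m2_obs}) / (n_perm + 1)``.
    """
    A = np.asarray(loadings_a, dtype=float)
    B = np.asarray(loadings_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape != B.shape:
        raise ValueError(f"configuration shapes differ: {A.shape} vs {B.shape}")

    X = _centre_norm(A)
    Y = _centre_norm(B)
    m2, rotation, scale = _procrustes_m2(X, Y)
    if not scaling:
        # unscaled residual: ||X - Y R||^2 = 2 (1 - trace Sigma)
        m2 = max(2.0 * (1.0 - scale), 0.0)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp = _centre_norm(Y[rng.permutation(Y.shape[0])])
        m2p, _, sp = _procrustes_m2(X, Yp)
        if not scaling:
            m2p = max(2.0 * (1.0 - sp), 0.0)
        if m2p <= m2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ProcrustesResult(
        m2=float(m2), rotation=rotation, scale=scale,
        p_value=float(p), n_permutations=n_perm, scaling=scaling,
    )
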