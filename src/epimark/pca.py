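"""PCA with per-variable contributions, sized for p >> n methylation data.

The decomposition runs through the singular value decomposition of the
column-centered samples x probes matrix, so memory stays linear in the
number of probes (the p x p covariance matrix is never materialized).
Variable contributions follow the standard definition used in
factor-analysis software: 100 * loading^2 for unit-norm loading columns,
summing to 100 within each component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ContributionPCA", "pca_fit", "variable_contributions"]


class ContributionPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis with variable contributions.

    Parameters
    ----------
    n_components : int or None
        Number of components kept; defaults to min(n_samples - 1, n_vars).
    center : bool
        Column-center the data (default True).
    scale : bool
        Scale columns to unit variance (default False, matching the
        covariance-based convention of classical PCA).

    Attributes
    ----------
    eigenvalues_ : (k,) eigenvalues of the sample covariance, non-increasing.
    explained_fraction_ : (k,) eigenvalue / total variance.
    loadings_ : DataFrame, variables x components, unit-norm columns.
    scores_ : DataFrame, samples x components (centered data @ loadings).
    contributions_ : DataFrame, variables x components, percentages that
        sum to 100 per component.
    """

    def __init__(self, n_components: int | None = None, center: bool = True,
                 scale: bool = False):
        self.n_components = n_components
        self.center = center
        self.scale = scale

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        n, p = X.shape
        if n < 3:
            raise ValueError("PCA requires at least 3 samples")
        if p < 2:
            raise ValueError("PCA requires at least 2 variables")
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0) if self.center else np.zeros(p)
        centered = values - self.mean_
        if self.scale:
            sd = centered.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("cannot scale: constant variable present")
            centered = centered / sd
            self.scale_ = sd
        else:
            self.scale_ = np.ones(p)
        total_var = float((centered ** 2).sum() / (n - 1))
        if total_var <= 1e-300:
            raise ValueError("degenerate input: matrix has no variance")

        # economy SVD of the n x p matrix: memory O(n*p), never p x p
        u, s, vt = linalg.svd(centered, full_matrices=False)
        k_max = min(n - 1, p)
        k = k_max if self.n_components is None else min(self.n_components, k_max)
        u, s, vt = u[:, :k], s[:k], vt[:k]

        self.eigenvalues_ = s ** 2 / (n - 1)
        self.explained_fraction_ = self.eigenvalues_ / total_var
        comps = [f"PC{i + 1}" for i in range(k)]
        self.loadings_ = pd.DataFrame(vt.T, index=X.columns, columns=comps)
        self.scores_ = pd.DataFrame(u * s, index=X.index, columns=comps)
        self.contributions_ = pd.DataFrame(
            100.0 * vt.T ** 2 / (vt ** 2).sum(axis=1),
            index=X.columns, columns=comps)
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        centered = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(centered @ self.loadings_.to_numpy(),
                            index=X.index, columns=self.loadings_.columns)


def pca_fit(m: pd.DataFrame, center: bool = True, scale: bool = False,
            n_components: int | None = None) -> ContributionPCA:
    """Fit PCA on a probes x samples M-value matrix.

    Samples are the observations and probes the variables, so the matrix
    is transposed internally to the sklearn orientation.
    """
    return ContributionPCA(n_components=n_components, center=center,
                           scale=scale).fit(m.T)


def variable_contributions(p: ContributionPCA) -> pd.DataFrame:
    """Per-variable contribution percentages (variables x components)."""
    if not hasattr(p, "contributions_"):
        raise ValueError("PCA is not fitted")
    return p.contributions_
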