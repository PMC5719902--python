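"""SVD-based principal component analysis in feature-by-sample orientation.

The feature matrix F is N x p (N features, p samples).  Rows are centered
(and by default standardized — the descriptors mix counts, cm, cm^3 and
degrees, so unscaled PCA would be dominated by whichever unit has the
largest variance).  The reduced SVD of the centered matrix, F~ = U S V^T,
yields the k-dimensional feature basis U; per-component variance fractions
are S_i^2 / sum S^2, which makes them independent of the covariance
normalizer.  Projected coordinates are D = U^T F~.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PCABasis", "center_and_scale", "fit_pca", "project", "loadings_report"]


@dataclass
class PCABasis:
    U: np.ndarray  # N x k orthonormal feature basis
    singular_values: np.ndarray  # (k,)
    variance_fraction: np.ndarray  # (k,), non-increasing, sums to <= 1
    k: int
    feature_means: np.ndarray  # (N,)
    feature_sds: Optional[np.ndarray]  # (N,) when standardized, else None
    feature_names: Optional[List[str]] = None


def center_and_scale(
    F: Union[np.ndarray, pd.DataFrame], standardize: bool = True
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray], List[int]]:
    """Center every feature row at 0 (and scale to unit SD if requested).

    Returns ``(F_tilde, means, sds, kept_rows)``.  Zero-variance rows are
    dropped under standardization (they carry no information and would
    divide by zero); their indices are excluded from ``kept_rows``.
    """
    names = list(F.index) if isinstance(F, pd.DataFrame) else None
    F = np.asarray(F, dtype=float)
    if np.isnan(F).any():
        raise ValueError("feature matrix contains missing values")
    means = F.mean(axis=1)
    Ft = F - means[:, None]
    sds = None
    kept = list(range(F.shape[0]))
    if standardize:
        sds = Ft.std(axis=1, ddof=0)
        zero = sds == 0
        if zero.any():
            dropped = [names[i] if names else i for i in np.where(zero)[0]]
            logger.warning("center_and_scale: dropped zero-variance rows %s", dropped)
            kept = [i for i in range(F.shape[0]) if not zero[i]]
            Ft = Ft[kept]
            means = means[kept]
            sds = sds[kept]
        Ft = Ft / sds[:, None]
    return Ft, means, sds, kept


def fit_pca(
    F_tilde: np.ndarray,
    k: Optional[int] = None,
    feature_means: Optional[np.ndarray] = None,
    feature_sds: Optional[np.ndarray] = None,
    feature_names: Optional[Sequence[str]] = None,
    min_variance: Optional[float] = None,
) -> PCABasis:
    """Reduced SVD of a centered feature-by-sample matrix.

    ``k`` defaults to 5; alternatively ``min_variance`` (e.g. 0.88) picks
    the smallest k whose cumulative variance fraction reaches it.  k is
    truncated to the matrix rank with a warning.  Eigenvector signs follow
    a deterministic convention: the largest-|loading| entry of each
    component is positive.
    """
    F_tilde = np.asarray(F_tilde, dtype=float)
    U, S, Vt = np.linalg.svd(F_tilde, full_matrices=False)
    tol = S.max() * max(F_tilde.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    frac_all = S**2 / (S**2).sum() if S.size else S

    if min_variance is not None:
        k = int(np.searchsorted(np.cumsum(frac_all), min_variance) + 1)
    if k is None:
        k = 5
    if k > rank:
        logger.warning("fit_pca: k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    U, S = U[:, :k], S[:k]
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    n_feat = F_tilde.shape[0]
    return PCABasis(
        U=U,
        singular_values=S,
        variance_fraction=frac_all[:k],
        k=k,
        feature_means=(
            np.asarray(feature_means) if feature_means is not None else np.zeros(n_feat)
        ),
        feature_sds=np.asarray(feature_sds) if feature_sds is not None else None,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def project(basis: PCABasis, X: np.ndarray, raw: bool = False) -> np.ndarray:
    """Coordinates D = U^T X~ in the k-dimensional basis.

    ``X`` is feature-by-sample (a single feature vector is accepted as 1-D).
    With ``raw=True`` the stored means/SDs are applied first, so new samples
    can be projected on the training scale.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[:, None]
    if X.shape[0] != basis.U.shape[0]:
        raise ValueError(
            f"dimension mismatch: {X.shape[0]} features, basis has {basis.U.shape[0]}"
        )
    if raw:
        X = X - basis.feature_means[:, None]
        if basis.feature_sds is not None:
            X = X / basis.feature_sds[:, None]
    D = basis.U.T @ X
    return D[:, 0] if single else D


def loadings_report(
    basis: PCABasis, feature_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Feature-by-PC loadings table with per-component variance percentages.

    Mirrors the published layout: one row per feature, columns labelled
    ``PC1 (xx.xx%)`` etc.
    """
    names = feature_names or basis.feature_names
    if names is None:
        names = [f"f{i+1}" for i in range(basis.U.shape[0])]
    cols = [
        f"PC{j+1} ({100.0 * basis.variance_fraction[j]:.2f}%)" for j in range(basis.k)
    ]
    return pd.DataFrame(basis.U, index=list(names), columns=cols)
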