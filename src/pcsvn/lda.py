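"""Fisher linear discriminant with a midpoint threshold and k-fold CV.

The discriminant direction maximizes the Rayleigh quotient
J(w) = (w^T S_B w) / (w^T S_W w) with between-class scatter
S_B = (m2 - m1)(m2 - m1)^T and pooled within-class scatter S_W; the
optimum is the leading eigenvector of the generalized problem
S_B w = lambda S_W w, equal (up to scale) to S_W^{-1} (m2 - m1) whenever
S_W is nonsingular.  After orienting w so class-1 (low-risk) projections
lie left of class-2 (high-risk), the decision threshold is the midpoint of
the innermost projected extremes,

    alpha = ( min w^T D2 + max w^T D1 ) / 2,

and a sample p is labeled low-risk iff w^T p <= alpha (ties inclusive).
The midpoint rule is the default for single-sample scoring; the
cross-validated error statistics default to shared-covariance Gaussian
discriminant scores under the empirical class priors, the protocol the
study describes for its CV (the midpoint rule, built from two extreme
order statistics, is erratic when the projected classes overlap).

Data matrices are k x n (samples in columns), matching the projected
coordinates D = U^T F~ produced by the PCA stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "LDAModel",
    "CVReport",
    "fit_lda",
    "threshold",
    "classify",
    "cross_validate",
    "class_priors",
]

LOW, HIGH = "low_risk", "high_risk"

#: Ridge factor for singular within-class scatter (eps * trace(S_W)/k on the diagonal).
RIDGE_EPS = 1e-8


@dataclass
class LDAModel:
    w_opt: np.ndarray  # unit vector
    alpha: float
    m1: np.ndarray  # low-risk class mean
    m2: np.ndarray  # high-risk class mean
    S_W: np.ndarray
    S_B: np.ndarray
    n_per_class: Tuple[int, int] = (0, 0)
    priors: Optional[Tuple[float, float]] = None  # (low, high) for Gaussian mode

    @property
    def k(self) -> int:
        return len(self.w_opt)


@dataclass
class CVReport:
    fold_fp: List[float]
    fold_fn: List[float]
    fold_error: List[float]
    fp_rate: float  # mean fraction of a test fold that is low-risk called high
    fn_rate: float  # mean fraction that is high-risk called low
    overall_error: float
    fold_assignment: np.ndarray
    seed: Optional[int]
    stratified: bool
    rule: str = "gaussian"


def _as_columns(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[None, :]  # 1-D data: one feature, n samples
    return D


def fit_lda(D1, D2, ridge: float = RIDGE_EPS) -> LDAModel:
    """Fit the Fisher direction from low-risk (D1) and high-risk (D2) points.

    Each D_i is k x n_i (a 1-D array is one-dimensional data).  Raises for
    degenerate classes (equal means); a singular S_W gets a logged ridge.
    """
    D1, D2 = _as_columns(D1), _as_columns(D2)
    if D1.shape[1] < 2 or D2.shape[1] < 2:
        raise ValueError("each class needs at least 2 points")
    if D1.shape[0] != D2.shape[0]:
        raise ValueError("class dimensions differ")
    k = D1.shape[0]
    m1, m2 = D1.mean(axis=1), D2.mean(axis=1)
    diff = m2 - m1
    scale = max(np.linalg.norm(m1), np.linalg.norm(m2), 1.0)
    if np.linalg.norm(diff) < 1e-12 * scale:
        raise ValueError("degenerate classes: identical class means (S_B = 0)")
    S_B = np.outer(diff, diff)
    X1, X2 = D1 - m1[:, None], D2 - m2[:, None]
    S_W = X1 @ X1.T + X2 @ X2.T

    Sw = S_W.copy()
    try:
        cond_bad = np.linalg.cond(Sw) > 1e12
    except np.linalg.LinAlgError:  # pragma: no cover
        cond_bad = True
    if cond_bad:
        lam = ridge * np.trace(Sw) / k if np.trace(Sw) > 0 else ridge
        Sw = Sw + lam * np.eye(k)
        logger.warning("fit_lda: singular within-class scatter, ridge %.3e added", lam)

    # leading eigenvector of S_B w = lambda S_W w
    evals, evecs = linalg.eigh(S_B, Sw)
    w = evecs[:, int(np.argmax(evals))]
    w = w / np.linalg.norm(w)
    if w @ m1 > w @ m2:  # orient: low-risk projects left
        w = -w
    model = LDAModel(
        w_opt=w,
        alpha=np.nan,
        m1=m1,
        m2=m2,
        S_W=S_W,
        S_B=S_B,
        n_per_class=(D1.shape[1], D2.shape[1]),
    )
    model.alpha = threshold(model, D1, D2)
    return model


def threshold(model: LDAModel, D1, D2) -> float:
    """Midpoint of the innermost projected extremes of the two classes."""
    D1, D2 = _as_columns(D1), _as_columns(D2)
    p1 = model.w_opt @ D1
    p2 = model.w_opt @ D2
    return float(0.5 * (p2.min() + p1.max()))


def classify(model: LDAModel, p) -> str:
    """Label one k-vector: low-risk iff w^T p <= alpha."""
    p = np.asarray(p, dtype=float).ravel()
    if len(p) != model.k:
        raise ValueError(f"dimension mismatch: point has {len(p)}, model has {model.k}")
    if model.priors is not None:
        return _classify_gaussian(model, p)
    return LOW if float(model.w_opt @ p) <= model.alpha else HIGH


def classify_many(model: LDAModel, D, rule: str = "midpoint") -> np.ndarray:
    D = _as_columns(D)
    if rule == "gaussian":
        s1, s2 = _gaussian_scores(model, D)
        return np.where(s1 >= s2, LOW, HIGH)
    proj = model.w_opt @ D
    return np.where(proj <= model.alpha, LOW, HIGH)


def _gaussian_scores(model: LDAModel, D: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linear discriminant scores under a shared covariance and class priors."""
    dof = max(sum(model.n_per_class) - 2, 1)
    cov = model.S_W / dof
    prec = np.linalg.pinv(cov + 1e-12 * np.eye(model.k))
    n1, n2 = model.n_per_class
    pi1, pi2 = model.priors if model.priors is not None else (
        n1 / max(n1 + n2, 1),
        n2 / max(n1 + n2, 1),
    )
    s1 = (prec @ model.m1) @ D - 0.5 * model.m1 @ prec @ model.m1 + np.log(pi1)
    s2 = (prec @ model.m2) @ D - 0.5 * model.m2 @ prec @ model.m2 + np.log(pi2)
    return s1, s2


def _classify_gaussian(model: LDAModel, p: np.ndarray) -> str:
    s1, s2 = _gaussian_scores(model, p[:, None])
    return LOW if s1[0] >= s2[0] else HIGH


def class_priors(labels: Sequence) -> Dict[str, float]:
    """Empirical class proportions, in percent."""
    labels = np.asarray(labels)
    n = len(labels)
    return {
        str(c): 100.0 * float((labels == c).sum()) / n for c in np.unique(labels)
    }


def cross_validate(
    D,
    labels: Sequence,
    folds: int = 10,
    stratified: bool = False,
    seed: Optional[int] = None,
    rule: str = "gaussian",
) -> CVReport:
    """k-fold cross-validated error statistics for the discriminant.

    ``D`` is k x n projected coordinates.  Folds are near-equal random
    splits (class proportions preserved per fold when ``stratified``).  A
    false positive is a low-risk sample called high-risk; rates are
    fractions of the test fold, so fp + fn = overall error.  If a training
    split misses a class the folds are reshuffled once, then it is an error.

    ``rule`` selects the test-time decision: ``"gaussian"`` (default)
    scores with the shared-covariance discriminant under the empirical
    class priors — the protocol that produced the study's error statistics
    — while ``"midpoint"`` applies the prior-free innermost-extremes
    threshold, which is noisy whenever the projected classes overlap.
    """
    D = _as_columns(D)
    labels = np.asarray(labels)
    n = D.shape[1]
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")

    for attempt in range(2):
        rs = (seed + attempt) if seed is not None else None
        splitter = (
            StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            if stratified
            else KFold(n_splits=folds, shuffle=True, random_state=rs)
        )
        split_iter = list(splitter.split(D.T, labels))
        ok = all(len(np.unique(labels[tr])) == 2 for tr, _ in split_iter)
        if ok:
            break
    else:
        raise ValueError("a training split is missing a class even after reshuffling")

    assignment = np.empty(n, dtype=int)
    fp_rates, fn_rates, errs = [], [], []
    for f, (train, test) in enumerate(split_iter):
        assignment[test] = f
        Dtr, ytr = D[:, train], labels[train]
        model = fit_lda(Dtr[:, ytr == LOW], Dtr[:, ytr == HIGH])
        pred = classify_many(model, D[:, test], rule=rule)
        ytest = labels[test]
        m = len(test)
        fp = float(np.sum((ytest == LOW) & (pred == HIGH))) / m
        fn = float(np.sum((ytest == HIGH) & (pred == LOW))) / m
        fp_rates.append(fp)
        fn_rates.append(fn)
        errs.append(fp + fn)
    return CVReport(
        fold_fp=fp_rates,
        fold_fn=fn_rates,
        fold_error=errs,
        fp_rate=float(np.mean(fp_rates)),
        fn_rate=float(np.mean(fn_rates)),
        overall_error=float(np.mean(errs)),
        fold_assignment=assignment,
        seed=seed,
        stratified=stratified,
        rule=rule,
    )
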