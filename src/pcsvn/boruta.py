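"""All-relevant feature selection with shadow attributes (Boruta).

Each attribute gets a "shadow": a row-permuted copy that preserves the
marginal distribution but destroys any association with the class label.
A random forest is fit on the still-active attributes plus shadows; an
attribute scores a *hit* in a run when its importance z-score exceeds the
maximum z-score among all shadow attributes (MZSA).  Across runs, hit
counts are compared to the 50% coin-flip rate by a two-sided exact
binomial test (Bonferroni corrected over all attributes): significantly
above confirms the attribute, significantly below rejects it — rejected
attributes then leave the forest — and anything still undecided at the
run cap stays Tentative.  The final ranking orders attributes by their
median z-score over the runs in which they participated.

Importance here is out-of-bag permutation importance: for every tree, the
drop in OOB accuracy when one column is permuted, and z = mean / SD of
that drop across trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

__all__ = ["BorutaConfig", "BorutaResult", "shadow_augment", "importance_z", "run_boruta"]

#: Minimum completed runs before any Confirmed/Rejected decision.
MIN_RUNS_FOR_DECISION = 5


@dataclass
class BorutaConfig:
    """Knobs of the selection loop and the forest underneath it.

    ``alpha`` follows the reference implementation's 0.01 default; the
    Bonferroni correction spans all attributes.  Rejected attributes are
    dropped from subsequent forests, which concentrates the importance
    signal on the remaining candidates.
    """

    max_runs: int = 500
    alpha: float = 0.01
    correction: str = "bonferroni"  # or "none"
    n_trees: int = 500
    max_features: str = "sqrt"  # candidate features per split
    max_depth: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class BorutaResult:
    decision: Dict[str, str]  # attribute -> Confirmed | Rejected | Tentative
    z_history: pd.DataFrame  # runs x attributes
    mzsa_history: List[float]
    ranking: List[str]  # attributes ordered by decreasing median z
    hits: Dict[str, int]
    n_runs: int

    @property
    def confirmed(self) -> List[str]:
        return [a for a in self.ranking if self.decision[a] == "Confirmed"]

    @property
    def rejected(self) -> List[str]:
        return [a for a in self.ranking if self.decision[a] == "Rejected"]

    @property
    def tentative(self) -> List[str]:
        return [a for a in self.ranking if self.decision[a] == "Tentative"]

    def summary(self) -> pd.DataFrame:
        med = self.z_history.median(axis=0)
        return pd.DataFrame(
            {
                "median_z": med[self.ranking],
                "hits": pd.Series(self.hits)[self.ranking],
                "n_runs": self.n_runs,
                "decision": pd.Series(self.decision)[self.ranking],
            }
        )


def shadow_augment(
    table: pd.DataFrame, rng: np.random.Generator, label_col: Optional[str] = None
) -> pd.DataFrame:
    """Append one shadow (independent row permutation) per attribute.

    Shadow columns are named ``shadow_<attr>``; a label column, when named,
    is carried through untouched.
    """
    attrs = [c for c in table.columns if c != label_col]
    if not attrs:
        raise ValueError("table has no attributes to shadow")
    out = table.copy()
    for c in attrs:
        out[f"shadow_{c}"] = rng.permutation(table[c].to_numpy())
    return out


def _oob_masks(forest: RandomForestClassifier, n: int) -> List[np.ndarray]:
    masks = []
    for sample_idx in forest.estimators_samples_:
        m = np.ones(n, dtype=bool)
        m[sample_idx] = False
        masks.append(m)
    return masks


def importance_z(
    X: np.ndarray,
    y_enc: np.ndarray,
    config: BorutaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-attribute z-score of OOB permutation importance.

    z_j = mean_i(drop_ij) / sd_i(drop_ij) over trees i, where drop is the
    OOB-accuracy decrease after permuting column j.  Deterministic given the
    generator state.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    classes = np.unique(y_enc)
    if len(classes) < 2:
        raise ValueError("importance requires at least two classes")
    n, k = X.shape
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        max_depth=config.max_depth,
        bootstrap=True,
        n_jobs=1,
        random_state=int(rng.integers(2**31 - 1)),
    )
    forest.fit(X, y_enc)

    drops = np.zeros((config.n_trees, k))
    for i, (est, oob) in enumerate(zip(forest.estimators_, _oob_masks(forest, n))):
        if not oob.any():
            continue
        Xo = X[oob]
        yo = y_enc[oob]
        tree = est.tree_
        base_pred = np.argmax(tree.predict(Xo), axis=-1).ravel()
        base_acc = float(np.mean(base_pred == yo))
        perm = rng.permutation(len(yo))
        Xp = Xo.copy()
        for j in range(k):
            saved = Xp[:, j].copy()
            Xp[:, j] = Xo[perm, j]
            pred = np.argmax(tree.predict(Xp), axis=-1).ravel()
            drops[i, j] = base_acc - float(np.mean(pred == yo))
            Xp[:, j] = saved
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0, ddof=1)
    z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def run_boruta(
    table: pd.DataFrame,
    labels: Optional[Sequence] = None,
    config: Optional[BorutaConfig] = None,
    label_col: str = "cohort",
) -> BorutaResult:
    """Run the full shadow-attribute selection loop.

    ``table`` may carry its labels in ``label_col`` or they may be passed
    separately.  Rows with missing values are dropped (the package's
    sentinel policy for undefined features).
    """
    config = config or BorutaConfig()
    if labels is None:
        if label_col not in table.columns:
            raise ValueError(f"no labels: column {label_col!r} absent and none passed")
        labels = table[label_col]
        table = table.drop(columns=[label_col])
    labels = np.asarray(labels)
    keep = ~table.isna().any(axis=1).to_numpy()
    table = table.loc[keep]
    labels = labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")

    attrs = list(table.columns)
    k = len(attrs)
    rng = np.random.default_rng(config.seed)
    _, y_enc = np.unique(labels, return_inverse=True)
    Xorig = table.to_numpy(dtype=float)

    decision = {a: "Tentative" for a in attrs}
    hits = {a: 0 for a in attrs}
    runs_counted = {a: 0 for a in attrs}
    z_rows = []
    mzsa_hist: List[float] = []
    bonf = k if config.correction == "bonferroni" else 1

    n_runs = 0
    for _run in range(config.max_runs):
        undecided = [a for a in attrs if decision[a] == "Tentative"]
        if not undecided:
            break
        # rejected attributes leave the forest; confirmed ones stay (they
        # shape the trees) but are no longer tested.  Shadows are always
        # permuted copies of ALL original attributes: the MZSA yardstick
        # must keep its max-over-k multiplicity, otherwise a surviving
        # chance-correlated attribute faces an ever weaker null reference.
        active = [a for a in attrs if decision[a] != "Rejected"]
        if not active:
            break
        act_idx = [attrs.index(a) for a in active]
        Xact = Xorig[:, act_idx]
        shadows = np.column_stack([rng.permutation(Xorig[:, j]) for j in range(k)])
        X = np.hstack([Xact, shadows])
        z = importance_z(X, y_enc, config, rng)
        z_real, z_shadow = z[: len(active)], z[len(active) :]
        mzsa = float(z_shadow.max())
        mzsa_hist.append(mzsa)
        row = np.full(k, np.nan)
        row[act_idx] = z_real
        z_rows.append(row)
        n_runs += 1
        for pos, a in enumerate(active):
            if decision[a] != "Tentative":
                continue
            runs_counted[a] += 1
            if z_real[pos] > mzsa:
                hits[a] += 1
        if n_runs >= MIN_RUNS_FOR_DECISION:
            for a in active:
                if decision[a] != "Tentative":
                    continue
                res = binomtest(hits[a], runs_counted[a], 0.5, alternative="two-sided")
                if res.pvalue * bonf < config.alpha:
                    decision[a] = (
                        "Confirmed" if hits[a] / runs_counted[a] > 0.5 else "Rejected"
                    )

    z_history = pd.DataFrame(z_rows, columns=attrs)
    if n_runs < MIN_RUNS_FOR_DECISION:
        decision = {a: "Tentative" for a in attrs}
    med = z_history.median(axis=0)
    ranking = list(med.sort_values(ascending=False).index)
    return BorutaResult(
        decision=decision,
        z_history=z_history,
        mzsa_history=mzsa_hist,
        ranking=ranking,
        hits=hits,
        n_runs=n_runs,
    )
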