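"""End-to-end orchestration: preprocess -> feature-select -> classify.

``run_all`` drives the three-stage flow over a manifest of traced-placenta
rasters: feature extraction per placenta, Boruta selection on the feature
table, PCA reduction of the confirmed attributes, and Fisher-LDA with
plain and stratified 10-fold cross-validation.  One global seed fans out
to per-stage seeds through ``numpy.random.SeedSequence`` so a single
integer reproduces a whole run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .boruta import BorutaConfig, run_boruta
from .features import ARTERIAL_FEATURES, extract_all
from .lda import class_priors, cross_validate
from .pca import center_and_scale, fit_pca, loadings_report, project
from .skeleton import DEFAULT_SPUR_PX, VesselMask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "select_reduce_classify"]


@dataclass
class PipelineConfig:
    """Serializable configuration of the whole pipeline."""

    scale_px_per_cm: float = 35.0
    canvas: Tuple[int, int] = (1380, 1440)
    spur_px: float = DEFAULT_SPUR_PX
    standardize: bool = True
    n_components: int = 5
    boruta_max_runs: int = 500
    boruta_alpha: float = 0.01
    boruta_trees: int = 500
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0
    arterial_only: bool = False  # restrict selection to the 28 arterial attributes
    drop_missing: bool = True  # sentinel policy: drop placentas with undefined features

    def __post_init__(self) -> None:
        for name in ("scale_px_per_cm", "n_components", "boruta_max_runs", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        return cls(**d)


def _stage_seeds(seed: int, n: int = 4) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def extract_manifest(manifest: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Feature table for every placenta listed in a manifest.

    The manifest needs columns ``id``, ``label``, ``vessel_path`` and
    optionally ``disc_path``, ``cord_row``, ``cord_col``.
    """
    rows = []
    for _, rec in manifest.iterrows():
        try:
            vessel = pio.read_mask_png(rec["vessel_path"])
        except Exception as exc:
            raise RuntimeError(f"extract: unreadable image for id {rec['id']!r}: {exc}")
        disc = (
            pio.read_mask_png(rec["disc_path"])
            if "disc_path" in rec and isinstance(rec["disc_path"], str)
            else None
        )
        cord = (
            (int(rec["cord_row"]), int(rec["cord_col"]))
            if "cord_row" in rec
            else (vessel.shape[0] // 2, vessel.shape[1] // 2)
        )
        mask = VesselMask(
            grid=vessel,
            scale_px_per_cm=config.scale_px_per_cm,
            cord_xy=cord,
            boundary=disc,
        )
        fv = extract_all(mask, spur_px=config.spur_px)
        row = {"id": rec["id"], "cohort": rec["label"], **fv.values}
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_feature_table(
    n_earli: int,
    n_ncs: int,
    seed: int,
    scale: float = 35.0,
    canvas: Tuple[int, int] = (1380, 1440),
    keep_truth: bool = False,
) -> pd.DataFrame:
    """Simulate both cohorts and extract features, one placenta at a time.

    Rasters are discarded after extraction, so memory stays flat.  With
    ``keep_truth`` the planted descriptor values are attached under
    ``df.attrs['truth']`` (a list of dicts, same row order).
    """
    from .synthetic import cohort_tree_spec, rasterize, sample_tree

    rows = []
    truths = []
    rng = np.random.default_rng(seed)
    for cohort, label, n in (("earli", "high_risk", n_earli), ("ncs", "low_risk", n_ncs)):
        for i in range(n):
            for _retry in range(6):
                spec = cohort_tree_spec(cohort, rng)
                try:
                    truth = sample_tree(spec, rng)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError(f"failed to grow a {cohort} tree after 6 attempts")
            vessel, disc, cord = rasterize(truth, canvas=canvas, scale=scale)
            mask = VesselMask(
                grid=vessel, scale_px_per_cm=scale, cord_xy=cord, boundary=disc
            )
            fv = extract_all(mask)
            rows.append({"id": f"{cohort}_{i:04d}", "cohort": label, **fv.values})
            if keep_truth:
                truths.append(dict(truth.true_feature_values))
    df = pd.DataFrame(rows)
    if keep_truth:
        df.attrs["truth"] = truths
    return df


def select_reduce_classify(
    table: pd.DataFrame, config: PipelineConfig, label_col: str = "cohort"
) -> Dict:
    """Boruta -> PCA -> LDA on an extracted feature table.

    Returns a dict with the Boruta result, the PCA basis and loadings
    report, projected coordinates, and plain + stratified CV reports.
    """
    seeds = _stage_seeds(config.seed)
    feats = table.drop(columns=[c for c in ("id",) if c in table.columns])
    if config.arterial_only:
        keep = [c for c in feats.columns if c in ARTERIAL_FEATURES or c == label_col]
        feats = feats[keep]
    if config.drop_missing:
        n0 = len(feats)
        feats = feats.dropna()
        if len(feats) < n0:
            logger.info("dropped %d placenta(s) with undefined features", n0 - len(feats))

    bcfg = BorutaConfig(
        max_runs=config.boruta_max_runs,
        alpha=config.boruta_alpha,
        n_trees=config.boruta_trees,
        seed=seeds[0],
    )
    bres = run_boruta(feats, config=bcfg, label_col=label_col)
    confirmed = bres.confirmed
    if not confirmed:
        # tiny or uninformative runs may confirm nothing; fall back to the
        # undecided attributes rather than abort with no model at all
        logger.warning(
            "selection confirmed no attributes; falling back to %d tentative ones",
            len(bres.tentative),
        )
        confirmed = bres.tentative
    if not confirmed:
        # everything rejected (tiny n): keep the top-ranked attributes so the
        # downstream stages still produce a (clearly flagged) model
        confirmed = bres.ranking[: min(5, len(bres.ranking))]
        logger.warning("selection rejected everything; using top-%d by median z", len(confirmed))
    if not confirmed:
        raise RuntimeError("selection stage confirmed no attributes")

    labels = feats[label_col].to_numpy()
    F = feats[confirmed].to_numpy().T  # features x samples
    Ft, means, sds, kept = center_and_scale(F, standardize=config.standardize)
    names = [confirmed[i] for i in kept]
    basis = fit_pca(
        Ft,
        k=min(config.n_components, Ft.shape[0]),
        feature_means=means,
        feature_sds=sds,
        feature_names=names,
    )
    D = project(basis, Ft)

    cv_plain = cross_validate(D, labels, folds=config.cv_folds, stratified=False, seed=seeds[1])
    cv_strat = cross_validate(D, labels, folds=config.cv_folds, stratified=True, seed=seeds[2])
    return {
        "boruta": bres,
        "confirmed": confirmed,
        "basis": basis,
        "loadings": loadings_report(basis),
        "projection": D,
        "labels": labels,
        "priors_percent": class_priors(labels),
        "cv": cv_plain,
        "cv_stratified": cv_strat,
    }


def run_all(manifest: pd.DataFrame, config: PipelineConfig, out_dir) -> Dict:
    """Execute the full pipeline and write stage outputs under ``out_dir``.

    Emits ``features.csv`` (+ units sidecar), ``boruta.csv``/``boruta.json``,
    ``loadings.csv``, ``projection.csv`` and ``cv_report.json``.  Failures
    halt with a stage-tagged error; outputs written so far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        table = extract_manifest(manifest, config)
    except Exception as exc:
        raise RuntimeError(f"[extract] {exc}") from exc
    pio.write_feature_table(table, out / "features.csv")

    try:
        res = select_reduce_classify(table, config)
    except Exception as exc:
        raise RuntimeError(f"[select/reduce/classify] {exc}") from exc

    bres = res["boruta"]
    bres.summary().to_csv(out / "boruta.csv")
    (out / "boruta.json").write_text(
        json.dumps(
            {
                "decision": bres.decision,
                "ranking": bres.ranking,
                "median_z": bres.z_history.median(axis=0).to_dict(),
                "mzsa_history": bres.mzsa_history,
                "n_runs": bres.n_runs,
            },
            indent=1,
        )
    )
    res["loadings"].to_csv(out / "loadings.csv")
    proj = pd.DataFrame(
        res["projection"].T, columns=[f"PC{i+1}" for i in range(res["basis"].k)]
    )
    proj["cohort"] = res["labels"]
    proj.to_csv(out / "projection.csv", index=False)

    cv, cvs = res["cv"], res["cv_stratified"]
    report = {
        "priors_percent": res["priors_percent"],
        "n": int(len(res["labels"])),
        "confirmed_attributes": res["confirmed"],
        "variance_fraction": [float(v) for v in res["basis"].variance_fraction],
        "cv": {
            "fp_rate": cv.fp_rate,
            "fn_rate": cv.fn_rate,
            "overall_error": cv.overall_error,
            "per_fold_error": cv.fold_error,
        },
        "cv_stratified": {
            "fp_rate": cvs.fp_rate,
            "fn_rate": cvs.fn_rate,
            "overall_error": cvs.overall_error,
            "per_fold_error": cvs.fold_error,
        },
        "config": config.to_dict(),
    }
    (out / "cv_report.json").write_text(json.dumps(report, indent=1))
    return res
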