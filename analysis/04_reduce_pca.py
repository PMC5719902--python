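"""PCA-reduce the selected descriptors and report loadings per component.

Reads the feature table and the selection result, keeps the confirmed
attributes, fits the feature-by-sample SVD, and writes the loadings table
(results/loadings.csv) and projected coordinates (results/projection.csv).

    python analysis/04_reduce_pca.py
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pcsvn.pca import center_and_scale, fit_pca, loadings_report, project  # noqa: E402


def run() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", default="results/features.csv")
    ap.add_argument("--selection", default="results/boruta.csv")
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--out-loadings", default="results/loadings.csv")
    ap.add_argument("--out-projection", default="results/projection.csv")
    args = ap.parse_args()

    df = pd.read_csv(args.table).drop(columns=["id"], errors="ignore").dropna()
    sel = pd.read_csv(args.selection, index_col=0)
    confirmed = list(sel.index[sel.decision == "Confirmed"])
    if not confirmed:
        raise SystemExit("no confirmed attributes; run 03_select_features.py first")

    labels = df["cohort"].to_numpy()
    F = df[confirmed].to_numpy().T
    Ft, means, sds, kept = center_and_scale(F)
    basis = fit_pca(
        Ft, k=args.k, feature_means=means, feature_sds=sds,
        feature_names=[confirmed[i] for i in kept],
    )
    rep = loadings_report(basis)
    Path(args.out_loadings).parent.mkdir(parents=True, exist_ok=True)
    rep.to_csv(args.out_loadings)

    D = project(basis, Ft)
    proj = pd.DataFrame(D.T, columns=[f"PC{i+1}" for i in range(basis.k)])
    proj["cohort"] = labels
    proj.to_csv(args.out_projection, index=False)

    cum = 100 * basis.variance_fraction.cumsum()
    print(f"{len(confirmed)} confirmed attributes, k={basis.k} components")
    print("variance captured per PC (%):", ", ".join(f"{100*v:.2f}" for v in basis.variance_fraction))
    print(f"cumulative: {cum[-1]:.2f}%")
    print(f"loadings -> {args.out_loadings}; projection -> {args.out_projection}")


if __name__ == "__main__":
    run()
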