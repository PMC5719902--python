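"""Fisher-LDA risk classification with plain and stratified 10-fold CV.

Reads the projected coordinates, fits the discriminant, and reports false
positive / false negative / overall error rates under both CV schemes,
writing results/cv_report.json.

    python analysis/05_classify_lda.py --seed 1
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pcsvn.lda import class_priors, cross_validate  # noqa: E402


def run() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--projection", default="results/projection.csv")
    ap.add_argument("--out", default="results/cv_report.json")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    proj = pd.read_csv(args.projection)
    labels = proj.pop("cohort").to_numpy()
    D = proj.to_numpy().T

    priors = class_priors(labels)
    plain = cross_validate(D, labels, folds=10, stratified=False, seed=args.seed)
    strat = cross_validate(D, labels, folds=10, stratified=True, seed=args.seed)

    report = {
        "priors_percent": priors,
        "n": int(len(labels)),
        "cv": {
            "fp_rate_percent": 100 * plain.fp_rate,
            "fn_rate_percent": 100 * plain.fn_rate,
            "overall_error_percent": 100 * plain.overall_error,
        },
        "cv_stratified": {
            "fp_rate_percent": 100 * strat.fp_rate,
            "fn_rate_percent": 100 * strat.fn_rate,
            "overall_error_percent": 100 * strat.overall_error,
        },
    }
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    Path(args.out).write_text(json.dumps(report, indent=1))

    print(f"class priors: {priors}")
    print(
        f"10-fold CV:            fp {100*plain.fp_rate:.2f}%  fn {100*plain.fn_rate:.2f}%"
        f"  overall {100*plain.overall_error:.2f}%"
    )
    print(
        f"stratified 10-fold CV: fp {100*strat.fp_rate:.2f}%  fn {100*strat.fn_rate:.2f}%"
        f"  overall {100*strat.overall_error:.2f}%"
    )
    print(f"report -> {args.out}")


if __name__ == "__main__":
    run()
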