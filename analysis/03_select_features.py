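"""Rank all 36 descriptors by all-relevant (shadow-attribute) selection.

Reads results/features.csv and writes the decision/ranking table to
results/boruta.csv plus a plot-ready JSON of the per-run z-score spreads.

    python analysis/03_select_features.py --table results/features.csv --seed 1
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pcsvn.boruta import BorutaConfig, run_boruta  # noqa: E402


def run() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", default="results/features.csv")
    ap.add_argument("--out", default="results/boruta.csv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--max-runs", type=int, default=500)
    ap.add_argument("--trees", type=int, default=500)
    args = ap.parse_args()

    df = pd.read_csv(args.table).drop(columns=["id"], errors="ignore").dropna()
    cfg = BorutaConfig(max_runs=args.max_runs, n_trees=args.trees, seed=args.seed)
    res = run_boruta(df, config=cfg, label_col="cohort")

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    res.summary().to_csv(args.out)
    Path(args.out).with_suffix(".json").write_text(
        json.dumps(
            {
                "decision": res.decision,
                "ranking": res.ranking,
                "z_quartiles": {
                    c: list(res.z_history[c].quantile([0.25, 0.5, 0.75]))
                    for c in res.z_history.columns
                },
                "n_runs": res.n_runs,
            },
            indent=1,
        )
    )
    print(f"{res.n_runs} runs; confirmed {len(res.confirmed)} attributes:")
    for a in res.confirmed:
        print(f"  {a}")
    print(f"rejected {len(res.rejected)}, tentative {len(res.tentative)} -> {args.out}")


if __name__ == "__main__":
    run()
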