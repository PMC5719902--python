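"""Simulate the two study-sized synthetic cohorts to disk.

Writes vessel/disc PNG masks, ground-truth JSON and a manifest CSV for an
enriched-risk-like cohort (default 89 placentas) and a population-like
cohort (default 201), using the calibrated cohort distributions.

Run from the repository root:

    python analysis/01_simulate_cohorts.py --out results/cohorts --seed 1
"""

import argparse
import sys
from pathlib import Path

from click.testing import CliRunner

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pcsvn.cli import main as cli_main  # noqa: E402


def run() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/cohorts")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-earli", type=int, default=89)
    ap.add_argument("--n-ncs", type=int, default=201)
    args = ap.parse_args()

    runner = CliRunner()
    for cohort, n, seed in (("earli", args.n_earli, args.seed), ("ncs", args.n_ncs, args.seed + 1)):
        res = runner.invoke(
            cli_main,
            ["simulate", "--cohort", cohort, "--n", str(n), "--seed", str(seed), "--out", f"{args.out}/{cohort}"],
            catch_exceptions=False,
        )
        print(res.output.strip())
    print(f"cohorts written under {args.out}/")


if __name__ == "__main__":
    run()
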