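#!/usr/bin/env python
"""Benchmark the pipeline against the planted truth: three-way
differential-splicing classification recovery, DEG recovery at the
stated effect size, and the binomial test's null calibration.
Writes results/recovery.tsv.
"""
import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

import sys

sys.path.insert(0, str(ROOT / "scripts"))
from acceptance import binomial_null_rate, deg_recovery, dse_recovery  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "recovery.tsv")
    args = parser.parse_args()

    rows = []
    for name, (value, n) in dse_recovery(args.seed).items():
        rows.append({"metric": name, "value": round(value, 4), "n": n})
    for name, (value, n) in deg_recovery(args.seed).items():
        rows.append({"metric": name, "value": round(value, 4), "n": n})
    rows.append({"metric": "binomial_test_null_p05_rate_pct",
                 "value": round(binomial_null_rate(args.seed), 2), "n": 2000})

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
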