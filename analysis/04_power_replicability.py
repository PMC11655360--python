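#!/usr/bin/env python
"""Convert the scheme-experiment effect sizes into power, replicability and
required sample sizes.

For every (scheme, n) cell of the experiments in 03: the empirical power
(share of replicates rejecting at 5%) with its Wilson interval, the implied
replicability (power squared), and the sample size needed for 80%
replicability from the mean RESI via the non-central F distribution.
Writes results/power_replicability.csv.
"""

from pathlib import Path

import pandas as pd

from bwasdesign import PowerQuery, n_for_replicability, wilson_interval

ROOT = Path(__file__).resolve().parent.parent / "results"
DF_MODEL = 4  # intercept + 2 spline age columns + sex
B = 300
TARGET_R = 0.8


def main() -> None:
    rows = []
    for fname, label in [
        ("scheme_cross_sectional.csv", "cross-sectional"),
        ("scheme_longitudinal.csv", "longitudinal"),
    ]:
        summary = pd.read_csv(ROOT / fname)
        for _, r in summary.iterrows():
            k = int(round(r["power"] * B))
            lo, hi = wilson_interval(k, B)
            q = PowerQuery(S=max(r["mean_S"], 1e-9), alpha=0.05, df_model=DF_MODEL,
                           m=2)
            rows.append(
                {
                    "experiment": label,
                    "scheme": r["scheme"],
                    "n": int(r["n"]),
                    "mean_S": r["mean_S"],
                    "power": r["power"],
                    "power_wilson_low": lo,
                    "power_wilson_high": hi,
                    "replicability": r["power"] ** 2,
                    "n_for_80pct_replicability": n_for_replicability(q, TARGET_R),
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "power_replicability.csv", index=False)

    print("sample size for 80% replicability by scheme (largest n cell):")
    last = out.loc[out.groupby(["experiment", "scheme"])["n"].idxmax()]
    print(
        last[["experiment", "scheme", "mean_S", "n_for_80pct_replicability"]]
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
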