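#!/usr/bin/env python
"""Targeted-sampling bootstrap experiments on the large synthetic cohorts.

Cross-sectional experiment (UKB-like): bell / uniform / U-shaped target
distributions for age at sample sizes 40-320.  Longitudinal experiment
(ADNI-like): each bootstrap participant keeps a (baseline, follow-up) pair;
the baseline age follows uniform or U-shaped targets while the age change
independently follows decreasing / uniform / increasing targets.

Writes results/scheme_cross_sectional.csv and results/scheme_longitudinal.csv
and prints the effect-size ordering each experiment shows.
"""

from pathlib import Path

from bwasdesign import (
    CohortTable,
    ModelSpec,
    TargetShape,
    cross_sectional_weights,
    longitudinal_combination_weights,
    run_scheme_experiment,
)
from bwasdesign.cohort import CROSS_SECTIONAL, LONGITUDINAL

SEED = 20_240_103
ROOT = Path(__file__).resolve().parent.parent / "results"
B = 300  # bootstrap replicates per (scheme, n) at desk scale


def cross_sectional_experiment() -> None:
    table = CohortTable.from_csv(ROOT.parent / "scratch" / "cohorts" / "ukb_like.csv")
    ages = table.data["age"].to_numpy()
    schemes = {
        fam: cross_sectional_weights(ages, TargetShape(fam), (50.0, 78.0))
        for fam in ("bell", "uniform", "u_shaped")
    }
    spec = ModelSpec.from_formula("y ~ ns(age, df=2) + sex", design=CROSS_SECTIONAL)
    res = run_scheme_experiment(
        table, schemes, [40, 80, 160, 320], spec, "age", B=B, seed=SEED
    )
    res.summary.to_csv(ROOT / "scheme_cross_sectional.csv", index=False)
    print("cross-sectional mean RESI by scheme and n:")
    print(
        res.summary.pivot(index="n", columns="scheme", values="mean_S")
        .round(3)
        .to_string()
    )


def longitudinal_experiment() -> None:
    table = CohortTable.from_csv(ROOT.parent / "scratch" / "cohorts" / "adni_like.csv")
    schemes = {}
    for between in ("uniform", "u_shaped"):
        for within in ("decreasing", "uniform", "increasing"):
            schemes[f"{between}+{within}"] = longitudinal_combination_weights(
                table,
                TargetShape(between),
                TargetShape(within),
                winsor_between=(65.0, 85.0),
                winsor_within=(0.0, 5.0),
            )
    spec = ModelSpec.from_formula("y ~ ns(age, df=2) + sex", design=LONGITUDINAL)
    res = run_scheme_experiment(
        table, schemes, [60, 120, 240], spec, "age", B=B, seed=SEED + 1
    )
    res.summary.to_csv(ROOT / "scheme_longitudinal.csv", index=False)
    print("\nlongitudinal mean RESI by scheme and n:")
    print(
        res.summary.pivot(index="n", columns="scheme", values="mean_S")
        .round(3)
        .to_string()
    )


def main() -> None:
    cross_sectional_experiment()
    longitudinal_experiment()


if __name__ == "__main__":
    main()
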