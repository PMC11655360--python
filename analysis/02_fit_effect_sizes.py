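#!/usr/bin/env python
"""Fit the study-level association models and estimate RESIs with bootstrap CIs.

Reads the cohorts from 01, removes site effects where present, fits the
standard mean model (spline age term + sex, plus the covariate where one was
generated), and writes per-study effect sizes with design features to
results/study_effects.csv — the input for the meta-regression in 06.
"""

from pathlib import Path

import pandas as pd

from bwasdesign import (
    CohortTable,
    ModelSpec,
    bootstrap_resi_ci,
    remove_site_effects,
    summarize_design,
)

SEED = 20_240_102
ROOT = Path(__file__).resolve().parent.parent / "results"
N_BOOT = 200  # percentile CI resolution for desk-scale runs


def main() -> None:
    rows = []
    for k, path in enumerate(sorted((ROOT.parent / "scratch" / "cohorts").glob("study_*.csv"))):
        table = CohortTable.from_csv(path)
        spec = ModelSpec.from_formula("y ~ ns(age, df=2) + sex", design=table.design)
        if table.data["site_id"].nunique() > 1:
            table = remove_site_effects(table, spec)
        summary = summarize_design(table)
        spec = ModelSpec.from_formula("y ~ ns(age, df=2) + sex", design=summary.design)
        for term in ("age", "sex"):
            est = bootstrap_resi_ci(
                table, spec, term, n_boot=N_BOOT, seed=SEED + k
            )
            rows.append(
                {
                    "study_id": summary.study_id,
                    "term": term,
                    "S_hat": est.S_hat,
                    "SE": (est.ci_high - est.ci_low) / (2 * 1.959964),
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "design": summary.design,
                    "mean_age": summary.mean_age,
                    "sd_age": summary.sd_age,
                    "skew_age": summary.skew_age,
                    "prop_male": summary.prop_male,
                    "n_subjects": summary.n_subjects,
                }
            )
        print(f"{summary.study_id}: design={summary.design}, "
              f"S_age={rows[-2]['S_hat']:.3f}, S_sex={rows[-1]['S_hat']:.3f}")

    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "study_effects.csv", index=False)
    by_design = out[out["term"] == "age"].groupby("design")["S_hat"].mean()
    print("\nmean age-effect RESI by design:")
    print(by_design.to_string())


if __name__ == "__main__":
    main()
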