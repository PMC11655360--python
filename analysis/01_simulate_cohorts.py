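#!/usr/bin/env python
"""Generate the synthetic cohorts every later analysis step consumes.

Produces, under scratch/cohorts/ (bulky raw data, regenerable):
  * a UKB-like large cross-sectional cohort (age-outcome association),
  * an ADNI-like three-visit longitudinal cohort,
  * an ABCD-like two-wave cohort with a noisy behavioural covariate whose
    within-subject effect is null,
  * a 60-study collection varying mean age, age SD, skewness and design,
    with additive site effects injected into a third of the studies.
"""

from pathlib import Path

import numpy as np

from bwasdesign import (
    SimConfig,
    SiteConfig,
    inject_site_effects,
    make_study_spec,
    simulate_longitudinal_study,
    simulate_multistudy_collection,
    simulate_two_wave_behavioral,
)

SEED = 20_240_101
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    rng = np.random.default_rng(SEED)

    ukb_like = simulate_longitudinal_study(
        SimConfig(
            n_subjects=8000,
            visits_per_subject=1,
            baseline_age_distribution=("normal", 64.0, 7.5),
            age_effect=(1.2, -0.1, 0.0),
            sex_effect=0.5,
            subject_intercept_sd=0.0,
            residual_sd=8.0,
            seed=SEED,
        )
    )
    ukb_like.to_csv(OUT / "ukb_like.csv")
    print(f"ukb_like: {ukb_like.n_subjects} subjects, design={ukb_like.design}")

    adni_like = simulate_longitudinal_study(
        SimConfig(
            n_subjects=1500,
            visits_per_subject=3,
            baseline_age_distribution=("uniform", 65.0, 85.0),
            visit_gap_distribution=("uniform", 0.5, 3.0),
            age_effect=(1.5, 0.0, 0.0),
            sex_effect=0.5,
            beta_between=0.3,
            beta_within=0.3,
            subject_intercept_sd=2.0,
            covariate_between_sd=1.0,
            covariate_within_sd=0.8,
            missing_rate=0.1,
            seed=SEED + 1,
        )
    )
    adni_like.to_csv(OUT / "adni_like.csv")
    print(
        f"adni_like: {adni_like.n_subjects} subjects, "
        f"{adni_like.n_obs} observations, design={adni_like.design}"
    )

    abcd_like = simulate_two_wave_behavioral(
        SimConfig(
            n_subjects=4000,
            visits_per_subject=2,
            baseline_age_distribution=("uniform", 9.0, 11.0),
            visit_gap_distribution=("constant", 2.0),
            beta_between=0.4,
            beta_within=0.0,
            covariate_between_sd=1.0,
            covariate_within_sd=0.9,
            subject_intercept_sd=1.0,
            seed=SEED + 2,
        ),
        covariate_measurement_noise_sd=0.4,
    )
    abcd_like.to_csv(OUT / "abcd_like.csv")
    print(f"abcd_like: {abcd_like.n_subjects} subjects, two-wave behavioural design")

    # 60-study collection spanning the design features the meta-model uses.
    # The raw age-outcome slope is the same in every study (0.15 units/year),
    # so studies sampling a wider age range see a larger standardized effect
    # — the design property the meta-regression should detect.  age_effect
    # coefficients act on age standardized by each study's own SD, hence the
    # sd_age rescaling.
    specs = []
    for k in range(60):
        sd_age = float(rng.uniform(3, 20))
        specs.append(
            make_study_spec(
                mean_age=float(rng.uniform(15, 70)),
                sd_age=sd_age,
                skew=float(rng.uniform(-0.8, 0.8)),
                n_subjects=int(rng.integers(150, 500)),
                visits=int(rng.choice([1, 1, 2, 3])),
                age_effect=(0.15 * sd_age, 0.0, 0.0),
                sex_effect=0.4,
                subject_intercept_sd=1.5,
                residual_sd=6.0,
                seed=0,
            )
        )
    studies = simulate_multistudy_collection(specs, seed=SEED + 3)
    site_cfg = SiteConfig(n_sites=4, additive_shift_sd=3.0, scale_sd=0.05)
    n_long = 0
    for k, tab in enumerate(studies):
        if k % 3 == 0:
            tab = inject_site_effects(tab, site_cfg, seed=SEED + 100 + k)
        tab.to_csv(OUT / f"study_{k:03d}.csv")
        n_long += tab.design == "longitudinal"
    print(f"collection: 60 studies written, {n_long} longitudinal")


if __name__ == "__main__":
    main()
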