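"""Robust effect size index (RESI) estimation.

The RESI standardizes a robust Wald chi-squared statistic into an effect
size on the scale of Cohen's d/2:

    S_hat = sqrt(max{0, (T^2 - m) / N})

with ``T^2`` the Wald statistic for the tested coefficients, ``m`` the number
of coefficients tested, and ``N`` the number of *subjects* (not
observations — in longitudinal fits repeated visits do not inflate N).
Confidence intervals are non-parametric percentile bootstraps resampling
whole subjects.  The cross-sectional-equivalent RESI (CS-RESI) of a
longitudinal cohort — the effect size the same population would have yielded
under a one-visit-per-subject design — is estimated by averaging the
cross-sectional RESI over repeated random one-visit-per-subject subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable
from .models import FitResult, ModelSpec, fit_study_model, wald_test

__all__ = [
    "EffectSizeEstimate",
    "resi_point",
    "resi_for_terms",
    "bootstrap_resi_ci",
    "d_to_resi",
    "resi_to_d",
    "cs_resi",
    "percentile_bounds",
]

log = logging.getLogger(__name__)


def percentile_bounds(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile-interval bounds as order statistics.

    The lower bound is the ``floor(alpha * n)``-th order statistic (at least
    the first) and the upper the ``ceil((1 - alpha) * n)``-th, with
    ``alpha = (1 - level)/2`` — at ``n = 1000`` and 95% these are the 25th
    and 975th order statistics.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    alpha = (1.0 - level) / 2.0
    k_lo = max(1, int(np.floor(alpha * n)))
    k_hi = min(n, int(np.ceil((1.0 - alpha) * n)))
    return float(v[k_lo - 1]), float(v[k_hi - 1])


@dataclass
class EffectSizeEstimate:
    S_hat: float
    m: int
    n_subjects: int
    T2: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    ci_level: float = np.nan
    n_boot: int = 0
    variant: str = "RESI"
    p: float = np.nan


def resi_point(T2: float, m: int, N: int) -> float:
    """Consistent RESI point estimate ``sqrt(max{0, (T2 - m)/N})``.

    The subtraction of ``m`` removes the mean of the null chi-squared
    distribution; truncation at zero keeps the index non-negative.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    if T2 < 0:
        raise ValueError("T2 must be >= 0")
    return float(np.sqrt(max(0.0, (T2 - m) / N)))


def resi_for_terms(fit: FitResult, terms) -> EffectSizeEstimate:
    """RESI for the named model terms from a fitted association model."""
    w = wald_test(fit, terms)
    return EffectSizeEstimate(
        S_hat=resi_point(w.T2, w.m, fit.n_subjects),
        m=w.m,
        n_subjects=fit.n_subjects,
        T2=w.T2,
        p=w.p,
        variant="RESI",
    )


def d_to_resi(d: float) -> float:
    """Convert Cohen's d to RESI: ``S = d / 2`` under Cohen's assumptions."""
    return float(d) / 2.0


def resi_to_d(S: float) -> float:
    """Convert RESI to Cohen's d: ``d = 2 S``."""
    if S < 0:
        raise ValueError("RESI must be >= 0")
    return 2.0 * float(S)


def _resample_subjects(
    table: CohortTable, rng: np.random.Generator
) -> CohortTable:
    """Subject-level bootstrap: whole subjects, all their visits."""
    d = table.data.reset_index(drop=True)
    codes, _ = pd.factorize(d["subject_id"])
    n_subj = codes.max() + 1
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(n_subj))
    stops = np.append(starts[1:], len(codes))
    picks = rng.integers(0, n_subj, n_subj)
    rows = np.concatenate([order[starts[s]:stops[s]] for s in picks])
    sizes = stops[picks] - starts[picks]
    data = d.iloc[rows].copy()
    data["subject_id"] = np.repeat(np.arange(n_subj), sizes)
    return CohortTable(
        data,
        design=table.design,
        covariates=list(table.covariates),
        outcomes=list(table.outcomes),
    )


def bootstrap_resi_ci(
    table: CohortTable,
    spec: ModelSpec,
    terms,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EffectSizeEstimate:
    """RESI with a subject-level non-parametric percentile bootstrap CI.

    The point estimate comes from the full table; the interval is the
    percentile interval (lower/upper (1-level)/2 quantiles) of the ``n_boot``
    resampled estimates.  Replicates whose model fit fails are excluded with
    a logged count, never silently retried.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = resi_for_terms(fit_study_model(table, spec), terms)
    seeds = np.random.SeedSequence(seed).spawn(n_boot)
    values = []
    failures = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        try:
            boot = _resample_subjects(table, rng)
            values.append(resi_for_terms(fit_study_model(boot, spec), terms).S_hat)
        except Exception as exc:  # noqa: BLE001 — replicate-level failure
            failures += 1
            log.debug("bootstrap replicate failed: %s", exc)
    if not values:
        raise RuntimeError("all bootstrap replicates failed to fit")
    if failures:
        log.warning("%d/%d bootstrap replicates failed and were excluded",
                    failures, n_boot)
    est.ci_low, est.ci_high = percentile_bounds(values, level)
    est.ci_level = level
    est.n_boot = len(values)
    return est


def _one_visit_subsample(
    table: CohortTable, rng: np.random.Generator
) -> CohortTable:
    """Pick one visit uniformly at random per subject."""
    d = table.data.reset_index(drop=True)
    codes, _ = pd.factorize(d["subject_id"])
    n_subj = codes.max() + 1
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(n_subj))
    stops = np.append(starts[1:], len(codes))
    offsets = (rng.random(n_subj) * (stops - starts)).astype(int)
    pick = d.iloc[order[starts + offsets]]
    return CohortTable(
        pick.reset_index(drop=True),
        design=CROSS_SECTIONAL,
        covariates=list(table.covariates),
        outcomes=list(table.outcomes),
    )


def cs_resi(
    table: CohortTable,
    spec: ModelSpec,
    terms,
    n_boot: int = 0,
    seed: int = 0,
    n_subsamples: int = 20,
    level: float = 0.95,
) -> EffectSizeEstimate:
    """Cross-sectional-equivalent RESI of a longitudinal cohort.

    Averages the cross-sectional RESI over ``n_subsamples`` random
    one-visit-per-subject subsamples of the full table.  With ``n_boot > 0``
    a percentile CI is added by resampling subjects and drawing one
    subsample per bootstrap replicate.  A degenerate longitudinal table with
    one visit per subject reduces exactly to the ordinary RESI.
    """
    if table.design != LONGITUDINAL:
        raise ValueError(
            "cs_resi expects a longitudinal table; "
            "use resi_for_terms for cross-sectional data"
        )
    cs_spec = ModelSpec(
        outcome=spec.outcome,
        terms=spec.terms,
        design=CROSS_SECTIONAL,
        observation_weights=spec.observation_weights,
    )
    degenerate = table.n_longitudinal_subjects() == 0
    ss = np.random.SeedSequence(seed)

    def one_estimate(tab: CohortTable, rng) -> float:
        sub = _one_visit_subsample(tab, rng) if not degenerate else CohortTable(
            tab.data, design=CROSS_SECTIONAL,
            covariates=list(tab.covariates), outcomes=list(tab.outcomes),
        )
        return resi_for_terms(fit_study_model(sub, cs_spec), terms).S_hat

    n_point = 1 if degenerate else n_subsamples
    point_seeds = ss.spawn(n_point)
    vals = [one_estimate(table, np.random.default_rng(s)) for s in point_seeds]
    w = wald_test(fit_study_model(table, spec), terms)
    est = EffectSizeEstimate(
        S_hat=float(np.mean(vals)),
        m=w.m,
        n_subjects=table.n_subjects,
        T2=w.T2,
        variant="CS-RESI",
    )
    if n_boot > 0:
        boot_seeds = ss.spawn(n_boot)
        bvals = []
        failures = 0
        for bs in boot_seeds:
            rng = np.random.default_rng(bs)
            try:
                boot = _resample_subjects(table, rng)
                bvals.append(one_estimate(boot, rng))
            except Exception:  # noqa: BLE001
                failures += 1
        if failures:
            log.warning("%d/%d CS-RESI bootstrap replicates failed", failures, n_boot)
        est.ci_low, est.ci_high = percentile_bounds(bvals, level)
        est.ci_level = level
        est.n_boot = len(bvals)
    return est
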