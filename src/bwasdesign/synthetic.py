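"""Synthetic cohorts with the statistical structure the design analyses assume.

The generator produces long-format cohorts from an explicit data-generating
model that mirrors the association models fitted downstream:

.. code-block:: text

    y_ij = b0 + f_age(age_ij) + b_sex * sex_i
         + beta_between * u_i + beta_within * w_ij
         + subject_intercept_i + e_ij

where ``u_i`` is the subject-level covariate component (SD
``covariate_between_sd``), ``w_ij`` the visit-level deviation (SD
``covariate_within_sd``), and the observed covariate is ``x_ij = u_i + w_ij``.
``f_age`` is a fixed cubic polynomial on standardized age, a smooth
non-linearity that a low-df spline fit can track.

Randomness is governed by one master seed; per-study and per-replicate
streams are derived with :class:`numpy.random.SeedSequence` spawning so
collections and experiments parallelize reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable

__all__ = [
    "SimConfig",
    "SiteConfig",
    "simulate_longitudinal_study",
    "simulate_multistudy_collection",
    "simulate_two_wave_behavioral",
    "inject_site_effects",
]


_DISTRIBUTIONS = {"normal", "uniform", "skewnorm", "constant", "lognormal"}


def _draw(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    """Draw from a named distribution ``(name, *params)``."""
    name, *params = dist
    if name == "normal":
        loc, scale = params
        return rng.normal(loc, scale, size)
    if name == "uniform":
        low, high = params
        return rng.uniform(low, high, size)
    if name == "skewnorm":
        # (shape a, loc, scale); a=0 reduces to the normal
        a, loc, scale = params
        u0 = rng.standard_normal(size)
        v = rng.standard_normal(size)
        d = a / np.sqrt(1 + a * a)
        return loc + scale * (d * np.abs(u0) + np.sqrt(1 - d * d) * v)
    if name == "constant":
        (value,) = params
        return np.full(size, float(value))
    if name == "lognormal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, size)
    raise ValueError(f"unknown distribution {name!r}; known: {sorted(_DISTRIBUTIONS)}")


def _dist_moments(dist: tuple) -> tuple[float, float]:
    """Nominal (mean, sd) of a named distribution, for age standardization."""
    name, *params = dist
    if name == "normal":
        return params[0], params[1]
    if name == "uniform":
        low, high = params
        return (low + high) / 2, (high - low) / np.sqrt(12)
    if name == "skewnorm":
        a, loc, scale = params
        d = a / np.sqrt(1 + a * a)
        mean = loc + scale * d * np.sqrt(2 / np.pi)
        sd = scale * np.sqrt(1 - 2 * d * d / np.pi)
        return mean, sd
    if name == "constant":
        return float(params[0]), 1.0
    if name == "lognormal":
        mu, sigma = params
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.exp(sigma**2) - 1)
        return mean, sd
    raise ValueError(f"unknown distribution {name!r}")


@dataclass
class SimConfig:
    """Data-generating parameters for one synthetic study.

    ``age_effect`` are coefficients on the fixed basis ``(z, z^2, z^3)`` with
    ``z`` the age standardized by the nominal mean/SD of
    ``baseline_age_distribution`` (outcome units per basis unit).
    """

    n_subjects: int = 500
    visits_per_subject: int = 1
    baseline_age_distribution: tuple = ("uniform", 45.0, 80.0)
    visit_gap_distribution: tuple = ("uniform", 0.5, 2.5)
    beta_between: float = 0.0
    beta_within: float = 0.0
    age_effect: tuple = (1.0, 0.0, 0.0)
    sex_effect: float = 0.0
    intercept: float = 0.0
    prop_male: float = 0.5
    subject_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    covariate_between_sd: float = 1.0
    covariate_within_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.visits_per_subject < 1:
            raise ValueError("visits_per_subject must be >= 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for name, v in [
            ("subject_intercept_sd", self.subject_intercept_sd),
            ("covariate_between_sd", self.covariate_between_sd),
            ("covariate_within_sd", self.covariate_within_sd),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.prop_male <= 1:
            raise ValueError("prop_male must be in [0, 1]")
        name = self.baseline_age_distribution[0]
        if name not in _DISTRIBUTIONS:
            raise ValueError(f"unknown age distribution {name!r}")


@dataclass
class SiteConfig:
    """Additive/multiplicative site heterogeneity injected into outcomes."""

    n_sites: int = 1
    additive_shift_sd: float = 0.0
    scale_sd: float = 0.0  # log-scale SD of the multiplicative factor
    assignment: str = "random"  # subject-level allocation rule

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.additive_shift_sd < 0 or self.scale_sd < 0:
            raise ValueError("site effect SDs must be >= 0")
        if self.assignment not in ("random", "round_robin"):
            raise ValueError(f"unknown assignment rule {self.assignment!r}")


def _age_curve(config: SimConfig, age: np.ndarray) -> np.ndarray:
    mean, sd = _dist_moments(config.baseline_age_distribution)
    z = (age - mean) / sd
    coef = np.asarray(config.age_effect, dtype=float)
    basis = np.column_stack([z**k for k in range(1, len(coef) + 1)])
    return basis @ coef


def _simulate(
    config: SimConfig,
    rng: np.random.Generator,
    study_id: str = "study_0",
    covariate_measurement_noise_sd: float = 0.0,
) -> CohortTable:
    n, m = config.n_subjects, config.visits_per_subject
    subj = np.repeat(np.arange(n), m)
    visit = np.tile(np.arange(m), n)

    age0 = _draw(rng, config.baseline_age_distribution, n)
    gaps = np.maximum(_draw(rng, config.visit_gap_distribution, n * m), 1e-2)
    gaps = gaps.reshape(n, m)
    gaps[:, 0] = 0.0
    age = (age0[:, None] + np.cumsum(gaps, axis=1)).ravel()

    sex = rng.binomial(1, config.prop_male, n)
    u = rng.normal(0.0, config.covariate_between_sd, n)  # subject covariate level
    w = rng.normal(0.0, config.covariate_within_sd, n * m)  # visit deviation
    b = rng.normal(0.0, config.subject_intercept_sd, n)
    e = rng.normal(0.0, config.residual_sd, n * m)

    x_latent = u[subj] + w
    y = (
        config.intercept
        + _age_curve(config, age)
        + config.sex_effect * sex[subj]
        + config.beta_between * u[subj]
        + config.beta_within * w
        + b[subj]
        + e
    )
    x = x_latent
    if covariate_measurement_noise_sd > 0:
        x = x_latent + rng.normal(0.0, covariate_measurement_noise_sd, n * m)

    data = pd.DataFrame(
        {
            "subject_id": [f"s{j:06d}" for j in subj],
            "visit_index": visit,
            "age": age,
            "sex": sex[subj],
            "site_id": "site_0",
            "study_id": study_id,
            "x": x,
            "y": y,
        }
    )
    if config.missing_rate > 0 and m > 1:
        # baseline-anchored: only non-baseline visits can be missing
        drop = (visit > 0) & (rng.random(n * m) < config.missing_rate)
        data = data.loc[~drop].reset_index(drop=True)

    design = LONGITUDINAL if m > 1 else CROSS_SECTIONAL
    table = CohortTable(data, design=design, covariates=["x"], outcomes=["y"])
    return table.apply_curation_rule()


def simulate_longitudinal_study(config: SimConfig) -> CohortTable:
    """Generate one cohort from the configured data-generating model.

    Deterministic given ``config.seed``.  With ``visits_per_subject=1`` the
    result is a valid cross-sectional table.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return _simulate(config, rng)


def simulate_multistudy_collection(
    study_specs: list[SimConfig], seed: int
) -> list[CohortTable]:
    """Generate a collection of studies differing in design features.

    Per-study seeds are spawned from the master ``seed`` so each study is an
    independent, reproducible stream.
    """
    if len(study_specs) < 2:
        raise ValueError("a collection requires at least 2 study specs")
    children = np.random.SeedSequence(seed).spawn(len(study_specs))
    tables = []
    for k, (spec, ss) in enumerate(zip(study_specs, children)):
        rng = np.random.default_rng(ss)
        tables.append(_simulate(spec, rng, study_id=f"study_{k:03d}"))
    return tables


def simulate_two_wave_behavioral(
    config: SimConfig, covariate_measurement_noise_sd: float
) -> CohortTable:
    """Two-visit cohort whose covariate carries extra measurement noise.

    Emulates a behavioural covariate that is noisier than the outcome: the
    outcome responds to the *latent* covariate components, while the observed
    covariate is latent value plus visit-level measurement error.  With
    ``beta_within=0`` the outcome's within-subject change is independent of
    the covariate's within-subject change.
    """
    if config.visits_per_subject != 2:
        raise ValueError("two-wave design requires visits_per_subject=2")
    if covariate_measurement_noise_sd < 0:
        raise ValueError("measurement noise SD must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return _simulate(
        config, rng, covariate_measurement_noise_sd=covariate_measurement_noise_sd
    )


def inject_site_effects(
    table: CohortTable, site_config: SiteConfig, seed: int
) -> CohortTable:
    """Shift and scale outcomes by site-specific factors.

    Each subject is assigned to exactly one site for all its visits; every
    outcome column becomes ``scale_s * y + shift_s`` with
    ``shift_s ~ N(0, additive_shift_sd)`` and
    ``log(scale_s) ~ N(0, scale_sd)``.
    """
    if table.n_obs == 0:
        raise ValueError("empty cohort table")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subjects = table.data["subject_id"].unique()
    k = site_config.n_sites
    if site_config.assignment == "round_robin":
        alloc = np.arange(len(subjects)) % k
    else:
        alloc = rng.integers(0, k, len(subjects))
    site_of = dict(zip(subjects, alloc))

    shifts = rng.normal(0.0, site_config.additive_shift_sd, k)
    scales = np.exp(rng.normal(0.0, site_config.scale_sd, k))

    data = table.data.copy()
    idx = data["subject_id"].map(site_of).to_numpy()
    data["site_id"] = [f"site_{i}" for i in idx]
    for col in table.outcomes:
        data[col] = scales[idx] * data[col].to_numpy() + shifts[idx]
    return CohortTable(
        data,
        design=table.design,
        covariates=list(table.covariates),
        outcomes=list(table.outcomes),
    )


def make_study_spec(
    mean_age: float,
    sd_age: float,
    skew: float = 0.0,
    *,
    n_subjects: int = 300,
    visits: int = 1,
    **overrides,
) -> SimConfig:
    """Convenience: a study spec hitting target age moments.

    Converts (mean, SD, skewness direction) into skew-normal parameters; the
    skew-normal caps |skewness| below ~0.995, which covers the design range
    the meta-analysis explores.
    """
    a = 0.0
    if skew != 0.0:
        # invert the skew-normal skewness formula for |g1| < 0.995
        g = min(abs(skew), 0.99)
        r = (2 * g / (4 - np.pi)) ** (1 / 3)
        d = r / np.sqrt(2 / np.pi * (1 + r**2))
        d = min(d, 0.999)
        a = np.sign(skew) * d / np.sqrt(1 - d**2)
    d = a / np.sqrt(1 + a * a)
    scale = sd_age / np.sqrt(1 - 2 * d * d / np.pi)
    loc = mean_age - scale * d * np.sqrt(2 / np.pi)
    return SimConfig(
        n_subjects=n_subjects,
        visits_per_subject=visits,
        baseline_age_distribution=("skewnorm", a, loc, scale),
        **overrides,
    )
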