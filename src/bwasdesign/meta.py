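"""Meta-regression of study-level effect sizes on design features.

Each study contributes one effect-size estimate with its standard error and
a handful of design features: mean, SD and skewness of age (computed at
baseline, one record per subject), the proportion of males, design type and
N.  Effect sizes are regressed on the design indicator plus natural-spline
(df=3) terms of the continuous features by weighted least squares with
weights 1/SE — the weighting used for the study-level estimates — and
heteroskedasticity-robust standard errors.  Partial-prediction curves vary
one feature over a grid while holding the others at reference values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable, MIN_LONGITUDINAL_SUBJECTS
from .splines import NaturalSplineBasis

__all__ = [
    "StudySummary",
    "MetaResult",
    "summarize_design",
    "fit_meta_regression",
    "predict_partial",
    "adjust_pvalues_bh",
]

#: reference feature values for partial-prediction curves
PARTIAL_DEFAULTS = {"mean_age": 45.0, "sd_age": 7.0, "skew_age": 0.0, "prop_male": 0.5}


@dataclass
class StudySummary:
    study_id: str
    mean_age: float
    sd_age: float
    skew_age: float
    prop_male: float
    design: str
    n_subjects: int


def summarize_design(table: CohortTable) -> StudySummary:
    """Design features of one study, computed at baseline (one row/subject).

    The skewness is the adjusted Fisher–Pearson sample skewness.  A
    longitudinal table with fewer than three subjects having repeat visits
    is summarized as cross-sectional.
    """
    if table.n_obs == 0:
        raise ValueError("empty table")
    curated = table.apply_curation_rule()
    base = curated.baseline()
    ages = base["age"].to_numpy(dtype=float)
    return StudySummary(
        study_id=str(base["study_id"].iloc[0]),
        mean_age=float(np.mean(ages)),
        sd_age=float(np.std(ages, ddof=1)) if ages.size > 1 else 0.0,
        skew_age=float(stats.skew(ages, bias=False)) if ages.size > 2 else 0.0,
        prop_male=float(np.mean(base["sex"])),
        design=curated.design,
        n_subjects=int(base.shape[0]),
    )


@dataclass
class MetaResult:
    coefficients: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray
    model: str
    features: pd.DataFrame = field(repr=False)
    spline_bases: dict = field(repr=False, default_factory=dict)
    bh_pvalues: pd.Series | None = None


_MODEL_FEATURES = {
    "age": ["mean_age", "sd_age", "skew_age"],
    "sex": ["mean_age", "sd_age", "prop_male"],
}


def _meta_design(
    feats: pd.DataFrame,
    model: str,
    bases: dict | None = None,
    spline_df: int | None = 3,
) -> tuple[np.ndarray, list[str], dict]:
    cols = [np.ones(len(feats))]
    names = ["Intercept"]
    cols.append((feats["design"] == LONGITUDINAL).to_numpy(dtype=float))
    names.append("design[longitudinal]")
    fitted_bases: dict = {}
    for f in _MODEL_FEATURES[model]:
        x = feats[f].to_numpy(dtype=float)
        if bases is not None:
            basis = bases.get(f)
        elif spline_df is not None:
            basis = NaturalSplineBasis.from_data(x, spline_df)
        else:
            basis = None
        fitted_bases[f] = basis
        if basis is None:  # linear feature term
            cols.append(x)
            names.append(f)
            continue
        B = basis.transform(x)
        for j in range(B.shape[1]):
            cols.append(B[:, j])
            names.append(f"ns({f}).{j + 1}")
    return np.column_stack(cols), names, fitted_bases


def fit_meta_regression(
    estimates,
    summaries: list[StudySummary],
    model: str = "age",
    robust: str = "HC0",
    inverse_variance: bool = False,
    spline_df: int | None = 3,
) -> MetaResult:
    """Weighted meta-regression of effect sizes on design features.

    ``estimates`` is a sequence of ``(S_hat, SE)`` pairs (or objects with
    those attributes) aligned with ``summaries``.  Weights are ``1/SE`` by
    default — matching the weighting the study-level estimator uses — with
    ``inverse_variance=True`` switching to the conventional ``1/SE^2``.
    Spline terms (default df=3) put interior knots at the 33rd/66th
    percentiles of each feature; ``spline_df=None`` uses linear feature
    terms (small collections).  Coefficient inference uses HC-sandwich
    robust SEs (``robust`` in {"HC0", "HC1", "HC3"}).
    """
    if model not in _MODEL_FEATURES:
        raise ValueError("model must be 'age' or 'sex'")
    s_hat, se = [], []
    for e in estimates:
        if hasattr(e, "S_hat"):
            s_hat.append(float(e.S_hat))
            se.append(float(e.SE if hasattr(e, "SE") else e.se))
        else:
            a, b = e
            s_hat.append(float(a))
            se.append(float(b))
    s_hat = np.asarray(s_hat)
    se = np.asarray(se)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    if len(s_hat) != len(summaries):
        raise ValueError("estimates and summaries must align")

    feats = pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "mean_age": s.mean_age,
                "sd_age": s.sd_age,
                "skew_age": s.skew_age,
                "prop_male": s.prop_male,
                "design": s.design,
            }
            for s in summaries
        ]
    )
    X, names, bases = _meta_design(feats, model, spline_df=spline_df)
    if len(s_hat) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} studies for {X.shape[1]} parameters"
        )
    w = 1.0 / se**2 if inverse_variance else 1.0 / se
    res = sm.WLS(s_hat, X, weights=w).fit(cov_type=robust)
    coef = pd.Series(res.params, index=names)
    rse = pd.Series(np.sqrt(np.diag(res.cov_params())), index=names)
    pv = pd.Series(res.pvalues, index=names)
    fitted = X @ res.params
    return MetaResult(
        coefficients=coef,
        robust_se=rse,
        pvalues=pv,
        fitted=np.asarray(fitted),
        residuals=s_hat - np.asarray(fitted),
        weights=w,
        model=model,
        features=feats,
        spline_bases=bases,
    )


def predict_partial(
    meta: MetaResult,
    vary: str | None = None,
    grid=None,
    fixed: dict | None = None,
    design: str = CROSS_SECTIONAL,
) -> pd.DataFrame:
    """Expected effect size varying one feature, others held at references.

    With ``vary=None`` returns the single prediction at the reference
    values.  Grids outside the observed feature range trigger a warning
    (the spline extrapolates linearly there).
    """
    fixed = {**PARTIAL_DEFAULTS, **(fixed or {})}
    feat_names = _MODEL_FEATURES[meta.model]
    if vary is None:
        grid = [None]
        rows = [dict(fixed)]
    else:
        if vary not in feat_names:
            raise ValueError(f"{vary!r} is not a feature of the {meta.model} model")
        grid = np.asarray(grid, dtype=float)
        obs = meta.features[vary].to_numpy(dtype=float)
        if grid.min() < obs.min() or grid.max() > obs.max():
            warnings.warn(
                f"grid for {vary} extends beyond the observed range "
                f"[{obs.min():.3g}, {obs.max():.3g}]; predictions extrapolate linearly",
                stacklevel=2,
            )
        rows = [{**fixed, vary: g} for g in grid]
    f = pd.DataFrame(rows)
    f["design"] = design
    X, _, _ = _meta_design(f, meta.model, bases=meta.spline_bases)
    pred = X @ meta.coefficients.to_numpy()
    out = pd.DataFrame({"predicted_S": pred})
    if vary is not None:
        out.insert(0, vary, grid)
    return out


def adjust_pvalues_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
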