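"""Study-level association models with robust covariance.

Cross-sectional studies are fitted by least squares with a
heteroskedasticity-robust (HC sandwich) covariance; longitudinal studies by
generalized estimating equations with identity link, exchangeable working
correlation and a subject-clustered sandwich covariance.  Both paths return a
:class:`FitResult` carrying the coefficient vector, its robust covariance,
the subject count ``N`` (subjects, not observations) and a term→column map,
which is all the downstream effect-size machinery needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable
from .splines import NaturalSplineBasis

__all__ = [
    "Term",
    "ModelSpec",
    "FitResult",
    "WaldResult",
    "BetweenWithinFit",
    "fit_study_model",
    "wald_test",
    "fit_between_within",
    "remove_site_effects",
]


@dataclass
class Term:
    name: str
    transform: str = "linear"  # linear | ns | categorical
    df: int | None = None
    knots: tuple | None = None

    def __post_init__(self):
        if self.transform not in ("linear", "ns", "categorical"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "ns" and self.df is None and self.knots is None:
            raise ValueError("ns term requires df or explicit knots")


_NS_RE = re.compile(r"ns\(\s*(\w+)\s*,\s*(?:df\s*=\s*)?(\d+)\s*\)")
_CAT_RE = re.compile(r"C\(\s*(\w+)\s*\)")


@dataclass
class ModelSpec:
    """What to regress on what, and under which design."""

    outcome: str
    terms: list[Term]
    design: str = CROSS_SECTIONAL
    observation_weights: str | None = None

    @classmethod
    def from_formula(
        cls, formula: str, design: str = CROSS_SECTIONAL, observation_weights=None
    ) -> "ModelSpec":
        """Parse ``"y ~ ns(age, df=2) + sex + x"`` style strings."""
        lhs, rhs = (s.strip() for s in formula.split("~", 1))
        terms = []
        for piece in (p.strip() for p in rhs.split("+")):
            if not piece or piece == "1":
                continue
            if m := _NS_RE.fullmatch(piece):
                terms.append(Term(m.group(1), "ns", df=int(m.group(2))))
            elif m := _CAT_RE.fullmatch(piece):
                terms.append(Term(m.group(1), "categorical"))
            else:
                terms.append(Term(piece))
        return cls(lhs, terms, design=design, observation_weights=observation_weights)

    def columns_used(self) -> list[str]:
        cols = [self.outcome] + [t.name for t in self.terms]
        if self.observation_weights:
            cols.append(self.observation_weights)
        return cols


@dataclass
class FitResult:
    beta_hat: pd.Series
    robust_cov: pd.DataFrame
    n_subjects: int
    n_obs: int
    df_model: int
    term_index: dict[str, list[int]]
    pvalues: dict[str, float]
    design: str
    n_dropped: int = 0
    spline_bases: dict = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "coefficients": self.beta_hat.to_dict(),
            "robust_cov": self.robust_cov.values.tolist(),
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "df_model": self.df_model,
            "design": self.design,
            "pvalues": self.pvalues,
        }


@dataclass
class WaldResult:
    T2: float
    m: int
    p: float


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict[str, list[int]], dict]:
    """Design matrix with intercept, column names and a term→positions map."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    term_index: dict[str, list[int]] = {}
    bases: dict[str, NaturalSplineBasis] = {}
    for t in spec.terms:
        x = data[t.name].to_numpy()
        start = len(names)
        if t.transform == "linear":
            cols.append(np.asarray(x, dtype=float))
            names.append(t.name)
        elif t.transform == "ns":
            basis = NaturalSplineBasis.from_data(
                np.asarray(x, dtype=float), t.df, interior_knots=t.knots
            )
            B = basis.transform(x)
            bases[t.name] = basis
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                names.append(f"ns({t.name}).{j + 1}")
        else:  # categorical, treatment coding, first level reference
            levels = pd.unique(pd.Series(x).sort_values())
            for lev in levels[1:]:
                cols.append((x == lev).astype(float))
                names.append(f"{t.name}[{lev}]")
        term_index[t.name] = list(range(start, len(names)))
    X = np.column_stack(cols)
    return X, names, term_index, bases


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name columns implicated by the rank deficiency via pivoted QR
        _, R, piv = __import__("scipy").linalg.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = [names[piv[j]] for j in range(X.shape[1]) if diag[j] < 1e-8 * diag.max()]
        raise ValueError(f"singular design matrix; collinear terms: {bad}")


def fit_study_model(
    table: CohortTable, spec: ModelSpec, small_sample_correction: bool = False
) -> FitResult:
    """Fit the study-level association model with robust covariance.

    Rows with missing values in any modelled column are dropped (listwise);
    the count is reported on the result.  The HC flavour is HC0 / the plain
    clustered sandwich by default; ``small_sample_correction`` switches to
    HC1-style scaling for the cross-sectional path.
    """
    used = spec.columns_used()
    missing_cols = [c for c in used if c not in table.data.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    data = table.data.dropna(subset=used)
    n_dropped = len(table.data) - len(data)

    X, names, term_index, bases = build_design_matrix(data, spec)
    _check_full_rank(X, names)
    y = data[spec.outcome].to_numpy(dtype=float)
    weights = (
        data[spec.observation_weights].to_numpy(dtype=float)
        if spec.observation_weights
        else None
    )

    if spec.design == CROSS_SECTIONAL:
        model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
        res = model.fit(cov_type="HC1" if small_sample_correction else "HC0")
        beta = res.params
        cov = res.cov_params()
        n_subjects = data["subject_id"].nunique()
    else:
        groups = data["subject_id"].to_numpy()
        model = sm.GEE(
            y,
            X,
            groups=groups,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
            weights=weights,
        )
        res = model.fit(maxiter=100, ctol=1e-8, cov_type="robust")
        beta = res.params
        cov = res.cov_params()
        n_subjects = data["subject_id"].nunique()

    beta = pd.Series(np.asarray(beta), index=names)
    cov = pd.DataFrame(np.asarray(cov), index=names, columns=names)
    fit = FitResult(
        beta_hat=beta,
        robust_cov=cov,
        n_subjects=int(n_subjects),
        n_obs=len(data),
        df_model=X.shape[1],
        term_index=term_index,
        pvalues={},
        design=spec.design,
        n_dropped=n_dropped,
        spline_bases=bases,
    )
    fit.pvalues = {t: wald_test(fit, t).p for t in term_index}
    return fit


def wald_test(fit: FitResult, terms, beta0=None) -> WaldResult:
    """Robust Wald chi-squared test of H0: beta = beta0 for the named terms.

    ``T2 = (b - b0)' V^{-1} (b - b0)`` with ``V`` the robust covariance of the
    coefficient estimates restricted to the tested positions; the p-value is
    from a chi-squared distribution with ``m`` degrees of freedom.
    """
    if isinstance(terms, str):
        terms = [terms]
    idx: list[int] = []
    for t in terms:
        if t not in fit.term_index:
            raise KeyError(f"unknown term {t!r}; have {list(fit.term_index)}")
        idx.extend(fit.term_index[t])
    b = fit.beta_hat.to_numpy()[idx]
    if beta0 is not None:
        b = b - np.asarray(beta0, dtype=float)
    V = fit.robust_cov.to_numpy()[np.ix_(idx, idx)]
    # degenerate fits (e.g. constant outcome) leave both b and V at rounding
    # noise; the ratio is then meaningless and the test statistic is 0
    scale = max(1.0, float(np.max(np.abs(fit.beta_hat.to_numpy()))))
    if np.all(np.abs(b) < 1e-10 * scale):
        return WaldResult(T2=0.0, m=len(idx), p=1.0)
    try:
        T2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        T2 = float(b @ np.linalg.pinv(V) @ b)
    T2 = max(T2, 0.0)
    m = len(idx)
    return WaldResult(T2=T2, m=m, p=float(stats.chi2.sf(T2, m)))


@dataclass
class BetweenWithinFit:
    """Decomposition of a covariate's effect into between/within components.

    ``beta_between`` is the coefficient on the subject's baseline covariate
    value (constant across visits); ``beta_within`` the coefficient on the
    deviation of each visit's covariate value from baseline.  The two
    variance components are the sample variance of the baseline values and
    the mean square of the change values.
    """

    beta_between: float
    beta_within: float
    se_between: float
    se_within: float
    between_variance: float
    within_variance: float
    fit: FitResult


def fit_between_within(
    table: CohortTable, covariate: str, spec: ModelSpec
) -> BetweenWithinFit:
    """Fit the longitudinal model with explicit between/within covariate terms.

    The mean model is ``outcome ~ <adjustment terms> + X_bl + X_change``
    fitted by GEE, where ``X_bl`` is the subject's baseline covariate value
    and ``X_change`` the per-visit difference from baseline.  Subjects
    without a baseline row are excluded.
    """
    if table.design != LONGITUDINAL:
        raise ValueError("between/within decomposition requires a longitudinal table")
    data = table.data.copy()
    has_baseline = data.groupby("subject_id")["visit_index"].transform("min") == 0
    base_mask = data["visit_index"] == 0
    baseline_val = (
        data.loc[base_mask].set_index("subject_id")[covariate]
    )
    data = data.loc[data["subject_id"].isin(baseline_val.index) & has_baseline].copy()
    data["X_bl"] = data["subject_id"].map(baseline_val)
    data["X_change"] = data[covariate] - data["X_bl"]
    if np.allclose(data["X_change"], 0.0):
        raise ValueError(
            "X_change is identically zero (no follow-up variation); "
            "the within-subject effect is undefined"
        )

    adj_terms = [t for t in spec.terms if t.name != covariate]
    bw_spec = ModelSpec(
        outcome=spec.outcome,
        terms=adj_terms + [Term("X_bl"), Term("X_change")],
        design=LONGITUDINAL,
        observation_weights=spec.observation_weights,
    )
    sub = CohortTable(
        data,
        design=LONGITUDINAL,
        covariates=list(table.covariates) + ["X_bl", "X_change"],
        outcomes=list(table.outcomes),
    )
    fit = fit_study_model(sub, bw_spec)
    i_b = fit.term_index["X_bl"][0]
    i_w = fit.term_index["X_change"][0]
    between_var = float(np.var(baseline_val.loc[data["subject_id"].unique()], ddof=1))
    within_var = float(np.mean(data["X_change"].to_numpy() ** 2))
    return BetweenWithinFit(
        beta_between=float(fit.beta_hat.iloc[i_b]),
        beta_within=float(fit.beta_hat.iloc[i_w]),
        se_between=float(np.sqrt(fit.robust_cov.iloc[i_b, i_b])),
        se_within=float(np.sqrt(fit.robust_cov.iloc[i_w, i_w])),
        between_variance=between_var,
        within_variance=within_var,
        fit=fit,
    )


def remove_site_effects(table: CohortTable, spec: ModelSpec) -> CohortTable:
    """Residualize the outcome for additive site effects (location only).

    Site main effects are estimated jointly with the spec's covariate terms
    so covariate–outcome associations are preserved; each outcome value is
    then shifted by its site's (observation-weighted, centred) effect.  A
    simplified stand-in for empirical-Bayes harmonization: multiplicative
    site differences are not corrected.
    """
    if "site_id" not in table.data.columns:
        raise ValueError("site column missing")
    data = table.data
    sites = pd.unique(data["site_id"])
    if len(sites) < 2:
        return table

    used = [c for c in spec.columns_used() if c != spec.outcome]
    sub = data.dropna(subset=[spec.outcome] + used)
    X, names, _, _ = build_design_matrix(sub, spec)
    dummies = pd.get_dummies(sub["site_id"], dtype=float)
    dummies = dummies[sorted(dummies.columns)]
    D = dummies.to_numpy()[:, 1:]  # treatment coding, first site reference
    full = np.column_stack([X, D])
    beta, *_ = np.linalg.lstsq(full, sub[spec.outcome].to_numpy(dtype=float), rcond=None)
    alpha = np.concatenate([[0.0], beta[X.shape[1]:]])
    site_order = sorted(dummies.columns)
    counts = sub["site_id"].value_counts()
    w = np.array([counts.get(s, 0) for s in site_order], dtype=float)
    alpha_centered = alpha - np.average(alpha, weights=w)
    effect = dict(zip(site_order, alpha_centered))

    out = data.copy()
    out[spec.outcome] = out[spec.outcome] - out["site_id"].map(effect).fillna(0.0)
    return CohortTable(
        out,
        design=table.design,
        covariates=list(table.covariates),
        outcomes=list(table.outcomes),
    )
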