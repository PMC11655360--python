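"""Targeted sampling weights and weighted-bootstrap design experiments.

The design experiments ask how the variance of a covariate in the *sample*
changes standardized effect sizes.  Sampling weights are built in two steps:
each record (or per-subject visit combination) is first inversely weighted by
its local frequency — the number of records within a +/- halfwidth window in
every weighting dimension — which targets a uniform sampling distribution;
the weights are then rescaled by a target density so resamples follow
bell-shaped, uniform, U-shaped (between-subject) or decreasing / uniform /
increasing (within-subject, on the covariate change) distributions.
Extreme values are winsorized *for weight assignment only*: the data values
carried into analysis are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable
from .effects import percentile_bounds, resi_for_terms
from .models import ModelSpec, fit_study_model

__all__ = [
    "TargetShape",
    "WeightTable",
    "local_frequency",
    "cross_sectional_weights",
    "longitudinal_combination_weights",
    "binary_weights",
    "weighted_bootstrap",
    "run_scheme_experiment",
    "SchemeExperimentResult",
    "quantile_winsor_bounds",
]

#: default quadratic floor so edge/centre weights never vanish
DEFAULT_DELTA = 0.05
#: default exponential rate for increasing/decreasing change targets
DEFAULT_LAMBDA = 2.0
#: default local-frequency window halfwidth (years or covariate units)
DEFAULT_HALFWIDTH = 0.5

_FAMILIES = (
    "bell",
    "uniform",
    "u_shaped",
    "decreasing",
    "increasing",
    "binary_proportion",
)


@dataclass
class TargetShape:
    """A target sampling density on a winsorized support.

    Quadratic shapes use ``u = (x - centre)/halfspan`` mapping the support to
    [-1, 1]: bell is ``(1 - u^2) + delta``, U-shaped ``u^2 + delta``.
    Exponential shapes use ``u01`` in [0, 1]: increasing ``exp(lambda*u01)``,
    decreasing ``exp(-lambda*u01)``.  All are strictly positive on the
    support.
    """

    family: str
    delta: float = DEFAULT_DELTA
    rate: float = DEFAULT_LAMBDA
    target_prop: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown target family {self.family!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (density must stay positive)")

    def density(self, x, support: tuple[float, float]) -> np.ndarray:
        lo, hi = support
        if hi <= lo:
            raise ValueError("support must satisfy lo < hi")
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        if self.family == "uniform":
            return np.ones_like(x)
        if self.family in ("bell", "u_shaped"):
            u = 2.0 * (x - lo) / (hi - lo) - 1.0
            return (1.0 - u**2) + self.delta if self.family == "bell" else u**2 + self.delta
        u01 = (x - lo) / (hi - lo)
        if self.family == "increasing":
            return np.exp(self.rate * u01)
        if self.family == "decreasing":
            return np.exp(-self.rate * u01)
        raise ValueError(f"{self.family} has no continuous density")


@dataclass
class WeightTable:
    """Sampling weights for records or per-subject visit combinations.

    ``unit`` is ``record`` (cross-sectional), ``subject_pair`` (baseline +
    one follow-up) or ``subject_triple``; ``keys`` holds row positions
    (record unit) or tuples of row positions into the source table.
    """

    unit: str
    keys: list
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.keys) != w.size:
            raise ValueError("keys and weights length mismatch")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and >= 0")
        if w.size and not np.any(w > 0):
            raise ValueError("weights must not be all zero")
        self.weights = w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"key": self.keys, "weight": self.weights})


def local_frequency(points, halfwidth: float) -> np.ndarray:
    """Number of records within ``+/- halfwidth`` of each record, per axis.

    ``points`` is (n,) or (n, k) with k in {1, 2, 3}; the count includes the
    record itself and uses closed intervals on every dimension (Chebyshev
    ball).  Duplicated records each count.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.size == 0:
        raise ValueError("empty input")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    if pts.shape[1] not in (1, 2, 3):
        raise ValueError("points must be 1-, 2- or 3-dimensional")
    tree = cKDTree(pts)
    # tiny inflation keeps boundary points (distance exactly halfwidth) inside
    r = halfwidth * (1.0 + 1e-12)
    return np.asarray(
        tree.query_ball_point(pts, r=r, p=np.inf, return_length=True), dtype=int
    )


def quantile_winsor_bounds(x, lower: float = 0.05, upper: float = 0.95):
    """Winsorization bounds at sample quantiles (covariate-generic rule)."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, [lower, upper])
    return float(lo), float(hi)


def cross_sectional_weights(
    ages,
    shape: TargetShape,
    winsor_bounds: tuple[float, float],
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> WeightTable:
    """Per-record weights targeting a between-subject age distribution.

    Ages are clamped to ``winsor_bounds`` for weight assignment only; the
    weight is ``target_density(clamped age) / local_frequency(clamped age)``.
    Analyses of resampled data keep each record's actual age.
    """
    if shape.family not in ("bell", "uniform", "u_shaped"):
        raise ValueError("cross-sectional shapes are bell, uniform or u_shaped")
    lo, hi = winsor_bounds
    if hi <= lo:
        raise ValueError("winsor bounds inverted")
    ages = np.asarray(ages, dtype=float)
    clamped = np.clip(ages, lo, hi)
    freq = local_frequency(clamped, halfwidth)
    w = shape.density(clamped, (lo, hi)) / freq
    return WeightTable(
        unit="record",
        keys=list(range(ages.size)),
        weights=w,
        provenance={
            "shape": shape.family,
            "winsor_bounds": (lo, hi),
            "halfwidth": halfwidth,
        },
    )


def longitudinal_combination_weights(
    table: CohortTable,
    between_shape: TargetShape,
    within_shape: TargetShape,
    winsor_between: tuple[float, float],
    winsor_within: tuple[float, float],
    halfwidth: float = DEFAULT_HALFWIDTH,
    n_followups: int = 1,
    feature: str = "age",
) -> WeightTable:
    """Weights over per-subject (baseline, follow-up...) visit combinations.

    Each subject contributes every combination of its baseline record with
    ``n_followups`` of its follow-up records.  The combination's features are
    the baseline value and the change(s) from baseline of ``feature``.  The
    weight is the product of the between-target density at the (winsorized)
    baseline value and the within-target density at each (winsorized)
    change, divided by the multivariate local frequency of the combination.
    Between and within targets act independently by construction.
    """
    d = table.data.reset_index(drop=True)
    keys: list[tuple] = []
    feats: list[list[float]] = []
    for _, g in d.groupby("subject_id"):
        g = g.sort_values("visit_index")
        if g["visit_index"].iloc[0] != 0:
            continue  # no baseline record
        base = g.index[0]
        follows = list(g.index[1:])
        if len(follows) < n_followups:
            continue
        b_val = float(d.loc[base, feature])
        for combo in combinations(follows, n_followups):
            changes = [float(d.loc[f, feature]) - b_val for f in combo]
            keys.append((base, *combo))
            feats.append([b_val, *changes])
    if not keys:
        raise ValueError(
            f"no subject has a baseline plus >= {n_followups} follow-ups"
        )
    F = np.asarray(feats)
    blo, bhi = winsor_between
    wlo, whi = winsor_within
    if bhi <= blo or whi <= wlo:
        raise ValueError("winsor bounds inverted")
    clamped = F.copy()
    clamped[:, 0] = np.clip(F[:, 0], blo, bhi)
    clamped[:, 1:] = np.clip(F[:, 1:], wlo, whi)
    freq = local_frequency(clamped, halfwidth)
    w = between_shape.density(clamped[:, 0], (blo, bhi)) / freq
    for j in range(1, clamped.shape[1]):
        w = w * within_shape.density(clamped[:, j], (wlo, whi))
    unit = "subject_pair" if n_followups == 1 else "subject_triple"
    return WeightTable(
        unit=unit,
        keys=keys,
        weights=w,
        provenance={
            "between_shape": between_shape.family,
            "within_shape": within_shape.family,
            "winsor_between": (blo, bhi),
            "winsor_within": (wlo, whi),
            "halfwidth": halfwidth,
            "feature": feature,
        },
    )


def binary_weights(values, target_prop: float) -> WeightTable:
    """Weights steering a binary covariate's resample prevalence.

    Class 1 gets weight proportional to ``target_prop / prevalence`` and
    class 0 to ``(1-target_prop) / (1-prevalence)``, so the expected
    resampled proportion of class 1 equals ``target_prop``.
    """
    v = np.asarray(values)
    if not 0.0 < target_prop < 1.0:
        raise ValueError("target_prop must be in (0, 1)")
    if not set(np.unique(v)) <= {0, 1}:
        raise ValueError("values must be coded {0, 1}")
    prev = float(np.mean(v))
    if prev in (0.0, 1.0):
        raise ValueError("both classes must be present")
    w = np.where(v == 1, target_prop / prev, (1.0 - target_prop) / (1.0 - prev))
    return WeightTable(
        unit="record",
        keys=list(range(v.size)),
        weights=w,
        provenance={"target_prop": target_prop, "prevalence": prev},
    )


def weighted_bootstrap(
    table: CohortTable, weights: WeightTable, n: int, seed: int
) -> CohortTable:
    """Draw ``n`` units with replacement with probability proportional to weight.

    Record units yield one row each; subject_pair / subject_triple units
    yield the baseline plus follow-up rows renumbered as visits 0, 1, ...
    Every sampled unit becomes a fresh bootstrap subject so longitudinal
    fits cluster correctly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = weights.weights / weights.weights.sum()
    picks = rng.choice(len(weights.keys), size=n, replace=True, p=p)
    d = table.data.reset_index(drop=True)
    if weights.unit == "record":
        rows = [weights.keys[i] for i in picks]
        out = d.iloc[rows].copy()
        out["subject_id"] = [f"b{j:07d}" for j in range(n)]
        out["visit_index"] = 0
        design = CROSS_SECTIONAL
    else:
        row_idx, subj, visit = [], [], []
        for j, i in enumerate(picks):
            key = weights.keys[i]
            for v, r in enumerate(key):
                row_idx.append(r)
                subj.append(f"b{j:07d}")
                visit.append(v)
        out = d.iloc[row_idx].copy()
        out["subject_id"] = subj
        out["visit_index"] = visit
        design = LONGITUDINAL
    return CohortTable(
        out.reset_index(drop=True),
        design=design,
        covariates=list(table.covariates),
        outcomes=list(table.outcomes),
    )


@dataclass
class SchemeExperimentResult:
    """Per-(scheme, n) bootstrap summaries plus per-replicate records."""

    summary: pd.DataFrame  # scheme, n, mean_S, ci_low, ci_high, power, n_failed
    replicates: pd.DataFrame  # scheme, n, rep, S_hat, p

    def pvalues(self, scheme: str, n: int) -> np.ndarray:
        r = self.replicates
        return r.loc[(r["scheme"] == scheme) & (r["n"] == n), "p"].to_numpy()


def run_scheme_experiment(
    table: CohortTable,
    schemes: dict[str, WeightTable],
    n_grid: list[int],
    spec: ModelSpec,
    terms,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SchemeExperimentResult:
    """Bootstrap experiment over sampling schemes and sample sizes.

    For every scheme and every ``n`` in the grid, draws ``B`` weighted
    bootstrap replicates, fits the model, and records the RESI and the
    tested terms' p-value.  The summary reports the mean RESI across
    replicates, the 2.5/97.5 percentile band, and the share of replicates
    rejecting at ``alpha`` (empirical power).  Replicate fit failures are
    excluded and counted.
    """
    ss = np.random.SeedSequence(seed)
    rows, reps = [], []
    for scheme_name, wt in schemes.items():
        for n in n_grid:
            child = ss.spawn(1)[0]
            rep_seeds = child.generate_state(B)
            svals, pvals, failed = [], [], 0
            for r in range(B):
                try:
                    boot = weighted_bootstrap(
                        table, wt, n, int(rep_seeds[r] % (2**31))
                    )
                    est = resi_for_terms(fit_study_model(boot, spec), terms)
                    svals.append(est.S_hat)
                    pvals.append(est.p)
                    reps.append(
                        {"scheme": scheme_name, "n": n, "rep": r,
                         "S_hat": est.S_hat, "p": est.p}
                    )
                except Exception:  # noqa: BLE001 — replicate-level failure
                    failed += 1
            if not svals:
                raise RuntimeError(
                    f"all {B} replicates failed for scheme={scheme_name}, n={n}"
                )
            lo, hi = percentile_bounds(svals, 0.95) if len(svals) > 1 else (svals[0], svals[0])
            pv = np.asarray(pvals)
            rows.append(
                {
                    "scheme": scheme_name,
                    "n": n,
                    "mean_S": float(np.mean(svals)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "power": float(np.mean(pv <= alpha)),
                    "n_failed": failed,
                }
            )
    return SchemeExperimentResult(
        summary=pd.DataFrame(rows), replicates=pd.DataFrame(reps)
    )
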