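"""End-to-end orchestration: simulate -> harmonize -> fit -> effect sizes ->
sampling experiment -> power/replicability -> meta-analysis.

A run is driven by one :class:`RunConfig` (YAML or dict) and writes every
stage's outputs under a run directory together with a manifest recording the
seed, a content hash of each output and a per-stage cache key.  Re-running
with the same config reproduces all numeric outputs exactly; stages whose
inputs are unchanged and whose outputs are intact are skipped, so deleting a
downstream output re-executes only that stage and the ones after it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects, meta, power, sampling
from .cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable
from .models import ModelSpec, fit_between_within, fit_study_model, remove_site_effects
from .synthetic import (
    SimConfig,
    SiteConfig,
    inject_site_effects,
    simulate_multistudy_collection,
)

__all__ = ["RunConfig", "run_pipeline", "compare_designs_report"]

log = logging.getLogger(__name__)

STAGES = ["simulate", "harmonize", "fit", "sampling", "power", "between_within", "meta"]

#: centralized defaults (documented in docs/methods.md)
DEFAULTS = {
    "alpha": 0.05,
    "B": 1000,
    "halfwidth": sampling.DEFAULT_HALFWIDTH,
    "delta": sampling.DEFAULT_DELTA,
    "lambda": sampling.DEFAULT_LAMBDA,
    "replicability_target": 0.8,
    "n_boot": 200,
}


@dataclass
class RunConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    studies: list[dict] = field(default_factory=list)
    site: dict | None = None
    model: dict = field(
        default_factory=lambda: {"formula": "y ~ ns(age, df=2) + sex + x", "terms": "x"}
    )
    sampling: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    between_within: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.studies:
            raise ValueError("config must define at least one study")
        for d in self.studies:
            SimConfig(**d)  # raises on invalid values
        # generated tables carry these columns; catch typos before any stage runs
        available = {"age", "sex", "x", "y", "site_id", "study_id"}
        spec = ModelSpec.from_formula(self.model["formula"])
        used = set(spec.columns_used())
        missing = used - available
        if missing:
            raise ValueError(
                f"model references columns the simulation does not produce: "
                f"{sorted(missing)}"
            )
        if "meta" in self.stages and len(self.studies) < 7:
            raise ValueError(
                "the meta stage needs at least 7 studies (5 linear-model "
                "parameters + 2); disable it or add studies"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stable_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = (
            json.loads(path.read_text()) if path.exists() else {"stages": {}, "files": {}}
        )

    def stage_fresh(self, name: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(name)
        if rec is None or rec["key"] != key:
            return False
        for p in outputs:
            if not p.exists() or self.data["files"].get(str(p)) != _sha256(p):
                return False
        return True

    def record(self, name: str, key: str, outputs: list[Path]) -> None:
        self.data["stages"][name] = {"key": key, "outputs": [str(p) for p in outputs]}
        for p in outputs:
            self.data["files"][str(p)] = _sha256(p)

    def save(self, extra: dict) -> None:
        self.data.update(extra)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir`` and return it."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    cfg_dict = asdict(config)
    spec = ModelSpec.from_formula(config.model["formula"])
    terms = config.model.get("terms", "x")

    def stage_key(name: str, upstream: list[Path]) -> str:
        return _stable_hash(
            {
                "config": cfg_dict.get(name, cfg_dict),
                "seed": config.seed,
                "model": config.model,
                "upstream": [manifest.data["files"].get(str(p)) for p in upstream],
            }
        )

    def run_stage(name: str, upstream: list[Path], outputs: list[Path], fn) -> None:
        if name not in config.stages:
            log.info("stage %s disabled", name)
            return
        key = stage_key(name, upstream)
        if manifest.stage_fresh(name, key, outputs):
            log.info("stage %s up to date, skipping", name)
            return
        log.info("stage %s running", name)
        try:
            fn()
        except Exception as exc:
            manifest.save({"failed_stage": name})
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, key, outputs)

    # ---------------------------------------------------------- simulate
    study_paths = [out / f"study_{k:03d}.csv" for k in range(len(config.studies))]

    def do_simulate():
        specs = [SimConfig(**d) for d in config.studies]
        for tab, p in zip(simulate_multistudy_collection(specs, config.seed), study_paths):
            tab.to_csv(p)

    run_stage("simulate", [], study_paths + [p.with_suffix(".meta.json") for p in study_paths], do_simulate)

    # --------------------------------------------------------- harmonize
    harmonized = [out / f"study_{k:03d}.harmonized.csv" for k in range(len(config.studies))]

    def do_harmonize():
        site_cfg = SiteConfig(**config.site) if config.site else None
        for k, (src, dst) in enumerate(zip(study_paths, harmonized)):
            tab = CohortTable.from_csv(src)
            if site_cfg and site_cfg.n_sites > 1:
                tab = inject_site_effects(tab, site_cfg, config.seed + 1000 + k)
                tab = remove_site_effects(tab, spec)
            tab.to_csv(dst)

    run_stage("harmonize", study_paths, harmonized + [p.with_suffix(".meta.json") for p in harmonized], do_harmonize)

    tables_src = harmonized if "harmonize" in config.stages else study_paths

    # --------------------------------------------------------------- fit
    fits_path = out / "fits.json"

    def do_fit():
        records = []
        for k, p in enumerate(tables_src):
            tab = CohortTable.from_csv(p)
            s = ModelSpec(spec.outcome, spec.terms, design=tab.design,
                          observation_weights=spec.observation_weights)
            fit = fit_study_model(tab, s)
            est = effects.resi_for_terms(fit, terms)
            n_boot = int(config.model.get("n_boot", DEFAULTS["n_boot"]))
            ci = effects.bootstrap_resi_ci(
                tab, s, terms, n_boot=n_boot, seed=config.seed + 2000 + k
            )
            se = (ci.ci_high - ci.ci_low) / (2 * 1.959964) if n_boot > 1 else np.nan
            records.append(
                {
                    "study": f"study_{k:03d}",
                    "design": tab.design,
                    "fit": fit.to_json_dict(),
                    "S_hat": est.S_hat,
                    "p": est.p,
                    "SE": se,
                    "ci": [ci.ci_low, ci.ci_high],
                }
            )
        fits_path.write_text(json.dumps(records, indent=1))

    run_stage("fit", list(tables_src), [fits_path], do_fit)

    # ---------------------------------------------------------- sampling
    sampling_summary = out / "sampling_summary.csv"
    sampling_reps = out / "sampling_replicates.csv"

    def do_sampling():
        scfg = config.sampling
        k = int(scfg.get("study", 0))
        tab = CohortTable.from_csv(tables_src[k])
        ages = tab.baseline()["age"].to_numpy()
        winsor = tuple(scfg.get("winsor", np.quantile(ages, [0.05, 0.95])))
        shapes = scfg.get("schemes", ["bell", "uniform", "u_shaped"])
        halfwidth = float(scfg.get("halfwidth", DEFAULTS["halfwidth"]))
        schemes = {}
        for name in shapes:
            shape = sampling.TargetShape(name)
            if tab.design == CROSS_SECTIONAL:
                wt = sampling.cross_sectional_weights(
                    tab.data["age"].to_numpy(), shape, winsor, halfwidth
                )
            else:
                within = sampling.TargetShape(scfg.get("within", "uniform"))
                changes = []
                for _, g in tab.data.groupby("subject_id"):
                    g = g.sort_values("visit_index")
                    changes.extend(g["age"].iloc[1:] - g["age"].iloc[0])
                wwin = tuple(scfg.get("winsor_within",
                                      np.quantile(changes, [0.05, 0.95])))
                wt = sampling.longitudinal_combination_weights(
                    tab, shape, within, winsor, wwin, halfwidth
                )
            schemes[name] = wt
        mspec = ModelSpec(
            spec.outcome, spec.terms,
            design=CROSS_SECTIONAL if tab.design == CROSS_SECTIONAL else LONGITUDINAL,
        )
        res = sampling.run_scheme_experiment(
            tab,
            schemes,
            [int(n) for n in scfg.get("n_grid", [50, 100, 200])],
            mspec,
            terms,
            B=int(scfg.get("B", DEFAULTS["B"])),
            seed=config.seed + 3000,
            alpha=float(config.power.get("alpha", DEFAULTS["alpha"])),
        )
        res.summary.to_csv(sampling_summary, index=False)
        res.replicates.to_csv(sampling_reps, index=False)

    run_stage("sampling", list(tables_src), [sampling_summary, sampling_reps], do_sampling)

    # ------------------------------------------------------------- power
    power_path = out / "power_summary.csv"

    def do_power():
        alpha = float(config.power.get("alpha", DEFAULTS["alpha"]))
        target_r = float(
            config.power.get("replicability_target", DEFAULTS["replicability_target"])
        )
        fits = json.loads(fits_path.read_text())
        rows = []
        if sampling_summary.exists() and "sampling" in config.stages:
            summ = pd.read_csv(sampling_summary)
            reps = pd.read_csv(sampling_reps)
            df_model = fits[int(config.sampling.get("study", 0))]["fit"]["df_model"]
            for _, r in summ.iterrows():
                q = power.PowerQuery(S=max(r["mean_S"], 1e-12), alpha=alpha,
                                     df_model=int(df_model))
                emp = r["power"]
                n_rep = int(
                    ((reps["scheme"] == r["scheme"]) & (reps["n"] == r["n"])).sum()
                )
                lo, hi = power.wilson_interval(int(round(emp * n_rep)), n_rep)
                rows.append(
                    {
                        "scheme": r["scheme"],
                        "n": int(r["n"]),
                        "mean_S": r["mean_S"],
                        "empirical_power": emp,
                        "power_wilson_low": lo,
                        "power_wilson_high": hi,
                        "replicability": emp**2,
                        "n_for_target_replicability": (
                            power.n_for_replicability(q, target_r)
                            if r["mean_S"] > 0 else np.nan
                        ),
                    }
                )
        else:
            # no sampling stage: derive from the full-data fits only
            for rec in fits:
                q = power.PowerQuery(
                    S=max(rec["S_hat"], 1e-12), alpha=alpha,
                    df_model=int(rec["fit"]["df_model"]),
                )
                N = int(rec["fit"]["n_subjects"])
                pw = power.power_ncf(q, N)
                rows.append(
                    {
                        "scheme": "full_data",
                        "study": rec["study"],
                        "n": N,
                        "mean_S": rec["S_hat"],
                        "power": pw,
                        "replicability": power.replicability_from_power(pw),
                        "n_for_target_replicability": (
                            power.n_for_replicability(q, target_r)
                            if rec["S_hat"] > 0 else np.nan
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(power_path, index=False)

    run_stage("power", [fits_path, sampling_summary, sampling_reps], [power_path], do_power)

    # ---------------------------------------------------- between/within
    bw_path = out / "between_within.json"

    def do_bw():
        k = int(config.between_within.get("study", 0))
        tab = CohortTable.from_csv(tables_src[k])
        if tab.design != LONGITUDINAL:
            raise ValueError("between_within stage requires a longitudinal study")
        covariate = config.between_within.get("covariate", "x")
        bw = fit_between_within(tab, covariate, ModelSpec(
            spec.outcome, spec.terms, design=LONGITUDINAL))
        base = CohortTable(
            tab.baseline().reset_index(drop=True), design=CROSS_SECTIONAL,
            covariates=tab.covariates, outcomes=tab.outcomes,
        )
        cs_fit = fit_study_model(
            base, ModelSpec(spec.outcome, spec.terms, design=CROSS_SECTIONAL)
        )
        cs_est = effects.resi_for_terms(cs_fit, covariate)
        long_fit = fit_study_model(
            tab, ModelSpec(spec.outcome, spec.terms, design=LONGITUDINAL)
        )
        single_est = effects.resi_for_terms(long_fit, covariate)
        bw_est = effects.resi_for_terms(bw.fit, "X_bl")
        bw_path.write_text(json.dumps({
            "beta_between": bw.beta_between,
            "beta_within": bw.beta_within,
            "se_between": bw.se_between,
            "se_within": bw.se_within,
            "between_variance": bw.between_variance,
            "within_variance": bw.within_variance,
            "S_baseline_cross_sectional": cs_est.S_hat,
            "S_longitudinal_single_effect": single_est.S_hat,
            "S_between_decomposed": bw_est.S_hat,
        }, indent=1))

    run_stage("between_within", list(tables_src), [bw_path], do_bw)

    # -------------------------------------------------------------- meta
    meta_path = out / "meta.json"

    def do_meta():
        fits = json.loads(fits_path.read_text())
        summaries, ests = [], []
        for k, p in enumerate(tables_src):
            tab = CohortTable.from_csv(p)
            summaries.append(meta.summarize_design(tab))
            rec = fits[k]
            ests.append((rec["S_hat"], max(rec["SE"], 1e-6)))
        # df=3 feature splines need 2 + 3*3 parameters; fall back to linear
        # feature terms for small collections
        spline_df = config.meta.get(
            "spline_df", 3 if len(summaries) >= 13 else None
        )
        mres = meta.fit_meta_regression(
            ests, summaries, model=config.meta.get("model", "age"),
            spline_df=spline_df,
        )
        meta_path.write_text(json.dumps({
            "model": mres.model,
            "coefficients": mres.coefficients.to_dict(),
            "robust_se": mres.robust_se.to_dict(),
            "pvalues": mres.pvalues.to_dict(),
            "bh_pvalues": meta.adjust_pvalues_bh(mres.pvalues.to_numpy()).tolist(),
            "fitted": mres.fitted.tolist(),
        }, indent=1))

    run_stage("meta", [fits_path] + list(tables_src), [meta_path], do_meta)

    manifest.save({"seed": config.seed, "config": cfg_dict})
    return out


def compare_designs_report(run_dir) -> pd.DataFrame:
    """Summary table across schemes and sample sizes from a completed run.

    One row per (scheme, n) with the mean effect size, empirical power and
    replicability, and the sample size needed for the configured target
    replicability; between/within decomposition results are appended as
    pseudo-rows when that stage ran.
    """
    run_dir = Path(run_dir)
    ppath = run_dir / "power_summary.csv"
    if not ppath.exists():
        raise FileNotFoundError(
            "power_summary.csv missing; run the power stage first"
        )
    table = pd.read_csv(ppath)
    bw_path = run_dir / "between_within.json"
    if bw_path.exists():
        bw = json.loads(bw_path.read_text())
        extra = pd.DataFrame(
            [
                {"scheme": "baseline_cross_sectional", "mean_S": bw["S_baseline_cross_sectional"]},
                {"scheme": "longitudinal_single_effect", "mean_S": bw["S_longitudinal_single_effect"]},
                {"scheme": "longitudinal_between_effect", "mean_S": bw["S_between_decomposed"]},
            ]
        )
        table = pd.concat([table, extra], ignore_index=True)
    return table
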