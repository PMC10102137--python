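"""End-to-end orchestration of the analysis pipeline.

Stage order: simulate -> prep -> dimensionality -> mlirt -> trajectories ->
covariates -> validate -> report.  Each stage writes its artefacts plus a
manifest (seed, parameters, output hashes) into its own sub-directory of
the output folder, and stages communicate only through the in-memory bundle
and those files.  One global seed fans out to per-stage generators through
a fixed counter scheme, so toggling a stage never shifts another stage's
random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import class_covariates as cc
from . import dimensionality as dm
from . import item_prep as ip
from . import mlirt as ml
from . import synthetic as syn
from . import trajectories as tr
from . import validation as vd
from .utils import STAGE_IDS

__all__ = ["PipelineConfig", "run_pipeline", "report", "load_config"]

_STAGES = ["simulate", "prep", "dimensionality", "mlirt", "trajectories",
           "covariates", "validate"]


@dataclass
class PipelineConfig:
    """Demo-scale defaults; every block is overridable from a JSON config."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # synthetic cohort (desk-scale demo; SimConfig's own defaults are the
    # full emulated-cohort conditions)
    n_persons: int = 600
    n_waves: int = 8
    item_bank_sizes: tuple = (20, 4)
    missing_rate: float = 0.05
    attrition_hazard: float = 0.08
    # mlirt
    mlirt_variants: tuple = ("a", "d")
    mlirt_n_iter: int = 1200
    mlirt_n_burnin: int = 300
    # trajectories
    gmm_k_range: tuple = (2, 4)
    gmm_n_starts: int = 20
    gmm_n_final: int = 5
    growth_shape: str | None = None  # None -> select by BIC
    run_lcga: bool = True
    verbosity: int = 1

    def sim_config(self) -> syn.SimConfig:
        return syn.SimConfig(
            n_persons=self.n_persons, n_waves=self.n_waves,
            seed=int(np.random.SeedSequence([self.seed, STAGE_IDS["simulate"]])
                     .generate_state(1)[0] % (2**31)),
            item_bank_sizes=tuple(self.item_bank_sizes),
            missing_rate=self.missing_rate,
            attrition_hazard=self.attrition_hazard,
            basis_loadings=tuple(np.round(np.interp(
                np.arange(self.n_waves), [0, self.n_waves - 1], [0, 1]
            ), 6)) if self.n_waves != 8 else syn.SimConfig.basis_loadings,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a JSON key/value config; unknown keys raise."""
    raw = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return PipelineConfig(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, STAGE_IDS[stage]])
               .generate_state(1)[0] % (2**31))


def _write_manifest(stage_dir: Path, stage: str, seed: int, params: dict,
                    files: dict[str, Path]) -> None:
    manifest = {
        "stage": stage, "seed": seed, "params": params,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            k: {"path": str(p), "sha256": hashlib.sha256(
                Path(p).read_bytes()).hexdigest()}
            for k, p in files.items() if Path(p).exists()
        },
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    log = print if config.verbosity else (lambda *a, **k: None)

    def stage_dir(name):
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    # -- simulate -----------------------------------------------------------
    if config.stages.get("simulate", True):
        log("[simulate] generating synthetic cohort")
        d = stage_dir("simulate")
        sim_cfg = config.sim_config()
        cohort = syn.apply_missingness(syn.simulate_cohort(sim_cfg))
        files = syn.write_panel(cohort, d)
        bundle["cohort"] = cohort
        _write_manifest(d, "simulate", sim_cfg.seed,
                        {"n_persons": sim_cfg.n_persons,
                         "n_waves": sim_cfg.n_waves,
                         "item_bank_sizes": list(sim_cfg.item_bank_sizes)},
                        files)
    elif "cohort" not in bundle:
        raise FileNotFoundError("simulate stage disabled and no cohort in bundle")

    cohort = bundle["cohort"]

    # -- prep ---------------------------------------------------------------
    if config.stages.get("prep", True):
        log("[prep] recoding items, applying gates and split")
        d = stage_dir("prep")
        seed = _stage_seed(config.seed, "prep")
        panel = ip.prepare_panel(cohort, seed=seed)
        bundle["panel"] = panel
        elig = pd.DataFrame({
            "person_id": np.arange(cohort.n_persons),
            "baseline_missing_fraction": panel.baseline_missing_fraction,
            "baseline_eligible": panel.baseline_eligible,
        })
        elig = elig.merge(panel.split.rename("split"), how="left",
                          left_on="person_id", right_index=True)
        f = {"eligibility": d / "eligibility.csv"}
        elig.to_csv(f["eligibility"], index=False)
        _write_manifest(d, "prep", seed, {"max_missing": 0.25,
                                          "dev_fraction": 0.70}, f)

    panel = bundle.get("panel")

    # -- dimensionality -----------------------------------------------------
    if config.stages.get("dimensionality", True):
        if panel is None:
            raise FileNotFoundError("dimensionality requires the prep stage")
        log("[dimensionality] polychoric EFA + second-order CFA")
        d = stage_dir("dimensionality")
        seed = _stage_seed(config.seed, "dimensionality")
        dev_ids = panel.split.index[panel.split == "development"].to_numpy()
        val_ids = panel.split.index[panel.split == "validation"].to_numpy()
        dev = panel.baseline_matrix(dev_ids)
        R, keep, dropped_var = dm.polychoric_matrix(dev, panel.n_categories)
        m, scan = dm.select_n_factors(R, len(dev_ids), max_factors=5, seed=seed)
        sol = dm.efa(R, m, seed=seed)
        retained, drop_log = dm.retain_items(sol)
        assignment = np.abs(sol.loadings[retained]).argmax(axis=1)
        val = panel.baseline_matrix(val_ids)[:, keep[retained]]
        fi, lam, gam, heywood = dm.cfa_second_order(
            val, assignment, panel.n_categories[keep[retained]])
        bundle["dimensionality"] = {
            "n_factors": m, "solution": sol, "retained": keep[retained],
            "drop_log": drop_log, "cfa_fit": fi, "general_loadings": gam,
            "heywood": heywood,
        }
        ids = [panel.bank[j].item_id for j in keep]
        loadings = pd.DataFrame(sol.loadings, index=ids,
                                columns=[f"F{i+1}" for i in range(m)])
        f = {"loadings": d / "efa_loadings.csv", "drops": d / "drop_log.csv",
             "fit": d / "fit_report.json"}
        loadings.to_csv(f["loadings"])
        pd.DataFrame([{"item_id": ids[i], "reason": why}
                      for i, why in drop_log]).to_csv(f["drops"], index=False)
        f["fit"].write_text(json.dumps({
            "n_factors": m,
            "cfa": dataclasses.asdict(fi),
            "general_factor_loadings": list(np.round(gam, 4)),
            "heywood": heywood,
        }, indent=2))
        _write_manifest(d, "dimensionality", seed, {"n_factors": m}, f)

    # -- mlirt --------------------------------------------------------------
    if config.stages.get("mlirt", True):
        if panel is None:
            raise FileNotFoundError("mlirt requires the prep stage")
        log(f"[mlirt] fitting variants {config.mlirt_variants}")
        d = stage_dir("mlirt")
        seed = _stage_seed(config.seed, "mlirt")
        fits = {}
        for v in config.mlirt_variants:
            spec = ml.MlirtSpec(variant=v, n_iter=config.mlirt_n_iter,
                                n_burnin=config.mlirt_n_burnin, seed=seed)
            fits[v] = ml.fit_mlirt(panel.responses, panel.n_categories, spec,
                                   include=panel.personwave_eligible,
                                   item_ids=[s.item_id for s in panel.bank])
            log(f"  variant {v}: reliability {fits[v].eap_reliability:.3f}, "
                f"DIC {fits[v].dic:.0f}")
        chosen, sel_log = ml.select_mlirt_model(fits)
        best = fits[chosen]
        scores = ml.rescale_0_100(best.theta_eap)
        bundle["mlirt"] = {"fits": fits, "chosen": chosen, "scores": scores,
                           "selection_log": sel_log}
        n, T = scores.shape
        pidx, tidx = np.nonzero(best.included)
        f = {"scores": d / "scores.csv", "fit": d / "fit_report.json"}
        pd.DataFrame({
            "person_id": pidx, "wave": tidx,
            "theta_eap": best.theta_eap[pidx, tidx],
            "theta_sd": best.theta_sd[pidx, tidx],
            "aha_0_100": scores[pidx, tidx],
        }).to_csv(f["scores"], index=False)
        f["fit"].write_text(json.dumps({
            "chosen_variant": chosen,
            "selection_log": sel_log,
            "variants": {v: {"eap_reliability": fits[v].eap_reliability,
                             "dic": fits[v].dic,
                             "icc_wave": (ml.icc_wave(fits[v])
                                          if fits[v].icc_draws is not None else None),
                             "rhat": fits[v].rhat}
                         for v in fits},
        }, indent=2))
        _write_manifest(d, "mlirt", seed,
                        {"variants": list(config.mlirt_variants),
                         "n_iter": config.mlirt_n_iter}, f)

    # -- trajectories -------------------------------------------------------
    if config.stages.get("trajectories", True):
        if "mlirt" not in bundle:
            raise FileNotFoundError("trajectories requires mlirt scores")
        log("[trajectories] growth curves and mixtures")
        d = stage_dir("trajectories")
        seed = _stage_seed(config.seed, "trajectories")
        scores = bundle["mlirt"]["scores"]
        shape = config.growth_shape
        shape_report = None
        if shape is None:
            shape, shape_report = tr.select_growth_shape(scores, seed=seed)
            log(f"  selected growth shape: {shape}")
        lgcm = tr.fit_lgcm(scores, shape=shape, seed=seed)
        k_lo, k_hi = config.gmm_k_range
        fits = {1: lgcm}
        lcga_fits = {}
        rows = []
        for K in range(k_lo, k_hi + 1):
            spec = tr.GrowthSpec(shape=shape, K=K, seed=seed,
                                 n_starts=config.gmm_n_starts,
                                 n_final=config.gmm_n_final)
            try:
                fits[K] = tr.fit_gmm(scores, spec)
            except RuntimeError as e:
                log(f"  K={K}: {e}")
                continue
            if config.run_lcga:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        lcga_fits[K] = tr.fit_gmm(
                            scores, dataclasses.replace(spec, lcga=True))
                    except RuntimeError:
                        pass
            fk = fits[K]
            p_v, p_a = tr.lmr_tests(fk, fits[K - 1]) if K - 1 in fits else (np.nan, np.nan)
            rows.append({
                "K": K, "aic": fk.fit["aic"], "bic": fk.fit["bic"],
                "ssabic": fk.fit["ssabic"], "entropy": fk.fit["entropy"],
                "vlmr_p": p_v, "adj_lmr_p": p_a,
                "class_sizes": "/".join(map(str, fk.class_counts)),
                "best_seed": fk.start_seeds[0] if fk.start_seeds else None,
            })
        mixture_fits = {K: f for K, f in fits.items() if K >= 2}
        chosen_K, sel_log = tr.select_K(mixture_fits, lcga_fits or None)
        bundle["trajectories"] = {
            "shape": shape, "shape_report": shape_report, "lgcm": lgcm,
            "fits": fits, "chosen_K": chosen_K, "selection_log": sel_log,
            "selection_table": pd.DataFrame(rows),
        }
        f = {"selection": d / "model_selection.csv",
             "report": d / "fit_report.json"}
        pd.DataFrame(rows).to_csv(f["selection"], index=False)
        best = fits[chosen_K]
        f["report"].write_text(json.dumps({
            "growth_shape": shape, "chosen_K": chosen_K,
            "selection_log": sel_log,
            "class_proportions": list(np.round(best.pi, 4)),
            "class_means": best.mu.round(3).tolist(),
            "basis_loadings": list(np.round(best.basis, 4)),
            "entropy": best.fit["entropy"],
            "avg_posterior": list(np.round(best.avg_posterior, 3)),
            "best_start_seeds": best.start_seeds[:2],
        }, indent=2))
        _write_manifest(d, "trajectories", seed,
                        {"k_range": list(config.gmm_k_range), "shape": shape}, f)

    # -- covariates (three-step) -------------------------------------------
    if config.stages.get("covariates", True):
        if "trajectories" not in bundle:
            raise FileNotFoundError("covariates requires the trajectories stage")
        log("[covariates] three-step multinomial model")
        d = stage_dir("covariates")
        seed = _stage_seed(config.seed, "covariates")
        best = bundle["trajectories"]["fits"][bundle["trajectories"]["chosen_K"]]
        W, Q = cc.step2_classify(best.posterior)
        X = syn.covariate_design(cohort.covariates)
        growth_est = np.einsum("ik,ikq->iq", best.posterior,
                               _eta_posterior_means(bundle["mlirt"]["scores"], best))
        res = cc.step3_fit(W, Q, X, distal_outcome=cohort.distal_outcome,
                           growth_estimates=growth_est)
        table4 = cc.class_descriptives(W, cohort.covariates)
        bundle["covariates"] = {"assignments": W, "Q": Q, "result": res,
                                "descriptives": table4}
        f = {"coefficients": d / "class_regression.csv",
             "descriptives": d / "class_descriptives.csv",
             "distal": d / "distal_outcome.csv"}
        res.coefficients.to_csv(f["coefficients"], index=False)
        table4.to_csv(f["descriptives"], index=False)
        if res.distal is not None:
            res.distal.to_csv(f["distal"], index=False)
        _write_manifest(d, "covariates", seed,
                        {"reference_class": int(res.reference_class)}, f)

    # -- validate -----------------------------------------------------------
    if config.stages.get("validate", True):
        if "mlirt" not in bundle:
            raise FileNotFoundError("validate requires mlirt scores")
        log("[validate] adjusted AUC and mixed models")
        d = stage_dir("validate")
        seed = _stage_seed(config.seed, "validate")
        scores = bundle["mlirt"]["scores"]
        base = scores[:, 0]
        roc = vd.adjusted_auc(base, cohort.distal_outcome,
                              stratum=cohort.covariates["female"].to_numpy(),
                              n_boot=500, seed=seed)
        lmm_panel = _behaviour_panel(cohort, scores)
        fixed = ["time", "age", "female", "nonwhite",
                 "smoke_former", "smoke_current", "alc_low", "alc_high",
                 "act_mild", "act_moderate", "act_vigorous"]
        fit0 = vd.fit_lmm(lmm_panel, fixed=fixed, random_slope=False)
        fit1 = vd.fit_lmm(lmm_panel, fixed=fixed, random_slope=True)
        chi2, p = vd.lrt_nested(fit0, fit1, df=1)
        bundle["validate"] = {"roc": roc, "lmm0": fit0, "lmm1": fit1,
                              "lrt": (chi2, p)}
        f = {"roc": d / "roc_report.json", "lmm": d / "lmm_report.csv"}
        f["roc"].write_text(json.dumps({
            "auc": roc.auc, "ci": roc.ci, "n_cases": roc.n_cases,
            "n_controls": roc.n_controls, "stratum": roc.stratum_variable,
        }, indent=2))
        fit1.fixed_effects.assign(model="random_slope").to_csv(f["lmm"], index=False)
        _write_manifest(d, "validate", seed, {"lrt_chi2": chi2, "lrt_p": p}, f)

    report(bundle, out / "report.md")
    return bundle


def _eta_posterior_means(scores, fit) -> np.ndarray:
    """Per-person, per-class conditional growth-factor means under the fit."""
    Y = np.asarray(scores, dtype=float)
    n, T = Y.shape
    K, q = fit.spec.K, fit.spec.q
    out = np.tile(fit.mu[None, :, :], (n, 1, 1))
    if not np.any(fit.psi):
        return out
    for obs, rows in tr._patterns(Y):
        if not obs.any():
            continue
        Lo = fit.loadings[obs]
        S = Lo @ fit.psi @ Lo.T + np.diag(fit.sigma2[obs])
        A = fit.psi @ Lo.T @ np.linalg.inv(S)
        Yo = Y[np.ix_(rows, np.flatnonzero(obs))]
        for k in range(K):
            out[rows, k] = fit.mu[k] + (Yo - (Lo @ fit.mu[k])[None, :]) @ A.T
    return out


def _behaviour_panel(cohort, scores) -> pd.DataFrame:
    """Long person-wave frame of scores, behaviours and covariates for the
    mixed-model sensitivity analysis (complete cases handled downstream)."""
    n, T = scores.shape
    pid = np.repeat(np.arange(n), T)
    wave = np.tile(np.arange(T), n)
    cov = cohort.covariates
    beh = cohort.behaviours or {}
    df = pd.DataFrame({
        "person_id": pid, "wave": wave,
        "time": wave * 2.0,  # biennial waves, in years
        "aha": scores[pid, wave],
        "age": cov["age"].to_numpy()[pid] + wave * 2.0,
        "female": cov["female"].to_numpy()[pid].astype(float),
        "nonwhite": cov["nonwhite"].to_numpy()[pid].astype(float),
    })
    if beh:
        smoke = beh["smoking"][pid, wave]
        alc = beh["alcohol"][pid, wave]
        act = beh["activity"][pid, wave]
        df["smoke_former"] = (smoke == 1).astype(float)
        df["smoke_current"] = (smoke == 2).astype(float)
        df["alc_low"] = (alc == 1).astype(float)
        df["alc_high"] = (alc == 2).astype(float)
        df["act_mild"] = (act == 1).astype(float)
        df["act_moderate"] = (act == 2).astype(float)
        df["act_vigorous"] = (act == 3).astype(float)
    return df


def report(bundle: dict, path: str | Path | None = None) -> str:
    """Markdown summary with analogues of the five result tables; missing
    stages are flagged rather than fatal."""
    lines = ["# Pipeline report", ""]
    if "mlirt" in bundle:
        lines += ["## Measurement model (variant comparison)", ""]
        fits = bundle["mlirt"]["fits"]
        lines.append("| variant | EAP reliability | DIC |")
        lines.append("|---|---|---|")
        for v in sorted(fits):
            f = fits[v]
            lines.append(f"| {v} | {f.eap_reliability:.3f} | {f.dic:.0f} |")
        lines.append(f"\nChosen variant: **{bundle['mlirt']['chosen']}**\n")
    else:
        lines.append("_Measurement stage missing._\n")
    if "trajectories" in bundle:
        t = bundle["trajectories"]
        lines += ["## Mixture model selection", "",
                  t["selection_table"].to_markdown(index=False), "",
                  f"Chosen number of classes: **{t['chosen_K']}** "
                  f"(growth shape: {t['shape']})", ""]
        best = t["fits"][t["chosen_K"]]
        lines += ["## Growth-factor estimates by class", ""]
        lines.append("| class | share | mean intercept | mean slope |")
        lines.append("|---|---|---|---|")
        for k in range(best.spec.K):
            lines.append(f"| {k} | {best.pi[k]:.3f} | {best.mu[k, 0]:.2f} | "
                         f"{best.mu[k, 1]:.2f} |")
        lines.append("")
    else:
        lines.append("_Trajectory stage missing._\n")
    if "covariates" in bundle:
        res = bundle["covariates"]["result"]
        lines += ["## Socio-economic predictors of class membership", "",
                  res.coefficients.round(3).to_markdown(index=False), ""]
        if res.distal is not None:
            lines += ["## Distal outcome by class", "",
                      res.distal.round(3).to_markdown(index=False), ""]
    else:
        lines.append("_Covariate stage missing._\n")
    if "validate" in bundle:
        v = bundle["validate"]
        roc = v["roc"]
        chi2, p = v["lrt"]
        lines += ["## Sensitivity analyses", "",
                  f"Sex-adjusted AUC (baseline score vs final-wave outcome): "
                  f"{roc.auc:.3f} (95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f})",
                  f"Random-slope LRT: chi2(1) = {chi2:.2f}, p = {p:.3g}", "",
                  v["lmm1"].fixed_effects.round(3).to_markdown(index=False), ""]
    else:
        lines.append("_Validation stage missing._\n")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
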