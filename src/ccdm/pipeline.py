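"""Orchestration: simulate -> preprocess -> stats -> curves -> DDM -> report.

Each stage writes delimited-text tables into the run directory and the
run manifest records the configuration, seeds and input hash, so any
table can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, design, hbayes, learning_curve, synthetic_data

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure wrapper naming the stage; partial outputs stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either ``scenario`` (synthetic cohort) or ``input_path`` (existing
    trial table, e.g. a download of the deposited study data) must be
    set.  The default MCMC budget is reduced for desk-scale runs; the
    study-scale budget (15000/5000) is available by raising ``mcmc``.
    """

    out_dir: str
    scenario: str | None = "paper_like"
    input_path: str | None = None
    seed: int = 0
    n_subjects: int = 14
    mcmc: dict = field(default_factory=lambda: {"n_draws": 2000, "n_burn_in": 500, "n_chains": 2})
    model_ids: tuple[int, ...] = (1, 9)
    n_boot: int = 500
    run_ddm: bool = True
    run_bootstrap: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "model_ids" in raw:
            raw["model_ids"] = tuple(raw["model_ids"])
        return cls(**raw)


def _write(df: pd.DataFrame, out: Path, name: str) -> None:
    df.to_csv(out / name, index=False)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Stages: cohort simulation or loading, trial filtering for both
    purposes, epoch aggregation + contextual-cueing + ANOVAs, joint
    exponential learning-curve fits with scatter indices and bootstrap
    amplitude CIs, hierarchical DDM fits with DIC comparison, the named
    drift/boundary contrasts, and a posterior predictive table.
    Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(config), "model_ids": list(config.model_ids)}, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - stage context is the point
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return result

        return deco

    @stage("simulate")
    def trials() -> pd.DataFrame:
        if config.input_path:
            tbl = pd.read_csv(config.input_path)
        else:
            truth = synthetic_data.default_ground_truth(
                config.scenario, n_subjects=config.n_subjects
            )
            truth.to_records().to_csv(out / "ground_truth.csv", index=False)
            tbl = synthetic_data.simulate_cohort(truth, seed=config.seed)
            _write(tbl, out, "trials.csv")
        manifest["input_hash"] = _hash_frame(tbl)
        return tbl

    @stage("preprocess")
    def filtered():
        rt_tbl, rt_rep = behavior.filter_trials(trials, purpose="rt_analysis")
        ddm_tbl, ddm_rep = behavior.filter_trials(trials, purpose="ddm")
        _write(
            pd.concat([rt_rep.to_frame(), ddm_rep.to_frame()], ignore_index=True),
            out,
            "exclusion_report.csv",
        )
        return rt_tbl, rt_rep, ddm_tbl, ddm_rep

    rt_tbl, rt_rep, ddm_tbl, ddm_rep = filtered

    @stage("behavior")
    def behav():
        epochs_rt = behavior.aggregate_epochs(rt_tbl)
        epochs_acc = behavior.aggregate_epochs(ddm_tbl)  # errors retained
        _write(epochs_rt, out, "epochs_rt.csv")
        _write(epochs_acc, out, "epochs_accuracy.csv")
        cc_subject, cc_summary = behavior.contextual_cueing(epochs_rt)
        _write(cc_subject, out, "cc_per_subject.csv")
        _write(cc_summary, out, "cc_summary.csv")
        anova_rt = behavior.rm_anova(
            epochs_rt, dv="rt_ms", within=["trial_type", "configuration", "epoch"]
        )
        anova_acc = behavior.rm_anova(
            epochs_acc, dv="accuracy", within=["trial_type", "configuration", "epoch"]
        )
        _write(anova_rt, out, "anova_rt.csv")
        _write(anova_acc, out, "anova_accuracy.csv")
        return epochs_rt, epochs_acc, cc_subject, cc_summary

    epochs_rt, epochs_acc, cc_subject, cc_summary = behav

    @stage("curves")
    def curves():
        group_means = epochs_rt.groupby(
            ["trial_type", "configuration", "epoch"], as_index=False
        )["rt_ms"].mean()
        fit = learning_curve.fit_exponential(group_means)
        fit_table = fit.to_frame()
        _write(fit_table, out, "learning_fits.csv")
        observed = {}
        for (tt, cfg), grp in group_means.groupby(["trial_type", "configuration"]):
            observed[(tt, cfg)] = grp.sort_values("epoch")["rt_ms"].to_numpy()
        rows, curve_rows = [], []
        for tt in sorted(epochs_rt["trial_type"].unique()):
            curve = learning_curve.cc_curve(fit, tt)
            quality = learning_curve.trial_type_scatter_index(fit, observed, tt)
            rows.append(
                {
                    "trial_type": tt,
                    "amplitude_ms": curve.amplitude,
                    "rmse": quality.rmse,
                    "si_percent": quality.si_percent,
                }
            )
            for g, val in zip(curve.grid, curve.values):
                curve_rows.append({"trial_type": tt, "epoch": g, "cc_ms": val})
        cc_fit = pd.DataFrame(rows)
        _write(cc_fit, out, "cc_curve_fits.csv")
        _write(pd.DataFrame(curve_rows), out, "cc_curves.csv")
        ci = None
        if config.run_bootstrap:
            ci = learning_curve.amplitude_ci(
                epochs_rt, n_boot=config.n_boot, seed=config.seed + 1
            )
            _write(ci, out, "amplitude_ci.csv")
        return fit, cc_fit, ci

    fit, cc_fit, ci = curves

    ddm_results = None
    if config.run_ddm:

        @stage("ddm")
        def ddm():
            specs = {s.model_id: s for s in hbayes.build_model_space()}
            comparisons, fits = [], {}
            for mid in config.model_ids:
                samples = hbayes.fit_hierarchical(
                    specs[mid], ddm_tbl, mcmc={**config.mcmc, "seed": config.seed + mid}
                )
                fits[mid] = samples
                comparisons.append(hbayes.compute_dic(samples, ddm_tbl).to_dict())
            comp = pd.DataFrame(comparisons).sort_values("dic").reset_index(drop=True)
            comp["delta_dic_vs_best"] = comp["dic"] - comp["dic"].min()
            if 1 in set(config.model_ids):
                base = comp.loc[comp["model_id"] == 1, "dic"].iloc[0]
                comp["delta_dic_vs_baseline"] = comp["dic"] - base
            _write(comp, out, "dic_table.csv")

            contrast_rows = []
            for mid, samples in fits.items():
                if samples.spec.dependence["v"] == hbayes.BY_CONDITION:
                    for param in ("v", "t"):
                        if samples.spec.dependence[param] != hbayes.BY_CONDITION:
                            continue
                        res = hbayes.old_new_contrast(samples, param)
                        contrast_rows.append(
                            {"model_id": mid, "contrast": res.description, "p_percent": res.p_percent}
                        )
                if samples.spec.dependence["a"] == hbayes.EPOCH_COVARIATE:
                    for c in range(hbayes.N_CELLS):
                        col = hbayes.cell_columns(samples, "a", which="beta1")[c]
                        res = hbayes.posterior_probability(
                            samples, {col: -1.0}, description=f"{col} < 0"
                        )
                        contrast_rows.append(
                            {"model_id": mid, "contrast": res.description, "p_percent": res.p_percent}
                        )
            contrasts = pd.DataFrame(contrast_rows)
            _write(contrasts, out, "contrasts.csv")

            best_id = int(comp.iloc[0]["model_id"])
            ppc = hbayes.posterior_predictive(
                fits[best_id], ddm_tbl, n_rep=10, seed=config.seed + 99
            )
            _write(ppc, out, "posterior_predictive.csv")
            for mid, samples in fits.items():
                samples.group_draws.to_csv(out / f"posterior_draws_m{mid:02d}.csv", index=False)
                with open(out / f"run_manifest_m{mid:02d}.json", "w") as fh:
                    json.dump(samples.manifest(), fh, indent=2, default=str)
            return comp, contrasts, ppc, fits

        ddm_results = ddm

    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "manifest": manifest,
        "trials": trials,
        "exclusions": {"rt_analysis": rt_rep, "ddm": ddm_rep},
        "epochs_rt": epochs_rt,
        "epochs_accuracy": epochs_acc,
        "cc_summary": cc_summary,
        "learning_fit": fit,
        "cc_fit": cc_fit,
        "amplitude_ci": ci,
        "ddm": ddm_results,
    }
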