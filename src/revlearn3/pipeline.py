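"""End-to-end analysis pipeline: behavioural statistics, model comparison,
drug-effect inference, posterior-predictive validation, optimal learning
rate.  Thin orchestration over the library; every stage writes a plain
table and is recorded in the run manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, simulate
from .cohort import CohortSpec, generate_cohort
from .fitting import extract_subject_parameters, fit_subjects, parameter_summary
from .hbi import HBI
from .io import RunManifest, read_subjects, read_trials, write_subjects, write_trials
from .models import BASE_MODELS, DRUG_MODELS, get_model
from .task import TaskConfig

__all__ = ["run_pipeline"]

DEFAULTS = {
    "seed": 0,
    "models_base": list(BASE_MODELS),
    "models_drug": list(DRUG_MODELS),
    "n_agents": 100,
    "n_restarts": 8,
    "hbi_max_iter": 12,
    "rt_filter_ms": 200.0,
    "phi_grid": [round(x, 2) for x in np.arange(0.05, 1.0, 0.05)],
    "optimal_lr_sims": 300,
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis described by ``config`` into ``out_dir``.

    ``config`` must contain either ``trials`` (+ optional ``subjects``)
    paths, or ``cohort`` generator settings.  Returns a dict of headline
    results; every artefact is also written to disk.  Any stage failure
    raises with the stage named.
    """
    cfg = {**DEFAULTS, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ["cohort", "fit_base", "fit_drug", "fit_subject", "ppc", "optlr"],
        ss.spawn(6))}
    manifest = RunManifest(command="run_pipeline", seeds={"master": seed, **stage_seeds},
                           config_hash=RunManifest.hash_config(cfg))
    manifest.start(out / "manifest.json")
    results: dict = {}

    def stage(name):
        manifest.record_stage(name)

    try:
        stage("load_data")
        task_config = TaskConfig(**cfg.get("task", {})) if cfg.get("task") else TaskConfig()
        if "trials" in cfg:
            subjects = read_subjects(cfg["subjects"]) if cfg.get("subjects") else None
            dataset = read_trials(cfg["trials"], task_config, subjects)
            manifest.inputs["trials"] = str(cfg["trials"])
        else:
            spec = CohortSpec(**{"config": task_config, **cfg.get("cohort", {})})
            dataset, subjects, truth = generate_cohort(spec, stage_seeds["cohort"])
            write_trials(dataset, out / "trials.csv")
            write_subjects(subjects, out / "subjects.csv")
            truth.to_json(out / "truth.json")

        stage("rt_filter")
        n_excluded = sum(behaviour.filter_fast_rt(s, cfg["rt_filter_ms"])[1]
                         for sessions in dataset for s in sessions)
        results["n_fast_rt_trials"] = n_excluded

        stage("behaviour_stats")
        acc = behaviour.accuracy_table(dataset)
        acc.to_csv(out / "accuracy.csv", index=False)
        anova = behaviour.rm_anova(acc)
        anova.to_csv(out / "anova.csv", index=False)
        simple = behaviour.simple_effects(acc, split_by="phase")
        for level, rep in simple.items():
            rep.to_csv(out / f"simple_effects_{level}.csv", index=False)
        results["anova"] = anova

        stage("base_model_hbi")
        base_specs = [get_model(m) for m in cfg["models_base"]]
        hbi_base = HBI(dataset, base_specs, seed=stage_seeds["fit_base"]).fit(
            max_iter=cfg["hbi_max_iter"])
        hbi_base.summary().to_csv(out / "base_comparison.csv", index=False)
        results["base_comparison"] = hbi_base.summary()
        winner_base = hbi_base.model_names[int(np.argmax(hbi_base.pxp))]
        results["winning_base_model"] = winner_base

        stage("drug_model_hbi")
        drug_specs = [get_model(m) for m in cfg["models_drug"]]
        hbi_drug = HBI(dataset, drug_specs, seed=stage_seeds["fit_drug"]).fit(
            max_iter=cfg["hbi_max_iter"])
        hbi_drug.summary().to_csv(out / "drug_comparison.csv", index=False)
        results["drug_comparison"] = hbi_drug.summary()
        winner_drug = hbi_drug.model_names[int(np.argmax(hbi_drug.pxp))]
        results["winning_drug_model"] = winner_drug

        stage("parameter_inference")
        infer_model = get_model(cfg.get("inference_model", "EWA+F+dphi"))
        fits = fit_subjects(infer_model, dataset, seed=stage_seeds["fit_subject"],
                            n_restarts=cfg["n_restarts"])
        params = extract_subject_parameters(fits)
        sids = [sess[0].subject_id for sess in dataset]
        params.index = pd.Index(sids, name="subject")
        params.to_csv(out / "subject_params.csv")
        parameter_summary(params).to_csv(out / "param_summary.csv")
        cov = acc.groupby("subject")[["wm_span", "bis"]].first()
        perf = behaviour.performance_change(acc)
        split = infer_model.split_param or "phi"
        stats = behaviour.parameter_change_stats(params, cov, perf, param=split)
        (out / "param_stats.json").write_text(json.dumps(stats, indent=1))
        results["parameter_stats"] = stats

        stage("posterior_predictive")
        ppc = simulate.posterior_predictive(fits, task_config,
                                            n_agents=cfg["n_agents"],
                                            seed=stage_seeds["ppc"])
        sim_acc = ppc.accuracy_table()
        sim_acc.to_csv(out / "ppc_accuracy.csv", index=False)
        sim_anova = behaviour.rm_anova(sim_acc)
        sim_anova.to_csv(out / "ppc_anova.csv", index=False)
        results["ppc_anova"] = sim_anova

        stage("optimal_learning_rate")
        ref = parameter_summary(params)["median"].to_dict()
        ref = {"rho": ref.get("rho", 0.63), "beta": ref.get("beta", 4.2),
               "alpha_f": ref.get("alpha_f", 0.35)}
        curves = {}
        for label, tc in (("3-option", task_config),
                          ("2-option", simulate.two_option_config(
                              task_config.n_trials, task_config.reversal_trial))):
            curves[label] = simulate.optimal_learning_rate_curve(
                tc, ref, cfg["phi_grid"], n_sims=cfg["optimal_lr_sims"],
                seed=stage_seeds["optlr"], label=label)
        pd.DataFrame({
            "phi": curves["3-option"].phi_grid,
            "accuracy_3option": curves["3-option"].accuracy,
            "accuracy_2option": curves["2-option"].accuracy,
            "reward_3option": curves["3-option"].mean_reward,
            "reward_2option": curves["2-option"].mean_reward,
        }).to_csv(out / "optimal_lr.csv", index=False)
        results["optimal_phi"] = {k: c.argmax_phi() for k, c in curves.items()}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {manifest.stages[-1]!r} failed: {exc}") from exc

    manifest.outputs = {p.name: str(p) for p in sorted(out.iterdir())}
    manifest.finish(out / "manifest.json")
    results["manifest"] = manifest
    return results
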