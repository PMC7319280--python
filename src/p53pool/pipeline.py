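"""Config-driven pipeline tying the stages together.

Stages: ``generate`` synthetic calibration/perturbation datasets →
``features`` per-cell dynamic features → ``cluster`` subpopulations and
peak-based means → ``calibrate`` the model pool → ``screen`` sensitivity
combinations → ``infer`` perturbation fold changes → ``validate``
time-variant onsets and qualitative filters → ``report`` tables and
figures.  Every run writes the resolved configuration and seed next to its
outputs so stochastic stages regenerate bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from typing import Sequence

from . import io as pio
from .calibration import CalibrationConfig, ModelPoolCalibration
from .clustering import (ClusterFeatureSummary, PeakBasedMean, assign_to_clusters,
                         assignment_percentages, cluster_weights, peak_based_mean,
                         select_cluster_count)
from .parameters import REFERENCE_PARAMETERS
from .pool import ModelPool
from .screen import (enumerate_combinations, condensed_report,
                     fit_combination, group_mechanisms, match_expected_pattern,
                     qualitative_filters, rank_combinations, validate_time_variant)
from .synthetic import (GeneratorConfig, default_pool, generate_calibration_cells,
                        generate_perturbed_cells, inhibition_triplet)
from .trajectories import features_dataframe

__all__ = ["default_config", "run_pipeline", "export_report"]

log = logging.getLogger("p53pool")

ALL_STAGES = ("generate", "features", "cluster", "calibrate",
              "screen", "infer", "validate", "report")


def default_config(output_dir: str = "p53pool_run", seed: int = 0) -> dict[str, Any]:
    """Demo-scale pipeline configuration (small synthetic dataset)."""
    return {
        "output_dir": output_dir,
        "seed": seed,
        "stages": list(ALL_STAGES),
        "generate": {
            "n_subpopulations": 3,
            "n_cells": 60,
            "jitter_sd": 0.005,
            "noise_cv": 0.02,
            "perturbation_strength": 0.3,
            "validation_onsets": [1.5, 5.0],
        },
        "features": {"sigma": 0.5, "max_peaks": 4},
        "cluster": {"k_min": 2, "k_max": 6},
        "calibrate": {"n_starts": 1, "max_nfev": 40, "fit_shared": False},
        "screen": {"delta": 0.01, "min_subpopulations": 2,
                   "parameters": ["beta_s", "alpha_s", "alpha_mpi",
                                  "alpha_m", "beta_sp", "alpha_mpa"]},
        "infer": {
            "t_inh": -1.0,
            "candidates": [["alpha_mpi", "alpha_m", "beta_sp"],
                           ["alpha_mpa", "alpha_sm", "beta_sp"],
                           ["beta_wt", "alpha_wt"]],
            "top_n": 30,
        },
    }


def _condition_targets(cells, assignment: pd.DataFrame, k_star: int,
                       sigma: float = 0.5) -> dict[int, PeakBasedMean]:
    """Peak-based means of assigned cells, keyed by calibration cluster."""
    out: dict[int, PeakBasedMean] = {}
    for k in range(1, k_star + 1):
        ids = set(assignment.loc[assignment["cluster"] == k, "cell_id"])
        members = [c for c in cells if c.cell_id in ids]
        if members:
            out[k] = peak_based_mean(members, cluster=k, sigma=sigma)
    return out


def _restrict_pool(pool: ModelPool, by_cluster: dict[int, PeakBasedMean]):
    """Sub-pool over the clusters that actually received cells."""
    idx = [k - 1 for k in sorted(by_cluster)]
    sub = ModelPool(shared=pool.shared, modifiers=pool.modifiers[idx],
                    weights=pool.weights[idx] / pool.weights[idx].sum(),
                    scale=pool.scale, offset=pool.offset)
    return sub, [by_cluster[k] for k in sorted(by_cluster)]


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute the selected stages; returns the in-memory results bundle."""
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    pio.save_config(config, out / "resolved_config.yaml")
    stages = config.get("stages", list(ALL_STAGES))
    seed = int(config.get("seed", 0))
    results: dict[str, Any] = {"config": config}
    t_start = time.time()

    gen = config["generate"]
    pool_true = default_pool(gen["n_subpopulations"])
    strength = gen.get("perturbation_strength", 0.3)
    planted = inhibition_triplet(strength, -1.0)

    if "generate" in stages:
        log.info("stage generate: %d cells", gen["n_cells"])
        cal_cfg = GeneratorConfig(pool=pool_true, n_cells=gen["n_cells"],
                                  jitter_sd=gen["jitter_sd"], noise_cv=gen["noise_cv"],
                                  seed=seed)
        cells, truth = generate_calibration_cells(cal_cfg)
        pert_cfg = GeneratorConfig(pool=pool_true, n_cells=gen["n_cells"],
                                   jitter_sd=gen["jitter_sd"], noise_cv=gen["noise_cv"],
                                   seed=seed + 1, perturbations=planted)
        pcells, ptruth = generate_perturbed_cells(pert_cfg)
        pio.save_trajectories(cells, out / "calibration_trajectories.csv")
        pio.save_trajectories(pcells, out / "perturbation_trajectories.csv")
        (out / "ground_truth.json").write_text(json.dumps(
            {"calibration": truth.to_dict(), "perturbation": ptruth.to_dict()}, indent=2))
        results.update(cells=cells, pcells=pcells, truth=truth)
    else:
        cells = pio.load_trajectories(out / "calibration_trajectories.csv")
        pcells = pio.load_trajectories(out / "perturbation_trajectories.csv")
        results.update(cells=cells, pcells=pcells)

    feat_cfg = config.get("features", {})
    if "features" in stages:
        log.info("stage features")
        feats = features_dataframe(cells, sigma=feat_cfg.get("sigma", 0.5),
                                   max_peaks=feat_cfg.get("max_peaks", 4))
        pfeats = features_dataframe(pcells, sigma=feat_cfg.get("sigma", 0.5),
                                    max_peaks=feat_cfg.get("max_peaks", 4))
        feats.to_csv(out / "features_calibration.csv", index=False)
        pfeats.to_csv(out / "features_perturbation.csv", index=False)
        results.update(features=feats, pfeatures=pfeats)

    if "cluster" in stages:
        cl = config.get("cluster", {})
        log.info("stage cluster")
        k_star, labels, scores = select_cluster_count(
            cells, range(cl.get("k_min", 2), cl.get("k_max", 15) + 1))
        scores.to_csv(out / "cluster_scores.csv", index=False)
        pd.DataFrame({"cell_id": [c.cell_id for c in cells],
                      "cluster": labels}).to_csv(out / "clusters.csv", index=False)
        targets = [
            peak_based_mean([c for c, l in zip(cells, labels) if l == k],
                            cluster=k, sigma=feat_cfg.get("sigma", 0.5))
            for k in range(1, k_star + 1)
        ]
        pio.save_peak_based_means(targets, out / "peak_based_means.json")
        # assignment of the perturbation condition to calibration clusters
        summary = ClusterFeatureSummary.from_features(
            results["features"], labels, [c.cell_id for c in cells])
        assignment = assign_to_clusters(pcells, summary)
        assignment.to_csv(out / "assignment.csv", index=False)
        ptargets = _condition_targets(pcells, assignment, k_star,
                                      sigma=feat_cfg.get("sigma", 0.5))
        results.update(k_star=k_star, labels=labels, targets=targets,
                       ptargets=ptargets, assignment=assignment,
                       cluster_summary=summary)

    cal_conf = CalibrationConfig(max_nfev=config.get("calibrate", {}).get("max_nfev", 60))
    if "calibrate" in stages:
        cal = config.get("calibrate", {})
        log.info("stage calibrate")
        model = ModelPoolCalibration(results["targets"],
                                     shared_init=REFERENCE_PARAMETERS,
                                     config=cal_conf,
                                     fit_shared=cal.get("fit_shared", False))
        fit = model.fit(n_starts=cal.get("n_starts", 1), seed=seed)
        pio.save_pool(fit.pool, out / "calibrated_pool.json")
        (out / "calibration_summary.txt").write_text(fit.summary())
        results.update(calibration=fit, pool=fit.pool)

    if "screen" in stages:
        sc = config.get("screen", {})
        log.info("stage screen")
        combos = enumerate_combinations(sc.get("parameters", ["beta_s", "alpha_mpi"]),
                                        size=2)
        report = condensed_report(results["pool"], combos,
                                  delta=sc.get("delta", 0.01), config=cal_conf)
        report.to_csv(out / "sensitivity_condensed.csv", index=False)
        matched = match_expected_pattern(report, combos,
                                         sc.get("min_subpopulations", 7))
        (out / "matched_combinations.json").write_text(
            json.dumps([m.label for m in matched], indent=2))
        results.update(sensitivity=report, matched=matched)

    if "infer" in stages:
        inf = config.get("infer", {})
        log.info("stage infer")
        sub_pool, sub_targets = _restrict_pool(results["pool"], results["ptargets"])
        fits = [
            fit_combination(sub_pool, tuple(cand), sub_targets,
                            t_inh=inf.get("t_inh", -1.0), config=cal_conf)
            for cand in inf.get("candidates", [])
        ]
        ranked = rank_combinations(fits, top_n=inf.get("top_n", 30))
        results.update(fits=fits, ranked=ranked, infer_pool=sub_pool)

    if "validate" in stages:
        log.info("stage validate")
        onsets = gen.get("validation_onsets", [1.5, 5.0])
        datasets: dict[float, dict[int, PeakBasedMean]] = {}
        for i, onset in enumerate(onsets):
            vcfg = GeneratorConfig(pool=pool_true, n_cells=gen["n_cells"],
                                   jitter_sd=gen["jitter_sd"], noise_cv=gen["noise_cv"],
                                   seed=seed + 100 + i,
                                   perturbations=inhibition_triplet(strength, onset))
            vcells, _ = generate_perturbed_cells(vcfg)
            vassign = assign_to_clusters(vcells, results["cluster_summary"])
            datasets[onset] = _condition_targets(vcells, vassign, results["k_star"])
        validated = []
        for fit in results["ranked"]:
            per_onset: dict[float, Sequence[PeakBasedMean]] = {}
            vpool = None
            for onset, by_cluster in datasets.items():
                pool_o, targets_o = _restrict_pool(results["pool"], by_cluster)
                per_onset[onset] = (pool_o, targets_o)
            if per_onset:
                validation = {}
                for onset, (pool_o, targets_o) in per_onset.items():
                    from .calibration import weighted_chi2
                    chi2, _ = weighted_chi2(pool_o, targets_o, cal_conf,
                                            perturbations=fit.perturbations(t_inh=onset))
                    validation[onset] = chi2
                fit.validation = validation
                fit.summarized_log10_chi2 = float(
                    np.sum([np.log10(max(v, cal_conf.log_chi2_floor))
                            for v in validation.values()]))
            fit.filter_verdicts = qualitative_filters(
                results["pool"], fit.perturbations(), config=cal_conf)
            validated.append(fit)
        survivors = [f for f in validated if f.filter_verdicts.get("pass_all")]
        groups = group_mechanisms(survivors if survivors else validated)
        results.update(validated=validated, mechanisms=groups)

    if "report" in stages:
        export_report(results, out)
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return results


def export_report(results: dict[str, Any], out: Path | str) -> None:
    """Write ranking tables, mechanism groups and figures."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if "ranked" in results or "validated" in results:
        fits = results.get("validated") or results.get("ranked") or []
        table = pd.DataFrame([
            {"combination": f.label,
             "pi": json.dumps([round(float(v), 4) for v in f.pi]),
             "chi2": f.chi2, "log10_chi2": f.log10_chi2,
             **{f"chi2_tinh_{o:g}h": v for o, v in (f.validation or {}).items()},
             "summarized_log10_chi2": f.summarized_log10_chi2,
             "pass_filters": f.filter_verdicts.get("pass_all")}
            for f in sorted(fits, key=lambda f: (f.chi2, f.label))
        ])
        table.to_csv(out / "combination_ranking.csv", index=False)
        if not table.empty and np.isfinite(table["chi2"]).all():
            from .plotting import plot_ranking
            plot_ranking(table, out / "combination_ranking.svg")
    if "mechanisms" in results:
        payload = [
            {"processes": g.label, "members": [m.label for m in g.members]}
            for g in results["mechanisms"]
        ]
        (out / "mechanism_groups.json").write_text(json.dumps(payload, indent=2))
    if "sensitivity" in results:
        from .plotting import plot_sensitivity_grid
        plot_sensitivity_grid(results["sensitivity"], out / "sensitivity_grid.svg")
    if "pool" in results and "targets" in results:
        if len(results["targets"]) == results["pool"].n_subpopulations:
            from .plotting import plot_fit_overlays
            plot_fit_overlays(results["pool"], results["targets"],
                              out / "fit_overlays.svg")
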