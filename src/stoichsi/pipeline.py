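"""End-to-end orchestration: simulate -> preprocess -> SI -> DE -> classify ->
polygenicity, under a single YAML-able configuration with a provenance
manifest (seeds, parameters, output checksums)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from stoichsi import classify as clf
from stoichsi import diff_expr, polygenicity, preprocess, si_core
from stoichsi.gene_select import gene_set_table, select_genes
from stoichsi.io_formats import (
    SampleTable,
    read_counts,
    read_locus_table,
    read_samples,
    validate_cohort,
)
from stoichsi.synthetic_data import (
    SimConfig,
    generate_cohort,
    panel_gene_ids,
    write_fixture,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"l2g": 0.5, "tie_tolerance": 0.05, "imbalance": 2.0,
                      "fdr": 0.05, "prevalence": 0.02}


def default_config(seed: int = 0, *, n_genes: int = 20,
                   cohorts=((10, 22), (8, 20), (9, 21), (11, 23)),
                   iterations: int = 4, delta: float = 2.0,
                   n_lambda: int = 12) -> dict:
    """A small, fast, fully synthetic run configuration (smoke-test scale)."""
    return {
        "seed": seed,
        "simulate": {
            "n_genes": n_genes,
            "module_spec": [[max(4, n_genes // 3), 0.7], [max(3, n_genes // 6), -0.5]],
            "cohorts": [list(c) for c in cohorts],
            "delta": delta,
            "imbalance_rate_lambda": 3.0,
        },
        "cohort_names": [f"cohort{i}" for i in range(len(cohorts))],
        "gene_set": "all",
        "si": {"iterations": iterations, "n_lambda": n_lambda, "n_folds": 10},
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "control_analyses": False,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 -- re-raised with stage label
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _load_or_simulate(config: dict, outdir: Path):
    cohorts = {}
    names = config.get("cohort_names")
    if "simulate" in config:
        sim = dict(config["simulate"])
        if "module_spec" in sim:
            sim["module_spec"] = [tuple(m) for m in sim["module_spec"]]
        if "cohorts" in sim:
            sim["cohorts"] = [tuple(c) for c in sim["cohorts"]]
        sim_config = SimConfig(seed=config.get("seed", 0), **sim)
        names = names or [f"cohort{i}" for i in range(sim_config.n_cohorts)]
        for i, name in enumerate(names):
            dataset, samples, truth = generate_cohort(sim_config, i)
            write_fixture(dataset, samples, truth, outdir / "fixtures" / name)
            cohorts[name] = (dataset, samples, truth)
    else:
        for entry in config["cohorts"]:
            dataset = read_counts(entry["counts"], entry.get("gene_lengths"))
            samples = read_samples(entry["samples"])
            validate_cohort(dataset, samples)
            cohorts[entry["name"]] = (dataset, samples, None)
    return cohorts


@_stage("preprocess")
def _preprocess(dataset, samples: SampleTable, pca_k: float = 6.0):
    """Adult filter, PCA outlier screen, TMM + log2 RPKM, low-expression filter."""
    adults = samples.adults()
    dataset = dataset.subset_samples([dataset.sample_ids.index(s)
                                      for s in adults.sample_ids])
    keep_genes = preprocess.filter_low_expression(dataset)
    dataset = dataset.subset_genes(keep_genes)
    norm = preprocess.to_log2_rpkm(dataset)
    _, flagged = preprocess.pca_screen(norm.log2_rpkm, k=pca_k)
    if flagged.any():
        logger.info("PCA screen removed %d outlier samples", int(flagged.sum()))
        keep = [s for s in norm.log2_rpkm.columns if not flagged[s]]
        dataset = dataset.subset_samples([dataset.sample_ids.index(s) for s in keep])
        adults = adults.reindex(keep)
        norm = preprocess.to_log2_rpkm(dataset)
    resid = preprocess.residualize_absolute(norm.log2_rpkm, adults)
    return dataset, adults, norm, resid


def run_all(config: dict, outdir) -> dict:
    """Run the full analysis; returns a result bundle and writes artifacts.

    The run directory receives, per cohort, the simulated fixture, the SI
    profile matrices (WSR, sWSR, SI score), DE tables, performance reports,
    polygenicity summaries and a manifest of checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    si_params = {"iterations": 100, "n_lambda": 50, "n_folds": 10,
                 **config.get("si", {})}
    seed = int(config.get("seed", 0))

    cohorts = _load_or_simulate(config, outdir)

    # gene set
    if config.get("gene_set", "all") == "all":
        gene_set_ids = None
    else:
        table = read_locus_table(config["gene_set"])
        gs = select_genes(table, l2g_threshold=thresholds["l2g"],
                          tie_tolerance=thresholds["tie_tolerance"])
        gene_set_ids = gs.gene_ids
        gene_set_table(gs).to_csv(outdir / "gene_set.tsv", sep="\t", index=False)

    profiles: dict[str, si_core.SIProfile] = {}
    abs_resid_std: dict[str, pd.DataFrame] = {}
    wsr_mats: dict[str, pd.DataFrame] = {}
    abs_mats: dict[str, pd.DataFrame] = {}
    diagnoses: dict[str, np.ndarray] = {}
    results: dict = {"config": config, "cohorts": {}}

    for i, (name, (dataset, samples, truth)) in enumerate(cohorts.items()):
        dataset, adults, norm, resid = _preprocess(dataset, samples)
        expr = norm.log2_rpkm
        if gene_set_ids is not None:
            expr = expr.loc[[g for g in gene_set_ids if g in expr.index]]
        else:  # drop synthetic background filler, if any
            expr = expr.loc[panel_gene_ids(expr.index)]
        plan_cfg = config.get("plans", {}).get(name, {})
        try:
            profile = si_core.run_si(
                expr, adults, mode="model_on_controls",
                model_size=plan_cfg.get("model_size"),
                iterations=plan_cfg.get("iterations", si_params["iterations"]),
                seed=seed + i, n_lambda=si_params["n_lambda"],
                n_folds=si_params["n_folds"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("si", exc) from exc
        profiles[name] = profile
        dx = profile.diagnosis.to_numpy()
        diagnoses[name] = dx
        wsr_mats[name] = profile.WSR
        # absolute residuals, HC-standardized, individuals x genes
        abs_std = preprocess.standardize_by_hc(
            resid.residual.loc[expr.index], dx).T
        abs_resid_std[name] = abs_std
        abs_mats[name] = resid.residual.loc[expr.index].T

        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        profile.WSR.to_csv(cdir / "WSR.tsv", sep="\t")
        profile.sWSR.to_csv(cdir / "sWSR.tsv", sep="\t")
        profile.si.rename("SI").to_csv(cdir / "si_score.tsv", sep="\t")
        with open(cdir / "plan.json", "w") as fh:
            json.dump(profile.plan.to_json(), fh)
        results["cohorts"][name] = {"profile": profile, "truth": truth,
                                    "norm": norm, "residual": resid}

    # differential expression, pooled BH across genes and datasets
    try:
        swsr_for_de = {n: p.WSR for n, p in profiles.items()}
        de_rel = diff_expr.de_table(swsr_for_de, diagnoses, level="relative",
                                    alpha=thresholds["fdr"])
        de_abs = diff_expr.de_table(abs_mats, diagnoses, level="absolute",
                                    alpha=thresholds["fdr"])
        de = pd.concat([de_abs, de_rel], ignore_index=True)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        results["de"] = de
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", exc) from exc

    # cross-dataset classification + performance
    try:
        swsr_mats = {n: p.sWSR for n, p in profiles.items()}
        perf_rows = []
        for name, profile in profiles.items():
            dx = diagnoses[name]
            reports = [clf.performance_report(
                profile.si.to_numpy(), dx, metric="SI",
                prevalence=thresholds["prevalence"])]
            if len(profiles) >= 3:
                prob_rel = clf.cross_dataset_probabilities(swsr_mats, diagnoses, name)
                prob_abs = clf.cross_dataset_probabilities(abs_resid_std, diagnoses, name)
                reports.append(clf.performance_report(
                    prob_rel.to_numpy(), dx, metric="prob_relative",
                    prevalence=thresholds["prevalence"]))
                reports.append(clf.performance_report(
                    prob_abs.to_numpy(), dx, metric="prob_absolute",
                    prevalence=thresholds["prevalence"]))
                prob_rel.to_csv(outdir / name / "prob_relative.tsv", sep="\t")
                prob_abs.to_csv(outdir / name / "prob_absolute.tsv", sep="\t")
            perf_rows.append(clf.report_table(reports, name))
        perf = pd.concat(perf_rows, ignore_index=True)
        perf.to_csv(outdir / "performance.tsv", sep="\t", index=False)
        results["performance"] = perf
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", exc) from exc

    # polygenicity
    try:
        poly_rows = []
        for name, profile in profiles.items():
            summary = polygenicity.summarize_imbalance(
                profile.sWSR, diagnoses[name], threshold=thresholds["imbalance"])
            poly_rows.append(polygenicity.summary_table(summary, name))
            summary.per_individual_counts.rename("n_imbalanced").to_csv(
                outdir / name / "imbalance_counts.tsv", sep="\t")
            results["cohorts"][name]["imbalance"] = summary
        poly = pd.concat(poly_rows, ignore_index=True)
        poly.to_csv(outdir / "polygenicity.tsv", sep="\t", index=False)
        results["polygenicity"] = poly
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("polygenicity", exc) from exc

    # optional control analyses on the first cohort
    if config.get("control_analyses"):
        try:
            name = next(iter(profiles))
            dataset, samples, _ = cohorts[name]
            _, adults, norm, _ = _preprocess(dataset, samples)
            expr = norm.log2_rpkm
            if gene_set_ids is not None:
                expr = expr.loc[[g for g in gene_set_ids if g in expr.index]]
            else:
                expr = expr.loc[panel_gene_ids(expr.index)]
            case_profile = si_core.run_si(
                expr, adults, mode="model_on_cases",
                iterations=si_params["iterations"], seed=seed,
                n_lambda=si_params["n_lambda"], n_folds=si_params["n_folds"])
            null_profile = si_core.run_si(
                expr, adults, mode="hc_split_null",
                iterations=si_params["iterations"], seed=seed,
                n_lambda=si_params["n_lambda"], n_folds=si_params["n_folds"])
            case_profile.sWSR.to_csv(outdir / name / "sWSR_case_modelled.tsv", sep="\t")
            null_profile.sWSR.to_csv(outdir / name / "sWSR_hc_split.tsv", sep="\t")
            results["control_analyses"] = {"model_on_cases": case_profile,
                                           "hc_split_null": null_profile}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("control_analyses", exc) from exc

    manifest = {
        "seed": seed,
        "thresholds": thresholds,
        "si_params": si_params,
        "outputs": {str(p.relative_to(outdir)): _sha256(p)
                    for p in sorted(outdir.rglob("*")) if p.is_file()
                    and p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
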