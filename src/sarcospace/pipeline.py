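"""End-to-end orchestration: QC -> normalization (with strategy evaluation)
-> contamination -> differential expression -> distance gradient ->
heterogeneity -> classifier, driven by one YAML config and fully
deterministic under a fixed seed.

The output bundle contains every stage's table as TSV (each with a
provenance header carrying the tool version and config hash), a classifier
report in JSON, and a run log; rerunning with the same config produces a
byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .classifier import ClassifierConfig, train_classifier
from .contamination import flag_myocyte_segments
from .data import config_hash, read_manifest_dataset, write_table
from .de import CONTRAST_TERMS, run_contrast
from .errors import AnalysisError, ValidationError
from .gradient import ordinal_gradient_test
from .heterogeneity import cov_intra_inter, pca_nearest_neighbor, variance_comparison
from .normalize import evaluate_normalizations, normalize
from .qc import QCThresholds, filter_segments
from .simulate import default_study_config, write_fixture

log = logging.getLogger("sarcospace")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {"manifest": None, "simulate": True},
    "qc": {"min_nuclei": 20, "min_area": 1600.0,
           "binding_density_range": [0.1, 2.25], "max_background_ratio": 3.0},
    "normalization": {"methods": ["quantile", "library_size", "background"],
                      "negative_control": 1.0},
    "contamination": {"threshold": 0.2, "percentile": 0.8},
    "de": {"contrasts": ["stage", "distance", "infiltrate", "cs_vs_control"],
           "stratum": "full_roi", "selection_alpha": 0.05},
    "gradient": {"stratum": "full_roi"},
    "heterogeneity": {"n_components": 2, "top_k": 10},
    "classifier": {"lasso_penalty": 0.001, "max_features": 7,
                   "train_fraction": 0.67, "split_mode": "roi_level"},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def run_pipeline(config_path=None, out_dir="sarcospace_run", config: dict | None = None,
                 seed: int | None = None) -> dict:
    """Execute the full analysis; returns a summary dict (also written to disk).

    Any stage failure aborts the run with the stage name and cause.
    """
    cfg = config if config is not None else load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    t_start = time.time()
    summary: dict = {"tool_version": __version__, "config_hash": chash, "seed": cfg["seed"],
                     "stages": {}}
    stage = "setup"
    try:
        # ---- input -------------------------------------------------------
        stage = "input"
        if cfg["input"].get("manifest"):
            manifest = Path(cfg["input"]["manifest"])
            if not manifest.exists():
                raise ValidationError(f"input manifest not found: {manifest}")
        else:
            fixture_dir = out / "fixture"
            manifest = write_fixture(default_study_config(seed=cfg["seed"]), fixture_dir)
        counts, ann, panel = read_manifest_dataset(manifest)
        log.info("input: %d probes x %d segments", *counts.shape)
        summary["stages"]["input"] = {"n_probes": counts.shape[0],
                                      "n_segments": counts.shape[1]}

        # ---- qc ----------------------------------------------------------
        stage = "qc"
        q = cfg["qc"]
        thresholds = QCThresholds(min_nuclei=q["min_nuclei"], min_area=q["min_area"],
                                  binding_density_range=tuple(q["binding_density_range"]),
                                  max_background_ratio=q["max_background_ratio"])
        counts, ann, qc_report = filter_segments(counts, ann, thresholds)
        write_table(qc_report.as_frame(), out / "qc_report.tsv", chash,
                    extra_comments=[qc_report.threshold_comment()])
        log.info("qc: flagged %d segments", qc_report.n_flagged)
        summary["stages"]["qc"] = {"n_flagged": qc_report.n_flagged,
                                   "per_criterion": qc_report.counts_per_criterion}

        # ---- normalization ----------------------------------------------
        stage = "normalization"
        ncfg = cfg["normalization"]
        eval_table, winner = evaluate_normalizations(
            counts, ann, methods=ncfg["methods"],
            negative_control=ncfg.get("negative_control"),
            housekeepers=ncfg.get("housekeepers"))
        write_table(eval_table, out / "normalization_evaluation.tsv", chash)
        norm = normalize(counts, winner, housekeepers=ncfg.get("housekeepers"),
                         negative_control=ncfg.get("negative_control"))
        write_table(norm, out / "normalized.tsv", chash)
        log.info("normalization: selected %s", winner)
        summary["stages"]["normalization"] = {"selected": winner}

        # ---- contamination ----------------------------------------------
        stage = "contamination"
        ccfg = cfg["contamination"]
        contam_table, kept_myocyte = flag_myocyte_segments(
            norm, ann, panel, threshold=ccfg["threshold"], percentile=ccfg["percentile"])
        write_table(contam_table, out / "contamination.tsv", chash)
        n_dropped = int(contam_table["dropped"].sum()) if len(contam_table) else 0
        log.info("contamination: dropped %d of %d myocyte segments",
                 n_dropped, len(contam_table))
        summary["stages"]["contamination"] = {"n_myocyte": len(contam_table),
                                              "n_dropped": n_dropped}

        # view for myocyte-level analyses: contaminated myocyte AOIs removed
        non_myo = [s for s in ann.aoi_ids
                   if ann.table.loc[s, "compartment"] != "myocyte"]
        myocyte_view = norm.subset_segments(non_myo + kept_myocyte)

        # ---- differential expression ------------------------------------
        stage = "de"
        dcfg = cfg["de"]
        de_counts = {}
        for contrast in dcfg["contrasts"]:
            stratum = dcfg["stratum"]
            mat = myocyte_view if stratum == "myocyte" else norm
            table = run_contrast(mat, ann, panel, contrast, stratum=stratum,
                                 selection_alpha=dcfg["selection_alpha"])
            write_table(table, out / f"de_{contrast}.tsv", chash)
            alpha = 0.1 if contrast == "cs_vs_control" else 0.05
            de_counts[contrast] = int((table["p_value"] < alpha).sum())
            log.info("de[%s]: %d/%d probes at p<%g", contrast, de_counts[contrast],
                     len(table), alpha)
        summary["stages"]["de"] = {"n_significant": de_counts,
                                   "contrasts": list(dcfg["contrasts"])}

        # ---- distance gradient -------------------------------------------
        stage = "gradient"
        grad = ordinal_gradient_test(norm, ann, stratum=cfg["gradient"]["stratum"])
        write_table(grad, out / "gradient.tsv", chash)
        n_grad = int((grad["p_value"] < 0.05).sum())
        log.info("gradient: %d/%d probes significant", n_grad, len(grad))
        summary["stages"]["gradient"] = {"n_significant": n_grad, "n_probes": len(grad)}

        # ---- heterogeneity ------------------------------------------------
        stage = "heterogeneity"
        hcfg = cfg["heterogeneity"]
        var_table, frac_higher, top = variance_comparison(norm, ann, top_k=hcfg["top_k"])
        write_table(var_table, out / "heterogeneity_variance.tsv", chash)
        cov_table, cov_counts = cov_intra_inter(norm, ann)
        write_table(cov_table, out / "heterogeneity_cov.tsv", chash)
        nn_frac, nn_table = pca_nearest_neighbor(norm, ann,
                                                 n_components=hcfg["n_components"])
        write_table(nn_table, out / "heterogeneity_pca_nn.tsv", chash)
        mean_cov = (sum(cov_counts.values()) / len(cov_counts)) if cov_counts else 0.0
        log.info("heterogeneity: %.0f%% probes more variable in granulomas; "
                 "NN cross-sample fraction %.3f", 100 * frac_higher, nn_frac)
        summary["stages"]["heterogeneity"] = {
            "fraction_granuloma_higher_variance": frac_higher,
            "top_variable_probes": top,
            "mean_intra_exceeds_inter_markers": mean_cov,
            "pca_nn_cross_sample_fraction": nn_frac,
        }

        # ---- classifier ---------------------------------------------------
        stage = "classifier"
        kcfg = cfg["classifier"]
        clf_config = ClassifierConfig(seed=cfg["seed"],
                                      lasso_penalty=kcfg["lasso_penalty"],
                                      max_features=kcfg["max_features"],
                                      train_fraction=kcfg["train_fraction"],
                                      split_mode=kcfg["split_mode"])
        report = train_classifier(norm, ann, panel, clf_config)
        write_table(report.coefficient_table(), out / "classifier_coefficients.tsv", chash)
        with open(out / "classifier_report.json", "w") as fh:
            json.dump(report.summary(), fh, indent=1, sort_keys=True)
        log.info("classifier: %d features, held-out accuracy %.3f / AUROC %.3f",
                 len(report.model.features), report.test_metrics["accuracy"],
                 report.test_metrics["auroc"])
        summary["stages"]["classifier"] = report.summary()
    except (ValidationError, AnalysisError) as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["wall_time_s"] = round(time.time() - t_start, 3)
    with open(out / "run_summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "wall_time_s"},
                  fh, indent=1, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"sarcospace v{__version__} config={chash} seed={cfg['seed']}\n")
        fh.write(yaml.safe_dump(cfg, sort_keys=True))
    return summary
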