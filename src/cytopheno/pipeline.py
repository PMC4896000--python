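"""End-to-end run of the five-step framework on synthetic data.

``run_all`` generates the configured synthetic experiment, fits and selects a
clustering model on the training treatments, transfers the model to every
condition, and writes the machine-readable result bundle: subpopulation
fractions, criteria reports, model file, decomposition diagnostics,
inter-cluster tests, single-cell correlations, region annotations, and a
manifest that makes the run bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, framework, io, stats, synthetic

log = logging.getLogger(__name__)


def build_synthetic_config(run_config: io.RunConfig) -> synthetic.SyntheticConfig:
    factory = synthetic.fast_config if run_config.profile == "fast" \
        else synthetic.default_config
    return factory(seed=run_config.seed,
                   pixel_size_um=run_config.pixel_size_um)


def base_cluster_params(run_config: io.RunConfig) -> clustering.ClusterParams:
    return clustering.ClusterParams(
        features=run_config.feature_combos[0],
        arcsinh_cofactor=run_config.arcsinh_cofactor,
        neighborhood_size=run_config.neighborhood_size,
        density_approx_factor=run_config.density_approx_factor,
        max_pooled=run_config.max_pooled,
        target_remaining=run_config.target_remaining,
        n_restarts=run_config.n_restarts,
        seed=run_config.seed,
    )


def run_all(run_config: io.RunConfig, outdir) -> dict:
    """Execute the full framework and write the result bundle to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    syn = build_synthetic_config(run_config)
    log.info("simulating %d treatments x %d replicates x %d cells",
             len(syn.trajectories), syn.n_replicates, syn.n_cells_per_timepoint)
    events = synthetic.generate_timecourse(syn)

    train = events[events["treatment"].isin(run_config.training_treatments)]
    if train.empty:
        raise ValueError(
            f"training treatments {run_config.training_treatments} not found"
        )
    merged = framework.merge_experiments([train], seed=run_config.seed)

    thresholds = framework.SearchThresholds(
        c1_threshold=run_config.c1_threshold,
        c2_r_threshold=run_config.c2_r_threshold,
        separation_p=run_config.separation_p,
    )
    search = framework.search_models(
        merged,
        feature_combos=[list(c) for c in run_config.feature_combos],
        k_values=list(run_config.k_values),
        base_params=base_cluster_params(run_config),
        ranking_feature=run_config.ranking_feature,
        thresholds=thresholds,
        seed=run_config.seed,
    )
    candidates = pd.DataFrame([
        {
            "features": "+".join(c.features),
            "k": c.k,
            "criterion1_worst": c.c1_overall,
            "criterion1_passed": c.criterion1.passed,
            "criterion2_passed": c.criterion2.passed,
            "separation_passed": c.separation_passed,
            "unimodal_passed": c.unimodal_passed,
            "passed": c.passed,
            "selected": i == search.selected_index,
        }
        for i, c in enumerate(search.candidates)
    ])
    if search.selected_model is None:
        io.write_table(candidates, out / "candidates.tsv")
        raise RuntimeError("no candidate clustering passed the criteria; "
                           "see candidates.tsv")
    model = search.selected_model
    model.save(out / "model.json")

    labels = clustering.classify_events(model, events)
    tc = framework.compute_timecourse(labels, events,
                                      label_order=list(model.labels))
    c1 = framework.evaluate_criterion1(tc, run_config.c1_threshold)
    c2 = framework.evaluate_criterion2(tc, run_config.c2_r_threshold)

    predictions = framework.predict_mean_from_subpops(
        events, labels, run_config.ranking_feature, mode="per_condition"
    )
    predictions_global = framework.predict_mean_from_subpops(
        events, labels, run_config.ranking_feature, mode="global"
    )

    regions = {
        tr: framework.annotate_regions(tc, tr, label="Active")
        for tr in sorted(events["treatment"].unique())
    }

    baseline = events[events["time_h"] == events["time_h"].min()].copy()
    baseline["log_ratio"] = np.log(baseline["mean_pixel_nuc_cyto"])
    corr_rc = stats.single_cell_correlation(baseline, "log_ratio",
                                            "concentration_cell")
    corr_mcp = stats.single_cell_correlation(
        baseline, "lamp1_max_contour_position", "log_ratio"
    )
    correlations = pd.DataFrame([
        {"x": corr_rc.x, "y": corr_rc.y, "r": corr_rc.r, "n": corr_rc.n},
        {"x": corr_mcp.x, "y": corr_mcp.y, "r": corr_mcp.r, "n": corr_mcp.n},
    ])

    tests = stats.intercluster_test(
        events[run_config.ranking_feature], labels, test="wilcoxon",
        n_subsample=1000, seed=run_config.seed,
    )
    tests_df = pd.DataFrame([asdict(t) for t in tests])

    criteria = {
        "criterion1": {"metric_per_label": c1.metric_per_label,
                       "threshold": c1.threshold, "passed": c1.passed},
        "criterion2": {
            "pairs": [
                {"a": a, "b": b, "r": None if np.isnan(r) else r,
                 "flagged": f, "note": n}
                for a, b, r, f, n in c2.pairs
            ],
            "threshold": c2.threshold,
            "passed": c2.passed,
        },
        "regions": regions,
    }
    (out / "criteria.json").write_text(
        json.dumps(criteria, indent=2, sort_keys=True)
    )

    manifest = stats.export_report(
        {
            "fractions": tc,
            "candidates": candidates,
            "predictions_per_condition": predictions,
            "predictions_global": predictions_global,
            "correlations": correlations,
            "intercluster_tests": tests_df,
        },
        out,
        manifest_extra={
            "seed": run_config.seed,
            "config_hash": run_config.config_hash(),
            "extra_files": sorted(["model.json", "criteria.json"]),
        },
    )
    return manifest
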