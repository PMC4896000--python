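"""Five-step subpopulation framework: merge, cluster, assess, decompose.

Steps: (I) per-cell feature extraction (``cytopheno.features`` or the
synthetic generator), (II) merging of all treatments and time points so the
clustering cannot be influenced by condition identity, (III) density-
normalized clustering (``cytopheno.clustering``), (IV) assessment of the
candidate clustering against biological-soundness criteria, and (V) time
courses of the population fraction in each phenotype.

The assessment criteria quantify two requirements:

* Criterion 1 (reproducibility): the fraction time course of every cluster
  must be consistent across independent replicates.  Metric: mean over
  (treatment, time) of the across-replicate SD of the fraction; a cluster
  fails above a configurable threshold (default 0.10).
* Criterion 2 (non-redundancy): no two clusters may respond to the
  treatments in the same way.  Metric: Pearson correlation between
  replicate-averaged fraction time courses concatenated across treatments;
  a pair is redundant at r >= +0.9.  Only positive co-movement counts -
  fractions are compositional, so complementary clusters are necessarily
  anticorrelated.

Model search additionally requires that adjacent clusters differ in the
ranking feature (two-sided Wilcoxon rank-sum on 1000-cell subsamples,
p <= 0.001) and that each cluster's ranking-feature distribution is unimodal
(a merged pair of phenotypes shows up as a bimodal cluster).  Among passing
candidates the minimal model wins: fewest features, then smallest k, then
best reproducibility.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .clustering import (
    ClusterParams,
    classify_events,
    fit_cluster_model,
    label_clusters,
)
from .stats import intercluster_test

CONDITION_KEYS = ["treatment", "time_h", "replicate"]


# ---------------------------------------------------------------------------
# Merge and time course
# ---------------------------------------------------------------------------


def merge_experiments(tables: list[pd.DataFrame], seed: int = 0) -> pd.DataFrame:
    """Concatenate event tables and shuffle rows with a seeded permutation.

    The shuffle removes any ordering by condition, so downstream clustering
    cannot exploit row order.  All tables must share the same columns.
    """
    if not tables:
        raise ValueError("merge_experiments requires at least one table")
    cols = set(tables[0].columns)
    for i, t in enumerate(tables[1:], start=1):
        diff = cols.symmetric_difference(t.columns)
        if diff:
            raise ValueError(
                f"table {i} column mismatch vs table 0: {sorted(diff)}"
            )
    merged = pd.concat(tables, ignore_index=True)
    rng = np.random.default_rng(seed)
    return merged.iloc[rng.permutation(len(merged))].reset_index(drop=True)


def compute_timecourse(labels, table: pd.DataFrame,
                       label_order: list[str] | None = None) -> pd.DataFrame:
    """Phenotype fractions per (treatment, time, replicate).

    Labels with zero count in a condition are reported with fraction 0, so
    every condition carries the full label set and fractions sum to 1.
    """
    labels = pd.Series(np.asarray(labels), index=table.index, name="phenotype")
    if len(labels) != len(table):
        raise ValueError("one label per event is required")
    all_labels = label_order or sorted(labels.unique())
    df = table[CONDITION_KEYS].copy()
    df["phenotype"] = labels.values
    counts = (
        df.groupby(CONDITION_KEYS + ["phenotype"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    # complete the (condition x label) grid with zeros
    conditions = df[CONDITION_KEYS].drop_duplicates()
    grid = conditions.merge(pd.DataFrame({"phenotype": all_labels}), how="cross")
    tc = grid.merge(counts, on=CONDITION_KEYS + ["phenotype"], how="left")
    tc["n_cells"] = tc["n_cells"].fillna(0).astype(int)
    totals = tc.groupby(CONDITION_KEYS)["n_cells"].transform("sum")
    tc["fraction"] = tc["n_cells"] / totals
    return tc.sort_values(CONDITION_KEYS + ["phenotype"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------


@dataclass
class Criterion1Report:
    """Replicate-reproducibility of cluster fraction time courses."""

    metric_per_label: dict
    threshold: float
    passed: bool
    evaluable: bool = True


@dataclass
class Criterion2Report:
    """Redundancy (positive co-movement) between cluster time courses."""

    pairs: list  # (label_a, label_b, r, flagged, note)
    threshold: float
    passed: bool
    evaluable: bool = True


def evaluate_criterion1(tc: pd.DataFrame, threshold: float = 0.10) -> Criterion1Report:
    """Mean across (treatment, time) of the across-replicate SD of each
    cluster's fraction; every cluster must stay at or below the threshold."""
    n_reps = tc["replicate"].nunique()
    if n_reps < 2:
        return Criterion1Report({}, threshold, passed=False, evaluable=False)
    sd = (
        tc.groupby(["treatment", "time_h", "phenotype"])["fraction"]
        .std(ddof=1)
        .reset_index()
    )
    metric = sd.groupby("phenotype")["fraction"].mean().to_dict()
    passed = all(v <= threshold for v in metric.values())
    return Criterion1Report(metric, threshold, passed)


def _replicate_averaged_courses(tc: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged fraction per (treatment, time, phenotype), ordered."""
    return (
        tc.groupby(["treatment", "time_h", "phenotype"])["fraction"]
        .mean()
        .reset_index()
        .sort_values(["treatment", "time_h", "phenotype"])
    )


def evaluate_criterion2(tc: pd.DataFrame, r_threshold: float = 0.9) -> Criterion2Report:
    """Flag cluster pairs whose replicate-averaged time courses co-move with
    Pearson r >= +r_threshold across all treatments."""
    avg = _replicate_averaged_courses(tc)
    n_points = avg[["treatment", "time_h"]].drop_duplicates().shape[0]
    if n_points < 3:
        return Criterion2Report([], r_threshold, passed=False, evaluable=False)
    wide = avg.pivot_table(index=["treatment", "time_h"], columns="phenotype",
                           values="fraction").sort_index()
    labels = list(wide.columns)
    pairs = []
    passed = True
    for a, b in itertools.combinations(labels, 2):
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
            pairs.append((a, b, float("nan"), False,
                          "constant time course; correlation undefined"))
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        flagged = r >= r_threshold
        passed &= not flagged
        pairs.append((a, b, r, flagged, ""))
    return Criterion2Report(pairs, r_threshold, passed)


def count_modes(values, rel_prominence: float = 0.05, grid_size: int = 512) -> int:
    """Number of modes of a Gaussian KDE with a prominence floor.

    A peak only counts as a mode if its prominence exceeds
    ``rel_prominence`` x the global density maximum, which suppresses
    sampling ripples on unimodal data while detecting genuinely merged
    phenotype pairs.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.std(x) < 1e-12:
        return 1
    kde = gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=rel_prominence * dens.max())
    return max(int(len(peaks)), 1)


# ---------------------------------------------------------------------------
# Model search
# ---------------------------------------------------------------------------


@dataclass
class SearchThresholds:
    c1_threshold: float = 0.10
    c2_r_threshold: float = 0.9
    separation_p: float = 1e-3
    separation_n: int = 1000
    require_unimodal: bool = True
    unimodal_n: int = 1000


@dataclass
class CandidateResult:
    features: tuple
    k: int
    criterion1: Criterion1Report
    criterion2: Criterion2Report
    separation_pvalues: dict
    separation_passed: bool
    modes_per_label: dict
    unimodal_passed: bool
    passed: bool
    c1_overall: float  # worst per-cluster reproducibility metric


@dataclass
class ModelSearchResult:
    candidates: list
    selected_index: int | None
    selected_model: object | None

    @property
    def selected(self) -> CandidateResult | None:
        if self.selected_index is None:
            return None
        return self.candidates[self.selected_index]


def _separation_check(events: pd.DataFrame, labels: pd.Series, model,
                      ranking_feature: str, thresholds: SearchThresholds,
                      seed: int):
    """Adjacent clusters (by ranking-feature mean) must differ in that feature
    (two-sided Wilcoxon rank-sum on seeded 1000-cell subsamples)."""
    stats = model.training_summary["feature_stats"][ranking_feature]["mean"]
    order = [model.label_map[i] for i in np.argsort(stats)]
    results = intercluster_test(
        events[ranking_feature], labels, test="wilcoxon",
        n_subsample=thresholds.separation_n, seed=seed,
        pairs=list(zip(order, order[1:])),
    )
    pvalues = {(r.group_a, r.group_b): r.pvalue for r in results}
    passed = bool(pvalues) and all(
        p <= thresholds.separation_p for p in pvalues.values()
    )
    return pvalues, passed


def search_models(merged: pd.DataFrame, feature_combos: list, k_values: list,
                  base_params: ClusterParams | None = None,
                  ranking_feature: str = "mean_pixel_nuc_cyto",
                  thresholds: SearchThresholds | None = None,
                  seed: int = 0) -> ModelSearchResult:
    """Grid search over feature combinations and cluster numbers.

    Every candidate is fitted, classified, and scored against criterion 1,
    criterion 2, the inter-cluster separation test, and the within-cluster
    unimodality check.  Among passing candidates the minimal one is selected
    (fewest features, smallest k, lowest worst-cluster criterion-1 metric).
    If nothing passes, the result carries the full report with no selection.
    """
    if not feature_combos or not k_values:
        raise ValueError("feature_combos and k_values must be nonempty")
    thresholds = thresholds or SearchThresholds()
    base = base_params or ClusterParams()

    candidates: list[CandidateResult] = []
    models = []
    from dataclasses import replace as _replace

    for combo in feature_combos:
        for k in k_values:
            params = _replace(base, features=tuple(combo), k=int(k), seed=seed)
            model = fit_cluster_model(merged, params)
            with warnings.catch_warnings():
                # generic labels for k != 3 are routine during a grid search
                warnings.simplefilter("ignore", UserWarning)
                model = label_clusters(model, ranking_feature)
            labels = classify_events(model, merged)
            tc = compute_timecourse(labels, merged, label_order=list(model.labels))
            c1 = evaluate_criterion1(tc, thresholds.c1_threshold)
            c2 = evaluate_criterion2(tc, thresholds.c2_r_threshold)
            sep_p, sep_ok = _separation_check(
                merged, labels, model, ranking_feature, thresholds, seed
            )
            modes: dict = {}
            uni_ok = True
            if thresholds.require_unimodal:
                rng = np.random.default_rng(seed)
                for lab in model.labels:
                    vals = merged.loc[labels == lab, ranking_feature].to_numpy()
                    if vals.size > thresholds.unimodal_n:
                        vals = rng.choice(vals, size=thresholds.unimodal_n,
                                          replace=False)
                    modes[lab] = count_modes(vals)
                uni_ok = all(m <= 1 for m in modes.values())
            c1_overall = (max(c1.metric_per_label.values())
                          if c1.metric_per_label else float("inf"))
            passed = (c1.evaluable and c1.passed and c2.evaluable and c2.passed
                      and sep_ok and uni_ok)
            candidates.append(CandidateResult(
                features=tuple(combo), k=int(k), criterion1=c1, criterion2=c2,
                separation_pvalues=sep_p, separation_passed=sep_ok,
                modes_per_label=modes, unimodal_passed=uni_ok,
                passed=passed, c1_overall=c1_overall,
            ))
            models.append(model)

    passing = [i for i, c in enumerate(candidates) if c.passed]
    if not passing:
        return ModelSearchResult(candidates, None, None)
    best = min(passing, key=lambda i: (len(candidates[i].features),
                                       candidates[i].k,
                                       candidates[i].c1_overall))
    return ModelSearchResult(candidates, best, models[best])


# ---------------------------------------------------------------------------
# Decomposition and region annotation
# ---------------------------------------------------------------------------


def predict_mean_from_subpops(table: pd.DataFrame, labels, feature: str,
                              mode: str = "per_condition") -> pd.DataFrame:
    """Predict the mean population response from subpopulation fractions.

    predicted mean = sum over clusters of fraction x cluster mean, per
    (treatment, time, replicate).  In ``per_condition`` mode the cluster means
    are computed within each condition from the same events, so the prediction
    reproduces the direct event mean exactly (weighted-mean identity).  In
    ``global`` mode a single cluster mean across all conditions is used and the
    difference from the direct mean is reported as a residual diagnostic.
    """
    if mode not in ("per_condition", "global"):
        raise ValueError("mode must be 'per_condition' or 'global'")
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    df = table[CONDITION_KEYS + [feature]].copy()
    df["phenotype"] = np.asarray(labels)

    direct = df.groupby(CONDITION_KEYS)[feature].mean().rename("direct_mean")
    counts = (df.groupby(CONDITION_KEYS + ["phenotype"])[feature]
              .agg(n="size", cond_mean="mean").reset_index())
    totals = counts.groupby(CONDITION_KEYS)["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    if mode == "global":
        gmeans = df.groupby("phenotype")[feature].mean()
        counts["cluster_mean"] = counts["phenotype"].map(gmeans)
    else:
        counts["cluster_mean"] = counts["cond_mean"]
    counts["contribution"] = counts["fraction"] * counts["cluster_mean"]
    predicted = (counts.groupby(CONDITION_KEYS)["contribution"].sum()
                 .rename("predicted_mean"))
    out = pd.concat([predicted, direct], axis=1).reset_index()
    out["residual"] = out["predicted_mean"] - out["direct_mean"]
    return out


def annotate_regions(tc: pd.DataFrame, treatment: str,
                     label: str = "Active") -> list[dict]:
    """Segment a treatment's time axis at sign changes of the phenotype-fraction
    derivative (replicate averaged).  Reporting convenience only."""
    avg = _replicate_averaged_courses(tc)
    sel = avg[(avg["treatment"] == treatment) & (avg["phenotype"] == label)]
    sel = sel.sort_values("time_h")
    times = sel["time_h"].to_numpy()
    frac = sel["fraction"].to_numpy()
    if times.size < 3:
        warnings.warn(
            f"{treatment}: fewer than 3 time points, no region annotation",
            stacklevel=2,
        )
        return []
    diffs = np.diff(frac)
    signs = np.sign(diffs)
    # zero derivatives inherit the previous trend
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    regions = []
    start = 0
    for i in range(1, signs.size):
        if signs[i] != signs[i - 1] and signs[i] != 0:
            regions.append((start, i))
            start = i
    regions.append((start, signs.size))
    out = []
    for r, (a, b) in enumerate(regions, start=1):
        out.append({
            "name": f"R{r}",
            "t_start": float(times[a]),
            "t_end": float(times[b]),
            "trend": "rising" if signs[a] > 0 else
                     ("falling" if signs[a] < 0 else "flat"),
        })
    return out
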