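"""Statistical comparisons, correlations, and report export.

Inter-cluster comparisons use a two-sided Wilcoxon rank-sum test on seeded
1000-cell subsamples for non-normal features (nuclear/cytoplasmic ratio, Max
Contour Position) and Student's two-tailed t-test for concentration-type
features.  Time-point comparisons are made on replicate-level means (n =
number of replicates), not on single cells - per-cell testing would inflate
significance.  Raw p-values are reported by default; Benjamini-Hochberg
adjustment is available behind a flag.

The rank-sum test uses the normal approximation with tie correction and no
continuity correction, so two identical samples give p = 1 exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    seed: int | None = None
    note: str = ""
    pvalue_adjusted: float | None = None


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    n: int
    note: str = ""


def _run_test(a: np.ndarray, b: np.ndarray, test: str):
    if test == "wilcoxon":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    elif test == "ttest":
        res = sps.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r} (use 'wilcoxon' or 'ttest')")
    return float(res.statistic), float(res.pvalue)


def intercluster_test(values, assignments, test: str = "wilcoxon",
                      n_subsample: int = 1000, seed: int = 0,
                      pairs: list | None = None,
                      correct: bool = False) -> list[ComparisonResult]:
    """Pairwise cluster comparisons of one feature on seeded subsamples.

    Clusters smaller than ``n_subsample`` contribute all their cells (noted in
    the result).  Empty clusters are skipped with a note.  ``pairs`` restricts
    the comparisons (default: all unordered pairs, sorted).
    """
    vals = pd.Series(np.asarray(values, dtype=float))
    labs = pd.Series(np.asarray(assignments), index=vals.index)
    groups = {g: vals[labs == g].dropna().to_numpy() for g in sorted(labs.unique())}
    if pairs is None:
        keys = list(groups)
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]

    rng = np.random.default_rng(seed)
    results = []
    for a, b in pairs:
        xa, xb = groups.get(a), groups.get(b)
        if xa is None or xb is None or xa.size == 0 or xb.size == 0:
            results.append(ComparisonResult(str(a), str(b), test, float("nan"),
                                            float("nan"), 0, 0, seed,
                                            note="empty cluster; skipped"))
            continue
        note = ""
        if xa.size > n_subsample:
            xa = rng.choice(xa, size=n_subsample, replace=False)
        else:
            note = "fewer cells than subsample size; used all"
        if xb.size > n_subsample:
            xb = rng.choice(xb, size=n_subsample, replace=False)
        else:
            note = "fewer cells than subsample size; used all"
        stat, p = _run_test(xa, xb, test)
        results.append(ComparisonResult(str(a), str(b), test, stat, p,
                                        int(xa.size), int(xb.size), seed, note))
    if correct:
        ps = [r.pvalue for r in results if np.isfinite(r.pvalue)]
        adj = _benjamini_hochberg(ps)
        it = iter(adj)
        for r in results:
            if np.isfinite(r.pvalue):
                r.pvalue_adjusted = next(it)
    return results


def _benjamini_hochberg(pvalues: list[float]) -> list[float]:
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def timepoint_test(table: pd.DataFrame, treatment: str, time_h: float,
                   reference_time: float, feature: str,
                   test: str = "ttest") -> ComparisonResult:
    """Compare a feature at one time point against a reference time point.

    The testing unit is the replicate mean (n = replicate count per group),
    matching reporting as "mean among independent experiments".
    """
    sel = table[table["treatment"] == treatment]
    for t in (time_h, reference_time):
        if not (sel["time_h"] == t).any():
            raise KeyError(f"time {t} h not present for treatment {treatment!r}")
    means = sel.groupby(["time_h", "replicate"])[feature].mean()
    a = means.loc[time_h].to_numpy()
    b = means.loc[reference_time].to_numpy()
    if a.size < 2 or b.size < 2:
        return ComparisonResult(f"t={time_h}", f"t={reference_time}", test,
                                float("nan"), float("nan"), a.size, b.size,
                                note="fewer than 2 replicates; not evaluable")
    stat, p = _run_test(a, b, test)
    return ComparisonResult(f"t={time_h}", f"t={reference_time}", test, stat, p,
                            int(a.size), int(b.size))


def single_cell_correlation(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation between two features over all pooled single cells."""
    sub = table[[x, y]].to_numpy(dtype=float)
    ok = np.isfinite(sub).all(axis=1)
    sub = sub[ok]
    if sub.shape[0] < 3:
        return CorrelationResult(x, y, float("nan"), int(sub.shape[0]),
                                 note="fewer than 3 paired finite values")
    if np.std(sub[:, 0]) < 1e-15 or np.std(sub[:, 1]) < 1e-15:
        return CorrelationResult(x, y, float("nan"), int(sub.shape[0]),
                                 note="zero variance; correlation undefined")
    r = float(sps.pearsonr(sub[:, 0], sub[:, 1]).statistic)
    return CorrelationResult(x, y, r, int(sub.shape[0]))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def export_report(tables: dict[str, pd.DataFrame], outdir,
                  manifest_extra: dict | None = None) -> dict:
    """Write delimited result tables plus a run manifest enabling exact rerun.

    Each table is written as ``<name>.tsv``; the manifest records the SHA-256
    of every file, the package version, and whatever the caller supplies
    (config hash, seeds).  No timestamps are written, so a rerun with the same
    inputs is byte-identical.
    """
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        data = df.to_csv(sep="\t", index=False).encode("utf-8")
        path.write_bytes(data)
        files[path.name] = _sha256_bytes(data)
    manifest = {
        "version": __version__,
        "files": files,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_bytes = json.dumps(manifest, indent=2, sort_keys=True).encode("utf-8")
    (out / "manifest.json").write_bytes(manifest_bytes)
    return manifest
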