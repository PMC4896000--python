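"""Density-normalized downsampling + k-means clustering of cytometry features.

The clustering core follows the density-normalized-events approach used for
rare-population-preserving cytometry clustering: features are variance
stabilized with an arcsinh transform, a local density is estimated for every
event by neighbor counting, events are downsampled with probability inversely
proportional to their local density (so dense majority phenotypes are thinned
while rare phenotypes survive), k-means with multiple restarts is fitted on
the retained events, and every event - retained or not - is assigned to its
nearest centroid ("upsampling").  A fitted model carries its transform
parameters, centroids and phenotype labels, and can be applied unchanged to
new conditions (classification-model transfer).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.neighbors import KDTree, NearestNeighbors

from .synthetic import METADATA_COLUMNS

MODEL_FORMAT_VERSION = 1

PHENOTYPE_LABELS_K3 = ("Inactive", "Medium", "Active")


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the clustering pipeline.

    Defaults mirror the standard density-normalized-clustering settings for
    imaging-cytometry features: arcsinh cofactor 5, neighborhood size 5,
    local density approximation factor 1.5, at most 50000 pooled cells, 20000
    retained after downsampling, k-means.
    """

    features: tuple[str, ...] = ("mean_pixel_nuc_cyto",)
    arcsinh_cofactor: float = 5.0
    neighborhood_size: float = 5.0
    density_approx_factor: float = 1.5
    max_pooled: int = 50000
    target_remaining: int = 20000
    k: int = 3
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_remaining > self.max_pooled:
            raise ValueError("target_remaining must be <= max_pooled")
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be > 0")
        if not self.features:
            raise ValueError("at least one clustering feature is required")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass
class ClusterModel:
    """A fitted clustering model: transform, centroids, labels, training summary."""

    params: ClusterParams
    centroids: np.ndarray  # (k, d) in transformed space
    label_map: dict  # centroid index -> phenotype label
    training_summary: dict  # counts + per-feature raw-space mean/sd per cluster

    def label_of(self, index: int) -> str:
        return self.label_map[int(index)]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.label_map[i] for i in range(len(self.centroids)))

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": asdict(self.params),
            "centroids": np.asarray(self.centroids).tolist(),
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "training_summary": self.training_summary,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        payload = json.loads(text)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version!r} "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        params = payload["params"]
        params["features"] = tuple(params["features"])
        return cls(
            params=ClusterParams(**params),
            centroids=np.asarray(payload["centroids"], dtype=float),
            label_map={int(k): v for k, v in payload["label_map"].items()},
            training_summary=payload["training_summary"],
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Transform and density
# ---------------------------------------------------------------------------


def arcsinh_transform(value, cofactor: float):
    """Variance-stabilizing transform asinh(value / cofactor)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return np.arcsinh(np.asarray(value, dtype=float) / cofactor)


def local_density(points: np.ndarray, params: ClusterParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Neighbor-count local density per point.

    The counting radius is ``density_approx_factor`` x the median *nonzero*
    nearest-neighbor distance over a seeded subsample (size <= 2000).  The
    count includes the point itself, so densities are >= 1 and exact
    duplicates accumulate density.  If every pairwise distance is zero, all
    densities equal n.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("local_density needs at least 2 points")
    rng = rng or np.random.default_rng(params.seed)

    n = pts.shape[0]
    sub_n = min(n, 2000)
    sub_idx = rng.choice(n, size=sub_n, replace=False) if sub_n < n else np.arange(n)

    # nearest *distinct* neighbor: look past exact duplicates
    k_query = min(n, 64)
    nn = NearestNeighbors(n_neighbors=k_query).fit(pts)
    dists, _ = nn.kneighbors(pts[sub_idx])
    nonzero = np.where(dists > 0, dists, np.inf)
    nn_dist = nonzero.min(axis=1)
    finite = nn_dist[np.isfinite(nn_dist)]
    if finite.size == 0:
        # all points inside duplicate groups larger than k_query (or identical)
        radius = 0.0
    else:
        radius = params.density_approx_factor * float(np.median(finite))

    tree = KDTree(pts)
    counts = tree.query_radius(pts, r=max(radius, 0.0), count_only=True)
    return counts.astype(float)


def density_downsample(points: np.ndarray, densities: np.ndarray,
                       params: ClusterParams,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Density-dependent downsampling: keep point i with prob min(1, TD/density_i).

    The target density TD is found by bisection so the expected retained count
    equals ``min(target_remaining, n)``.  If n exceeds ``max_pooled`` a uniform
    pre-subsample to ``max_pooled`` is applied first.  Returns the sorted index
    set of retained points (indices into the original array).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dens = np.asarray(densities, dtype=float)
    if dens.shape[0] != pts.shape[0]:
        raise ValueError("densities must match points")
    rng = rng or np.random.default_rng(params.seed)

    n = pts.shape[0]
    pool = np.arange(n)
    if n > params.max_pooled:
        pool = np.sort(rng.choice(n, size=params.max_pooled, replace=False))
    d = dens[pool]
    target = min(params.target_remaining, pool.size)
    if target >= pool.size:
        return pool

    keep_prob = _keep_probabilities(d, target)
    kept = rng.random(pool.size) < keep_prob
    return pool[kept]


def _keep_probabilities(densities: np.ndarray, target: int) -> np.ndarray:
    """min(1, TD/d) with TD solved by bisection so sum(prob) == target."""
    d = np.asarray(densities, dtype=float)
    lo, hi = 0.0, float(d.max())
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        expected = np.minimum(1.0, mid / d).sum()
        if expected < target:
            lo = mid
        else:
            hi = mid
    return np.minimum(1.0, hi / d)


# ---------------------------------------------------------------------------
# Fitting, labeling, classification
# ---------------------------------------------------------------------------


def _feature_matrix(events: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    missing = [f for f in features if f not in events.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    X = events.loc[:, list(features)].to_numpy(dtype=float)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        rows = np.flatnonzero(bad)[:10].tolist()
        raise ValueError(
            f"non-finite feature values in {int(bad.sum())} row(s), e.g. rows {rows}"
        )
    return X


def _summary_columns(events: pd.DataFrame) -> list[str]:
    num = events.select_dtypes(include=[np.number]).columns
    return [c for c in num if c not in METADATA_COLUMNS]


def fit_cluster_model(events: pd.DataFrame, params: ClusterParams) -> ClusterModel:
    """Fit the full pipeline on an event table.

    select features -> arcsinh -> local density -> density downsampling ->
    k-means (k-means++ init, best of ``n_restarts``) -> assign every event to
    its nearest centroid.  Ties in nearest-centroid go to the lowest index.
    """
    X = arcsinh_transform(_feature_matrix(events, params.features),
                          params.arcsinh_cofactor)
    rng = np.random.default_rng(params.seed)
    dens = local_density(X, params, rng)
    kept = density_downsample(X, dens, params, rng)
    Xk = X[kept]
    if np.unique(Xk, axis=0).shape[0] < params.k:
        raise ValueError(
            f"fewer than k={params.k} distinct points after downsampling"
        )
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_restarts,
        random_state=int(params.seed) % (2**31),
    ).fit(Xk)
    centroids = km.cluster_centers_

    assign = assign_clusters_to_matrix(X, centroids)
    summary_cols = _summary_columns(events)
    counts = np.bincount(assign, minlength=params.k).tolist()
    stats: dict = {}
    for col in summary_cols:
        vals = events[col].to_numpy(dtype=float)
        means, sds = [], []
        for c in range(params.k):
            sel = assign == c
            if sel.any():
                means.append(float(np.nanmean(vals[sel])))
                sds.append(float(np.nanstd(vals[sel], ddof=1)) if sel.sum() > 1
                           else 0.0)
            else:
                means.append(float("nan"))
                sds.append(float("nan"))
        stats[col] = {"mean": means, "sd": sds}

    model = ClusterModel(
        params=params,
        centroids=centroids,
        label_map={i: f"C{i + 1}" for i in range(params.k)},
        training_summary={"counts": counts, "feature_stats": stats},
    )
    return model


def assign_clusters_to_matrix(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest centroid (Euclidean) per row; ties go to the lowest index."""
    dist = cdist(np.atleast_2d(X), np.atleast_2d(centroids))
    return dist.argmin(axis=1)


def label_clusters(model: ClusterModel,
                   ranking_feature: str = "mean_pixel_nuc_cyto") -> ClusterModel:
    """Attach phenotype labels ordered by the training mean of a feature.

    With k = 3 the clusters are labeled Inactive < Medium < Active by
    ascending mean (ties broken by cluster size, larger first).  Any other k
    falls back to generic C1..Ck labels with a warning.
    """
    stats = model.training_summary["feature_stats"]
    if ranking_feature not in stats:
        raise KeyError(
            f"ranking feature {ranking_feature!r} not in training summary; "
            f"available: {sorted(stats)}"
        )
    k = len(model.centroids)
    if k != len(PHENOTYPE_LABELS_K3):
        warnings.warn(
            f"phenotype labeling requires k=3, got k={k}; using generic labels",
            stacklevel=2,
        )
        return replace(model, label_map={i: f"C{i + 1}" for i in range(k)})
    means = stats[ranking_feature]["mean"]
    counts = model.training_summary["counts"]
    order = sorted(range(k), key=lambda i: (means[i], -counts[i]))
    label_map = {c: PHENOTYPE_LABELS_K3[rank] for rank, c in enumerate(order)}
    return replace(model, label_map=label_map)


def assign_clusters(model: ClusterModel, events: pd.DataFrame) -> np.ndarray:
    """Centroid indices for new events (stored transform, no refit)."""
    X = arcsinh_transform(_feature_matrix(events, model.params.features),
                          model.params.arcsinh_cofactor)
    return assign_clusters_to_matrix(X, model.centroids)


def classify_events(model: ClusterModel, events: pd.DataFrame) -> pd.Series:
    """Phenotype label per event via the stored centroids and label map."""
    idx = assign_clusters(model, events)
    return pd.Series([model.label_map[int(i)] for i in idx],
                     index=events.index, name="phenotype")
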