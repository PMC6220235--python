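"""Country typology: PCA of the six fisheries/economic variables + k-means.

The six variables (% unreported, value per fisher, % catch outside EEZ, GDP
per capita, % subsidy, catch-weighted mean distance) mix percentages, US
dollars and kilometres, so the PCA is run on the correlation matrix
(z-scored input). Countries are then grouped by k-means on their scores on
the first two components, with the cluster count chosen by maximising the
average silhouette width over a candidate range (the within-cluster
sum-of-squares curve is reported alongside as an elbow diagnostic).

Conventions that make outputs reproducible across runs:

* each principal component is sign-flipped so that its largest-magnitude
  loading is positive;
* k-means uses Lloyd's algorithm with ``n_restarts`` random initialisations
  (centroids drawn from the data points), keeping the restart with the
  lowest within-cluster sum of squares;
* cluster labels are renumbered 1..k by ascending mean PC1 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import silhouette_score

from .errors import InputError, UndefinedResultError


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # variable x component, orthonormal columns
    scores: pd.DataFrame  # country x component
    explained_fraction: np.ndarray = field(repr=False)  # per component, sums to 1
    eigenvalues: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # country -> 1..k, renumbered by ascending mean PC1
    k: int
    within_cluster_ss: float
    seed: int


def standardize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (sample SD, ddof=1)."""
    if len(metrics) < 2:
        raise InputError("need at least two countries to standardize")
    X = metrics.astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise InputError(f"missing values in columns: {bad}")
    sd = X.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise InputError(f"zero-variance columns cannot be standardized: {zero}")
    return (X - X.mean()) / sd


def pca(z: pd.DataFrame) -> PCAResult:
    """PCA of a z-scored matrix (equivalently, of the correlation matrix).

    Components are eigenvectors of the correlation matrix ordered by
    descending eigenvalue; scores are the projections of the z-scored rows.
    """
    if not np.all(np.isfinite(z.to_numpy(dtype=float))):
        raise InputError("non-finite values in PCA input")
    model = _SKPCA(n_components=min(z.shape), svd_solver="full")
    model.fit(z.to_numpy(dtype=float))
    loadings = model.components_.T.copy()  # variables x components
    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    scores = z.to_numpy(dtype=float) @ loadings
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        explained_fraction=model.explained_variance_ratio_.copy(),
        eigenvalues=model.explained_variance_.copy(),
    )


def _n_distinct(X: np.ndarray) -> int:
    return len(np.unique(X, axis=0))


def kmeans_cluster(
    scores: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> ClusterAssignment:
    """k-means (Lloyd) on the leading PCA scores, best of ``n_restarts``.

    Initial centroids are data points drawn at random under ``seed``; the
    restart with the lowest within-cluster sum of squares is kept and labels
    are canonicalised by ascending mean PC1 (first column) score.
    """
    X = scores.to_numpy(dtype=float)
    if k < 1:
        raise InputError("k must be >= 1")
    distinct = _n_distinct(X)
    if k > distinct:
        raise InputError(f"k={k} exceeds the {distinct} distinct points")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    raw = km.labels_
    order = (
        pd.Series(X[:, 0]).groupby(raw).mean().sort_values().index.to_list()
    )  # raw label -> rank by mean PC1
    remap = {old: rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=scores.index, name="cluster")
    return ClusterAssignment(
        labels=labels, k=k, within_cluster_ss=float(km.inertia_), seed=seed
    )


def choose_k(
    scores: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[int, pd.DataFrame]:
    """Pick the cluster count by maximum average silhouette width.

    Evaluates each k in the inclusive ``k_range`` (skipping k where there
    are not enough distinct points), returning the winning k and a
    diagnostics table with the silhouette and within-cluster-SS (elbow)
    curves. Ties break toward the smaller k.
    """
    X = scores.to_numpy(dtype=float)
    n = len(X)
    k_lo, k_hi = k_range
    if k_lo < 2:
        raise InputError("k_range must start at 2 (silhouette undefined for k=1)")
    distinct = _n_distinct(X)
    rows = []
    for k in range(k_lo, min(k_hi, n - 1) + 1):
        if k > distinct:
            continue
        assign = kmeans_cluster(scores, k, seed=seed, n_restarts=n_restarts)
        if assign.labels.nunique() < 2:
            continue
        sil = float(silhouette_score(X, assign.labels.to_numpy()))
        rows.append({"k": k, "silhouette": sil, "within_cluster_ss": assign.within_cluster_ss})
    if not rows:
        raise UndefinedResultError("no valid k in range (too few distinct points)")
    diag = pd.DataFrame(rows)
    best = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return best, diag


def biplot_data(pca_result: PCAResult, assignment: ClusterAssignment | None = None) -> dict:
    """Plot-ready biplot structure: variable arrows, country points, clusters."""
    arrows = [
        {"variable": v, "pc1": float(r["PC1"]), "pc2": float(r["PC2"])}
        for v, r in pca_result.loadings.iterrows()
    ]
    points = []
    for c, r in pca_result.scores.iterrows():
        pt = {"country": c, "pc1": float(r["PC1"]), "pc2": float(r["PC2"])}
        if assignment is not None:
            pt["cluster"] = int(assignment.labels[c])
        points.append(pt)
    return {
        "arrows": arrows,
        "points": points,
        "explained_fraction": [float(x) for x in pca_result.explained_fraction[:2]],
    }
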