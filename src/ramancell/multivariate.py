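"""Pooled PCA and K-means cluster analysis of Raman maps.

All preprocessed maps are pooled into one pixel-by-band matrix so that the
principal components are, by construction, identical for every map. PCA is
the eigendecomposition of the sample covariance after subtraction of the
overall mean spectrum; bands are not standardized (loadings keep
intensity-like units) and scores are not whitened, so the K-means metric is
the plain Euclidean distance in PC1–PC6 score space. K-means imposes seven
clusters: six addressed inside the cells plus one that collects the
low-intensity extracellular pixels. No PC-truncation denoising is applied
to the spectra themselves — only the clustering lives in the reduced space.

Cluster colors follow the conventional pseudo-color semantics: red for the
nucleic-acid-dominated cluster (strongest 785 cm⁻¹ band), yellow for
cytochrome c (748 + 1585 cm⁻¹), blue for the Amide-III/protein cluster
(1244 cm⁻¹), green for the low-intensity thin cell regions, dark red/dark
green for their weaker counterparts, and black outside the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .band_imaging import band_area
from .errors import DataError, DimensionError, ParameterError
from .types import MapMetadata, SpectralMap, WavenumberAxis

__all__ = [
    "PooledDataset",
    "PCAModel",
    "ClusterModel",
    "ClusterSummary",
    "GroupComparison",
    "CLUSTER_PALETTE",
    "pool_maps",
    "fit_pca",
    "project",
    "fit_kmeans",
    "identify_outside_cluster",
    "assign_cluster_colors",
    "make_cluster_map",
    "cluster_mean_spectra",
    "percent_areas",
    "summarize_clusters",
    "compare_groups",
    "compare_all_clusters",
]

#: RGB triples for the stable cluster color names; dark variants at half value.
CLUSTER_PALETTE: dict[str, tuple[float, float, float]] = {
    "red": (1.0, 0.0, 0.0),
    "dark_red": (0.5, 0.0, 0.0),
    "yellow": (1.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "green": (0.0, 1.0, 0.0),
    "dark_green": (0.0, 0.5, 0.0),
    "outside": (0.0, 0.0, 0.0),
}


@dataclass
class PooledDataset:
    """All pixels of all maps as rows, with per-row provenance."""

    X: np.ndarray                       # (n_pixels_total, n_bands)
    axis: WavenumberAxis
    provenance: pd.DataFrame            # columns: map_id, row, col
    map_info: dict[str, MapMetadata]
    map_shapes: dict[str, tuple[int, int]]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def rows_of(self, map_id: str) -> np.ndarray:
        if map_id not in self.map_shapes:
            raise DataError(f"map_id {map_id!r} not present in pooled dataset")
        return np.flatnonzero((self.provenance["map_id"] == map_id).to_numpy())

    def total_areas(self) -> np.ndarray:
        """Per-row total spectral area (trapezoidal integral)."""
        return np.trapezoid(self.X, self.axis.values, axis=1)


def pool_maps(maps: list[SpectralMap]) -> PooledDataset:
    """Concatenate maps row-major into one collection; axes must match."""
    if not maps:
        raise DataError("no maps to pool")
    axis = maps[0].axis
    for m in maps[1:]:
        if m.axis != axis:
            raise DimensionError(
                f"map {m.metadata.map_id!r} has a different wavenumber axis "
                "than the first map; pooled PCA requires a shared axis"
            )
    ids = [m.metadata.map_id for m in maps]
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicate map_id in pooled maps: {ids}")
    blocks, prov = [], []
    for m in maps:
        blocks.append(m.pixels())
        rr, cc = np.divmod(np.arange(m.n_pixels), m.width)
        prov.append(
            pd.DataFrame(
                {"map_id": m.metadata.map_id, "row": rr, "col": cc}
            )
        )
    return PooledDataset(
        X=np.vstack(blocks),
        axis=axis,
        provenance=pd.concat(prov, ignore_index=True),
        map_info={m.metadata.map_id: m.metadata for m in maps},
        map_shapes={m.metadata.map_id: (m.height, m.width) for m in maps},
    )


@dataclass
class PCAModel:
    """Overall mean spectrum, orthonormal loadings, explained variances.

    ``loadings[i]`` is the PC(i+1) loading vector; the sign convention fixes
    each loading's largest-magnitude element to be positive. Explained
    variance fractions are relative to the total variance (trace of the
    sample covariance), so they sum to 1 exactly at full rank.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray                # (n_components, n_bands)
    explained_variance: np.ndarray      # descending sample variances
    total_variance: float
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / self.total_variance


def fit_pca(dataset: PooledDataset | np.ndarray, n_components: int | None = None) -> PCAModel:
    """PCA of the pooled pixel spectra via covariance eigendecomposition."""
    X = dataset.X if isinstance(dataset, PooledDataset) else np.asarray(dataset, float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise DataError("PCA needs at least 2 rows and 2 bands")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    total = float(np.trace(cov))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T            # rows are loadings
    # sign convention: largest-|element| of each loading is positive
    for v in evecs:
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v *= -1.0
    if n_components is not None:
        if not 1 <= n_components <= p:
            raise ParameterError(f"n_components must be in [1, {p}]")
        evals, evecs = evals[:n_components], evecs[:n_components]
    degenerate = total == 0.0
    if degenerate:
        warnings.warn("dataset has zero variance; PCA model is degenerate")
    return PCAModel(
        mean_spectrum=mean,
        loadings=evecs,
        explained_variance=evals,
        total_variance=total,
        degenerate=degenerate,
    )


def project(dataset: PooledDataset | np.ndarray, model: PCAModel, K: int = 6) -> np.ndarray:
    """Scores of each row on PC1…PCK: ``(x − mean) · loadingᵀ``."""
    X = dataset.X if isinstance(dataset, PooledDataset) else np.asarray(dataset, float)
    if not 1 <= K <= model.n_components:
        raise ParameterError(
            f"K={K} out of range; model holds {model.n_components} components"
        )
    return (X - model.mean_spectrum) @ model.loadings[:K].T


@dataclass
class ClusterModel:
    """K-means result in PC-score space."""

    k: int
    centroids: np.ndarray               # (k, d)
    labels: np.ndarray                  # (n,)
    inertia: float
    seed: int
    n_restarts: int
    inertia_history: list[float] = field(default_factory=list)
    outside_id: int | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy probabilistic seeding: next seed drawn ∝ squared distance."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    labels = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ centroids.T
            + np.sum(centroids**2, axis=1)[None, :]
        )
        new_labels = np.argmin(d2, axis=1)
        point_d2 = np.sum((X - centroids[new_labels]) ** 2, axis=1)
        # empty clusters are re-seeded from the farthest point
        for j in range(centroids.shape[0]):
            if not np.any(new_labels == j):
                far = int(np.argmax(point_d2))
                centroids[j] = X[far]
                new_labels[far] = j
                point_d2[far] = 0.0
        history.append(float(point_d2.sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(centroids.shape[0]):
            centroids[j] = X[labels == j].mean(axis=0)
    return labels, centroids, history[-1], history


def fit_kmeans(
    scores: np.ndarray,
    k: int = 7,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> ClusterModel:
    """Lloyd's algorithm, best of *n_restarts* seeded k-means++ starts.

    Deterministic given *seed*; empty clusters are re-seeded from the point
    farthest from its centroid, so every cluster in the result is non-empty.
    """
    X = np.asarray(scores, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1 or k > n:
        raise ParameterError(f"k={k} out of range for {n} rows")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        init = _kmeanspp_init(X, k, rng)
        labels, centroids, inertia, history = _lloyd(X, init.copy(), max_iter)
        if best is None or inertia < best[0]:
            best = (inertia, labels, centroids, history)
    inertia, labels, centroids, history = best
    return ClusterModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
        inertia_history=history,
    )


def identify_outside_cluster(model: ClusterModel, dataset: PooledDataset) -> int:
    """Flag the cluster whose members have the lowest mean total area.

    Extracellular pixels are easily discriminated by their very small
    intensities; ties within 1e-12 indicate pathological input. If even the
    lowest-intensity cluster is not clearly dim (an all-cell crop), a
    warning is emitted and the id is still returned and recorded.
    """
    if model.labels.shape[0] != dataset.n_rows:
        raise DimensionError("cluster model was not fitted on this dataset")
    areas = dataset.total_areas()
    means = np.array(
        [areas[model.labels == j].mean() for j in range(model.k)]
    )
    order = np.argsort(means)
    if model.k > 1 and abs(means[order[1]] - means[order[0]]) < 1e-12:
        raise DataError(
            "two clusters tie for lowest mean total area; cannot identify "
            "the extracellular cluster"
        )
    outside = int(order[0])
    if means[outside] > 0.5 * areas.mean():
        warnings.warn(
            "lowest-intensity cluster is not clearly dim; the dataset may "
            "contain no extracellular pixels"
        )
    model.outside_id = outside
    return outside


def cluster_mean_spectra(model: ClusterModel, dataset: PooledDataset) -> np.ndarray:
    """(k, n_bands) arithmetic means of member spectra; NaN rows if empty."""
    if model.labels.shape[0] != dataset.n_rows:
        raise DimensionError("cluster model was not fitted on this dataset")
    out = np.full((model.k, dataset.X.shape[1]), np.nan)
    for j in range(model.k):
        sel = model.labels == j
        if sel.any():
            out[j] = dataset.X[sel].mean(axis=0)
        else:
            warnings.warn(f"cluster {j} is empty; mean spectrum set to NaN")
    return out


def assign_cluster_colors(
    model: ClusterModel,
    dataset: PooledDataset,
    spectra: np.ndarray | None = None,
    half_width: float = 10.0,
) -> dict[int, str]:
    """Stable cluster → color-name assignment for the 6+1 cluster layout.

    Among intracellular clusters, ranked on their mean spectra: strongest
    785 cm⁻¹ band → red; strongest 748+1585 cm⁻¹ (cyt c) among the rest →
    yellow; strongest 1244 cm⁻¹ (Amide III) → blue; lowest total area →
    green; the remaining two become dark_red/dark_green by centroid
    proximity to the red and green clusters. The extracellular cluster is
    black ("outside"). Requires ``outside_id`` and exactly 7 clusters; for
    other k use an explicit palette in :func:`make_cluster_map`.
    """
    if model.outside_id is None:
        raise DataError("identify_outside_cluster must run before color assignment")
    if model.k != 7:
        raise ParameterError("stable color semantics are defined for k=7 only")
    if spectra is None:
        spectra = cluster_mean_spectra(model, dataset)
    nu = dataset.axis
    colors: dict[int, str] = {model.outside_id: "outside"}
    remaining = [j for j in range(model.k) if j != model.outside_id]

    def _pick(key, pool):
        j = max(pool, key=key)
        pool.remove(j)
        return j

    red = _pick(lambda j: band_area(nu, spectra[j], (785.0,), half_width), remaining)
    yellow = _pick(
        lambda j: band_area(nu, spectra[j], (748.0, 1585.0), half_width), remaining
    )
    blue = _pick(lambda j: band_area(nu, spectra[j], (1244.0,), half_width), remaining)
    green = min(
        remaining, key=lambda j: np.trapezoid(spectra[j], nu.values)
    )
    remaining.remove(green)
    colors.update({red: "red", yellow: "yellow", blue: "blue", green: "green"})
    a, b = remaining
    d = lambda i, j: float(np.linalg.norm(model.centroids[i] - model.centroids[j]))
    # the more red-ward of the last two is dark_red, the other dark_green
    if d(a, red) - d(a, green) <= d(b, red) - d(b, green):
        colors[a], colors[b] = "dark_red", "dark_green"
    else:
        colors[a], colors[b] = "dark_green", "dark_red"
    return colors


def make_cluster_map(
    model: ClusterModel,
    dataset: PooledDataset,
    map_id: str,
    palette: dict[int, tuple[float, float, float]] | None = None,
    colors: dict[int, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-color cluster image and label grid for one map.

    *palette* maps cluster id → RGB directly; otherwise *colors* (or the
    stable assignment computed on the fly) maps ids to named palette
    entries. Returns ``(rgb, labels)`` with shapes (h, w, 3) and (h, w).
    """
    rows = dataset.rows_of(map_id)
    h, w = dataset.map_shapes[map_id]
    labels = np.empty((h, w), dtype=int)
    prov = dataset.provenance.iloc[rows]
    labels[prov["row"].to_numpy(), prov["col"].to_numpy()] = model.labels[rows]
    if palette is None:
        if colors is None:
            colors = assign_cluster_colors(model, dataset)
        palette = {j: CLUSTER_PALETTE[name] for j, name in colors.items()}
    if len(set(map(tuple, palette.values()))) != len(palette):
        raise ParameterError("palette reuses a color for two clusters")
    rgb = np.zeros((h, w, 3))
    for j, color in palette.items():
        rgb[labels == j] = color
    return rgb, labels


def percent_areas(
    model: ClusterModel, dataset: PooledDataset, in_cell_only: bool = True
) -> pd.DataFrame:
    """Per map and intracellular cluster: pixel count and % of in-cell area.

    With ``in_cell_only`` (default) the denominator is the number of pixels
    of that map not assigned to the extracellular cluster, so per-map
    percentages sum to 100.
    """
    if in_cell_only and model.outside_id is None:
        raise DataError("identify_outside_cluster must run before percent_areas")
    records = []
    cluster_ids = [
        j for j in range(model.k) if not (in_cell_only and j == model.outside_id)
    ]
    for map_id in dataset.map_shapes:
        rows = dataset.rows_of(map_id)
        lab = model.labels[rows]
        if in_cell_only:
            lab = lab[lab != model.outside_id]
        if lab.size == 0:
            raise DataError(f"map {map_id!r} has zero in-cell pixels")
        for j in cluster_ids:
            count = int(np.sum(lab == j))
            records.append(
                {
                    "map_id": map_id,
                    "line_label": dataset.map_info[map_id].line_label,
                    "cluster": j,
                    "pixel_count": count,
                    "percent": 100.0 * count / lab.size,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class ClusterSummary:
    """Joint per-map/per-cluster summary: areas table + mean spectra."""

    areas: pd.DataFrame
    spectra: np.ndarray                 # (k, n_bands)
    axis: WavenumberAxis
    outside_id: int
    colors: dict[int, str] | None = None


def summarize_clusters(model: ClusterModel, dataset: PooledDataset) -> ClusterSummary:
    if model.outside_id is None:
        identify_outside_cluster(model, dataset)
    spectra = cluster_mean_spectra(model, dataset)
    colors = assign_cluster_colors(model, dataset, spectra) if model.k == 7 else None
    return ClusterSummary(
        areas=percent_areas(model, dataset),
        spectra=spectra,
        axis=dataset.axis,
        outside_id=model.outside_id,
        colors=colors,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sample comparison of one cluster's percent areas."""

    cluster: int
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    df: int


def compare_groups(
    areas: pd.DataFrame, cluster: int, group_col: str = "line_label"
) -> GroupComparison:
    """Pooled-variance two-sample t test on one cluster's percent areas.

    Groups are the two values of *group_col* (map line labels by default);
    values are reported as mean ± SEM (sd/√n). Requires ≥ 2 maps per group.
    """
    sub = areas[areas["cluster"] == cluster]
    groups = sorted(sub[group_col].unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, found {groups}")
    a = sub.loc[sub[group_col] == groups[0], "percent"].to_numpy()
    b = sub.loc[sub[group_col] == groups[1], "percent"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 maps for a t test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        cluster=cluster,
        group_a=groups[0],
        group_b=groups[1],
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        t_statistic=float(t),
        p_value=float(p),
        df=len(a) + len(b) - 2,
    )


def compare_all_clusters(
    areas: pd.DataFrame, group_col: str = "line_label"
) -> pd.DataFrame:
    """Group comparison for every intracellular cluster, with a
    Bonferroni-adjusted p column (single comparisons remain the primary
    readout; the adjustment guards the family)."""
    clusters = sorted(areas["cluster"].unique())
    rows = []
    for c in clusters:
        g = compare_groups(areas, c, group_col)
        rows.append(
            {
                "cluster": c,
                "group_a": g.group_a,
                "mean_a": g.mean_a,
                "sem_a": g.sem_a,
                "group_b": g.group_b,
                "mean_b": g.mean_b,
                "sem_b": g.sem_b,
                "t": g.t_statistic,
                "p": g.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(clusters), 1.0)
    return out
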