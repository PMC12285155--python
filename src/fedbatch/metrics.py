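"""Batch-integration and biology-preservation metrics.

All metrics operate on a low-dimensional embedding (by default the top 20
principal components of expression). Batch-mixing metrics: kBET
acceptance, iLISI, ASW_B (reversed, cell-type-stratified silhouette),
EBM (normalized neighborhood entropy), graph connectivity, KNN accuracy.
Biology-preservation metrics: cLISI, ASW_C, ARI and NMI against Louvain
clusterings, isolated-label F1. Except for the raw iLISI/cLISI scores
(range [1, #labels]), every metric lies in [0, 1].

The comparison harness computes per-metric performance differences
between two methods and applies a two-sided Wilcoxon-Mann-Whitney test
per (metric, dataset) pair with Benjamini-Hochberg correction across all
pairs jointly.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, silhouette_samples, silhouette_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingView",
    "MetricResult",
    "pca_embed",
    "kbet_acceptance",
    "lisi",
    "asw_cell",
    "asw_batch",
    "louvain_clusters",
    "ari_score",
    "nmi_score",
    "ebm_score",
    "ilf1_score",
    "f1_from_counts",
    "graph_connectivity",
    "knn_accuracy",
    "perf_diff",
    "compare_methods",
    "evaluate_embedding",
]

RESOLUTION_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 1))


@dataclass
class EmbeddingView:
    """Cells x d coordinates plus the labels the metrics consume."""

    coords: np.ndarray
    batch_labels: np.ndarray
    type_labels: np.ndarray
    shared_types: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        self.type_labels = np.asarray(self.type_labels, dtype=object)
        n = self.coords.shape[0]
        if len(self.batch_labels) != n or len(self.type_labels) != n:
            raise ValueError("label lengths must match the number of cells")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float


def pca_embed(
    X: np.ndarray,
    batch_labels,
    type_labels,
    n_components: int = 20,
    shared_types: frozenset = frozenset(),
) -> EmbeddingView:
    """Top principal components with a deterministic sign convention.

    Components are ordered by decreasing explained variance and each is
    flipped so its largest-magnitude loading is positive. If the matrix
    rank supports fewer than ``n_components`` components, the available
    ones are kept with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    limit = min(X.shape[0] - 1, X.shape[1])
    if limit < n_components:
        warnings.warn(f"rank supports only {limit} components, requested {n_components}")
        n_components = max(1, limit)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return EmbeddingView(coords, batch_labels, type_labels, frozenset(shared_types))


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each point, self excluded."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, coords.shape[0])).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    return idx[:, 1:]


def kbet_acceptance(
    emb: EmbeddingView,
    k_fracs: tuple = (0.05, 0.10, 0.15, 0.20, 0.25),
    alpha: float = 0.05,
) -> float:
    """Median chi-square acceptance rate over neighborhood sizes.

    For each neighborhood size (a fraction of the dataset), every cell's
    k-nearest-neighbor batch composition is tested against the global
    batch proportions with Pearson's chi-square; the acceptance rate is
    the fraction of cells whose p-value is >= ``alpha``. Returns the
    median acceptance over the sizes. One batch -> 1.0 by convention.
    For very large data pass a single small fraction (e.g. 0.001).
    """
    batches, inv = np.unique(emb.batch_labels.astype(str), return_inverse=True)
    n_b = len(batches)
    if n_b < 2:
        return 1.0
    n = emb.n_cells
    props = np.bincount(inv, minlength=n_b) / n
    rates = []
    for frac in k_fracs:
        k = int(round(frac * n))
        if k < n_b:
            warnings.warn(f"neighborhood size {k} below number of batches; skipped")
            continue
        k = min(k, n - 1)
        idx = _knn_indices(emb.coords, k)
        counts = np.zeros((n, n_b))
        for b in range(n_b):
            counts[:, b] = (inv[idx] == b).sum(axis=1)
        expected = k * props
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        pvals = stats.chi2.sf(chi2, df=n_b - 1)
        rates.append(float((pvals >= alpha).mean()))
    if not rates:
        raise ValueError("no usable neighborhood size; dataset too small")
    return float(np.median(rates))


def lisi(
    emb: EmbeddingView,
    labels: np.ndarray,
    perplexity: float = 30.0,
    restrict_to: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell inverse Simpson's index of label diversity.

    Neighbor weights use a Gaussian kernel whose bandwidth is calibrated
    per cell so the weight entropy matches ``log(perplexity)`` (as in
    t-SNE). A score of 1 means all effective neighbors share one label; a
    score of L means L labels are equally represented. ``restrict_to``
    (boolean mask) computes the score within a cell subset only — used
    for iLISI over shared-type cells.
    """
    labels = np.asarray(labels, dtype=object)
    coords = emb.coords
    if restrict_to is not None:
        mask = np.asarray(restrict_to, dtype=bool)
        coords = coords[mask]
        labels = labels[mask]
    n = coords.shape[0]
    if n < 5:
        raise ValueError("too few cells for LISI")
    if n <= 3 * perplexity:
        perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity reduced to {perplexity:.1f} for {n} cells")
    k = min(int(3 * perplexity), n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]
    _, inv = np.unique(labels.astype(str), return_inverse=True)
    n_labels = inv.max() + 1
    target = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        beta = 1.0
        lo, hi = 0.0, np.inf
        for _ in range(64):
            w = np.exp(-beta * d2)
            s = w.sum()
            if s <= 1e-300:
                h = 0.0
            else:
                p = w / s
                nzp = p[p > 0]
                h = -(nzp * np.log(nzp)).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        w = np.exp(-beta * d2)
        p = w / w.sum() if w.sum() > 0 else np.full_like(w, 1.0 / len(w))
        pl = np.bincount(inv[idx[i]], weights=p, minlength=n_labels)
        scores[i] = 1.0 / np.sum(pl**2)
    return scores


def asw_cell(emb: EmbeddingView) -> float:
    """Cell-type silhouette mapped to [0, 1] via (s + 1) / 2."""
    types = np.unique(emb.type_labels.astype(str))
    if len(types) < 2:
        raise ValueError("ASW_C needs at least 2 cell types")
    s = silhouette_score(emb.coords, emb.type_labels.astype(str))
    return float((s + 1.0) / 2.0)


def asw_batch(emb: EmbeddingView) -> float:
    """Cell-type-stratified, reversed batch silhouette: mean of 1 - |s_i|.

    Within each cell type spanning >= 2 batches, per-cell silhouettes on
    batch labels are computed; a type's score is mean(1 - |s|), and the
    final score averages over eligible types. 1 = batches fully mixed
    within every type; 0 = batches fully separated.
    """
    type_scores = []
    for t in np.unique(emb.type_labels.astype(str)):
        sel = emb.type_labels.astype(str) == t
        b = emb.batch_labels[sel].astype(str)
        uniq = np.unique(b)
        if len(uniq) < 2 or sel.sum() <= len(uniq):
            continue
        s = silhouette_samples(emb.coords[sel], b)
        type_scores.append(float(np.mean(1.0 - np.abs(s))))
    if not type_scores:
        raise ValueError("no cell type spans two batches")
    return float(np.mean(type_scores))


def louvain_clusters(
    emb: EmbeddingView, k: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Louvain partition of the union kNN graph, seeded."""
    import igraph as ig

    n = emb.n_cells
    if n <= k:
        raise ValueError("need more cells than neighbors")
    idx = _knn_indices(emb.coords, k)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    _pyrandom.seed(seed)
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership)


def ari_score(emb: EmbeddingView, k: int = 15, resolution: float = 1.0, seed: int = 0) -> float:
    """Adjusted Rand index between a Louvain partition and cell-type labels."""
    clusters = louvain_clusters(emb, k=k, resolution=resolution, seed=seed)
    return float(adjusted_rand_score(emb.type_labels.astype(str), clusters))


def nmi_score(
    emb: EmbeddingView,
    k: int = 15,
    resolutions: tuple = RESOLUTION_GRID,
    seed: int = 0,
) -> float:
    """Max over a Louvain resolution grid of arithmetic-normalized NMI."""
    best = 0.0
    for res in resolutions:
        clusters = louvain_clusters(emb, k=k, resolution=res, seed=seed)
        nmi = normalized_mutual_info_score(
            emb.type_labels.astype(str), clusters, average_method="arithmetic"
        )
        best = max(best, float(nmi))
    return best


def ebm_score(
    emb: EmbeddingView,
    k: int = 15,
    n_cells_per_pool: int = 100,
    n_pools: int = 50,
    seed: int = 0,
) -> float:
    """Normalized entropy of batch mixing among nearest neighbors.

    Per sampled cell, the Shannon entropy of batch labels among its k
    nearest neighbors; averaged within each sampling pool, then across
    pools, then divided by log(#batches). One batch -> 0 with a warning.
    """
    batches, inv = np.unique(emb.batch_labels.astype(str), return_inverse=True)
    n_b = len(batches)
    if n_b < 2:
        warnings.warn("single batch: EBM is 0 by convention")
        return 0.0
    n = emb.n_cells
    idx = _knn_indices(emb.coords, min(k, n - 1))
    counts = np.zeros((n, n_b))
    for b in range(n_b):
        counts[:, b] = (inv[idx] == b).sum(axis=1)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    rng = np.random.default_rng(seed)
    pool_means = [
        ent[rng.choice(n, size=min(n_cells_per_pool, n), replace=False)].mean()
        for _ in range(n_pools)
    ]
    return float(np.mean(pool_means) / np.log(n_b))


def f1_from_counts(n_overlap: int, n_cluster: int, n_label: int) -> float:
    """Harmonic-mean F1 of a cluster against a label."""
    if n_overlap == 0:
        return 0.0
    precision = n_overlap / n_cluster
    recall = n_overlap / n_label
    return 2.0 * precision * recall / (precision + recall)


def isolated_labels(type_labels, batch_labels) -> list:
    """Cell types present in the minimum number of batches.

    Empty when every type spans the same number of batches (no type is
    more isolated than another).
    """
    df = pd.DataFrame({"t": np.asarray(type_labels, dtype=object).astype(str),
                       "b": np.asarray(batch_labels, dtype=object).astype(str)})
    presence = df.groupby("t")["b"].nunique()
    if presence.min() == presence.max():
        return []
    return sorted(presence.index[presence == presence.min()])


def ilf1_score(
    emb: EmbeddingView,
    k: int = 15,
    resolutions: tuple = RESOLUTION_GRID,
    seed: int = 0,
    labels: list | None = None,
) -> float:
    """Mean best-cluster F1 over isolated cell-type labels.

    For each isolated label (type present in the fewest batches), every
    cluster of every Louvain partition on the resolution grid is scored
    by the F1 of (cluster vs label); the label's score is the maximum,
    and ILF1 averages over isolated labels. Pass ``labels`` to override
    the isolated-label detection.
    """
    if labels is None:
        labels = isolated_labels(emb.type_labels, emb.batch_labels)
    if not labels:
        raise ValueError("no isolated labels; every type spans the same number of batches")
    tl = emb.type_labels.astype(str)
    best = {lab: 0.0 for lab in labels}
    for res in resolutions:
        clusters = louvain_clusters(emb, k=k, resolution=res, seed=seed)
        for lab in labels:
            in_label = tl == lab
            n_label = int(in_label.sum())
            for c in np.unique(clusters):
                in_c = clusters == c
                f1 = f1_from_counts(int((in_c & in_label).sum()), int(in_c.sum()), n_label)
                best[lab] = max(best[lab], f1)
    return float(np.mean([best[lab] for lab in labels]))


def graph_connectivity(emb: EmbeddingView, k: int = 15) -> float:
    """Mean over types of |largest connected component| / n_type.

    The kNN graph is built within each cell type separately; singleton
    types score 1.
    """
    scores = []
    for t in np.unique(emb.type_labels.astype(str)):
        sel = emb.type_labels.astype(str) == t
        n_t = int(sel.sum())
        if n_t == 1:
            scores.append(1.0)
            continue
        idx = _knn_indices(emb.coords[sel], min(k, n_t - 1))
        rows = np.repeat(np.arange(n_t), idx.shape[1])
        adj = csr_matrix(
            (np.ones(rows.size), (rows, idx.ravel())), shape=(n_t, n_t)
        )
        n_comp, memb = connected_components(adj, directed=False)
        scores.append(float(np.bincount(memb).max() / n_t))
    return float(np.mean(scores))


def knn_accuracy(emb: EmbeddingView, k: int = 15) -> float:
    """Macro-averaged fraction of k nearest neighbors sharing the cell's type."""
    n = emb.n_cells
    if n <= k:
        raise ValueError("need more cells than neighbors")
    tl = emb.type_labels.astype(str)
    idx = _knn_indices(emb.coords, k)
    per_cell = (tl[idx] == tl[:, None]).mean(axis=1)
    per_type = [per_cell[tl == t].mean() for t in np.unique(tl)]
    return float(np.mean(per_type))


def perf_diff(fed: MetricResult, cent: MetricResult) -> float:
    """Performance difference: federated value minus centralized value."""
    if fed.metric != cent.metric:
        raise ValueError(f"metric mismatch: {fed.metric} vs {cent.metric}")
    return float(fed.value - cent.value)


def compare_methods(results_a: dict, results_b: dict, alpha: float = 0.05) -> pd.DataFrame:
    """WMW test per (metric, dataset) pair with joint BH correction.

    ``results_a`` and ``results_b`` map ``(metric, dataset)`` to a
    sequence of per-seed values (>= 2 each). Returns a table with the
    mean performance difference, raw and BH-adjusted p-values, and a
    significance flag at ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    if set(results_a) != set(results_b):
        raise ValueError("the two result sets must cover identical (metric, dataset) pairs")
    rows = []
    for key in sorted(results_a):
        a = np.asarray(results_a[key], dtype=float)
        b = np.asarray(results_b[key], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 seeds per side for {key}")
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {"metric": key[0], "dataset": key[1], "delta": float(a.mean() - b.mean()), "p_raw": p}
        )
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p_raw"].values, alpha=alpha, method="fdr_bh")
    table["p_adj"] = np.maximum(p_adj, table["p_raw"])
    table["significant"] = table["p_adj"] < alpha
    return table


def evaluate_embedding(emb: EmbeddingView, seed: int = 0, skip: tuple = ()) -> dict:
    """All ten metrics on one embedding; metrics that do not apply
    (e.g. ILF1 without isolated labels) are reported as NaN."""
    out: dict = {}

    def _try(name, fn):
        if name in skip:
            return
        try:
            out[name] = fn()
        except ValueError:
            out[name] = float("nan")

    shared = emb.shared_types or frozenset(np.unique(emb.type_labels.astype(str)))
    shared_mask = np.isin(emb.type_labels.astype(str), sorted(map(str, shared)))
    _try("kbet", lambda: kbet_acceptance(emb))
    _try("ilisi", lambda: float(np.mean(lisi(emb, emb.batch_labels, restrict_to=shared_mask))))
    _try("clisi", lambda: float(np.mean(lisi(emb, emb.type_labels))))
    _try("asw_c", lambda: asw_cell(emb))
    _try("asw_b", lambda: asw_batch(emb))
    _try("ari", lambda: ari_score(emb, seed=seed))
    _try("nmi", lambda: nmi_score(emb, seed=seed))
    _try("ebm", lambda: ebm_score(emb, seed=seed))
    _try("ilf1", lambda: ilf1_score(emb, seed=seed))
    _try("gc", lambda: graph_connectivity(emb))
    _try("knn_acc", lambda: knn_accuracy(emb))
    return out
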