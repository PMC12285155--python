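"""Expression data model, h5ad I/O, preprocessing, and federated partitioning.

The preprocessing pipeline follows the standard single-cell recipe: remove
low-coverage cells (likely empty droplets), scale every cell to a common
total count, keep highly variable genes selected by a binned-dispersion
rule, and log1p-transform with a hard cap to stabilise variance. Stages are
ordered and each records the layer state so out-of-order application fails
loudly rather than silently producing nonsense.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class LayerTag(str, enum.Enum):
    """Processing state of the expression matrix."""

    raw_counts = "raw_counts"
    normalized = "normalized"
    log_transformed = "log_transformed"


class PipelineStateError(RuntimeError):
    """Raised when a preprocessing stage is applied out of order."""


class ConfigurationError(ValueError):
    """Raised for malformed inputs such as missing annotation columns."""


@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with per-cell batch and cell-type labels.

    Attributes
    ----------
    matrix
        Dense float array, shape (n_cells, n_genes), finite and non-negative.
    batch_labels, cell_type_labels
        Per-cell string labels (compared as exact strings, no case folding).
    gene_ids, cell_ids
        Unique gene identifiers; cell identifiers.
    layer_tag
        Which preprocessing stage the matrix is in.
    """

    matrix: np.ndarray
    batch_labels: np.ndarray
    cell_type_labels: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer_tag: LayerTag = LayerTag.raw_counts

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ConfigurationError("matrix must be 2-D (cells x genes)")
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n, g = self.matrix.shape
        if len(self.batch_labels) != n or len(self.cell_type_labels) != n:
            raise ConfigurationError("label length does not match number of cells")
        if len(self.gene_ids) != g:
            raise ConfigurationError("gene_ids length does not match number of genes")
        if len(self.cell_ids) != n:
            raise ConfigurationError("cell_ids length does not match number of cells")
        if len(set(self.gene_ids)) != g:
            raise ConfigurationError("gene_ids must be unique")
        if self.matrix.size and (~np.isfinite(self.matrix)).any():
            raise ConfigurationError("matrix entries must be finite")
        if self.matrix.size and (self.matrix < 0).any():
            raise ConfigurationError("matrix entries must be non-negative")
        self.layer_tag = LayerTag(self.layer_tag)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def batches(self) -> list[str]:
        """Distinct batch labels in order of first appearance."""
        return list(pd.unique(self.batch_labels))

    def cell_types(self) -> list[str]:
        return list(pd.unique(self.cell_type_labels))

    def type_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.cell_type_labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            matrix=self.matrix[mask],
            batch_labels=self.batch_labels[mask],
            cell_type_labels=self.cell_type_labels[mask],
            cell_ids=self.cell_ids[mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return replace(self, matrix=self.matrix[:, mask], gene_ids=self.gene_ids[mask])

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(
            {
                "batch": pd.Categorical(self.batch_labels.astype(str)),
                "cell_type": pd.Categorical(self.cell_type_labels.astype(str)),
            },
            index=pd.Index(self.cell_ids.astype(str), name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id"))
        adata = ad.AnnData(X=self.matrix.copy(), obs=obs, var=var)
        adata.uns["layer_tag"] = self.layer_tag.value
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata,
        batch_key: str = "batch",
        cell_type_key: str = "cell_type",
        layer_tag: LayerTag | None = None,
    ) -> "ExpressionDataset":
        for key in (batch_key, cell_type_key):
            if key not in adata.obs.columns:
                raise ConfigurationError(
                    f"annotation column {key!r} not found in obs "
                    f"(available: {list(adata.obs.columns)})"
                )
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        if layer_tag is None:
            tag = adata.uns.get("layer_tag")
            layer_tag = LayerTag(tag) if tag is not None else _infer_layer_tag(X)
        return cls(
            matrix=np.asarray(X, dtype=np.float64).reshape(adata.n_obs, adata.n_vars),
            batch_labels=np.asarray(adata.obs[batch_key].astype(str)),
            cell_type_labels=np.asarray(adata.obs[cell_type_key].astype(str)),
            gene_ids=np.asarray(adata.var_names.astype(str)),
            cell_ids=np.asarray(adata.obs_names.astype(str)),
            layer_tag=layer_tag,
        )


def _infer_layer_tag(X: np.ndarray) -> LayerTag:
    # Integral entries -> counts; small dynamic range -> log scale.
    if X.size == 0:
        return LayerTag.raw_counts
    if np.allclose(X, np.round(X)):
        return LayerTag.raw_counts
    if X.max(initial=0.0) <= 30.0:
        return LayerTag.log_transformed
    return LayerTag.normalized


def read_h5ad(
    path,
    batch_key: str = "batch",
    cell_type_key: str = "cell_type",
) -> ExpressionDataset:
    """Read an AnnData h5ad file into an :class:`ExpressionDataset`."""
    import anndata as ad

    return ExpressionDataset.from_anndata(
        ad.read_h5ad(path), batch_key=batch_key, cell_type_key=cell_type_key
    )


def write_h5ad(ds: ExpressionDataset, path) -> None:
    ds.to_anndata().write_h5ad(path)


# ---------------------------------------------------------------------------
# Preprocessing stages
# ---------------------------------------------------------------------------


def filter_low_coverage(ds: ExpressionDataset, min_genes: int = 200) -> ExpressionDataset:
    """Remove cells expressing fewer than ``min_genes`` genes.

    A gene counts as expressed when its entry is strictly positive; cells
    with exactly ``min_genes`` expressed genes are kept.
    """
    if ds.layer_tag is not LayerTag.raw_counts:
        raise PipelineStateError("coverage filtering applies to raw counts")
    n_expressed = (ds.matrix > 0).sum(axis=1)
    return ds.subset_cells(n_expressed >= min_genes)


def normalize_total(ds: ExpressionDataset, target_sum: float = 10_000.0) -> ExpressionDataset:
    """Scale each cell so its total count equals ``target_sum``.

    Cells with zero total are left at zero. Returns a dataset tagged
    ``normalized``.
    """
    if ds.layer_tag is not LayerTag.raw_counts:
        raise PipelineStateError("total-count normalization applies to raw counts")
    if target_sum <= 0:
        raise ConfigurationError("target_sum must be positive")
    totals = ds.matrix.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    out = replace(ds, matrix=ds.matrix * scale)
    out.layer_tag = LayerTag.normalized
    return out


def gene_dispersion(matrix: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and bin-normalized dispersion (variance/mean z-scored
    within equal-frequency mean bins).

    Returns ``(means, normalized_dispersions)``. Genes with zero mean get
    dispersion -inf (never selected).
    """
    means = matrix.mean(axis=0)
    variances = matrix.var(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros_like(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, variances / means, -np.inf)
    finite = np.isfinite(disp)
    norm = np.full_like(disp, -np.inf)
    if finite.sum() > 0:
        n_bins = min(n_bins, max(1, finite.sum()))
        ranks = pd.Series(means[finite]).rank(method="first")
        bins = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
        d = disp[finite]
        z = np.empty_like(d)
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() > 1:
                mu = d[sel].mean()
                sd = d[sel].std(ddof=1)
            else:
                mu, sd = 0.0, 0.0
            z[sel] = (d[sel] - mu) / sd if sd > 0 else 0.0
        norm[finite] = z
    return means, norm


def select_hvg(
    ds: ExpressionDataset,
    min_mean: float = 0.0125,
    max_mean: float = 2.5,
    min_disp: float = 0.7,
    n_bins: int = 20,
) -> ExpressionDataset:
    """Keep highly variable genes on the normalized layer.

    A gene is kept when its mean lies strictly inside ``(min_mean, max_mean)``
    and its bin-normalized dispersion is strictly greater than ``min_disp``.
    Gene order is preserved.
    """
    if ds.layer_tag is not LayerTag.normalized:
        raise PipelineStateError("HVG selection applies to the normalized layer")
    means, disp = gene_dispersion(ds.matrix, n_bins=n_bins)
    keep = (means > min_mean) & (means < max_mean) & (disp > min_disp)
    if keep.sum() == 0:
        raise ConfigurationError(
            "no genes pass the HVG thresholds; relax min_mean/max_mean/min_disp"
        )
    return ds.subset_genes(keep)


def log1p_cap(ds: ExpressionDataset, cap: float = 10.0) -> ExpressionDataset:
    """Apply ``x -> min(log1p(x), cap)`` and tag the layer ``log_transformed``."""
    if ds.layer_tag is not LayerTag.normalized:
        raise PipelineStateError("log transform applies to the normalized layer")
    out = replace(ds, matrix=np.minimum(np.log1p(ds.matrix), cap))
    out.layer_tag = LayerTag.log_transformed
    return out


def preprocess(
    ds: ExpressionDataset,
    min_genes: int = 200,
    target_sum: float = 10_000.0,
    min_mean: float = 0.0125,
    max_mean: float = 2.5,
    min_disp: float = 0.7,
    cap: float = 10.0,
    hvg: bool = True,
) -> ExpressionDataset:
    """Full pipeline: coverage filter -> normalize -> HVG -> log1p-cap."""
    ds = filter_low_coverage(ds, min_genes=min_genes)
    ds = normalize_total(ds, target_sum=target_sum)
    if hvg:
        ds = select_hvg(ds, min_mean=min_mean, max_mean=max_mean, min_disp=min_disp)
    return log1p_cap(ds, cap=cap)


# ---------------------------------------------------------------------------
# Federated partitioning and cell-type inclusion scenarios
# ---------------------------------------------------------------------------


@dataclass
class ClientPartition:
    """One federated client's slice of a dataset (one batch per client)."""

    client_id: int
    dataset: ExpressionDataset
    batch: str = ""
    type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.type_counts:
            self.type_counts = self.dataset.type_counts()
        assert sum(self.type_counts.values()) == self.dataset.n_cells

    @property
    def n_cells(self) -> int:
        return self.dataset.n_cells


def partition_by_batch(ds: ExpressionDataset) -> list[ClientPartition]:
    """Split a dataset into one client per batch (order of first appearance)."""
    parts = []
    for i, b in enumerate(ds.batches()):
        sub = ds.subset_cells(ds.batch_labels == b)
        parts.append(ClientPartition(client_id=i, dataset=sub, batch=str(b)))
    return parts


class InclusionMode(str, enum.Enum):
    All = "All"
    Combined = "Combined"
    Dropped = "Dropped"


@dataclass
class InclusionScenario:
    """Handling of minority/standalone cell types.

    ``All`` keeps every type as-is; ``Combined`` relabels minority and
    standalone types to ``combined_label``; ``Dropped`` removes their cells.
    A type is a minority when its global count is below ``minority_threshold``;
    standalone types (present in a single batch) are always flagged.
    """

    mode: InclusionMode = InclusionMode.All
    minority_threshold: int = 10
    combined_label: str = "others"

    def __post_init__(self) -> None:
        self.mode = InclusionMode(self.mode)
        if self.minority_threshold < 0:
            raise ConfigurationError("minority_threshold must be >= 0")


def _flagged_types(ds: ExpressionDataset, scenario: InclusionScenario) -> set[str]:
    counts = ds.type_counts()
    flagged = {t for t, c in counts.items() if c < scenario.minority_threshold}
    # standalone: type occurs in exactly one batch
    df = pd.DataFrame(
        {"t": ds.cell_type_labels.astype(str), "b": ds.batch_labels.astype(str)}
    )
    n_batches = df.groupby("t")["b"].nunique()
    flagged |= set(n_batches.index[n_batches == 1])
    return flagged


def apply_inclusion_scenario(
    ds: ExpressionDataset, scenario: InclusionScenario
) -> ExpressionDataset:
    if scenario.mode is InclusionMode.All:
        return ds
    flagged = _flagged_types(ds, scenario)
    is_flagged = np.isin(ds.cell_type_labels.astype(str), sorted(flagged))
    if scenario.mode is InclusionMode.Combined:
        labels = ds.cell_type_labels.copy()
        labels[is_flagged] = scenario.combined_label
        return replace(ds, cell_type_labels=labels)
    return ds.subset_cells(~is_flagged)


def concatenate(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Stack datasets cell-wise (gene panels must match exactly)."""
    ref = datasets[0]
    for d in datasets[1:]:
        if list(d.gene_ids) != list(ref.gene_ids):
            raise ConfigurationError("gene panels differ; cannot concatenate")
        if d.layer_tag is not ref.layer_tag:
            raise PipelineStateError("layer tags differ; cannot concatenate")
    return ExpressionDataset(
        matrix=np.vstack([d.matrix for d in datasets]),
        batch_labels=np.concatenate([d.batch_labels for d in datasets]),
        cell_type_labels=np.concatenate([d.cell_type_labels for d in datasets]),
        gene_ids=ref.gene_ids,
        cell_ids=np.concatenate([d.cell_ids for d in datasets]),
        layer_tag=ref.layer_tag,
    )


def client_summary(parts: list[ClientPartition]) -> pd.DataFrame:
    """Tidy per-client summary (client_id, batch, n_cells, one column per type)."""
    rows = []
    for p in parts:
        row = {"client_id": p.client_id, "batch": p.batch, "n_cells": p.n_cells}
        row.update(p.type_counts)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
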