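"""Centralized batch correction by latent-space arithmetic.

After VAE training, every shared cell type (present in at least two
batches) gets a reference latent centroid M^t computed over the dominant
batch — the batch holding the most cells of that type. Each cell of a
shared type is shifted by the delta vector (M^t minus its own batch's
type centroid), which aligns per-batch centroids of every shared type
exactly while leaving standalone types untouched. The corrected
expression is the decoder image of the shifted latents, clipped at zero.

A ``literal_subtraction`` mode subtracts M^t from every cell of a type
instead; it centers types rather than aligning batches and exists for
comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fedbatch.data import ExpressionDataset
from fedbatch.vae import VAEConfig, VAEParams, decode, encode, init_vae, train_local

__all__ = [
    "TypeSharing",
    "TypeMeanMap",
    "identify_sharing",
    "dominant_batch_for",
    "compute_type_means",
    "correct_latent",
    "decode_corrected",
    "run_centralized",
]


@dataclass(frozen=True)
class TypeSharing:
    """Partition of cell types into shared (>= 2 batches) and standalone."""

    shared: frozenset
    standalone: frozenset

    def __post_init__(self):
        if self.shared & self.standalone:
            raise ValueError("a type cannot be both shared and standalone")


@dataclass
class TypeMeanMap:
    """Reference latent centroid per shared cell type.

    ``means[t]`` is the latent centroid of type ``t`` in its dominant
    batch ``dominant_batch[t]`` (the batch with the most type-``t`` cells,
    ties to the lexicographically smallest batch id).
    """

    means: dict
    dominant_batch: dict
    dominant_count: dict

    def __post_init__(self):
        if set(self.means) != set(self.dominant_batch) or set(self.means) != set(
            self.dominant_count
        ):
            raise ValueError("means, dominant_batch and dominant_count must share keys")
        for t, m in self.means.items():
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite latent mean for type {t!r}")

    def types(self) -> set:
        return set(self.means)


def identify_sharing(ds: ExpressionDataset) -> TypeSharing:
    """A type is standalone iff it occurs in exactly one batch."""
    types = np.asarray(ds.cell_type_labels, dtype=object)
    batches = np.asarray(ds.batch_labels, dtype=object)
    shared, standalone = set(), set()
    for t in set(types.tolist()):
        n_batches = len(set(batches[types == t].tolist()))
        (shared if n_batches >= 2 else standalone).add(t)
    return TypeSharing(shared=frozenset(shared), standalone=frozenset(standalone))


def dominant_batch_for(ds: ExpressionDataset, t) -> tuple[str, int]:
    """Batch holding the most cells of shared type ``t`` (ties: smallest id)."""
    sharing = identify_sharing(ds)
    if t not in sharing.shared:
        raise ValueError(f"type {t!r} is not shared across batches")
    mask = ds.cell_type_labels == t
    batches = ds.batch_labels[mask].astype(str)
    vals, counts = np.unique(batches, return_counts=True)
    best = counts.max()
    winners = sorted(vals[counts == best])
    return winners[0], int(best)


def compute_type_means(
    params: VAEParams, ds: ExpressionDataset, sharing: TypeSharing | None = None
) -> TypeMeanMap:
    """Deterministic latent centroid of each shared type in its dominant batch."""
    if sharing is None:
        sharing = identify_sharing(ds)
    Z = encode(params, ds.matrix, deterministic=True)
    means, dom, cnt = {}, {}, {}
    for t in sorted(sharing.shared, key=str):
        b_star, n = dominant_batch_for(ds, t)
        sel = (ds.cell_type_labels == t) & (ds.batch_labels.astype(str) == b_star)
        means[t] = Z[sel].mean(axis=0)
        dom[t] = b_star
        cnt[t] = n
    return TypeMeanMap(means=means, dominant_batch=dom, dominant_count=cnt)


def correct_latent(
    Z: np.ndarray,
    type_labels: np.ndarray,
    batch_labels: np.ndarray,
    means: TypeMeanMap,
    literal_subtraction: bool = False,
) -> np.ndarray:
    """Shift each shared-type cell by its batch's delta vector.

    For cell i of shared type t in batch b:
    ``z_i' = z_i + (M^t - mean(Z over type-t cells of batch b))``, which
    moves every batch's type-t centroid onto the dominant batch's. Cells
    of types absent from ``means`` (standalone) are returned unchanged.

    ``literal_subtraction=True`` computes ``z_i' = z_i - M^t`` instead.
    """
    Z = np.asarray(Z, dtype=np.float64)
    type_labels = np.asarray(type_labels, dtype=object)
    batch_labels = np.asarray(batch_labels, dtype=object)
    shared_present = {t for t in set(type_labels.tolist()) if _occurs_in_two(type_labels, batch_labels, t)}
    missing = shared_present - means.types()
    if missing:
        raise ValueError(f"shared types missing from the mean map: {sorted(map(str, missing))}")
    out = Z.copy()
    for t in means.types():
        t_mask = type_labels == t
        if not t_mask.any():
            continue
        if literal_subtraction:
            out[t_mask] = Z[t_mask] - means.means[t]
            continue
        for b in set(batch_labels[t_mask].tolist()):
            sel = t_mask & (batch_labels == b)
            delta = means.means[t] - Z[sel].mean(axis=0)
            out[sel] = Z[sel] + delta
    return out


def _occurs_in_two(type_labels, batch_labels, t) -> bool:
    return len(set(batch_labels[type_labels == t].tolist())) >= 2


def decode_corrected(params: VAEParams, ds: ExpressionDataset, Z_corrected: np.ndarray) -> ExpressionDataset:
    """Decoder image of corrected latents, clipped at zero, original labels."""
    Xc = np.maximum(decode(params, Z_corrected), 0.0)
    if Xc.shape[0] != ds.n_cells:
        raise ValueError("corrected latents do not match the dataset")
    return replace(ds, matrix=Xc)


def run_centralized(
    ds: ExpressionDataset,
    config: VAEConfig,
    epochs: int = 100,
    params: VAEParams | None = None,
    literal_subtraction: bool = False,
):
    """Train (or reuse) a VAE and run the full correction pipeline.

    Returns ``(params, corrected_ds, artifacts)`` where ``artifacts`` holds
    the raw latents, corrected latents, sharing split and mean map.
    """
    if params is None:
        params = init_vae(config)
        params, _, _ = train_local(params, ds, epochs, config, seed=config.seed)
    sharing = identify_sharing(ds)
    Z = encode(params, ds.matrix, deterministic=True)
    means = compute_type_means(params, ds, sharing)
    Zc = correct_latent(
        Z, ds.cell_type_labels, ds.batch_labels.astype(str), means,
        literal_subtraction=literal_subtraction,
    )
    corrected = decode_corrected(params, ds, Zc)
    artifacts = {"latent": Z, "latent_corrected": Zc, "sharing": sharing, "means": means}
    return params, corrected, artifacts
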