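"""Cross-silo federated training and delta-vector correction.

Training: over R communication rounds the coordinator broadcasts global
VAE parameters, every client runs a few local epochs on its own batch,
and the coordinator aggregates the returned parameters by sample-size
weighted averaging (FedAvg) — in plaintext or through the secure
weighted sum of :mod:`fedbatch.sharing`.

Correction: the dominant client for each shared cell type is detected
from per-client counts (securely when requested, revealing only the
winner's identity), computes the latent centroid of its own type-t
cells under the global model, and broadcasts it; every client then
shifts its local latents and decodes, so raw expression never leaves a
client. Held-out clients can join correction without having trained.

Each client's minibatch stream is derived from (federation seed,
client id) with epoch offsets that advance across rounds, so a
single-client federation reproduces an unbroken centralized run
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fedbatch.data import ClientPartition, ExpressionDataset
from fedbatch.scgen import TypeMeanMap, TypeSharing, correct_latent, decode_corrected
from fedbatch.sharing import Transcript, secure_argmax, secure_weighted_sum
from fedbatch.vae import AdamState, VAEConfig, VAEParams, encode, init_vae, params_digest, train_local

__all__ = [
    "FederationConfig",
    "CorrectionResult",
    "client_stream_seed",
    "fedavg",
    "federated_train",
    "global_type_sharing",
    "federated_correction",
    "export_public_means",
    "apply_public_means",
]


@dataclass
class FederationConfig:
    n_rounds: int = 8
    local_epochs: int = 2
    secure: bool = False
    n_parties: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.n_parties < 2:
            raise ValueError("n_parties must be >= 2")


def client_stream_seed(seed: int, client_id: int) -> int:
    """Deterministic per-client minibatch seed (below 2**31)."""
    return int(np.random.default_rng([int(seed), int(client_id)]).integers(2**31))


def fedavg(params_list: list[VAEParams], weights: list[float]) -> VAEParams:
    """Sample-size weighted average of client parameters."""
    if len(params_list) != len(weights):
        raise ValueError("one weight per client required")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    sig = params_list[0].shape_signature()
    for p in params_list[1:]:
        if p.shape_signature() != sig:
            raise ValueError("parameter shape signatures differ")
    total = float(sum(weights))
    out = VAEParams()
    for k in params_list[0]:
        out[k] = sum((w / total) * p[k] for p, w in zip(params_list, weights))
    return out


def _secure_fedavg(params_list, weights, n_parties, rng, transcript):
    ref = params_list[0]
    flat = [p.flatten() for p in params_list]
    avg = secure_weighted_sum(flat, weights, n_parties=n_parties, rng=rng, transcript=transcript)
    return ref.unflatten(avg)


def federated_train(
    clients: list[ClientPartition],
    fed_config: FederationConfig,
    vae_config: VAEConfig,
):
    """FedAvg training over ``fed_config.n_rounds`` communication rounds.

    All clients start from the same seeded initial parameters. Local Adam
    state persists at each client across rounds. Returns
    ``(global_params, round_logs)``; the logs carry only losses, cell
    counts and parameter digests — never data or raw parameters.
    """
    if not clients:
        raise ValueError("at least one client required")
    global_params = init_vae(vae_config)
    opt_states = [AdamState() for _ in clients]
    smpc_rng = np.random.default_rng([int(fed_config.seed), 31337])
    transcript = Transcript()
    round_logs = []
    e = fed_config.local_epochs
    for r in range(fed_config.n_rounds):
        local_params, local_weights = [], []
        for ci, c in enumerate(clients):
            p, trace, opt_states[ci] = train_local(
                global_params,
                c.dataset,
                e,
                vae_config,
                seed=client_stream_seed(fed_config.seed, c.client_id),
                epoch_offset=r * e,
                opt_state=opt_states[ci],
            )
            local_params.append(p)
            local_weights.append(float(c.n_cells))
            round_logs.append(
                {
                    "round": r,
                    "client": c.client_id,
                    "loss": trace[-1][0],
                    "n_cells": c.n_cells,
                    "digest": params_digest(p),
                }
            )
        if fed_config.secure:
            global_params = _secure_fedavg(
                local_params, local_weights, fed_config.n_parties, smpc_rng, transcript
            )
        else:
            global_params = fedavg(local_params, local_weights)
        round_logs.append(
            {"round": r, "client": None, "global_digest": params_digest(global_params)}
        )
    return global_params, round_logs


def global_type_sharing(clients: list[ClientPartition], secure: bool = False) -> TypeSharing:
    """Shared = held by >= 2 clients; standalone = exactly one.

    Only presence bits are exchanged; counts stay local. With one batch per
    client this matches the centralized sharing split on pooled data.
    """
    holders: dict = {}
    for c in clients:
        for t, n in c.type_counts.items():
            if n > 0:
                holders.setdefault(t, set()).add(c.client_id)
    shared = frozenset(t for t, h in holders.items() if len(h) >= 2)
    standalone = frozenset(t for t, h in holders.items() if len(h) == 1)
    return TypeSharing(shared=shared, standalone=standalone)


@dataclass
class CorrectionResult:
    corrected: dict  # client_id -> ExpressionDataset
    latents: dict  # client_id -> raw latent matrix
    latents_corrected: dict  # client_id -> corrected latent matrix
    mean_map: TypeMeanMap
    dominant_client: dict  # shared type -> client_id
    sharing: TypeSharing
    transcript: Transcript = field(default_factory=Transcript)
    model_digest: str = ""


def federated_correction(
    clients: list[ClientPartition],
    global_params: VAEParams,
    fed_config: FederationConfig,
) -> CorrectionResult:
    """Federated delta-vector estimation and local correction.

    ``clients`` may include held-out members that never trained; they take
    part in dominance counting and receive the broadcast centroids like
    everyone else. Dominance ties resolve to the lexicographically
    smallest batch id, matching the centralized rule.
    """
    sharing = global_type_sharing(clients)
    transcript = Transcript()
    rng = np.random.default_rng([int(fed_config.seed), 20177])
    by_batch = {str(c.batch): c for c in clients}
    if len(by_batch) != len(clients):
        raise ValueError("clients must hold distinct batches")

    dominant_client: dict = {}
    for t in sorted(sharing.shared, key=str):
        counts = {str(c.batch): int(c.type_counts.get(t, 0)) for c in clients}
        if fed_config.secure:
            win_batch = secure_argmax(
                counts, n_parties=fed_config.n_parties, rng=rng, transcript=transcript
            )
        else:
            best = max(counts.values())
            win_batch = min(b for b, n in counts.items() if n == best)
            transcript.record("coordinator", "argmax_winner", win_batch)
        dominant_client[t] = by_batch[win_batch].client_id

    # step 2: dominant clients broadcast their local type centroids
    means, dom_batch, dom_count = {}, {}, {}
    for t, cid in dominant_client.items():
        c = next(cl for cl in clients if cl.client_id == cid)
        sel = c.dataset.cell_type_labels == t
        if not sel.any():
            raise RuntimeError(f"dominant client for {t!r} holds no such cells")
        Z_t = encode(global_params, c.dataset.matrix[sel], deterministic=True)
        means[t] = Z_t.mean(axis=0)
        dom_batch[t] = str(c.batch)
        dom_count[t] = int(sel.sum())
        transcript.record("coordinator", "type_mean", {"type": t, "mean": means[t]})
    mean_map = TypeMeanMap(means=means, dominant_batch=dom_batch, dominant_count=dom_count)

    # step 3: every client corrects and decodes locally
    corrected, latents, latents_c = {}, {}, {}
    for c in clients:
        Z = encode(global_params, c.dataset.matrix, deterministic=True)
        Zc = correct_latent(
            Z, c.dataset.cell_type_labels, c.dataset.batch_labels.astype(str), mean_map
        )
        latents[c.client_id] = Z
        latents_c[c.client_id] = Zc
        corrected[c.client_id] = decode_corrected(global_params, c.dataset, Zc)
    return CorrectionResult(
        corrected=corrected,
        latents=latents,
        latents_corrected=latents_c,
        mean_map=mean_map,
        dominant_client=dominant_client,
        sharing=sharing,
        transcript=transcript,
        model_digest=params_digest(global_params),
    )


def export_public_means(result: CorrectionResult) -> dict:
    """Self-contained, JSON-serializable artifact of the broadcast centroids.

    Contains the model digest and per-type mean latent vectors — no
    per-cell data — so a new site holding the model can correct locally
    without rejoining the federation (valid while dominance is unchanged).
    """
    return {
        "model_digest": result.model_digest,
        "n_cells": 0,
        "types": {
            str(t): {
                "mean": np.asarray(result.mean_map.means[t]).tolist(),
                "dominant_batch": result.mean_map.dominant_batch[t],
                "dominant_count": result.mean_map.dominant_count[t],
            }
            for t in result.mean_map.types()
        },
    }


def apply_public_means(
    artifact: dict, params: VAEParams, ds: ExpressionDataset
) -> tuple[ExpressionDataset, np.ndarray]:
    """Correct a new site's data locally from an exported centroid artifact."""
    if artifact.get("model_digest") and artifact["model_digest"] != params_digest(params):
        raise ValueError("artifact was exported for a different model")
    mean_map = TypeMeanMap(
        means={t: np.asarray(v["mean"], dtype=np.float64) for t, v in artifact["types"].items()},
        dominant_batch={t: v["dominant_batch"] for t, v in artifact["types"].items()},
        dominant_count={t: v["dominant_count"] for t, v in artifact["types"].items()},
    )
    Z = encode(params, ds.matrix, deterministic=True)
    Zc = correct_latent(Z, ds.cell_type_labels, ds.batch_labels.astype(str), mean_map)
    return decode_corrected(params, ds, Zc), Zc
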