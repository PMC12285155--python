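"""Variational autoencoder for log-transformed expression, in NumPy.

Architecture: fully connected encoder and decoder with ReLU hidden layers
(defaults 800-800), a Gaussian latent of dimension 10, dropout on hidden
layers during training, linear output. The loss is mean-squared-error
reconstruction plus a KL divergence to the standard normal prior weighted
by ``kl_weight``. Training uses Adam with per-epoch seeded minibatching so
runs are bit-reproducible and federated schedules can match centralized
ones epoch for epoch.

Parameters live in a plain name->array mapping (:class:`VAEParams`) that
flattens to a single vector and back exactly — the unit of exchange in
federated averaging and secret sharing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VAEConfig",
    "VAEParams",
    "init_vae",
    "encode",
    "decode",
    "reparameterize",
    "vae_loss",
    "train_local",
    "train_with_early_stopping",
    "AdamState",
    "params_digest",
    "save_params",
    "load_params",
]

_LOGVAR_CLIP = 15.0  # numerical guard on exp(logvar)


@dataclass
class VAEConfig:
    input_dim: int
    hidden_dims: tuple[int, ...] = (800, 800)
    latent_dim: int = 10
    dropout: float = 0.05
    kl_weight: float = 0.005
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if self.input_dim < 1 or self.latent_dim < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("all layer dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


class VAEParams(dict):
    """Named parameter tensors of encoder and decoder.

    A thin dict subclass with exact flatten/unflatten (sorted name order)
    and a shape signature for compatibility checks.
    """

    def shape_signature(self) -> tuple[tuple[str, tuple[int, ...]], ...]:
        return tuple((k, self[k].shape) for k in sorted(self))

    def flatten(self) -> np.ndarray:
        return np.concatenate([self[k].ravel() for k in sorted(self)])

    def unflatten(self, vec: np.ndarray) -> "VAEParams":
        out = VAEParams()
        i = 0
        for k in sorted(self):
            n = self[k].size
            out[k] = vec[i : i + n].reshape(self[k].shape).copy()
            i += n
        if i != vec.size:
            raise ValueError("vector length does not match parameter count")
        return out

    def copy(self) -> "VAEParams":
        return VAEParams({k: v.copy() for k, v in self.items()})


def _layer_dims(config: VAEConfig) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    enc = []
    d = config.input_dim
    for h in config.hidden_dims:
        enc.append((d, h))
        d = h
    dec = []
    d = config.latent_dim
    for h in reversed(config.hidden_dims):
        dec.append((d, h))
        d = h
    return enc, dec


def init_vae(config: VAEConfig) -> VAEParams:
    """He-initialised parameters, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params = VAEParams()
    enc, dec = _layer_dims(config)
    for i, (fan_in, fan_out) in enumerate(enc):
        params[f"enc_W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"enc_b{i}"] = np.zeros(fan_out)
    h_last = config.hidden_dims[-1]
    for head in ("mu", "logvar"):
        params[f"enc_{head}_W"] = rng.normal(
            0, np.sqrt(1.0 / h_last), size=(h_last, config.latent_dim)
        )
        params[f"enc_{head}_b"] = np.zeros(config.latent_dim)
    for i, (fan_in, fan_out) in enumerate(dec):
        params[f"dec_W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"dec_b{i}"] = np.zeros(fan_out)
    params["dec_out_W"] = rng.normal(
        0, np.sqrt(1.0 / config.hidden_dims[0]), size=(config.hidden_dims[0], config.input_dim)
    )
    params["dec_out_b"] = np.zeros(config.input_dim)
    return params


def _n_hidden(params: VAEParams, prefix: str) -> int:
    return sum(1 for k in params if k.startswith(f"{prefix}_W") and k[len(prefix) + 2 :].isdigit())


def _forward_encoder(params, X, dropout=0.0, rng=None):
    h = X
    cache = []
    for i in range(_n_hidden(params, "enc")):
        pre = h @ params[f"enc_W{i}"] + params[f"enc_b{i}"]
        act = np.maximum(pre, 0.0)
        mask = None
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(act.shape) >= dropout) / (1.0 - dropout)
            act = act * mask
        cache.append((h, pre, mask))
        h = act
    mu = h @ params["enc_mu_W"] + params["enc_mu_b"]
    logvar = np.clip(h @ params["enc_logvar_W"] + params["enc_logvar_b"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    return mu, logvar, h, cache


def _forward_decoder(params, z, dropout=0.0, rng=None):
    h = z
    cache = []
    for i in range(_n_hidden(params, "dec")):
        pre = h @ params[f"dec_W{i}"] + params[f"dec_b{i}"]
        act = np.maximum(pre, 0.0)
        mask = None
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(act.shape) >= dropout) / (1.0 - dropout)
            act = act * mask
        cache.append((h, pre, mask))
        h = act
    Xr = h @ params["dec_out_W"] + params["dec_out_b"]
    return Xr, h, cache


def encode(params: VAEParams, X: np.ndarray, deterministic: bool = True):
    """Map expression rows to latent space in evaluation mode (no dropout).

    With ``deterministic=True`` returns the posterior mean only; otherwise
    returns ``(mu, logvar)``. A pure function of ``(params, X)``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params["enc_W0"].shape[0]:
        raise ValueError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
            f"model expects {params['enc_W0'].shape[0]}"
        )
    mu, logvar, _, _ = _forward_encoder(params, X)
    return mu if deterministic else (mu, logvar)


def decode(params: VAEParams, Z: np.ndarray) -> np.ndarray:
    """Decoder image of latent rows, evaluation mode."""
    Xr, _, _ = _forward_decoder(params, np.asarray(Z, dtype=np.float64))
    return Xr


def reparameterize(mu: np.ndarray, logvar: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """z = mu + exp(logvar / 2) * eps with eps ~ N(0, I)."""
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(0.5 * logvar) * eps


def vae_loss(X, X_recon, mu, logvar, kl_weight: float):
    """(total, recon, kl): MSE + weighted per-cell-mean Gaussian KL."""
    recon = float(np.mean((X - X_recon) ** 2))
    kl = float(0.5 * np.mean(np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar, axis=1)))
    return recon + kl_weight * kl, recon, kl


@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0


def _adam_step(params, grads, state: AdamState, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state.t += 1
    for k in params:
        g = grads[k]
        if k not in state.m:
            state.m[k] = np.zeros_like(params[k])
            state.v[k] = np.zeros_like(params[k])
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        mhat = state.m[k] / (1 - beta1**state.t)
        vhat = state.v[k] / (1 - beta2**state.t)
        params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)


def _backward(params, X, mu, logvar, eps_noise, z, Xr, h_enc, enc_cache, h_dec, dec_cache, kl_weight):
    B, G = X.shape
    grads = {}
    # reconstruction: d/dXr mean((X-Xr)^2)
    dXr = 2.0 * (Xr - X) / (B * G)
    grads["dec_out_W"] = h_dec.T @ dXr
    grads["dec_out_b"] = dXr.sum(axis=0)
    dh = dXr @ params["dec_out_W"].T
    for i in reversed(range(len(dec_cache))):
        h_in, pre, mask = dec_cache[i]
        if mask is not None:
            dh = dh * mask
        dpre = dh * (pre > 0)
        grads[f"dec_W{i}"] = h_in.T @ dpre
        grads[f"dec_b{i}"] = dpre.sum(axis=0)
        dh = dpre @ params[f"dec_W{i}"].T
    dz = dh
    # KL contributes through mu and logvar directly (per-cell mean)
    dmu = dz + kl_weight * mu / B
    dlogvar = dz * eps_noise * 0.5 * np.exp(0.5 * logvar) + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / B
    grads["enc_mu_W"] = h_enc.T @ dmu
    grads["enc_mu_b"] = dmu.sum(axis=0)
    grads["enc_logvar_W"] = h_enc.T @ dlogvar
    grads["enc_logvar_b"] = dlogvar.sum(axis=0)
    dh = dmu @ params["enc_mu_W"].T + dlogvar @ params["enc_logvar_W"].T
    for i in reversed(range(len(enc_cache))):
        h_in, pre, mask = enc_cache[i]
        if mask is not None:
            dh = dh * mask
        dpre = dh * (pre > 0)
        grads[f"enc_W{i}"] = h_in.T @ dpre
        grads[f"enc_b{i}"] = dpre.sum(axis=0)
        dh = dpre @ params[f"enc_W{i}"].T
    return grads


def train_local(
    params: VAEParams,
    ds,
    epochs: int,
    config: VAEConfig,
    seed: int | None = None,
    epoch_offset: int = 0,
    opt_state: AdamState | None = None,
):
    """Minibatch Adam training for ``epochs`` full passes.

    Epoch ``e`` (counting from ``epoch_offset``) draws its shuffle, dropout
    masks and reparameterization noise from ``default_rng([seed, e])``, so
    a schedule split across federation rounds reproduces an unbroken
    centralized run exactly when the offsets line up. Pass ``opt_state`` to
    continue Adam moments across calls.

    Returns ``(params', loss_trace, opt_state)`` with one
    ``(total, recon, kl)`` triple per epoch.
    """
    from fedbatch.data import LayerTag

    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X_all = ds.matrix if hasattr(ds, "matrix") else np.asarray(ds, dtype=np.float64)
    if hasattr(ds, "layer_tag") and ds.layer_tag is not LayerTag.log_transformed:
        raise ValueError("training expects the log-transformed layer")
    if X_all.shape[0] == 0:
        raise ValueError("cannot train on an empty dataset")
    if seed is None:
        seed = config.seed
    params = params.copy()
    state = opt_state if opt_state is not None else AdamState()
    trace = []
    n = X_all.shape[0]
    for e in range(epochs):
        rng = np.random.default_rng([int(seed), int(epoch_offset + e)])
        order = rng.permutation(n)
        tot = rec = kl = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X = X_all[idx]
            mu, logvar, h_enc, enc_cache = _forward_encoder(
                params, X, dropout=config.dropout, rng=rng
            )
            eps_noise = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * logvar) * eps_noise
            Xr, h_dec, dec_cache = _forward_decoder(params, z, dropout=config.dropout, rng=rng)
            t, r, k = vae_loss(X, Xr, mu, logvar, config.kl_weight)
            grads = _backward(
                params, X, mu, logvar, eps_noise, z, Xr, h_enc, enc_cache, h_dec, dec_cache,
                config.kl_weight,
            )
            _adam_step(params, grads, state, config.learning_rate)
            tot += t
            rec += r
            kl += k
            n_batches += 1
        trace.append((tot / n_batches, rec / n_batches, kl / n_batches))
    return params, trace, state


def _validation_loss(params, X_val, kl_weight):
    mu, logvar, _, _ = _forward_encoder(params, X_val)
    Xr, _, _ = _forward_decoder(params, mu)
    total, _, _ = vae_loss(X_val, Xr, mu, logvar, kl_weight)
    return total


def train_with_early_stopping(
    params: VAEParams,
    ds,
    config: VAEConfig,
    max_epochs: int = 100,
    patience: int = 20,
    min_delta: float = 0.0,
    val_fraction: float = 0.1,
    seed: int | None = None,
):
    """Train with a held-out validation split and patience-based stopping.

    Stops once the best validation loss has not improved by more than
    ``min_delta`` for ``patience`` consecutive epochs; returns the
    parameters from the best-validation epoch and the validation trace.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    if ds.n_cells < 2:
        raise ValueError("need at least 2 cells to split off validation")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 977])
    n = ds.n_cells
    n_val = max(1, int(round(val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_val = ds.matrix[val_idx]
    train_ds = ds.subset_cells(train_idx)

    best_loss = np.inf
    best_params = params.copy()
    stall = 0
    state = AdamState()
    val_trace = []
    cur = params.copy()
    for epoch in range(max_epochs):
        cur, _, state = train_local(
            cur, train_ds, 1, config, seed=seed, epoch_offset=epoch, opt_state=state
        )
        vl = _validation_loss(cur, X_val, config.kl_weight)
        val_trace.append(vl)
        if vl < best_loss - min_delta:
            best_loss = vl
            best_params = cur.copy()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return best_params, val_trace


# ---------------------------------------------------------------------------
# Checkpointing / audit
# ---------------------------------------------------------------------------


def params_digest(params: VAEParams) -> str:
    """SHA-256 of the flattened parameter vector (round-audit identifier)."""
    return hashlib.sha256(np.ascontiguousarray(params.flatten()).tobytes()).hexdigest()


def save_params(params: VAEParams, path) -> None:
    np.savez(path, **{k: params[k] for k in sorted(params)})


def load_params(path) -> VAEParams:
    with np.load(path) as f:
        return VAEParams({k: f[k].copy() for k in f.files})
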