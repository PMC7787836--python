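"""Stacked denoising sparse autoencoder, implemented from scratch in numpy.

One layer is a denoising sparse autoencoder (DSAE): a sigmoid autoencoder
trained to reconstruct the *clean* input from a masking-corrupted copy
(a fraction q of each sample's coordinates set to zero), with a KL-divergence
sparsity penalty pushing each hidden unit's mean activation toward a target
rho.  Three such layers are pretrained greedily — each on the previous
layer's clean hidden activations — then stacked under a softmax head and
fine-tuned end to end with early stopping on a held-out validation split.

Everything trains by plain mini-batch gradient descent with hand-derived
backpropagation; gradients of every parameter block are finite-difference
checkable via :func:`layer_loss_and_grads` and :func:`stack_loss_and_grads`.
All randomness (initialization, shuffling, corruption masks, the train/val
split) flows from a single seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DSAELayer",
    "TrainConfig",
    "TrainingDivergedError",
    "corrupt",
    "kl_sparsity",
    "layer_loss_and_grads",
    "stack_loss_and_grads",
    "pretrain_layer",
    "build_stack",
    "encode",
    "finetune",
    "softmax",
    "stack_forward",
    "stratified_split",
]

EPS = 1e-7  # clamp for logs in BCE and KL


class TrainingDivergedError(RuntimeError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def corrupt(X: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """Masking corruption: exactly floor(q*d) coordinates per sample set to zero.

    The zeroed coordinates are chosen uniformly at random, independently per
    sample; the deterministic per-sample count (rather than i.i.d. Bernoulli
    masking) makes the corruption level exactly testable.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"corruption fraction q must lie in [0, 1], got {q}")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    k = int(np.floor(q * d))
    if k == 0:
        return X.copy()
    # ranks of uniform draws give k uniformly-chosen coordinates per row
    u = rng.random((n, d))
    thresh = np.partition(u, k - 1, axis=1)[:, k - 1 : k]
    mask = u > thresh  # keeps d - k coordinates
    return X * mask


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || rho_hat) for Bernoulli means.

    Zero iff every unit's mean activation equals the target rho; strictly
    positive otherwise (Gibbs' inequality).  rho_hat is clamped away from
    {0, 1} for numerical safety.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"sparsity target rho must lie in (0, 1), got {rho}")
    rh = np.clip(np.asarray(rho_hat, dtype=float), EPS, 1.0 - EPS)
    return float(np.sum(rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh))))


@dataclass
class DSAELayer:
    """One denoising sparse autoencoder layer (sigmoid encoder + decoder)."""

    input_dim: int
    hidden_dim: int = 20
    q: float = 0.5  # corruption fraction
    rho: float = 0.1  # sparsity target
    beta: float = 0.1  # sparsity-penalty weight
    recon_loss: str = "bce"  # "bce" for binary inputs, "mse" optional
    tied: bool = False  # tie W_dec = W_enc.T
    W_enc: np.ndarray = field(default=None, repr=False)
    b_enc: np.ndarray = field(default=None, repr=False)
    W_dec: np.ndarray = field(default=None, repr=False)
    b_dec: np.ndarray = field(default=None, repr=False)
    loss_trace: list = field(default_factory=list, repr=False)

    def initialize(self, rng: np.random.Generator) -> "DSAELayer":
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")
        self.W_enc = glorot_uniform(rng, self.input_dim, self.hidden_dim)
        self.b_enc = np.zeros(self.hidden_dim)
        self.W_dec = (
            self.W_enc.T.copy() if self.tied else glorot_uniform(rng, self.hidden_dim, self.input_dim)
        )
        self.b_dec = np.zeros(self.input_dim)
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected input width {self.input_dim}, got {X.shape[1]}")
        return _sigmoid(X @ self.W_enc + self.b_enc)

    def params(self) -> dict[str, np.ndarray]:
        return {"W_enc": self.W_enc, "b_enc": self.b_enc, "W_dec": self.W_dec, "b_dec": self.b_dec}


def layer_loss_and_grads(
    params: dict[str, np.ndarray],
    x_clean: np.ndarray,
    x_corrupt: np.ndarray,
    rho: float,
    beta: float,
    recon_loss: str = "bce",
) -> tuple[float, dict[str, np.ndarray]]:
    """Denoising reconstruction loss + beta * KL sparsity, with analytic gradients.

    Reconstruction loss is summed over features and averaged over the batch;
    the KL penalty is computed on the batch-mean hidden activation.  The
    corrupted batch is an explicit argument so gradients are exactly
    finite-difference checkable for a fixed corruption draw.
    """
    W_enc, b_enc, W_dec, b_dec = params["W_enc"], params["b_enc"], params["W_dec"], params["b_dec"]
    B = x_clean.shape[0]

    h = _sigmoid(x_corrupt @ W_enc + b_enc)  # (B, H)
    rho_hat = h.mean(axis=0)
    xhat = _sigmoid(h @ W_dec + b_dec)  # (B, D)

    if recon_loss == "bce":
        xh = np.clip(xhat, EPS, 1.0 - EPS)
        rec = -np.sum(x_clean * np.log(xh) + (1.0 - x_clean) * np.log(1.0 - xh)) / B
        dz2 = (xhat - x_clean) / B  # sigmoid + BCE cancellation
    elif recon_loss == "mse":
        diff = xhat - x_clean
        rec = 0.5 * np.sum(diff * diff) / B
        dz2 = diff * xhat * (1.0 - xhat) / B
    else:
        raise ValueError(f"unknown recon_loss {recon_loss!r}")

    loss = rec + beta * kl_sparsity(rho, rho_hat)

    dW_dec = h.T @ dz2
    db_dec = dz2.sum(axis=0)

    dh = dz2 @ W_dec.T
    rh = np.clip(rho_hat, EPS, 1.0 - EPS)
    dkl_drho_hat = -rho / rh + (1.0 - rho) / (1.0 - rh)
    dh = dh + beta * dkl_drho_hat / B  # rho_hat = mean over batch
    dz1 = dh * h * (1.0 - h)
    dW_enc = x_corrupt.T @ dz1
    db_enc = dz1.sum(axis=0)

    return loss, {"W_enc": dW_enc, "b_enc": db_enc, "W_dec": dW_dec, "b_dec": db_dec}


@dataclass(frozen=True)
class TrainConfig:
    epochs_pretrain: int = 100
    epochs_finetune: int = 200
    learning_rate: float = 0.1
    batch_size: int = 32
    val_fraction: float = 0.20
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must lie in (0, 1), got {self.val_fraction}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        for name in ("epochs_pretrain", "epochs_finetune", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def pretrain_layer(
    X: np.ndarray, layer: DSAELayer, cfg: TrainConfig, rng: np.random.Generator
) -> DSAELayer:
    """Train one DSAE by mini-batch gradient descent on the denoising objective."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != layer.input_dim:
        raise ValueError(f"data width {X.shape[1]} != layer input_dim {layer.input_dim}")
    if layer.W_enc is None:
        layer.initialize(rng)

    n = X.shape[0]
    for epoch in range(cfg.epochs_pretrain):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start : start + cfg.batch_size]]
            corrupted = corrupt(batch, layer.q, rng)
            loss, grads = layer_loss_and_grads(
                layer.params(), batch, corrupted, layer.rho, layer.beta, layer.recon_loss
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"pretraining loss diverged at epoch {epoch}")
            if layer.tied:
                gW = grads["W_enc"] + grads["W_dec"].T
                layer.W_enc -= cfg.learning_rate * gW
                layer.W_dec = layer.W_enc.T.copy()
            else:
                layer.W_enc -= cfg.learning_rate * grads["W_enc"]
                layer.W_dec -= cfg.learning_rate * grads["W_dec"]
            layer.b_enc -= cfg.learning_rate * grads["b_enc"]
            layer.b_dec -= cfg.learning_rate * grads["b_dec"]
            epoch_loss += loss
            n_batches += 1
        layer.loss_trace.append(epoch_loss / n_batches)
    return layer


def build_stack(
    X: np.ndarray,
    cfg: TrainConfig,
    hidden_dims: tuple[int, ...] = (20, 20, 20),
    q: float = 0.5,
    rho: float = 0.1,
    beta: float = 0.1,
    recon_loss: str = "bce",
    tied: bool = False,
) -> list[DSAELayer]:
    """Greedy layerwise pretraining: each layer trains on the previous layer's
    clean (uncorrupted) hidden activations."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    layers: list[DSAELayer] = []
    rep = X
    for h in hidden_dims:
        layer = DSAELayer(
            input_dim=rep.shape[1], hidden_dim=h, q=q, rho=rho, beta=beta,
            recon_loss=recon_loss, tied=tied,
        )
        pretrain_layer(rep, layer, cfg, rng)
        layers.append(layer)
        rep = layer.encode(rep)
    return layers


def encode(layers: list[DSAELayer], X: np.ndarray) -> np.ndarray:
    rep = np.asarray(X, dtype=float)
    for layer in layers:
        rep = layer.encode(rep)
    return rep


def stack_forward(params: list[tuple[np.ndarray, np.ndarray]], X: np.ndarray) -> np.ndarray:
    """Forward pass through sigmoid encoder layers + softmax head.

    ``params`` is [(W1, b1), ..., (Wk, bk), (W_soft, b_soft)].
    Returns class probabilities (n, 2).
    """
    rep = np.asarray(X, dtype=float)
    for W, b in params[:-1]:
        rep = _sigmoid(rep @ W + b)
    W_s, b_s = params[-1]
    return softmax(rep @ W_s + b_s)


def stack_loss_and_grads(
    params: list[tuple[np.ndarray, np.ndarray]], X: np.ndarray, y: np.ndarray
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean cross-entropy of the stacked network, with gradients for all blocks."""
    B = X.shape[0]
    acts = [np.asarray(X, dtype=float)]
    for W, b in params[:-1]:
        acts.append(_sigmoid(acts[-1] @ W + b))
    W_s, b_s = params[-1]
    probs = softmax(acts[-1] @ W_s + b_s)
    p_true = np.clip(probs[np.arange(B), y], EPS, 1.0)
    loss = float(-np.mean(np.log(p_true)))

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads: list[tuple[np.ndarray, np.ndarray]] = [(acts[-1].T @ dlogits, dlogits.sum(axis=0))]
    da = dlogits @ W_s.T
    for k in range(len(params) - 2, -1, -1):
        W, _ = params[k]
        dz = da * acts[k + 1] * (1.0 - acts[k + 1])
        grads.append((acts[k].T @ dz, dz.sum(axis=0)))
        da = dz @ W.T
    grads.reverse()
    return loss, grads


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/validation index split.

    Total validation size is round(val_fraction * n); per-class allocation by
    largest remainder, with at least one training sample kept per class.
    """
    y = np.asarray(labels)
    n = len(y)
    n_val = int(round(val_fraction * n))
    classes, counts = np.unique(y, return_counts=True)
    quotas = val_fraction * counts
    alloc = np.floor(quotas).astype(int)
    remainder_order = np.argsort(-(quotas - alloc))
    for k in remainder_order:
        if alloc.sum() >= n_val:
            break
        alloc[k] += 1
    alloc = np.minimum(alloc, counts - 1)  # keep >= 1 training sample per class
    train_idx, val_idx = [], []
    for cls, a in zip(classes, alloc):
        idx = rng.permutation(np.flatnonzero(y == cls))
        val_idx.append(idx[:a])
        train_idx.append(idx[a:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def finetune(
    layers: list[DSAELayer], X: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict]:
    """Supervised fine-tuning of the stacked encoders + softmax head.

    Splits samples into a stratified train/validation partition, minimizes
    cross-entropy on the training part by full backpropagation (no corruption),
    and stops early when validation loss has not improved for ``patience``
    epochs, restoring the best-validation parameters.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("fine-tuning requires both classes present")

    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_split, rng_init, rng_shuffle = (np.random.default_rng(s) for s in ss)

    train_idx, val_idx = stratified_split(y, cfg.val_fraction, rng_split)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split is single-class; increase n or reduce val_fraction")
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    params: list[tuple[np.ndarray, np.ndarray]] = [
        (layer.W_enc.copy(), layer.b_enc.copy()) for layer in layers
    ]
    h_dim = layers[-1].hidden_dim
    params.append((glorot_uniform(rng_init, h_dim, 2), np.zeros(2)))

    best_val = np.inf
    best_params = [(W.copy(), b.copy()) for W, b in params]
    best_epoch = -1
    since_improved = 0
    log = {"train_loss": [], "val_loss": [], "n_train": len(train_idx), "n_val": len(val_idx)}

    n = len(y_tr)
    for epoch in range(cfg.epochs_finetune):
        order = rng_shuffle.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, grads = stack_loss_and_grads(params, X_tr[sel], y_tr[sel])
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"fine-tuning loss diverged at epoch {epoch}")
            params = [
                (W - cfg.learning_rate * gW, b - cfg.learning_rate * gb)
                for (W, b), (gW, gb) in zip(params, grads)
            ]
            epoch_loss += loss
            n_batches += 1
        val_loss, _ = stack_loss_and_grads(params, X_val, y_val) if len(y_val) else (epoch_loss / n_batches, None)
        log["train_loss"].append(epoch_loss / n_batches)
        log["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = float(val_loss)
            best_params = [(W.copy(), b.copy()) for W, b in params]
            best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= cfg.patience:
                break
    log["best_epoch"] = best_epoch
    log["best_val_loss"] = best_val
    return best_params, log
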