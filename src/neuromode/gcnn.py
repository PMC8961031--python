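"""Attention-based spectral graph convolutional network over EEG channels.

Each vertex is an EEG channel; the adjacency A (initialised randomly,
symmetric, unit self-loops) is re-estimated by a graph-attention layer:

    alpha_ij = softmax_j( LeakyReLU( w^T [ z_i || z_j ] ) )        (attention)
    A' = sym( alpha A )                                            (adjacency update)
    h'_i = sigma( sum_j alpha_ij * z_i )                           (feature update)

where z is either ``A h`` (the "adjacency" attention input) or a learned
linear projection ``W h`` (the "projection" input, canonical graph-attention
form; the default).  The network then applies spectral graph convolutions on
the Laplacian of the updated adjacency,

    L = D - A' = U Lambda U^T,     y = U g_theta U^T x,

with a free per-eigenvalue gain vector g_theta per layer, global mean
pooling over vertices, and a dense sigmoid head trained with cross-entropy
by plain full-batch gradient descent.  All gradients are computed
analytically in numpy, including the backward pass through the symmetric
eigendecomposition.

The feature update as written above is degenerate in the "adjacency" mode:
the row sums of alpha are identically 1, so alpha drops out of h' and the
attention parameters receive gradient only through the Laplacian.  The
"projection" mode uses the canonical form h'_i = sigma(sum_j alpha_ij z_j),
which keeps the attention trainable through the features as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# elementary pieces (kept standalone so they can be verified in isolation)


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, np.exp(np.minimum(x, 0.0)))


def attention_coefficients(
    h: np.ndarray,
    w: np.ndarray,
    adjacency: np.ndarray,
    leaky_slope: float = 0.2,
    mode: str = "adjacency",
    projection: np.ndarray | None = None,
    neighbor_threshold: float = 0.0,
) -> np.ndarray:
    """Attention coefficient matrix alpha (rows sum to 1 over neighbourhoods).

    ``mode='adjacency'`` feeds ``z = A h`` into the scoring function exactly
    as the update rule above states; ``mode='projection'`` feeds ``z = h W^T``
    (canonical graph attention).  The neighbourhood of i is every j with
    ``A_ij > neighbor_threshold``; an empty neighbourhood falls back to the
    self edge.
    """
    n = adjacency.shape[0]
    if h.shape[0] != n:
        raise ValueError("feature rows must match the number of nodes")
    if mode == "adjacency":
        z = adjacency @ h
    elif mode == "projection":
        if projection is None:
            raise ValueError("projection mode requires a projection matrix")
        z = h @ projection.T
    else:
        raise ValueError(f"unknown attention mode {mode!r}")
    fdim = z.shape[1]
    if w.shape[0] != 2 * fdim:
        raise ValueError(f"attention vector must have length {2 * fdim}")
    a1 = z @ w[:fdim]
    a2 = z @ w[fdim:]
    scores = leaky_relu(a1[:, None] + a2[None, :], leaky_slope)
    mask = adjacency > neighbor_threshold
    empty = ~mask.any(axis=1)
    if empty.any():
        mask[np.flatnonzero(empty), np.flatnonzero(empty)] = True
    scores = np.where(mask, scores, -np.inf)
    scores -= scores.max(axis=1, keepdims=True)
    expo = np.exp(scores)
    return expo / expo.sum(axis=1, keepdims=True)


def update_adjacency(alpha: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """A' = alpha @ A (matrix product), symmetrised to (A' + A'^T)/2.

    The product of a row-stochastic matrix with a symmetric one is generally
    asymmetric; the symmetrisation keeps the downstream Laplacian
    real-symmetric.
    """
    a1 = alpha @ adjacency
    return 0.5 * (a1 + a1.T)


def update_features(
    h: np.ndarray,
    alpha: np.ndarray,
    adjacency: np.ndarray,
    mode: str = "adjacency",
    projection: np.ndarray | None = None,
) -> np.ndarray:
    """Attention-layer feature update h'.

    ``adjacency`` mode: h'_i = elu( (sum_j alpha_ij) * (A h)_i ) — the rule
    as stated, whose alpha-sum is identically one.  ``projection`` mode:
    h'_i = elu( sum_j alpha_ij (h W^T)_j ).
    """
    if mode == "adjacency":
        z = adjacency @ h
        s = alpha.sum(axis=1)
        return elu(s[:, None] * z)
    if mode == "projection":
        if projection is None:
            raise ValueError("projection mode requires a projection matrix")
        return elu(alpha @ (h @ projection.T))
    raise ValueError(f"unknown attention mode {mode!r}")


def laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - A for a symmetric non-negative adjacency."""
    if not np.allclose(adjacency, adjacency.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    return np.diag(adjacency.sum(axis=1)) - adjacency


def spectral_decomposition(lap: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition L = U diag(lam) U^T with ascending eigenvalues."""
    lam, u = np.linalg.eigh(lap)
    return u, lam


def spectral_conv(x: np.ndarray, u: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Spectral graph convolution y = U diag(g) U^T x.

    ``g`` is the free per-eigenvalue gain vector (one gain per Laplacian
    eigenvalue, in the same ascending order as the decomposition).
    """
    if x.shape[-2] != u.shape[0] or g.shape[0] != u.shape[0]:
        raise ValueError("dimension mismatch in spectral convolution")
    return u @ (g[:, None] * (u.T @ x))


# ---------------------------------------------------------------------------
# model


@dataclass
class GraphModel:
    """Learnable state of the attention GCNN.

    ``params`` holds every gradient-trained array; ``adjacency`` is the
    graph state, updated by the attention rule (not by gradients).
    """

    n_nodes: int
    n_features: int = 1
    n_hidden: int = 4
    n_gcn_layers: int = 2
    attention_mode: str = "projection"
    leaky_slope: float = 0.2
    neighbor_threshold: float = 0.0
    backprop_spectrum: bool = True
    adjacency_update_rate: float = 0.3
    seed: int = 0
    adjacency: np.ndarray = field(init=False)
    params: dict = field(init=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        rng = np.random.default_rng(self.seed)
        a = rng.uniform(0.0, 1.0, (self.n_nodes, self.n_nodes))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)  # documented rule: unit self-loops
        self.adjacency = a
        fdim = self.n_hidden if self.attention_mode == "projection" else self.n_features
        self.params = {
            "w": 0.1 * rng.standard_normal(2 * fdim),
            "g": [
                1.0 + 0.01 * rng.standard_normal(self.n_nodes)
                for _ in range(self.n_gcn_layers)
            ],
            "dense_w": 0.1 * rng.standard_normal(fdim),
            "dense_b": 0.0,
        }
        if self.attention_mode == "projection":
            self.params["proj"] = rng.standard_normal((self.n_hidden, self.n_features)) / np.sqrt(
                self.n_features
            )

    # -- forward -----------------------------------------------------------

    def forward(self, h: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Class-1 probabilities for a batch ``h`` of shape (B, nodes, F).

        Attention coefficients are computed per sample (the layer is meant
        to track state-dependent network dynamics); the shared adjacency is
        updated from the batch-mean coefficient matrix, and the Laplacian of
        that updated adjacency drives the spectral convolutions for every
        sample.  Mean pooling over vertices and a dense sigmoid head close
        the network.
        """
        p = self.params
        if self.attention_mode == "adjacency":
            z = np.matmul(self.adjacency, h)
        else:
            z = np.matmul(h, p["proj"].T)
        fdim = z.shape[2]
        a1 = z @ p["w"][:fdim]  # (B, n)
        a2 = z @ p["w"][fdim:]
        raw = a1[:, :, None] + a2[:, None, :]  # (B, n, n)
        scores = leaky_relu(raw, self.leaky_slope)
        mask = self.adjacency > self.neighbor_threshold
        empty = ~mask.any(axis=1)
        if empty.any():
            mask[np.flatnonzero(empty), np.flatnonzero(empty)] = True
        shifted = np.where(mask[None, :, :], scores, -np.inf)
        mx = shifted.max(axis=2, keepdims=True)
        expo = np.exp(shifted - mx)
        alpha = expo / expo.sum(axis=2, keepdims=True)  # (B, n, n)

        alpha_mean = alpha.mean(axis=0)
        a_upd = update_adjacency(alpha_mean, self.adjacency)
        lap = np.diag(a_upd.sum(axis=1)) - a_upd
        lam, u = np.linalg.eigh(lap)

        if self.attention_mode == "adjacency":
            s = alpha.sum(axis=2)  # identically 1 per row
            pre_f = s[:, :, None] * z
        else:
            pre_f = np.matmul(alpha, z)
        hf = elu(pre_f)

        xs = [hf]
        pres = []
        for g in p["g"]:
            t = np.matmul(u.T, xs[-1])  # U^T x, broadcast over the batch
            y = np.matmul(u, g[None, :, None] * t)  # U (g o t)
            pres.append((t, y))
            xs.append(elu(y))
        pooled = xs[-1].mean(axis=1)
        logit = np.clip(pooled @ p["dense_w"] + p["dense_b"], -30.0, 30.0)
        prob = 1.0 / (1.0 + np.exp(-logit))

        if cache is not None:
            cache.update(
                h=h, z=z, raw=raw, mask=mask, alpha=alpha,
                a_upd=a_upd, lap=lap, u=u, lam=lam, pre_f=pre_f,
                xs=xs, pres=pres, pooled=pooled, logit=logit, prob=prob,
            )
        return prob

    # -- loss and analytic gradients --------------------------------------

    def loss(self, h: np.ndarray, labels: np.ndarray) -> float:
        prob = self.forward(h)
        return float(_bce(prob, labels))

    def loss_and_grads(
        self, h: np.ndarray, labels: np.ndarray, cache: dict | None = None
    ) -> tuple[float, dict]:
        """Cross-entropy loss and analytic gradients of every parameter."""
        p = self.params
        if cache is None:
            cache = {}
        prob = self.forward(h, cache)
        y = np.asarray(labels, dtype=float)
        bsz = y.size
        loss_val = float(_bce(prob, y))

        grads = {
            "w": np.zeros_like(p["w"]),
            "g": [np.zeros_like(g) for g in p["g"]],
            "dense_w": np.zeros_like(p["dense_w"]),
            "dense_b": 0.0,
        }
        if "proj" in p:
            grads["proj"] = np.zeros_like(p["proj"])

        u, lam = cache["u"], cache["lam"]
        dlogit = (prob - y) / bsz
        grads["dense_w"] = cache["pooled"].T @ dlogit
        grads["dense_b"] = float(dlogit.sum())
        dpooled = dlogit[:, None] * p["dense_w"][None, :]
        n = self.n_nodes
        dx = np.repeat(dpooled[:, None, :], n, axis=1) / n

        dU = np.zeros_like(u)
        for gi in reversed(range(len(p["g"]))):
            g = p["g"][gi]
            t, ypre = cache["pres"][gi]
            x_in = cache["xs"][gi]
            dy = dx * _elu_grad(ypre)
            dM = np.matmul(u.T, dy)  # U^T dy
            grads["g"][gi] += (dM * t).sum(axis=(0, 2))
            dt = g[None, :, None] * dM
            gt = g[None, :, None] * t
            dU += np.tensordot(dy, gt, axes=([0, 2], [0, 2]))  # dy @ M^T
            dU += np.tensordot(x_in, dt, axes=([0, 2], [0, 2]))  # x @ dt^T
            dx = np.matmul(u, dt)

        dhf = dx
        dpre_f = dhf * _elu_grad(cache["pre_f"])
        alpha = cache["alpha"]
        z = cache["z"]
        bsz_f = float(alpha.shape[0])
        dz = np.zeros_like(z)
        if self.attention_mode == "projection":
            dalpha = np.matmul(dpre_f, z.transpose(0, 2, 1))
            dz += np.matmul(alpha.transpose(0, 2, 1), dpre_f)
        else:
            ds = (dpre_f * z).sum(axis=2)  # via row sums of alpha
            dalpha = ds[:, :, None] * np.ones_like(alpha)
            s = alpha.sum(axis=2)
            dz += s[:, :, None] * dpre_f

        if self.backprop_spectrum:
            # backward through L = U diag(lam) U^T (dlam = 0: the gains are
            # indexed by eigenvalue position, not by eigenvalue magnitude)
            ut_du = u.T @ dU
            gap = lam[None, :] - lam[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(np.abs(gap) > 1e-9, 1.0 / gap, 0.0)
            inner = f * ut_du
            dlap = u @ inner @ u.T
            dlap = 0.5 * (dlap + dlap.T)
            # L = D - A': dA'_ij = dL_ii - dL_ij
            dA = np.diag(dlap)[:, None] * np.ones_like(dlap) - dlap
            dA1 = 0.5 * (dA + dA.T)
            dalpha += (dA1 @ self.adjacency.T)[None, :, :] / bsz_f

        # softmax backward, per sample and row
        row_dot = (dalpha * alpha).sum(axis=2, keepdims=True)
        dscores = alpha * (dalpha - row_dot)
        slope = self.leaky_slope
        draw = dscores * np.where(cache["raw"] >= 0, 1.0, slope) * cache["mask"][None, :, :]
        da1 = draw.sum(axis=2)  # (B, n)
        da2 = draw.sum(axis=1)
        fdim = z.shape[2]
        grads["w"][:fdim] += (z * da1[:, :, None]).sum(axis=(0, 1))
        grads["w"][fdim:] += (z * da2[:, :, None]).sum(axis=(0, 1))
        dz += da1[:, :, None] * p["w"][None, None, :fdim] \
            + da2[:, :, None] * p["w"][None, None, fdim:]
        if self.attention_mode == "projection":
            grads["proj"] += np.tensordot(dz, h, axes=([0, 1], [0, 1]))
        # adjacency mode: z = A h has no trainable parameters upstream

        return loss_val, grads


def _bce(prob: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    y = np.asarray(labels, dtype=float)
    return float(-(y * np.log(prob) + (1 - y) * np.log(1 - prob)).mean())


def save_graph_batch(path_arrays, path_labels, features: np.ndarray, labels: np.ndarray) -> None:
    """Write a node-feature batch (.npz) plus a delimited label file."""
    np.savez_compressed(path_arrays, features=features)
    pd.DataFrame({"label": np.asarray(labels).astype(int)}).to_csv(
        path_labels, sep="\t", index=False
    )


def load_graph_batch(path_arrays, path_labels) -> tuple[np.ndarray, np.ndarray]:
    """Read a batch written by :func:`save_graph_batch`."""
    with np.load(path_arrays, allow_pickle=False) as data:
        features = data["features"]
    labels = pd.read_csv(path_labels, sep="\t")["label"].to_numpy()
    return features, labels


def init_model(n_nodes: int, n_gcn_layers: int = 2, seed: int = 0, **kw) -> GraphModel:
    """Construct a reproducible model with a random symmetric adjacency."""
    return GraphModel(n_nodes=n_nodes, n_gcn_layers=n_gcn_layers, seed=seed, **kw)


@dataclass
class TrainResult:
    """Outcome of a training run: final model, accuracies, loss trace."""

    model: GraphModel
    train_accuracy: float
    val_accuracy: float
    losses: np.ndarray
    adjacency: np.ndarray  # final updated adjacency A'

    def summary(self) -> str:
        return (
            f"attention-GCNN ({self.model.attention_mode} attention, "
            f"{self.model.n_gcn_layers} conv layers, {self.model.n_nodes} nodes)\n"
            f"  epochs run      : {len(self.losses)}\n"
            f"  final loss      : {self.losses[-1]:.4f}\n"
            f"  train accuracy  : {self.train_accuracy:.3f}\n"
            f"  held-out accuracy: {self.val_accuracy:.3f}"
        )


def train(
    model: GraphModel,
    features: np.ndarray,
    labels: np.ndarray,
    lr: float = 0.05,
    epochs: int = 200,
    val_fraction: float = 0.25,
    seed: int | None = None,
    momentum: float = 0.9,
) -> TrainResult:
    """Train by full-batch gradient descent (heavy-ball momentum) on
    cross-entropy.

    ``momentum=0`` gives plain gradient descent.  A stratified held-out
    split (``val_fraction``) provides the reported accuracy.  After every
    gradient step the adjacency state is moved toward the attention-updated
    adjacency at ``model.adjacency_update_rate``.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each of two classes")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    val_idx = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        val_idx.extend(idx[: max(1, int(round(val_fraction * idx.size)))])
    val_mask = np.zeros(labels.size, dtype=bool)
    val_mask[val_idx] = True
    h_tr, y_tr = features[~val_mask], labels[~val_mask]
    h_va, y_va = features[val_mask], labels[val_mask]

    losses = []
    velocity: dict = {}
    for _ in range(epochs):
        fwd_cache: dict = {}
        loss_val, grads = model.loss_and_grads(h_tr, y_tr, cache=fwd_cache)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss at epoch {len(losses)}; "
                f"lr={lr}, mode={model.attention_mode}"
            )
        losses.append(loss_val)
        p = model.params

        def _step(key, param, grad):
            vel = velocity.get(key)
            vel = momentum * vel - lr * grad if vel is not None else -lr * grad
            velocity[key] = vel
            param += vel

        _step("w", p["w"], grads["w"])
        for li, (g, dg) in enumerate(zip(p["g"], grads["g"])):
            _step(f"g{li}", g, dg)
        _step("dense_w", p["dense_w"], grads["dense_w"])
        p["dense_b"] -= lr * grads["dense_b"]
        if "proj" in p:
            _step("proj", p["proj"], grads["proj"])
        if model.adjacency_update_rate > 0:
            # attention rule: move the graph state toward the updated
            # adjacency of this epoch's forward pass
            tau = model.adjacency_update_rate
            model.adjacency = (1 - tau) * model.adjacency + tau * fwd_cache["a_upd"]
            # documented diagonal rule: unit self-loops are maintained
            # through the attention updates
            np.fill_diagonal(model.adjacency, 1.0)

    cache = {}
    prob_tr = model.forward(h_tr, cache)
    acc_tr = float(((prob_tr > 0.5).astype(int) == y_tr).mean())
    prob_va = model.forward(h_va)
    acc_va = float(((prob_va > 0.5).astype(int) == y_va).mean())
    return TrainResult(
        model=model,
        train_accuracy=acc_tr,
        val_accuracy=acc_va,
        losses=np.array(losses),
        adjacency=cache["a_upd"],
    )


def rank_edges(
    result: TrainResult | np.ndarray,
    k: int = 15,
    channel_names: list[str] | None = None,
    norm_rule: str = "max",
) -> pd.DataFrame:
    """Top-k edges of the final updated adjacency, weights normalised.

    Edges are the strict upper triangle (i < j); self-loops are never
    edges.  ``norm_rule``: 'max' divides by the largest edge weight of the
    full adjacency (so the top-ranked edge is exactly 1), 'sum' by the sum
    of the selected weights, 'minmax' maps the selected weights to [0, 1].
    """
    a = result.adjacency if isinstance(result, TrainResult) else np.asarray(result)
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = a[iu, ju]
    k = min(k, weights.size)
    top = np.argsort(weights)[::-1][:k]
    sel = weights[top]
    if norm_rule == "max":
        sel = sel / np.abs(weights).max()
    elif norm_rule == "sum":
        sel = sel / sel.sum()
    elif norm_rule == "minmax":
        rng_ = sel.max() - sel.min()
        sel = (sel - sel.min()) / (rng_ if rng_ > 0 else 1.0)
    else:
        raise ValueError(f"unknown norm rule {norm_rule!r}")
    names = channel_names if channel_names is not None else [str(i) for i in range(n)]
    return pd.DataFrame(
        {
            "node_i": [names[i] for i in iu[top]],
            "node_j": [names[j] for j in ju[top]],
            "weight_normalized": sel,
        }
    )
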