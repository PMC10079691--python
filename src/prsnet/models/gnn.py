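"""LD-graph convolutional classifier.

Each sample is a graph whose nodes are the selected variants.  Node
features are the allele dosage plus functional-annotation counts
(coding/UTR flags and histone, open-chromatin, polymerase and
transcription-factor-binding event counts), normalized dimension-wise.
Edges connect variant pairs whose dosage r^2 exceeds a threshold (default
0.6); self-loops are added and the adjacency is symmetrically normalized
``D^{-1/2} (A + I) D^{-1/2}`` for the convolution.

The network is three graph-convolution layers (rectifier nonlinearity,
hidden width 128), global max pooling over nodes, a dense rectifier layer
of width 64, and a sigmoid output unit.  Training uses adaptive-moment
(Adam) optimisation with early stopping (patience 20).  Implementation is
plain numpy in float32; fully seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..datamodel import ANNOTATION_KEYS, GenotypeMatrix

__all__ = ["SampleGraphs", "GraphPRSModel", "build_graphs", "train_gnn",
           "gnn_score"]


@dataclass
class SampleGraphs:
    """Per-sample node-feature tensor plus the shared normalized adjacency.

    ``features`` has shape (n_samples, n_nodes, n_features); ``adjacency``
    is the raw 0/1 edge matrix (no self-loops) and ``a_hat`` the
    normalized operator used by the convolution.
    """

    features: np.ndarray
    adjacency: np.ndarray
    a_hat: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def build_graphs(geno: GenotypeMatrix, ld: np.ndarray, *,
                 r2_threshold: float = 0.6,
                 normalize: bool = True,
                 feature_stats: Optional[tuple] = None) -> SampleGraphs:
    """Assemble per-sample variant graphs from dosages, annotations and LD.

    ``feature_stats`` (mean, sd) lets held-out data reuse the training
    normalization.
    """
    n_nodes = geno.n_variants
    if ld.shape != (n_nodes, n_nodes):
        raise ValueError("LD matrix does not match the genotype variants")
    adj = (ld > r2_threshold).astype(np.float32)
    np.fill_diagonal(adj, 0.0)
    a = adj + np.eye(n_nodes, dtype=np.float32)
    deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    a_hat = (a * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]

    dosage = geno.impute_mean().dosage.astype(np.float32)
    ann = np.stack([v.annotation_vector(ANNOTATION_KEYS) for v in geno.variants]
                   ).astype(np.float32)  # (n_nodes, n_ann)
    n_samples = geno.n_samples
    feats = np.empty((n_samples, n_nodes, 1 + ann.shape[1]), dtype=np.float32)
    feats[:, :, 0] = dosage
    feats[:, :, 1:] = ann[None, :, :]
    if normalize:
        if feature_stats is None:
            flat = feats.reshape(-1, feats.shape[2])
            mean = flat.mean(axis=0)
            sd = flat.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
        else:
            mean, sd = feature_stats
        feats = (feats - mean) / sd
    else:
        mean = np.zeros(feats.shape[2], dtype=np.float32)
        sd = np.ones(feats.shape[2], dtype=np.float32)
    return SampleGraphs(feats.astype(np.float32), adj,
                        a_hat.astype(np.float32),
                        mean.astype(np.float32), sd.astype(np.float32))


def _relu(x):
    return np.maximum(x, 0.0)


@dataclass
class GraphPRSModel:
    """Trained graph-convolutional risk classifier."""

    conv_weights: list = field(repr=False, default=None)
    conv_biases: list = field(repr=False, default=None)
    dense_weights: list = field(repr=False, default=None)
    dense_biases: list = field(repr=False, default=None)
    hidden_dim: int = 128
    classifier_dim: int = 64
    r2_threshold: float = 0.6
    feature_mean: np.ndarray = field(repr=False, default=None)
    feature_sd: np.ndarray = field(repr=False, default=None)
    init_seed: int = 0
    trained: bool = False
    history: dict = field(default_factory=dict, repr=False)

    def _forward(self, feats: np.ndarray, a_hat: np.ndarray,
                 keep_cache: bool = False):
        h = feats
        cache = {"conv_in": [], "conv_pre": []}
        for W, b in zip(self.conv_weights, self.conv_biases):
            if keep_cache:
                cache["conv_in"].append(h)
            # shared adjacency: contract over the node axis then mix features
            ah = np.einsum("uv,bvf->buf", a_hat, h, optimize=True)
            pre = ah @ W + b
            if keep_cache:
                cache["conv_pre"].append((ah, pre))
            h = _relu(pre)
        pooled = h.max(axis=1)
        argmax = h.argmax(axis=1) if keep_cache else None
        z = pooled
        dense_caches = []
        for li, (W, b) in enumerate(zip(self.dense_weights, self.dense_biases)):
            pre = z @ W + b
            if li < len(self.dense_weights) - 1:
                out = _relu(pre)
            else:
                out = 1.0 / (1.0 + np.exp(-np.clip(pre, -30, 30)))
            if keep_cache:
                dense_caches.append((z, pre))
            z = out
        if keep_cache:
            cache["pooled"] = pooled
            cache["argmax"] = argmax
            cache["dense"] = dense_caches
            cache["h_last"] = h
        return z[:, 0], cache

    def scores(self, graphs: SampleGraphs) -> np.ndarray:
        if graphs.features.shape[2] != self.conv_weights[0].shape[0]:
            raise ValueError("node feature schema does not match the model")
        out, _ = self._forward(graphs.features, graphs.a_hat)
        return out.astype(float)


def _init_gnn(n_feat: int, hidden: int, classifier: int, seed: int) -> GraphPRSModel:
    rng = np.random.default_rng(seed)

    def glorot(fi, fo):
        lim = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-lim, lim, size=(fi, fo)).astype(np.float32)

    conv_w = [glorot(n_feat, hidden), glorot(hidden, hidden), glorot(hidden, hidden)]
    conv_b = [np.zeros(hidden, dtype=np.float32) for _ in range(3)]
    dense_w = [glorot(hidden, classifier), glorot(classifier, 1)]
    dense_b = [np.zeros(classifier, dtype=np.float32), np.zeros(1, dtype=np.float32)]
    return GraphPRSModel(conv_weights=conv_w, conv_biases=conv_b,
                         dense_weights=dense_w, dense_biases=dense_b,
                         hidden_dim=hidden, classifier_dim=classifier,
                         init_seed=seed)


def train_gnn(graphs: SampleGraphs, labels: np.ndarray, *,
              hidden_dim: int = 128, classifier_dim: int = 64,
              lr: float = 1e-3, batch_size: int = 256,
              max_epochs: int = 200, patience: int = 20,
              validation_fraction: float = 0.2,
              seed: int = 0) -> GraphPRSModel:
    """Train the graph classifier with Adam and early stopping.

    A fraction of the samples is held out for the early-stopping criterion
    (binary cross-entropy); the best weights are restored at the end.
    """
    y = np.asarray(labels, dtype=np.float32)
    feats = graphs.features
    a_hat = graphs.a_hat
    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    model = _init_gnn(feats.shape[2], hidden_dim, classifier_dim, seed)
    model.feature_mean, model.feature_sd = graphs.feature_mean, graphs.feature_sd

    params = model.conv_weights + model.conv_biases + \
        model.dense_weights + model.dense_biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_state = None
    since_best = 0
    hist_train, hist_val = [], []
    for epoch in range(max_epochs):
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for s in range(0, len(order), batch_size):
            idx = order[s:s + batch_size]
            xb, yb = feats[idx], y[idx]
            out, cache = model._forward(xb, a_hat, keep_cache=True)
            p = np.clip(out, 1e-7, 1 - 1e-7)
            loss = float(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
            if not np.isfinite(loss):
                raise FloatingPointError(f"graph training diverged at epoch {epoch}")
            ep_loss += loss * len(idx)
            grads = _gnn_grads(model, cache, yb, a_hat)
            step += 1
            bc1 = 1 - beta1**step
            bc2 = 1 - beta2**step
            for pi, (par, g) in enumerate(zip(params, grads)):
                m_t[pi] = beta1 * m_t[pi] + (1 - beta1) * g
                v_t[pi] = beta2 * v_t[pi] + (1 - beta2) * g * g
                par -= lr * (m_t[pi] / bc1) / (np.sqrt(v_t[pi] / bc2) + eps)
        hist_train.append(ep_loss / len(order))
        val_out, _ = model._forward(feats[val_idx], a_hat)
        pv = np.clip(val_out, 1e-7, 1 - 1e-7)
        val_loss = float(-np.mean(y[val_idx] * np.log(pv) +
                                  (1 - y[val_idx]) * np.log(1 - pv)))
        hist_val.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
        if since_best >= patience:
            break
    if best_state is not None:
        for par, best in zip(params, best_state):
            par[...] = best
    model.trained = True
    model.history = {"train_loss": hist_train, "val_loss": hist_val}
    return model


def _gnn_grads(model: GraphPRSModel, cache: dict, y: np.ndarray,
               a_hat: np.ndarray) -> list:
    """Backward pass; returns gradients ordered like the parameter list
    (conv weights, conv biases, dense weights, dense biases)."""
    B = len(y)
    dense = cache["dense"]
    grads_dense_w = [None] * len(model.dense_weights)
    grads_dense_b = [None] * len(model.dense_biases)
    # output layer: sigmoid + BCE cancel to (out - y)
    _, pre_out = dense[-1]
    out = 1.0 / (1.0 + np.exp(-np.clip(pre_out[:, 0], -30, 30)))
    dpre = ((out - y) / B)[:, None].astype(np.float32)
    for li in range(len(model.dense_weights) - 1, -1, -1):
        z_in, _pre = dense[li]
        grads_dense_w[li] = z_in.T @ dpre
        grads_dense_b[li] = dpre.sum(axis=0)
        dz = dpre @ model.dense_weights[li].T
        if li > 0:
            prev_pre = dense[li - 1][1]
            dpre = dz * (prev_pre > 0)
    dpooled = dz  # gradient w.r.t. the max-pooled vector

    # max pooling routes gradient to the argmax node per (sample, channel)
    h_last = cache["h_last"]
    dh = np.zeros_like(h_last)
    idx = cache["argmax"][:, None, :]
    np.put_along_axis(dh, idx, dpooled[:, None, :], axis=1)

    n_conv = len(model.conv_weights)
    grads_conv_w = [None] * n_conv
    grads_conv_b = [None] * n_conv
    for l in range(n_conv - 1, -1, -1):
        ah, pre = cache["conv_pre"][l]
        dpre_c = dh * (pre > 0)
        grads_conv_w[l] = np.einsum("bnf,bnh->fh", ah, dpre_c, optimize=True)
        grads_conv_b[l] = dpre_c.sum(axis=(0, 1))
        if l > 0:
            dah = np.einsum("bnh,fh->bnf", dpre_c, model.conv_weights[l],
                            optimize=True)
            # a_hat is symmetric, so A^T contraction equals A contraction
            dh = np.einsum("uv,bvf->buf", a_hat, dah, optimize=True)
    return grads_conv_w + grads_conv_b + grads_dense_w + grads_dense_b


def gnn_score(model: GraphPRSModel, graphs: SampleGraphs) -> np.ndarray:
    """Per-sample risk probability from the trained graph classifier."""
    return model.scores(graphs)
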