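"""The three node classifiers: MLP, GCN, GAT.

All three map the 11 processed features of every subject to 3 class scores
(Control / MCI / AD); softmax is left to the loss.

* **MLP** -- 11 -> 16 -> 8 -> 3 dense layers, ReLU, dropout 0.1 on hidden
  activations.  Ignores the graph: the per-subject baseline.
* **GCN** -- two graph-convolution layers, 11 -> 16 -> 3, ReLU, dropout 0.1.
  Propagation uses the symmetric-normalized adjacency with added self-loops,
  ``A_hat = D~^{-1/2} (A + I) D~^{-1/2}``; each layer computes
  ``A_hat X W + b``.
* **GAT** -- two graph-attention layers.  Layer 1: 8 heads of 16 units, head
  outputs concatenated (width 128) then ELU; layer 2: a single head mapping
  128 -> 3.  Per head, attention logits on each edge (self-loops added) are
  ``e_ij = LeakyReLU_{0.2}(a_src . W x_i + a_dst . W x_j)``, normalized by a
  softmax over each node's in-neighborhood.  Dropout 0.2 on layer inputs and
  on attention coefficients.

Attention and propagation are computed densely (n x n); the intended regime
is a population graph of a few hundred subjects, where dense linear algebra
is both simplest and fastest.

Parameters are plain numpy arrays in a flat dict keyed by layer name,
initialized with Glorot-uniform fan scaling (biases zero) from a seeded
generator, and serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelSpec",
    "init_params",
    "normalized_adjacency",
    "mlp_forward",
    "gcn_forward",
    "gat_forward",
    "forward",
    "save_params",
    "load_params",
]

KINDS = ("MLP", "GCN", "GAT")


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    in_features: int = 11
    n_classes: int = 3
    mlp_hidden: tuple[int, int] = (16, 8)
    gcn_hidden: int = 16
    gat_heads: int = 8
    gat_head_units: int = 16
    dropout: float = 0.1
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.mlp_hidden) <= 0 or self.gcn_hidden <= 0 \
                or self.gat_heads <= 0 or self.gat_head_units <= 0:
            raise ValueError("layer widths must be positive")

    @classmethod
    def for_kind(cls, kind: str) -> "ModelSpec":
        """The study architecture for a given kind (dropout 0.2 for GAT)."""
        return cls(kind=kind, dropout=0.2 if kind == "GAT" else 0.1)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "in_features": self.in_features,
            "n_classes": self.n_classes, "mlp_hidden": list(self.mlp_hidden),
            "gcn_hidden": self.gcn_hidden, "gat_heads": self.gat_heads,
            "gat_head_units": self.gat_head_units, "dropout": self.dropout,
            "leaky_slope": self.leaky_slope,
        }


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in, fan_out = (shape[-2], shape[-1]) if len(shape) >= 2 else (shape[0], 1)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(spec: ModelSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform weights, zero biases; deterministic."""
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    f, c = spec.in_features, spec.n_classes
    if spec.kind == "MLP":
        h1, h2 = spec.mlp_hidden
        p["W1"], p["b1"] = _glorot(rng, (f, h1)), np.zeros(h1)
        p["W2"], p["b2"] = _glorot(rng, (h1, h2)), np.zeros(h2)
        p["W3"], p["b3"] = _glorot(rng, (h2, c)), np.zeros(c)
    elif spec.kind == "GCN":
        h = spec.gcn_hidden
        p["W1"], p["b1"] = _glorot(rng, (f, h)), np.zeros(h)
        p["W2"], p["b2"] = _glorot(rng, (h, c)), np.zeros(c)
    else:  # GAT
        heads, u = spec.gat_heads, spec.gat_head_units
        for k in range(heads):
            p[f"W1_h{k}"] = _glorot(rng, (f, u))
            p[f"a1_src_h{k}"] = _glorot(rng, (u,))
            p[f"a1_dst_h{k}"] = _glorot(rng, (u,))
        p["b1"] = np.zeros(heads * u)
        p["W2"] = _glorot(rng, (heads * u, c))
        p["a2_src"] = _glorot(rng, (c,))
        p["a2_dst"] = _glorot(rng, (c,))
        p["b2"] = np.zeros(c)
    return p


def _check_edges(edge_index: np.ndarray, n: int) -> np.ndarray:
    edge_index = np.asarray(edge_index, dtype=int).reshape(-1, 2)
    if edge_index.size and (edge_index.min() < 0 or edge_index.max() >= n):
        raise IndexError("edge index references a node outside the feature matrix")
    return edge_index


def normalized_adjacency(edge_index: np.ndarray, n: int) -> np.ndarray:
    """Dense ``D~^{-1/2} (A + I) D~^{-1/2}`` from a directed edge index."""
    edge_index = _check_edges(edge_index, n)
    a = np.zeros((n, n))
    if edge_index.size:
        a[edge_index[:, 0], edge_index[:, 1]] = 1.0
        a = np.maximum(a, a.T)  # symmetrize defensively
    np.fill_diagonal(a, 0.0)
    a_tilde = a + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _as_tensors(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: v if isinstance(v, Tensor) else Tensor(v, requires_grad=True)
            for k, v in params.items()}


def mlp_forward(x: np.ndarray, params: dict, training: bool = False,
                rng: np.random.Generator | None = None,
                spec: ModelSpec | None = None) -> Tensor:
    spec = spec or ModelSpec.for_kind("MLP")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != spec.in_features:
        raise ValueError(f"expected {spec.in_features} feature columns, "
                         f"got {x.shape[1]}")
    p = _as_tensors(params)
    rng = rng or np.random.default_rng(0)
    xt = Tensor(x)
    h1 = ad.relu(ad.add(ad.matmul(xt, p["W1"]), p["b1"]))
    h1 = ad.dropout(h1, spec.dropout, rng, training)
    h2 = ad.relu(ad.add(ad.matmul(h1, p["W2"]), p["b2"]))
    h2 = ad.dropout(h2, spec.dropout, rng, training)
    logits = ad.add(ad.matmul(h2, p["W3"]), p["b3"])
    return logits


def gcn_forward(x: np.ndarray, edge_index: np.ndarray, params: dict,
                training: bool = False,
                rng: np.random.Generator | None = None,
                spec: ModelSpec | None = None) -> Tensor:
    spec = spec or ModelSpec.for_kind("GCN")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    a_hat = Tensor(normalized_adjacency(edge_index, n))
    p = _as_tensors(params)
    rng = rng or np.random.default_rng(0)
    xt = Tensor(x)
    h = ad.relu(ad.add(ad.matmul(a_hat, ad.matmul(xt, p["W1"])), p["b1"]))
    h = ad.dropout(h, spec.dropout, rng, training)
    logits = ad.add(ad.matmul(a_hat, ad.matmul(h, p["W2"])), p["b2"])
    return logits


def _attention_mask_bias(edge_index: np.ndarray, n: int) -> np.ndarray:
    """0 on allowed (edge or self) positions, -1e9 elsewhere."""
    allowed = np.zeros((n, n), dtype=bool)
    edge_index = _check_edges(edge_index, n)
    if edge_index.size:
        allowed[edge_index[:, 0], edge_index[:, 1]] = True
        allowed |= allowed.T
    np.fill_diagonal(allowed, True)
    return np.where(allowed, 0.0, -1e9)


def _gat_layer(h_in: Tensor, w: Tensor, a_src: Tensor, a_dst: Tensor,
               bias_mask: np.ndarray, slope: float, attn_dropout: float,
               rng: np.random.Generator, training: bool) -> Tensor:
    h = ad.matmul(h_in, w)                                   # (n, u)
    s_src = ad.matmul(h, a_src)                              # (n,)
    s_dst = ad.matmul(h, a_dst)                              # (n,)
    col = Tensor(s_src.data[:, None], requires_grad=s_src.requires_grad,
                 parents=(s_src,),
                 backward=(lambda g: s_src.grad.__iadd__(g[:, 0]))
                 if s_src.requires_grad else None)
    row = Tensor(s_dst.data[None, :], requires_grad=s_dst.requires_grad,
                 parents=(s_dst,),
                 backward=(lambda g: s_dst.grad.__iadd__(g[0, :]))
                 if s_dst.requires_grad else None)
    e = ad.leaky_relu(ad.add(col, row), slope)               # (n, n)
    alpha = ad.softmax_rows(ad.add_const(e, bias_mask))      # rows sum to 1
    alpha = ad.dropout(alpha, attn_dropout, rng, training)
    return ad.matmul(alpha, h)


def gat_forward(x: np.ndarray, edge_index: np.ndarray, params: dict,
                training: bool = False,
                rng: np.random.Generator | None = None,
                spec: ModelSpec | None = None) -> Tensor:
    spec = spec or ModelSpec.for_kind("GAT")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    bias_mask = _attention_mask_bias(edge_index, n)
    p = _as_tensors(params)
    rng = rng or np.random.default_rng(0)
    xt = ad.dropout(Tensor(x), spec.dropout, rng, training)
    heads = []
    for k in range(spec.gat_heads):
        heads.append(_gat_layer(
            xt, p[f"W1_h{k}"], p[f"a1_src_h{k}"], p[f"a1_dst_h{k}"],
            bias_mask, spec.leaky_slope, spec.dropout, rng, training))
    z = ad.elu(ad.add(ad.concat(heads, axis=1), p["b1"]))
    z = ad.dropout(z, spec.dropout, rng, training)
    out = _gat_layer(z, p["W2"], p["a2_src"], p["a2_dst"],
                     bias_mask, spec.leaky_slope, spec.dropout, rng, training)
    return ad.add(out, p["b2"])


def forward(spec: ModelSpec, x: np.ndarray, edge_index: np.ndarray | None,
            params: dict, training: bool = False,
            rng: np.random.Generator | None = None) -> Tensor:
    """Dispatch to the right forward pass; edge_index required for GCN/GAT."""
    if spec.kind == "MLP":
        return mlp_forward(x, params, training, rng, spec)
    if edge_index is None:
        raise ValueError(f"{spec.kind} requires an edge index")
    if spec.kind == "GCN":
        return gcn_forward(x, edge_index, params, training, rng, spec)
    return gat_forward(x, edge_index, params, training, rng, spec)


def gat_attention(x: np.ndarray, edge_index: np.ndarray, params: dict,
                  head: int = 0, spec: ModelSpec | None = None) -> np.ndarray:
    """Layer-1 attention matrix of one head in evaluation mode (rows sum to 1)."""
    spec = spec or ModelSpec.for_kind("GAT")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    bias_mask = _attention_mask_bias(edge_index, n)
    h = x @ np.asarray(params[f"W1_h{head}"])
    e = h @ np.asarray(params[f"a1_src_h{head}"])[:, None] \
        + (h @ np.asarray(params[f"a1_dst_h{head}"]))[None, :]
    e = np.where(e > 0, e, spec.leaky_slope * e) + bias_mask
    e -= e.max(axis=1, keepdims=True)
    w = np.exp(e)
    return w / w.sum(axis=1, keepdims=True)


def save_params(params: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: np.asarray(v).tolist() for k, v in params.items()}, fh)


def load_params(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}
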