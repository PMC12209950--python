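"""Graph neural network layers and task models.

Three message-passing layers, written directly from their update rules:

* GCN:  h_i' = sum_{j in N(i)} (1 / sqrt(deg i * deg j)) W h_j, with a
  self-loop added to every neighbourhood and degrees computed after the
  insertion.
* GIN:  h_i' = MLP((1 + eps) h_i + sum_{j in N(i)} h_j), eps learnable, MLP
  defaulting to two affine maps with a ReLU between.
* GAT:  alpha_ij = softmax_j LeakyReLU(a^T [W h_i || W h_j]),
  h_i' = sigma(sum_j alpha_ij W h_j); self-loops are added so alpha_ii is
  well defined, one attention head, LeakyReLU slope 0.2.

Both task models use a single hidden layer.  The node-classification model
(mode of inheritance: AD, AR) stacks two message-passing layers —
input -> hidden with ReLU, hidden -> 2 output units — and applies a sigmoid
per unit.  The graph-classification model (mechanism: DN, HI, GOF) runs one
message-passing layer to the hidden width, ReLU, mean-pools over nodes, and
applies an affine head to 3 sigmoid units.  Dropout (default 0.3) acts on
input features and hidden activations during training only.

Everything runs on the dense reverse-mode engine in ``moimech._autodiff``;
graphs here have at most a few hundred nodes, so dense adjacency is both
simplest and fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, bce_with_logits, leaky_relu, relu, sigmoid, exp
from .graphs import AttributedGraph

__all__ = [
    "LayerParams",
    "GNNModel",
    "gcn_forward",
    "gin_forward",
    "gat_forward",
    "model_forward",
    "make_layer",
    "gcn_norm",
    "save_checkpoint",
    "load_checkpoint",
]

_BIG_NEG = -1e9


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def gcn_norm(adj: np.ndarray) -> np.ndarray:
    """Symmetrically normalized adjacency D^-1/2 (A + I) D^-1/2."""
    A = np.asarray(adj, dtype=np.float64).copy()
    np.fill_diagonal(A, 1.0)
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class LayerParams:
    """Parameters of one message-passing layer."""

    arch: str  # gcn | gat | gin
    W: Tensor
    bias: Tensor | None = None
    # GAT
    a_src: Tensor | None = None  # first half of the attention vector a
    a_dst: Tensor | None = None  # second half
    negative_slope: float = 0.2
    # GIN
    eps: Tensor | None = None
    mlp: list[tuple[Tensor, Tensor]] = field(default_factory=list)  # (W, b) pairs

    def parameters(self) -> list[Tensor]:
        out = [self.W]
        if self.bias is not None:
            out.append(self.bias)
        for t in (self.a_src, self.a_dst, self.eps):
            if t is not None:
                out.append(t)
        for w, b in self.mlp:
            out.extend([w, b])
        return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def make_layer(arch: str, d_in: int, d_out: int, rng: np.random.Generator,
               negative_slope: float = 0.2) -> LayerParams:
    W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
    bias = Tensor(np.zeros(d_out), requires_grad=True)
    if arch == "gcn":
        return LayerParams("gcn", W, bias=bias)
    if arch == "gat":
        # halves of the attention vector a (length 2 d_out), kept as columns
        a_src = Tensor(_glorot(rng, d_out, 1), requires_grad=True)
        a_dst = Tensor(_glorot(rng, d_out, 1), requires_grad=True)
        return LayerParams("gat", W, bias=bias, a_src=a_src, a_dst=a_dst,
                           negative_slope=negative_slope)
    if arch == "gin":
        eps = Tensor(0.0, requires_grad=True)
        mlp = [
            (Tensor(_glorot(rng, d_in, d_out), requires_grad=True),
             Tensor(np.zeros(d_out), requires_grad=True)),
            (Tensor(_glorot(rng, d_out, d_out), requires_grad=True),
             Tensor(np.zeros(d_out), requires_grad=True)),
        ]
        return LayerParams("gin", W, eps=eps, mlp=mlp)
    raise ValueError(f"unknown architecture {arch!r}")


def gcn_forward(H, adj: np.ndarray, params: LayerParams, activation=None) -> Tensor:
    """One GCN layer: norm-adjacency aggregation of W h_j."""
    H = _as_tensor(H)
    if H.shape[1] != params.W.shape[0]:
        raise ValueError(f"feature dim {H.shape[1]} != W rows {params.W.shape[0]}")
    out = Tensor(gcn_norm(adj)) @ (H @ params.W)
    if params.bias is not None:
        out = out + params.bias
    return activation(out) if activation else out


def gin_forward(H, adj: np.ndarray, params: LayerParams, activation=None) -> Tensor:
    """One GIN layer: MLP over (1 + eps) h_i + neighbour sum."""
    H = _as_tensor(H)
    A = np.asarray(adj, dtype=np.float64).copy()
    np.fill_diagonal(A, 0.0)  # the (1 + eps) h_i term stands in for the self-loop
    agg = Tensor(A) @ H + (1.0 + params.eps) * H
    out = agg
    for k, (w, b) in enumerate(params.mlp):
        out = out @ w + b
        if k < len(params.mlp) - 1:
            out = relu(out)
    return activation(out) if activation else out


def gat_forward(H, adj: np.ndarray, params: LayerParams, activation=None):
    """One single-head GAT layer; returns (output, attention matrix).

    Attention is a masked softmax over each neighbourhood (self-loop
    included); returned alpha rows sum to 1 over N(i).
    """
    H = _as_tensor(H)
    if H.shape[1] != params.W.shape[0]:
        raise ValueError(f"feature dim {H.shape[1]} != W rows {params.W.shape[0]}")
    n = H.shape[0]
    mask = np.asarray(adj, dtype=np.float64).copy()
    np.fill_diagonal(mask, 1.0)
    Z = H @ params.W  # (n, d')
    # e_ij = LeakyReLU(a_src . z_i + a_dst . z_j)  (a = [a_src ; a_dst])
    src = (Z @ params.a_src).reshape(n, 1)
    dst = (Z @ params.a_dst).reshape(1, n)
    E = leaky_relu(src + dst, params.negative_slope)
    # mask non-edges with a large negative constant, stabilize, softmax
    E = E * mask + Tensor(_BIG_NEG * (1.0 - mask))
    rowmax = Tensor(E.data.max(axis=1, keepdims=True))  # constant shift
    expE = exp(E - rowmax) * mask
    alpha = expE / expE.sum(axis=1, keepdims=True)
    out = alpha @ Z
    if params.bias is not None:
        out = out + params.bias
    out = activation(out) if activation else out
    return out, alpha


_LAYER_FORWARD = {
    "gcn": lambda H, A, p, act: gcn_forward(H, A, p, act),
    "gin": lambda H, A, p, act: gin_forward(H, A, p, act),
    "gat": lambda H, A, p, act: gat_forward(H, A, p, act)[0],
}


def _pool(H: Tensor, how: str) -> Tensor:
    if how == "mean":
        return H.mean(axis=0, keepdims=True)
    if how == "sum":
        return H.sum(axis=0, keepdims=True)
    if how == "max":
        idx = H.data.argmax(axis=0)
        data = H.data.max(axis=0, keepdims=True)

        def backward(g):
            out = np.zeros_like(H.data)
            out[idx, np.arange(H.data.shape[1])] = g[0]
            return (out,)

        return Tensor._from_op(data, (H,), backward)
    raise ValueError(f"unknown pooling {how!r}")


class GNNModel:
    """Single-hidden-layer GNN for either task.

    ``task='node'``: two stacked message-passing layers (input -> hidden,
    ReLU; hidden -> n_out) producing per-node sigmoid probabilities.
    ``task='graph'``: one message-passing layer to the hidden width, ReLU,
    permutation-invariant pooling over nodes, affine head to n_out sigmoid
    units.
    """

    def __init__(self, arch: str, input_dim: int, hidden_dim: int, n_out: int,
                 task: str, pooling: str = "mean", dropout: float = 0.3,
                 negative_slope: float = 0.2, seed: int = 0):
        if task not in ("node", "graph"):
            raise ValueError(f"unknown task {task!r}")
        self.arch = arch
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_out = n_out
        self.task = task
        self.pooling = pooling
        self.dropout = dropout
        self.negative_slope = negative_slope
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layer1 = make_layer(arch, input_dim, hidden_dim, rng, negative_slope)
        if task == "node":
            self.layer2 = make_layer(arch, hidden_dim, n_out, rng, negative_slope)
            self.head_W = self.head_b = None
        else:
            self.layer2 = None
            self.head_W = Tensor(_glorot(rng, hidden_dim, n_out), requires_grad=True)
            self.head_b = Tensor(np.zeros(n_out), requires_grad=True)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    def parameters(self) -> list[Tensor]:
        out = self.layer1.parameters()
        if self.layer2 is not None:
            out += self.layer2.parameters()
        if self.head_W is not None:
            out += [self.head_W, self.head_b]
        return out

    def _drop(self, t: Tensor, training: bool) -> Tensor:
        if not training or self.dropout <= 0:
            return t
        keep = 1.0 - self.dropout
        mask = self._dropout_rng.random(t.shape) < keep
        return t * Tensor(mask / keep)

    def forward(self, X, adj: np.ndarray, training: bool = False) -> Tensor:
        """Logits: (nodes, n_out) for the node task, (1, n_out) for graph."""
        H = _as_tensor(X)
        if H.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {H.shape[1]}")
        step = _LAYER_FORWARD[self.arch]
        H = self._drop(H, training)
        H1 = step(H, adj, self.layer1, relu)
        H1 = self._drop(H1, training)
        if self.task == "node":
            return step(H1, adj, self.layer2, None)
        pooled = _pool(H1, self.pooling)
        return pooled @ self.head_W + self.head_b

    def predict_proba(self, X, adj: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(X, adj, training=False)).data


def model_forward(model: GNNModel, graph: AttributedGraph) -> np.ndarray:
    """Per-label sigmoid probabilities for an annotated graph.

    Node task: (nodes, n_out); graph task: (1, n_out) after pooling.
    """
    if graph.X is None:
        raise ValueError("graph has no node features attached")
    return model.predict_proba(graph.X, graph.adjacency())


# -- checkpoints ---------------------------------------------------------------

def save_checkpoint(model: GNNModel, path, feature_names=None):
    """Self-describing checkpoint: JSON header + named weight arrays (npz)."""
    header = {
        "format_version": 1,
        "arch": model.arch,
        "task": model.task,
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
        "n_out": model.n_out,
        "pooling": model.pooling,
        "dropout": model.dropout,
        "negative_slope": model.negative_slope,
        "seed": model.seed,
        "feature_names": list(feature_names) if feature_names else None,
    }
    arrays = {f"param_{k}": p.data for k, p in enumerate(model.parameters())}
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> tuple[GNNModel, list[str] | None]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        model = GNNModel(
            header["arch"], header["input_dim"], header["hidden_dim"],
            header["n_out"], header["task"], pooling=header["pooling"],
            dropout=header["dropout"], negative_slope=header["negative_slope"],
            seed=header["seed"],
        )
        for k, p in enumerate(model.parameters()):
            p.data = np.asarray(z[f"param_{k}"], dtype=np.float64)
    return model, header["feature_names"]
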