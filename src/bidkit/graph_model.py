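"""Residue graphs, pluggable embeddings and the graph-attention (GAT)
immunodominance regressor.

The antigen chain is represented as a molecular graph: nodes are residues,
undirected edges connect residues whose CA atoms lie within 10 A. Node
features come from pluggable embedding providers (one-hot baseline, or
precomputed per-residue matrices such as protein-language-model embeddings);
multiple providers are concatenated along the feature axis.

The regressor stacks three multi-head graph-attention layers (additive
attention over each node's neighborhood including itself, softmax-normalized
per node; heads concatenated in the first two layers, averaged in the last)
followed by a two-layer fully connected head, trained with MSE loss and Adam.
The default hyperparameters are hidden dims 2048-512-128, FC 128-32-1,
8 heads, learning rate 1e-6, batch size 4, 200 epochs; ``GATConfig.reduced()``
is the documented small configuration used for synthetic-scale experiments.

Everything runs in NumPy with hand-written backpropagation; gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmbeddingError, ModelError
from .io_formats import (
    STANDARD_AA,
    ComplexRecord,
    IDProfile,
    read_embedding_matrix,
)

GRAPH_EDGE_RADIUS = 10.0


# ---------------------------------------------------------------------------
# Embedding providers
# ---------------------------------------------------------------------------

class OneHotProvider:
    """Canonical 20-letter one-hot encoding; 'X' maps to an all-zero row.

    Amino-acid order is alphabetical by one-letter code (ACDEFGHIKLMNPQRSTVWY).
    """

    name = "one_hot"
    dim = 20

    _index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    def embed(self, sequence: str) -> np.ndarray:
        out = np.zeros((len(sequence), self.dim))
        for i, aa in enumerate(sequence):
            j = self._index.get(aa)
            if j is not None:
                out[i, j] = 1.0
        return out


class ExternalEmbeddingProvider:
    """Precomputed per-residue embedding matrix (e.g. ESM-2 / ESM-IF1 output
    saved to .npy or CSV). Values are passed through unchanged; the row count
    must equal the chain length."""

    def __init__(self, matrix: np.ndarray, name: str = "external") -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise EmbeddingError(f"{name}: embedding matrix must be 2-D")
        self.matrix = matrix
        self.name = name
        self.dim = int(matrix.shape[1])

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "ExternalEmbeddingProvider":
        return cls(read_embedding_matrix(path), name=name or Path(path).stem)

    def embed(self, sequence: str) -> np.ndarray:
        if self.matrix.shape[0] != len(sequence):
            raise EmbeddingError(
                f"{self.name}: {self.matrix.shape[0]} embedding rows for a "
                f"{len(sequence)}-residue chain"
            )
        return self.matrix


# ---------------------------------------------------------------------------
# Residue graph
# ---------------------------------------------------------------------------

@dataclass
class ResidueGraph:
    """Residue-level graph: node embeddings, 10 A proximity edges, optional
    per-node ID targets. Edges are stored once (i < j); self-loops are added
    at message-passing time."""

    antigen_id: str
    node_embeddings: np.ndarray        # (n, d)
    edges: np.ndarray                  # (m, 2) int, i < j
    targets: np.ndarray | None = None  # (n,) float

    def __post_init__(self) -> None:
        self.node_embeddings = np.asarray(self.node_embeddings, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = self.n_nodes
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ModelError(f"{self.antigen_id}: self-loops must not be stored")
            if self.edges.max() >= n or self.edges.min() < 0:
                raise ModelError(f"{self.antigen_id}: edge index out of range")
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=float)
            if self.targets.shape != (n,):
                raise ModelError(f"{self.antigen_id}: targets length != node count")

    @property
    def n_nodes(self) -> int:
        return self.node_embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.node_embeddings.shape[1]

    def adjacency_mask(self) -> np.ndarray:
        """Dense boolean neighborhood mask with self-loops."""
        n = self.n_nodes
        mask = np.eye(n, dtype=bool)
        if self.edges.size:
            mask[self.edges[:, 0], self.edges[:, 1]] = True
            mask[self.edges[:, 1], self.edges[:, 0]] = True
        return mask


def build_graph(
    record: ComplexRecord,
    chain_id: str,
    providers: list,
    targets: IDProfile | np.ndarray | None = None,
    radius: float = GRAPH_EDGE_RADIUS,
    distance: str = "ca",
) -> ResidueGraph:
    """Build a residue graph for one antigen chain.

    Node features are the concatenation of all providers' embeddings (in the
    given order). Edges connect residues at CA-CA distance <= radius
    (``distance="heavy"`` switches to minimal heavy-atom distance). Residues
    without a CA atom are dropped with a warning and the graph re-indexed.
    """
    chain = record.chain(chain_id)
    n = chain.n_residues
    keep = ~np.isnan(chain.ca_coords).any(axis=1)
    if not keep.all():
        warnings.warn(
            f"{record.complex_id} chain {chain_id}: dropping "
            f"{int((~keep).sum())} residues without CA", stacklevel=2,
        )
    idx = np.flatnonzero(keep)
    seq = "".join(chain.sequence[i] for i in idx)

    blocks = []
    for provider in providers:
        mat = provider.embed(chain.sequence)
        if mat.shape[0] != n:
            raise EmbeddingError(
                f"{provider.name}: {mat.shape[0]} rows for {n} residues"
            )
        blocks.append(np.asarray(mat, dtype=float)[idx])
    if not blocks:
        raise EmbeddingError("at least one embedding provider is required")
    emb = np.concatenate(blocks, axis=1)

    if distance == "ca":
        coords = chain.ca_coords[idx]
        from scipy.spatial.distance import pdist, squareform
        dmat = squareform(pdist(coords))
    elif distance == "heavy":
        m = idx.size
        dmat = np.zeros((m, m))
        res_coords = [chain.residue_atom_coords(int(i)) for i in idx]
        for a in range(m):
            for b in range(a + 1, m):
                diff = res_coords[a][:, None, :] - res_coords[b][None, :, :]
                dmat[a, b] = dmat[b, a] = np.sqrt((diff ** 2).sum(-1)).min()
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    iu = np.triu_indices(idx.size, k=1)
    hit = dmat[iu] <= radius
    edges = np.column_stack([iu[0][hit], iu[1][hit]])

    tvec = None
    if targets is not None:
        tvec = targets.scores if isinstance(targets, IDProfile) else np.asarray(targets, float)
        if tvec.shape[0] != n:
            raise ModelError(f"targets length {tvec.shape[0]} != chain length {n}")
        tvec = tvec[idx]
    _ = seq
    return ResidueGraph(
        antigen_id=f"{record.complex_id}:{chain_id}",
        node_embeddings=emb,
        edges=edges,
        targets=tvec,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GATConfig:
    """Architecture and training recipe for the GAT regressor."""

    gat_dims: tuple[int, int, int] = (2048, 512, 128)
    heads: int = 8
    fc_dims: tuple[int, int, int] = (128, 32, 1)
    lr: float = 1e-6
    epochs: int = 200
    batch_size: int = 4
    seed: int = 0
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.fc_dims[-1] != 1:
            raise ValueError("last FC dim must be 1")
        if self.gat_dims[-1] != self.fc_dims[0]:
            raise ValueError("gat_dims[-1] must equal fc_dims[0]")
        for d in self.gat_dims[:-1]:
            if d % self.heads:
                raise ValueError("hidden GAT dims must be divisible by the head count")

    @classmethod
    def reduced(cls, seed: int = 0) -> "GATConfig":
        """Small configuration for synthetic-scale experiments on one CPU:
        dims 32-16-8, 2 heads, FC 8-8-1, lr 7e-3, 200 epochs."""
        return cls(gat_dims=(32, 16, 8), heads=2, fc_dims=(8, 8, 1),
                   lr=7e-3, epochs=200, batch_size=4, seed=seed)


# ---------------------------------------------------------------------------
# Layers (NumPy, manual backprop)
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad_from_out(y: np.ndarray) -> np.ndarray:
    # d elu/dx = 1 for x>0, exp(x) = y + 1 for x<=0
    return np.where(y > 0, 1.0, y + 1.0)


class _GATLayer:
    """One multi-head graph-attention layer.

    Per head: z = x W; attention logit e_ij = LeakyReLU(a_src.z_i + a_dst.z_j)
    over j in N(i) u {i}; alpha = row softmax; out_i = sum_j alpha_ij z_j + b.
    Heads are concatenated (``combine="concat"``) or averaged (``"mean"``).
    """

    def __init__(self, d_in: int, d_head: int, heads: int, combine: str,
                 rng: np.random.Generator) -> None:
        self.heads = heads
        self.combine = combine
        self.slope = 0.2
        limit = np.sqrt(6.0 / (d_in + d_head))
        self.W = rng.uniform(-limit, limit, size=(heads, d_in, d_head))
        a_limit = np.sqrt(6.0 / (d_head + 1))
        self.a_src = rng.uniform(-a_limit, a_limit, size=(heads, d_head))
        self.a_dst = rng.uniform(-a_limit, a_limit, size=(heads, d_head))
        self.b = np.zeros((heads, d_head))
        self._zero_grads()

    def _zero_grads(self) -> None:
        self.gW = np.zeros_like(self.W)
        self.ga_src = np.zeros_like(self.a_src)
        self.ga_dst = np.zeros_like(self.a_dst)
        self.gb = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.a_src, self.a_dst, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.ga_src, self.ga_dst, self.gb]

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        self._x, self._mask = x, mask
        self._z, self._alpha, self._pre = [], [], []
        outs = []
        for h in range(self.heads):
            z = x @ self.W[h]
            s = z @ self.a_src[h]
            t = z @ self.a_dst[h]
            pre = s[:, None] + t[None, :]
            e = np.where(pre > 0, pre, self.slope * pre)
            e = np.where(mask, e, -np.inf)
            e = e - e.max(axis=1, keepdims=True)
            ex = np.exp(e)
            alpha = ex / ex.sum(axis=1, keepdims=True)
            outs.append(alpha @ z + self.b[h])
            self._z.append(z)
            self._alpha.append(alpha)
            self._pre.append(pre)
        if self.combine == "concat":
            return np.concatenate(outs, axis=1)
        return np.mean(outs, axis=0)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x, mask = self._x, self._mask
        d_x = np.zeros_like(x)
        d_head = self.W.shape[2]
        for h in range(self.heads):
            if self.combine == "concat":
                dH = d_out[:, h * d_head : (h + 1) * d_head]
            else:
                dH = d_out / self.heads
            z, alpha, pre = self._z[h], self._alpha[h], self._pre[h]
            self.gb[h] += dH.sum(axis=0)
            d_alpha = dH @ z.T
            d_z = alpha.T @ dH
            # softmax backward, rows
            d_pre_post = alpha * (d_alpha - (alpha * d_alpha).sum(axis=1, keepdims=True))
            d_pre = np.where(pre > 0, 1.0, self.slope) * d_pre_post
            d_pre = np.where(mask, d_pre, 0.0)
            d_s = d_pre.sum(axis=1)
            d_t = d_pre.sum(axis=0)
            d_z += np.outer(d_s, self.a_src[h]) + np.outer(d_t, self.a_dst[h])
            self.ga_src[h] += z.T @ d_s
            self.ga_dst[h] += z.T @ d_t
            self.gW[h] += x.T @ d_z
            d_x += d_z @ self.W[h].T
        return d_x


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self._zero_grads()

    def _zero_grads(self) -> None:
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ d_out
        self.gb += d_out.sum(axis=0)
        return d_out @ self.W.T


class GATNetwork:
    """Three GAT layers + two FC layers, per the regressor architecture."""

    def __init__(self, in_dim: int, cfg: GATConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.in_dim = in_dim
        g1, g2, g3 = cfg.gat_dims
        self.gat1 = _GATLayer(in_dim, g1 // cfg.heads, cfg.heads, "concat", rng)
        self.gat2 = _GATLayer(g1, g2 // cfg.heads, cfg.heads, "concat", rng)
        self.gat3 = _GATLayer(g2, g3, cfg.heads, "mean", rng)
        self.fc1 = _Dense(cfg.fc_dims[0], cfg.fc_dims[1], rng)
        self.fc2 = _Dense(cfg.fc_dims[1], cfg.fc_dims[2], rng)
        for layer in (self.gat1, self.gat2, self.gat3):
            layer.slope = cfg.leaky_slope

    def _layers(self):
        return [self.gat1, self.gat2, self.gat3, self.fc1, self.fc2]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    def zero_grads(self) -> None:
        for layer in self._layers():
            layer._zero_grads()

    def forward(self, graph: ResidueGraph) -> np.ndarray:
        if graph.dim != self.in_dim:
            raise ModelError(
                f"graph embedding dim {graph.dim} != model input dim {self.in_dim}"
            )
        mask = graph.adjacency_mask()
        h = self.gat1.forward(graph.node_embeddings, mask)
        self._e1 = _elu(h)
        h = self.gat2.forward(self._e1, mask)
        self._e2 = _elu(h)
        h = self.gat3.forward(self._e2, mask)
        h = self.fc1.forward(h)
        self._e3 = _elu(h)
        out = self.fc2.forward(self._e3)
        return out[:, 0]

    def backward(self, d_pred: np.ndarray) -> None:
        d = self.fc2.backward(d_pred[:, None])
        d = d * _elu_grad_from_out(self._e3)
        d = self.fc1.backward(d)
        d = self.gat3.backward(d)
        d = d * _elu_grad_from_out(self._e2)
        d = self.gat2.backward(d)
        d = d * _elu_grad_from_out(self._e1)
        self.gat1.backward(d)

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_snapshot(self, snap: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), snap):
            p[...] = s


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _mse_and_grad(pred: np.ndarray, target: np.ndarray, scale: float) -> tuple[float, np.ndarray]:
    err = pred - target
    return float((err ** 2).sum() * scale), 2.0 * err * scale


def _validation_loss(net: GATNetwork, graphs: list[ResidueGraph]) -> float:
    total, n = 0.0, 0
    for g in graphs:
        pred = net.forward(g)
        total += float(((pred - g.targets) ** 2).sum())
        n += g.n_nodes
    return total / n


def train(
    graphs_train: list[ResidueGraph],
    graphs_val: list[ResidueGraph] | None,
    cfg: GATConfig,
) -> tuple[GATNetwork, pd.DataFrame]:
    """Train the GAT regressor with MSE loss and Adam.

    Minibatches of ``cfg.batch_size`` graphs; the loss of a batch is the mean
    squared error over all nodes in the batch. The returned network carries
    the parameters with the lowest validation loss ("best snapshot"); without
    validation graphs the final-epoch parameters are returned with a warning.
    The run is fully deterministic given ``cfg.seed``.
    """
    if not graphs_train:
        raise ModelError("at least one training graph is required")
    for g in graphs_train + (graphs_val or []):
        if g.targets is None:
            raise ModelError(f"{g.antigen_id}: training requires targets")
    rng = np.random.default_rng(cfg.seed)
    net = GATNetwork(graphs_train[0].dim, cfg, rng)
    opt = _Adam(net.params(), lr=cfg.lr)

    best_val = np.inf
    best_snap = net.snapshot()
    log_rows = []
    order = np.arange(len(graphs_train))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_sse, epoch_nodes = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            batch = [graphs_train[i] for i in order[start : start + cfg.batch_size]]
            total_nodes = sum(g.n_nodes for g in batch)
            net.zero_grads()
            for g in batch:
                pred = net.forward(g)
                sse, d_pred = _mse_and_grad(pred, g.targets, 1.0 / total_nodes)
                net.backward(d_pred)
                epoch_sse += sse * total_nodes
            epoch_nodes += total_nodes
            opt.step(net.params(), net.grads())
        train_loss = epoch_sse / epoch_nodes
        if graphs_val:
            val_loss = _validation_loss(net, graphs_val)
            if val_loss < best_val:
                best_val = val_loss
                best_snap = net.snapshot()
        else:
            val_loss = np.nan
        log_rows.append({"epoch": epoch + 1, "train_loss": train_loss,
                         "val_loss": val_loss})
    if graphs_val:
        net.load_snapshot(best_snap)
    else:
        warnings.warn("no validation graphs: returning final-epoch parameters",
                      stacklevel=2)
    return net, pd.DataFrame(log_rows)


@dataclass
class PredictionResult:
    """Per-residue predicted ID scores for one antigen."""

    antigen_id: str
    scores_raw: np.ndarray
    targets: np.ndarray | None = None

    @property
    def scores(self) -> np.ndarray:
        """Raw predictions clipped to [0, 1] for reporting."""
        return np.clip(self.scores_raw, 0.0, 1.0)

    def __len__(self) -> int:
        return self.scores_raw.size


def predict(graph: ResidueGraph, net: GATNetwork) -> PredictionResult:
    """Per-node predicted ID scores (raw regression output; ``.scores`` is
    the [0, 1]-clipped view)."""
    raw = net.forward(graph)
    return PredictionResult(antigen_id=graph.antigen_id, scores_raw=raw,
                            targets=graph.targets)


def split_validation(
    graphs: list[ResidueGraph], fraction: float = 0.1, seed: int = 0
) -> tuple[list[ResidueGraph], list[ResidueGraph]]:
    """Seeded train/validation split (validation = ceil(fraction * n),
    at least 1 when more than one graph is available)."""
    if len(graphs) < 2:
        return list(graphs), []
    rng = np.random.default_rng(seed)
    n_val = max(1, int(np.ceil(fraction * len(graphs))))
    idx = rng.permutation(len(graphs))
    val_set = set(idx[:n_val].tolist())
    train_g = [g for i, g in enumerate(graphs) if i not in val_set]
    val_g = [g for i, g in enumerate(graphs) if i in val_set]
    return train_g, val_g


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class GATRegressor:
    """Immunodominance regressor: configure with graphs, ``fit()`` trains.

    Example
    -------
    >>> model = GATRegressor(train_graphs, val_graphs, GATConfig.reduced(seed=1))
    >>> res = model.fit()
    >>> res.predict(test_graph).scores
    """

    def __init__(
        self,
        graphs_train: list[ResidueGraph],
        graphs_val: list[ResidueGraph] | None = None,
        config: GATConfig | None = None,
    ) -> None:
        self.graphs_train = graphs_train
        self.graphs_val = graphs_val
        self.config = config or GATConfig()

    def fit(self) -> "GATResults":
        net, history = train(self.graphs_train, self.graphs_val, self.config)
        return GATResults(net, history, self)


class GATResults:
    """Fitted GAT regressor: parameters, training history, prediction."""

    def __init__(self, network: GATNetwork, history: pd.DataFrame,
                 model: GATRegressor) -> None:
        self.network = network
        self.history = history
        self.model = model

    @property
    def final_train_loss(self) -> float:
        return float(self.history["train_loss"].iloc[-1])

    @property
    def best_val_loss(self) -> float:
        v = self.history["val_loss"].dropna()
        return float(v.min()) if len(v) else float("nan")

    def predict(self, graph: ResidueGraph) -> PredictionResult:
        return predict(graph, self.network)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "GAT immunodominance regressor",
            f"  input dim      : {self.network.in_dim}",
            f"  GAT dims/heads : {cfg.gat_dims} x {cfg.heads} heads",
            f"  FC dims        : {cfg.fc_dims}",
            f"  optimizer      : Adam, lr={cfg.lr:g}, batch={cfg.batch_size}, "
            f"epochs={cfg.epochs}, seed={cfg.seed}",
            f"  train graphs   : {len(self.model.graphs_train)}"
            f" | val graphs: {len(self.model.graphs_val or [])}",
            f"  final train MSE: {self.final_train_loss:.6g}",
            f"  best val MSE   : {self.best_val_loss:.6g}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        save_model(self.network, path)


# ---------------------------------------------------------------------------
# Serialization (JSON text: deterministic byte-for-byte given identical params)
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(net: GATNetwork, path: str | Path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "in_dim": net.in_dim,
        "config": asdict(net.cfg),
        "params": [p.tolist() for p in net.params()],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> GATNetwork:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ModelError(f"{path}: unsupported model format")
    cfg_d = payload["config"]
    cfg_d["gat_dims"] = tuple(cfg_d["gat_dims"])
    cfg_d["fc_dims"] = tuple(cfg_d["fc_dims"])
    cfg = GATConfig(**cfg_d)
    net = GATNetwork(payload["in_dim"], cfg, np.random.default_rng(0))
    net.load_snapshot([np.asarray(p, dtype=float) for p in payload["params"]])
    return net
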