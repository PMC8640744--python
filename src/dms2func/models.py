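"""Regression architectures over encoded variants.

Four architectures are supported: linear regression, fully connected,
sequence convolutional (valid convolution, no end padding) and graph
convolutional using the order-independent operator

    z_i = sigma(W_C . x_i + (1/|N_i|) * sum_{j in N_i} W_N . x_j + b)

where the neighbor term is zero for isolated nodes.  Everything is plain
numpy with hand-written backpropagation, which keeps the models portable and
gives exact input gradients for attribution methods.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dms2func.structure_graph import StructureGraph

ARCHITECTURES = ("linear", "fully_connected", "seq_conv", "graph_conv")


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: params/grads dicts plus forward/backward with caching."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    a = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-a, a, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _uniform_fan_in(rng, n_in, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] += self._x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float = 0.2) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Conv1d(Layer):
    """Valid (unpadded) 1-D convolution over the position axis, stride 1.

    Input (B, L, F) -> output (B, L - k + 1, C).
    """

    def __init__(self, n_in: int, filters: int, kernel: int, rng) -> None:
        super().__init__()
        self.kernel = kernel
        self.params["W"] = _uniform_fan_in(rng, n_in * kernel, (kernel, n_in, filters))
        self.params["b"] = np.zeros(filters)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"sequence length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        self._x = x
        T = x.shape[1] - self.kernel + 1
        # k strided matmuls beat a single einsum over the window view
        out = x[:, :T, :] @ self.params["W"][0]
        for dk in range(1, self.kernel):
            out += x[:, dk : dk + T, :] @ self.params["W"][dk]
        return out + self.params["b"]

    def backward(self, g):
        T = g.shape[1]
        windows = sliding_window_view(self._x, self.kernel, axis=1)  # (B,T,F,k)
        self.grads["W"] += np.einsum("btfk,btc->kfc", windows, g)
        self.grads["b"] += g.sum(axis=(0, 1))
        B = g.shape[0]
        F = self.params["W"].shape[1]
        dx = np.zeros((B, T + self.kernel - 1, F))
        for dk in range(self.kernel):
            dx[:, dk : dk + T, :] += g @ self.params["W"][dk].T
        return dx


class GraphConv(Layer):
    """Order-independent graph convolution with neighbor averaging.

    The neighbor signal is (1/|N_i|) sum_j W_N . x_j; isolated nodes get a
    zero neighbor term.  Graph topology is shared by all layers of a model.
    """

    def __init__(self, n_in: int, filters: int, graph: StructureGraph, rng) -> None:
        super().__init__()
        self.norm_adj = graph.norm_adjacency()
        self.params["W_C"] = _uniform_fan_in(rng, n_in, (n_in, filters))
        self.params["W_N"] = _uniform_fan_in(rng, n_in, (n_in, filters))
        self.params["b"] = np.zeros(filters)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        if x.shape[1] != self.norm_adj.shape[0]:
            raise ValueError(
                f"node count {x.shape[1]} does not match graph "
                f"({self.norm_adj.shape[0]} nodes)"
            )
        self._x = x
        self._nx = np.matmul(self.norm_adj[None], x)
        return (
            x @ self.params["W_C"] + self._nx @ self.params["W_N"] + self.params["b"]
        )

    def backward(self, g):
        self.grads["W_C"] += np.einsum("blf,blc->fc", self._x, g)
        self.grads["W_N"] += np.einsum("blf,blc->fc", self._nx, g)
        self.grads["b"] += g.sum(axis=(0, 1))
        dx = g @ self.params["W_C"].T
        dy = g @ self.params["W_N"].T
        dx += np.matmul(self.norm_adj.T[None], dy)
        return dx


def graph_conv_apply(
    X: np.ndarray,
    g: StructureGraph,
    W_C: np.ndarray,
    W_N: np.ndarray,
    b: np.ndarray,
    activation=None,
) -> np.ndarray:
    """Apply one graph convolution to an (L, F) node-feature matrix.

    Functional form of the :class:`GraphConv` layer for a single graph;
    ``activation`` defaults to identity.
    """
    if X.shape[0] != g.n_nodes:
        raise ValueError("feature row count does not match graph node count")
    if W_C.shape != W_N.shape:
        raise ValueError("W_C and W_N must have the same shape")
    if X.shape[1] != W_C.shape[0]:
        raise ValueError("feature width does not match weight matrix")
    z = X @ W_C + g.norm_adjacency() @ X @ W_N + b
    return z if activation is None else activation(z)


# ---------------------------------------------------------------------------
# model specs and assembly


@dataclass
class ModelSpec:
    """Architecture description; everything needed to rebuild a model."""

    architecture: str = "linear"
    hidden_sizes: tuple[int, ...] = (100,)  # fully_connected only
    conv_layers: int = 1
    filters: int = 16
    kernel_size: int = 5  # seq_conv only
    dense_width: int = 100
    include_final_dense: bool = True
    dropout: float = 0.20
    leaky_slope: float = 0.2
    seed: int = 0
    graph: Optional[StructureGraph] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "graph_conv" and self.graph is None:
            raise ValueError("graph_conv requires a structure graph")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("graph")
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict, graph: Optional[StructureGraph] = None) -> "ModelSpec":
        d = dict(d)
        d["hidden_sizes"] = tuple(d.get("hidden_sizes", (100,)))
        return cls(graph=graph, **d)


class Model:
    """A feed-forward stack over (N, L, F) encoded variants with one output."""

    def __init__(self, layers: list[Layer], spec: ModelSpec, L: int, in_features: int):
        self.layers = layers
        self.spec = spec
        self.L = L
        self.in_features = in_features
        self.trained = False

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    # -- inference ---------------------------------------------------------

    def _check_shape(self, X: np.ndarray) -> None:
        if X.ndim != 3 or X.shape[1] != self.L or X.shape[2] != self.in_features:
            raise ValueError(
                f"expected input of shape (N, {self.L}, {self.in_features}), "
                f"got {X.shape}"
            )

    def predict(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """One scalar per variant; dropout disabled."""
        self._check_shape(X)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out[sl] = self.forward(X[sl], train=False).ravel()
        return out

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(input) for each example, via backpropagation."""
        self._check_shape(X)
        self.zero_grads()
        out = self.forward(X, train=False)
        return self.backward(np.ones_like(out))

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Activations entering the final output node (the last internal layer)."""
        if len(self.layers) < 3:
            raise ValueError("model has no internal layer before the output node")
        self._check_shape(X)
        h = X
        for layer in self.layers[:-1]:
            h = layer.forward(h, train=False)
        return h

    # -- parameter plumbing ------------------------------------------------

    def param_items(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]

    def params_list(self) -> list[np.ndarray]:
        return [layer.params[k] for layer, k in self.param_items()]

    def grads_list(self) -> list[np.ndarray]:
        return [layer.grads[k] for layer, k in self.param_items()]

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params_list()]

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        for (layer, k), v in zip(self.param_items(), values):
            layer.params[k] = v.copy()

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params_list())

    def describe(self) -> str:
        lines = [f"{self.spec.architecture} model, input ({self.L}, {self.in_features})"]
        for layer in self.layers:
            shapes = {k: v.shape for k, v in layer.params.items()}
            lines.append(f"  {type(layer).__name__} {shapes if shapes else ''}".rstrip())
        lines.append(f"trainable parameters: {self.param_count}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {
            f"p{i}": p for i, p in enumerate(self.params_list())
        }
        meta = {
            "spec": self.spec.to_dict(),
            "L": self.L,
            "in_features": self.in_features,
            "trained": self.trained,
            "edges": sorted(self.spec.graph.edges()) if self.spec.graph else None,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        import networkx as nx

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            graph = None
            if meta["edges"] is not None:
                g = nx.Graph()
                g.add_nodes_from(range(meta["L"]))
                g.add_edges_from([tuple(e) for e in meta["edges"]])
                graph = StructureGraph(g, kind="contact")
            spec = ModelSpec.from_dict(meta["spec"], graph=graph)
            model = build_model(spec, meta["L"], meta["in_features"])
            n = len(model.params_list())
            model.set_params([data[f"p{i}"] for i in range(n)])
            model.trained = meta["trained"]
        return model


def build_model(spec: ModelSpec, L: int, in_features: int) -> Model:
    """Assemble a model with seeded initial parameters.

    Two builds with the same spec (including seed) produce bit-identical
    initial parameters.
    """
    rng = np.random.default_rng(spec.seed)
    act = lambda: LeakyReLU(spec.leaky_slope)  # noqa: E731
    layers: list[Layer] = []
    if spec.architecture == "linear":
        layers = [Flatten(), Dense(L * in_features, 1, rng)]
    elif spec.architecture == "fully_connected":
        layers = [Flatten()]
        width = L * in_features
        for h in spec.hidden_sizes:
            layers += [Dense(width, h, rng), act(), Dropout(spec.dropout)]
            width = h
        layers.append(Dense(width, 1, rng))
    elif spec.architecture == "seq_conv":
        layers = []
        width, length = in_features, L
        for _ in range(spec.conv_layers):
            layers += [Conv1d(width, spec.filters, spec.kernel_size, rng), act()]
            width = spec.filters
            length = length - spec.kernel_size + 1
            if length < 1:
                raise ValueError("kernel too wide for sequence length")
        layers.append(Flatten())
        layers += _dense_head(length * width, spec, rng)
    elif spec.architecture == "graph_conv":
        if spec.graph.n_nodes != L:
            raise ValueError(
                f"graph has {spec.graph.n_nodes} nodes but sequence length is {L}"
            )
        layers = []
        width = in_features
        for _ in range(spec.conv_layers):
            layers += [GraphConv(width, spec.filters, spec.graph, rng), act()]
            width = spec.filters
        layers.append(Flatten())
        layers += _dense_head(L * width, spec, rng)
    return Model(layers, spec, L, in_features)


def _dense_head(width: int, spec: ModelSpec, rng) -> list[Layer]:
    if spec.include_final_dense:
        return [
            Dense(width, spec.dense_width, rng),
            LeakyReLU(spec.leaky_slope),
            Dropout(spec.dropout),
            Dense(spec.dense_width, 1, rng),
        ]
    return [Dense(width, 1, rng)]


class Adam:
    """Adam with default betas/epsilon; only lr is exposed."""

    def __init__(self, model: Model, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.params_list()]
        self.v = [np.zeros_like(p) for p in model.params_list()]

    def step(self) -> None:
        self.t += 1
        params = self.model.params_list()
        grads = self.model.grads_list()
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
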