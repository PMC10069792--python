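"""Network architectures for phenotype prediction.

Three feed-forward geometries are used throughout:

* fitness net — 63 fitness features -> 256 -> 128 -> 64 -> 1;
* sequence net — 31x21 one-hot matrix, three position-wise dense layers
  (31x128, 31x64, 31x32), flattened to 992, a 32-node layer, then a single
  output;
* MD net — 62 averaged distances -> 128 -> 64 -> 32 -> 1, or 128 -> 64
  followed by a self-attention layer feeding the output.

Hidden layers use ReLU; softmax appears only inside attention.  All
networks expose ``hidden`` (the last hidden activation) and a ``head``
dense layer so that pre-trained branches can be combined (feed-last /
concat-last) with frozen weights.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, glorot_uniform


class Dense:
    """Affine layer ``x @ W + b`` with optional freezing."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor.param(glorot_uniform(rng, n_in, n_out))
        self.b = Tensor.param(np.zeros(n_out))
        self.trainable = True

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


def self_attention(h: Tensor, scaled: bool = False) -> Tensor:
    """Self-attention over the units of a hidden vector.

    The hidden activation itself serves as query, key and value; each unit
    is a token carrying a scalar value.  For a batch ``h`` of shape (B, d):
    similarities ``S = q k^T`` (B, d, d), attention weights are the row-wise
    softmax of ``S`` (each row sums to 1), and the output is ``weights @ v``
    (B, d).  A constant hidden vector is returned unchanged (uniform
    weights averaging identical values).

    ``scaled`` divides similarities by sqrt(d); off by default (plain dot
    product), provided as a toggle.
    """
    if not np.all(np.isfinite(h.value)):
        raise ValueError("non-finite activations entering attention")
    B, d = h.shape
    q = h.reshape(B, d, 1)
    sim = q @ q.transpose_last()            # (B, d, d)
    if scaled:
        sim = sim * (1.0 / np.sqrt(d))
    weights = sim.softmax(axis=-1)
    out = weights @ q                       # (B, d, 1)
    return out.reshape(B, d)


def attention_weights(h: np.ndarray, scaled: bool = False) -> np.ndarray:
    """Attention weight matrix for inspection (rows sum to 1)."""
    hh = np.atleast_2d(h)
    sim = hh[:, :, None] * hh[:, None, :]
    if scaled:
        sim = sim / np.sqrt(hh.shape[-1])
    sim = sim - sim.max(axis=-1, keepdims=True)
    e = np.exp(sim)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Base class: ``forward = head(hidden(x))`` with weight (de)serialisation."""

    layers: list[Dense]
    head: Dense
    hidden_width: int

    def hidden(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def _lift(self, X) -> Tensor:
        return X if isinstance(X, Tensor) else Tensor.const(np.asarray(X, dtype=float))

    def forward(self, X) -> Tensor:
        return self.head(self.hidden(self._lift(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Point predictions as a 1-D array (no gradient tracking)."""
        return self.forward(np.asarray(X, dtype=float)).value.ravel()

    # -- parameters ----------------------------------------------------------

    @property
    def all_layers(self) -> list[Dense]:
        return [*self.layers, self.head]

    def parameters(self, trainable_only: bool = True) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.all_layers:
            if layer.trainable or not trainable_only:
                out.extend(layer.params)
        return out

    def freeze(self) -> "Network":
        for layer in self.all_layers:
            layer.trainable = False
        return self

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters(trainable_only=False)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters(trainable_only=False)
        if len(params) != len(weights):
            raise ValueError(
                f"weight count mismatch: model has {len(params)}, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {w.shape}")
            p.value = np.array(w, dtype=float)


class DenseNet(Network):
    """Plain multilayer perceptron with ReLU hidden layers and one output.

    Covers the fitness geometry (63 -> 256/128/64 -> 1) and the MD geometry
    (62 -> 128/64/32 -> 1).
    """

    def __init__(self, input_dim: int, hidden_widths: tuple[int, ...],
                 rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_widths = tuple(hidden_widths)
        widths = [input_dim, *hidden_widths]
        self.layers = [Dense(rng, widths[i], widths[i + 1]) for i in range(len(hidden_widths))]
        self.hidden_width = hidden_widths[-1]
        self.head = Dense(rng, self.hidden_width, 1)

    def hidden(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h).relu()
        return h


class AttentionDenseNet(Network):
    """MD-feature net with a self-attention layer after the last hidden layer.

    62 -> 128 -> 64 -> attention over the 64 units -> single output.  With
    the attention step removed this is exactly the plain 128/64 net.
    """

    def __init__(self, input_dim: int, hidden_widths: tuple[int, ...] = (128, 64),
                 rng: np.random.Generator | None = None, scaled: bool = False):
        rng = rng if rng is not None else np.random.default_rng()
        self.input_dim = input_dim
        self.hidden_widths = tuple(hidden_widths)
        self.scaled = scaled
        widths = [input_dim, *hidden_widths]
        self.layers = [Dense(rng, widths[i], widths[i + 1]) for i in range(len(hidden_widths))]
        self.hidden_width = hidden_widths[-1]
        self.head = Dense(rng, self.hidden_width, 1)

    def hidden(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h).relu()
        return self_attention(h, scaled=self.scaled)


class SequenceNet(Network):
    """One-hot sequence net with position-wise dense layers.

    Input (B, 31, 21); dense layers act on the channel axis only, keeping
    the 31-position axis: (B, 31, 128) -> (B, 31, 64) -> (B, 31, 32);
    flattened to 992, passed through a 32-node layer, then the output.
    """

    def __init__(self, seq_len: int = 31, n_channels: int = 21,
                 position_widths: tuple[int, ...] = (128, 64, 32),
                 dense_width: int = 32, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.seq_len = seq_len
        self.n_channels = n_channels
        self.position_widths = tuple(position_widths)
        widths = [n_channels, *position_widths]
        self.layers = [Dense(rng, widths[i], widths[i + 1]) for i in range(len(position_widths))]
        self.flat_width = seq_len * position_widths[-1]   # 31 * 32 = 992
        self.post_flatten = Dense(rng, self.flat_width, dense_width)
        self.hidden_width = dense_width
        self.head = Dense(rng, dense_width, 1)

    @property
    def all_layers(self) -> list[Dense]:
        return [*self.layers, self.post_flatten, self.head]

    def hidden(self, x: Tensor) -> Tensor:
        h = x                                   # (B, 31, 21)
        for layer in self.layers:
            h = layer(h).relu()                 # position-wise: (B, 31, w)
        B = h.shape[0]
        flat = h.reshape(B, self.flat_width)    # (B, 992)
        return self.post_flatten(flat).relu()   # (B, 32)


class CombinedNet(Network):
    """Two branches joined at the top with the pretrained branch frozen.

    ``feed-last`` adds the new branch's hidden activation into the
    pretrained branch's last hidden layer (the new branch learns a
    projection to the pretrained hidden width); a zeroed new branch then
    reproduces the pretrained outputs exactly.  ``concat-last``
    concatenates both last hidden layers and fits a fresh output layer.
    """

    def __init__(self, pretrained: Network, branch: Network, mode: str,
                 rng: np.random.Generator | None = None):
        if mode not in ("feed-last", "concat-last"):
            raise ValueError(f"unknown combine mode {mode!r}")
        rng = rng if rng is not None else np.random.default_rng()
        self.mode = mode
        self.pretrained = pretrained.freeze()
        self.branch = branch
        if mode == "feed-last":
            self.injection = Dense(rng, branch.hidden_width, pretrained.hidden_width)
            # Zero-init so that at construction the combined model equals
            # the pretrained model (additive-injection null).
            self.injection.W.value[:] = 0.0
            self.head = pretrained.head          # frozen
            self.hidden_width = pretrained.hidden_width
        else:
            self.injection = None
            self.hidden_width = pretrained.hidden_width + branch.hidden_width
            self.head = Dense(rng, self.hidden_width, 1)

    @property
    def all_layers(self) -> list[Dense]:
        layers = [*self.pretrained.all_layers, *self.branch.all_layers]
        if self.injection is not None:
            layers.append(self.injection)
        if self.mode == "concat-last":
            layers.append(self.head)
        return layers

    def forward(self, inputs) -> Tensor:
        x_pre, x_new = inputs
        h_pre = self.pretrained.hidden(self._lift(x_pre))
        h_new = self.branch.hidden(self._lift(x_new))
        if self.mode == "feed-last":
            return self.head(h_pre + self.injection(h_new))
        return self.head(concatenate([h_pre, h_new], axis=-1))

    def predict(self, inputs) -> np.ndarray:
        return self.forward(inputs).value.ravel()


def transfer_combine(pretrained: Network, branch: Network, mode: str,
                     rng: np.random.Generator | None = None) -> CombinedNet:
    """Combine a frozen pre-trained model with a trainable branch."""
    return CombinedNet(pretrained, branch, mode, rng=rng)
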