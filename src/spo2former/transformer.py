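"""Transformer encoder for per-second apnea sequence labeling.

The network maps a normalized SpO2 window ``X = [x_0, ..., x_n]`` to one
apnea probability per second. A pointwise linear layer lifts the single
SpO2 feature to ``d_model``; a positional-encoding stage injects order
information (or, in the learnable variant, a convolutional autoencoder
re-represents the raw window before the lift); a stack of identical
encoder layers — multi-head scaled-dot-product self-attention and a
position-wise feedforward, each with residual connection and layer
normalization — contextualizes every timestep; and a per-timestep linear
head with a sigmoid emits probabilities.

Attention follows ``Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V``
with ``d_k = d_model / n_heads`` per head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import PE_VARIANTS, CaeConfig, ConvAutoencoder, constant_pe, sinusoidal_pe
from .nn import Dropout, LayerNorm, Linear, Module, Tensor, softmax


class ConfigurationError(ValueError):
    """An inconsistent model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``d_model=32`` matches the sinusoidal-table depth; four encoder layers
    form the reference stack. ``n_heads=4``, ``d_ff=64`` and the dropout
    rate are free choices, kept small and configurable.
    """

    n_encoder_layers: int = 4
    d_model: int = 32
    n_heads: int = 4
    d_ff: int = 64
    dropout_rate: float = 0.1
    sequence_length: int = 120
    pe: str = "learnable"
    cae: CaeConfig = field(default_factory=CaeConfig)
    cae_additive: bool = False
    sinusoidal_table_length: int = 64
    norm_placement: str = "post"
    head: str = "per_second"

    def __post_init__(self):
        if self.pe not in PE_VARIANTS:
            raise ConfigurationError(f"pe must be one of {PE_VARIANTS}, got {self.pe!r}")
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")
        if self.n_encoder_layers < 1:
            raise ConfigurationError("need at least one encoder layer")
        if not 1 <= self.sequence_length:
            raise ConfigurationError("sequence_length must be >= 1")
        if self.pe == "learnable" and self.cae is None:
            raise ConfigurationError("learnable positional encoding requires a CaeConfig")
        if self.norm_placement not in ("post", "pre"):
            raise ConfigurationError("norm_placement must be 'post' or 'pre'")
        if self.head not in ("per_second", "segment"):
            raise ConfigurationError("head must be 'per_second' or 'segment'")


def scaled_dot_product_attention(Q, K, V):
    """``softmax(Q K^T / sqrt(d_k)) V`` on plain arrays.

    Returns ``(output, weights)``; each weights row is a probability
    distribution over key positions, so every output row is a convex
    combination of the rows of ``V``.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share depth d_k")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share time extent")
    d_k = Q.shape[-1]
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V, weights


def _attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    d_k = q.shape[-1]
    logits = (q @ k.transpose(tuple(range(q.data.ndim - 2)) + (q.data.ndim - 1, q.data.ndim - 2)))
    logits = logits * (1.0 / np.sqrt(d_k))
    return softmax(logits, axis=-1) @ v


class MultiHeadAttention(Module):
    """Self-attention with ``n_heads`` parallel heads of depth d_model/n_heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.n_heads, self.d_k).transpose((0, 2, 1, 3))

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        heads = _attention(q, k, v)  # (b, h, t, d_k)
        merged = heads.transpose((0, 2, 1, 3)).reshape(b, t, d)
        return self.wo(merged)


class EncoderLayer(Module):
    """MHA and feedforward sublayers, each with residual + layer norm."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.mha = MultiHeadAttention(config.d_model, config.n_heads, rng)
        self.ff1 = Linear(config.d_model, config.d_ff, rng)
        self.ff2 = Linear(config.d_ff, config.d_model, rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)
        self.dropout = Dropout(config.dropout_rate, rng)
        self.pre_norm = config.norm_placement == "pre"

    def forward(self, x: Tensor) -> Tensor:
        if self.pre_norm:
            x = x + self.dropout(self.mha(self.norm1(x)))
            return x + self.dropout(self.ff2(self.ff1(self.norm2(x)).relu()))
        x = self.norm1(x + self.dropout(self.mha(x)))
        return self.norm2(x + self.dropout(self.ff2(self.ff1(x).relu())))


class SpO2Transformer(Module):
    """The full detector: embedding, positional stage, encoder stack, head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.cae = ConvAutoencoder(config.cae, rng) if config.pe == "learnable" else None
        self.embed = Linear(1, config.d_model, rng)
        self.layers = [EncoderLayer(config, rng) for _ in range(config.n_encoder_layers)]
        self.out = Linear(config.d_model, 1, rng)
        if config.pe == "constant":
            self._pe_table = constant_pe(config.sequence_length)
        elif config.pe == "sinusoidal":
            n = max(config.sequence_length, config.sinusoidal_table_length)
            self._pe_table = sinusoidal_pe(n, config.d_model).values
        else:
            self._pe_table = None

    def forward_parts(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """(batch, T, 1) normalized SpO2 -> (logits, CAE reconstruction).

        Logits are (batch, T) for the per-second head, (batch,) for the
        window-level mean-pool head; the reconstruction is None unless the
        learnable encoding is active.
        """
        b, t, f = x.shape
        if f != 1:
            raise ValueError("expected a single SpO2 feature per timestep")
        recon = None
        if self.cae is not None:
            recon = self.cae(x)
            # reconstruction replaces the raw input (optionally adds to it)
            x = x + recon if self.config.cae_additive else recon
        h = self.embed(x)
        if self._pe_table is not None:
            if t > self._pe_table.shape[0]:
                raise ValueError("window longer than the positional table")
            table = self._pe_table[:t]
            h = h + Tensor(table[:, None] if table.ndim == 1 else table)
        for layer in self.layers:
            h = layer(h)
        if self.config.head == "segment":
            return self.out(h.mean(axis=1)).reshape(b), recon
        return self.out(h).reshape(b, t), recon

    def forward_logits(self, x: Tensor) -> Tensor:
        return self.forward_parts(x)[0]

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x)

    def predict_proba(self, values: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-second apnea probabilities for (n, T) or (n, T, 1) windows."""
        x = np.asarray(values, dtype=np.float64)
        if x.ndim == 2:
            x = x[..., None]
        self.eval()
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(Tensor(x[i : i + batch_size])).data
            out.append(0.5 * (1.0 + np.tanh(0.5 * logits)))
        return np.concatenate(out, axis=0) if out else np.empty((0, x.shape[1]))


def build_model(config: ModelConfig, seed: int = 0) -> SpO2Transformer:
    """Construct a detector with seeded Glorot initialization."""
    return SpO2Transformer(config, seed=seed)


def save_model(model: SpO2Transformer, path) -> None:
    """Serialize parameters (.npz) with a JSON sidecar of the configuration."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    np.savez(path, *[p.data for p in model.parameters()])
    cfg = asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_model(path) -> SpO2Transformer:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["cae"] = CaeConfig(**{**cfg["cae"], "filters": tuple(cfg["cae"]["filters"])})
    model = SpO2Transformer(ModelConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_arrays([data[f"arr_{i}"] for i in range(len(data.files))])
    return model
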