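"""Positional-information mechanisms for the transformer detector.

Three interchangeable variants are provided (plus ``none``):

``constant``
    The normalized sample index, ``PE(i) = i / (n - 1)``, broadcast across
    the model depth and added to the input embedding.
``sinusoidal``
    The classic fixed table ``PE(pos, 2i) = sin(pos / 10000^(2i/d_model))``,
    ``PE(pos, 2i+1) = cos(...)``, added to the input embedding.
``learnable``
    A 1-D convolutional autoencoder (CAE): strided convolutions (kernel 7,
    stride 2, ReLU, dropout) compress the raw window to a bottleneck;
    transposed convolutions and a final kernel-7 stride-1 convolution
    reconstruct a sequence of the input's length. The reconstruction
    replaces the raw input fed to the transformer and is trained end-to-end
    through the classification loss, so the network learns a
    position-and-context-aware representation rather than being handed a
    fixed positional table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv1d, ConvTranspose1d, Dropout, Module, Tensor

PE_VARIANTS = ("none", "constant", "sinusoidal", "learnable")


@dataclass(frozen=True)
class PEMatrix:
    """A positions × depth table of positional-encoding values."""

    values: np.ndarray

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def d_model(self) -> int:
        return self.values.shape[1]


def constant_pe(n: int) -> np.ndarray:
    """Normalized-index encoding: ``[0, 1/(n-1), ..., 1]``; ``[0]`` for n=1."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    if n == 1:
        return np.zeros(1)
    return np.arange(n, dtype=np.float64) / (n - 1)


def sinusoidal_pe(length: int, d_model: int) -> PEMatrix:
    """Fixed sine/cosine positional table of shape (length, d_model)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if d_model < 2 or d_model % 2 != 0:
        raise ValueError("d_model must be a positive even integer")
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    table = np.empty((length, d_model))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return PEMatrix(values=table)


def additive_combine(input_embedding: np.ndarray, pe) -> np.ndarray:
    """Add a positional encoding to an input embedding, ``Z_i = E(x_i) + PE(i)``.

    ``pe`` may be a :class:`PEMatrix`, a 2-D table, or a 1-D vector (the
    constant encoding), which broadcasts across depth. The table is
    truncated to the embedding's time extent.
    """
    x = np.asarray(input_embedding, dtype=np.float64)
    table = pe.values if isinstance(pe, PEMatrix) else np.asarray(pe, dtype=np.float64)
    t = x.shape[-2]
    if table.ndim == 1:
        if table.shape[0] < t:
            raise ValueError("positional encoding shorter than the input")
        return x + table[:t, None]
    if table.shape[0] < t:
        raise ValueError("positional encoding shorter than the input")
    if table.shape[1] != x.shape[-1]:
        raise ValueError(
            f"depth mismatch: embedding depth {x.shape[-1]}, encoding depth {table.shape[1]}"
        )
    return x + table[:t]


@dataclass(frozen=True)
class CaeConfig:
    """Architecture of the learnable-encoding convolutional autoencoder.

    Kernel size 7, down-stride 2 and a final stride-1 kernel-7 convolution
    are the pinned values; depth and filter counts are configurable.
    """

    n_down_layers: int = 2
    filters: tuple[int, ...] = (32, 16)
    kernel_size: int = 7
    down_stride: int = 2
    final_kernel: int = 7
    final_stride: int = 1
    dropout_rate: float = 0.1

    def __post_init__(self):
        if len(self.filters) != self.n_down_layers:
            raise ValueError("filters must list one channel count per down layer")
        if self.n_down_layers < 1:
            raise ValueError("need at least one strided layer")

    @property
    def n_up_layers(self) -> int:
        return self.n_down_layers


def cae_latent_length(input_length: int, config: CaeConfig = CaeConfig()) -> int:
    """Bottleneck time extent: ``input_length`` halved (ceil) per strided layer."""
    n = input_length
    for _ in range(config.n_down_layers):
        n = -(-n // config.down_stride)
    return n


class ConvAutoencoder(Module):
    """1-D convolutional autoencoder producing a same-length reconstruction.

    Encoder: ``n_down_layers`` same-padded convolutions (kernel 7, stride 2,
    ReLU) with dropout between. Decoder: mirrored transposed convolutions
    (ReLU) targeting the exact intermediate lengths, then a final kernel-7
    stride-1 convolution back to one channel, so the output length equals
    the input length for any window size.
    """

    def __init__(self, config: CaeConfig, rng: np.random.Generator):
        self.config = config
        k, s = config.kernel_size, config.down_stride
        self.down = []
        c_prev = 1
        for c in config.filters:
            self.down.append(Conv1d(c_prev, c, k, s, rng))
            c_prev = c
        up_channels = tuple(reversed(config.filters))[1:] + (config.filters[0],)
        self.up = []
        for c in up_channels:
            self.up.append(ConvTranspose1d(c_prev, c, k, s, rng))
            c_prev = c
        self.final = Conv1d(c_prev, 1, config.final_kernel, config.final_stride, rng)
        self.dropout = Dropout(config.dropout_rate, rng)

    def forward(self, x: Tensor) -> Tensor:
        lengths = [x.shape[1]]
        h = x
        for layer in self.down:
            h = layer(h).relu()
            h = self.dropout(h)
            lengths.append(h.shape[1])
        # lengths[:-1] reversed are the targets for the transposed stack
        targets = lengths[-2::-1]
        for layer, t_out in zip(self.up, targets):
            h = layer(h, t_out).relu()
        return self.final(h)


def cae_forward(segment_values: np.ndarray, cae: ConvAutoencoder) -> np.ndarray:
    """Run the autoencoder on raw values; shape-flexible convenience wrapper.

    Accepts (T,), (batch, T) or (batch, T, 1) arrays and returns the
    reconstruction with the same leading shape.
    """
    x = np.asarray(segment_values, dtype=np.float64)
    squeeze_batch = x.ndim == 1
    if x.ndim == 1:
        x = x[None, :, None]
    elif x.ndim == 2:
        x = x[..., None]
    out = cae(Tensor(x)).data[..., 0]
    return out[0] if squeeze_batch else out
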