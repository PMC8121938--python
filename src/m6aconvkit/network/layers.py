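"""Layer primitives built on the autodiff core."""

from __future__ import annotations

import numpy as np

from m6aconvkit.network import autodiff as ad
from m6aconvkit.network.autodiff import Tensor

_ACTIVATIONS = {
    "linear": lambda t: t,
    "relu": ad.relu,
    "sigmoid": ad.sigmoid,
    "tanh": ad.tanh,
}


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    @property
    def params(self) -> list[Tensor]:
        raise NotImplementedError


class Dense(Layer):
    def __init__(
        self, rng: np.random.Generator, in_dim: int, out_dim: int, activation: str = "linear"
    ) -> None:
        self.w = ad.parameter(_glorot(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = ad.parameter(np.zeros(out_dim))
        self.activation = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        return self.activation(ad.matmul(x, self.w) + self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (batch, T, channels) input."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int,
        out_channels: int,
        kernel: int,
        activation: str = "relu",
    ) -> None:
        fan_in = kernel * in_channels
        fan_out = kernel * out_channels
        self.w = ad.parameter(_glorot(rng, (kernel, in_channels, out_channels), fan_in, fan_out))
        self.b = ad.parameter(np.zeros(out_channels))
        self.kernel = kernel
        self.activation = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        return self.activation(ad.conv1d(x, self.w, self.b))

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class LSTM(Layer):
    """Unidirectional LSTM returning the hidden state at every time step."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden: int) -> None:
        h = hidden
        self.wx = ad.parameter(_glorot(rng, (in_dim, 4 * h), in_dim, 4 * h))
        self.wh = ad.parameter(_glorot(rng, (h, 4 * h), h, 4 * h))
        bias = np.zeros(4 * h)
        bias[h : 2 * h] = 1.0  # forget-gate bias
        self.b = ad.parameter(bias)
        self.hidden = h

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        hd = self.hidden
        z = ad.matmul(x_t, self.wx) + ad.matmul(h, self.wh) + self.b
        i = ad.sigmoid(z[:, 0:hd])
        f = ad.sigmoid(z[:, hd : 2 * hd])
        g = ad.tanh(z[:, 2 * hd : 3 * hd])
        o = ad.sigmoid(z[:, 3 * hd : 4 * hd])
        c_new = f * c + i * g
        return o * ad.tanh(c_new), c_new

    def run(self, x: Tensor, reverse: bool = False) -> list[Tensor]:
        batch, t_len, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        order = range(t_len - 1, -1, -1) if reverse else range(t_len)
        outputs: dict[int, Tensor] = {}
        for t in order:
            h, c = self.step(x[:, t, :], h, c)
            outputs[t] = h
        return [outputs[t] for t in range(t_len)]

    @property
    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]


class BiLSTM(Layer):
    """Bidirectional LSTM; output channel width is 2 × per-direction width."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_per_direction: int) -> None:
        self.forward = LSTM(rng, in_dim, hidden_per_direction)
        self.backward = LSTM(rng, in_dim, hidden_per_direction)
        self.out_dim = 2 * hidden_per_direction

    def __call__(self, x: Tensor) -> Tensor:
        """Return the (batch, T, 2H) output matrix."""
        fwd = self.forward.run(x, reverse=False)
        bwd = self.backward.run(x, reverse=True)
        batch = x.shape[0]
        steps = [
            ad.reshape(ad.concat([f, b], axis=1), (batch, 1, self.out_dim))
            for f, b in zip(fwd, bwd)
        ]
        return ad.concat(steps, axis=1)

    @property
    def params(self) -> list[Tensor]:
        return self.forward.params + self.backward.params
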