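"""Neural-network layers on top of the autodiff tape.

Layout convention: sequence tensors are (batch, length, channels); dense
inputs are (batch, features).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, get_dtype


class Module:
    """Base class: tracks parameters and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- flat state dict of raw arrays, for JSON/NPZ-free text persistence --
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.state_arrays(prefix + name + "."))
        for attr in ("running_mean", "running_var"):
            if attr in self.__dict__:
                out[prefix + attr] = self.__dict__[attr]
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=get_dtype())
        for name, child in self._children.items():
            child.load_state_arrays(state, prefix + name + ".")
        for attr in ("running_mean", "running_var"):
            if attr in self.__dict__ and prefix + attr in state:
                self.__dict__[attr] = np.asarray(state[prefix + attr],
                                                 dtype=get_dtype())


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he"):
        super().__init__()
        if init == "he":
            scale = np.sqrt(2.0 / n_in)
        else:
            scale = np.sqrt(1.0 / n_in)
        self.register("W", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.register("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.affine(self.W, self.b)


class Conv1d(Module):
    """1-D convolution, stride 1, length-preserving (same) zero padding.

    A transposed convolution at stride 1 with same padding is itself a
    convolution, so this layer also serves as the decoder "deconvolution".
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        scale = np.sqrt(2.0 / (kernel * c_in))  # He
        self.register("W", rng.normal(0.0, scale, size=(kernel * c_in, c_out)))
        self.register("b", np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        pad = (self.kernel - 1) // 2
        patches = x.pad1d(pad, pad).unfold1d(self.kernel)
        B, L, KC = patches.shape
        # 2-D affine so the weight gradient never materializes per-batch
        out = patches.reshape(B * L, KC).affine(self.W, self.b)
        return out.reshape(B, L, -1)


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel.

    Also handles (batch, features) input, normalizing per feature.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.register("gamma", np.ones(n_channels))
        self.register("beta", np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels, dtype=get_dtype())
        self.running_var = np.ones(n_channels, dtype=get_dtype())

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = x.batchnorm(self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
            return out
        mu = Tensor(self.running_mean)
        var = Tensor(self.running_var)
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout parameterized by *keep* probability."""

    def __init__(self, keep_prob: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError("keep_prob must be in (0, 1]")
        self.keep_prob = keep_prob
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.keep_prob == 1.0:
            return x
        mask = (self.rng.random(x.shape) < self.keep_prob).astype(x.data.dtype)
        return x * Tensor(mask / self.keep_prob)
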