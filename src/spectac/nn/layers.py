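"""Layer objects owning parameters; graphs are built per forward call."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, conv3d, linear


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        stack = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Module):
                    mods.append(v)
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    for m in v:
                        if isinstance(m, Module):
                            mods.append(m)
                            stack.append(m)
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and batch-norm running
        statistics, for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                out[f"bn_{i}_mean"] = m.running_mean
                out[f"bn_{i}_var"] = m.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"param_{i}"], dtype=DTYPE)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                m.running_mean = np.asarray(arrays[f"bn_{i}_mean"], dtype=DTYPE)
                m.running_var = np.asarray(arrays[f"bn_{i}_var"], dtype=DTYPE)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1):
        fan_in = c_in * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.pad = (kernel - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Dense(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W) with running
    statistics for deterministic inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x.data - mu.reshape(shape)) * invstd.reshape(shape)
        out_data = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        out = Tensor(out_data, parents=(x, self.gamma, self.beta))
        gamma, beta, training = self.gamma, self.beta, self.training

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if not x.requires_grad:
                return
            gxhat = g * gamma.data.reshape(shape)
            if training:
                m = x.data.size / x.data.shape[1]
                t1 = gxhat.sum(axis=axes, keepdims=True)
                t2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (invstd.reshape(shape) / m) * (m * gxhat - t1 - xhat * t2)
            else:
                gx = gxhat * invstd.reshape(shape)
            x._accumulate(gx.astype(DTYPE))

        out._backward = backward
        return out
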