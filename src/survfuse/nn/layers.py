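"""Dense layers, batch normalization, dropout and Adam for the fusion networks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, add, matmul, relu, scale

__all__ = ["Linear", "BatchNorm1d", "Dropout", "HiddenBlock", "Adam"]


class Linear:
    """Fully connected layer; init mirrors the Kaiming-uniform convention."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, n_out))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.W)
        return add(out, self.b) if self.b is not None else out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm1d:
    """Batch normalization with running statistics for inference."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, width)))
        self.beta = Tensor(np.zeros((1, width)))
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            n = x.data.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        gamma, beta = self.gamma, self.beta
        out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))

        def bw(g):
            gamma.grad += (g * xhat).sum(axis=0, keepdims=True)
            beta.grad += g.sum(axis=0, keepdims=True)
            dxhat = g * gamma.data
            if training:
                n = x.data.shape[0]
                x.grad += (inv / n) * (
                    n * dxhat
                    - dxhat.sum(axis=0)
                    - xhat * (dxhat * xhat).sum(axis=0)
                )
            else:
                x.grad += dxhat * inv

        out._backward = bw
        return out

    def parameters(self):
        return [self.gamma, self.beta]


class Dropout:
    """Inverted feature-level dropout."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.p == 0.0:
            return x
        mask = (rng.uniform(size=x.data.shape) >= self.p) / (1.0 - self.p)
        return scale(x, mask)


class HiddenBlock:
    """Linear -> batch norm -> ReLU -> dropout, the repeated unit of every net."""

    def __init__(self, n_in, n_out, rng, dropout_p):
        self.linear = Linear(n_in, n_out, rng)
        self.bn = BatchNorm1d(n_out)
        self.dropout = Dropout(dropout_p)

    def __call__(self, x, training, rng):
        h = relu(self.bn(self.linear(x), training))
        return self.dropout(h, training, rng)

    def parameters(self):
        return self.linear.parameters() + self.bn.parameters()


class Adam:
    """Adam with L2 weight decay folded into the gradient (coupled decay)."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return [p.data.copy() for p in self.params]

    def load_params(self, snapshot):
        for p, s in zip(self.params, snapshot):
            p.data = s.copy()
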