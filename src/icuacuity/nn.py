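"""Neural network building blocks for the acuity sequence model.

All layers run on the package's own autodiff engine (:mod:`._autograd`).
The central piece is :class:`SSMBlock`, a gated selective state-space
block: an input projection, a causal depthwise convolution, an
input-conditioned diagonal linear recurrence

    h_t = exp(dt_t * A) h_{t-1} + dt_t * B_t x_t,    y_t = C_t h_t + D x_t

with multiplicative (SiLU) gating and a residual output projection. With
``selective=False`` the discretization step and the B/C projections become
input-independent, and with gating, convolution and activation disabled the
block reduces to a linear time-invariant system — the configuration the
contract tests compare against a direct convolution with the implied
impulse response.
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import (
    Tensor,
    causal_depthwise_conv,
    diag_scan,
    diag_scan_sequential,
    take_along_seq,
)

__all__ = [
    "Linear",
    "SSMBlock",
    "Adam",
    "sinusoidal_positional_encoding",
    "topk_pool",
]


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                out[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=np.float64).copy()


def _init_weight(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _init_weight(rng, (d_in, d_out), d_in)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def sinusoidal_positional_encoding(L: int, D: int) -> np.ndarray:
    """Standard parameter-free sinusoidal encoding, shape (L, D).

    Channel 2i holds sin(p / 10000^(2i/D)), channel 2i+1 the cosine.
    """
    pe = np.zeros((L, D))
    position = np.arange(L)[:, None].astype(float)
    div = np.exp(np.arange(0, D, 2) * (-math.log(10000.0) / D))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: pe[:, 1::2].shape[1]])
    return pe


def topk_selection(x_data: np.ndarray, mask: np.ndarray, k: int):
    """Indices and averaging weights of the top-k pooling selection.

    Selects the (at most) k unmasked positions with the largest L2 norm;
    rows with fewer real positions select all of them, fully masked rows
    select nothing (zero weights).
    """
    N, L, D = x_data.shape
    k = min(k, L)
    norms = np.linalg.norm(x_data, axis=2)
    norms = np.where(mask > 0, norms, -np.inf)
    order = np.argsort(-norms, axis=1, kind="stable")[:, :k]
    counts = np.minimum(mask.sum(axis=1), k)
    selected = np.arange(k)[None, :] < counts[:, None]  # (N, k)
    indices = np.where(selected, order, 0)
    weights = selected[:, :, None] / np.maximum(counts, 1)[:, None, None]
    return indices, weights


def pool_with_selection(x: Tensor, indices: np.ndarray, weights: np.ndarray) -> Tensor:
    gathered = take_along_seq(x, indices)  # (N, k, D)
    return (gathered * weights).sum(axis=1)


def topk_pool(x: Tensor, mask: np.ndarray, k: int) -> Tensor:
    """Average the k unmasked positions with the largest L2 norm.

    ``x`` is (N, L, D), ``mask`` is (N, L) with 1 marking real events.
    If a row has fewer than k real positions, all of them are averaged;
    a fully masked row pools to the zero vector. Selection indices are
    treated as constants, so gradients flow only to selected positions.
    """
    indices, weights = topk_selection(x.data, mask, k)
    return pool_with_selection(x, indices, weights)


def fused_selective_scan(
    dt: Tensor, A_mag: Tensor, B: Tensor, u: Tensor, cap: float
) -> Tensor:
    """Differentiable fused selective scan (numba kernels, one memory pass).

    Computes h_l = exp(-min(dt_l A, cap)) h_{l-1} + dt_l u_l B_l with the
    adjoint recurrence in the backward kernel.
    """
    from . import _kernels

    args = (
        np.ascontiguousarray(dt.data),
        np.ascontiguousarray(A_mag.data),
        np.ascontiguousarray(B.data),
        np.ascontiguousarray(u.data),
    )
    h_data = _kernels.scan_fwd(*args, cap)

    def backward(g):
        g_dt, g_A, g_B, g_u = _kernels.scan_bwd(
            *args, h_data, np.ascontiguousarray(g), cap
        )
        if dt.requires_grad:
            dt._accumulate(g_dt)
        if A_mag.requires_grad:
            A_mag._accumulate(g_A)
        if B.requires_grad:
            B._accumulate(g_B)
        if u.requires_grad:
            u._accumulate(g_u)

    return Tensor._make(h_data, (dt, A_mag, B, u), backward)


class SSMBlock(Module):
    """Gated selective state-space block with residual connection."""

    def __init__(
        self,
        d_model: int,
        d_inner: int,
        state_dim: int,
        dt_rank: int,
        conv_kernel: int,
        rng: np.random.Generator,
        *,
        selective: bool = True,
        gated: bool = True,
        use_conv: bool = True,
        use_activation: bool = True,
        scan_chunk: int = 8,
        fused: bool = True,
    ):
        self.selective = selective
        self.gated = gated
        self.use_conv = use_conv
        self.use_activation = use_activation
        self.scan_chunk = scan_chunk
        self.fused = fused
        self.d_inner = d_inner
        self.state_dim = state_dim

        self.in_proj = Linear(d_model, 2 * d_inner, rng)
        self.conv_weight = _init_weight(rng, (conv_kernel, d_inner), conv_kernel)
        self.conv_bias = Tensor(np.zeros(d_inner), requires_grad=True)
        # bias set so softplus(b) spreads initial time steps over [1e-3, 1e-1]
        dt_init = np.exp(
            rng.uniform(math.log(1e-3), math.log(1e-1), size=d_inner)
        )
        self.b_dt = Tensor(np.log(np.expm1(dt_init)), requires_grad=True)
        if selective:
            self.W_dt_down = _init_weight(rng, (d_inner, dt_rank), d_inner)
            self.W_dt_up = _init_weight(rng, (dt_rank, d_inner), dt_rank)
            self.W_B = _init_weight(rng, (d_inner, state_dim), d_inner)
            self.W_C = _init_weight(rng, (d_inner, state_dim), d_inner)
        else:
            # input-independent B/C for the LTI configuration
            self.b_B = Tensor(rng.standard_normal(state_dim) * 0.5, requires_grad=True)
            self.b_C = Tensor(rng.standard_normal(state_dim) * 0.5, requires_grad=True)
        # S4D-style real initialization: A_s = -(1 + s)
        A = np.tile(1.0 + np.arange(state_dim, dtype=float), (d_inner, 1))
        self.A_log = Tensor(np.log(A), requires_grad=True)
        self.D_skip = Tensor(np.ones(d_inner), requires_grad=True)
        self.out_proj = Linear(d_inner, d_model, rng)

    # scan core -----------------------------------------------------------
    #: cap on the per-step log-decay dt*A; exp(-30) per event step is
    #: already total forgetting, and the cap keeps the chunked numpy scan's
    #: running products well inside double-precision range
    LOG_DECAY_CAP = 30.0

    def _ssm(self, u: Tensor, *, sequential: bool = False) -> Tensor:
        N, L, Di = u.shape
        S = self.state_dim
        if self.selective:
            dt = ((u @ self.W_dt_down) @ self.W_dt_up + self.b_dt).softplus()
            B = u @ self.W_B
            C = u @ self.W_C
        else:
            dt = self.b_dt.softplus() * Tensor(np.ones((N, L, Di)))
            B = self.b_B * Tensor(np.ones((N, L, S)))
            C = self.b_C * Tensor(np.ones((N, L, S)))
        A_mag = self.A_log.exp()  # (Di, S), decay rate magnitude
        if sequential:
            h = Tensor(self._states_sequential(dt.data, A_mag.data, B.data, u.data))
        elif self.fused:
            h = fused_selective_scan(dt, A_mag, B, u, self.LOG_DECAY_CAP)
        else:
            h = self._states_numpy(dt, A_mag, B, u, N, L, Di, S)
        y = (h @ C.reshape(N, L, S, 1)).reshape(N, L, Di)
        return y + self.D_skip * u

    def _states_numpy(self, dt, A_mag, B, u, N, L, Di, S) -> Tensor:
        """Differentiable numpy expression-graph scan (reference path)."""
        m = (dt.reshape(N, L, Di, 1) * A_mag).clip_max(self.LOG_DECAY_CAP)
        a = (m * -1.0).exp()
        du = dt * u  # (N, L, Di)
        bu = du.reshape(N, L, Di, 1) @ B.reshape(N, L, 1, S)  # outer product
        h = diag_scan(
            a.reshape(N, L, Di * S), bu.reshape(N, L, Di * S), chunk=self.scan_chunk
        )
        return h.reshape(N, L, Di, S)

    def _states_sequential(self, dt, A_mag, B, u) -> np.ndarray:
        """Plain step-by-step scan (no gradients), the slow oracle."""
        N, L, Di = dt.shape
        a = np.exp(-np.minimum(dt[..., None] * A_mag, self.LOG_DECAY_CAP))
        bu = (dt * u)[..., None] * B[:, :, None, :]
        S = A_mag.shape[1]
        return diag_scan_sequential(
            a.reshape(N, L, Di * S), bu.reshape(N, L, Di * S)
        ).reshape(N, L, Di, S)

    def __call__(self, x: Tensor, *, sequential_scan: bool = False) -> Tensor:
        uz = self.in_proj(x)
        u = uz[:, :, : self.d_inner]
        z = uz[:, :, self.d_inner :]
        if self.use_conv:
            u = causal_depthwise_conv(u, self.conv_weight, self.conv_bias)
        if self.use_activation:
            u = u.silu()
        y = self._ssm(u, sequential=sequential_scan)
        if self.gated:
            y = y * z.silu()
        return x + self.out_proj(y)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
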