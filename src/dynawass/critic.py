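"""Lipschitz critic network for the Wasserstein-1 dual, in pure NumPy.

By Kantorovich-Rubinstein duality, W1(y_i, y_j) is the supremum over
1-Lipschitz f of E_{y_i}[f] - E_{y_j}[f].  The critic approximates the
optimal f with a fully connected net: hidden layers with bias and
leaky-ReLU, and a single linear output node without bias or activation.
The Lipschitz constraint is enforced softly with a gradient penalty
lambda * E[(||grad_x f(x_hat)|| - 1)^2] at random interpolates x_hat
between the two batches.

The penalty requires the gradient of ||grad_x f|| with respect to the
parameters (double backprop).  For a piecewise-linear net the activation
pattern is locally constant, so its parameter-derivative vanishes almost
everywhere and the double-backprop reduces to closed-form products of the
layer matrices with the activation masks held fixed; the formulas below
are exact a.e. and are verified against finite differences in the tests.

Weight init: every layer's weights are uniform with mean 0 and standard
deviation 1/sqrt(k), k the layer's input feature count (a uniform law on
[-sqrt(3/k), sqrt(3/k)]); biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError

__all__ = ["CriticConfig", "Critic", "critic_loss", "AdamState", "adam_step"]

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class CriticConfig:
    """Architecture of the critic network."""

    input_dim: int
    hidden_widths: tuple[int, ...] = (2048, 2048, 2048)
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise PreconditionError("input_dim must be >= 1")
        if not self.hidden_widths or any(w < 1 for w in self.hidden_widths):
            raise PreconditionError("hidden widths must be positive")
        if not 0 < self.leaky_slope < 1:
            raise PreconditionError("leaky_slope must be in (0, 1)")


class Critic:
    """MLP critic f: R^input_dim -> R with parameter-gradient machinery."""

    def __init__(self, config: CriticConfig, seed: int | np.random.Generator):
        self.config = config
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        dims = [config.input_dim, *config.hidden_widths]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for k, n_out in zip(dims[:-1], dims[1:]):
            half = np.sqrt(3.0 / k)  # uniform[-half, half] has std 1/sqrt(k)
            self.weights.append(rng.uniform(-half, half, size=(n_out, k)))
            self.biases.append(np.zeros(n_out))
        half = np.sqrt(3.0 / dims[-1])
        self.w_out = rng.uniform(-half, half, size=dims[-1])

    # -- parameter flattening (optimizer state) ------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.w_out]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        h = len(self.weights)
        self.weights = [np.asarray(p) for p in params[:h]]
        self.biases = [np.asarray(p) for p in params[h : 2 * h]]
        self.w_out = np.asarray(params[2 * h])

    # -- persistence ----------------------------------------------------
    def to_npz(self, path) -> None:
        """Serialize architecture + parameters to a NumPy .npz archive."""
        arrays = {f"w{l}": w for l, w in enumerate(self.weights)}
        arrays |= {f"b{l}": b for l, b in enumerate(self.biases)}
        arrays["w_out"] = self.w_out
        arrays["meta"] = np.asarray(
            [self.config.input_dim, self.config.leaky_slope, len(self.weights)]
        )
        arrays["hidden_widths"] = np.asarray(self.config.hidden_widths)
        np.savez(path, **arrays)

    @classmethod
    def from_npz(cls, path) -> "Critic":
        with np.load(path) as data:
            input_dim = int(data["meta"][0])
            config = CriticConfig(
                input_dim=input_dim,
                hidden_widths=tuple(int(w) for w in data["hidden_widths"]),
                leaky_slope=float(data["meta"][1]),
            )
            critic = cls(config, 0)
            critic.weights = [data[f"w{l}"] for l in range(len(config.hidden_widths))]
            critic.biases = [data[f"b{l}"] for l in range(len(config.hidden_widths))]
            critic.w_out = data["w_out"]
        return critic

    # -- forward --------------------------------------------------------
    def _forward(self, x: np.ndarray):
        """Returns (f, activations, masks): masks are phi'(z) per hidden layer."""
        slope = self.config.leaky_slope
        a = x
        acts = [x]
        masks = []
        for w, b in zip(self.weights, self.biases):
            z = a @ w.T + b
            mask = np.where(z > 0, 1.0, slope)
            a = z * mask
            acts.append(a)
            masks.append(mask)
        return a @ self.w_out, acts, masks

    def forward(self, windows: np.ndarray) -> np.ndarray:
        """Critic values, one scalar per window; accepts (B, n, L, 3) or (B, d)."""
        x = self._flatten(windows)
        return self._forward(x)[0]

    __call__ = forward

    def _flatten(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise PreconditionError(
                f"windows flatten to dimension {x.shape[-1] if x.ndim >= 2 else x.shape}, "
                f"critic expects {self.config.input_dim}"
            )
        return x

    def input_gradient(self, windows: np.ndarray) -> np.ndarray:
        """grad_x f(x) per sample, shape (B, input_dim)."""
        x = self._flatten(windows)
        _, _, masks = self._forward(x)
        s = masks[-1] * self.w_out[None, :]
        for w, mask in zip(self.weights[:0:-1], masks[-2::-1]):
            s = mask * (s @ w)
        return s @ self.weights[0]

    # -- backward -------------------------------------------------------
    def value_param_grads(self, x: np.ndarray, df: np.ndarray, acts, masks) -> list[np.ndarray]:
        """Gradients of sum_b df[b] * f(x_b) w.r.t. all parameters."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grad_out = acts[-1].T @ df
        da = df[:, None] * self.w_out[None, :]
        for l in range(len(self.weights) - 1, -1, -1):
            dz = da * masks[l]
            grads_w[l] = dz.T @ acts[l]
            grads_b[l] = dz.sum(axis=0)
            if l > 0:
                da = dz @ self.weights[l]
        return [*grads_w, *grads_b, grad_out]

    def gradient_penalty_grads(self, x_hat: np.ndarray):
        """Penalty mean((||grad_x f|| - 1)^2) and its parameter gradients.

        Activation masks are held fixed (exact a.e. for leaky-ReLU nets);
        bias gradients of the penalty are identically zero for the same
        reason.
        """
        _, _, masks = self._forward(x_hat)
        B = x_hat.shape[0]
        H = len(self.weights)
        # backward sweep: s_l per sample
        s_list = [None] * H
        s = masks[-1] * self.w_out[None, :]
        s_list[H - 1] = s
        for l in range(H - 2, -1, -1):
            s = masks[l] * (s @ self.weights[l + 1])
            s_list[l] = s
        g = s_list[0] @ self.weights[0]  # (B, d) input gradients
        norms = np.sqrt((g**2).sum(axis=1))
        penalty = float(((norms - 1.0) ** 2).mean())
        # dp/dg per sample
        u = (2.0 / B) * ((norms - 1.0) / np.maximum(norms, _NORM_EPS))[:, None] * g
        # forward sweep with u: v_l = D_l W_l v_{l-1}
        v_prev = u
        v_list = []
        for l in range(H):
            v = masks[l] * (v_prev @ self.weights[l].T)
            v_list.append(v)
            v_prev = v
        grads_w = [s_list[l].T @ (u if l == 0 else v_list[l - 1]) for l in range(H)]
        grads_b = [np.zeros_like(b) for b in self.biases]
        grad_out = v_list[-1].sum(axis=0)
        return penalty, [*grads_w, *grads_b, grad_out]


def critic_loss(
    critic: Critic,
    batch_i: np.ndarray,
    batch_j: np.ndarray,
    gp_coefficient: float,
    rng: np.random.Generator,
    with_grads: bool = True,
):
    """WGAN-style critic loss and its parameter gradients.

    loss = mean f(batch_j) - mean f(batch_i)
           + lambda * mean_over_interpolates (||grad_x f(x_hat)|| - 1)^2

    with x_hat = eps * x_i + (1 - eps) * x_j, eps ~ U(0,1) per pair.
    Minimizing the loss maximizes the dual gap E_i[f] - E_j[f], whose value
    is returned as ``gap``.
    """
    xi = critic._flatten(batch_i)
    xj = critic._flatten(batch_j)
    if xi.shape[0] == 0 or xj.shape[0] == 0:
        raise PreconditionError("batches must be non-empty")
    if xi.shape[1] != xj.shape[1]:
        raise PreconditionError("batch window shapes differ between systems")

    x = np.concatenate([xi, xj], axis=0)
    f, acts, masks = critic._forward(x)
    bi, bj = xi.shape[0], xj.shape[0]
    gap = float(f[:bi].mean() - f[bi:].mean())
    loss = -gap

    grads = None
    if with_grads:
        df = np.concatenate([np.full(bi, -1.0 / bi), np.full(bj, 1.0 / bj)])
        grads = critic.value_param_grads(x, df, acts, masks)

    if gp_coefficient > 0:
        m = min(bi, bj)
        eps = rng.uniform(size=(m, 1))
        x_hat = eps * xi[:m] + (1.0 - eps) * xj[:m]
        if with_grads:
            penalty, gp_grads = critic.gradient_penalty_grads(x_hat)
            for g_tot, g_pen in zip(grads, gp_grads):
                g_tot += gp_coefficient * g_pen
        else:
            g = critic.input_gradient(x_hat)
            norms = np.sqrt((g**2).sum(axis=1))
            penalty = float(((norms - 1.0) ** 2).mean())
        loss += gp_coefficient * penalty

    return (loss, gap, grads) if with_grads else (loss, gap)


@dataclass
class AdamState:
    """First/second-moment accumulators for Adam."""

    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)
    t: int = 0

    @classmethod
    def for_parameters(cls, params: list[np.ndarray]) -> "AdamState":
        return cls(m=[np.zeros_like(p) for p in params], v=[np.zeros_like(p) for p in params])


def adam_step(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: AdamState,
    learning_rate: float,
    beta1: float,
    beta2: float,
    eps: float = 1e-8,
) -> None:
    """One in-place Adam update with bias correction."""
    state.t += 1
    b1t = 1.0 - beta1**state.t
    b2t = 1.0 - beta2**state.t
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m *= beta1
        m += (1.0 - beta1) * g
        v *= beta2
        v += (1.0 - beta2) * g * g
        p -= learning_rate * (m / b1t) / (np.sqrt(v / b2t) + eps)
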