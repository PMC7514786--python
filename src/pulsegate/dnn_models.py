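"""The two pulse-detection network architectures.

S1 is a fully convolutional network: λ blocks of (valid 1-D convolution →
ReLU → max-pool K=2 → dropout), a global max pooling that reduces the M
channel maps to an M-element feature vector v_D1, and a single sigmoid
unit.  S2 replaces the global max pooling with a bidirectional GRU whose
final forward/backward hidden states are concatenated into a 2ϑ-element
vector v_D2, followed by dropout and the sigmoid unit.

Everything is implemented directly in numpy — forward passes, exact
gradients, dropout and the max-norm weight constraint — because these
small architectures (about 1.4k and 4.8k trainable parameters at their
reference configurations) are the object of study, and a from-scratch
implementation keeps every operation inspectable and testable against
loop-based oracles.

Conventions that pin down the parameter accounting:
  * convolutions carry one bias per output kernel;
  * each GRU gate has a single bias vector (no separate input/recurrent
    biases);
  * the dense output unit is a weight vector plus one scalar bias.
With these conventions S1{λ=4, M=8, L=7} has 1441 trainable parameters and
S2{λ=2, M=24, L=6, ϑ=6} has 4777.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "S1Config", "S2Config", "Prediction", "GruParams", "ConfigurationError",
    "conv_layer_forward", "max_pool", "global_max_pool", "gru_forward",
    "bgru_forward", "dense_sigmoid", "build_s1", "build_s2",
    "count_parameters", "s1_param_count", "s2_param_count", "predict",
    "min_input_length",
]

POOL_SIZE = 2          # max-pool window, non-overlapping
MAX_NORM_GAMMA = 3.5   # ||w|| bound on constrained kernels
RECURRENT_DROPOUT = 0.15


class ConfigurationError(ValueError):
    """Architecture cannot be built (e.g. signal too short for λ blocks)."""


@dataclass(frozen=True)
class S1Config:
    """Hyper-parameters of the fully convolutional architecture."""

    n_blocks: int          # λ
    n_kernels: int         # M
    kernel_len: int        # L
    dropout: float         # α

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_kernels < 1 or self.kernel_len < 1:
            raise ValueError("n_blocks, n_kernels and kernel_len must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class S2Config(S1Config):
    """S1 hyper-parameters plus the GRU width ϑ (units per direction)."""

    gru_units: int = 4     # ϑ

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.gru_units < 1:
            raise ValueError("gru_units must be >= 1")


@dataclass(frozen=True)
class Prediction:
    """Classifier output: PR likelihood, hard label, optional uncertainty."""

    p_pr: float
    label: str
    uncertainty: float | None = None


# ---------------------------------------------------------------------------
# Functional forward operations (single instance; the layer classes below
# use the batched equivalents).
# ---------------------------------------------------------------------------

def conv_layer_forward(x: np.ndarray, weights: np.ndarray,
                       biases: np.ndarray) -> np.ndarray:
    """Valid (no-padding) temporal cross-correlation + ReLU.

    ``x`` is (C, N_in), ``weights`` is (M, C, L), ``biases`` is (M,).
    Returns (M, N_in - L + 1): the first L - 1 lags are discarded.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    W = np.asarray(weights, dtype=float)
    b = np.asarray(biases, dtype=float)
    M, C, L = W.shape
    if x.shape[0] != C:
        raise ValueError(f"input has {x.shape[0]} channels, weights expect {C}")
    if x.shape[1] < L:
        raise ValueError(f"input length {x.shape[1]} < kernel length {L}")
    win = sliding_window_view(x, L, axis=1)              # (C, Nout, L)
    pre = np.einsum("cnl,mcl->mn", win, W) + b[:, None]
    return np.maximum(pre, 0.0)


def max_pool(x: np.ndarray, pool_size: int = POOL_SIZE) -> np.ndarray:
    """Per-channel max over non-overlapping windows; remainder discarded."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    if n < pool_size:
        raise ValueError(f"time axis {n} shorter than pool size {pool_size}")
    n_out = n // pool_size
    return x[..., : n_out * pool_size].reshape(*x.shape[:-1], n_out,
                                               pool_size).max(axis=-1)


def global_max_pool(x: np.ndarray) -> np.ndarray:
    """Temporal max of each channel map: (M, N) -> (M,)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] < 1:
        raise ValueError("empty time axis")
    return x.max(axis=-1)


@dataclass
class GruParams:
    """One GRU direction: gate kernels W_* (ϑ×M), recurrent kernels U_*
    (ϑ×ϑ) and one bias vector per gate."""

    Wz: np.ndarray
    Wr: np.ndarray
    W: np.ndarray
    Uz: np.ndarray
    Ur: np.ndarray
    U: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    b: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gru_forward(inputs: np.ndarray, params: GruParams,
                direction: str = "forward") -> np.ndarray:
    """Run one GRU direction over (M channels × N steps); return h at the
    last step (ϑ values).  The update gate z blends the previous state with
    the candidate, the reset gate r scales the recurrent term inside the
    candidate, and h_0 = 0.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))     # (M, T)
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if x.shape[0] != params.Wz.shape[1]:
        raise ValueError(
            f"input has {x.shape[0]} channels, W expects {params.Wz.shape[1]}")
    if x.shape[1] < 1:
        raise ValueError("need at least one time step")
    seq = x.T if direction == "forward" else x.T[::-1]
    h = np.zeros(params.Wz.shape[0])
    for xn in seq:
        z = _sigmoid(params.Wz @ xn + params.Uz @ h + params.bz)
        r = _sigmoid(params.Wr @ xn + params.Ur @ h + params.br)
        h_cand = np.tanh(params.W @ xn + r * (params.U @ h) + params.b)
        h = z * h + (1.0 - z) * h_cand
    return h


def bgru_forward(inputs: np.ndarray, params_fwd: GruParams,
                 params_bwd: GruParams) -> np.ndarray:
    """Concatenate final forward and backward GRU states: 2ϑ features."""
    return np.concatenate([
        gru_forward(inputs, params_fwd, "forward"),
        gru_forward(inputs, params_bwd, "backward"),
    ])


def dense_sigmoid(v: np.ndarray, w: np.ndarray, b: float) -> float:
    """p_PR = σ(w·v + b), numerically stable, clamped inside (0, 1)."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError(f"dimension mismatch: v has {v.size}, w has {w.size}")
    p = float(_sigmoid(np.array([float(v @ w) + float(b)]))[0])
    return float(np.clip(p, 1e-12, 1.0 - 1e-12))


# ---------------------------------------------------------------------------
# Trainable layers (batched, with exact backward passes)
# ---------------------------------------------------------------------------

class Param:
    """A trainable array with its gradient accumulator.

    ``constrained`` marks kernels subject to the max-norm bound; the
    constraint applies row-wise after reshaping to (n_vectors, -1), i.e.
    per convolution kernel and per recurrent unit.
    """

    def __init__(self, value: np.ndarray, name: str, constrained: bool = False):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.constrained = constrained

    @property
    def size(self) -> int:
        return self.value.size


class ConvBlock:
    """conv (valid, ReLU) -> max-pool (K=2) -> dropout(α)."""

    def __init__(self, in_channels: int, n_kernels: int, kernel_len: int,
                 dropout: float, rng: np.random.Generator, index: int):
        limit = np.sqrt(6.0 / (in_channels * kernel_len + n_kernels * kernel_len))
        self.W = Param(rng.uniform(-limit, limit,
                                   (n_kernels, in_channels, kernel_len)),
                       f"conv{index}.W", constrained=True)
        self.b = Param(np.zeros(n_kernels), f"conv{index}.b")
        self.L = kernel_len
        self.dropout = dropout
        self._cache: dict = {}

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        B, C, N = x.shape
        if N < self.L:
            raise ValueError(f"input length {N} < kernel length {self.L}")
        win = sliding_window_view(x, self.L, axis=2)          # (B,C,Nout,L)
        pre = np.einsum("bcnl,mcl->bmn", win, self.W.value) \
            + self.b.value[None, :, None]
        act = np.maximum(pre, 0.0)
        # max-pool
        n = act.shape[2]
        if n < POOL_SIZE:
            raise ValueError(f"conv output length {n} shorter than pool size")
        n_out = n // POOL_SIZE
        pooled_in = act[:, :, : n_out * POOL_SIZE].reshape(
            B, act.shape[1], n_out, POOL_SIZE)
        arg = pooled_in.argmax(axis=-1)
        pooled = np.take_along_axis(pooled_in, arg[..., None], axis=-1)[..., 0]
        # dropout (inverted)
        if training and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            mask = (rng.random(pooled.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = None
        out = pooled if mask is None else pooled * mask
        self._cache = dict(x=x, win=win, pre=pre, arg=arg,
                           n_pooled=n_out, mask=mask, n_conv=n)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        c = self._cache
        if c["mask"] is not None:
            g = g * c["mask"]
        # un-pool: scatter into the argmax positions
        B, M, n_out = g.shape
        g4 = np.zeros((B, M, n_out, POOL_SIZE))
        np.put_along_axis(g4, c["arg"][..., None], g[..., None], axis=-1)
        g_act = np.zeros((B, M, c["n_conv"]))
        g_act[:, :, : n_out * POOL_SIZE] = g4.reshape(B, M, -1)
        # ReLU
        g_pre = g_act * (c["pre"] > 0.0)
        # conv grads
        self.W.grad += np.einsum("bmn,bcnl->mcl", g_pre, c["win"])
        self.b.grad += g_pre.sum(axis=(0, 2))
        # input grad: full correlation with the flipped kernel
        L = self.L
        gp = np.pad(g_pre, ((0, 0), (0, 0), (L - 1, L - 1)))
        gwin = sliding_window_view(gp, L, axis=2)             # (B,M,N,L)
        w_flip = self.W.value[:, :, ::-1]
        return np.einsum("bmtl,mcl->bct", gwin, w_flip)


class GlobalMaxPool:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        self._arg = x.argmax(axis=-1)                         # (B, M)
        self._n = x.shape[-1]
        return np.take_along_axis(x, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = np.zeros((*g.shape, self._n))
        np.put_along_axis(out, self._arg[..., None], g[..., None], axis=-1)
        return out


class GruDirection:
    """One GRU direction with exact backpropagation through time.

    Recurrent dropout is variational: one mask per sequence applied to the
    previous hidden state wherever it enters a gate (not in the state
    interpolation itself).
    """

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator,
                 tag: str, recurrent_dropout: float = RECURRENT_DROPOUT):
        lim_w = np.sqrt(6.0 / (in_channels + units))
        lim_u = np.sqrt(6.0 / (2 * units))

        def kin(name):
            return Param(rng.uniform(-lim_w, lim_w, (units, in_channels)),
                         f"gru_{tag}.{name}", constrained=True)

        def krec(name):
            return Param(rng.uniform(-lim_u, lim_u, (units, units)),
                         f"gru_{tag}.{name}", constrained=True)

        self.Wz, self.Wr, self.W = kin("Wz"), kin("Wr"), kin("W")
        self.Uz, self.Ur, self.U = krec("Uz"), krec("Ur"), krec("U")
        self.bz = Param(np.zeros(units), f"gru_{tag}.bz")
        self.br = Param(np.zeros(units), f"gru_{tag}.br")
        self.b = Param(np.zeros(units), f"gru_{tag}.b")
        self.units = units
        self.recurrent_dropout = recurrent_dropout

    def params(self) -> list[Param]:
        return [self.Wz, self.Wr, self.W, self.Uz, self.Ur, self.U,
                self.bz, self.br, self.b]

    def as_gru_params(self) -> GruParams:
        return GruParams(self.Wz.value, self.Wr.value, self.W.value,
                         self.Uz.value, self.Ur.value, self.U.value,
                         self.bz.value, self.br.value, self.b.value)

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        """x: (B, T, M) in this direction's time order; returns h_T (B, ϑ)."""
        B, T, _ = x.shape
        if training and self.recurrent_dropout > 0.0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            dmask = (rng.random((B, self.units)) >= self.recurrent_dropout) \
                / (1.0 - self.recurrent_dropout)
        else:
            dmask = np.ones((B, self.units))
        h = np.zeros((B, self.units))
        steps = []
        for n in range(T):
            xn = x[:, n, :]
            hd = h * dmask
            z = _sigmoid(xn @ self.Wz.value.T + hd @ self.Uz.value.T
                         + self.bz.value)
            r = _sigmoid(xn @ self.Wr.value.T + hd @ self.Ur.value.T
                         + self.br.value)
            uh = hd @ self.U.value.T
            hb = np.tanh(xn @ self.W.value.T + r * uh + self.b.value)
            h_new = z * h + (1.0 - z) * hb
            steps.append(dict(xn=xn, h_prev=h, hd=hd, z=z, r=r, uh=uh, hb=hb))
            h = h_new
        self._cache = dict(steps=steps, dmask=dmask, shape=(B, T, x.shape[2]))
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        c = self._cache
        B, T, M = c["shape"]
        dmask = c["dmask"]
        dx = np.zeros((B, T, M))
        for n in range(T - 1, -1, -1):
            s = c["steps"][n]
            dz = dh * (s["h_prev"] - s["hb"])
            dhb = dh * (1.0 - s["z"])
            dh_prev = dh * s["z"]
            da = dhb * (1.0 - s["hb"] ** 2)
            self.W.grad += da.T @ s["xn"]
            self.b.grad += da.sum(axis=0)
            dr = da * s["uh"]
            duh = da * s["r"]
            self.U.grad += duh.T @ s["hd"]
            dhd = duh @ self.U.value
            dar = dr * s["r"] * (1.0 - s["r"])
            self.Wr.grad += dar.T @ s["xn"]
            self.Ur.grad += dar.T @ s["hd"]
            self.br.grad += dar.sum(axis=0)
            dhd += dar @ self.Ur.value
            daz = dz * s["z"] * (1.0 - s["z"])
            self.Wz.grad += daz.T @ s["xn"]
            self.Uz.grad += daz.T @ s["hd"]
            self.bz.grad += daz.sum(axis=0)
            dhd += daz @ self.Uz.value
            dx[:, n, :] = da @ self.W.value + dar @ self.Wr.value \
                + daz @ self.Wz.value
            dh = dh_prev + dhd * dmask
        return dx


class BGru:
    """Bidirectional GRU: concatenated final hidden states (B, 2ϑ)."""

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator):
        self.fwd = GruDirection(in_channels, units, rng, "fwd")
        self.bwd = GruDirection(in_channels, units, rng, "bwd")
        self.units = units

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        # x arrives as (B, M, T) channel maps; the GRU consumes (B, T, M)
        seq = np.swapaxes(x, 1, 2)
        hf = self.fwd.forward(seq, training, rng)
        hb = self.bwd.forward(seq[:, ::-1, :], training, rng)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        k = self.units
        dseq = self.fwd.backward(g[:, :k])
        dseq += self.bwd.backward(g[:, k:])[:, ::-1, :]
        return np.swapaxes(dseq, 1, 2)


class FeatureDropout:
    """Plain dropout on a feature vector (the extra layer before S2's
    classification stage)."""

    def __init__(self, rate: float):
        self.rate = rate

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if training and self.rate > 0.0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class DenseSigmoid:
    """Single sigmoid unit; forward returns the pre-sigmoid score."""

    def __init__(self, in_features: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_features + 1))
        self.w = Param(rng.uniform(-limit, limit, in_features), "dense.w")
        self.b = Param(np.zeros(1), "dense.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if x.shape[1] != self.w.size:
            raise ValueError(
                f"feature dimension {x.shape[1]} != dense weight {self.w.size}")
        self._x = x
        return x @ self.w.value + self.b.value[0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += g @ self._x
        self.b.grad += np.array([g.sum()])
        return np.outer(g, self.w.value)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _block_lengths(input_len: int, n_blocks: int, kernel_len: int) -> list[tuple[int, int]]:
    """(conv_out, pool_out) per block; raises if any layer would be empty."""
    lengths = []
    n = input_len
    for i in range(n_blocks):
        if n < kernel_len:
            raise ConfigurationError(
                f"block {i + 1}: input length {n} < kernel length {kernel_len}")
        n_conv = n - kernel_len + 1
        if n_conv < POOL_SIZE:
            raise ConfigurationError(
                f"block {i + 1}: conv output length {n_conv} < pool size")
        n = n_conv // POOL_SIZE
        lengths.append((n_conv, n))
    return lengths


def min_input_length(config: S1Config) -> int:
    """Smallest input length for which all λ blocks stay non-empty."""
    need = 1
    for _ in range(config.n_blocks):
        need = POOL_SIZE * need + config.kernel_len - 1
    return need


class PulseNet:
    """A built S1 or S2 model: an ordered stack of layers ending in a
    sigmoid unit, accepting (B, N) or (B, 1, N) inputs of any length at or
    above :func:`min_input_length` of its config."""

    def __init__(self, kind: str, config: S1Config, input_len: int,
                 layers: list):
        self.kind = kind
        self.config = config
        self.input_len = input_len
        self.layers = layers
        self.min_len = min_input_length(config)

    def parameters(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[:] = 0.0

    def forward_score(self, X: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Pre-sigmoid scores for a batch; X is (B, N) or (B, 1, N)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim == 2:
            X = X[:, None, :]
        if X.shape[2] < self.min_len:
            raise ValueError(
                f"input length {X.shape[2]} below model minimum {self.min_len}")
        h = X
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        return h

    def predict_proba(self, X: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        p = _sigmoid(self.forward_score(X, training, rng))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def backward(self, dscore: np.ndarray) -> None:
        g = dscore
        for layer in reversed(self.layers):
            g = layer.backward(g)

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]


def build_s1(config: S1Config, input_len: int = 500,
             seed: int = 0) -> PulseNet:
    """Build the fully convolutional architecture for a given input length."""
    _block_lengths(input_len, config.n_blocks, config.kernel_len)
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i in range(config.n_blocks):
        layers.append(ConvBlock(in_ch, config.n_kernels, config.kernel_len,
                                config.dropout, rng, i + 1))
        in_ch = config.n_kernels
    layers.append(GlobalMaxPool())
    layers.append(DenseSigmoid(config.n_kernels, rng))
    return PulseNet("s1", config, input_len, layers)


def build_s2(config: S2Config, input_len: int = 500,
             seed: int = 0) -> PulseNet:
    """Build the convolutional + bidirectional-GRU architecture."""
    _block_lengths(input_len, config.n_blocks, config.kernel_len)
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for i in range(config.n_blocks):
        layers.append(ConvBlock(in_ch, config.n_kernels, config.kernel_len,
                                config.dropout, rng, i + 1))
        in_ch = config.n_kernels
    layers.append(BGru(config.n_kernels, config.gru_units, rng))
    layers.append(FeatureDropout(config.dropout))
    layers.append(DenseSigmoid(2 * config.gru_units, rng))
    return PulseNet("s2", config, input_len, layers)


def count_parameters(model: PulseNet) -> int:
    """Number of trainable scalars, by enumerating the built model."""
    return sum(p.size for p in model.parameters())


def s1_param_count(config: S1Config) -> int:
    """Closed form: M(L+1) for the first block, M(ML+1) for each further
    block, M+1 for the output unit."""
    M, L, lam = config.n_kernels, config.kernel_len, config.n_blocks
    return M * (L + 1) + (lam - 1) * M * (M * L + 1) + (M + 1)


def s2_param_count(config: S2Config) -> int:
    """Closed form: conv blocks + 2 directions × 3 gates × (Mϑ + ϑ² + ϑ)
    + the (2ϑ + 1)-parameter output unit."""
    M, L, lam, th = (config.n_kernels, config.kernel_len, config.n_blocks,
                     config.gru_units)
    conv = M * (L + 1) + (lam - 1) * M * (M * L + 1)
    gru = 2 * 3 * (M * th + th * th + th)
    return conv + gru + (2 * th + 1)


def predict(model: PulseNet, signal) -> Prediction:
    """Deterministic (dropout-off) prediction for one processed signal."""
    s = getattr(signal, "s", signal)
    p = float(model.predict_proba(np.asarray(s, dtype=float)[None, :])[0])
    return Prediction(p_pr=p, label="PR" if p >= 0.5 else "PEA")
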