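"""Training recipe for the pulse-detection networks.

ADAM (lr 0.001, decay rates 0.9/0.999), mini-batches of 8, 75 epochs with
epoch-level shuffling.  Each mini-batch is augmented with fresh zero-mean
Gaussian noise (SD 1e-4) and a per-segment amplitude rescaling of ±2%.
The loss is binary cross-entropy with per-segment weights η chosen so that
every patient contributes equally: a patient with k segments gives each of
them weight 1/k, hence Ση over a patient is 1 and Ση over the dataset is
the number of patients.  After every optimizer step constrained kernels
are projected back onto the max-norm ball ‖w‖ ≤ γ = 3.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulsegate.dnn_models import MAX_NORM_GAMMA, Param, PulseNet, _sigmoid

_P_CLAMP = 1e-7


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    decay_rates: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 8
    epochs: int = 75
    noise_sd: float = 1e-4
    amplitude_jitter: float = 0.02
    max_norm: float = MAX_NORM_GAMMA

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.max_norm) <= 0:
            raise ValueError("learning_rate, batch_size, epochs and max_norm "
                             "must be positive")
        if self.noise_sd < 0 or not 0 <= self.amplitude_jitter < 1:
            raise ValueError("noise_sd must be >= 0 and amplitude_jitter in [0, 1)")


def compute_sample_weights(patient_ids) -> np.ndarray:
    """η_i = 1 / (#segments of that patient); per-patient sums are 1."""
    pids = np.asarray(patient_ids, dtype=object)
    if pids.size == 0:
        raise ValueError("empty dataset")
    _, inverse, counts = np.unique(pids, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def augment(batch: np.ndarray, rng: np.random.Generator,
            noise_sd: float = 1e-4, amplitude_jitter: float = 0.02) -> np.ndarray:
    """Per-segment amplitude rescale a ~ U(1-jitter, 1+jitter) plus white
    noise ε ~ N(0, noise_sd²); fresh draws every call."""
    X = np.asarray(batch, dtype=float)
    a = rng.uniform(1.0 - amplitude_jitter, 1.0 + amplitude_jitter,
                    size=(X.shape[0],) + (1,) * (X.ndim - 1))
    eps = rng.standard_normal(X.shape) * noise_sd if noise_sd > 0 else 0.0
    return X * a + eps


def weighted_bce(p: np.ndarray, y: np.ndarray,
                 weights: np.ndarray | None = None) -> float:
    """Negated patient-equalized binary cross-entropy,
    −Σ η_i [y_i ln p_i + (1−y_i) ln(1−p_i)], with p clamped to
    [1e-7, 1−1e-7]."""
    p = np.clip(np.asarray(p, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    y = np.asarray(y, dtype=float)
    eta = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    return float(-np.sum(eta * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def apply_max_norm(w: np.ndarray, gamma: float = MAX_NORM_GAMMA) -> np.ndarray:
    """Project a weight vector onto the ball ‖w‖ ≤ γ (no-op inside)."""
    w = np.asarray(w, dtype=float)
    norm = float(np.linalg.norm(w))
    if norm > gamma:
        return w * (gamma / norm)
    return w.copy()


def _constrain(param: Param, gamma: float) -> None:
    """Row-wise max-norm on a constrained kernel (one row per output
    kernel / recurrent unit)."""
    flat = param.value.reshape(param.value.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1)
    over = norms > gamma
    if np.any(over):
        flat[over] *= (gamma / norms[over])[:, None]


class Adam:
    """Adaptive moment estimation on a list of Params."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(model: PulseNet, X: np.ndarray, y: np.ndarray, patient_ids,
          config: TrainingConfig = TrainingConfig(), seed: int = 0,
          ) -> list[float]:
    """Train a built model in place; returns the per-epoch loss history.

    ``X`` is (n_segments, N) of preprocessed signals, ``y`` binary labels
    (1 = PR), ``patient_ids`` aligned identifiers.  Reproducible given
    ``seed``: shuffling, augmentation and dropout all draw from one
    generator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if not (X.shape[0] == y.shape[0] == len(patient_ids)):
        raise ValueError("X, y and patient_ids must be aligned")
    eta = compute_sample_weights(patient_ids)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               betas=config.decay_rates)
    n = X.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = augment(X[idx], rng, config.noise_sd, config.amplitude_jitter)
            model.zero_grad()
            score = model.forward_score(xb, training=True, rng=rng)
            p = np.clip(_sigmoid(score), _P_CLAMP, 1.0 - _P_CLAMP)
            epoch_loss += weighted_bce(p, y[idx], eta[idx])
            # d(loss)/d(score) of the clamped weighted BCE
            model.backward(eta[idx] * (p - y[idx]))
            opt.step()
            for prm in model.parameters():
                if prm.constrained:
                    _constrain(prm, config.max_norm)
        history.append(epoch_loss)
    return history
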