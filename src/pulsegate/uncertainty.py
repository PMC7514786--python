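"""Monte-Carlo-dropout uncertainty and selective prediction.

A trained network's likelihood p_PR says nothing about its own confidence.
Repeating the prediction N times with dropout active and fresh white noise
added to the input yields N values of p_PR whose mean is the reported
likelihood and whose variance is the decision uncertainty.  Decisions with
uncertainty above a threshold are withheld (no feedback to the rescuer);
the threshold is calibrated on the training set as the quantile of
training uncertainties at which a target fraction of decisions would
receive feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulsegate.dnn_models import PulseNet
from pulsegate.evaluation import Metrics, patient_weighted_metrics

TEST_NOISE_SD = 1e-4   # same scale as the training augmentation noise


@dataclass(frozen=True)
class UncertaintyPolicy:
    n_repeats: int = 100
    threshold: float = np.inf
    target_feedback_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 < self.target_feedback_fraction <= 1.0:
            raise ValueError("target_feedback_fraction must be in (0, 1]")


def mc_predict_batch(model: PulseNet, X: np.ndarray, n_repeats: int = 100,
                     seed: int = 0, noise_sd: float = TEST_NOISE_SD,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic forward passes for a whole batch.

    Returns (mean p_PR, population variance), each of shape (n_segments,).
    Each repeat draws fresh dropout masks and fresh input white noise;
    amplitude jitter is not applied at test time.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    rng = np.random.default_rng(seed)
    ps = np.empty((n_repeats, X.shape[0]))
    for k in range(n_repeats):
        noisy = X + rng.standard_normal(X.shape) * noise_sd if noise_sd > 0 else X
        ps[k] = model.predict_proba(noisy, training=True, rng=rng)
    return ps.mean(axis=0), ps.var(axis=0)


def mc_predict(model: PulseNet, signal, n_repeats: int = 100, seed: int = 0,
               noise_sd: float = TEST_NOISE_SD) -> tuple[float, float]:
    """Monte-Carlo-dropout prediction for one signal: (mean, variance)."""
    s = getattr(signal, "s", signal)
    mean, var = mc_predict_batch(model, np.asarray(s, dtype=float)[None, :],
                                 n_repeats=n_repeats, seed=seed,
                                 noise_sd=noise_sd)
    return float(mean[0]), float(var[0])


def calibrate_threshold(train_uncertainties, feedback_fraction: float) -> float:
    """Nearest-rank quantile of training uncertainties.

    The threshold is the smallest value u such that at least
    ``feedback_fraction`` of the training decisions have uncertainty <= u;
    decisions at exactly the threshold are retained.
    """
    u = np.sort(np.asarray(train_uncertainties, dtype=float))
    if u.size == 0:
        raise ValueError("empty uncertainty list")
    if not 0.0 < feedback_fraction <= 1.0:
        raise ValueError("feedback_fraction must be in (0, 1]")
    rank = int(np.ceil(feedback_fraction * u.size)) - 1
    return float(u[rank])


@dataclass(frozen=True)
class SelectiveResult:
    """Outcome of uncertainty-gated evaluation."""

    metrics: Metrics | None
    feedback_fraction: float
    n_retained: int
    n_total: int

    @property
    def no_feedback(self) -> bool:
        return self.n_retained == 0


def selective_evaluate(model: PulseNet, X: np.ndarray, y, patient_ids,
                       policy: UncertaintyPolicy, seed: int = 0,
                       ) -> SelectiveResult:
    """Evaluate only the decisions whose uncertainty is within the policy
    threshold; report patient-weighted metrics on the retained decisions
    and the realized feedback fraction."""
    X = np.asarray(X, dtype=float)
    mean, var = mc_predict_batch(model, X, n_repeats=policy.n_repeats,
                                 seed=seed)
    keep = var <= policy.threshold
    n_total = X.shape[0]
    n_keep = int(keep.sum())
    if n_keep == 0:
        return SelectiveResult(metrics=None, feedback_fraction=0.0,
                               n_retained=0, n_total=n_total)
    y = np.asarray(y, dtype=object)
    pids = np.asarray(patient_ids, dtype=object)
    try:
        metrics = patient_weighted_metrics(mean[keep] >= 0.5, y[keep], pids[keep])
    except ValueError:
        # every retained decision is of one class; Se or Sp is undefined
        metrics = None
    return SelectiveResult(metrics=metrics,
                           feedback_fraction=n_keep / n_total,
                           n_retained=n_keep, n_total=n_total)
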