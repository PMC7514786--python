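"""Bayesian hyper-parameter optimization against cross-validated BER.

Training data are split patient-wise into 4 folds (stratified by the
patient's class) and the mean patient-weighted balanced error rate over
the held-out folds is the objective.  Two sequential optimizers are
provided: a tree-structured Parzen estimator (TPE), used for the network
architectures, and Gaussian-process optimization with expected
improvement (GP, on sklearn's GaussianProcessRegressor surrogate), used
for the feature-based baselines.

Search spaces follow the study grid: S1 draws λ∈{1..5}, M∈{8,16,24},
L∈{5..8}, α~U(0.05,0.5); S2 adds ϑ∈{4..8}; RF draws φ~U(0.5,1), ψ∈{1..9};
SVM draws C,γs~U(0.001,10000); KLR draws λl~U(0.0001,0.2), γs~U(0.0001,15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulsegate.baseline_ml import (
    KlrBaseline,
    RandomForestBaseline,
    SvmBaseline,
    extract_feature_matrix,
)
from pulsegate.dnn_models import S1Config, S2Config, build_s1, build_s2
from pulsegate.evaluation import patient_weighted_metrics
from pulsegate.training import TrainingConfig, train


@dataclass(frozen=True)
class Dimension:
    """One search dimension: a discrete choice set or a uniform interval."""

    name: str
    choices: tuple | None = None          # discrete set
    low: float | None = None              # or U(low, high)
    high: float | None = None

    @property
    def is_discrete(self) -> bool:
        return self.choices is not None

    def sample(self, rng: np.random.Generator):
        if self.is_discrete:
            return self.choices[rng.integers(len(self.choices))]
        return float(rng.uniform(self.low, self.high))

    def contains(self, value) -> bool:
        if self.is_discrete:
            return value in self.choices
        return self.low <= value <= self.high


SEARCH_SPACES: dict[str, tuple[Dimension, ...]] = {
    "s1": (
        Dimension("n_blocks", choices=(1, 2, 3, 4, 5)),
        Dimension("n_kernels", choices=(8, 16, 24)),
        Dimension("kernel_len", choices=(5, 6, 7, 8)),
        Dimension("dropout", low=0.05, high=0.5),
    ),
    "s2": (
        Dimension("n_blocks", choices=(1, 2, 3, 4, 5)),
        Dimension("n_kernels", choices=(8, 16, 24)),
        Dimension("kernel_len", choices=(5, 6, 7, 8)),
        Dimension("dropout", low=0.05, high=0.5),
        Dimension("gru_units", choices=(4, 5, 6, 7, 8)),
    ),
    "rf": (
        Dimension("resample_fraction", low=0.5, high=1.0),
        Dimension("features_per_node", choices=tuple(range(1, 10))),
    ),
    "svm": (
        Dimension("C", low=0.001, high=10000.0),
        Dimension("gamma_s", low=0.001, high=10000.0),
    ),
    "klr": (
        Dimension("lambda_l", low=0.0001, high=0.2),
        Dimension("gamma_s", low=0.0001, high=15.0),
    ),
}


@dataclass
class TrialRecord:
    config: dict
    ber: float
    fold_bers: list[float] = field(default_factory=list)
    seed: int = 0


def make_patient_folds(patient_ids, patient_labels, k: int = 4,
                       seed: int = 0) -> dict:
    """Assign each patient to one of ``k`` folds, stratified by class.

    ``patient_ids``/``patient_labels`` are per-segment sequences; every
    segment of a patient lands in that patient's fold.  Fold sizes (in
    patients) differ by at most one, and each class is spread as evenly
    as possible across folds.  Returns {patient_id: fold}.
    """
    pids = np.asarray(patient_ids, dtype=object)
    labs = np.asarray(patient_labels, dtype=object)
    patients: dict = {}
    for pid, lab in zip(pids, labs):
        if pid in patients and patients[pid] != lab:
            raise ValueError(f"patient {pid} has inconsistent labels")
        patients[pid] = lab
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    slot = rng.integers(k)  # rotate so no fold is systematically larger
    for cls in sorted(set(patients.values()), key=str):
        members = [p for p, c in patients.items() if c == cls]
        rng.shuffle(members)
        for p in members:
            assignment[p] = int(slot % k)
            slot += 1
    return assignment


def _split_fold(X, y, pids, assignment, fold):
    in_fold = np.array([assignment[p] == fold for p in pids])
    return ((X[~in_fold], y[~in_fold], pids[~in_fold]),
            (X[in_fold], y[in_fold], pids[in_fold]))


def cv_objective(model_family: str, config: dict, X: np.ndarray,
                 y: np.ndarray, patient_ids, folds: dict, seed: int = 0,
                 epochs: int = 75) -> TrialRecord:
    """Cross-validated balanced error rate (fraction scale) of one config.

    Trains on k−1 folds, evaluates patient-weighted BER on the held-out
    fold, and averages.  For the network families ``epochs`` may be
    reduced below the full training recipe for cheap screening.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pids = np.asarray(patient_ids, dtype=object)
    k = len(set(folds.values()))
    fold_bers = []
    for fold in range(k):
        (Xtr, ytr, ptr), (Xte, yte, pte) = _split_fold(X, y, pids, folds, fold)
        try:
            pred = _fit_predict(model_family, config, Xtr, ytr, ptr, Xte,
                                seed + fold, epochs)
            metrics = patient_weighted_metrics(pred, yte, pte)
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        fold_bers.append(metrics.ber_pct / 100.0)
    return TrialRecord(config=dict(config), ber=float(np.mean(fold_bers)),
                       fold_bers=fold_bers, seed=seed)


def _fit_predict(model_family, config, Xtr, ytr, ptr, Xte, seed, epochs):
    if model_family in ("s1", "s2"):
        if model_family == "s1":
            model = build_s1(S1Config(**config), input_len=Xtr.shape[1],
                             seed=seed)
        else:
            model = build_s2(S2Config(**config), input_len=Xtr.shape[1],
                             seed=seed)
        tc = TrainingConfig(epochs=epochs)
        train(model, Xtr, ytr, ptr, tc, seed=seed)
        return model.predict_proba(Xte) >= 0.5
    Vtr = extract_feature_matrix(Xtr)
    Vte = extract_feature_matrix(Xte)
    if model_family == "rf":
        clf = RandomForestBaseline(**config, seed=seed)
    elif model_family == "svm":
        clf = SvmBaseline(**config)
    elif model_family == "klr":
        clf = KlrBaseline(**config)
    else:
        raise ValueError(f"unknown model family {model_family!r}")
    clf.fit(Vtr, ytr)
    return clf.predict(Vte)


# ---------------------------------------------------------------------------
# Sequential optimizers
# ---------------------------------------------------------------------------

def _tpe_propose(space, history, rng, gamma=0.25, n_candidates=24,
                 n_startup=10):
    """Tree-structured Parzen estimator proposal.

    Observations are split at the γ-quantile of the objective into good
    and bad sets; per dimension, a Parzen density (Gaussian mixture for
    continuous, smoothed categorical for discrete) is fitted to each set,
    and the candidate maximizing the good/bad density ratio is returned.
    """
    if len(history) < n_startup:
        return {d.name: d.sample(rng) for d in space}
    losses = np.array([t.ber for t in history])
    n_good = max(1, int(np.ceil(gamma * len(history))))
    good_idx = np.argsort(losses)[:n_good]
    good = [history[i].config for i in good_idx]
    bad = [history[i].config for i in np.argsort(losses)[n_good:]]

    def density(configs, dim, value):
        vals = [c[dim.name] for c in configs]
        if dim.is_discrete:
            counts = {c: 1.0 for c in dim.choices}        # +1 smoothing
            for v in vals:
                counts[v] += 1.0
            return counts[value] / sum(counts.values())
        arr = np.array(vals, dtype=float)
        bw = max((dim.high - dim.low) / max(len(arr), 1) * 2.0,
                 1e-3 * (dim.high - dim.low))
        return float(np.mean(np.exp(-0.5 * ((value - arr) / bw) ** 2))
                     / (bw * np.sqrt(2 * np.pi))) + 1e-12

    best_cand, best_score = None, -np.inf
    for _ in range(n_candidates):
        cand = {}
        for d in space:
            if d.is_discrete:
                # sample from the good-set categorical
                probs = np.array([density(good, d, c) for c in d.choices])
                cand[d.name] = d.choices[rng.choice(len(d.choices),
                                                    p=probs / probs.sum())]
            else:
                src = good[rng.integers(len(good))][d.name]
                bw = (d.high - d.low) / max(len(good), 1) * 2.0
                cand[d.name] = float(np.clip(src + bw * rng.standard_normal(),
                                             d.low, d.high))
        score = sum(np.log(density(good, d, cand[d.name]))
                    - np.log(density(bad, d, cand[d.name])) for d in space)
        if score > best_score:
            best_cand, best_score = cand, score
    return best_cand


def _gp_propose(space, history, rng, n_candidates=512, n_startup=8):
    """Gaussian-process proposal by expected improvement over random
    candidates; continuous dimensions are scaled to [0, 1] and discrete
    ones one-hot-free index-coded for the surrogate."""
    if len(history) < n_startup:
        return {d.name: d.sample(rng) for d in space}
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    def encode(config):
        row = []
        for d in space:
            if d.is_discrete:
                row.append(d.choices.index(config[d.name]) /
                           max(len(d.choices) - 1, 1))
            else:
                row.append((config[d.name] - d.low) / (d.high - d.low))
        return row

    Xobs = np.array([encode(t.config) for t in history])
    yobs = np.array([t.ber for t in history])
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-6,
                                  normalize_y=True,
                                  random_state=int(rng.integers(2**31)))
    gp.fit(Xobs, yobs)
    cands = [{d.name: d.sample(rng) for d in space} for _ in range(n_candidates)]
    Xc = np.array([encode(c) for c in cands])
    mu, sigma = gp.predict(Xc, return_std=True)
    best = yobs.min()
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
    return cands[int(np.argmax(ei))]


def tune(model_family: str, objective, n_trials: int = 50,
         method: str | None = None, seed: int = 0,
         space: tuple[Dimension, ...] | None = None,
         ) -> tuple[TrialRecord, list[TrialRecord]]:
    """Sequential Bayesian optimization of ``objective(config) -> BER``.

    ``method`` defaults to TPE for the network families and GP for the
    baselines.  Returns (best trial, full history).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if space is None:
        if model_family not in SEARCH_SPACES:
            raise ValueError(f"unknown model family {model_family!r}")
        space = SEARCH_SPACES[model_family]
    for d in space:
        if d.is_discrete:
            if not d.choices:
                raise ValueError(f"dimension {d.name} has no choices")
        elif not (d.low is not None and d.high is not None and d.low < d.high):
            raise ValueError(f"dimension {d.name} has an invalid interval")
    if method is None:
        method = "tpe" if model_family in ("s1", "s2") else "gp"
    if method not in ("tpe", "gp"):
        raise ValueError("method must be 'tpe' or 'gp'")
    propose = _tpe_propose if method == "tpe" else _gp_propose
    rng = np.random.default_rng(seed)
    history: list[TrialRecord] = []
    for _ in range(n_trials):
        config = propose(space, history, rng)
        ber = objective(config)
        rec = ber if isinstance(ber, TrialRecord) else TrialRecord(
            config=dict(config), ber=float(ber), seed=seed)
        history.append(rec)
    best = min(history, key=lambda t: t.ber)
    return best, history
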