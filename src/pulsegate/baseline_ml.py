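"""Hand-crafted-feature baselines: RF, SVM and kernel logistic regression.

Nine features summarize the PR/PEA contrasts of a processed (0.5-30 Hz,
100 Hz) ECG segment in four domains: QRS rate and narrowness, slope
steepness, spectral energy distribution, and signal regularity (fuzzy
entropy and RR-interval variability).  The formulas are standard
re-implementations written for this package — they follow the usual
definitions of each quantity, not any particular published feature set
bit for bit.

The same classifiers also accept network-derived feature vectors (the
global-max-pool features of S1 or the concatenated BGRU states of S2), so
learned and hand-crafted representations can be compared under identical
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths, welch

from pulsegate.dnn_models import PulseNet, _sigmoid

FEATURE_NAMES = [
    "qrs_rate_bpm",        # detected beats per minute
    "qrs_width_ms",        # median width at half prominence
    "slope_steepness",     # mean absolute first difference
    "band_energy_low",     # PSD fraction in 0.5-4 Hz
    "band_energy_mid",     # PSD fraction in 4-12 Hz
    "band_energy_high",    # PSD fraction in 12-30 Hz
    "fuzzy_entropy",       # FuzzEn(m=2, r=0.2*SD)
    "rr_cv",               # coefficient of variation of RR intervals
    "spectral_centroid",   # PSD-weighted mean frequency (Hz)
]

_FS = 100.0


def _detect_peaks(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    if ax.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(ax, height=0.4 * ax.max(),
                          distance=max(1, int(0.24 * _FS)))
    return peaks


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Fuzzy entropy: −ln(φ_{m+1}/φ_m) with Gaussian-like membership
    exp(−(d/r)²) of Chebyshev distances between baseline-removed templates.

    ``r`` defaults to 0.2 × SD of the signal, making the value invariant
    to amplitude scaling.  Returns 0 for flat signals.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd <= 0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        n_tmpl = len(x) - mm
        tmpl = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_tmpl]
        tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
        # pairwise Chebyshev distance, built one embedding dim at a time
        d = np.zeros((n_tmpl, n_tmpl))
        for j in range(mm):
            d = np.maximum(d, np.abs(tmpl[:, j, None] - tmpl[None, :, j]))
        sim = np.exp(-((d / r) ** 2))
        np.fill_diagonal(sim, 0.0)
        return float(sim.sum() / (n_tmpl * (n_tmpl - 1)))

    phi_m, phi_m1 = phi(m), phi(m + 1)
    if phi_m <= 0 or phi_m1 <= 0:
        return 0.0
    return float(np.log(phi_m) - np.log(phi_m1))


def extract_features(signal) -> np.ndarray:
    """Nine-element feature vector for one processed signal (>= 2 s)."""
    x = np.asarray(getattr(signal, "s", signal), dtype=float)
    if x.size < 200:
        raise ValueError("need at least 200 samples (2 s at 100 Hz)")
    feats = np.zeros(9)
    peaks = _detect_peaks(x)
    dur_min = x.size / _FS / 60.0
    feats[0] = len(peaks) / dur_min
    if len(peaks) > 0:
        widths, _, _, _ = peak_widths(np.abs(x), peaks, rel_height=0.5)
        feats[1] = float(np.median(widths)) / _FS * 1000.0
    feats[2] = float(np.abs(np.diff(x)).mean())
    f, pxx = welch(x, fs=_FS, nperseg=min(x.size, 200))
    band = (f >= 0.5) & (f <= 30.0)
    total = pxx[band].sum()
    if total > 0:
        feats[3] = pxx[(f >= 0.5) & (f < 4.0)].sum() / total
        feats[4] = pxx[(f >= 4.0) & (f < 12.0)].sum() / total
        feats[5] = pxx[(f >= 12.0) & (f <= 30.0)].sum() / total
        feats[8] = float((f[band] * pxx[band]).sum() / total)
    feats[6] = fuzzy_entropy(x)
    if len(peaks) >= 3:
        rr = np.diff(peaks) / _FS
        feats[7] = float(rr.std() / rr.mean()) if rr.mean() > 0 else 0.0
    return feats


def extract_feature_matrix(X: np.ndarray) -> np.ndarray:
    """Feature vectors for an (n_segments, N) array of processed signals."""
    return np.stack([extract_features(x) for x in np.asarray(X, dtype=float)])


def dnn_features(model: PulseNet, X: np.ndarray) -> np.ndarray:
    """The network's penultimate representation for each signal: the
    global-max-pool vector v_D1 of S1 (M values) or the concatenated BGRU
    state v_D2 of S2 (2ϑ values)."""
    X = np.asarray(X, dtype=float)
    h = X[:, None, :]
    for layer in model.layers[:-1]:
        if layer.__class__.__name__ == "FeatureDropout":
            continue
        h = layer.forward(h, training=False, rng=None)
    return h


def gaussian_kernel(v: np.ndarray, v_i: np.ndarray, gamma_s: float) -> float:
    """K(v, v_i) = exp(−γs ‖v − v_i‖²)."""
    v = np.asarray(v, dtype=float).ravel()
    v_i = np.asarray(v_i, dtype=float).ravel()
    if v.shape != v_i.shape:
        raise ValueError("dimension mismatch")
    if gamma_s <= 0:
        raise ValueError("gamma_s must be positive")
    return float(np.exp(-gamma_s * np.sum((v - v_i) ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, gamma_s: float) -> np.ndarray:
    d2 = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-gamma_s * np.maximum(d2, 0.0))


def _as_binary_labels(y) -> np.ndarray:
    arr = np.asarray(y, dtype=object).ravel()
    out = np.empty(arr.size, dtype=int)
    for i, v in enumerate(arr):
        out[i] = (1 if v == "PR" else 0) if isinstance(v, str) else int(round(float(v)))
    return out


@dataclass
class SvmBaseline:
    """Soft-margin Gaussian-kernel SVM; prediction by the sign of the
    kernel expansion b + Σ w_i K(v, v_i)."""

    C: float = 1.0
    gamma_s: float = 1.0

    def fit(self, V: np.ndarray, y) -> "SvmBaseline":
        from sklearn.svm import SVC

        yb = _as_binary_labels(y)
        if len(np.unique(yb)) < 2:
            raise ValueError("training set must contain both classes")
        self._clf = SVC(C=self.C, gamma=self.gamma_s, kernel="rbf")
        self._clf.fit(np.asarray(V, dtype=float), yb)
        return self

    def decision_value(self, V: np.ndarray) -> np.ndarray:
        return self._clf.decision_function(np.asarray(V, dtype=float))

    def predict(self, V: np.ndarray) -> np.ndarray:
        return np.where(self.decision_value(V) > 0, "PR", "PEA")


@dataclass
class KlrBaseline:
    """Kernel logistic regression, fit by iteratively reweighted least
    squares on the kernel expansion with ridge penalty λl.

    p(PR|v) = σ(b + Σ α_i K(v, v_i)); label by the sign of the expansion.
    """

    lambda_l: float = 0.01
    gamma_s: float = 1.0
    tol: float = 1e-8
    max_iter: int = 100

    def fit(self, V: np.ndarray, y) -> "KlrBaseline":
        V = np.asarray(V, dtype=float)
        yb = _as_binary_labels(y).astype(float)
        if len(np.unique(yb)) < 2:
            raise ValueError("training set must contain both classes")
        n = V.shape[0]
        K = _kernel_matrix(V, V, self.gamma_s)
        design = np.hstack([K, np.ones((n, 1))])
        beta = np.zeros(n + 1)
        penalty = self.lambda_l * np.eye(n + 1)
        penalty[-1, -1] = 0.0                 # intercept unpenalized
        for _ in range(self.max_iter):
            f = design @ beta
            p = np.clip(_sigmoid(f), 1e-10, 1 - 1e-10)
            w = p * (1.0 - p)
            z = f + (yb - p) / w
            wd = design * w[:, None]
            beta_new = np.linalg.solve(design.T @ wd + penalty, wd.T @ z)
            if np.max(np.abs(beta_new - beta)) < self.tol:
                beta = beta_new
                break
            beta = beta_new
        self._V = V
        self._alpha = beta[:-1]
        self._b = float(beta[-1])
        return self

    def decision_value(self, V: np.ndarray) -> np.ndarray:
        K = _kernel_matrix(np.asarray(V, dtype=float), self._V, self.gamma_s)
        return K @ self._alpha + self._b

    def predict_proba(self, V: np.ndarray) -> np.ndarray:
        return np.clip(_sigmoid(self.decision_value(V)), 1e-12, 1 - 1e-12)

    def predict(self, V: np.ndarray) -> np.ndarray:
        return np.where(self.decision_value(V) > 0, "PR", "PEA")


@dataclass
class RandomForestBaseline:
    """Random forest of 300 trees; each tree sees a with-replacement
    resample of fraction φ of the data and draws ψ candidate features at
    each node; decision by majority vote."""

    resample_fraction: float = 0.75   # φ
    features_per_node: int = 3        # ψ
    n_trees: int = 300
    seed: int = 0

    def fit(self, V: np.ndarray, y) -> "RandomForestBaseline":
        from sklearn.ensemble import RandomForestClassifier

        V = np.asarray(V, dtype=float)
        if self.features_per_node > V.shape[1]:
            raise ValueError(
                f"features_per_node {self.features_per_node} exceeds "
                f"feature dimension {V.shape[1]}")
        yb = _as_binary_labels(y)
        self._clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.features_per_node,
            max_samples=None if self.resample_fraction >= 1.0
            else self.resample_fraction,
            bootstrap=True, min_samples_leaf=1, random_state=self.seed)
        self._clf.fit(V, yb)
        return self

    def predict(self, V: np.ndarray) -> np.ndarray:
        yb = self._clf.predict(np.asarray(V, dtype=float))
        return np.where(yb == 1, "PR", "PEA")


@dataclass
class BaselinePipeline:
    """Feature extraction + classifier, operating directly on processed
    signals (used by the duration sweep)."""

    classifier: object

    def fit_signals(self, X: np.ndarray, y) -> "BaselinePipeline":
        self.classifier.fit(extract_feature_matrix(X), y)
        return self

    def predict_signals(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(extract_feature_matrix(X))
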