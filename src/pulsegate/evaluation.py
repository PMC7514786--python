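"""Patient-weighted performance metrics and the segment-duration sweep.

Sensitivity (Se) is the probability of correctly identifying a
pulse-generating rhythm, specificity (Sp) of correctly identifying
pulseless electrical activity, balanced accuracy BAC = (Se + Sp)/2 and
balanced error rate BER = 1 − BAC.  Because patients contribute different
numbers of segments, every patient is weighted equally: Se is the mean
over PR-bearing patients of that patient's fraction of correctly
classified PR segments, and Sp the analogue over PEA-bearing patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Metrics:
    """Se/Sp/BAC/BER in percent."""

    se_pct: float
    sp_pct: float

    @property
    def bac_pct(self) -> float:
        return (self.se_pct + self.sp_pct) / 2.0

    @property
    def ber_pct(self) -> float:
        return 100.0 - self.bac_pct

    def __str__(self) -> str:
        return (f"Se={self.se_pct:.1f}% Sp={self.sp_pct:.1f}% "
                f"BAC={self.bac_pct:.1f}% BER={self.ber_pct:.1f}%")


def patient_weighted_metrics(predictions, labels, patient_ids) -> Metrics:
    """Compute patient-equalized Se/Sp from hard labels.

    ``predictions`` and ``labels`` are sequences of "PR"/"PEA" (or binary
    with 1 = PR); patients lacking a class simply do not contribute to that
    class's average.
    """
    pred = _as_binary(predictions)
    truth = _as_binary(labels)
    pids = np.asarray(patient_ids, dtype=object)
    if not (pred.size == truth.size == pids.size):
        raise ValueError("predictions, labels and patient_ids must be aligned")
    if pred.size == 0:
        raise ValueError("empty evaluation set")

    se_per_patient, sp_per_patient = [], []
    for pid in dict.fromkeys(pids):          # preserve first-seen order
        mask = pids == pid
        pr = mask & (truth == 1)
        pea = mask & (truth == 0)
        if pr.any():
            se_per_patient.append(float((pred[pr] == 1).mean()))
        if pea.any():
            sp_per_patient.append(float((pred[pea] == 0).mean()))
    if not se_per_patient:
        raise ValueError("no PR segments: sensitivity undefined")
    if not sp_per_patient:
        raise ValueError("no PEA segments: specificity undefined")
    return Metrics(se_pct=100.0 * float(np.mean(se_per_patient)),
                   sp_pct=100.0 * float(np.mean(sp_per_patient)))


def _as_binary(values) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    out = np.empty(arr.size, dtype=int)
    for i, v in enumerate(arr.ravel()):
        if isinstance(v, str):
            out[i] = 1 if v == "PR" else 0
        else:
            out[i] = 1 if float(v) >= 0.5 else 0
    return out


def evaluate_model(model, X: np.ndarray, y, patient_ids) -> Metrics:
    """Dropout-off evaluation of a trained network on preprocessed signals."""
    p = model.predict_proba(np.asarray(X, dtype=float))
    return patient_weighted_metrics(p >= 0.5, y, patient_ids)


def duration_sweep(models: dict, X: np.ndarray, y, patient_ids,
                   durations=(2.0, 3.0, 4.0, 5.0)) -> dict:
    """BAC per (model, duration) for models trained on 5-s inputs.

    Signals are truncated to the FIRST seconds of the segment; a model
    whose minimum input length exceeds the truncated length gets None.
    Returns {model_name: {duration: bac_pct or None}}.
    """
    X = np.asarray(X, dtype=float)
    out: dict = {}
    for name, model in models.items():
        out[name] = {}
        for dur in durations:
            n = int(np.floor(dur * 100.0))
            if n > X.shape[1]:
                raise ValueError(f"duration {dur}s exceeds signal length")
            if hasattr(model, "min_len") and n < model.min_len:
                out[name][dur] = None
                continue
            Xd = X[:, :n]
            if hasattr(model, "predict_proba") and hasattr(model, "forward_score"):
                p = model.predict_proba(Xd)
                pred = p >= 0.5
            else:
                # baseline pipeline object with its own predict on signals
                pred = model.predict_signals(Xd)
            out[name][dur] = patient_weighted_metrics(
                pred, y, patient_ids).bac_pct
    return out


def feature_auc(feature_values, labels) -> float:
    """Area under the ROC curve of a single scalar feature (1 = PR),
    orientation-corrected so an anti-correlated feature still scores
    above 0.5."""
    from sklearn.metrics import roc_auc_score

    y = _as_binary(labels)
    auc = float(roc_auc_score(y, np.asarray(feature_values, dtype=float)))
    return max(auc, 1.0 - auc)
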