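"""Front-end conditioning of raw ECG segments.

Raw 250-Hz segments are band-pass filtered to the typical AED bandwidth
(0.5-30 Hz) and downsampled to 100 Hz, so a 5-s segment becomes the
N = 500-sample input s[n] of the classifiers.  The filter is a 4th-order
Butterworth applied forward-backward (zero phase), which leaves QRS
morphology undistorted; resampling uses polyphase rational resampling
(up 2, down 5) with its built-in anti-aliasing filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, resample_poly

from pulsegate.synthetic import Dataset, EcgSegment

TARGET_FS = 100.0


@dataclass(frozen=True)
class ProcessedSignal:
    """Band-limited ECG at 100 Hz, the network input s[n]."""

    s: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.s)

    @property
    def fs(self) -> float:
        return TARGET_FS


def bandpass(samples: np.ndarray, fs: float = 250.0,
             low_hz: float = 0.5, high_hz: float = 30.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass.

    Output has the same length as the input.  Band edges must satisfy
    0 < low < high < fs/2.
    """
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {fs / 2}")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    sos = butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def resample_100hz(samples: np.ndarray, fs: float = 250.0) -> ProcessedSignal:
    """Resample a 250-Hz sequence to 100 Hz (polyphase, up 2 / down 5)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if abs(fs - 250.0) > 1e-9:
        raise ValueError("resample_100hz expects 250 Hz input")
    return ProcessedSignal(s=resample_poly(x, 2, 5))


def truncate(signal: ProcessedSignal, seconds: float) -> ProcessedSignal:
    """Keep the first ``seconds`` of a processed signal."""
    n = int(np.floor(seconds * TARGET_FS))
    if n > signal.n_samples:
        raise ValueError(
            f"cannot truncate to {seconds} s: signal has {signal.n_samples} samples")
    if n < 1:
        raise ValueError("truncation must keep at least one sample")
    return ProcessedSignal(s=signal.s[:n])


def preprocess(segment: EcgSegment, low_hz: float = 0.5,
               high_hz: float = 30.0) -> ProcessedSignal:
    """Full front end: band-pass at 250 Hz, then downsample to 100 Hz."""
    return resample_100hz(bandpass(segment.samples, fs=segment.fs,
                                   low_hz=low_hz, high_hz=high_hz),
                          fs=segment.fs)


def dataset_to_arrays(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess a whole dataset into aligned arrays.

    Returns ``(X, y, patient_ids)`` with ``X`` of shape (n_segments, 500),
    ``y`` binary (1 = PR) and ``patient_ids`` an object array.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    X = np.stack([preprocess(seg).s for seg in dataset.segments])
    y = np.array([1.0 if seg.label == "PR" else 0.0 for seg in dataset.segments])
    pids = np.array([seg.patient_id for seg in dataset.segments], dtype=object)
    return X, y, pids
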