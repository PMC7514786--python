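"""Synthetic PR/PEA ECG generator.

Emulates the structure of out-of-hospital cardiac-arrest ECG collections:
patients contribute variable numbers of 5-s single-lead segments at 250 Hz,
every segment of a patient carries the same rhythm label, and the two
classes differ statistically — pulse-generating rhythms (PR) beat faster,
with narrower QRS complexes and less rate variability, than pulseless
electrical activity (PEA), whose slow wide complexes are also more variable
from segment to segment within a patient.

The waveform model is deliberately minimal: a train of Gaussian-shaped QRS
pulses at jittered RR intervals, occasional wider ectopic beats, slow
sinusoidal baseline wander and additive white noise.  No P/T-wave dynamics
are modelled; see docs/methods.md for what this does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PR = "PR"
PEA = "PEA"

FS_HZ = 250
DURATION_S = 5.0
SEGMENT_LEN = int(round(FS_HZ * DURATION_S))  # 1250

# Fraction of the nominal amplitude given to the QRS peak vs. baseline wander;
# they sum to <= 1 so the clean signal never exceeds amplitude_mv.
_QRS_AMPL_FRAC = 0.92
_WANDER_AMPL_FRAC = 0.05


@dataclass(frozen=True)
class RhythmParams:
    """Per-patient rhythm parameters.

    heart_rate_bpm : mean heart rate (beats per minute), > 0
    rate_cv        : coefficient of variation of RR intervals, >= 0
    qrs_width_ms   : full width of the Gaussian QRS pulse (4 sigma), > 0
    ectopy_prob    : probability that a beat is ectopic (wider, inverted)
    amplitude_mv   : nominal peak amplitude of the clean signal in mV
    noise_sd_mv    : white-noise standard deviation in mV
    """

    rhythm_class: str
    heart_rate_bpm: float
    rate_cv: float
    qrs_width_ms: float
    ectopy_prob: float = 0.0
    amplitude_mv: float = 1.0
    noise_sd_mv: float = 0.02

    def __post_init__(self) -> None:
        if self.rhythm_class not in (PR, PEA):
            raise ValueError(f"rhythm_class must be PR or PEA, got {self.rhythm_class!r}")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be nonnegative")
        if self.qrs_width_ms <= 0:
            raise ValueError("qrs_width_ms must be positive")
        if not 0.0 <= self.ectopy_prob <= 1.0:
            raise ValueError("ectopy_prob must be in [0, 1]")
        if self.amplitude_mv <= 0:
            raise ValueError("amplitude_mv must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be nonnegative")


def pr_defaults(**overrides) -> RhythmParams:
    """A typical pulse-generating rhythm: fast, narrow, regular."""
    kw = dict(rhythm_class=PR, heart_rate_bpm=95.0, rate_cv=0.03,
              qrs_width_ms=80.0, ectopy_prob=0.02)
    kw.update(overrides)
    return RhythmParams(**kw)


def pea_defaults(**overrides) -> RhythmParams:
    """A typical pulseless electrical activity rhythm: slow, wide, irregular."""
    kw = dict(rhythm_class=PEA, heart_rate_bpm=45.0, rate_cv=0.15,
              qrs_width_ms=170.0, ectopy_prob=0.1)
    kw.update(overrides)
    return RhythmParams(**kw)


@dataclass(frozen=True)
class EcgSegment:
    """A labelled 5-s single-lead ECG segment at 250 Hz (mV)."""

    samples: np.ndarray
    fs: float
    patient_id: str
    label: str
    duration_s: float = DURATION_S

    def __post_init__(self) -> None:
        expected = int(round(self.fs * self.duration_s))
        if len(self.samples) != expected:
            raise ValueError(
                f"segment length {len(self.samples)} != fs*duration = {expected}")


@dataclass
class Dataset:
    """A collection of segments with a patient index."""

    segments: list[EcgSegment] = field(default_factory=list)

    @property
    def patient_index(self) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for i, seg in enumerate(self.segments):
            index.setdefault(seg.patient_id, []).append(i)
        return index

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.segments]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, indices) -> "Dataset":
        return Dataset([self.segments[i] for i in indices])

    def split_by_patients(self, patient_ids) -> tuple["Dataset", "Dataset"]:
        """Patient-wise split: (segments of `patient_ids`, the rest)."""
        chosen = set(patient_ids)
        inside = [i for i, s in enumerate(self.segments) if s.patient_id in chosen]
        outside = [i for i, s in enumerate(self.segments) if s.patient_id not in chosen]
        return self.subset(inside), self.subset(outside)


def _synthesize_segment(params: RhythmParams, rng: np.random.Generator) -> np.ndarray:
    """One clean-beat-train + wander + noise realization, in mV."""
    n = SEGMENT_LEN
    t = np.arange(n) / FS_HZ
    mean_rr = 60.0 / params.heart_rate_bpm

    # Beat times: random phase, then RR intervals with multiplicative jitter.
    # Truncation at 0.3*mean keeps all RR intervals strictly positive even for
    # large rate_cv.
    beat_times = [float(rng.uniform(0.0, mean_rr))]
    while beat_times[-1] < DURATION_S + mean_rr:
        rr = mean_rr * (1.0 + params.rate_cv * rng.standard_normal())
        rr = max(rr, 0.3 * mean_rr)
        beat_times.append(beat_times[-1] + rr)

    qrs_sigma = params.qrs_width_ms / 1000.0 / 4.0  # width = 4 sigma
    peak = _QRS_AMPL_FRAC * params.amplitude_mv
    x = np.zeros(n)
    for bt in beat_times:
        if rng.uniform() < params.ectopy_prob:
            # Ectopic beat: wider, partially inverted, reduced amplitude.
            sig = qrs_sigma * 1.8
            amp = -0.7 * peak
        else:
            sig = qrs_sigma
            amp = peak
        x += amp * np.exp(-0.5 * ((t - bt) / sig) ** 2)

    wander_f = rng.uniform(0.15, 0.35)  # Hz, respiratory-range drift
    wander_phase = rng.uniform(0.0, 2 * np.pi)
    x += _WANDER_AMPL_FRAC * params.amplitude_mv * np.sin(
        2 * np.pi * wander_f * t + wander_phase)

    if params.noise_sd_mv > 0:
        x += params.noise_sd_mv * rng.standard_normal(n)
    return x


def generate_patient(params: RhythmParams, n_segments: int, seed: int,
                     patient_id: str | None = None) -> list[EcgSegment]:
    """Generate ``n_segments`` labelled segments for one synthetic patient.

    Deterministic given ``seed``.  All segments share the patient id and the
    rhythm label of ``params``.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    if patient_id is None:
        patient_id = f"{params.rhythm_class}-{seed}"
    return [
        EcgSegment(samples=_synthesize_segment(params, rng), fs=FS_HZ,
                   patient_id=patient_id, label=params.rhythm_class)
        for _ in range(n_segments)
    ]


def _sample_patient_params(rhythm_class: str, rng: np.random.Generator) -> RhythmParams:
    """Class-conditional priors over per-patient rhythm parameters.

    The numeric ranges are plausible clinical stand-ins chosen so that PR
    stochastically dominates PEA in rate and is dominated in QRS width and
    rate variability; they are not estimates from any clinical dataset.
    """
    if rhythm_class == PR:
        return RhythmParams(
            rhythm_class=PR,
            heart_rate_bpm=float(rng.uniform(70, 130)),
            rate_cv=float(rng.uniform(0.01, 0.05)),
            qrs_width_ms=float(rng.uniform(60, 100)),
            ectopy_prob=float(rng.uniform(0.0, 0.05)),
            amplitude_mv=float(rng.uniform(0.5, 1.5)),
            noise_sd_mv=float(rng.uniform(0.01, 0.05)),
        )
    return RhythmParams(
        rhythm_class=PEA,
        heart_rate_bpm=float(rng.uniform(20, 70)),
        rate_cv=float(rng.uniform(0.08, 0.25)),
        qrs_width_ms=float(rng.uniform(120, 220)),
        ectopy_prob=float(rng.uniform(0.0, 0.2)),
        amplitude_mv=float(rng.uniform(0.5, 1.5)),
        noise_sd_mv=float(rng.uniform(0.01, 0.05)),
    )


def _perturb(params: RhythmParams, rng: np.random.Generator) -> RhythmParams:
    """Per-segment drift of patient-level parameters.

    PEA is more variable than PR, so PEA patients get larger segment-to-segment
    drift of rate and width.
    """
    drift = 0.03 if params.rhythm_class == PR else 0.10
    return RhythmParams(
        rhythm_class=params.rhythm_class,
        heart_rate_bpm=params.heart_rate_bpm * float(1.0 + drift * rng.standard_normal()),
        rate_cv=params.rate_cv,
        qrs_width_ms=params.qrs_width_ms * float(1.0 + drift * rng.standard_normal()),
        ectopy_prob=params.ectopy_prob,
        amplitude_mv=params.amplitude_mv,
        noise_sd_mv=params.noise_sd_mv,
    )


def generate_dataset(n_pr_patients: int, n_pea_patients: int,
                     segments_per_patient_range: tuple[int, int] = (2, 6),
                     seed: int = 0) -> Dataset:
    """Generate a patient-structured dataset from class-conditional priors.

    Each patient draws its own :class:`RhythmParams` from the class prior;
    each of its segments then perturbs those parameters slightly (more for
    PEA) before synthesis.  Segment counts per patient are uniform over
    ``segments_per_patient_range`` (inclusive).
    """
    if n_pr_patients < 0 or n_pea_patients < 0:
        raise ValueError("patient counts must be nonnegative")
    lo, hi = segments_per_patient_range
    if lo < 1 or hi < lo:
        raise ValueError("segments_per_patient_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    segments: list[EcgSegment] = []
    classes = [PR] * n_pr_patients + [PEA] * n_pea_patients
    for k, cls in enumerate(classes):
        params = _sample_patient_params(cls, rng)
        n_seg = int(rng.integers(lo, hi + 1))
        pid = f"{cls.lower()}{k:04d}"
        for _ in range(n_seg):
            seg_params = _perturb(params, rng)
            segments.append(EcgSegment(
                samples=_synthesize_segment(seg_params, rng), fs=FS_HZ,
                patient_id=pid, label=cls))
    return Dataset(segments)


def detect_beats(samples: np.ndarray, fs: float = FS_HZ,
                 min_height_frac: float = 0.4) -> np.ndarray:
    """Simple threshold peak detector, used for sanity checks and features.

    Returns beat sample indices.  Peaks of the absolute signal must exceed
    ``min_height_frac`` of the maximum and be separated by >= 240 ms
    (250 bpm ceiling).
    """
    from scipy.signal import find_peaks

    x = np.abs(np.asarray(samples, dtype=float))
    if x.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(x, height=min_height_frac * x.max(),
                          distance=max(1, int(0.24 * fs)))
    return peaks
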