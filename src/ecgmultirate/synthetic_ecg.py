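"""Synthetic multi-subject, multi-class ECG generation.

Emulates the structure of a four-class arrhythmia beat dataset: single-channel
ECG sampled at 360 Hz, digitised with an 11-bit ADC, organised as 4 beat
classes (N, RBBB, APC, LBBB) x 3 subjects x 170 beats = 2040 instances.
Beats are modelled as a sum of five Gaussian deflections (P, Q, R, S, T); the
bundle-branch-block classes widen the QRS and add a secondary R' notch, and
the atrial-premature class suppresses the P wave and shortens its latency.
Additive noise combines powerline interference (60 Hz), baseline wander
(0.3 Hz) and white Gaussian noise.

This is deliberately a minimal morphological model — one beat per fixed
0.9 s window with a known R-peak location — so that every downstream stage
(windowing, threshold-based QRS selection, denoising, wavelet features,
classification) is testable without an external database download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "WaveParams",
    "SubjectParams",
    "SynthConfig",
    "EcgRecord",
    "make_subject_params",
    "synthesize_beat",
    "synthesize_dataset",
    "quantize_adc",
    "write_record",
]

CLASS_LABELS = ("N", "RBBB", "APC", "LBBB")

#: Hz of the simulated powerline interference / baseline wander.
POWERLINE_HZ = 60.0
BASELINE_HZ = 0.3


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian deflection of the beat template.

    amplitude in mV; width is the Gaussian sigma in seconds; latency is the
    bump centre in seconds relative to the beat centre (the R peak sits at
    latency 0 by convention).
    """

    amplitude: float
    width: float
    latency: float


@dataclass(frozen=True)
class SubjectParams:
    """Morphology and noise parameters of one synthetic subject."""

    class_label: str
    waves: dict[str, WaveParams]  # keys: P, Q, R, S, T and optionally Rp
    rr_interval: float = 0.9  # s, the average cardiac pulse duration
    powerline_mv: float = 0.05
    baseline_mv: float = 0.10
    white_std_mv: float = 0.02

    def __post_init__(self) -> None:
        r = self.waves["R"].amplitude
        if not (r > 0 and r > self.waves["P"].amplitude and r > self.waves["T"].amplitude):
            raise ValueError("R amplitude must be positive and dominate P and T")
        if any(w.width <= 0 for w in self.waves.values()):
            raise ValueError("wave widths must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level generation parameters (defaults give 2040 beats)."""

    n_classes: int = 4
    subjects_per_class: int = 3
    beats_per_subject: int = 170
    fs: float = 360.0
    adc_bits: int = 11
    adc_range_mv: float = 10.0  # full span, i.e. +-5 mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.adc_bits <= 0:
            raise ValueError("fs and adc_bits must be positive")


@dataclass
class EcgRecord:
    """A labelled single-channel ECG trace for one subject."""

    samples: np.ndarray  # mV
    fs: float
    subject_id: str
    class_label: str
    r_peaks: np.ndarray | None = None  # sample indices of true R peaks

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=int)
            if len(self.r_peaks) and (
                np.any(np.diff(self.r_peaks) <= 0)
                or self.r_peaks[0] < 0
                or self.r_peaks[-1] >= len(self.samples)
            ):
                raise ValueError("r_peaks must be strictly increasing and in bounds")


# Class-specific parameter ranges (low, high) drawn uniformly per subject.
# QRS width separates N/APC (narrow) from RBBB/LBBB (wide); the blocks add a
# secondary R' notch on opposite sides of R; APC suppresses P and pulls it
# closer to the QRS.
_COMMON_RANGES = {
    "P": {"amplitude": (0.10, 0.15), "width": (0.022, 0.028), "latency": (-0.19, -0.17)},
    "Q": {"amplitude": (-0.12, -0.08), "width": (0.010, 0.014), "latency": (-0.038, -0.032)},
    "R": {"amplitude": (1.10, 1.50), "width": (0.010, 0.014), "latency": (0.0, 0.0)},
    "S": {"amplitude": (-0.20, -0.12), "width": (0.012, 0.018), "latency": (0.032, 0.038)},
    "T": {"amplitude": (0.20, 0.30), "width": (0.060, 0.080), "latency": (0.20, 0.24)},
}

CLASS_WAVE_RANGES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "N": _COMMON_RANGES,
    "RBBB": {
        **_COMMON_RANGES,
        "R": {"amplitude": (1.10, 1.50), "width": (0.022, 0.028), "latency": (0.0, 0.0)},
        "Rp": {"amplitude": (0.50, 0.70), "width": (0.016, 0.022), "latency": (0.042, 0.050)},
    },
    "APC": {
        **_COMMON_RANGES,
        "P": {"amplitude": (-0.02, 0.02), "width": (0.016, 0.022), "latency": (-0.13, -0.11)},
    },
    "LBBB": {
        **_COMMON_RANGES,
        "R": {"amplitude": (1.10, 1.50), "width": (0.026, 0.034), "latency": (0.0, 0.0)},
        "Rp": {"amplitude": (0.50, 0.70), "width": (0.016, 0.022), "latency": (-0.050, -0.042)},
    },
}

_DEFAULT_NOISE = {"powerline_mv": 0.05, "baseline_mv": 0.10, "white_std_mv": 0.02}


def make_subject_params(
    class_label: str,
    rng: np.random.Generator,
    noise_levels: dict[str, float] | None = None,
) -> SubjectParams:
    """Draw one subject's morphology from the class-specific ranges.

    Deterministic for a given generator state; raises ``ValueError`` for an
    unknown class label.
    """
    if class_label not in CLASS_WAVE_RANGES:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    ranges = CLASS_WAVE_RANGES[class_label]
    waves = {}
    for name, fields_ in ranges.items():
        drawn = {k: float(rng.uniform(*bounds)) for k, bounds in fields_.items()}
        waves[name] = WaveParams(**drawn)
    noise = dict(_DEFAULT_NOISE)
    if noise_levels:
        noise.update(noise_levels)
    return SubjectParams(class_label=class_label, waves=waves, **noise)


def synthesize_beat(
    params: SubjectParams, fs: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one beat of ``round(rr_interval * fs)`` samples.

    The beat is the sum of the subject's Gaussian deflections centred at
    ``rr_interval / 2`` plus powerline, baseline-wander and white noise.
    Noise phases are drawn from ``rng`` (required unless all noise levels
    are zero).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(params.rr_interval * fs))
    t = np.arange(n) / fs
    centre = params.rr_interval / 2.0
    beat = np.zeros(n)
    for wave in params.waves.values():
        beat += wave.amplitude * np.exp(-0.5 * ((t - centre - wave.latency) / wave.width) ** 2)
    noisy = params.powerline_mv or params.baseline_mv or params.white_std_mv
    if noisy:
        if rng is None:
            raise ValueError("rng required when noise levels are non-zero")
        beat += params.powerline_mv * np.sin(
            2 * np.pi * POWERLINE_HZ * t + rng.uniform(0, 2 * np.pi)
        )
        beat += params.baseline_mv * np.sin(
            2 * np.pi * BASELINE_HZ * t + rng.uniform(0, 2 * np.pi)
        )
        beat += rng.normal(0.0, params.white_std_mv, size=n)
    return beat


def r_index_of(params: SubjectParams, fs: float) -> int:
    """Ground-truth R-peak sample index within one beat."""
    centre = params.rr_interval / 2.0 + params.waves["R"].latency
    return int(round(centre * fs))


def quantize_adc(x: np.ndarray, bits: int, vrange: float) -> np.ndarray:
    """Uniform mid-tread quantisation to ``2**bits`` levels over span ``vrange``.

    The grid covers [-vrange/2, vrange/2 - q] where q is one LSB; values
    outside the span clip to the edge codes. Idempotent, and for in-range
    input the error is bounded by half an LSB.
    """
    if bits <= 0:
        raise ValueError("bits must be positive")
    if vrange <= 0:
        raise ValueError("vrange must be positive")
    x = np.asarray(x, dtype=float)
    q = vrange / 2**bits
    codes = np.clip(np.round(x / q), -(2 ** (bits - 1)), 2 ** (bits - 1) - 1)
    return codes * q


def _subject_rng(seed: int, class_label: str, subject_index: int) -> np.random.Generator:
    # stable per-subject stream: spawn key = (class index, subject index)
    ss = np.random.SeedSequence([seed, CLASS_LABELS.index(class_label), subject_index])
    return np.random.default_rng(ss)


def synthesize_dataset(config: SynthConfig = SynthConfig()) -> list[EcgRecord]:
    """Generate one quantised record per subject per class.

    Each record concatenates ``beats_per_subject`` beats (one per 0.9 s
    window) and carries the ground-truth R-peak indices. Bit-identical for
    identical configs.
    """
    records = []
    for class_label in CLASS_LABELS[: config.n_classes]:
        for s in range(config.subjects_per_class):
            rng = _subject_rng(config.seed, class_label, s)
            params = make_subject_params(class_label, rng)
            beat_len = int(round(params.rr_interval * config.fs))
            r_in_beat = r_index_of(params, config.fs)
            beats = [
                synthesize_beat(params, config.fs, rng)
                for _ in range(config.beats_per_subject)
            ]
            samples = quantize_adc(
                np.concatenate(beats), config.adc_bits, config.adc_range_mv
            )
            r_peaks = np.arange(config.beats_per_subject) * beat_len + r_in_beat
            records.append(
                EcgRecord(
                    samples=samples,
                    fs=config.fs,
                    subject_id=f"{class_label}-s{s}",
                    class_label=class_label,
                    r_peaks=r_peaks,
                )
            )
    return records


def write_record(record: EcgRecord, path: str | Path) -> None:
    """Write a record as CSV (sample_index, amplitude_mV) + JSON sidecar.

    The sidecar (``<path>.json``) stores fs, labels and R-peak indices;
    :func:`ecgmultirate.io_cli.read_record` round-trips it bit-exactly.
    """
    path = Path(path)
    idx = np.arange(len(record.samples))
    with open(path, "w") as fh:
        fh.write("sample_index,amplitude_mV\n")
        for i, v in zip(idx, record.samples):
            fh.write(f"{i},{float(v)!r}\n")
    sidecar = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "class_label": record.class_label,
        "r_peaks": None if record.r_peaks is None else record.r_peaks.tolist(),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)
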