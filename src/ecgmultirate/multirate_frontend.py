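"""Multirate ECG front end: windowing, decimation, QRS selection, denoising.

The chain operates on a 360 Hz single-channel trace:

1. rectangular windowing into fixed 0.9 s windows (Nr = 324 samples);
2. first decimation by D1 = 2 (valid without anti-alias filtering because
   D <= fs / (2 * fmax) = 360 / 120 = 3 for the 60 Hz-bandlimited input),
   giving 162-sample windows at 180 Hz;
3. threshold-based QRS selection: on the first upward crossing of a
   calibrated threshold alpha (50% of the mean R amplitude) the R peak is
   located as the maximum on the leading edge, and a 60-sample excerpt
   centred on R is extracted (segment length 333 ms at 180 Hz); windows
   that never cross alpha are ignored;
4. equiripple (Parks-McClellan) linear-phase FIR low-pass denoising at
   180 Hz with a 40 Hz cut-off and 45 taps, group delay compensated;
5. second decimation by D2 = 2 (bound 180 / 80 = 2.25), giving N = 30
   samples per segment at 90 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_ecg import EcgRecord

__all__ = [
    "WindowedSegment",
    "QrsSegment",
    "DenoisedSegment",
    "FilterSpec",
    "FrontendConfig",
    "window_signal",
    "check_decimation_valid",
    "decimate",
    "calibrate_alpha",
    "select_qrs",
    "design_denoise_filter",
    "apply_fir",
    "process_record",
    "process_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowedSegment:
    """One fixed-length window of the raw trace (Nr samples at 360 Hz)."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    class_label: str = ""


@dataclass
class QrsSegment:
    """60-sample QRS-centred excerpt at 180 Hz; ``r_index`` marks the R peak."""

    samples: np.ndarray
    fs: float
    r_index: int
    subject_id: str = ""
    class_label: str = ""


@dataclass
class DenoisedSegment:
    """Denoised QRS excerpt (60 samples, 180 Hz) and its decimated form (30, 90 Hz)."""

    samples: np.ndarray
    decimated: np.ndarray
    subject_id: str = ""
    class_label: str = ""


@dataclass(frozen=True)
class FilterSpec:
    """A designed linear-phase FIR low-pass filter."""

    taps: np.ndarray
    fs: float
    fc: float
    passband_edge: float
    stopband_edge: float
    weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if not np.allclose(taps, taps[::-1]):
            raise ValueError("taps must be symmetric (linear phase)")
        if not self.fc < self.fs / 2:
            raise ValueError("cut-off must be below the Nyquist rate")

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    @property
    def group_delay(self) -> int:
        return (self.n_taps - 1) // 2


@dataclass(frozen=True)
class FrontendConfig:
    """Front-end stage parameters; defaults are the chain described above."""

    fs: float = 360.0
    window_s: float = 0.9
    D1: int = 2
    D2: int = 2
    fmax: float = 60.0  # input bandwidth, Hz
    fmaxf: float = 40.0  # post-denoising bandwidth, Hz
    fc: float = 40.0
    stopband_edge: float = 55.0
    n_taps: int = 45
    qrs_len: int = 60
    search_span: int = 15  # samples after the alpha crossing searched for R
    alpha: float | None = None  # mV; None = calibrate from annotations


def window_signal(record: EcgRecord, window_s: float = 0.9) -> list[WindowedSegment]:
    """Chop a record into consecutive non-overlapping rectangular windows.

    Window length is ``round(fs * window_s)`` samples; a trailing remainder
    shorter than one window is dropped. An empty record yields an empty list.
    """
    n_win = record.fs * window_s
    if abs(n_win - round(n_win)) >= 0.5 - 1e-12:
        raise ValueError("fs * window_s must be within 0.5 of an integer")
    n_win = int(round(n_win))
    x = record.samples
    out = []
    for start in range(0, len(x) - n_win + 1, n_win):
        out.append(
            WindowedSegment(
                samples=x[start : start + n_win],
                fs=record.fs,
                subject_id=record.subject_id,
                class_label=record.class_label,
            )
        )
    return out


def check_decimation_valid(fs: float, fmax: float, D: int) -> tuple[bool, float]:
    """Aliasing-safety check for decimation without a prior anti-alias filter.

    Returns ``(valid, bound)`` with ``bound = fs / (2 * fmax)``; decimation by
    D is alias-free for an fmax-bandlimited signal iff ``D <= bound``.
    """
    if fs <= 0 or fmax <= 0:
        raise ValueError("fs and fmax must be positive")
    if not isinstance(D, (int, np.integer)) or D < 1:
        raise ValueError("D must be a positive integer")
    bound = fs / (2.0 * fmax)
    return D <= bound, bound


def decimate(x: np.ndarray, D: int) -> np.ndarray:
    """Keep every D-th sample starting at index 0 (length ceil(len/D))."""
    if not isinstance(D, (int, np.integer)) or D < 1:
        raise ValueError("D must be a positive integer")
    return np.asarray(x)[::D]


def calibrate_alpha(records: list[EcgRecord]) -> float:
    """Threshold alpha = 50% of the mean annotated R-peak amplitude."""
    amps = [
        rec.samples[rec.r_peaks]
        for rec in records
        if rec.r_peaks is not None and len(rec.r_peaks)
    ]
    if not amps:
        raise ValueError("no annotated R peaks available for calibration")
    return 0.5 * float(np.mean(np.concatenate(amps)))


def select_qrs(
    window: WindowedSegment,
    alpha: float,
    qrs_len: int = 60,
    search_span: int = 15,
) -> QrsSegment | None:
    """Threshold-based QRS selection on a decimated (180 Hz) window.

    Finds the first upward crossing of ``alpha``, takes the maximum within
    the following ``search_span`` samples as the R peak, and returns the
    ``qrs_len``-sample excerpt with R as its 30th sample (29 before,
    ``qrs_len - 30`` after), reflect-padding when R sits near a window edge.
    Returns ``None`` when the window never reaches ``alpha``.
    """
    x = np.asarray(window.samples, dtype=float)
    if qrs_len > len(x):
        raise ValueError("qrs_len exceeds the window length")
    above = x >= alpha
    if not above.any():
        return None
    crossing = int(np.argmax(above))  # first sample at/above alpha
    stop = min(crossing + search_span, len(x))
    r = crossing + int(np.argmax(x[crossing:stop]))
    before = (qrs_len - 1) // 2  # 29 samples precede R for qrs_len = 60
    start, end = r - before, r - before + qrs_len
    pad_left = max(0, -start)
    pad_right = max(0, end - len(x))
    seg = x[max(0, start) : min(len(x), end)]
    if pad_left or pad_right:
        seg = np.pad(seg, (pad_left, pad_right), mode="reflect")
    return QrsSegment(
        samples=seg,
        fs=window.fs,
        r_index=before,
        subject_id=window.subject_id,
        class_label=window.class_label,
    )


def design_denoise_filter(
    fs: float = 180.0,
    fc: float = 40.0,
    n_taps: int = 45,
    stopband_edge: float = 55.0,
    weights: tuple[float, float] = (1.0, 1.0),
) -> FilterSpec:
    """Equiripple (Parks-McClellan) linear-phase FIR low-pass design.

    Passband [0, fc], stopband [stopband_edge, fs/2]. The odd default tap
    count gives an integer group delay of 22 samples at 180 Hz.
    """
    if not fc < fs / 2:
        raise ValueError("fc must be below fs/2")
    if not fc < stopband_edge < fs / 2:
        raise ValueError("infeasible band edges: need fc < stopband_edge < fs/2")
    taps = signal.remez(n_taps, [0, fc, stopband_edge, fs / 2], [1, 0], weight=weights, fs=fs)
    return FilterSpec(
        taps=taps,
        fs=fs,
        fc=fc,
        passband_edge=fc,
        stopband_edge=stopband_edge,
        weights=weights,
    )


def apply_fir(segment: QrsSegment, filt: FilterSpec) -> DenoisedSegment:
    """Denoise a QRS segment, compensating the filter group delay.

    The segment is reflect-padded by one group delay on each side, convolved
    with the taps, and the aligned same-length slice extracted, so the R peak
    keeps its position. Raises on a sampling-rate mismatch (the filter and
    signal rates must be coherent).
    """
    if segment.fs != filt.fs:
        raise ValueError(
            f"sampling-rate mismatch: segment at {segment.fs} Hz, filter designed "
            f"for {filt.fs} Hz"
        )
    x = np.asarray(segment.samples, dtype=float)
    gd = filt.group_delay
    ext = np.pad(x, (gd, gd), mode="reflect")
    y = np.convolve(ext, filt.taps)[2 * gd : 2 * gd + len(x)]
    return DenoisedSegment(
        samples=y,
        decimated=decimate(y, 2),
        subject_id=segment.subject_id,
        class_label=segment.class_label,
    )


def process_record(
    record: EcgRecord,
    alpha: float,
    config: FrontendConfig = FrontendConfig(),
    filt: FilterSpec | None = None,
) -> tuple[list[WindowedSegment], list[QrsSegment], list[DenoisedSegment], dict]:
    """Run the full front end on one record.

    Returns the windowed segments, the selected QRS segments, the denoised
    (and twice-decimated) segments, and a stage-count dict.
    """
    fs1 = config.fs / config.D1
    for stage_fs, stage_fmax, D in (
        (config.fs, config.fmax, config.D1),
        (fs1, config.fmaxf, config.D2),
    ):
        valid, bound = check_decimation_valid(stage_fs, stage_fmax, D)
        if not valid:
            raise ValueError(f"decimation by {D} at {stage_fs} Hz violates bound {bound}")
    if filt is None:
        filt = design_denoise_filter(fs1, config.fc, config.n_taps, config.stopband_edge)
    windows = window_signal(record, config.window_s)
    qrs: list[QrsSegment] = []
    ignored = 0
    for w in windows:
        dec = WindowedSegment(
            samples=decimate(w.samples, config.D1),
            fs=fs1,
            subject_id=w.subject_id,
            class_label=w.class_label,
        )
        seg = select_qrs(dec, alpha, config.qrs_len, config.search_span)
        if seg is None:
            ignored += 1
        else:
            qrs.append(seg)
    denoised = [apply_fir(seg, filt) for seg in qrs]
    stats = {
        "windows": len(windows),
        "qrs_selected": len(qrs),
        "qrs_ignored": ignored,
    }
    logger.info(
        "frontend %s: %d windows, %d QRS selected, %d ignored",
        record.subject_id,
        stats["windows"],
        stats["qrs_selected"],
        stats["qrs_ignored"],
    )
    return windows, qrs, denoised, stats


def process_dataset(
    records: list[EcgRecord],
    config: FrontendConfig = FrontendConfig(),
) -> tuple[list[WindowedSegment], list[DenoisedSegment], dict]:
    """Front end over a whole dataset with automatic alpha calibration.

    ``config.alpha`` overrides calibration when set. Returns all windows,
    all denoised segments (input order preserved) and aggregate counts.
    """
    alpha = config.alpha if config.alpha is not None else calibrate_alpha(records)
    fs1 = config.fs / config.D1
    for stage_fs, stage_fmax, D in (
        (config.fs, config.fmax, config.D1),
        (fs1, config.fmaxf, config.D2),
    ):
        valid, bound = check_decimation_valid(stage_fs, stage_fmax, D)
        if not valid:
            raise ValueError(f"decimation by {D} at {stage_fs} Hz violates bound {bound}")
    filt = design_denoise_filter(fs1, config.fc, config.n_taps, config.stopband_edge)
    all_windows: list[WindowedSegment] = []
    all_denoised: list[DenoisedSegment] = []
    totals = {"windows": 0, "qrs_selected": 0, "qrs_ignored": 0, "alpha_mv": alpha}
    for rec in records:
        windows, _, denoised, stats = process_record(rec, alpha, config, filt)
        all_windows.extend(windows)
        all_denoised.extend(denoised)
        for k in ("windows", "qrs_selected", "qrs_ignored"):
            totals[k] += stats[k]
    return all_windows, all_denoised, totals
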