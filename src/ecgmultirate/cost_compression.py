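"""Closed-form performance models: operation counts, compression, reconstruction.

The cost model counts additions and multiplications per 0.9 s window for two
front-end chains built from the same blocks:

* fixed-rate: a Kr-tap FIR denoiser on the full Nr = 324-sample window at
  360 Hz, followed by a full 4-level wavelet packet decomposition with
  Kwd-tap half-band filters —
  additions = (Kr - 1) * Nr + (Kwd - 1) * (8 * Nr + 28 * M),
  multiplications = Kr * Nr + Kwd * (8 * Nr + 28 * M), with M = Kwd - 1;
* proposed (multirate): QRS selection (80 magnitude comparisons per segment,
  booked as additions), a K ~= Kr/2-tap denoiser on the Nd = 60-sample
  segment at 180 Hz, then the partial tree on the N = 30-sample decimated
  segment — additions = (K - 1) * Nd + 80 + (Kwd - 1) * (3.75 * N + 8 * M),
  multiplications = K * Nd + Kwd * (3.75 * N + 8 * M).

Decimation itself is free (sample dropping), so the fold reduction is the
elementwise ratio of the two counts. The compression ratio is the
per-instance element-count ratio of the fixed-rate feature set (416
coefficients) to the selected set (32), identical to the bit ratio at equal
11-bit encoding.

Reconstruction fidelity of each decimation stage is measured by cubic-spline
interpolation back to the original grid and the mean squared error against
the undecimated series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CostParams",
    "OpCount",
    "ReconstructionReport",
    "cost_fixed_rate",
    "cost_proposed",
    "gain",
    "compression_ratio",
    "reconstruct_csi",
    "mse",
    "reconstruction_report",
]


@dataclass(frozen=True)
class CostParams:
    """Parameters of the operation-count model (defaults are canonical)."""

    Kr: int = 91  # fixed-rate denoising filter taps
    K: int = 45  # proposed (reduced-rate) denoising filter taps
    Kwd: int = 8  # half-band analysis filter taps
    Nr: int = 324  # samples per raw window
    Nd: int = 60  # samples per QRS segment
    N: int = 30  # samples per decimated segment
    n_comparisons: int = 80  # magnitude comparisons per segment (QRS selection)

    def __post_init__(self) -> None:
        if min(self.Kr, self.K, self.Kwd, self.Nr, self.Nd, self.N) <= 0:
            raise ValueError("all cost parameters must be positive")
        if abs(self.K - 0.5 * self.Kr) > 1:
            raise ValueError("K must be half of Kr (within 1 tap)")

    @property
    def M(self) -> int:
        return self.Kwd - 1


@dataclass(frozen=True)
class OpCount:
    """Additions and multiplications per window (may be fractional)."""

    additions: float
    multiplications: float

    def __post_init__(self) -> None:
        if self.additions < 0 or self.multiplications < 0:
            raise ValueError("operation counts must be non-negative")


@dataclass(frozen=True)
class ReconstructionReport:
    """Per-class and overall mean squared reconstruction errors (V^2 scale)."""

    mse1_per_class: dict[str, float]  # window-level, first decimation
    mse2_per_class: dict[str, float]  # segment-level, second decimation
    mse1_mean: float
    mse2_mean: float


def cost_fixed_rate(p: CostParams = CostParams()) -> OpCount:
    """Per-window operation count of the fixed-rate chain."""
    wavelet_samples = 8 * p.Nr + 28 * p.M
    return OpCount(
        additions=(p.Kr - 1) * p.Nr + (p.Kwd - 1) * wavelet_samples,
        multiplications=p.Kr * p.Nr + p.Kwd * wavelet_samples,
    )


def cost_proposed(p: CostParams = CostParams()) -> OpCount:
    """Per-segment operation count of the proposed multirate chain.

    The QRS-selection magnitude comparisons are booked as additions.
    """
    wavelet_samples = 3.75 * p.N + 8 * p.M
    return OpCount(
        additions=(p.K - 1) * p.Nd + p.n_comparisons + (p.Kwd - 1) * wavelet_samples,
        multiplications=p.K * p.Nd + p.Kwd * wavelet_samples,
    )


def gain(fixed: OpCount, proposed: OpCount) -> tuple[float, float]:
    """Fold reductions (additions, multiplications) = fixed / proposed."""
    if proposed.additions <= 0 or proposed.multiplications <= 0:
        raise ValueError("proposed operation counts must be positive")
    return (
        fixed.additions / proposed.additions,
        fixed.multiplications / proposed.multiplications,
    )


def compression_ratio(pr_elements: int, p2_elements: int) -> float:
    """Element-count (equivalently bit-count) ratio of the two feature sets."""
    if p2_elements <= 0:
        raise ValueError("p2_elements must be positive")
    return pr_elements / p2_elements


def reconstruct_csi(xd: np.ndarray, factor: int = 2, n_target: int | None = None) -> np.ndarray:
    """Cubic-spline reconstruction of a decimated series on the original grid.

    Fits a cubic interpolating spline through the knots (factor * i, xd[i])
    and evaluates it at 0 .. n_target - 1 (default factor * len(xd)); exact
    at the knots, extrapolated past the last knot.
    """
    xd = np.asarray(xd, dtype=float)
    if len(xd) < 4:
        raise ValueError("need at least 4 samples for cubic-spline reconstruction")
    if n_target is None:
        n_target = factor * len(xd)
    spline = CubicSpline(np.arange(len(xd)) * factor, xd)
    return spline(np.arange(n_target))


def mse(x: np.ndarray, x_recon: np.ndarray) -> float:
    """Mean squared difference between a series and its reconstruction."""
    x = np.asarray(x, dtype=float)
    x_recon = np.asarray(x_recon, dtype=float)
    if x.shape != x_recon.shape:
        raise ValueError("series lengths must match")
    return float(np.mean((x - x_recon) ** 2))


def reconstruction_report(windows, denoised_segments) -> ReconstructionReport:
    """Per-class mean reconstruction errors of both decimation stages.

    MSE1 compares each raw 324-sample window with the spline reconstruction
    of its 2-fold decimation; MSE2 does the same for each denoised 60-sample
    segment and its 30-sample decimation. Amplitudes in mV are converted to
    volts so errors are on the V^2 scale.
    """
    mse1: dict[str, list[float]] = {}
    mse2: dict[str, list[float]] = {}
    for w in windows:
        x = np.asarray(w.samples, float) * 1e-3
        rec = reconstruct_csi(x[::2], 2, len(x))
        mse1.setdefault(w.class_label, []).append(mse(x, rec))
    for s in denoised_segments:
        x = np.asarray(s.samples, float) * 1e-3
        rec = reconstruct_csi(np.asarray(s.decimated, float) * 1e-3, 2, len(x))
        mse2.setdefault(s.class_label, []).append(mse(x, rec))
    per1 = {c: float(np.mean(v)) for c, v in mse1.items()}
    per2 = {c: float(np.mean(v)) for c, v in mse2.items()}
    return ReconstructionReport(
        mse1_per_class=per1,
        mse2_per_class=per2,
        mse1_mean=float(np.mean(list(per1.values()))),
        mse2_mean=float(np.mean(list(per2.values()))),
    )
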