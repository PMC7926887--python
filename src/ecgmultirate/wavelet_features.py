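"""Wavelet subband feature extraction.

Implements a bespoke partial wavelet-packet decomposition of the 30-sample
denoised QRS segment and the frequency-content-based coefficient selection:

* one DWT step splits a length-n series into approximation and detail
  branches of length floor((n + 7) / 2) (8-tap Daubechies-4 analysis pair,
  symmetric boundary extension);
* the proposed tree decomposes 30 samples as
  x -> (a1, d1); a1 -> (a2, d2); a2 -> (a3, d3); a3 -> (aa4, ad4);
  d3 -> (da4, dd4), keeping d1 (18), d2 (12) and the four level-4 subbands
  (8 each) — 62 coefficients in total;
* the four level-4 subbands cover the diagnostically relevant 0-22 Hz band
  of the 90 Hz segment, so selecting [dd4, da4, ad4, aa4] keeps 32 features;
* the fixed-rate baseline is the full 4-level wavelet packet tree on a
  324-sample window: 16 leaves of 26 coefficients, 416 in total.

Subband names read the approximation (a) / detail (d) path root-to-leaf;
aa4/ad4 descend from a3, da4/dd4 from d3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .multirate_frontend import DenoisedSegment, WindowedSegment

__all__ = [
    "WaveletSpec",
    "SubbandSet",
    "FeatureMatrix",
    "dwt_step",
    "proposed_decompose",
    "full_packet_level4",
    "select_features",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
    "N_FEATURES",
]

#: Feature counts per mode: all proposed-tree coefficients (P1), the selected
#: level-4 subbands (P2), and the fixed-rate full-packet baseline (Pr).
N_FEATURES = {"P1": 62, "P2": 32, "Pr": 416}

#: Frozen concatenation orders.
P1_ORDER = ("d1", "d2", "dd4", "da4", "ad4", "aa4")
SELECTED_ORDER = ("dd4", "da4", "ad4", "aa4")


@dataclass(frozen=True)
class WaveletSpec:
    """The analysis filter pair and boundary convention.

    The 8-tap Daubechies-4 pair with symmetric extension is the load-bearing
    convention of the package: it reproduces every structural count above.
    """

    family: str = "db4"
    extension: str = "symmetric"
    g: np.ndarray = field(default=None, repr=False)  # low-pass analysis taps
    h: np.ndarray = field(default=None, repr=False)  # high-pass analysis taps

    def __post_init__(self) -> None:
        w = pywt.Wavelet(self.family)
        g = np.asarray(w.dec_lo) if self.g is None else np.asarray(self.g, float)
        h = np.asarray(w.dec_hi) if self.h is None else np.asarray(self.h, float)
        if len(g) != len(h):
            raise ValueError("analysis filters must have equal length")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "h", h)

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.family)


@dataclass
class SubbandSet:
    """Named coefficient blocks of the proposed decomposition of one segment."""

    d1: np.ndarray  # 18 coefficients
    d2: np.ndarray  # 12
    aa4: np.ndarray  # 8
    ad4: np.ndarray  # 8
    da4: np.ndarray  # 8
    dd4: np.ndarray  # 8

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("d1", "d2", "aa4", "ad4", "da4", "dd4")}

    @property
    def total_coefficients(self) -> int:
        return sum(len(v) for v in self.as_dict().values())


@dataclass
class FeatureMatrix:
    """Instances x features table with class and subject labels."""

    X: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.mode not in N_FEATURES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.X.shape[1] != N_FEATURES[self.mode]:
            raise ValueError(
                f"mode {self.mode} requires {N_FEATURES[self.mode]} features, "
                f"got {self.X.shape[1]}"
            )
        if not (len(self.labels) == len(self.subjects) == self.X.shape[0]):
            raise ValueError("labels/subjects must match the number of rows")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]


def dwt_step(
    x: np.ndarray, spec: WaveletSpec = WaveletSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: half-band filtering then keep-every-second-sample.

    Both outputs have length floor((len(x) + L - 1) / 2) for the L = 8 tap
    pair under symmetric extension.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    a, d = pywt.dwt(x, spec.wavelet, mode=spec.extension)
    return a, d


def proposed_decompose(x: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> SubbandSet:
    """The proposed partial-packet tree on a 30-sample decimated segment.

    Splits x -> (a1, d1), a1 -> (a2, d2), a2 -> (a3, d3), then both level-3
    branches once more; returns d1 (18), d2 (12) and the four 8-coefficient
    level-4 subbands (62 coefficients in total).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != 30:
        raise ValueError(f"expected a 30-sample segment, got {len(x)}")
    a1, d1 = dwt_step(x, spec)
    a2, d2 = dwt_step(a1, spec)
    a3, d3 = dwt_step(a2, spec)
    aa4, ad4 = dwt_step(a3, spec)
    da4, dd4 = dwt_step(d3, spec)
    return SubbandSet(d1=d1, d2=d2, aa4=aa4, ad4=ad4, da4=da4, dd4=dd4)


def full_packet_level4(
    x: np.ndarray, spec: WaveletSpec = WaveletSpec()
) -> list[np.ndarray]:
    """Full 4-level wavelet packet tree on a 324-sample window.

    Every node is split into (approximation, detail); the 16 leaves (26
    coefficients each, 416 in total) are returned in natural root-to-leaf
    order (approximation branch first at every node).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != 324:
        raise ValueError(f"expected a 324-sample window, got {len(x)}")
    blocks = [x]
    for _level in range(4):
        nxt = []
        for b in blocks:
            a, d = dwt_step(b, spec)
            nxt.extend((a, d))
        blocks = nxt
    return blocks


def select_features(sb: SubbandSet) -> np.ndarray:
    """Frequency-content-based selection: concatenate [dd4, da4, ad4, aa4].

    A pure projection — 32 values copied unmodified; d1 and d2 (the high-
    frequency subbands above the band of interest) are discarded.
    """
    return np.concatenate([sb.as_dict()[k] for k in SELECTED_ORDER])


def _p1_vector(sb: SubbandSet) -> np.ndarray:
    return np.concatenate([sb.as_dict()[k] for k in P1_ORDER])


def build_feature_matrix(
    segments: list[DenoisedSegment] | list[WindowedSegment],
    mode: str,
    spec: WaveletSpec = WaveletSpec(),
) -> FeatureMatrix:
    """Decompose a homogeneous list of segments into a feature matrix.

    Modes P1 (62 columns) and P2 (32) take denoised segments and decompose
    their 30-sample decimated series; mode Pr (416) takes 324-sample raw
    windows through the full packet tree. Row order preserves input order.
    """
    if mode not in N_FEATURES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(N_FEATURES)}")
    if not segments:
        raise ValueError("no segments")
    rows = []
    for seg in segments:
        if mode == "Pr":
            series = np.asarray(seg.samples, float)
            if len(series) != 324:
                raise ValueError("mode Pr requires 324-sample windows")
            rows.append(np.concatenate(full_packet_level4(series, spec)))
        else:
            series = np.asarray(seg.decimated, float)
            if len(series) != 30:
                raise ValueError(f"mode {mode} requires 30-sample decimated segments")
            sb = proposed_decompose(series, spec)
            rows.append(_p1_vector(sb) if mode == "P1" else select_features(sb))
    return FeatureMatrix(
        X=np.vstack(rows),
        labels=np.array([s.class_label for s in segments]),
        subjects=np.array([s.subject_id for s in segments]),
        mode=mode,
    )


def write_feature_matrix(
    fm: FeatureMatrix, path: str | Path, spec: WaveletSpec = WaveletSpec()
) -> None:
    """CSV with (subject, class, f_000...) columns + JSON sidecar of conventions."""
    path = Path(path)
    cols = [f"f_{i:03d}" for i in range(fm.X.shape[1])]
    df = pd.DataFrame(fm.X, columns=cols)
    df.insert(0, "class", fm.labels)
    df.insert(0, "subject", fm.subjects)
    df.to_csv(path, index=False)
    sidecar = {"mode": fm.mode, "wavelet": spec.family, "extension": spec.extension}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar file {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f_")]
    return FeatureMatrix(
        X=df[feat_cols].to_numpy(float),
        labels=df["class"].to_numpy(),
        subjects=df["subject"].to_numpy(),
        mode=sidecar["mode"],
    )
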