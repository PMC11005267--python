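"""Denoising and normalization pipeline.

Stages: 7-level db6 wavelet decomposition, per-level threshold chosen by
minimising an unbiased risk estimate over the sorted squared coefficients,
hard (keep-or-kill) thresholding of the detail layers, inverse transform,
and z-score normalization. Also provides the SNR metric used to report the
denoising effect.

Threshold selection for a detail level ``d``:

* noise scale ``sigma = median(|finest details|) / 0.6745`` (robust MAD
  estimate of a Gaussian noise standard deviation);
* ``P`` = ascending sorted squares of ``d / sigma``;
* risk ``R_i = [N - 2i + (N - i) P_i + sum_{k<=i} P_k] / N`` (1-based i);
* the threshold is ``sigma * sqrt(P_{i*})`` at the risk minimiser ``i*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import wavelets as wv
from .signal_io import ECGRecord

__all__ = [
    "WaveletCoefficients",
    "ThresholdSet",
    "NormalizationStats",
    "dwt_decompose",
    "dwt_reconstruct",
    "risk_vector",
    "select_threshold",
    "hard_threshold",
    "denoise",
    "zscore_fit_apply",
    "zscore_inverse",
    "snr_db",
]

logger = logging.getLogger(__name__)

MAD_GAUSSIAN_CONSTANT = 0.6745


@dataclass
class WaveletCoefficients:
    """L-level DWT of a signal.

    ``details`` runs finest (level 1) to coarsest (level L); ``approx`` is
    the level-L approximation. ``signal_length`` is retained so the inverse
    transform can truncate the odd-length reconstruction surplus.
    """

    wavelet_name: str
    levels: int
    approx: np.ndarray
    details: list[np.ndarray]
    signal_length: int

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError("number of detail arrays must equal levels")


@dataclass
class ThresholdSet:
    """Per-level threshold selection record (finest to coarsest)."""

    per_level_threshold: list[float]
    per_level_sigma: list[float]
    selected_index: list[int]

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.per_level_threshold):
            raise ValueError("thresholds must be non-negative")

    def to_dict(self) -> dict:
        return {
            "levels": [
                {"level": i + 1, "sigma": s, "threshold": t, "selected_index": k}
                for i, (s, t, k) in enumerate(
                    zip(
                        self.per_level_sigma,
                        self.per_level_threshold,
                        self.selected_index,
                    )
                )
            ]
        }


@dataclass(frozen=True)
class NormalizationStats:
    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("std must be positive")


def dwt_decompose(
    record: ECGRecord | np.ndarray,
    wavelet_name: str = "db6",
    levels: int = 7,
) -> WaveletCoefficients:
    """L-level discrete wavelet transform (symmetric boundary extension)."""
    x = record.samples if isinstance(record, ECGRecord) else np.asarray(record, float)
    cap = wv.max_decomposition_level(x.size, wavelet_name)
    if levels > cap:
        raise ValueError(
            f"signal of length {x.size} is too short for {levels} levels with "
            f"{wavelet_name}; at most {cap} levels are supported"
        )
    coeffs = wv.wavedec(x, wavelet_name, levels)
    approx = coeffs[0]
    details_coarse_to_fine = coeffs[1:]
    return WaveletCoefficients(
        wavelet_name=wavelet_name,
        levels=levels,
        approx=approx,
        details=details_coarse_to_fine[::-1],
        signal_length=x.size,
    )


def dwt_reconstruct(coeffs: WaveletCoefficients) -> np.ndarray:
    """Inverse transform back to a signal of the original length."""
    stack = [coeffs.approx] + list(coeffs.details[::-1])
    x = wv.waverec(stack, coeffs.wavelet_name)
    return x[: coeffs.signal_length]


def risk_vector(squared_sorted_coeffs: np.ndarray) -> np.ndarray:
    """Unbiased risk estimate for each candidate threshold index.

    ``R_i = [N - 2i + (N - i) * P_i + sum_{k=1..i} P_k] / N`` for the
    ascending vector ``P`` of squared coefficients, 1-based ``i``.
    """
    P = np.asarray(squared_sorted_coeffs, dtype=np.float64)
    if P.ndim != 1 or P.size == 0:
        raise ValueError("expected a non-empty 1-D vector")
    if np.any(np.diff(P) < 0):
        raise ValueError("squared coefficients must be sorted ascending")
    N = P.size
    i = np.arange(1, N + 1, dtype=np.float64)
    return (N - 2.0 * i + (N - i) * P + np.cumsum(P)) / N


def select_threshold(
    detail_coeffs: np.ndarray,
    finest_details: np.ndarray,
    sigma: Optional[float] = None,
) -> tuple[float, float, int]:
    """Pick the risk-minimising threshold for one detail level.

    Returns ``(threshold, sigma, selected_index)`` where ``selected_index``
    is the 0-based position of the chosen squared coefficient in the sorted
    vector. A zero noise scale degenerates to threshold 0 (logged).
    """
    d = np.asarray(detail_coeffs, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty coefficient array")
    if sigma is None:
        finest = np.asarray(finest_details, dtype=np.float64)
        if finest.size == 0:
            raise ValueError("empty finest-detail array")
        sigma = float(np.median(np.abs(finest)) / MAD_GAUSSIAN_CONSTANT)
    if sigma == 0.0:
        logger.warning("zero noise scale: degenerate threshold 0")
        return 0.0, 0.0, 0
    P = np.sort((d / sigma) ** 2)
    risks = risk_vector(P)
    i_star = int(np.argmin(risks))
    threshold = sigma * float(np.sqrt(P[i_star]))
    return threshold, sigma, i_star


def hard_threshold(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    """Keep-or-kill: zero every coefficient with magnitude below the
    threshold, pass the rest through unchanged."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    c = np.asarray(coeffs, dtype=np.float64)
    return np.where(np.abs(c) >= threshold, c, 0.0)


def denoise(
    record: ECGRecord,
    levels: int = 7,
    wavelet: str = "db6",
    sigma_per_level: bool = False,
) -> tuple[ECGRecord, ThresholdSet]:
    """Full wavelet-shrinkage pipeline.

    Decompose, select one threshold per detail level, hard-threshold the
    detail layers (approximation untouched), and inverse-transform. With
    ``sigma_per_level`` the noise scale is re-estimated from each level's
    own coefficients instead of once from the finest level.
    """
    coeffs = dwt_decompose(record, wavelet, levels)
    finest = coeffs.details[0]
    thresholds: list[float] = []
    sigmas: list[float] = []
    indices: list[int] = []
    new_details: list[np.ndarray] = []
    for d in coeffs.details:
        ref = d if sigma_per_level else finest
        t, s, k = select_threshold(d, ref)
        thresholds.append(t)
        sigmas.append(s)
        indices.append(k)
        new_details.append(hard_threshold(d, t))
    coeffs.details = new_details
    out = dwt_reconstruct(coeffs)
    return (
        record.with_samples(out, record_id=record.record_id + "~dn"),
        ThresholdSet(thresholds, sigmas, indices),
    )


def zscore_fit_apply(x: np.ndarray) -> tuple[np.ndarray, NormalizationStats]:
    """Standardize to zero mean and unit sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        raise ValueError("constant input: standard deviation is zero")
    return (x - mean) / std, NormalizationStats(mean=mean, std=std)


def zscore_inverse(z: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(z, dtype=np.float64) * stats.std + stats.mean


def snr_db(reference: np.ndarray, estimate: np.ndarray) -> float:
    """``10 log10(sum(reference^2) / sum((estimate - reference)^2))`` in dB.

    Returns ``inf`` when the error energy is exactly zero.
    """
    reference = np.asarray(reference, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if reference.shape != estimate.shape:
        raise ValueError("reference and estimate must have equal length")
    sig = float(np.sum(reference**2))
    if sig == 0.0:
        raise ValueError("all-zero reference signal")
    err = float(np.sum((estimate - reference) ** 2))
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(sig / err)
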