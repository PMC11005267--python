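"""Orthogonal discrete wavelet transform with symmetric boundary handling.

Self-contained single-level and multilevel DWT/IDWT for the Daubechies
family, compatible with the usual ``wavedec``/``waverec`` conventions
(half-sample symmetric extension, coefficient length ``(n + flen - 1) // 2``
per level). Only the filter banks actually needed by the denoising stage
are bundled; the decomposition is exact-reconstruction for any input
length.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Wavelet",
    "available_wavelets",
    "dwt",
    "idwt",
    "wavedec",
    "waverec",
    "max_decomposition_level",
]

# Daubechies scaling (low-pass decomposition) filters. Detail/reconstruction
# banks follow from the quadrature-mirror relations below.
_DB_DEC_LO = {
    "db4": [
        -0.010597401785069032,
        0.0328830116668852,
        0.030841381835560764,
        -0.18703481171909309,
        -0.027983769416859854,
        0.6308807679298589,
        0.7148465705529157,
        0.2303778133088965,
    ],
    "db6": [
        -0.0010773010853084796,
        0.004777257510945511,
        0.0005538422011614961,
        -0.03158203931748603,
        0.027522865530305727,
        0.09750160558732304,
        -0.12976686756726194,
        -0.22626469396543983,
        0.31525035170919763,
        0.7511339080210954,
        0.49462389039845306,
        0.11154074335010947,
    ],
    "db8": [
        -0.00011747678412476953,
        0.0006754494064505693,
        -0.00039174037337694705,
        -0.004870352993451574,
        0.008746094047405777,
        0.013981027917398282,
        -0.044088253930794755,
        -0.017369301001807547,
        0.12874742662047847,
        0.0004724845739132828,
        -0.2840155429615469,
        -0.015829105256349306,
        0.5853546836542067,
        0.6756307362972898,
        0.31287159091429995,
        0.05441584224310401,
    ],
}


class Wavelet:
    """Filter bank for an orthogonal wavelet (``db4``, ``db6``, ``db8``)."""

    def __init__(self, name: str):
        key = name.lower()
        if key not in _DB_DEC_LO:
            raise ValueError(
                f"unknown wavelet {name!r}; available: {sorted(_DB_DEC_LO)}"
            )
        self.name = key
        dec_lo = np.asarray(_DB_DEC_LO[key], dtype=np.float64)
        # QMF relations for an orthogonal bank.
        self.dec_lo = dec_lo
        self.dec_hi = (dec_lo[::-1] * np.where(np.arange(dec_lo.size) % 2, 1.0, -1.0))
        self.rec_lo = dec_lo[::-1]
        self.rec_hi = self.dec_hi[::-1]
        self.filter_length = dec_lo.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Wavelet({self.name!r})"


def available_wavelets() -> list[str]:
    return sorted(_DB_DEC_LO)


def _as_wavelet(wavelet: str | Wavelet) -> Wavelet:
    return wavelet if isinstance(wavelet, Wavelet) else Wavelet(wavelet)


def _symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric extension: ... x2 x1 | x1 x2 ... xn | xn xn-1 ...

    Built from the period-2n tiling [x, reversed(x)], which stays valid even
    when ``pad`` exceeds the signal length.
    """
    n = x.size
    flipped = x[::-1]
    k = -(-pad // n)  # whole mirrored blocks needed on each side
    ext = np.concatenate([flipped if b % 2 else x for b in range(-k, k + 1)])
    centre = k * n
    return ext[centre - pad : centre + n + pad]


def dwt(x: np.ndarray, wavelet: str | Wavelet) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: returns (approximation, detail) coefficients."""
    w = _as_wavelet(wavelet)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("dwt expects a 1-D signal")
    if x.size < 1:
        raise ValueError("dwt expects a non-empty signal")
    flen = w.filter_length
    pad = flen - 1
    ext = _symmetric_extend(x, pad)
    # Correlation with the time-reversed filter == convolution; np.convolve
    # already reverses, so feed filters directly.
    full_a = np.convolve(ext, w.dec_lo, mode="valid")
    full_d = np.convolve(ext, w.dec_hi, mode="valid")
    return full_a[1::2], full_d[1::2]


def idwt(
    ca: np.ndarray, cd: np.ndarray, wavelet: str | Wavelet
) -> np.ndarray:
    """One synthesis step; output length is ``2*len(ca) - flen + 2``."""
    w = _as_wavelet(wavelet)
    ca = np.asarray(ca, dtype=np.float64)
    cd = np.asarray(cd, dtype=np.float64)
    if ca.size != cd.size:
        raise ValueError("approximation/detail length mismatch")
    flen = w.filter_length
    up_a = np.zeros(2 * ca.size, dtype=np.float64)
    up_d = np.zeros(2 * cd.size, dtype=np.float64)
    up_a[::2] = ca
    up_d[::2] = cd
    rec = np.convolve(up_a, w.rec_lo, mode="full") + np.convolve(
        up_d, w.rec_hi, mode="full"
    )
    out_len = 2 * ca.size - flen + 2
    return rec[flen - 2 : flen - 2 + out_len]


def max_decomposition_level(n: int, wavelet: str | Wavelet) -> int:
    w = _as_wavelet(wavelet)
    if n < w.filter_length:
        return 0
    return int(np.floor(np.log2(n / (w.filter_length - 1.0))))


def wavedec(
    x: np.ndarray, wavelet: str | Wavelet, level: int
) -> list[np.ndarray]:
    """Multilevel analysis; returns ``[cA_L, cD_L, ..., cD_1]``."""
    w = _as_wavelet(wavelet)
    x = np.asarray(x, dtype=np.float64)
    if level < 1:
        raise ValueError("level must be >= 1")
    cap = max_decomposition_level(x.size, w)
    if level > cap:
        raise ValueError(
            f"signal of length {x.size} supports at most {cap} levels "
            f"with {w.name}; requested {level}"
        )
    details: list[np.ndarray] = []
    approx = x
    for _ in range(level):
        approx, d = dwt(approx, w)
        details.append(d)
    return [approx] + details[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str | Wavelet) -> np.ndarray:
    """Inverse of :func:`wavedec`. May be one sample longer than the input
    for odd lengths; callers truncate to the known length."""
    w = _as_wavelet(wavelet)
    if len(coeffs) < 2:
        raise ValueError("need at least one approximation and one detail array")
    a = np.asarray(coeffs[0], dtype=np.float64)
    for d in coeffs[1:]:
        d = np.asarray(d, dtype=np.float64)
        if a.size == d.size + 1:
            a = a[:-1]
        elif a.size != d.size:
            raise ValueError("inconsistent coefficient lengths")
        a = idwt(a, d, w)
    return a
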