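"""Orthogonal discrete wavelet transform with periodic boundary handling.

Implements the dyadic filter-bank DWT used for ERP feature extraction. The
default filter is the length-8 Daubechies least-asymmetric (symlet) filter —
``la8`` in the R *wavelets* package, ``sym4`` in PyWavelets. Periodization
keeps the transform exactly orthogonal, so Parseval's identity holds to
machine precision and the inverse is the transpose.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LA8_DEC_LO",
    "qmf_highpass",
    "dwt_level",
    "idwt_level",
    "wavedec",
    "waverec",
]

# Scaling (low-pass) analysis filter of the least-asymmetric length-8 wavelet.
# Normalized so sum(h) = sqrt(2) and sum(h^2) = 1.
LA8_DEC_LO = np.array(
    [
        -0.07576571478927333,
        -0.02963552764599851,
        0.49761866763201545,
        0.80373875180591614,
        0.29785779560527736,
        -0.09921954357684722,
        -0.01260396726203783,
        0.03222310060404270,
    ]
)


def qmf_highpass(lo: np.ndarray) -> np.ndarray:
    """Quadrature-mirror high-pass filter of an orthogonal scaling filter."""
    lo = np.asarray(lo, dtype=float)
    n = np.arange(lo.size)
    return (-1.0) ** n * lo[::-1]


def dwt_level(x: np.ndarray, lo: np.ndarray = LA8_DEC_LO) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step of the periodized DWT.

    Parameters
    ----------
    x
        Signal of even length S.

    Returns
    -------
    (approximation, detail), each of length S // 2.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size % 2:
        raise ValueError(f"signal length must be even, got shape {x.shape}")
    hi = qmf_highpass(lo)
    a = np.zeros(x.size // 2)
    d = np.zeros(x.size // 2)
    for n in range(lo.size):
        shifted = np.roll(x, -n)[::2]
        a += lo[n] * shifted
        d += hi[n] * shifted
    return a, d


def idwt_level(a: np.ndarray, d: np.ndarray, lo: np.ndarray = LA8_DEC_LO) -> np.ndarray:
    """One synthesis step, inverse of :func:`dwt_level`."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape != d.shape:
        raise ValueError("approximation and detail must have equal length")
    hi = qmf_highpass(lo)
    size = 2 * a.size
    up_a = np.zeros(size)
    up_d = np.zeros(size)
    up_a[::2] = a
    up_d[::2] = d
    x = np.zeros(size)
    for n in range(lo.size):
        x += lo[n] * np.roll(up_a, n) + hi[n] * np.roll(up_d, n)
    return x


def wavedec(x: np.ndarray, level: int, lo: np.ndarray = LA8_DEC_LO) -> list[np.ndarray]:
    """Multi-level periodized DWT.

    Returns ``[a_L, d_L, d_{L-1}, ..., d_1]`` (coarsest first), matching the
    conventional wavedec ordering. Requires ``len(x)`` divisible by 2**level.
    """
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.size % (1 << level):
        raise ValueError(
            f"signal length {x.size} not divisible by 2^{level}"
        )
    details: list[np.ndarray] = []
    a = x
    for _ in range(level):
        a, d = dwt_level(a, lo)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray], lo: np.ndarray = LA8_DEC_LO) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    a = np.asarray(coeffs[0], dtype=float)
    for d in coeffs[1:]:
        a = idwt_level(a, np.asarray(d, dtype=float), lo)
    return a
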