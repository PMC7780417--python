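"""Epoched-trial preprocessing and DWT feature extraction.

Pipeline: baseline correction over the pre-stimulus window, amplitude-based
trial rejection, trial averaging, level-L orthogonal DWT with retention of
the low-frequency blocks, and the reverse operations (inverse DWT,
scalogram export).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import wavelet
from .exceptions import LayoutError

__all__ = [
    "EpochedRecording",
    "WaveletBand",
    "WaveletLayout",
    "FeatureVector",
    "baseline_correct",
    "reject_trials",
    "average_trials",
    "decompose",
    "reconstruct",
    "scalogram",
    "estimate_snr",
    "default_layout",
    "format_band_edge",
]


@dataclass
class EpochedRecording:
    """T epoched trials of S samples each, with acquisition metadata.

    ``pre_stimulus_s`` is the duration of the baseline window at the start
    of each epoch. S must be a power of two for the dyadic DWT.
    """

    trials: np.ndarray
    fs: float
    pre_stimulus_s: float
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        t, s = self.trials.shape
        if t < 1:
            raise ValueError("need at least one trial")
        if s & (s - 1):
            raise ValueError(f"sample count {s} is not a power of two")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.pre_stimulus_s * self.fs < 1:
            raise ValueError("pre-stimulus window shorter than one sample")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]


@dataclass(frozen=True)
class WaveletBand:
    """One retained DWT block: label, frequency interval, geometry."""

    label: str           # "V8" approximation, "W8".."W1" details
    level: int
    low_hz: float
    high_hz: float
    count: int
    dt_s: float          # time support of one coefficient, 2^level / fs


@dataclass(frozen=True)
class WaveletLayout:
    """Ordered band structure of a retained DWT coefficient vector.

    Bands are stored approximation first, then details from lowest to
    highest frequency — the same order as the coefficients in a
    :class:`FeatureVector`.
    """

    bands: tuple[WaveletBand, ...]
    fs: float
    level: int
    total_samples: int

    @property
    def n_features(self) -> int:
        return sum(b.count for b in self.bands)

    @property
    def retain_hz(self) -> float:
        return self.bands[-1].high_hz

    def band_slices(self) -> dict[str, slice]:
        out = {}
        start = 0
        for band in self.bands:
            out[band.label] = slice(start, start + band.count)
            start += band.count
        return out

    def to_dict(self) -> dict:
        return {
            "fs": self.fs,
            "level": self.level,
            "total_samples": self.total_samples,
            "bands": [
                {
                    "label": b.label,
                    "level": b.level,
                    "low_hz": b.low_hz,
                    "high_hz": b.high_hz,
                    "count": b.count,
                    "dt_s": b.dt_s,
                }
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "WaveletLayout":
        bands = tuple(
            WaveletBand(
                label=b["label"], level=b["level"], low_hz=b["low_hz"],
                high_hz=b["high_hz"], count=b["count"], dt_s=b["dt_s"],
            )
            for b in payload["bands"]
        )
        return cls(
            bands=bands, fs=payload["fs"], level=payload["level"],
            total_samples=payload["total_samples"],
        )


@dataclass
class FeatureVector:
    """Retained DWT coefficients with their band layout."""

    values: np.ndarray
    layout: WaveletLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.layout.n_features:
            raise LayoutError(
                f"feature vector length {self.values.size} does not match "
                f"layout N={self.layout.n_features}"
            )


def baseline_correct(rec: EpochedRecording) -> EpochedRecording:
    """Subtract each trial's pre-stimulus mean from the whole trial."""
    n_pre = int(round(rec.pre_stimulus_s * rec.fs))
    if n_pre < 1:
        raise ValueError("empty pre-stimulus window")
    means = rec.trials[:, :n_pre].mean(axis=1, keepdims=True)
    return replace(rec, trials=rec.trials - means)


def reject_trials(
    rec: EpochedRecording, amplitude_threshold: Optional[float] = None
) -> tuple[EpochedRecording, float]:
    """Drop trials whose peak absolute amplitude exceeds the threshold.

    The default threshold is 5x the median per-trial peak — an automated
    surrogate for visual artifact inspection. Returns the cleaned recording
    and the fraction of trials kept.
    """
    peaks = np.abs(rec.trials).max(axis=1)
    if amplitude_threshold is None:
        amplitude_threshold = 5.0 * float(np.median(peaks))
    if amplitude_threshold <= 0:
        raise ValueError("amplitude threshold must be positive")
    keep = peaks <= amplitude_threshold
    if not keep.any():
        raise ValueError("all trials rejected by the amplitude threshold")
    kept_fraction = float(keep.mean())
    return replace(rec, trials=rec.trials[keep]), kept_fraction


def average_trials(rec: EpochedRecording) -> np.ndarray:
    """Sample-wise mean across trials (the ERP)."""
    return rec.trials.mean(axis=0)


def _band_labels_and_edges(fs: float, level: int) -> list[tuple[str, int, float, float]]:
    # (label, level, low_hz, high_hz); approximation then details low->high.
    out = [("V%d" % level, level, 0.0, fs / 2 ** (level + 1))]
    for lev in range(level, 0, -1):
        out.append(("W%d" % lev, lev, fs / 2 ** (lev + 1), fs / 2 ** lev))
    return out


def decompose(
    signal: np.ndarray, fs: float, level: int = 8, retain_hz: float = 156.25
) -> FeatureVector:
    """Level-L orthogonal DWT keeping the blocks entirely below ``retain_hz``.

    The approximation block and every detail block whose band lies at or
    below ``retain_hz`` are concatenated (approximation first, then details
    in increasing frequency). ``retain_hz`` must be a dyadic band edge
    fs / 2**j.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    coeffs = wavelet.wavedec(signal, level)  # raises on non-dyadic length
    edges = _band_labels_and_edges(fs, level)
    # retain_hz must equal fs / 2**j for some detail level j in range.
    uppers = [high for (_, _, _, high) in edges]
    if not any(math.isclose(retain_hz, u, rel_tol=1e-9) for u in uppers):
        raise LayoutError(
            f"retain_hz={retain_hz} is not a dyadic band edge for "
            f"fs={fs}, level={level}; valid edges: {uppers}"
        )
    bands = []
    values = []
    dt = lambda lev: 2 ** lev / fs
    for (label, lev, low, high), block in zip(edges, coeffs):
        if high <= retain_hz * (1 + 1e-9):
            bands.append(
                WaveletBand(
                    label=label, level=lev, low_hz=low, high_hz=high,
                    count=block.size, dt_s=dt(lev),
                )
            )
            values.append(block)
    layout = WaveletLayout(
        bands=tuple(bands), fs=fs, level=level, total_samples=signal.size
    )
    return FeatureVector(values=np.concatenate(values), layout=layout)


def reconstruct(features: FeatureVector, total_length: Optional[int] = None) -> np.ndarray:
    """Inverse DWT with all non-retained coefficients set to zero."""
    layout = features.layout
    if total_length is None:
        total_length = layout.total_samples
    if total_length != layout.total_samples:
        raise LayoutError(
            f"layout was built for {layout.total_samples} samples, "
            f"requested {total_length}"
        )
    level = layout.level
    # Rebuild the full wavedec coefficient list, zero outside retained bands.
    sizes = [total_length >> level] + [
        total_length >> lev for lev in range(level, 0, -1)
    ]
    coeffs = [np.zeros(s) for s in sizes]
    start = 0
    for band in layout.bands:
        block = features.values[start:start + band.count]
        start += band.count
        if band.label.startswith("V"):
            coeffs[0] = block.copy()
        else:
            # details are ordered [d_L, d_{L-1}, ..., d_1] after the approx
            pos = 1 + (level - band.level)
            if coeffs[pos].size != band.count:
                raise LayoutError(
                    f"band {band.label} count {band.count} inconsistent with "
                    f"total length {total_length}"
                )
            coeffs[pos] = block.copy()
    return wavelet.waverec(coeffs)


def scalogram(features: FeatureVector) -> list[dict]:
    """Tile the time-frequency plane with one signed cell per coefficient.

    Each cell is a dict with keys band, level, t_start, t_end, low_hz,
    high_hz, value. Cell count equals the feature length.
    """
    cells = []
    start = 0
    for band in features.layout.bands:
        block = features.values[start:start + band.count]
        start += band.count
        for k, value in enumerate(block):
            cells.append(
                {
                    "band": band.label,
                    "level": band.level,
                    "t_start": k * band.dt_s,
                    "t_end": (k + 1) * band.dt_s,
                    "low_hz": band.low_hz,
                    "high_hz": band.high_hz,
                    "value": float(value),
                }
            )
    return cells


def estimate_snr(rec: EpochedRecording) -> float:
    """Estimate the raw-trial SNR in dB from the ERP.

    One possible estimator (the acquisition papers rarely state theirs):
    signal power is the variance of the trial average across samples, noise
    power the mean per-trial variance of (trial - ERP). Returns +inf for
    noiseless (identical) trials.
    """
    if rec.n_trials < 2:
        raise ValueError("need at least 2 trials to estimate SNR")
    erp = average_trials(rec)
    noise_power = float(np.mean(np.var(rec.trials - erp, axis=1)))
    signal_power = float(np.var(erp))
    if noise_power == 0.0:
        return math.inf
    return 10.0 * math.log10(signal_power / noise_power)


def default_layout(
    fs: float = 5000.0, level: int = 8, total_samples: int = 2048,
    retain_hz: float = 156.25,
) -> WaveletLayout:
    """Layout for the standard setting without transforming any data."""
    return decompose(np.zeros(total_samples), fs, level, retain_hz).layout


def format_band_edge(hz: float, sig_digits: int = 3) -> str:
    """Display a band edge truncated (not rounded) to significant digits.

    Truncation toward zero reproduces conventional printed band tables
    (e.g. 9.765625 -> "9.76").
    """
    if hz == 0:
        return "0"
    exponent = math.floor(math.log10(abs(hz)))
    decimals = sig_digits - 1 - exponent
    factor = 10.0 ** decimals
    truncated = math.trunc(hz * factor) / factor
    if decimals <= 0:
        return str(int(truncated))
    return f"{truncated:.{decimals}f}"
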