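"""Geometry and reliability of fitted axes.

Angle between attribute axes, hyperspherical coordinate transforms,
bootstrap re-estimation of the axes from resampled trials, PCA-LDA
separability of the bootstrap clouds, and population-level scalogram
accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import core
from .exceptions import RankDeficiencyError
from .features import FeatureVector, WaveletLayout

__all__ = [
    "AxisPair",
    "BootstrapAxes",
    "ReliabilityResult",
    "angle_between",
    "to_spherical",
    "from_spherical",
    "bootstrap_axes",
    "reliability",
    "population_scalogram",
]


def angle_between(b1: np.ndarray, b2: np.ndarray) -> float:
    """Angle between two axes in degrees, in [0, 90].

    Axes are directions without orientation, so the absolute dot product is
    used: the result is invariant to sign flips of either input.
    """
    b1 = np.asarray(b1, dtype=float).ravel()
    b2 = np.asarray(b2, dtype=float).ravel()
    n1 = np.linalg.norm(b1)
    n2 = np.linalg.norm(b2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compute an angle with a zero vector")
    cosine = abs(float(b1 @ b2)) / (n1 * n2)
    cosine = min(cosine, 1.0)
    return math.degrees(math.acos(cosine))


@dataclass
class AxisPair:
    """Two unit axes for the same observations and their separation angle."""

    b_phi: np.ndarray
    b_psi: np.ndarray
    angle_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.b_phi = np.asarray(self.b_phi, dtype=float).ravel()
        self.b_psi = np.asarray(self.b_psi, dtype=float).ravel()
        for name, v in (("b_phi", self.b_phi), ("b_psi", self.b_psi)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} is not unit norm")
        self.angle_deg = angle_between(self.b_phi, self.b_psi)


def to_spherical(v: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Hyperspherical coordinates of a unit N-vector: N-1 angles.

    Recursive convention: the first N-2 polar angles lie in [0, pi], the
    last (azimuthal) angle in (-pi, pi]. The first basis vector e1 maps to
    all zeros.
    """
    v = np.asarray(v, dtype=float).ravel()
    if abs(np.linalg.norm(v) - 1.0) > atol:
        raise ValueError("input must be unit norm")
    n = v.size
    angles = np.zeros(n - 1)
    # tail_norm[k] = ||v[k:]||
    tail = np.sqrt(np.cumsum(v[::-1] ** 2))[::-1]
    for k in range(n - 2):
        angles[k] = math.atan2(tail[k + 1], v[k])
    angles[n - 2] = math.atan2(v[n - 1], v[n - 2])
    return angles


def from_spherical(angles: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spherical`."""
    angles = np.asarray(angles, dtype=float).ravel()
    n = angles.size + 1
    v = np.empty(n)
    sin_prod = 1.0
    for k in range(n - 1):
        v[k] = sin_prod * math.cos(angles[k])
        sin_prod *= math.sin(angles[k])
    v[n - 1] = sin_prod
    return v


@dataclass
class BootstrapAxes:
    """Replicate unit axes from trial resampling, one row per replicate."""

    phi: np.ndarray      # (B, N)
    psi: np.ndarray      # (B, N)
    seed: Optional[int] = None
    n_resampled: int = 0  # replicates that needed a resample retry

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi replicate blocks must match in shape")
        if self.phi.shape[0] < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        norms = np.linalg.norm(np.vstack([self.phi, self.psi]), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("replicate axes must be unit norm")

    @property
    def n_replicates(self) -> int:
        return self.phi.shape[0]


def bootstrap_axes(
    trials: Sequence[np.ndarray],
    y_phi: np.ndarray,
    y_psi: np.ndarray,
    n_replicates: int = 100,
    seed: Optional[int] = None,
    max_retries: int = 10,
) -> BootstrapAxes:
    """Re-estimate both attribute axes from resampled trials.

    For each replicate, each stimulus's trials (rows of the per-stimulus
    feature matrices in ``trials``) are resampled with replacement at their
    original count and averaged into one observation; the exact regression
    is run for each attribute; the resulting unit axes are sign-aligned to
    the full-data axes before storage (antipodal axes are identical, and
    unaligned signs would corrupt downstream PCA).
    """
    trials = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    if any(t.shape[0] < 2 for t in trials):
        raise ValueError("every stimulus needs at least 2 trials")
    rng = np.random.default_rng(seed)

    def fit_axes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f_phi = core.fit(core.ObservationSet(X, y_phi))
        f_psi = core.fit(core.ObservationSet(X, y_psi))
        return f_phi.b_hat, f_psi.b_hat

    full_X = np.vstack([t.mean(axis=0) for t in trials])
    ref_phi, ref_psi = fit_axes(full_X)

    phi = np.empty((n_replicates, full_X.shape[1]))
    psi = np.empty((n_replicates, full_X.shape[1]))
    n_resampled = 0
    for b in range(n_replicates):
        for attempt in range(max_retries + 1):
            X = np.vstack([
                t[rng.integers(0, t.shape[0], size=t.shape[0])].mean(axis=0)
                for t in trials
            ])
            try:
                bp, bq = fit_axes(X)
                break
            except RankDeficiencyError:
                n_resampled += 1
                if attempt == max_retries:
                    raise
        phi[b] = bp if bp @ ref_phi >= 0 else -bp
        psi[b] = bq if bq @ ref_psi >= 0 else -bq
    return BootstrapAxes(phi=phi, psi=psi, seed=seed, n_resampled=n_resampled)


@dataclass
class ReliabilityResult:
    """PCA-LDA summary of the bootstrap axis clouds."""

    scores: np.ndarray               # (2B, 2) PC scores
    labels: np.ndarray               # (2B,) 0 = phi, 1 = psi
    variance_fraction: float         # variance explained by the first 2 PCs
    misclassifications: int
    separatrix: dict                 # {"w": [w1, w2], "b": b}: w.s + b = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": "reliability/1",
            "variance_fraction": self.variance_fraction,
            "misclassifications": int(self.misclassifications),
            "separatrix": self.separatrix,
            "scores": self.scores.tolist(),
            "labels": self.labels.tolist(),
        }


def reliability(boot: BootstrapAxes) -> ReliabilityResult:
    """PCA on spherical coordinates of all replicates, then 2D Fisher LDA.

    All 2B replicate axes are transformed to hyperspherical coordinates,
    centered (not scaled), and projected onto the first two principal
    components; a shared-covariance LDA on the 2D scores yields the
    separatrix and the misclassification count against the known labels.
    """
    all_axes = np.vstack([boot.phi, boot.psi])
    coords = np.vstack([to_spherical(v) for v in all_axes])
    if np.allclose(coords, coords[0], atol=1e-12):
        raise ValueError("degenerate bootstrap cloud: all replicates coincide")
    labels = np.concatenate([
        np.zeros(boot.n_replicates, dtype=int),
        np.ones(boot.n_replicates, dtype=int),
    ])
    pca = PCA(n_components=2)
    scores = pca.fit_transform(coords)
    variance_fraction = float(pca.explained_variance_ratio_.sum())
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(scores, labels)
    predicted = lda.predict(scores)
    misses = int((predicted != labels).sum())
    separatrix = {
        "w": lda.coef_[0].tolist(),
        "b": float(lda.intercept_[0]),
    }
    return ReliabilityResult(
        scores=scores, labels=labels,
        variance_fraction=variance_fraction,
        misclassifications=misses, separatrix=separatrix,
    )


def population_scalogram(
    axes_list: Sequence[np.ndarray], layout: WaveletLayout
) -> FeatureVector:
    """Root-sum-of-squares accumulation of axes across participants.

    Squares each axis component (its "energy" in the time-frequency slot),
    sums over participants, and takes the square root component-wise.
    """
    if len(axes_list) == 0:
        raise ValueError("need at least one axis")
    mat = np.vstack([np.asarray(a, dtype=float).ravel() for a in axes_list])
    if mat.shape[1] != layout.n_features:
        raise ValueError(
            f"axes have length {mat.shape[1]}, layout expects {layout.n_features}"
        )
    return FeatureVector(values=np.sqrt((mat ** 2).sum(axis=0)), layout=layout)
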