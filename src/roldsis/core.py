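"""Spanned-subspace exact regression for HDLSS data.

Given M observation vectors in an N-dimensional feature space (N >= M) and
one scalar attribute per observation, the regression constrains the solution
axis to the (M-1)-dimensional subspace spanned by the centered observations.
Within that subspace the problem is even-determined and is solved exactly:
the fitted affine functional interpolates every observation with zero
residual, and the fitted axis coincides with the minimum-norm exact solution
of the underdetermined least-squares problem.

There are no tunable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .exceptions import DimensionMismatchError, RankDeficiencyError, SingularSystemError

__all__ = [
    "ObservationSet",
    "RoldsisFit",
    "spanned_basis",
    "fit",
    "predict",
    "project_observation",
]

#: Relative tolerance on the smallest retained singular value; below this the
#: observations are declared collinear. Safe double-precision margin for M <= 10.
RANK_RTOL = 1e-10

SCHEMA_VERSION = "roldsis-fit/1"


@dataclass
class ObservationSet:
    """M feature vectors with their scalar attributes.

    Attributes
    ----------
    X
        (M, N) matrix of observations, one row per stimulus/observation.
    y
        (M,) vector of scalar attributes (e.g. VOT in ms, or a proportion).
    feature_layout
        Optional :class:`~roldsis.features.WaveletLayout` describing the
        columns of ``X``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_layout: Optional[Any] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        m, n = self.X.shape
        if m < 2:
            raise ValueError(f"need at least 2 observations, got {m}")
        if n < m:
            raise ValueError(f"need N >= M (HDLSS), got M={m}, N={n}")
        if self.y.shape != (m,):
            raise DimensionMismatchError(
                f"y has length {self.y.size}, expected {m}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class RoldsisFit:
    """Result of the exact spanned-subspace regression.

    ``b`` is the (unnormalized) solution axis, ``b_hat`` its unit version,
    ``a`` the intercept; ``m``, ``V``, ``Z``, ``d``, ``c`` are the internal
    quantities of the construction (observation mean, orthonormal basis of
    the spanned subspace, subspace coordinates of the observations, subspace
    coefficients, centered intercept).
    """

    m: np.ndarray
    V: np.ndarray
    Z: np.ndarray
    d: np.ndarray
    c: float
    b: np.ndarray
    b_hat: np.ndarray
    a: float
    feature_layout: Optional[Any] = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.b.size

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "m": self.m.tolist(),
            "V": self.V.tolist(),
            "Z": self.Z.tolist(),
            "d": self.d.tolist(),
            "c": self.c,
            "b": self.b.tolist(),
            "b_hat": self.b_hat.tolist(),
            "a": self.a,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "RoldsisFit":
        version = payload.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported fit schema: {version!r}")
        return cls(
            m=np.asarray(payload["m"], dtype=float),
            V=np.asarray(payload["V"], dtype=float),
            Z=np.asarray(payload["Z"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            c=float(payload["c"]),
            b=np.asarray(payload["b"], dtype=float),
            b_hat=np.asarray(payload["b_hat"], dtype=float),
            a=float(payload["a"]),
        )

    @classmethod
    def from_json(cls, path) -> "RoldsisFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def spanned_basis(
    X: np.ndarray, rtol: float = RANK_RTOL
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the subspace spanned by the centered rows of X.

    Computed by SVD of the row-centered matrix (better conditioned than a
    covariance eigendecomposition when N >> M). Column signs are fixed so
    the largest-magnitude entry of each basis vector is positive; the fitted
    axis is invariant to this convention.

    Returns
    -------
    m : (N,) row mean.
    V : (N, M-1) orthonormal basis, principal directions of the centered rows.

    Raises
    ------
    RankDeficiencyError
        If the (M-1)-th singular value is <= rtol times the largest one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_obs = X.shape[0]
    if n_obs < 2:
        raise ValueError("need at least 2 observations to span a subspace")
    m = X.mean(axis=0)
    Xc = X - m
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_obs - 1
    if s[k - 1] <= rtol * s[0]:
        raise RankDeficiencyError(
            f"centered observations are rank deficient: singular value "
            f"{k} is {s[k - 1]:.3e} <= {rtol:.0e} * {s[0]:.3e}; "
            "collinear or duplicated observations?"
        )
    V = Vt[:k].T
    # Deterministic sign convention: largest-|entry| of each column positive.
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    return m, V * signs


def fit(obs: ObservationSet) -> RoldsisFit:
    """Solve the even-determined regression exactly.

    The observations are projected onto the spanned subspace (coordinates
    z_i), the M x M linear system y_i = c + d'z_i is solved directly, and
    the axis is lifted back to feature space: b = V d, a = c - d'V'm.
    """
    m, V = spanned_basis(obs.X)
    Z = (obs.X - m) @ V  # (M, M-1)
    n_obs = obs.n_observations
    A = np.hstack([np.ones((n_obs, 1)), Z])  # (M, M)
    try:
        sol = np.linalg.solve(A, obs.y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise SingularSystemError(str(exc)) from exc
    c = float(sol[0])
    d = sol[1:]
    b = V @ d
    a = c - float(d @ (V.T @ m))
    norm = float(np.linalg.norm(b))
    if norm == 0.0:
        # Constant attribute: the axis direction is undefined; keep a zero
        # b_hat rather than fail, predictions are still exact (constant).
        b_hat = np.zeros_like(b)
    else:
        b_hat = b / norm
    return RoldsisFit(
        m=m, V=V, Z=Z, d=d, c=c, b=b, b_hat=b_hat, a=a,
        feature_layout=obs.feature_layout,
    )


def _check_vector(fit_: RoldsisFit, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (fit_.n_features,):
        raise DimensionMismatchError(
            f"expected vector of length {fit_.n_features}, got shape {x.shape}"
        )
    return x


def predict(fit_: RoldsisFit, x: np.ndarray) -> float:
    """Evaluate the affine functional a + b'x."""
    x = _check_vector(fit_, x)
    return float(fit_.a + fit_.b @ x)


def project_observation(fit_: RoldsisFit, x: np.ndarray) -> np.ndarray:
    """Project x onto the line through the observation mean along the unit axis.

    Returns m + b_hat * (b_hat' (x - m)). Idempotent; the result minus the
    mean is parallel to the axis.
    """
    x = _check_vector(fit_, x)
    return fit_.m + fit_.b_hat * float(fit_.b_hat @ (x - fit_.m))
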