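"""Psychometric sigmoid fitting and stimulus selection.

The identification curve is p(t) = 100 / (1 + exp(beta * (t - t0))) with t
the stimulus VOT in ms and p the response percentage. ``beta`` is stored
with the sign produced by the data (the printed form decreases in t for
beta > 0; real /ta/ responses increase with VOT, giving beta < 0), and all
derived quantities are orientation-invariant.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "IdentificationData",
    "PsychometricFit",
    "fit_psychometric",
    "select_stimuli",
    "max_slope",
    "SEPARATION_BETA_CAP",
]

#: |beta| above this (1/ms) is treated as perfect separation / divergence.
SEPARATION_BETA_CAP = 10.0


@dataclass
class IdentificationData:
    """Binary forced-choice responses indexed by stimulus VOT."""

    vot: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.vot = np.asarray(self.vot, dtype=float).ravel()
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.vot.shape != self.response.shape:
            raise ValueError("vot and response must have the same length")
        if not np.isin(self.response, (0.0, 1.0)).all():
            raise ValueError("responses must be binary (0/1)")

    @classmethod
    def from_csv(cls, path) -> "IdentificationData":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(vot=data["vot_ms"], response=data["response"])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("vot_ms,response\n")
            for t, r in zip(self.vot, self.response):
                fh.write(f"{t},{int(r)}\n")


@dataclass
class PsychometricFit:
    """Fitted sigmoid parameters.

    p(t0) = 50 by construction; ``separation`` flags perfect-separation /
    divergent fits whose slope is not meaningful.
    """

    beta: float            # 1/ms, sign as fitted
    t0: float              # ms, inflection point
    converged: bool = True
    separation: bool = False
    se_beta: float = math.nan
    se_t0: float = math.nan

    def probability(self, t) -> np.ndarray:
        """p(t) in percent."""
        t = np.asarray(t, dtype=float)
        return 100.0 / (1.0 + np.exp(self.beta * (t - self.t0)))

    def to_dict(self) -> dict:
        return {
            "schema_version": "psychometric-fit/1",
            "beta_per_ms": self.beta,
            "t0_ms": self.t0,
            "converged": self.converged,
            "separation": self.separation,
            "se_beta": self.se_beta,
            "se_t0": self.se_t0,
            "max_slope_pct_per_ms": max_slope(self),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def fit_psychometric(data: IdentificationData) -> PsychometricFit:
    """Maximum-likelihood logistic fit of the identification responses.

    Uses a standard binomial logit on (intercept, vot); the natural
    parameters map to the sigmoid form via beta = -theta1 and
    t0 = -theta0 / theta1. Perfect separation is reported through the
    ``separation`` flag instead of raising.
    """
    y = data.response
    if y.min() == y.max():
        raise ValueError("need both response classes to fit the sigmoid")
    design = sm.add_constant(data.vot)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
        theta0, theta1 = result.params
        converged = bool(result.mle_retvals.get("converged", True))
        cov = np.asarray(result.cov_params())
    except Exception:
        # Divergence (e.g. perfect separation raising inside the optimizer).
        return PsychometricFit(
            beta=-math.inf, t0=math.nan, converged=False, separation=True
        )
    beta = -float(theta1)
    if theta1 == 0:
        t0 = math.nan
    else:
        t0 = -float(theta0) / float(theta1)
    se_beta = float(np.sqrt(cov[1, 1]))
    # Delta method for t0 = -theta0/theta1.
    if theta1 != 0 and np.all(np.isfinite(cov)):
        grad = np.array([-1.0 / theta1, theta0 / theta1 ** 2])
        se_t0 = float(np.sqrt(grad @ cov @ grad))
    else:
        se_t0 = math.nan
    separation = (not converged) or abs(beta) > SEPARATION_BETA_CAP
    return PsychometricFit(
        beta=beta, t0=t0, converged=converged, separation=separation,
        se_beta=se_beta, se_t0=se_t0,
    )


def select_stimuli(
    fit: PsychometricFit, percents, continuum: tuple[float, float]
) -> np.ndarray:
    """VOT values at the requested response percentages.

    Inverts the sigmoid for 0 < p < 100; the asymptotic requests p = 0 and
    p = 100 map to the continuum endpoints, ordered consistently with the
    curve's orientation (the endpoint on the 0%-side of the curve is the
    one the sigmoid approaches as p -> 0).
    """
    percents = np.asarray(percents, dtype=float).ravel()
    if np.any((percents < 0) | (percents > 100)):
        raise ValueError("percents must lie in [0, 100]")
    lo, hi = float(continuum[0]), float(continuum[1])
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("continuum endpoints must be finite")
    if fit.beta == 0:
        raise ValueError("flat psychometric curve cannot be inverted")
    out = np.empty_like(percents)
    for i, p in enumerate(percents):
        if p == 0.0:
            # p -> 0 as t -> +inf for beta > 0, as t -> -inf for beta < 0.
            out[i] = hi if fit.beta > 0 else lo
        elif p == 100.0:
            out[i] = lo if fit.beta > 0 else hi
        else:
            out[i] = fit.t0 + math.log(100.0 / p - 1.0) / fit.beta
    return out


def max_slope(fit: PsychometricFit) -> float:
    """Maximal |dp/dt| of the sigmoid, attained at t0: (100/4)|beta| %/ms."""
    return 100.0 / 4.0 * abs(fit.beta)
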