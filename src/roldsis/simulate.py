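"""Synthetic ERP-like experiment generator with planted ground truth.

Builds a complete experiment — two planted unit axes at a controlled angle,
stimulus templates satisfying the affine attribute constraints exactly,
noisy trials at a calibrated raw-trial SNR, and simulated identification
responses — so every stage of the analysis pipeline can be tested for
recovery against known truth, with no external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .axes import angle_between
from .exceptions import RankDeficiencyError
from .psychometrics import IdentificationData

__all__ = [
    "SyntheticConfig",
    "SyntheticExperiment",
    "make_axes",
    "make_templates",
    "make_trials",
    "simulate_identification",
    "generate",
]

PSI_DEFAULT = (0.0, 0.05, 0.5, 0.95, 1.0)
CONTINUUM_MS = (-52.0, 16.0)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic experiment.

    ``snr_db`` is the raw-trial SNR target (template power over noise
    power); set ``noise_sd`` to override the calibration directly, or to
    0.0 for noiseless trials. ``beta``/``t0`` drive both the attribute
    placement and the simulated identification task.
    """

    n_features: int = 128
    n_stimuli: int = 5
    trials_per_stimulus: int = 200
    n_samples: int = 2048
    fs: float = 5000.0
    angle_deg: float = 60.0
    psi: tuple = PSI_DEFAULT
    phi: Optional[tuple] = None       # derived from (beta, t0) when None
    snr_db: float = -12.0
    noise_sd: Optional[float] = None  # overrides snr_db when set
    beta: float = 0.25                # |slope| of the identification sigmoid, 1/ms
    t0: float = -22.0                 # inflection VOT, ms
    template_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.angle_deg <= 90:
            raise ValueError("angle must be in [0, 90] degrees")
        if self.n_stimuli < 3:
            raise ValueError("need M >= 3 stimuli for two distinct axes")
        if self.n_features < self.n_stimuli:
            raise ValueError("need N >= M")
        if self.trials_per_stimulus < 1:
            raise ValueError("need at least one trial per stimulus")
        if len(self.psi) != self.n_stimuli:
            if tuple(self.psi) == PSI_DEFAULT:
                # Adapt the canonical 5-point design to other stimulus counts.
                self.psi = tuple(np.linspace(0.0, 1.0, self.n_stimuli))
            else:
                raise ValueError("psi must have one value per stimulus")

    def phi_values(self) -> np.ndarray:
        """Physical attributes: continuum endpoints plus sigmoid-derived interior."""
        if self.phi is not None:
            phi = np.asarray(self.phi, dtype=float)
            if phi.size != self.n_stimuli:
                raise ValueError("phi must have one value per stimulus")
            return phi
        lo, hi = CONTINUUM_MS
        psi = np.asarray(self.psi, dtype=float)
        phi = np.empty(psi.size)
        for i, p in enumerate(psi):
            pct = 100.0 * p
            if pct <= 0.0:
                phi[i] = lo
            elif pct >= 100.0:
                phi[i] = hi
            else:
                # increasing-orientation sigmoid: p = 100/(1+exp(-beta(t-t0)))
                phi[i] = self.t0 - math.log(100.0 / pct - 1.0) / abs(self.beta)
        return phi


@dataclass
class SyntheticExperiment:
    """Planted ground truth plus generated data."""

    config: SyntheticConfig
    b_phi: np.ndarray           # planted unit axis for the physical attribute
    b_psi: np.ndarray           # planted unit axis for the psychophysical one
    a_phi: float
    a_psi: float
    templates: np.ndarray       # (M, N) noiseless observations
    phi: np.ndarray             # (M,) physical attributes, ms
    psi: np.ndarray             # (M,) psychophysical attributes, proportion
    trials: list = field(default_factory=list)  # per stimulus (T, N) matrices
    noise_sd: np.ndarray = None  # per-stimulus noise sd actually used

    def truth_dict(self) -> dict:
        return {
            "schema_version": "synthetic-truth/1",
            "angle_deg": angle_between(self.b_phi, self.b_psi),
            "b_phi": self.b_phi.tolist(),
            "b_psi": self.b_psi.tolist(),
            "a_phi": self.a_phi,
            "a_psi": self.a_psi,
            "phi_ms": self.phi.tolist(),
            "psi": self.psi.tolist(),
            "noise_sd": np.asarray(self.noise_sd).tolist(),
            "seed": self.config.seed,
        }


def make_axes(
    n_features: int, angle_deg: float, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two random unit vectors separated by exactly ``angle_deg`` degrees."""
    if not 0 <= angle_deg <= 90:
        raise ValueError("angle must be in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    b1 = rng.standard_normal(n_features)
    b1 /= np.linalg.norm(b1)
    u = rng.standard_normal(n_features)
    u -= (u @ b1) * b1
    u /= np.linalg.norm(u)
    theta = math.radians(angle_deg)
    b2 = math.cos(theta) * b1 + math.sin(theta) * u
    return b1, b2


def make_templates(
    config: SyntheticConfig,
    axes: tuple[np.ndarray, np.ndarray],
    max_retries: int = 10,
) -> tuple[np.ndarray, float, float]:
    """Noiseless stimulus templates satisfying both affine constraints exactly.

    Templates live in an (M-1)-dimensional affine frame whose direction
    space contains both planted axes; within the frame, each template's two
    constrained coordinates solve phi_i = a_phi + b_phi'x_i and
    psi_i = a_psi + b_psi'x_i, and the remaining coordinates are random.
    Returns (templates, a_phi, a_psi).
    """
    b1, b2 = axes
    n = b1.size
    m = config.n_stimuli
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1
    )
    phi = config.phi_values()
    psi = np.asarray(config.psi, dtype=float)
    # Orthonormal frame Q containing span{b1, b2}.
    b2_perp = b2 - (b2 @ b1) * b1
    perp_norm = np.linalg.norm(b2_perp)
    if perp_norm < 1e-12 and not np.allclose(
        phi / (np.abs(phi).max() or 1), psi / (np.abs(psi).max() or 1)
    ):
        # Coincident axes can only carry affinely dependent attributes.
        if np.linalg.matrix_rank(np.column_stack(
            [np.ones(m), phi, psi]
        )) > 2:
            raise ValueError(
                "planted angle 0 is inconsistent with two independent attributes"
            )
    for attempt in range(max_retries):
        frame = [b1]
        if perp_norm >= 1e-12:
            frame.append(b2_perp / perp_norm)
        while len(frame) < m - 1:
            v = rng.standard_normal(n)
            for q in frame:
                v -= (v @ q) * q
            vn = np.linalg.norm(v)
            if vn > 1e-8:
                frame.append(v / vn)
        Q = np.column_stack(frame)  # (N, M-1)
        mean0 = rng.standard_normal(n) * config.template_scale
        a_phi = float(rng.standard_normal()) - float(b1 @ mean0)
        a_psi = float(rng.standard_normal()) - float(b2 @ mean0)
        u1 = Q.T @ b1  # unit (b1 in span Q)
        u2 = Q.T @ b2
        C = np.vstack([u1, u2])  # (2, M-1)
        rhs = np.vstack([phi - a_phi - b1 @ mean0, psi - a_psi - b2 @ mean0])
        # Minimum-norm particular solution plus a random null-space part.
        S_part = np.linalg.pinv(C) @ rhs  # (M-1, M)
        null = _null_space(C)
        coords = S_part + null @ (
            rng.standard_normal((null.shape[1], m)) * config.template_scale
        )
        if not np.allclose(C @ coords, rhs, atol=1e-8):
            raise ValueError(
                "attribute constraints are inconsistent with the planted axes"
            )
        templates = mean0 + (Q @ coords).T  # (M, N)
        centered = templates - templates.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[m - 2] > 1e-10 * s[0]:
            return templates, a_phi, a_psi
    raise RankDeficiencyError(
        "failed to draw full-rank templates after retries"
    )


def _null_space(C: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    _, s, Vt = np.linalg.svd(C)
    rank = int((s > rtol * s[0]).sum())
    return Vt[rank:].T


def make_trials(
    config: SyntheticConfig, templates: np.ndarray, rng: Optional[np.random.Generator] = None
) -> tuple[list, np.ndarray]:
    """Noisy trials per stimulus: template plus i.i.d. Gaussian feature noise.

    The per-stimulus noise sd is calibrated from that template's power so
    the per-trial SNR matches ``config.snr_db`` exactly in expectation,
    unless ``config.noise_sd`` overrides it. Averaging n trials then raises
    the SNR by 10 log10 n in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(
            None if config.seed is None else config.seed + 2
        )
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    sds = np.empty(templates.shape[0])
    trials = []
    for i, template in enumerate(templates):
        if config.noise_sd is not None:
            sd = float(config.noise_sd)
        else:
            power = float(np.var(template))
            sd = math.sqrt(power * 10.0 ** (-config.snr_db / 10.0))
        sds[i] = sd
        noise = rng.standard_normal(
            (config.trials_per_stimulus, templates.shape[1])
        ) * sd
        trials.append(template + noise)
    return trials, sds


def simulate_identification(
    beta: float,
    t0: float,
    vot_grid: np.ndarray,
    n_per_vot: int = 1,
    seed: Optional[int] = None,
) -> IdentificationData:
    """Bernoulli responses around the sigmoid, /ta/ increasing with VOT."""
    if n_per_vot < 1:
        raise ValueError("need at least one presentation per VOT")
    rng = np.random.default_rng(seed)
    vot_grid = np.asarray(vot_grid, dtype=float).ravel()
    vot = np.repeat(vot_grid, n_per_vot)
    p_ta = 1.0 / (1.0 + np.exp(-abs(beta) * (vot - t0)))
    response = (rng.random(vot.size) < p_ta).astype(float)
    return IdentificationData(vot=vot, response=response)


def generate(config: SyntheticConfig) -> SyntheticExperiment:
    """Full deterministic experiment from one config + seed."""
    b_phi, b_psi = make_axes(config.n_features, config.angle_deg, config.seed)
    templates, a_phi, a_psi = make_templates(config, (b_phi, b_psi))
    trials, sds = make_trials(config, templates)
    return SyntheticExperiment(
        config=config,
        b_phi=b_phi, b_psi=b_psi, a_phi=a_phi, a_psi=a_psi,
        templates=templates,
        phi=config.phi_values(),
        psi=np.asarray(config.psi, dtype=float),
        trials=trials,
        noise_sd=sds,
    )
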