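"""Denoising-based approximate message passing (D-AMP).

The outer loop alternates a matched-filter step q_t = x_t + Phi^T z_t, a
black-box denoise x_{t+1} = D_{sigma_t}(q_t), and a residual update with an
Onsager correction

    z_{t+1} = y - Phi x_{t+1} + z_t * div(D)/M,

where div(D) — the trace of the denoiser's Jacobian at q_t — is estimated
by Monte-Carlo probing (a SURE-style estimator).  The correction keeps the
effective noise in q_t approximately Gaussian across iterations, which is
what lets a Gaussian-noise denoiser be plugged in; its level is tracked by
sigma_hat_t = ||z_t||_2 / sqrt(M).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .denoising import DenoiseConfig, make_denoiser
from .exceptions import DimensionError, DivergenceError
from .metrics import prd
from .sensing import MeasurementOperator, Observation, Signal1D

__all__ = ["AMPState", "ReconConfig", "mc_divergence", "amp_step", "reconstruct"]

logger = logging.getLogger(__name__)

Denoiser = Callable[[np.ndarray, float], np.ndarray]


@dataclass(frozen=True)
class AMPState:
    """One AMP iterate: estimate, residual, and noise-level estimate."""

    x: np.ndarray
    z: np.ndarray
    sigma_hat: float
    iteration: int = 0


@dataclass(frozen=True)
class ReconConfig:
    """Outer-loop parameters.

    n_iterations : number of AMP iterations K (fixed; no early exit by
        default).
    denoiser_name : one of the registry names ("iwnnm", "wnnm", "identity").
    mc_probes : Monte-Carlo probes per divergence estimate (1 is the usual
        D-AMP practice; raise it for variance-sensitive checks).
    seed : base seed; iteration t uses seed + t for its probe draws.
    stop_tol : optional relative-change tolerance for early stopping
        (None = run all K iterations).
    """

    n_iterations: int = 30
    denoiser_name: str = "iwnnm"
    mc_probes: int = 1
    seed: int = 0
    denoise_cfg: DenoiseConfig = field(default_factory=DenoiseConfig)
    stop_tol: float | None = None

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mc_probes < 1:
            raise ValueError("mc_probes must be >= 1")


def mc_divergence(
    denoiser: Denoiser,
    q: np.ndarray,
    sigma: float,
    probes: int,
    seed: int,
    base: np.ndarray | None = None,
) -> float:
    """Monte-Carlo estimate of div D(q) = tr(dD/dq).

    Averages b^T (D(q + tau*b) - D(q)) / tau over ``probes`` standard
    normal draws b, with tau = ||q||_inf / 1000.  ``base`` may supply a
    precomputed D(q).  Deterministic given the seed.
    """
    q = np.asarray(q, dtype=float)
    tau = float(np.max(np.abs(q))) / 1000.0
    if tau == 0.0:
        tau = 1e-6
        logger.warning("mc_divergence: all-zero input, falling back to tau=%g", tau)
    rng = np.random.default_rng(seed)
    if base is None:
        base = denoiser(q, sigma)
    total = 0.0
    for _ in range(probes):
        b = rng.standard_normal(q.size)
        total += float(b @ (denoiser(q + tau * b, sigma) - base)) / tau
    return total / probes


def amp_step(
    state: AMPState,
    y: np.ndarray,
    phi: MeasurementOperator,
    denoiser: Denoiser,
    cfg: ReconConfig,
) -> AMPState:
    """One D-AMP iteration (matched filter, denoise, Onsager-corrected residual)."""
    mat = phi.matrix
    m, n = mat.shape
    if state.x.size != n or state.z.size != m or np.asarray(y).size != m:
        raise DimensionError("AMP state dimensions do not match the operator")
    q = state.x + mat.T @ state.z
    x_new = denoiser(q, state.sigma_hat)
    probe_seed = (cfg.seed + state.iteration) % 2**31
    div = mc_divergence(denoiser, q, state.sigma_hat, cfg.mc_probes, probe_seed, base=x_new)
    z_new = y - mat @ x_new + state.z * (div / m)
    if not (np.all(np.isfinite(x_new)) and np.all(np.isfinite(z_new))):
        raise DivergenceError(state.iteration)
    sigma_new = float(np.linalg.norm(z_new) / np.sqrt(m))
    return AMPState(x=x_new, z=z_new, sigma_hat=sigma_new, iteration=state.iteration + 1)


def reconstruct(
    obs: Observation,
    phi: MeasurementOperator,
    cfg: ReconConfig,
    reference: Signal1D | None = None,
) -> tuple[Signal1D, list[AMPState], list[float] | None]:
    """Run K D-AMP iterations from x_0 = 0, z_0 = y.

    Returns the final estimate, the per-iteration states (including the
    initial one), and — when a ground-truth ``reference`` is supplied — the
    per-iteration PRD trajectory of the estimates x_1 .. x_K.
    """
    mat = phi.matrix
    m, n = mat.shape
    y = obs.y
    if y.size != m:
        raise DimensionError(f"observation length {y.size} != operator M={m}")
    if reference is not None and len(reference) != n:
        raise DimensionError("reference length does not match operator N")
    denoiser = make_denoiser(cfg.denoiser_name, cfg.denoise_cfg)
    state = AMPState(
        x=np.zeros(n), z=y.copy(), sigma_hat=float(np.linalg.norm(y) / np.sqrt(m)),
        iteration=0,
    )
    states = [state]
    traj: list[float] | None = [] if reference is not None else None
    for _ in range(cfg.n_iterations):
        prev = state
        state = amp_step(state, y, phi, denoiser, cfg)
        states.append(state)
        if traj is not None:
            traj.append(prd(reference.samples, state.x))
            logger.info(
                "iteration=%d sigma_hat=%.6g prd=%.6g",
                state.iteration, state.sigma_hat, traj[-1],
            )
        else:
            logger.info("iteration=%d sigma_hat=%.6g", state.iteration, state.sigma_hat)
        if cfg.stop_tol is not None:
            denom = np.linalg.norm(prev.x)
            if denom > 0 and np.linalg.norm(state.x - prev.x) / denom < cfg.stop_tol:
                break
    fs = reference.sampling_rate_hz if reference is not None else 1.0
    return Signal1D(samples=state.x, sampling_rate_hz=fs), states, traj
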