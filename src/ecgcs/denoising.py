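"""Weighted nuclear norm denoising of patch groups, with rank-weighted
aggregation (IWNNM) or plain averaging (WNNM).

Each group Q (d x g, columns are similar blocks) is denoised by weighted
singular value shrinkage: the clean singular values are estimated as

    sigma_x_j = sqrt(max(sigma_q_j^2 - g * sigma_n^2, 0)),

each gets a weight inversely proportional to its magnitude,

    w_j = c * g^p * sigma_n^2 / (sigma_x_j + eps),      (default p = 1)

and the shrunk matrix is A = U max(Sigma - w, 0) V^T.  Large (signal)
singular values are barely touched; small (noise) ones are removed.  The
sigma_n^2 factor is the convention of the original weighted nuclear norm
minimization literature and makes the shrinkage vanish as the noise does;
a literal noise-free weight c * g^p / (sigma_x + eps) is available via
``noise_scaled_weights=False``.

Overlapping block estimates are then averaged back into a signal.  In
``rank_weighted`` mode each group's estimates carry the weight
exp(-rank/block_len): groups whose post-shrinkage rank is high — the
signature of dissimilar blocks having been matched together under noise —
contribute less.  ``uniform`` mode is the classic equal-weight average.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .exceptions import CoverageError
from .patches import PatchConfig, PatchGroup, build_groups, group_member_indices

__all__ = [
    "ShrinkageParams",
    "DenoisedGroup",
    "DenoiseConfig",
    "singular_value_estimates",
    "singular_weights",
    "weighted_svt",
    "aggregate",
    "denoise",
    "make_denoiser",
    "DENOISERS",
]


@dataclass(frozen=True)
class ShrinkageParams:
    """Singular-value shrinkage constants.

    c : weight scale; the default 2*sqrt(2) follows the weighted nuclear
        norm image-denoising literature.
    eps : guard against division by zero in the weights.
    noise_sigma : std of the noise the group is assumed to carry (set per
        AMP iteration to the running estimate sigma_hat_t).
    d_power : exponent on the group size in the weight numerator; the
        default 1 gives the linear c*g scale, which is what makes the
        shrinkage strong enough to keep the AMP Onsager gain below one at
        the default 32x16 group geometry (0.5 gives the sqrt convention).
    noise_scaled_weights : include the sigma_n^2 factor in the weights
        (literature convention); False gives the bare c*g^p/(sigma_x+eps).
    sqrt_correction : estimate clean singular values with the square root
        (dimensionally consistent); False keeps the raw variance clamp.
    """

    c: float = 2.0 * math.sqrt(2.0)
    eps: float = 1e-16
    noise_sigma: float = 0.0
    d_power: float = 1.0
    noise_scaled_weights: bool = True
    sqrt_correction: bool = True

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class DenoisedGroup:
    """A shrunk group matrix with its retained rank and aggregation weight."""

    matrix: np.ndarray
    rank: int
    group_weight: float

    def __post_init__(self):
        if self.rank < 0 or self.rank > min(self.matrix.shape):
            raise ValueError("rank must lie in [0, min(d, g)]")
        if not (0.0 < self.group_weight <= 1.0):
            raise ValueError("group_weight must lie in (0, 1]")


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the full block-matching denoiser.

    inner_iters : number of regularized denoising passes per call.
    delta : relaxation of the regularization step
        q_t = xhat_{t-1} + delta*(q - xhat_{t-1}).
    aggregation : "rank_weighted" (IWNNM) or "uniform" (WNNM).
    """

    inner_iters: int = 1
    delta: float = 0.1
    aggregation: str = "rank_weighted"
    shrinkage: ShrinkageParams = field(default_factory=ShrinkageParams)
    patch: PatchConfig = field(default_factory=PatchConfig)

    def __post_init__(self):
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")
        if self.aggregation not in ("uniform", "rank_weighted"):
            raise ValueError("aggregation must be 'uniform' or 'rank_weighted'")


def singular_value_estimates(
    sigmas_q: np.ndarray, noise_sigma: float, d: int, sqrt_correction: bool = True
) -> np.ndarray:
    """Estimate clean singular values from the noisy group's.

    Subtracts the expected noise energy d*sigma_n^2 from each squared
    singular value and clamps at zero; with ``sqrt_correction`` the square
    root restores the amplitude scale.
    """
    s = np.asarray(sigmas_q, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    out = np.maximum(s**2 - d * noise_sigma**2, 0.0)
    return np.sqrt(out) if sqrt_correction else out


def singular_weights(sigmas_x: np.ndarray, params: ShrinkageParams, d: int) -> np.ndarray:
    """Per-singular-value shrinkage weights, inverse in the clean magnitude."""
    s = np.asarray(sigmas_x, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    scale = params.c * d**params.d_power
    if params.noise_scaled_weights:
        scale *= params.noise_sigma**2
    return scale / (s + params.eps)


def _rank_tol(shape: tuple[int, ...], s: np.ndarray) -> float:
    """Numerical-rank floor (same convention as matrix_rank): values below
    max(d, g) * eps * s_max are counted as zero."""
    return max(shape) * np.finfo(float).eps * (float(s.max()) if s.size else 0.0)


def weighted_svt(group: PatchGroup, params: ShrinkageParams) -> DenoisedGroup:
    """Weighted singular value thresholding of one patch group.

    Q = U Sigma V^T; each singular value is reduced by its weight and
    clamped at zero; the retained count is the group's rank and sets the
    aggregation weight exp(-rank/block_len).
    """
    mat = group.matrix
    if not np.all(np.isfinite(mat)):
        raise ValueError("group matrix must be finite")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    g = mat.shape[1]
    s_x = singular_value_estimates(s, params.noise_sigma, g, params.sqrt_correction)
    w = singular_weights(s_x, params, g)
    s_new = np.maximum(s - w, 0.0)
    rank = int(np.count_nonzero(s_new > _rank_tol(mat.shape, s_new)))
    denoised = (u * s_new) @ vt
    weight = math.exp(-rank / group.block_len)
    return DenoisedGroup(matrix=denoised, rank=rank, group_weight=weight)


def aggregate(
    groups: Sequence[DenoisedGroup],
    member_starts: Sequence[np.ndarray],
    n_samples: int,
    mode: str = "rank_weighted",
) -> np.ndarray:
    """Weighted per-sample average of all overlapping block estimates.

    Every sample's estimates are combined with weights that are 1 in
    ``uniform`` mode and the group's exp(-rank/block_len) in
    ``rank_weighted`` mode, normalized per sample so weights sum to one.
    """
    if mode not in ("uniform", "rank_weighted"):
        raise ValueError("mode must be 'uniform' or 'rank_weighted'")
    num = np.zeros(n_samples)
    den = np.zeros(n_samples)
    for grp, starts in zip(groups, member_starts):
        d = grp.matrix.shape[0]
        w = grp.group_weight if mode == "rank_weighted" else 1.0
        idx = (np.asarray(starts, dtype=int)[:, None] + np.arange(d)[None, :]).ravel()
        np.add.at(num, idx, w * grp.matrix.T.ravel())
        np.add.at(den, idx, w)
    if np.any(den == 0):
        missing = int(np.flatnonzero(den == 0)[0])
        raise CoverageError(f"sample {missing} not covered by any block estimate")
    return num / den


def _denoise_pass(q: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    """One grouping + shrinkage + aggregation pass (vectorized when possible)."""
    params = cfg.shrinkage
    if cfg.patch.threshold is None:
        try:
            return _denoise_pass_fast(q, cfg)
        except ValueError:
            pass
    groups = build_groups(q, cfg.patch)
    den = [weighted_svt(g, params) for g in groups]
    starts = [g.member_starts for g in groups]
    return aggregate(den, starts, q.size, cfg.aggregation)


def _denoise_pass_fast(q: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    """Batched implementation of the pass for the uniform-grid case."""
    params = cfg.shrinkage
    starts, members = group_member_indices(q, cfg.patch)
    d = cfg.patch.block_len
    blocks = q[starts[:, None] + np.arange(d)[None, :]]  # r x d
    gmats = blocks[members].transpose(0, 2, 1)  # r x d x g
    u, s, vt = np.linalg.svd(gmats, full_matrices=False)
    g = gmats.shape[2]
    s_x = singular_value_estimates(s, params.noise_sigma, g, params.sqrt_correction)
    w = singular_weights(s_x, params, g)
    s_new = np.maximum(s - w, 0.0)
    tol = max(gmats.shape[1:]) * np.finfo(float).eps * s_new.max(axis=1, keepdims=True)
    ranks = np.count_nonzero(s_new > tol, axis=1)
    denoised = np.einsum("rik,rk,rkj->rij", u, s_new, vt)  # r x d x g
    if cfg.aggregation == "rank_weighted":
        gw = np.exp(-ranks / d)
    else:
        gw = np.ones(len(ranks))
    pos = (starts[members][:, :, None] + np.arange(d)[None, None, :]).ravel()
    vals = denoised.transpose(0, 2, 1).ravel()  # r x g x d order, matching pos
    wts = np.repeat(gw, g * d)
    num = np.bincount(pos, weights=wts * vals, minlength=q.size)
    den = np.bincount(pos, weights=wts, minlength=q.size)
    if np.any(den == 0):
        missing = int(np.flatnonzero(den == 0)[0])
        raise CoverageError(f"sample {missing} not covered by any block estimate")
    return num / den


def denoise(q: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    """Full denoiser: ``inner_iters`` regularized passes over the signal.

    Starting from xhat = q, each pass regularizes
    q_t = xhat + delta*(q - xhat) and replaces xhat with the denoised q_t.
    With the default single pass this denoises q directly.
    """
    q = np.asarray(q, dtype=float)
    if q.size < cfg.patch.block_len:
        raise ValueError("signal shorter than block_len")
    xhat = q
    for _ in range(cfg.inner_iters):
        qt = xhat + cfg.delta * (q - xhat)
        xhat = _denoise_pass(qt, cfg)
    return xhat


def make_denoiser(name: str, cfg: DenoiseConfig) -> Callable[[np.ndarray, float], np.ndarray]:
    """Bind a named denoiser to a config, as a (signal, sigma) -> signal map.

    ``sigma`` overrides the config's shrinkage noise level at call time,
    which is how the AMP loop feeds its per-iteration noise estimate in.
    """
    if name == "identity":
        return lambda q, sigma: np.asarray(q, dtype=float)
    if name not in ("wnnm", "iwnnm"):
        raise KeyError(f"unknown denoiser '{name}'; choose from {sorted(DENOISERS)}")
    agg = "uniform" if name == "wnnm" else "rank_weighted"
    base = replace(cfg, aggregation=agg)

    def _denoiser(q: np.ndarray, sigma: float) -> np.ndarray:
        c = replace(base, shrinkage=replace(base.shrinkage, noise_sigma=float(sigma)))
        return denoise(q, c)

    return _denoiser


DENOISERS = {"identity": "pass-through", "wnnm": "uniform averaging", "iwnnm": "rank-weighted averaging"}
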