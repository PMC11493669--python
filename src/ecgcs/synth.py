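"""Synthetic quasi-periodic ECG signals and low-rank group fixtures.

The generator sums five Gaussian bumps per beat (P, Q, R, S, T waves at
fixed offsets relative to the R peak), repeats beats at the configured
heart rate with optional beat-to-beat period and amplitude jitter, and adds
a slow sinusoidal baseline wander.  This reproduces the one property the
block-matching denoiser relies on — repeated morphology across beats
(non-local self-similarity) — without attempting clinical realism.

Defaults mirror a 360 Hz arrhythmia-database recording: at 75 bpm the beat
period is exactly 288 samples, so zero-jitter signals are periodic on the
sample grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import PatchGroup
from .sensing import Signal1D

__all__ = ["EcgSynthParams", "WAVE_TABLE", "synth_ecg", "synth_lowrank_group"]

# (offset_s, width_s, relative amplitude) for the P, Q, R, S, T waves,
# relative to the R peak (amplitude 1.0 before per-beat jitter).
WAVE_TABLE = (
    (-0.20, 0.040, 0.15),
    (-0.03, 0.012, -0.12),
    (0.00, 0.016, 1.00),
    (0.03, 0.012, -0.25),
    (0.30, 0.060, 0.30),
)

_WANDER_FREQ_HZ = 0.3


@dataclass(frozen=True)
class EcgSynthParams:
    """Synthetic ECG parameters.

    duration_s defaults to 1024/360 s so the default record is 1024
    samples at the 360 Hz default rate.
    """

    duration_s: float = 1024.0 / 360.0
    fs_hz: float = 360.0
    heart_rate_bpm: float = 75.0
    rr_jitter_frac: float = 0.05
    amplitude_jitter_frac: float = 0.10
    baseline_wander_amp: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs_hz <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("duration, sampling rate and heart rate must be positive")
        if self.fs_hz * self.duration_s < 64:
            raise ValueError("signal must be at least 64 samples long")
        if not (0 <= self.rr_jitter_frac < 0.5):
            raise ValueError("rr_jitter_frac must lie in [0, 0.5)")
        if not (0 <= self.amplitude_jitter_frac < 0.5):
            raise ValueError("amplitude_jitter_frac must lie in [0, 0.5)")
        if self.baseline_wander_amp < 0:
            raise ValueError("baseline_wander_amp must be nonnegative")


def synth_ecg(params: EcgSynthParams) -> Signal1D:
    """Generate a quasi-periodic ECG-like trace; deterministic under seed."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fs_hz * params.duration_s))
    t = np.arange(n) / params.fs_hz
    period = 60.0 / params.heart_rate_bpm

    # Beat centers cover a margin beyond the record so edges carry partial
    # beats exactly as interior samples would see them.
    margin = 2.0 * period
    centers = []
    amps = []
    c = -margin
    while c < params.duration_s + margin:
        centers.append(c)
        amps.append(1.0 + rng.uniform(-1, 1) * params.amplitude_jitter_frac)
        c += period * (1.0 + rng.uniform(-1, 1) * params.rr_jitter_frac)

    x = np.zeros(n)
    for c, a in zip(centers, amps):
        for off, width, amp in WAVE_TABLE:
            x += a * amp * np.exp(-((t - c - off) ** 2) / (2.0 * width**2))
    if params.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += params.baseline_wander_amp * np.sin(2 * np.pi * _WANDER_FREQ_HZ * t + phase)
    return Signal1D(samples=x, sampling_rate_hz=params.fs_hz)


def synth_lowrank_group(
    block_len: int, group_size: int, rank: int, noise_sigma: float, seed: int
) -> tuple[PatchGroup, np.ndarray]:
    """A d x g group of exactly known rank, plus its clean ground truth.

    The clean matrix is U diag(s) V^T with orthonormal random factors and
    singular values 1, 1/2, 1/4, ... (spaced by factor 2); i.i.d. Gaussian
    noise of std ``noise_sigma`` is added on top.  Returns
    ``(group, clean)``.
    """
    if rank < 1 or rank > min(block_len, group_size):
        raise ValueError("rank must lie in [1, min(block_len, group_size)]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    u, _ = np.linalg.qr(rng.standard_normal((block_len, rank)))
    v, _ = np.linalg.qr(rng.standard_normal((group_size, rank)))
    s = 0.5 ** np.arange(rank)
    clean = (u * s) @ v.T
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma else clean.copy()
    group = PatchGroup(
        matrix=noisy,
        member_starts=np.arange(group_size) * block_len,
        reference_start=0,
    )
    return group, clean
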