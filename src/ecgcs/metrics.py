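"""Reconstruction quality metrics: CR, PRD, RMSE, SNR, P-SNR.

PRD (percentage root-mean-squared difference) is the standard distortion
measure in ECG compression: 100 * ||xhat - x|| / ||x||.  SNR and PRD are
algebraically linked (SNR = -20 log10(PRD/100)), as are RMSE and PRD;
these identities double as the module's self-checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError

__all__ = [
    "MetricsReport",
    "compression_ratio",
    "prd",
    "rmse",
    "snr_db",
    "psnr_db",
    "evaluate",
]


@dataclass(frozen=True)
class MetricsReport:
    """All metrics for one (reference, estimate) pair.

    ``cr`` is None when the measurement count is unknown (metrics computed
    on two stored signals without their sensing context).
    """

    prd_percent: float
    rmse: float
    snr_db: float
    psnr_db: float
    cr: float | None = None

    def to_dict(self) -> dict:
        return {
            "cr": self.cr,
            "prd_percent": self.prd_percent,
            "rmse": self.rmse,
            "snr_db": self.snr_db,
            "psnr_db": self.psnr_db,
        }


def _check_pair(x, xhat) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape or x.ndim != 1:
        raise DimensionError("signals must be 1-D and the same length")
    return x, xhat


def compression_ratio(n_samples: int, n_measurements: int) -> float:
    """CR = N / M."""
    if n_samples <= 0 or n_measurements <= 0:
        raise ValueError("n_samples and n_measurements must be positive")
    return n_samples / n_measurements


def prd(x, xhat) -> float:
    """Percentage root-mean-squared difference, 100 * ||xhat - x|| / ||x||."""
    x, xhat = _check_pair(x, xhat)
    ref = np.linalg.norm(x)
    if ref == 0:
        raise ValueError("reference signal has zero norm")
    return float(100.0 * np.linalg.norm(xhat - x) / ref)


def rmse(x, xhat) -> float:
    """Root mean square error, ||xhat - x|| / sqrt(N)."""
    x, xhat = _check_pair(x, xhat)
    return float(np.linalg.norm(xhat - x) / np.sqrt(x.size))


def snr_db(x, xhat) -> float:
    """10 log10(||x||^2 / ||x - xhat||^2); +inf for exact equality."""
    x, xhat = _check_pair(x, xhat)
    err = np.linalg.norm(x - xhat) ** 2
    if err == 0:
        return math.inf
    return float(10.0 * np.log10(np.linalg.norm(x) ** 2 / err))


def psnr_db(x, xhat, abs_peak: bool = False) -> float:
    """10 log10(max(x)^2 * N / ||x - xhat||^2); +inf for exact equality.

    The peak is the reference's maximum; ``abs_peak`` switches to
    max(|x|) for signals whose dominant excursion is negative.
    """
    x, xhat = _check_pair(x, xhat)
    peak = float(np.max(np.abs(x)) if abs_peak else np.max(x))
    if peak == 0:
        raise ValueError("reference peak is zero; P-SNR undefined")
    err = np.linalg.norm(x - xhat) ** 2
    if err == 0:
        return math.inf
    return float(10.0 * np.log10(peak**2 * x.size / err))


def evaluate(
    x, xhat, n_measurements: int | None = None, abs_peak: bool = False
) -> MetricsReport:
    """All metrics for one pair, with CR when the measurement count is known."""
    x, xhat = _check_pair(x, xhat)
    cr = compression_ratio(x.size, n_measurements) if n_measurements else None
    return MetricsReport(
        prd_percent=prd(x, xhat),
        rmse=rmse(x, xhat),
        snr_db=snr_db(x, xhat),
        psnr_db=psnr_db(x, xhat, abs_peak=abs_peak),
        cr=cr,
    )
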