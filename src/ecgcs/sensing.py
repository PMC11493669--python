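"""Compressive measurement model: y = Phi x, with optional measurement noise.

The sensing matrix is i.i.d. Gaussian with variance 1/M so that column
squared-norms are ~1 in expectation — the scaling under which AMP's
state-evolution heuristics hold.  Seeds are explicit everywhere; there is
no global random state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError

__all__ = [
    "Signal1D",
    "MeasurementOperator",
    "Observation",
    "make_gaussian_operator",
    "make_orthonormal_operator",
    "compress",
    "add_measurement_noise",
    "snr_db_to_sigma",
]


@dataclass(frozen=True)
class Signal1D:
    """A real-valued sampled trace.

    Parameters
    ----------
    samples
        The signal values, length N >= 1, all finite.
    sampling_rate_hz
        Sampling rate in Hz (informational; defaults to 1.0).
    """

    samples: np.ndarray
    sampling_rate_hz: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a 1-D vector of length >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class MeasurementOperator:
    """The M x N sensing matrix Phi.

    ``seed`` records how the matrix was generated (-1 for matrices supplied
    directly rather than drawn from the Gaussian ensemble).
    """

    matrix: np.ndarray
    seed: int = -1
    ensemble: str = "custom"

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise DimensionError("operator matrix must be 2-D")
        m, n = mat.shape
        if m < 1 or m > n:
            raise DimensionError(f"need 1 <= M <= N, got M={m}, N={n}")
        if not np.all(np.isfinite(mat)):
            raise ValueError("operator entries must be finite")
        object.__setattr__(self, "matrix", mat)

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def ref(self) -> str:
        """Identifier string used by Observation.operator_ref."""
        return f"{self.ensemble}-n{self.n_samples}-m{self.n_measurements}-seed{self.seed}"


@dataclass(frozen=True)
class Observation:
    """A measurement vector y with provenance.

    ``noise_sigma`` is the standard deviation of measurement noise that was
    added to y (0 for a noiseless observation).
    """

    y: np.ndarray
    noise_sigma: float = 0.0
    operator_ref: str = ""

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1 or y.size < 1:
            raise ValueError("y must be a 1-D vector")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.y.size


def make_gaussian_operator(n_samples: int, n_measurements: int, seed: int) -> MeasurementOperator:
    """Draw an M x N sensing matrix with i.i.d. N(0, 1/M) entries.

    Deterministic given ``seed``.  Column squared-norms are 1 in expectation,
    so ||Phi x|| ~ ||x|| for generic x.
    """
    if n_samples < 1 or n_measurements < 1:
        raise ValueError("n_samples and n_measurements must be positive")
    if n_measurements > n_samples:
        raise DimensionError(
            f"n_measurements ({n_measurements}) must not exceed n_samples ({n_samples})"
        )
    rng = np.random.default_rng(seed)
    mat = rng.normal(0.0, 1.0 / np.sqrt(n_measurements), size=(n_measurements, n_samples))
    return MeasurementOperator(matrix=mat, seed=seed, ensemble="gaussian")


def make_orthonormal_operator(n_samples: int, seed: int) -> MeasurementOperator:
    """A square orthonormal sensing matrix (Phi^T Phi = I), for sanity checks.

    With M = N and an orthonormal Phi the inverse problem is exactly solvable
    in one AMP step with the identity denoiser.
    """
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n_samples, n_samples)))
    return MeasurementOperator(matrix=q, seed=seed, ensemble="orthonormal")


def compress(x: Signal1D, phi: MeasurementOperator) -> Observation:
    """Project a signal to the measurement domain: y = Phi x (noiseless)."""
    if len(x) != phi.n_samples:
        raise DimensionError(
            f"signal length {len(x)} does not match operator N={phi.n_samples}"
        )
    return Observation(y=phi.matrix @ x.samples, noise_sigma=0.0, operator_ref=phi.ref)


def add_measurement_noise(obs: Observation, sigma: float, seed: int) -> Observation:
    """Add i.i.d. N(0, sigma^2) noise to an observation; deterministic under seed."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return Observation(y=obs.y.copy(), noise_sigma=0.0, operator_ref=obs.operator_ref)
    rng = np.random.default_rng(seed)
    noisy = obs.y + rng.normal(0.0, sigma, size=len(obs))
    return Observation(y=noisy, noise_sigma=sigma, operator_ref=obs.operator_ref)


def snr_db_to_sigma(y: np.ndarray, snr_db: float) -> float:
    """Noise std giving the requested measurement SNR (dB) for this y.

    SNR = 10 log10(mean(y^2) / sigma^2), so sigma = rms(y) * 10^(-SNR/20).
    """
    y = np.asarray(y, dtype=float)
    rms = float(np.sqrt(np.mean(y**2)))
    if rms == 0:
        raise ValueError("cannot set an SNR relative to an all-zero observation")
    return rms * 10.0 ** (-snr_db / 20.0)
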