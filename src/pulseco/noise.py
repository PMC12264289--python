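"""Measurement-artefact corruption of model-input vectors.

Two noise sources emulate tonometric acquisition artefacts on the
150-point waveform vector x: additive Gaussian noise n_i ~ N(μ, σ²)
at every point, plus random spikes r_i ~ U(−A, A) with amplitude
A = 10% of the signal maximum, added at a random subset I of 20% of
the points:

    x̃_i = x_i + n_i + r_i   for i ∈ I
    x̃_i = x_i + n_i         otherwise

Defaults for the Gaussian term are (μ = 0.7, σ = 1.0) mmHg for
calibrated signals and (μ = 0, σ = 0.1) for unit-range normalized
signals.  Corrupted vectors are *not* re-normalized, so noisy
uncalibrated values may leave [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError
from .preprocessing import VECTOR_LENGTH, WaveVector


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian-plus-spike corruption parameters (signal units)."""

    gaussian_mean: float = 0.0
    gaussian_sd: float = 0.0
    spike_fraction: float = 0.2
    spike_relative_amplitude: float = 0.1

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be ≥ 0")
        if not 0 <= self.spike_fraction <= 1:
            raise ConfigurationError("spike_fraction must lie in [0, 1]")
        if self.spike_relative_amplitude < 0:
            raise ConfigurationError("spike_relative_amplitude must be ≥ 0")


#: Defaults used in the noisy experiment conditions.
CALIBRATED_NOISE = NoiseConfig(gaussian_mean=0.7, gaussian_sd=1.0)
UNCALIBRATED_NOISE = NoiseConfig(gaussian_mean=0.0, gaussian_sd=0.1)


def spike_count(cfg: NoiseConfig, n: int = VECTOR_LENGTH) -> int:
    """Number of spiked indices: ``round(spike_fraction × n)``."""
    return int(round(cfg.spike_fraction * n))


def inject_noise(
    vec: WaveVector, cfg: NoiseConfig, rng: np.random.Generator
) -> WaveVector:
    """Corrupt one wave vector; deterministic given the generator state."""
    noisy, _, _ = inject_noise_with_draws(vec.values, cfg, rng)
    return replace(vec, values=noisy)


def inject_noise_with_draws(
    values: np.ndarray, cfg: NoiseConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """As :func:`inject_noise`, also returning the Gaussian draws and
    the spiked index set (for decomposability checks)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    gauss = rng.normal(cfg.gaussian_mean, cfg.gaussian_sd, size=n)
    k = spike_count(cfg, n)
    idx = rng.choice(n, size=k, replace=False) if k else np.empty(0, dtype=int)
    amp = cfg.spike_relative_amplitude * float(np.max(x))
    spikes = np.zeros(n)
    if k:
        spikes[idx] = rng.uniform(-amp, amp, size=k)
    return x + gauss + spikes, gauss, np.sort(idx)


def corrupt_matrix(
    X: np.ndarray, cfg: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt every row of a (n_subjects, 150) matrix, fresh draws per row."""
    out = np.empty_like(X, dtype=float)
    for i in range(X.shape[0]):
        out[i], _, _ = inject_noise_with_draws(X[i], cfg, rng)
    return out
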