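"""Fixed-length model-input vectors from single-cycle pressure waveforms.

Every cardiac cycle, whatever its duration or native sampling, is
linearly interpolated onto 150 uniformly spaced points spanning the
cycle (half-open grid ``t_j = j·T/150``), which deliberately discards
absolute timing.  Amplitude normalization rescales a vector to unit
range, ``(P − P_min)/(P_max − P_min)``, producing the "uncalibrated"
representation that retains only waveform shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateWaveformError, DomainError
from .population import PressureWaveform, VirtualSubject

#: Fixed model-input length.
VECTOR_LENGTH = 150


@dataclass(frozen=True)
class WaveVector:
    """Fixed-length (150-point) model-input representation of one cycle."""

    values: np.ndarray
    calibrated: bool
    site: str
    subject_id: int = -1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != VECTOR_LENGTH:
            raise DomainError(f"wave vector must have exactly {VECTOR_LENGTH} values")
        if not np.all(np.isfinite(v)):
            raise DomainError("wave vector values must be finite")
        object.__setattr__(self, "values", v)


def resample_to_fixed_length(wave: PressureWaveform, n: int = VECTOR_LENGTH) -> WaveVector:
    """Resample one cycle onto ``n`` uniform time points (calibrated).

    Piecewise-linear interpolation on the half-open grid ``j·T/n``; the
    cycle is closed periodically so grid points beyond the last native
    sample interpolate toward the cycle start.
    """
    t = np.asarray(wave.time, dtype=float)
    p = np.asarray(wave.pressure, dtype=float)
    if t.size < 2:
        raise DomainError("waveform must contain at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise DomainError("waveform time base must be strictly increasing")
    if n != VECTOR_LENGTH:
        raise DomainError(f"model input length is fixed at {VECTOR_LENGTH}")
    grid = np.arange(n) * (wave.period / n)
    # periodic closure: value at t = period equals value at t = 0
    t_ext = np.concatenate([t, [wave.period]])
    p_ext = np.concatenate([p, [p[0]]])
    values = np.interp(grid, t_ext, p_ext)
    return WaveVector(values=values, calibrated=True, site=wave.site)


def normalize_amplitude(vec: WaveVector) -> WaveVector:
    """Rescale to unit range: ``(v − min)/(max − min)`` (uncalibrated)."""
    v = vec.values
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi - lo <= 0:
        raise DegenerateWaveformError("constant waveform has zero amplitude range")
    return replace(vec, values=(v - lo) / (hi - lo), calibrated=False)


def cohort_matrix(
    pop: list[VirtualSubject], site: str, calibrated: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack one site's wave vectors for a whole cohort.

    Returns ``(X, y, subject_ids)`` where ``X`` is (n_subjects, 150)
    and ``y`` the ground-truth cardiac output in L/min.
    """
    xs, ys, ids = [], [], []
    for s in pop:
        vec = resample_to_fixed_length(s.waveforms[site])
        if not calibrated:
            vec = normalize_amplitude(vec)
        xs.append(vec.values)
        ys.append(s.params.cardiac_output)
        ids.append(s.id)
    return np.array(xs), np.array(ys), np.array(ids)


def matrix_frame(X: np.ndarray, ids: np.ndarray, site: str, calibrated: bool):
    """CSV-ready frame: metadata columns + one column per grid point."""
    import pandas as pd

    df = pd.DataFrame(X, columns=[f"p{j:03d}" for j in range(X.shape[1])])
    df.insert(0, "subject_id", ids)
    df.insert(1, "site", site)
    df.insert(2, "calibrated", calibrated)
    return df
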