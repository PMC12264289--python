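"""Method-comparison statistics for cardiac-output estimates.

For each model condition the predicted and reference CO series are
summarized by Pearson's r, RMSE, the range-normalized nRMSE
(``100 × RMSE/(y_max − y_min)`` over the *reference* range), MAE,
Bland–Altman bias and 95% limits of agreement (bias ± 1.96 × sample SD
of the differences), and the ordinary-least-squares regression of
predictions on references (slope, intercept, and the two-sided p-value
of the slope-vs-zero t-test).

Between-condition comparisons use the paired t-test on Fisher
z-transformed correlation coefficients; between-site variability is
expressed as the coefficient of variation (sample SD / mean, %).

The difference sign convention is d = predicted − reference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError

#: Bland–Altman limits-of-agreement multiplier (95% interval).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementReport:
    """Agreement statistics for one model condition (units: L/min)."""

    r: float
    rmse: float
    nrmse: float  # percent of reference range
    mae: float
    bias: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    slope_p: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(pred, ref) -> AgreementReport:
    """Full agreement report of predictions against reference values."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise DomainError("pred and ref must be 1-D arrays of equal length")
    n = pred.size
    if n < 3:
        raise DomainError("need at least 3 paired values")
    y_range = float(np.max(ref) - np.min(ref))
    if y_range <= 0:
        raise DomainError("constant reference: nRMSE undefined")
    d = pred - ref
    rmse = float(np.sqrt(np.mean(d**2)))
    bias = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    lm = stats.linregress(ref, pred)
    return AgreementReport(
        r=float(stats.pearsonr(pred, ref)[0]),
        rmse=rmse,
        nrmse=100.0 * rmse / y_range,
        mae=float(np.mean(np.abs(d))),
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd_d,
        loa_high=bias + LOA_MULTIPLIER * sd_d,
        slope=float(lm.slope),
        intercept=float(lm.intercept),
        slope_p=float(lm.pvalue),
        n=int(n),
    )


def fisher_z_paired_test(r_a, r_b) -> tuple[float, float]:
    """Paired t-test on Fisher z-transformed correlation pairs.

    Returns ``(t, p)`` (two-sided).  Requires |r| < 1 for every entry.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape or r_a.size < 2:
        raise DomainError("need two equal-length lists of ≥ 2 correlations")
    if np.any(np.abs(r_a) >= 1) or np.any(np.abs(r_b) >= 1):
        raise DomainError("|r| = 1 cannot be z-transformed")
    diff = np.arctanh(r_a) - np.arctanh(r_b)
    if np.all(diff == 0):  # identical lists: no evidence of a difference
        return 0.0, 1.0
    t, p = stats.ttest_rel(np.arctanh(r_a), np.arctanh(r_b))
    return float(t), float(p)


def coefficient_of_variation(values) -> float:
    """Relative variability in percent: 100 × sample SD (n−1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("need at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise DomainError("zero mean: CoV undefined")
    return 100.0 * float(np.std(v, ddof=1)) / mean
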