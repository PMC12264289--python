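"""Recovering the cohort's subpopulation structure from (CO, MAP).

A two-component Gaussian mixture with full covariances is fitted by
expectation-maximization to the (cardiac output, mean aortic pressure)
plane; the component with the higher CO mean is labelled hyperdynamic.
Group differences are then screened with Shapiro–Wilk normality tests
and compared with the two-sided Mann–Whitney U test.

The EM loop is written out explicitly (rather than delegated) so that
the log-likelihood trajectory is available and its monotonicity can be
asserted; scikit-learn's mixture model serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError
from .population import HYPERDYNAMIC, NORMODYNAMIC, VirtualSubject


@dataclass(frozen=True)
class GmmFit:
    """Result of the two-component EM fit on (CO, MAP) points."""

    weights: np.ndarray          # (2,), sum to 1
    means: np.ndarray            # (2, 2): [CO L/min, MAP mmHg]
    covariances: np.ndarray      # (2, 2, 2), symmetric positive-definite
    responsibilities: np.ndarray  # (n, 2)
    labels: np.ndarray           # (n,), 1 = hyperdynamic component
    log_likelihood: float
    log_likelihood_history: np.ndarray
    n_iter: int

    @property
    def hyperdynamic_component(self) -> int:
        """Index of the component with the higher CO mean (always 1)."""
        return 1


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = np.linalg.solve(chol, (x - mean).T)
    maha = np.sum(diff**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _regularize(cov: np.ndarray) -> np.ndarray:
    if np.linalg.det(cov) < 1e-12:
        cov = cov + 1e-6 * np.trace(cov) * np.eye(cov.shape[0])
    if np.linalg.det(cov) <= 0:
        raise DomainError("degenerate covariance: GMM fit failed")
    return cov


def _kmeans_init(x: np.ndarray, rng: np.random.Generator, n_iter: int = 10) -> np.ndarray:
    """Lloyd iterations from two random distinct points; returns labels."""
    idx = rng.choice(len(x), size=2, replace=False)
    centers = x[idx].copy()
    labels = np.zeros(len(x), dtype=int)
    for _ in range(n_iter):
        d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        labels = d.argmin(axis=1)
        for k in (0, 1):
            if np.any(labels == k):
                centers[k] = x[labels == k].mean(axis=0)
    return labels


def _em_once(
    x: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    n, d = x.shape
    labels = _kmeans_init(x, rng)
    resp = np.zeros((n, 2))
    resp[np.arange(n), labels] = 1.0
    resp = np.clip(resp, 1e-6, None)
    resp /= resp.sum(axis=1, keepdims=True)
    ll_hist = []
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        covs = np.empty((2, d, d))
        for k in (0, 1):
            diff = x - means[k]
            covs[k] = _regularize((resp[:, k, None] * diff).T @ diff / nk[k])
        # E step
        log_prob = np.column_stack(
            [np.log(weights[k]) + _log_gauss(x, means[k], covs[k]) for k in (0, 1)]
        )
        log_norm = np.logaddexp(log_prob[:, 0], log_prob[:, 1])
        resp = np.exp(log_prob - log_norm[:, None])
        ll = float(log_norm.sum())
        ll_hist.append(ll)
        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll
    return weights, means, covs, resp, np.array(ll_hist), it


def fit_two_component_gmm(
    points: np.ndarray,
    rng: np.random.Generator | int | None = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> GmmFit:
    """Fit the two-component full-covariance mixture by EM.

    ``points`` is (n, 2) with columns (CO, MAP).  The best of
    ``n_restarts`` seeded k-means-style initializations (by final
    log-likelihood) is kept; components are ordered so that index 1 is
    the higher-CO (hyperdynamic) one.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 4:
        raise DomainError("need at least 4 (CO, MAP) points")
    if not np.all(np.isfinite(x)):
        raise DomainError("points must be finite")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    best = None
    for _ in range(n_restarts):
        weights, means, covs, resp, ll_hist, it = _em_once(x, rng, max_iter, tol)
        if best is None or ll_hist[-1] > best[4][-1]:
            best = (weights, means, covs, resp, ll_hist, it)
    weights, means, covs, resp, ll_hist, it = best
    order = np.argsort(means[:, 0])  # ascending CO mean: 1 = hyperdynamic
    weights, means, covs, resp = weights[order], means[order], covs[order], resp[:, order]
    labels = resp.argmax(axis=1)
    return GmmFit(
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=resp,
        labels=labels,
        log_likelihood=float(ll_hist[-1]),
        log_likelihood_history=ll_hist,
        n_iter=it,
    )


def points_from_population(pop: list[VirtualSubject]) -> np.ndarray:
    """(CO, cycle-averaged aortic pressure) pairs for the GMM."""
    from .population import SITE_AORTA

    return np.array(
        [[s.params.cardiac_output, s.waveforms[SITE_AORTA].mean] for s in pop]
    )


def label_agreement(fit: GmmFit, true_groups: np.ndarray) -> float:
    """Fraction of points whose mixture label matches the planted group."""
    truth = (np.asarray(true_groups) == HYPERDYNAMIC).astype(int)
    return float(np.mean(fit.labels == truth))


def group_difference_tests(
    values: dict[str, np.ndarray], labels: np.ndarray
) -> pd.DataFrame:
    """Shapiro–Wilk per group/variable plus Mann–Whitney U between groups.

    ``values`` maps variable names (e.g. ``cardiac_output``,
    ``mean_aortic_pressure``) to per-subject arrays; ``labels`` is 0/1
    (0 = normodynamic).  The Mann–Whitney test is two-sided with the
    normal approximation and tie correction.
    """
    labels = np.asarray(labels)
    rows = []
    for name, v in values.items():
        v = np.asarray(v, dtype=float)
        g0, g1 = v[labels == 0], v[labels == 1]
        if len(g0) < 3 or len(g1) < 3:
            raise DomainError("each group needs at least 3 values")
        for gname, g in ((NORMODYNAMIC, g0), (HYPERDYNAMIC, g1)):
            w, p = stats.shapiro(g)
            rows.append(
                {"variable": name, "test": "shapiro_wilk", "group": gname,
                 "statistic": float(w), "p_value": float(p)}
            )
        u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic")
        rows.append(
            {"variable": name, "test": "mann_whitney_u", "group": "between",
             "statistic": float(u), "p_value": float(p)}
        )
    df = pd.DataFrame(rows)
    df["significant_0.05"] = df["p_value"] < 0.05
    return df
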