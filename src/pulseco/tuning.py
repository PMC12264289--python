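"""Data splitting, cross-validated scoring and hyperparameter search.

The cohort is divided 60/20/20 into train/validation/test, stratified
by hemodynamic group so both subpopulations are proportionally
represented in every partition.  Hyperparameters are selected by
sequential model-based (Bayesian) optimization: a Gaussian-process
surrogate with expected-improvement acquisition proposes trial
configurations, each scored by the mean validation MSE over a
stratified 5-fold cross-validation of the train+validation pool.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cnn import CNNRegressor, ModelHyperparameters
from .exceptions import ConfigurationError, DomainError

# ---------------------------------------------------------------------------
# stratified 60/20/20 split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive train/validation/test subject indices."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    labels: np.ndarray  # stratification label per subject (original order)

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise DomainError("split partitions overlap")
        if len(all_idx) != len(self.labels):
            raise DomainError("split partitions must be exhaustive")


def stratified_split(
    n: int,
    labels,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified train/val/test split with rounded ratio sizes.

    With n = 3818 and the default ratios the sizes are 2290/764/764.
    Degenerate ratios of the form (1, 0, 0) put every subject in the
    train partition (with a warning); other zero ratios are rejected.
    """
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ConfigurationError("labels must cover all subjects")
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must be non-negative and sum to 1")
    idx = np.arange(n)
    if ratios[1] == 0 and ratios[2] == 0:
        warnings.warn("degenerate split: all subjects assigned to train")
        empty = np.empty(0, dtype=int)
        return SplitAssignment(idx, empty, empty, labels)
    if ratios[1] == 0 or ratios[2] == 0:
        raise ConfigurationError("only the (1, 0, 0) degenerate split is supported")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise ConfigurationError("every stratum needs at least 3 subjects")
    n_test = int(round(ratios[2] * n))
    n_val = int(round(ratios[1] * n))
    trainval, test = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=labels
    )
    train, val = train_test_split(
        trainval, test_size=n_val, random_state=seed, stratify=labels[trainval]
    )
    return SplitAssignment(np.sort(train), np.sort(val), np.sort(test), labels)


# ---------------------------------------------------------------------------
# search space and encoding
# ---------------------------------------------------------------------------


def default_search_space() -> dict:
    """Default hyperparameter search space.

    learning_rate log-uniform [1e-4, 1e-2]; batch_size {16, 32, 64};
    n_filters {8, 16, 32, 64}; kernel_size {3, 5, 7, 9}; dropout_rate
    uniform [0.1, 0.5]; dense_units {16, 32, 64, 128}.
    """
    return {
        "learning_rate": ("log", 1e-4, 1e-2),
        "batch_size": ("choice", [16, 32, 64]),
        "n_filters": ("choice", [8, 16, 32, 64]),
        "kernel_size": ("choice", [3, 5, 7, 9]),
        "dropout_rate": ("uniform", 0.1, 0.5),
        "dense_units": ("choice", [16, 32, 64, 128]),
    }


def _decode(u: np.ndarray, space: dict, base: ModelHyperparameters) -> ModelHyperparameters:
    """Map a unit-cube point to a concrete hyperparameter set."""
    kw = {}
    for ui, (name, spec) in zip(u, space.items()):
        kind = spec[0]
        if kind == "log":
            lo, hi = spec[1], spec[2]
            kw[name] = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        elif kind == "uniform":
            lo, hi = spec[1], spec[2]
            kw[name] = float(lo + ui * (hi - lo))
        elif kind == "choice":
            opts = spec[1]
            kw[name] = opts[min(int(ui * len(opts)), len(opts) - 1)]
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown space kind {kind!r}")
    return dataclasses.replace(base, **kw)


# ---------------------------------------------------------------------------
# cross-validated scoring and GP-EI search
# ---------------------------------------------------------------------------


def cross_val_mse(
    x: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    h: ModelHyperparameters,
    seed: int = 0,
    n_folds: int = 5,
) -> float:
    """Mean validation MSE over a stratified k-fold CV.

    Every point is validated exactly once; each fold trains a fresh
    model with early stopping against the fold's validation part.
    """
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = []
    for fold, (tr, va) in enumerate(skf.split(x, labels)):
        model = CNNRegressor(h, seed=seed + fold)
        model.fit(x[tr], y[tr], x[va], y[va], seed=seed + 100 + fold)
        pred = model.predict(x[va])
        losses.append(float(np.mean((pred - y[va]) ** 2)))
    return float(np.mean(losses))


def tune_hyperparameters(
    x: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    space: dict | None = None,
    n_trials: int = 20,
    seed: int = 0,
    base: ModelHyperparameters | None = None,
    n_folds: int = 5,
) -> tuple[ModelHyperparameters, list[dict]]:
    """Bayesian hyperparameter search with 5-fold stratified CV scoring.

    A Matern-5/2 Gaussian process fitted to (encoded configuration,
    CV loss) pairs proposes each post-warmup trial by maximizing
    expected improvement over random candidate points.  Returns the
    best configuration and the full trial log.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be ≥ 1")
    if len(x) < 50:
        raise ConfigurationError("need at least 50 subjects for tuning")
    space = default_search_space() if space is None else space
    if not space:
        raise ConfigurationError("search space must be non-empty")
    base = base or ModelHyperparameters()
    rng = np.random.default_rng(seed)
    dim = len(space)
    n_warmup = max(1, min(n_trials, (n_trials + 2) // 3))
    us, losses, log = [], [], []
    for trial in range(n_trials):
        if trial < n_warmup:
            u = rng.random(dim)
        else:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(nu=2.5, length_scale=0.3),
                normalize_y=True,
                alpha=1e-4,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.array(us), np.array(losses))
            cand = rng.random((256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best_loss = min(losses)
            z = (best_loss - mu) / np.clip(sd, 1e-9, None)
            ei = (best_loss - mu) * _norm_cdf(z) + sd * _norm_pdf(z)
            u = cand[int(np.argmax(ei))]
        h = _decode(u, space, base)
        loss = cross_val_mse(x, y, labels, h, seed=seed, n_folds=n_folds)
        us.append(u)
        losses.append(loss)
        log.append({"trial": trial, "cv_mse": loss, "hyperparameters": dataclasses.asdict(h)})
    best = int(np.argmin(losses))
    return _decode(us[best], space, base), log


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)


def _norm_pdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
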