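"""AOA-driven hyperparameter search for the LS-SVM.

The optimizer explores the kernel hyperparameters on a log10 scale (C for the
linear kernel; C and gamma for the RBF kernel) and minimizes the stratified
k-fold cross-validated misclassification percentage

    error = 100 * (misclassified samples) / (total samples)

pooled over the held-out folds.  Fold assignment is seeded independently of
the optimizer, so changing the search seed never changes the folds.  The
winning parameters are refit on the full data set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import aoa
from .lssvm import KernelSpec, LSSVMModel, fit_lssvm, predict

logger = logging.getLogger(__name__)

__all__ = ["SearchSpace", "TuneResult", "decode_position", "encode_position",
           "cv_error_rate", "tune"]


@dataclass(frozen=True)
class SearchSpace:
    """Log10 box for the kernel hyperparameters."""

    kernel: str = "rbf"
    log10_C: tuple[float, float] = (-2.0, 4.0)
    log10_gamma: tuple[float, float] = (-4.0, 2.0)

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        for name, (lo, hi) in (("log10_C", self.log10_C), ("log10_gamma", self.log10_gamma)):
            if lo >= hi:
                raise ValueError(f"{name} interval must satisfy lo < hi")

    @property
    def dim(self) -> int:
        return 1 if self.kernel == "linear" else 2

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.kernel == "linear":
            return np.array([self.log10_C[0]]), np.array([self.log10_C[1]])
        return (np.array([self.log10_C[0], self.log10_gamma[0]]),
                np.array([self.log10_C[1], self.log10_gamma[1]]))


def decode_position(x: np.ndarray, space: SearchSpace) -> tuple[float, float | None]:
    """Search-space vector -> (C, gamma); gamma is None for the linear kernel."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if x.size != space.dim:
        raise ValueError(f"position has {x.size} dims; {space.kernel} kernel needs {space.dim}")
    C = float(10.0 ** x[0])
    gamma = float(10.0 ** x[1]) if space.kernel == "rbf" else None
    return C, gamma


def encode_position(C: float, gamma: float | None, space: SearchSpace) -> np.ndarray:
    """Inverse of :func:`decode_position`."""
    if space.kernel == "linear":
        return np.array([np.log10(C)])
    return np.array([np.log10(C), np.log10(gamma)])


def cv_error_rate(C: float, gamma: float | None, X: np.ndarray, y: np.ndarray,
                  k_folds: int = 5, seed: int = 0,
                  kernel: str | None = None) -> float:
    """Pooled stratified k-fold misclassification percentage in [0, 100]."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"a class has only {counts.min()} samples, fewer than k_folds={k_folds}; "
            "use a smaller k"
        )
    if kernel is None:
        kernel = "linear" if gamma is None else "rbf"
    spec = KernelSpec(kernel, gamma if kernel == "rbf" else None)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    n_wrong = 0
    for train_idx, test_idx in skf.split(X, y):
        model = fit_lssvm(X[train_idx], y[train_idx], C, spec)
        n_wrong += int(np.sum(predict(model, X[test_idx]) != y[test_idx]))
    return 100.0 * n_wrong / X.shape[0]


@dataclass
class TuneResult:
    """Outcome of a search: winning parameters, CV error and final refit."""

    best_C: float
    best_gamma: float | None
    best_cv_error: float
    final_model: LSSVMModel
    aoa_history: list[float] = field(default_factory=list)
    n_fitness_evaluations: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "best_C": self.best_C,
                "best_gamma": self.best_gamma,
                "best_cv_error_percent": self.best_cv_error,
                "aoa_history": self.aoa_history,
                "n_fitness_evaluations": self.n_fitness_evaluations,
            }, fh, indent=2)


def tune(X: np.ndarray, y: np.ndarray, space: SearchSpace = SearchSpace(),
         n_objects: int = 20, tmax: int = 30, k_folds: int = 5,
         seed: int = 0, aoa_seed: int | None = None) -> TuneResult:
    """Minimize the CV error over the search space with the AOA.

    ``seed`` fixes the CV folds; ``aoa_seed`` (default ``seed + 1``) drives
    the optimizer, so the two sources of randomness stay independent.
    Fitness values are cached on the decoded parameters (rounded to 1e-9) to
    avoid redundant refits within a run.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("tuning requires exactly two classes")
    lower, upper = space.bounds()
    cfg = aoa.AOAConfig(lower=lower, upper=upper, n_objects=n_objects,
                        tmax=tmax, seed=seed + 1 if aoa_seed is None else aoa_seed)
    cache: dict[tuple, float] = {}

    def fitness(pos: np.ndarray) -> float:
        C, gamma = decode_position(pos, space)
        key = (round(C, 9), None if gamma is None else round(gamma, 9))
        if key not in cache:
            try:
                cache[key] = cv_error_rate(C, gamma, X, y, k_folds=k_folds,
                                           seed=seed, kernel=space.kernel)
            except ValueError:
                cache[key] = 100.0  # ill-conditioned fit counts as total error
        return cache[key]

    result = aoa.optimize(fitness, cfg)
    best_C, best_gamma = decode_position(result.best_x, space)
    spec = KernelSpec(space.kernel, best_gamma if space.kernel == "rbf" else None)
    final_model = fit_lssvm(X, y, best_C, spec)
    logger.info("tuned C=%.4g gamma=%s cv_error=%.3f%% (%d unique fitness evals)",
                best_C, best_gamma, result.best_fitness, len(cache))
    return TuneResult(best_C=best_C, best_gamma=best_gamma,
                      best_cv_error=float(result.best_fitness),
                      final_model=final_model, aoa_history=result.history,
                      n_fitness_evaluations=result.n_evaluations)
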