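"""Epsilon-insensitive support vector regression with an RBF kernel.

The decision function is f(x) = sum_i beta_i k(x_i, x) + b with dual
coefficients beta_i = alpha_hat_i - alpha_i bounded by the box
|beta_i| <= C, where the alphas solve the standard epsilon-SVR dual.
Production fitting is delegated to scikit-learn (libsvm); the kernel and
decision function are evaluated by this module's own code, and
:func:`fit_svr_qp` solves the dense dual directly — it serves as the exact
oracle the solver is checked against in the test suite.

Defaults (gamma 0.1, C 1000, epsilon 0.1 on standardized data) match the
tracking models' configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize
from sklearn.svm import SVR as _SkSVR

__all__ = ["SVRConfig", "SVRModel", "rbf_kernel", "kernel_matrix",
           "fit_svr", "fit_svr_qp", "predict_svr"]


@dataclass(frozen=True)
class SVRConfig:
    """Kernel and regularization settings.

    ``kernel`` is "rbf" (k(u,v) = exp(-gamma ||u-v||^2)) or "linear"
    (k(u,v) = u.v, kept for oracle tests against the plain inner-product
    decision function).  ``tol`` is the solver's numerical stopping
    tolerance, not a model parameter.
    """

    kernel: str = "rbf"
    gamma: float = 0.1
    C: float = 1000.0
    epsilon: float = 0.1
    tol: float = 1e-3

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.gamma <= 0 or self.C <= 0 or self.epsilon < 0:
            raise ValueError("gamma > 0, C > 0, epsilon >= 0 required")


@dataclass
class SVRModel:
    """Fitted model: support vectors, dual coefficients and bias."""

    support_vectors: np.ndarray   # (m_sv, W)
    dual_coef: np.ndarray         # (m_sv,) beta_i = alpha_hat_i - alpha_i
    intercept: float
    config: SVRConfig

    def __post_init__(self):
        self.support_vectors = np.atleast_2d(
            np.asarray(self.support_vectors, dtype=float))
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()
        if np.any(np.abs(self.dual_coef) > self.config.C * (1 + 1e-8)):
            raise ValueError("|dual coefficients| must not exceed C")


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||u - v||^2); equals 1 iff u == v."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    return float(np.exp(-gamma * np.sum((u - v) ** 2)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, config: SVRConfig
                  ) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch")
    if config.kernel == "linear":
        return X @ Y.T
    sq = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Y ** 2, axis=1)[None, :]
          - 2.0 * X @ Y.T)
    return np.exp(-config.gamma * np.maximum(sq, 0.0))


def fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig | None = None
            ) -> SVRModel:
    """Fit epsilon-SVR (libsvm backend) and wrap the solution."""
    config = config or SVRConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) == 0 or len(X) != len(y):
        raise ValueError("need >= 1 sample with matching targets")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite data")
    sk = _SkSVR(kernel=config.kernel, gamma=config.gamma, C=config.C,
                epsilon=config.epsilon, tol=config.tol, cache_size=200)
    sk.fit(X, y)
    return SVRModel(support_vectors=sk.support_vectors_.copy(),
                    dual_coef=sk.dual_coef_.ravel().copy(),
                    intercept=float(sk.intercept_[0]),
                    config=config)


def predict_svr(model: SVRModel, X: np.ndarray) -> np.ndarray | float:
    """Evaluate f(x) = sum_i beta_i k(x_i, x) + b."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xm = np.atleast_2d(X)
    if model.dual_coef.size == 0:
        out = np.full(len(Xm), model.intercept)
    else:
        K = kernel_matrix(Xm, model.support_vectors, model.config)
        out = K @ model.dual_coef + model.intercept
    return float(out[0]) if single else out


def fit_svr_qp(X: np.ndarray, y: np.ndarray, config: SVRConfig | None = None,
               gtol: float = 1e-10) -> SVRModel:
    """Exact dense solve of the epsilon-SVR dual (small instances only).

    Minimizes 0.5 beta' K beta - y' beta + epsilon (alpha + alpha_hat) over
    alpha, alpha_hat in [0, C]^m with sum(beta) = 0, beta = alpha_hat -
    alpha, using trust-region constrained optimization with analytic
    gradient and Hessian.  Intended as ground truth for <= ~30 points.
    """
    config = config or SVRConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = len(X)
    if m == 0 or m != len(y):
        raise ValueError("need >= 1 sample with matching targets")
    K = kernel_matrix(X, X, config)
    eps, C = config.epsilon, config.C

    def beta_of(z):
        return z[:m] - z[m:]  # alpha_hat - alpha

    def objective(z):
        b = beta_of(z)
        return 0.5 * b @ K @ b - y @ b + eps * z.sum()

    def grad(z):
        g = K @ beta_of(z) - y
        return np.concatenate([g + eps, -g + eps])

    def hess(z):
        Hm = np.block([[K, -K], [-K, K]])
        return Hm

    A = np.concatenate([np.ones(m), -np.ones(m)])
    res = minimize(objective, np.zeros(2 * m), jac=grad, hess=hess,
                   method="trust-constr",
                   bounds=[(0.0, C)] * (2 * m),
                   constraints=[LinearConstraint(A, 0.0, 0.0)],
                   options={"gtol": gtol, "xtol": 1e-14, "maxiter": 3000})
    alpha_hat, alpha = res.x[:m], res.x[m:]
    beta = alpha_hat - alpha
    # clean tiny numerical residue so support vectors are well defined;
    # the cutoff scales with the solution, not with C
    scale = max(float(np.abs(beta).max()), 1e-12)
    beta[np.abs(beta) < 1e-5 * scale] = 0.0
    g = K @ beta  # decision values without bias

    # Bias from KKT: free support vectors pin f(x_i) to y_i -/+ epsilon;
    # otherwise intersect the feasibility intervals of all points.
    free_pos = (beta > 1e-6 * C) & (beta < C * (1 - 1e-6))
    free_neg = (beta < -1e-6 * C) & (beta > -C * (1 - 1e-6))
    pins = np.concatenate([y[free_pos] - eps - g[free_pos],
                           y[free_neg] + eps - g[free_neg]])
    if pins.size:
        b = float(np.median(pins))
    else:
        lo, hi = -np.inf, np.inf
        for i in range(m):
            if beta[i] >= C * (1 - 1e-6):
                hi = min(hi, y[i] - eps - g[i])
            elif beta[i] <= -C * (1 - 1e-6):
                lo = max(lo, y[i] + eps - g[i])
            else:
                lo = max(lo, y[i] - eps - g[i])
                hi = min(hi, y[i] + eps - g[i])
        if not np.isfinite(lo):
            lo = hi
        if not np.isfinite(hi):
            hi = lo
        b = float((lo + hi) / 2.0) if np.isfinite(lo) else 0.0

    keep = beta != 0.0
    return SVRModel(support_vectors=X[keep], dual_coef=beta[keep],
                    intercept=b, config=config)


def dual_objective(model: SVRModel, X: np.ndarray, y: np.ndarray) -> float:
    """Dual objective of a fitted model, in the minimization form
    0.5 beta' K beta - y' beta + epsilon sum|beta| (smaller is better).

    Support vectors are matched back to training rows by value; ``X``/``y``
    must be the set the model was fitted on.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    used: set[int] = set()
    idx = []
    for sv in model.support_vectors:
        for j in range(len(X)):
            if j not in used and np.allclose(X[j], sv):
                idx.append(j)
                used.add(j)
                break
    beta = model.dual_coef
    Ksv = kernel_matrix(model.support_vectors, model.support_vectors,
                        model.config)
    y_sv = y[np.array(idx, dtype=int)] if idx else np.empty(0)
    return float(0.5 * beta @ Ksv @ beta - y_sv @ beta
                 + model.config.epsilon * np.sum(np.abs(beta)))
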