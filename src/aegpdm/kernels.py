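"""Gaussian process regression foundation: kernels, Gram matrices, exact GPR.

Kernels are composable covariance functions.  The two composites used by the
dynamical model are

    kX(x, x') = a1 exp(-a2/2 ||x - x'||^2) + a3 + a4 x.x' + d_{x,x'} a5
    kY(x, x') = b1 exp(-b2/2 ||x - x'||^2) + d_{x,x'} b3

(squared-exponential + constant + linear + white noise for the latent
transition map, squared-exponential + white noise for the decoder), and the
encoder uses an ARD squared-exponential with per-feature lengthscales.  The
Kronecker delta d_{x,x'} is an *index* identity: the white-noise term
contributes only when a point is evaluated against itself in a Gram
diagonal, modelling independent per-observation noise.

Exact GPR follows the standard zero-mean construction: with training inputs
Z, targets T and noise variance s2, the log marginal likelihood is

    log p(T|Z) = -1/2 T'(K+s2 I)^{-1} T - 1/2 log|K+s2 I| - N/2 log 2pi

and the predictive distribution at x* has mean k*'(K+s2 I)^{-1} T and
variance k** - k*'(K+s2 I)^{-1} k* + s2.  All positive hyperparameters are
exposed in natural scale but intended to be optimized in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Kernel",
    "SquaredExponential",
    "ARDSquaredExponential",
    "Constant",
    "Linear",
    "WhiteNoise",
    "Sum",
    "transition_kernel",
    "decoder_kernel",
    "kernel_eval",
    "gram_matrix",
    "GPRegressor",
    "log_marginal_likelihood",
    "gp_predict",
]

#: Relative jitter added to the Gram diagonal before factorization.
JITTER = 1e-8


def _check_positive(**params: float) -> None:
    for name, v in params.items():
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"kernel hyperparameter {name!r} must be strictly positive")


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


class Kernel:
    """Base covariance function.

    Subclasses implement :meth:`cross` for distinct index sets; the white
    noise contribution on coinciding indices is handled by :meth:`gram` and
    the ``same_index`` flag of :func:`kernel_eval`.
    """

    def cross(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def diag_extra(self) -> float:
        """White-noise variance contributed only on Gram diagonals."""
        return 0.0

    def gram(self, X: np.ndarray) -> np.ndarray:
        X = _as2d(X)
        K = self.cross(X, X)
        # enforce exact symmetry (BLAS products are symmetric only to eps)
        K = 0.5 * (K + K.T)
        extra = self.diag_extra()
        if extra:
            K = K + extra * np.eye(X.shape[0])
        return K

    def __add__(self, other: "Kernel") -> "Sum":
        return Sum([self, other])


class SquaredExponential(Kernel):
    """``amplitude * exp(-inv_width/2 ||x-x'||^2)``."""

    def __init__(self, amplitude: float = 1.0, inv_width: float = 1.0):
        _check_positive(amplitude=amplitude, inv_width=inv_width)
        self.amplitude = float(amplitude)
        self.inv_width = float(inv_width)

    def cross(self, X, Z):
        X, Z = _as2d(X), _as2d(Z)
        d2 = sq_dists(X, Z)
        return self.amplitude * np.exp(-0.5 * self.inv_width * d2)


class ARDSquaredExponential(Kernel):
    """``amplitude * exp(-1/2 sum_d ((x_d-x'_d)/l_d)^2)`` with per-dimension lengthscales."""

    def __init__(self, amplitude: float, lengthscales: np.ndarray):
        lengthscales = np.asarray(lengthscales, dtype=float)
        _check_positive(amplitude=amplitude, lengthscales=lengthscales)
        self.amplitude = float(amplitude)
        self.lengthscales = lengthscales

    def cross(self, X, Z):
        X, Z = _as2d(X) / self.lengthscales, _as2d(Z) / self.lengthscales
        return self.amplitude * np.exp(-0.5 * sq_dists(X, Z))


class Constant(Kernel):
    def __init__(self, value: float = 1.0):
        _check_positive(value=value)
        self.value = float(value)

    def cross(self, X, Z):
        X, Z = _as2d(X), _as2d(Z)
        return np.full((X.shape[0], Z.shape[0]), self.value)


class Linear(Kernel):
    def __init__(self, variance: float = 1.0):
        _check_positive(variance=variance)
        self.variance = float(variance)

    def cross(self, X, Z):
        return self.variance * _as2d(X) @ _as2d(Z).T


class WhiteNoise(Kernel):
    """Per-index noise: contributes ``level`` only when an index meets itself."""

    def __init__(self, level: float = 1.0):
        _check_positive(level=level)
        self.level = float(level)

    def cross(self, X, Z):
        X, Z = _as2d(X), _as2d(Z)
        return np.zeros((X.shape[0], Z.shape[0]))

    def diag_extra(self) -> float:
        return self.level


class Sum(Kernel):
    def __init__(self, terms: list[Kernel]):
        if not terms:
            raise ValueError("Sum kernel needs at least one term")
        self.terms = list(terms)

    def cross(self, X, Z):
        return sum(t.cross(X, Z) for t in self.terms)

    def diag_extra(self) -> float:
        return sum(t.diag_extra() for t in self.terms)


def transition_kernel(alpha) -> Sum:
    """SE + constant + linear + white-noise composite with parameters (a1..a5)."""
    a1, a2, a3, a4, a5 = np.asarray(alpha, dtype=float)
    return Sum([
        SquaredExponential(a1, a2),
        Constant(a3),
        Linear(a4),
        WhiteNoise(a5),
    ])


def decoder_kernel(beta) -> Sum:
    """SE + white-noise composite with parameters (b1..b3)."""
    b1, b2, b3 = np.asarray(beta, dtype=float)
    return Sum([SquaredExponential(b1, b2), WhiteNoise(b3)])


def sq_dists(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0 for stability."""
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    return np.maximum(d2, 0.0)


def kernel_eval(kernel: Kernel, x, x2, same_index: bool = False) -> float:
    """Evaluate a covariance between two points.

    ``same_index`` encodes the Kronecker delta: set it only when evaluating
    a point against itself on a Gram diagonal, where white-noise terms
    contribute.
    """
    x, x2 = np.atleast_1d(np.asarray(x, float)), np.atleast_1d(np.asarray(x2, float))
    if x.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x2.shape}")
    v = float(kernel.cross(x[None, :], x2[None, :])[0, 0])
    if same_index:
        v += kernel.diag_extra()
    return v


def gram_matrix(kernel: Kernel, Z) -> np.ndarray:
    """N x N Gram matrix over points Z; white noise appears on the diagonal only."""
    return kernel.gram(_as2d(Z))


class GPRegressor:
    """Exact zero-mean Gaussian process regression.

    Parameters
    ----------
    kernel : Kernel
        Prior covariance function.
    noise : float
        Observation noise variance s2 added to the Gram diagonal.

    Attributes (after :meth:`fit`)
    ------------------------------
    Z_ : training inputs, T_ : targets, alpha_ : (K+s2 I)^{-1} T,
    L_ : Cholesky factorization of the jittered system.
    """

    def __init__(self, kernel: Kernel, noise: float = 0.0):
        if noise < 0:
            raise ValueError("noise variance must be non-negative")
        self.kernel = kernel
        self.noise = float(noise)

    def fit(self, Z, T) -> "GPRegressor":
        Z = _as2d(Z)
        T = np.asarray(T, dtype=float).ravel()
        if Z.shape[0] != T.shape[0]:
            raise ValueError("inputs and targets disagree in length")
        K = self.kernel.gram(Z) + self.noise * np.eye(Z.shape[0])
        K[np.diag_indices_from(K)] += JITTER * np.mean(np.diag(K))
        try:
            self.L_ = cho_factor(K, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(
                f"Gram matrix not positive definite after jitter: {exc}"
            ) from exc
        self.Z_ = Z
        self.T_ = T
        self.alpha_ = cho_solve(self.L_, T)
        return self

    def log_marginal_likelihood(self) -> float:
        n = self.T_.shape[0]
        logdet = 2.0 * np.sum(np.log(np.diag(self.L_[0])))
        return float(
            -0.5 * self.T_ @ self.alpha_ - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
        )

    def predict(self, Xstar, return_var: bool = True):
        Xstar = _as2d(Xstar)
        if Xstar.shape[1] != self.Z_.shape[1]:
            raise ValueError(
                f"dimension mismatch: test inputs have {Xstar.shape[1]} features, "
                f"training inputs have {self.Z_.shape[1]}"
            )
        Ks = self.kernel.cross(self.Z_, Xstar)          # (N, M)
        mean = Ks.T @ self.alpha_
        if not return_var:
            return mean
        kss = np.array([
            kernel_eval(self.kernel, x, x, same_index=True) for x in Xstar
        ])
        v = cho_solve(self.L_, Ks)
        var = kss - np.sum(Ks * v, axis=0) + self.noise
        # negative values beyond round-off would indicate a broken factorization
        var = np.maximum(var, 0.0)
        return mean, var


def log_marginal_likelihood(model: GPRegressor) -> float:
    """Eq.-(2)-style log marginal likelihood of a fitted :class:`GPRegressor`."""
    return model.log_marginal_likelihood()


def gp_predict(model: GPRegressor, x_star):
    """Predictive mean and variance at a single test point."""
    mean, var = model.predict(np.atleast_2d(np.asarray(x_star, float)))
    return float(mean[0]), float(var[0])
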