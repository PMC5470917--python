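"""Gaussian process dynamical model: latent dynamics prior, decoder likelihood,
MAP objective, and latent-space prediction.

The model couples two GPs over a latent trajectory ``X = [x_1..x_N]``
(rows in R^m):

* a transition GP ``x_{t+1} = f_X(x_t)`` with composite kernel
  kX = SE + constant + linear + white noise (parameters a1..a5), giving

      log p(X|a) = log N(x_1; 0, I)
                   - (N-1)m/2 log 2pi - m/2 log|K_X|
                   - 1/2 tr(K_X^{-1} X_out X_out')

  with K_X built over X_in = rows 1..N-1 and X_out = rows 2..N;

* a decoder GP ``y_t = g_Y(x_t)`` with kernel kY = SE + white noise
  (parameters b1..b3) and diagonal output scales W, giving

      log p(Y|X,b,W) = N sum_d log w_d - ND/2 log 2pi
                       - D/2 log|K_Y| - 1/2 tr(K_Y^{-1} Y W^2 Y')

Marginalizing the GP weights makes both densities closed-form functions of
the kernel matrices; gradients with respect to the latent coordinates and
the log hyperparameters are likewise closed-form and are returned on
request (``with_grads=True``) for use by the variational trainer.  The
initial-state prior p(x_1) is taken standard normal, the convention of the
GPDM literature.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kernels import JITTER, decoder_kernel, sq_dists, transition_kernel, kernel_eval

__all__ = [
    "decoder_log_likelihood",
    "latent_dynamics_log_density",
    "transition_consistency",
    "gpdm_neg_log_posterior",
    "decode_predict",
    "transition_predict",
]

LOG2PI = np.log(2.0 * np.pi)


def _chol(K: np.ndarray):
    K = K.copy()
    K[np.diag_indices_from(K)] += JITTER * np.mean(np.diag(K))
    return cho_factor(K, lower=True)


def _logdet(L) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L[0]))))


def _se_grad_X(G: np.ndarray, E: np.ndarray, X: np.ndarray, amp: float, inv_width: float):
    """d(scalar)/dX through an SE kernel block ``amp * E`` with symmetric sensitivity G."""
    A = G * E
    r = A.sum(axis=1)
    return -2.0 * amp * inv_width * (r[:, None] * X - A @ X)


def decoder_log_likelihood(Y, X, beta, W=None, with_grads: bool = False):
    """Log density of observations Y under the marginalized decoder GP.

    Parameters
    ----------
    Y : (N, D) observation matrix (normalized channels).
    X : (N, m) latent coordinates.
    beta : (b1, b2, b3) kernel hyperparameters of kY.
    W : optional (D,) diagonal output scales; defaults to ones.
    with_grads : also return ``{"X": dL/dX, "log_beta": dL/dlog(beta)}``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    b1, b2, b3 = np.asarray(beta, dtype=float)
    N, D = Y.shape
    if X.shape[0] != N:
        raise ValueError("Y and X disagree in frame count")
    w = np.ones(D) if W is None else np.asarray(W, dtype=float)

    d2 = sq_dists(X, X)
    E = np.exp(-0.5 * b2 * d2)
    KY = b1 * E + b3 * np.eye(N)
    L = _chol(KY)
    A = cho_solve(L, Y)                       # K^{-1} Y
    quad = float(np.sum(w**2 * np.einsum("nd,nd->d", Y, A)))
    value = (
        N * float(np.sum(np.log(w)))
        - 0.5 * N * D * LOG2PI
        - 0.5 * D * _logdet(L)
        - 0.5 * quad
    )
    if not with_grads:
        return value

    Kinv = cho_solve(L, np.eye(N))
    G = 0.5 * ((A * w**2) @ A.T - D * Kinv)   # dL/dK_Y, symmetric
    grad_X = _se_grad_X(G, E, X, b1, b2)
    g_b1 = float(np.sum(G * E))
    g_b2 = float(np.sum(G * (b1 * (-0.5 * d2) * E)))
    g_b3 = float(np.trace(G))
    grad_logbeta = np.array([g_b1 * b1, g_b2 * b2, g_b3 * b3])
    return value, {"X": grad_X, "log_beta": grad_logbeta}


def _dynamics_K(Xin: np.ndarray, alpha: np.ndarray):
    a1, a2, a3, a4, a5 = alpha
    d2 = sq_dists(Xin, Xin)
    E = np.exp(-0.5 * a2 * d2)
    Lin = Xin @ Xin.T
    K = a1 * E + a3 + a4 * Lin + a5 * np.eye(Xin.shape[0])
    return K, E, Lin, d2


def _dynamics_K_grads(G, E, Lin, d2, Xin, alpha):
    """Gradients of a scalar with K-sensitivity G through the kX kernel block."""
    a1, a2, a3, a4, a5 = alpha
    g_a = np.array([
        float(np.sum(G * E)),
        float(np.sum(G * (a1 * (-0.5 * d2) * E))),
        float(np.sum(G)),
        float(np.sum(G * Lin)),
        float(np.trace(G)),
    ])
    grad_Xin = _se_grad_X(G, E, Xin, a1, a2) + 2.0 * a4 * (G @ Xin)
    return g_a, grad_Xin


def latent_dynamics_log_density(X, alpha, with_grads: bool = False):
    """Log density of a latent trajectory under the marginalized transition GP.

    Includes the standard-normal prior on the first state.  With
    ``with_grads`` also returns ``{"X": dL/dX, "log_alpha": dL/dlog(alpha)}``.
    """
    X = np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    N, m = X.shape
    if N < 2:
        raise ValueError("need at least two frames for a transition")
    Xin, Xout = X[:-1], X[1:]
    K, E, Lin, d2 = _dynamics_K(Xin, alpha)
    L = _chol(K)
    B = cho_solve(L, Xout)                    # K^{-1} X_out
    value = (
        -0.5 * float(X[0] @ X[0]) - 0.5 * m * LOG2PI
        - 0.5 * (N - 1) * m * LOG2PI
        - 0.5 * m * _logdet(L)
        - 0.5 * float(np.sum(Xout * B))
    )
    if not with_grads:
        return value

    Kinv = cho_solve(L, np.eye(N - 1))
    G = 0.5 * (B @ B.T - m * Kinv)            # dL/dK_X, symmetric
    g_alpha, grad_Xin = _dynamics_K_grads(G, E, Lin, d2, Xin, alpha)
    grad_X = np.zeros_like(X)
    grad_X[:-1] += grad_Xin
    grad_X[1:] += -B
    grad_X[0] += -X[0]
    return value, {"X": grad_X, "log_alpha": g_alpha * alpha}


def transition_consistency(X, alpha, with_grads: bool = False):
    """Mean squared one-step transition residual on a latent trajectory.

    The transition GP's predictive mean at its own training inputs is
    ``X_out - a5 K_X^{-1} X_out`` (the white-noise term is excluded from the
    cross-covariance), so the residual is ``a5 K_X^{-1} X_out`` and the
    penalty has the closed form ``a5^2 ||K_X^{-1} X_out||_F^2 / (N-1)``.
    """
    X = np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    N, m = X.shape
    a5 = alpha[4]
    Xin, Xout = X[:-1], X[1:]
    K, E, Lin, d2 = _dynamics_K(Xin, alpha)
    L = _chol(K)
    B = cho_solve(L, Xout)
    c = a5**2 / (N - 1)
    value = c * float(np.sum(B * B))
    if not with_grads:
        return value

    KinvB = cho_solve(L, B)
    C = KinvB @ B.T
    G = -c * (C + C.T)                        # dP/dK_X
    g_alpha, grad_Xin = _dynamics_K_grads(G, E, Lin, d2, Xin, alpha)
    g_alpha[4] += 2.0 * a5 * float(np.sum(B * B)) / (N - 1)
    grad_X = np.zeros_like(X)
    grad_X[:-1] += grad_Xin
    grad_X[1:] += 2.0 * c * KinvB
    return value, {"X": grad_X, "log_alpha": g_alpha * alpha}


def gpdm_neg_log_posterior(
    Y, X, alpha, beta, W=None, hyperprior: str = "scale_invariant",
    return_components: bool = False,
):
    """Negative log posterior of the GPDM (MAP objective).

    ``hyperprior`` selects the prior over kernel hyperparameters and output
    scales: ``"scale_invariant"`` uses p(theta) ~ 1/theta per positive
    parameter, ``"flat"`` drops the prior terms.  The additive decomposition
    is returned with ``return_components=True``.
    """
    Y = np.asarray(Y, dtype=float)
    w = np.ones(Y.shape[1]) if W is None else np.asarray(W, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    comp = {
        "decoder_loglik": decoder_log_likelihood(Y, X, beta, W=w),
        "dynamics_logdensity": latent_dynamics_log_density(X, alpha),
    }
    if hyperprior == "scale_invariant":
        comp["log_hyperprior"] = -float(
            np.sum(np.log(alpha)) + np.sum(np.log(beta)) + np.sum(np.log(w))
        )
    elif hyperprior == "flat":
        comp["log_hyperprior"] = 0.0
    else:
        raise ValueError(f"unknown hyperprior {hyperprior!r}")
    value = -sum(comp.values())
    return (value, comp) if return_components else value


def _multi_gp_predict(kernel, Z, T, Xstar):
    """Shared-kernel GP prediction for multiple output columns.

    Returns per-point means (M, D) and the common variance (M,) with the
    white-noise term included in k** (noise of a new observation).
    """
    Z = np.asarray(Z, dtype=float)
    T = np.asarray(T, dtype=float)
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != Z.shape[1]:
        raise ValueError("dimension mismatch between query and support")
    K = kernel.gram(Z)
    L = _chol(K)
    A = cho_solve(L, T if T.ndim == 2 else T[:, None])
    Ks = kernel.cross(Z, Xstar)
    mean = Ks.T @ A
    kss = np.array([kernel_eval(kernel, x, x, same_index=True) for x in Xstar])
    var = np.maximum(kss - np.sum(Ks * cho_solve(L, Ks), axis=0), 0.0)
    return mean, var


def decode_predict(X_support, Y_support, beta, x_star, W=None):
    """Predict observations from latent positions via the decoder GP.

    Returns per-channel means (M, D) and variances (M, D); with output
    scales W the channel-d prior is GP(0, kY / w_d^2), so means are
    unaffected and variances divide by w_d^2.
    """
    Y_support = np.asarray(Y_support, dtype=float)
    w = np.ones(Y_support.shape[1]) if W is None else np.asarray(W, dtype=float)
    mean, var = _multi_gp_predict(decoder_kernel(beta), X_support, Y_support, x_star)
    return mean, var[:, None] / w**2


def transition_predict(Xin_support, Xout_support, alpha, x_t):
    """One-step latent prediction x_{t+1} | x_t via the transition GP.

    Returns per-dimension means (M, m) and the shared variance broadcast to
    (M, m).
    """
    Xout_support = np.asarray(Xout_support, dtype=float)
    mean, var = _multi_gp_predict(
        transition_kernel(alpha), Xin_support, Xout_support, x_t
    )
    return mean, np.repeat(var[:, None], Xout_support.shape[1], axis=1)
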