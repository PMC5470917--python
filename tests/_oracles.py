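"""Independent oracles used by the tests.

These deliberately avoid the package's own linear-algebra paths: densities
come from scipy.stats / explicit small-matrix formulas, and the log
evidence of the tiny dynamical model is computed by tensor Gauss-Hermite
quadrature with batched closed-form 2x2 and 3x3 kernel algebra.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from aegpdm.kernels import JITTER


def mvn_log_marginal(K: np.ndarray, noise: float, T: np.ndarray) -> float:
    """Log marginal likelihood via scipy's multivariate-normal density,
    including the same documented diagonal jitter the implementation adds."""
    S = K + noise * np.eye(K.shape[0])
    S = S + JITTER * np.mean(np.diag(S)) * np.eye(K.shape[0])
    return float(multivariate_normal(mean=np.zeros(len(T)), cov=S).logpdf(T))


def explicit_gp_predict(K, ks, kss, noise, T, x_noise_in_kss: bool = True):
    """Predictive moments via an explicit matrix inverse (no Cholesky)."""
    S = K + noise * np.eye(K.shape[0])
    S = S + JITTER * np.mean(np.diag(S)) * np.eye(K.shape[0])
    Sinv = np.linalg.inv(S)
    mean = ks @ Sinv @ T
    var = kss - ks @ Sinv @ ks + noise
    return float(mean), float(var)


def log_evidence_quadrature(Y, alpha, beta, sigma: float = 3.0,
                            n_nodes: int = 40) -> float:
    """log integral p_trans(x_{1:3}) p_dec(Y | x_{1:3}) dx over R^3.

    Valid for N = 3 frames and a scalar latent; the transition density is
    N(x1; 0, 1) * N((x2, x3); 0, K_X(x1, x2)) and the decoder density is a
    product over the D observation channels of N(y_d; 0, K_Y(x)).  Tensor
    Gauss-Hermite with an N(0, sigma^2) proposal per dimension.
    """
    Y = np.asarray(Y, dtype=float)
    N, D = Y.shape
    assert N == 3, "quadrature oracle is specialized to three frames"
    xi, w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = np.sqrt(2.0) * sigma * xi
    logw = np.log(w) + xi**2 + np.log(np.sqrt(2.0) * sigma)
    X1, X2, X3 = np.meshgrid(nodes, nodes, nodes, indexing="ij")
    LW = (logw[:, None, None] + logw[None, :, None]
          + logw[None, None, :]).ravel()
    x1, x2, x3 = X1.ravel(), X2.ravel(), X3.ravel()

    a1, a2, a3, a4, a5 = alpha
    k11 = a1 + a3 + a4 * x1 * x1 + a5
    k22 = a1 + a3 + a4 * x2 * x2 + a5
    k12 = a1 * np.exp(-0.5 * a2 * (x1 - x2) ** 2) + a3 + a4 * x1 * x2
    det = k11 * k22 - k12**2
    quad_tr = (k22 * x2**2 - 2 * k12 * x2 * x3 + k11 * x3**2) / det
    log_ptrans = (
        -0.5 * x1**2 - 0.5 * np.log(2 * np.pi)
        - np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad_tr
    )

    b1, b2, b3 = beta
    P = np.stack([x1, x2, x3], axis=1)[:, :, None]
    d2 = (P - P.transpose(0, 2, 1)) ** 2
    KY = b1 * np.exp(-0.5 * b2 * d2) + b3 * np.eye(3)
    _, logdetY = np.linalg.slogdet(KY)
    quad_dec = np.einsum("nd,bnm,md->b", Y, np.linalg.inv(KY), Y)
    log_pdec = (-0.5 * N * D * np.log(2 * np.pi) - 0.5 * D * logdetY
                - 0.5 * quad_dec)

    return float(logsumexp(LW + log_ptrans + log_pdec))
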