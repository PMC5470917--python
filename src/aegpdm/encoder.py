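"""Sparse GP encoder: observation frame -> Gaussian posterior over its latent
coordinate.

Each frame ``y`` is featurized by evaluating an ARD squared-exponential
kernel against ``P`` inducing inputs living in observation space,

    phi_p(y) = a * exp(-1/2 sum_d ((y_d - u_{p,d}) / l_d)^2),

and two affine readouts of ``phi(y)`` produce the posterior mean and
log-variance per latent dimension.  The per-feature lengthscales ``l_d``
implement automatic relevance determination: a very long lengthscale
switches the corresponding sensor channel off.  The resulting encoding
distribution factorizes over frames and latent dimensions (diagonal
Gaussian), so reparameterized sampling ``x = mu + sqrt(s) * eps`` is exact
and differentiable in the encoder parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["EncoderParams", "LatentPosterior", "encode", "sample_latent",
           "init_encoder_params"]

VARIANCE_FLOOR = 1e-6


@dataclass
class EncoderParams:
    """Parameters gamma_enc of the GP encoder.

    ``U`` are the inducing inputs (P x D, observation space), ``log_l`` the
    per-feature ARD log-lengthscales, ``log_amp`` the kernel log-amplitude
    and ``log_noise`` the white-noise log-level (contributing only at exact
    coincidence with an inducing input).  ``W_mean``/``b_mean`` and
    ``W_logvar``/``b_logvar`` are the affine readouts for the posterior
    mean and log-variance.
    """

    U: np.ndarray
    log_l: np.ndarray
    log_amp: float
    W_mean: np.ndarray
    b_mean: np.ndarray
    W_logvar: np.ndarray
    b_logvar: np.ndarray
    log_noise: float = np.log(1e-6)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.log_l = np.asarray(self.log_l, dtype=float)
        if self.U.ndim != 2:
            raise ValueError("inducing inputs U must be a (P, D) matrix")
        if self.log_l.shape != (self.U.shape[1],):
            raise ValueError("one ARD lengthscale per observation feature required")

    @property
    def n_inducing(self) -> int:
        return self.U.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W_mean.shape[0]


@dataclass
class LatentPosterior:
    """Frame-wise diagonal-Gaussian posterior q(x_t | y_t)."""

    mean: np.ndarray   # (N, m)
    var: np.ndarray    # (N, m), strictly positive

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var must share a shape")
        if np.any(self.var <= 0):
            raise ValueError("posterior variances must be strictly positive")

    def __len__(self) -> int:
        return self.mean.shape[0]


def _features(Y: np.ndarray, params: EncoderParams):
    """ARD-SE feature matrix Phi (N, P) and the cached differences (N, P, D)."""
    ell = np.exp(params.log_l)
    diff = Y[:, None, :] - params.U[None, :, :]
    scaled = diff / ell
    phi = np.exp(params.log_amp) * np.exp(-0.5 * np.sum(scaled**2, axis=2))
    return phi, diff


def encode(Y, params: EncoderParams) -> LatentPosterior:
    """Encode a (normalized) observation matrix frame-by-frame.

    Deterministic: each (mu_t, s_t) depends only on y_t through the inducing
    feature map; no optimization is performed.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != params.U.shape[1]:
        raise ValueError(
            f"expected (N, {params.U.shape[1]}) observations, got {Y.shape}"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("observations contain non-finite values")
    phi, _ = _features(Y, params)
    mean = phi @ params.W_mean.T + params.b_mean
    rho = phi @ params.W_logvar.T + params.b_logvar
    var = VARIANCE_FLOOR + np.exp(rho)
    return LatentPosterior(mean, var)


def sample_latent(q: LatentPosterior, n_samples: int, seed) -> np.ndarray:
    """Reparameterized draws from the encoding distribution.

    Returns an (n_samples, N, m) array ``mu + sqrt(s) * eps`` with eps from
    the seeded generator, so identical seeds give identical samples and the
    draws are differentiable in (mu, s).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_samples,) + q.mean.shape)
    return q.mean[None] + np.sqrt(q.var)[None] * eps


def encode_backprop(Y, params: EncoderParams, G_mean, G_rho):
    """Backpropagate sensitivities through the encoder.

    Given dJ/d(mu) and dJ/d(rho) (rho the pre-floor log-variance readout),
    returns a dict of gradients for every encoder parameter.  Used by the
    variational trainer; kept next to :func:`encode` so the forward and
    backward passes share the feature computation.
    """
    Y = np.asarray(Y, dtype=float)
    phi, diff = _features(Y, params)
    ell2 = np.exp(2.0 * params.log_l)
    dphi = G_mean @ params.W_mean + G_rho @ params.W_logvar      # (N, P)
    H = dphi * phi
    colsum = H.sum(axis=0)
    return {
        "W_mean": G_mean.T @ phi,
        "b_mean": G_mean.sum(axis=0),
        "W_logvar": G_rho.T @ phi,
        "b_logvar": G_rho.sum(axis=0),
        "U": (H.T @ Y - colsum[:, None] * params.U) / ell2[None, :],
        "log_l": np.einsum("tp,tpd->d", H, diff**2) / ell2,
        "log_amp": float(np.sum(H)),
    }


def init_encoder_params(
    Y, latent_dim: int, n_inducing: int, rng: np.random.Generator,
    readout_scale: float = 0.2, init_logvar: float = np.log(0.1),
) -> EncoderParams:
    """Initialize gamma_enc from training observations.

    Inducing inputs are k-means centres of the observations (a spread-out
    subset of the data); ARD lengthscales start at sqrt(D) so that typical
    Z-scored frame pairs have order-one scaled distances; mean-readout
    weights start small-random (near-collapsed latents, broken symmetry)
    and the log-variance readout starts constant.
    """
    Y = np.asarray(Y, dtype=float)
    n, D = Y.shape
    k = min(n_inducing, n)
    km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
    km.fit(Y)
    U = km.cluster_centers_
    if k < n_inducing:   # degenerate tiny datasets: repeat centres
        U = U[rng.integers(0, k, size=n_inducing)]
    return EncoderParams(
        U=U,
        log_l=np.full(D, 0.5 * np.log(D)),
        log_amp=0.0,
        W_mean=rng.normal(0.0, readout_scale, size=(latent_dim, n_inducing)),
        b_mean=np.zeros(latent_dim),
        W_logvar=np.zeros((latent_dim, n_inducing)),
        b_logvar=np.full(latent_dim, init_logvar),
    )
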