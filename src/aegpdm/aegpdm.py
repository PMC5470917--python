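"""Auto-encoded GPDM: variational objective, training loop, trained-model
services.

Training maximizes a Monte-Carlo estimate of the evidence lower bound

    L = E_q[ log p_dec(Y|X) ] + E_q[ log p_trans(X) ] + H[q],

where q is the frame-wise diagonal-Gaussian encoder posterior, the
expectation is estimated with reparameterized latent samples, the decoder
and transition densities are the closed-form marginalized GP densities of
:mod:`aegpdm.gpdm`, and the entropy H[q] is closed form.  A transition-
consistency penalty (the mean squared one-step prediction residual on the
sampled latents, weight ``lambda_trans``) realizes the "transition output
matches the next latent state" training subgoal.  All gradients are
analytic; optimization is Adam on log-scale kernel hyperparameters and the
encoder parameters over contiguous minibatches of frames.

The latent samples drawn in the final full pass over the training data are
cached on the model ("recycled") as the support set for novelty detection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import encoder as enc
from .encoder import EncoderParams, LatentPosterior, VARIANCE_FLOOR
from .features import FeatureSeries, NormalizationStats, zscore
from .gpdm import (
    decode_predict,
    decoder_log_likelihood,
    latent_dynamics_log_density,
    transition_consistency,
)

__all__ = [
    "TrainingConfig",
    "AutoEncodedGPDM",
    "elbo_mc",
    "elbo_estimate",
    "train",
    "reconstruct",
    "encode_trajectory",
    "export_latent_samples",
]

LOG2PIE = np.log(2.0 * np.pi) + 1.0


@dataclass
class TrainingConfig:
    """Training settings; the defaults echo the reference configuration
    (minibatch of 50 frames, 20 inducing points, unit initial kernel
    hyperparameters)."""

    batch_size: int = 50
    n_inducing: int = 20
    alpha_init: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    beta_init: tuple = (1.0, 1.0, 1.0)
    latent_dim: int = 2
    n_mc: int = 3
    lambda_trans: float = 1.0
    n_iter: int = 500
    learning_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "n_inducing", "latent_dim", "n_mc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.lambda_trans < 0:
            raise ValueError("lambda_trans must be non-negative")


def _entropy(var: np.ndarray) -> float:
    return 0.5 * float(np.sum(LOG2PIE + np.log(var)))


def elbo_mc(Y, mean, var, alpha, beta, n_mc: int, seed, W=None,
            return_stderr: bool = False):
    """Monte-Carlo ELBO for an explicit diagonal-Gaussian q = N(mean, var).

    Draws ``n_mc`` reparameterized latent trajectories, evaluates the
    decoder likelihood and dynamics prior at each, and adds the closed-form
    entropy of q.  With ``return_stderr`` also returns the Monte-Carlo
    standard error of the expectation term.
    """
    Y = np.asarray(Y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_mc,) + mean.shape)
    vals = np.empty(n_mc)
    for k in range(n_mc):
        X = mean + np.sqrt(var) * eps[k]
        vals[k] = decoder_log_likelihood(Y, X, beta, W=W) + \
            latent_dynamics_log_density(X, alpha)
    elbo = float(vals.mean()) + _entropy(var)
    if return_stderr:
        se = float(vals.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else np.inf
        return elbo, se
    return elbo


def _batch_objective(Yb, params: EncoderParams, log_alpha, log_beta, eps,
                     lambda_trans: float, with_grads: bool = False):
    """Objective J = -ELBO + lambda * consistency on one contiguous block.

    ``eps`` is the fixed (n_mc, N, m) standard-normal tensor, making J a
    deterministic function of the parameters (used for finite-difference
    gradient validation).  Returns (J, extras) or (J, grads, extras).
    """
    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    q = enc.encode(Yb, params)
    mu, var = q.mean, q.var
    sd = np.sqrt(var)
    K = eps.shape[0]
    N = Yb.shape[0]

    dec_vals, tr_vals, pen_vals = np.empty(K), np.empty(K), np.empty(K)
    gX_acc = np.zeros_like(mu)
    gX_eps_acc = np.zeros_like(mu)
    g_la = np.zeros(5)
    g_lb = np.zeros(3)
    for k in range(K):
        X = mu + sd * eps[k]
        if with_grads:
            dv, gdec = decoder_log_likelihood(Yb, X, beta, with_grads=True)
            tv, gtr = latent_dynamics_log_density(X, alpha, with_grads=True)
            gX = -(gdec["X"] + gtr["X"]) / K
            g_lb += -gdec["log_beta"] / K
            g_la += -gtr["log_alpha"] / K
            if lambda_trans > 0:
                pv, gpen = transition_consistency(X, alpha, with_grads=True)
                gX += lambda_trans * gpen["X"] / K
                g_la += lambda_trans * gpen["log_alpha"] / K
            else:
                pv = transition_consistency(X, alpha)
            gX_acc += gX
            gX_eps_acc += gX * eps[k]
        else:
            dv = decoder_log_likelihood(Yb, X, beta)
            tv = latent_dynamics_log_density(X, alpha)
            pv = transition_consistency(X, alpha)
        dec_vals[k], tr_vals[k], pen_vals[k] = dv, tv, pv

    H = _entropy(var)
    elbo = float(dec_vals.mean() + tr_vals.mean()) + H
    J = -elbo + lambda_trans * float(pen_vals.mean())
    extras = {
        "neg_elbo": -elbo / N,
        "recon_nll": -float(dec_vals.mean()) / N,
        "trans_consistency": float(pen_vals.mean()),
        "kl": -(float(tr_vals.mean()) + H) / N,
    }
    if not with_grads:
        return J, extras

    # chain through the reparameterization and the entropy
    dJ_dmu = gX_acc
    dJ_dvar = gX_eps_acc * 0.5 / sd - 0.5 / var
    G_rho = dJ_dvar * (var - VARIANCE_FLOOR)        # d var / d rho = exp(rho)
    grads = enc.encode_backprop(Yb, params, dJ_dmu, G_rho)
    grads["log_alpha"] = g_la
    grads["log_beta"] = g_lb
    return J, grads, extras


class _Adam:
    def __init__(self, shapes: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_matrix(Y) -> np.ndarray:
    if isinstance(Y, FeatureSeries):
        return Y.values
    return np.asarray(Y, dtype=float)


class AutoEncodedGPDM(BaseEstimator, TransformerMixin):
    """Auto-encoded Gaussian process dynamical model.

    A transformer mapping multichannel sensor frames to a low-dimensional
    latent space.  ``fit`` trains the GPDM decoder, transition prior and GP
    encoder jointly by stochastic gradient ascent on the Monte-Carlo ELBO;
    ``transform`` returns the encoder posterior means (no optimization at
    encoding time).

    Parameters mirror :class:`TrainingConfig`; ``normalize`` controls
    internal Z-scoring with training-set statistics.  Randomness (encoder
    init, minibatching, Monte-Carlo draws) is governed by ``random_state``.

    Attributes after fitting include ``alpha_`` and ``beta_`` (transition
    and decoder kernel hyperparameters), ``W_`` (output scales, identity by
    default), ``encoder_``, ``stats_`` (normalization), ``support_X_`` /
    ``support_Y_`` (latent support for decoding), ``latent_samples_`` (the
    recycled final-pass samples) and ``trace_`` (training diagnostics).
    """

    def __init__(self, latent_dim: int = 2, n_inducing: int = 20,
                 batch_size: int = 50, n_mc: int = 3,
                 lambda_trans: float = 1.0, n_iter: int = 500,
                 learning_rate: float = 0.02,
                 alpha_init: tuple = (1.0, 1.0, 1.0, 1.0, 1.0),
                 beta_init: tuple = (1.0, 1.0, 1.0),
                 normalize: bool = True, random_state=None):
        self.latent_dim = latent_dim
        self.n_inducing = n_inducing
        self.batch_size = batch_size
        self.n_mc = n_mc
        self.lambda_trans = lambda_trans
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.normalize = normalize
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _normalize(self, Y: np.ndarray) -> np.ndarray:
        if not self.normalize:
            return Y
        Z, _ = zscore(FeatureSeries(Y), self.stats_)
        return Z.values

    def fit(self, X, y=None):
        """Train on one sequence (N, D) or a list of sequences."""
        seqs = X if isinstance(X, (list, tuple)) else [X]
        seqs = [_as_matrix(s) for s in seqs]
        D = seqs[0].shape[1]
        for s in seqs:
            if s.ndim != 2 or s.shape[1] != D:
                raise ValueError("sequences must share their channel layout")
            if s.shape[0] < 2:
                raise ValueError("each sequence needs at least 2 frames")
        self.n_features_in_ = D
        pooled = np.vstack(seqs)
        if self.normalize:
            _, self.stats_ = zscore(FeatureSeries(pooled))
        else:
            self.stats_ = NormalizationStats(np.zeros(D), np.ones(D))
        seqs = [self._normalize(s) for s in seqs]

        rng = np.random.default_rng(self.random_state)
        params = enc.init_encoder_params(
            np.vstack(seqs), self.latent_dim, self.n_inducing, rng
        )
        pvec = {
            "log_alpha": np.log(np.asarray(self.alpha_init, dtype=float)),
            "log_beta": np.log(np.asarray(self.beta_init, dtype=float)),
            "U": params.U, "log_l": params.log_l,
            "log_amp": np.array(params.log_amp),
            "W_mean": params.W_mean, "b_mean": params.b_mean,
            "W_logvar": params.W_logvar, "b_logvar": params.b_logvar,
        }
        opt = _Adam({k: np.shape(v) for k, v in pvec.items()},
                    lr=self.learning_rate)
        lengths = np.array([s.shape[0] for s in seqs], dtype=float)
        probs = lengths / lengths.sum()
        trace: dict[str, list] = {
            "iteration": [], "neg_elbo": [], "recon_nll": [],
            "trans_consistency": [], "kl": [],
        }

        for it in range(self.n_iter):
            i = int(rng.choice(len(seqs), p=probs))
            n_i = seqs[i].shape[0]
            B = min(self.batch_size, n_i)
            start = int(rng.integers(0, n_i - B + 1))
            Yb = seqs[i][start:start + B]
            eps = rng.standard_normal((self.n_mc, B, self.latent_dim))
            cur = self._make_encoder(pvec)
            J, grads, extras = _batch_objective(
                Yb, cur, pvec["log_alpha"], pvec["log_beta"], eps,
                self.lambda_trans, with_grads=True,
            )
            if not np.isfinite(J):
                self.trace_ = {k: np.asarray(v) for k, v in trace.items()}
                raise FloatingPointError(
                    f"training diverged at iteration {it}: objective {J!r}"
                )
            opt.step(pvec, grads)
            trace["iteration"].append(it)
            for k in ("neg_elbo", "recon_nll", "trans_consistency", "kl"):
                trace[k].append(extras[k])

        self.alpha_ = np.exp(pvec["log_alpha"])
        self.beta_ = np.exp(pvec["log_beta"])
        self.W_ = np.ones(D)
        self.encoder_ = self._make_encoder(pvec)
        self.trace_ = {k: np.asarray(v) for k, v in trace.items()}

        # final full pass: latent support and recycled latent samples
        posts = [enc.encode(s, self.encoder_) for s in seqs]
        self.support_X_ = np.vstack([q.mean for q in posts])
        self.support_Y_ = np.vstack(seqs)
        samples = [
            enc.sample_latent(q, self.n_mc, rng) for q in posts
        ]
        self.latent_samples_ = np.vstack(
            [s.reshape(-1, self.latent_dim) for s in samples]
        )
        self.n_sequences_ = len(seqs)
        return self

    @staticmethod
    def _make_encoder(pvec: dict) -> EncoderParams:
        return EncoderParams(
            U=pvec["U"], log_l=pvec["log_l"], log_amp=float(pvec["log_amp"]),
            W_mean=pvec["W_mean"], b_mean=pvec["b_mean"],
            W_logvar=pvec["W_logvar"], b_logvar=pvec["b_logvar"],
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("model is not fitted")

    # -- services ----------------------------------------------------------

    def encode_posterior(self, Y) -> LatentPosterior:
        """Frame-wise Gaussian posterior q(x_t | y_t) for a sequence."""
        self._check_fitted()
        return enc.encode(self._normalize(_as_matrix(Y)), self.encoder_)

    def transform(self, Y) -> np.ndarray:
        """Latent trajectory (posterior means), optimization-free."""
        return self.encode_posterior(Y).mean

    def reconstruct(self, Y, denormalize: bool = False):
        """Encode then decode a sequence; returns (means, variances).

        Reconstruction is reported in Z-scored units unless ``denormalize``.
        """
        self._check_fitted()
        Z = self.transform(Y)
        mean, var = decode_predict(self.support_X_, self.support_Y_,
                                   self.beta_, Z, W=self.W_)
        if denormalize:
            sd = np.where(self.stats_.sd < 1e-12, 1.0, self.stats_.sd)
            mean = mean * sd + self.stats_.mean
            var = var * sd**2
        return mean, var

    def elbo(self, Y, n_mc: int = 100, seed=0, return_stderr: bool = False):
        """Monte-Carlo ELBO of a sequence under the trained model."""
        self._check_fitted()
        Z = self._normalize(_as_matrix(Y))
        q = enc.encode(Z, self.encoder_)
        return elbo_mc(Z, q.mean, q.var, self.alpha_, self.beta_,
                       n_mc, seed, W=self.W_, return_stderr=return_stderr)

    def export_latent_samples(self) -> np.ndarray:
        """The recycled final-pass latent samples, as an (S, m) point set."""
        self._check_fitted()
        return self.latent_samples_

    # -- persistence -------------------------------------------------------

    _ARRAYS = ("alpha_", "beta_", "W_", "support_X_", "support_Y_",
               "latent_samples_")

    def save(self, path) -> None:
        """Write all parameters to an HDF5 archive (bit-exact round trip)."""
        import h5py
        import hashlib

        self._check_fitted()
        cfg = json.dumps(self.get_params(), sort_keys=True)
        with h5py.File(path, "w", track_order=True) as f:
            f.attrs["config"] = cfg
            f.attrs["config_sha256"] = hashlib.sha256(cfg.encode()).hexdigest()
            f.attrs["format"] = "aegpdm-model-v1"

            def w(name, arr):
                f.create_dataset(name, data=np.asarray(arr), track_times=False)

            for name in self._ARRAYS:
                w(name, getattr(self, name))
            w("stats_mean", self.stats_.mean)
            w("stats_sd", self.stats_.sd)
            e = self.encoder_
            for name in ("U", "log_l", "W_mean", "b_mean", "W_logvar",
                         "b_logvar"):
                w(f"encoder/{name}", getattr(e, name))
            w("encoder/log_amp", e.log_amp)
            w("encoder/log_noise", e.log_noise)
            for k, v in self.trace_.items():
                w(f"trace/{k}", v)

    @classmethod
    def load(cls, path) -> "AutoEncodedGPDM":
        import h5py

        with h5py.File(path, "r") as f:
            model = cls(**json.loads(f.attrs["config"]))
            for name in cls._ARRAYS:
                setattr(model, name, f[name][...])
            model.stats_ = NormalizationStats(f["stats_mean"][...],
                                              f["stats_sd"][...])
            model.encoder_ = EncoderParams(
                U=f["encoder/U"][...], log_l=f["encoder/log_l"][...],
                log_amp=float(f["encoder/log_amp"][()]),
                W_mean=f["encoder/W_mean"][...],
                b_mean=f["encoder/b_mean"][...],
                W_logvar=f["encoder/W_logvar"][...],
                b_logvar=f["encoder/b_logvar"][...],
                log_noise=float(f["encoder/log_noise"][()]),
            )
            model.trace_ = {k: f[f"trace/{k}"][...] for k in f["trace"]}
            model.n_features_in_ = model.support_Y_.shape[1]
        return model


# -- thin functional wrappers ----------------------------------------------

def train(sequences, config: TrainingConfig | None = None):
    """Train an :class:`AutoEncodedGPDM` from a list of feature series."""
    config = config or TrainingConfig()
    model = AutoEncodedGPDM(
        latent_dim=config.latent_dim, n_inducing=config.n_inducing,
        batch_size=config.batch_size, n_mc=config.n_mc,
        lambda_trans=config.lambda_trans, n_iter=config.n_iter,
        learning_rate=config.learning_rate, alpha_init=config.alpha_init,
        beta_init=config.beta_init, random_state=config.seed,
    )
    model.fit(sequences)
    return model, model.trace_


def elbo_estimate(Y, model: AutoEncodedGPDM, n_mc: int = 100, seed=0):
    return model.elbo(Y, n_mc=n_mc, seed=seed)


def reconstruct(model: AutoEncodedGPDM, Y):
    return model.reconstruct(Y)


def encode_trajectory(model: AutoEncodedGPDM, Y) -> LatentPosterior:
    return model.encode_posterior(Y)


def export_latent_samples(model: AutoEncodedGPDM) -> np.ndarray:
    return model.export_latent_samples()
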