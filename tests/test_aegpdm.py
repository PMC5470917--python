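import numpy as np
import pytest
from scipy.spatial.distance import cdist

from aegpdm import (
    AutoEncodedGPDM,
    TrainingConfig,
    WalkSimConfig,
    hausdorff_distance,
    procrustes_correlation,
    simulate_posture,
    simulate_walk,
    train,
    zscore,
)
from aegpdm.aegpdm import _batch_objective, elbo_mc
from aegpdm.encoder import EncoderParams
from aegpdm.features import FeatureSeries
from _oracles import log_evidence_quadrature


def _zscored(model, Y):
    Z, _ = zscore(FeatureSeries(Y), model.stats_)
    return Z.values


class TestObjectiveGradients:
    def test_analytic_matches_finite_difference(self, rng):
        """Full-objective gradient check on a tiny instance at fixed seed."""
        N, D, m, P = 7, 4, 2, 3
        Y = rng.standard_normal((N, D))
        params = EncoderParams(
            U=rng.normal(size=(P, D)), log_l=np.zeros(D), log_amp=0.0,
            W_mean=0.3 * rng.normal(size=(m, P)), b_mean=np.zeros(m),
            W_logvar=0.1 * rng.normal(size=(m, P)),
            b_logvar=np.full(m, -2.0),
        )
        la = np.log([1.2, 0.8, 0.5, 0.7, 0.3])
        lb = np.log([1.1, 0.9, 0.4])
        eps = rng.standard_normal((3, N, m))
        _, grads, _ = _batch_objective(Y, params, la, lb, eps, 1.0,
                                       with_grads=True)

        base = {
            "U": params.U, "log_l": params.log_l,
            "log_amp": np.array(params.log_amp), "W_mean": params.W_mean,
            "b_mean": params.b_mean, "W_logvar": params.W_logvar,
            "b_logvar": params.b_logvar, "log_alpha": la, "log_beta": lb,
        }

        def objective(d):
            p = EncoderParams(
                U=d["U"], log_l=d["log_l"], log_amp=float(d["log_amp"]),
                W_mean=d["W_mean"], b_mean=d["b_mean"],
                W_logvar=d["W_logvar"], b_logvar=d["b_logvar"],
            )
            return _batch_objective(Y, p, d["log_alpha"], d["log_beta"],
                                    eps, 1.0)[0]

        h = 1e-6
        for key, g_analytic in grads.items():
            arr = np.asarray(base[key], dtype=float)
            g_fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                for sgn in (+1, -1):
                    d = {k: np.array(v, dtype=float) for k, v in base.items()}
                    d[key][i] += sgn * h
                    g_fd[i] += sgn * objective(d) / (2 * h)
            denom = np.max(np.abs(g_fd)) + 1e-10
            assert np.max(np.abs(np.asarray(g_analytic) - g_fd)) / denom \
                < 1e-4, key


class TestElbo:
    def test_fixed_seed_is_deterministic(self, rng):
        Y = rng.normal(size=(5, 3))
        mu = rng.normal(size=(5, 1))
        var = np.full((5, 1), 0.2)
        a = elbo_mc(Y, mu, var, np.ones(5), np.ones(3), n_mc=10, seed=3)
        b = elbo_mc(Y, mu, var, np.ones(5), np.ones(3), n_mc=10, seed=3)
        assert a == b

    def test_x_independent_decoder_limit(self, rng):
        """With the decoder's SE amplitude off, the ELBO minus the constant
        decoder term is -KL(q || p_trans) <= 0, and ~0 for matched q."""
        Y = rng.normal(size=(2, 2))
        alpha = np.array([1.0, 1.0, 0.5, 1e-12, 0.5])   # linear term off
        beta = np.array([1e-12, 1.0, 1.0])              # X-independent decoder
        from aegpdm.gpdm import decoder_log_likelihood

        const_dec = decoder_log_likelihood(Y, np.zeros((2, 1)), beta)
        # p_trans factorizes: x1 ~ N(0,1), x2 ~ N(0, a1+a3+a5) (a4 ~ 0)
        var2 = 1.0 + 0.5 + 0.5
        mu = np.zeros((2, 1))
        var = np.array([[1.0], [var2]])
        elbo, se = elbo_mc(Y, mu, var, alpha, beta, n_mc=400, seed=0,
                           return_stderr=True)
        gap = elbo - const_dec                 # = -KL, should be ~0 from below
        assert gap <= 3 * se
        assert gap == pytest.approx(0.0, abs=max(5 * se, 0.02))

    @pytest.mark.parametrize("trial", range(5))
    def test_jensen_bound_against_quadrature(self, trial):
        r = np.random.default_rng(100 + trial)
        Y = r.standard_normal((3, 2))
        alpha = r.uniform(0.5, 2.0, 5)
        beta = r.uniform(0.5, 2.0, 3)
        mu = r.normal(0.0, 1.0, (3, 1))
        var = r.uniform(0.05, 1.0, (3, 1))
        elbo, se = elbo_mc(Y, mu, var, alpha, beta, n_mc=200, seed=trial,
                           return_stderr=True)
        assert elbo <= log_evidence_quadrature(Y, alpha, beta) + 3 * se


class TestTraining:
    def test_default_configuration_echoes_reference_settings(self):
        cfg = TrainingConfig()
        assert cfg.batch_size == 50
        assert cfg.n_inducing == 20
        assert cfg.alpha_init == (1.0, 1.0, 1.0, 1.0, 1.0)
        assert cfg.beta_init == (1.0, 1.0, 1.0)
        est = AutoEncodedGPDM()
        assert est.batch_size == 50 and est.n_inducing == 20
        assert tuple(est.alpha_init) == (1.0,) * 5
        assert tuple(est.beta_init) == (1.0,) * 3

    def test_reconstruction_mse_drops_at_least_fivefold(
        self, walk_dataset, untrained_model, trained_model
    ):
        Y = walk_dataset.series.values
        Z = _zscored(trained_model, Y)
        mse0 = np.mean((untrained_model.reconstruct(Y)[0] - Z) ** 2)
        mse1 = np.mean((trained_model.reconstruct(Y)[0] - Z) ** 2)
        assert mse1 <= mse0 / 5.0

    def test_recovers_planar_limit_cycle(self, walk_dataset, trained_model):
        Zhat = trained_model.transform(walk_dataset.series.values)
        assert procrustes_correlation(Zhat, walk_dataset.latent) >= 0.8

    def test_smoothed_negative_elbo_trace_decreases(self, trained_model):
        ne = trained_model.trace_["neg_elbo"]
        w = 10
        smooth = np.convolve(ne, np.ones(w) / w, mode="valid")
        assert smooth[-1] < smooth[0]
        # the trend, quartile by quartile, is downhill
        quarters = np.array_split(smooth, 4)
        means = [q.mean() for q in quarters]
        assert all(b <= a for a, b in zip(means, means[1:]))

    def test_training_is_reproducible(self, walk_dataset):
        kw = dict(n_iter=40, random_state=7)
        m1 = AutoEncodedGPDM(**kw).fit(walk_dataset.series.values)
        m2 = AutoEncodedGPDM(**kw).fit(walk_dataset.series.values)
        np.testing.assert_array_equal(m1.alpha_, m2.alpha_)
        np.testing.assert_array_equal(m1.latent_samples_, m2.latent_samples_)

    def test_multiple_sequences_share_layout(self, walk_dataset):
        other = simulate_walk(WalkSimConfig(seed=12, duration=6.0))
        model = AutoEncodedGPDM(n_iter=20, random_state=0).fit(
            [walk_dataset.series.values, other.series.values]
        )
        assert model.n_sequences_ == 2
        assert model.support_X_.shape[0] == 160
        with pytest.raises(ValueError, match="channel layout"):
            AutoEncodedGPDM(n_iter=5).fit(
                [walk_dataset.series.values, np.zeros((10, 4))]
            )

    def test_functional_wrapper(self, walk_dataset):
        model, trace = train([walk_dataset.series.values],
                             TrainingConfig(n_iter=10, seed=1))
        assert len(trace["neg_elbo"]) == 10
        assert model.latent_samples_.shape[1] == 2


class TestTrainedModelServices:
    def test_encode_trajectory_is_optimization_free(self, trained_model,
                                                    walk_dataset):
        Y = walk_dataset.series.values
        q1 = trained_model.encode_posterior(Y)
        q2 = trained_model.encode_posterior(Y)
        np.testing.assert_array_equal(q1.mean, q2.mean)

    def test_heldout_walk_latent_path_near_training_support(
        self, trained_model
    ):
        new = simulate_walk(WalkSimConfig(seed=77))
        path = trained_model.transform(new.series.values)
        sup = trained_model.support_X_
        scale = sup.std(axis=0)
        d = hausdorff_distance(path / scale, sup / scale)
        assert d <= 1.0

    def test_lying_posture_maps_outside_walking_support(self, trained_model):
        lie = simulate_posture("lie", seed=3)
        Zl = trained_model.transform(lie.series.values)
        assert cdist(Zl, trained_model.support_X_).min() > 0.0

    def test_reconstruct_shape_and_idempotence_drift(self, trained_model,
                                                     walk_dataset):
        Y = walk_dataset.series.values
        Z = _zscored(trained_model, Y)
        rec1, var1 = trained_model.reconstruct(Y)
        assert rec1.shape == Y.shape and var1.shape == Y.shape
        mse1 = np.mean((rec1 - Z) ** 2)
        rec1_denorm, _ = trained_model.reconstruct(Y, denormalize=True)
        rec2, _ = trained_model.reconstruct(rec1_denorm)
        drift = np.mean((rec2 - rec1) ** 2)
        assert drift < mse1

    def test_exported_latent_samples_bookkeeping(self, trained_model,
                                                 walk_dataset):
        S = trained_model.export_latent_samples()
        n_frames = len(walk_dataset.series.values)
        assert S.shape == (n_frames * trained_model.n_mc, 2)
        assert np.all(np.isfinite(S))
        mu = trained_model.transform(walk_dataset.series.values)
        var = trained_model.encode_posterior(walk_dataset.series.values).var
        se = np.sqrt(var.sum(axis=0) / (n_frames**2 * trained_model.n_mc))
        assert np.all(np.abs(S.mean(axis=0) - mu.mean(axis=0)) < 3 * se)

    def test_archive_round_trip_is_exact(self, trained_model, tmp_path,
                                         walk_dataset):
        p = tmp_path / "model.h5"
        trained_model.save(p)
        loaded = AutoEncodedGPDM.load(p)
        Y = walk_dataset.series.values
        np.testing.assert_array_equal(loaded.alpha_, trained_model.alpha_)
        np.testing.assert_array_equal(
            loaded.transform(Y), trained_model.transform(Y)
        )
        np.testing.assert_array_equal(
            loaded.latent_samples_, trained_model.latent_samples_
        )

    def test_unfitted_model_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            AutoEncodedGPDM().export_latent_samples()
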