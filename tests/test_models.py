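"""Decay imputation equations, autoencoder gradients, training behavior."""

import math

import numpy as np
import pytest

from aomphen.errors import ConfigError, ContractError
from aomphen.featurize import TemporalDataset
from aomphen.models import (
    TrainConfig,
    decay_weight,
    decode,
    grud_backward,
    grud_forward,
    impute_input,
    init_grud_params,
    make_folds,
    masked_loss,
    reconstruction_loss,
    sae_forward,
    train_grud_ae,
    train_sae,
)
from aomphen.models.sae import _sae_backward, init_sae_params


class TestDecayWeight:
    def test_zero_delta_zero_bias_gives_one(self):
        assert decay_weight(0.0, 0.5, 0.0) == 1.0

    def test_negative_preactivation_clamped_to_one(self):
        assert decay_weight(1.0, 1.0, -6.0) == 1.0  # max(0, -5) = 0

    def test_scalar_hand_computation(self):
        assert decay_weight(30.0, 0.1, 0.0) == pytest.approx(math.exp(-3), abs=1e-15)

    def test_negative_delta_rejected(self):
        with pytest.raises(ContractError):
            decay_weight(-1.0, 0.1, 0.0)

    def test_gamma_in_unit_interval_and_monotone(self):
        deltas = np.linspace(0, 50, 100)
        g = decay_weight(deltas, 0.2, 0.1)
        assert ((g > 0) & (g <= 1)).all()
        assert (np.diff(g) <= 0).all()


class TestImputeInput:
    def test_observed_passthrough(self):
        assert impute_input(2.0, 1.0, 5.0, 9.0, 0.3) == 2.0

    def test_pure_carry_forward_limit(self):
        assert impute_input(0.0, 0.0, 1.5, 9.0, 1.0) == 1.5

    def test_decay_to_mean_limit(self):
        assert impute_input(0.0, 0.0, 1.5, 9.0, 0.0) == 9.0

    def test_chained_with_decay_weight(self):
        g = decay_weight(30.0, 0.1, 0.0)
        assert impute_input(0.0, 0.0, 1.0, 0.0, g) == pytest.approx(math.exp(-3), abs=1e-12)

    def test_matches_scalar_brute_force_on_random_tuples(self):
        rng = np.random.default_rng(42)
        n = 10_000
        x, xl, xm = rng.normal(size=(3, n))
        m = rng.integers(0, 2, n).astype(float)
        d = rng.uniform(0, 20, n)
        w, b = rng.uniform(0, 1, n), rng.uniform(-1, 1, n)
        g = decay_weight(d, w, b)
        out = impute_input(x, m, xl, xm, g)
        for i in range(n):
            gi = math.exp(-max(0.0, w[i] * d[i] + b[i]))
            ref = m[i] * x[i] + (1 - m[i]) * (gi * xl[i] + (1 - gi) * xm[i])
            assert abs(out[i] - ref) < 1e-12


class TestReconstructionLoss:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).normal(size=(2, 13, 3))
        assert reconstruction_loss(a, a) == 0.0

    def test_single_cell_difference(self):
        a = np.zeros((1, 13, 3))
        b = a.copy()
        b[0, 4, 1] = 2.0
        assert reconstruction_loss(a, b) == 4.0

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(1)
        xbar, xhat = rng.normal(size=(2, 4, 13, 6))
        ref = sum(
            (xhat[i, t, d] - xbar[i, t, d]) ** 2
            for i in range(4) for t in range(13) for d in range(6)
        )
        assert reconstruction_loss(xbar, xhat) == pytest.approx(ref, abs=1e-8)


def random_batch(rng, N=4, T=13, D=6, presence=0.5):
    X = rng.normal(size=(N, T, D))
    M = (rng.random((N, T, D)) < presence).astype(float)
    Delta = rng.uniform(0, 4, (N, T, D))
    XL = rng.normal(size=(N, T, D))
    xm = rng.normal(size=D)
    return X, M, Delta, XL, xm


class TestEncoderDecoder:
    def test_observed_passthrough_deactivates_imputation(self):
        """With everything observed, the imputation terms are inert: the
        embedding ignores x_last and x_mean entirely."""
        rng = np.random.default_rng(2)
        X, _, Delta, XL, xm = random_batch(rng)
        M = np.ones_like(X)
        params = init_grud_params(6, 5, seed=3, hidden_decay=False)
        h1, xhat, _ = grud_forward(params, X, M, Delta, XL, xm)
        h2, _, _ = grud_forward(params, X, M, Delta, rng.normal(size=XL.shape), rng.normal(size=6))
        assert np.array_equal(xhat, X)
        assert np.allclose(h1, h2)

    def test_deterministic_embeddings(self):
        rng = np.random.default_rng(3)
        batch = random_batch(rng)
        params = init_grud_params(6, 5, seed=3)
        a, _, _ = grud_forward(params, *batch)
        b, _, _ = grud_forward(params, *batch)
        assert np.array_equal(a, b)

    def test_feature_permutation_symmetry(self):
        """Permuting feature channels together with the per-feature weights
        leaves the embedding unchanged (3-feature toy)."""
        rng = np.random.default_rng(4)
        D, H = 3, 4
        X, M, Delta, XL, xm = random_batch(rng, N=2, D=D)
        params = init_grud_params(D, H, seed=5)
        perm = np.array([2, 0, 1])
        p2 = {k: v.copy() for k, v in params.items()}
        for k in ("w_gx", "b_gx"):
            p2[k] = params[k][perm]
        for k in ("Wz", "Wr", "Wc", "Vz", "Vr", "Vc"):
            p2[k] = params[k][perm, :]
        p2["W_gh"] = params["W_gh"][:, perm]
        p2["Wo"] = params["Wo"]  # decoder readout rows are hidden-indexed
        p2["Wo"] = params["Wo"][:, perm]
        p2["bo"] = params["bo"][perm]
        h1, _, _ = grud_forward(params, X, M, Delta, XL, xm)
        h2, _, _ = grud_forward(
            p2, X[:, :, perm], M[:, :, perm], Delta[:, :, perm], XL[:, :, perm], xm[perm]
        )
        assert np.allclose(h1, h2)

    def test_dimension_mismatch_named(self):
        params = init_grud_params(6, 5, seed=3)
        X = np.zeros((1, 13, 4))
        with pytest.raises(ContractError, match="6.*4|4.*6"):
            grud_forward(params, X, X, X, X, np.zeros(4))

    def test_decoder_zero_weights_constant_readout(self):
        params = init_grud_params(3, 4, seed=0)
        for k in ("Az", "Ar", "Ac", "Wo"):
            params[k] = np.zeros_like(params[k])
        params["bo"] = np.array([1.0, 2.0, 3.0])
        out = decode(np.random.default_rng(0).normal(size=(2, 4)), params, T=13)
        assert out.shape == (2, 13, 3)
        assert np.allclose(out, np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("hidden_decay", [True, False])
    @pytest.mark.parametrize("detach", [True, False])
    def test_gradients_match_finite_differences(self, hidden_decay, detach):
        rng = np.random.default_rng(10)
        N, T, D, H = 3, 5, 4, 4
        params = init_grud_params(D, H, seed=11, hidden_decay=hidden_decay)
        # keep the decay rectifiers strictly active so the loss is smooth
        params["w_gx"] = rng.uniform(0.05, 0.3, D)
        params["b_gx"] = rng.uniform(0.01, 0.1, D)
        if hidden_decay:
            params["W_gh"] = rng.uniform(0.02, 0.2, (H, D))
            params["b_gh"] = rng.uniform(0.01, 0.05, H)
        X, M, Delta, XL, xm = random_batch(rng, N=N, T=T, D=D)
        _, xhat0, _, cache = grud_forward(params, X, M, Delta, XL, xm, return_cache=True)
        grads = grud_backward(params, cache, detach_targets=detach)

        def loss():
            _, xhat, xbar = grud_forward(params, X, M, Delta, XL, xm)
            target = xhat0 if detach else xhat
            return float(np.sum((target - xbar) ** 2))

        eps = 1e-6
        for key, g in grads.items():
            flat_idx = rng.choice(params[key].size, size=min(3, params[key].size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, params[key].shape)
                orig = params[key][ix]
                params[key][ix] = orig + eps
                lp = loss()
                params[key][ix] = orig - eps
                lm = loss()
                params[key][ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[ix] == pytest.approx(fd, rel=1e-4, abs=1e-6), key


def toy_dataset(n=40, D=5, seed=0, n_persons=None, presence=0.7, scale=1.0):
    rng = np.random.default_rng(seed)
    n_persons = n_persons or n
    # rank-1 latent structure so a small bottleneck can reconstruct it
    u = rng.normal(size=(n, 1))
    v = rng.normal(size=(1, 13 * D))
    X = (u @ v).reshape(n, 13, D) * scale
    M = (rng.random((n, 13, D)) < presence).astype(float)
    Delta = rng.uniform(0, 4, (n, 13, D))
    XL = np.zeros((n, 13, D))
    return TemporalDataset(
        period_ids=np.arange(n), person_ids=np.arange(n) % n_persons,
        X=X, M=M, Delta=Delta, last_obs=XL, n_meas=D,
        feature_names=tuple(f"f{i}" for i in range(D)), x_mean=np.zeros(D),
    )


class TestTraining:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)

    def test_fewer_patients_than_folds_rejected(self):
        ds = toy_dataset(n=10, n_persons=3)
        with pytest.raises(ConfigError):
            make_folds(ds.person_ids, TrainConfig(n_folds=5, epochs=1))

    def test_patient_folds_partition_and_group(self):
        ds = toy_dataset(n=40, n_persons=20)
        folds = make_folds(ds.person_ids, TrainConfig(n_folds=4, epochs=1, seed=2))
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(40))
        for f in folds:
            inside = set(ds.person_ids[f].tolist())
            outside = set(ds.person_ids[np.setdiff1d(np.arange(40), f)].tolist())
            assert not inside & outside

    def test_training_reduces_loss(self):
        ds = toy_dataset(n=40, D=4, seed=1)
        cfg = TrainConfig(n_folds=2, epochs=20, bottleneck=6, seed=1, batch_size=16)
        results = train_grud_ae(ds, cfg)
        for r in results:
            assert r.history[-1] < r.history[0]

    def test_same_seed_reproducible(self):
        ds = toy_dataset(n=24, D=3, seed=2)
        cfg = TrainConfig(n_folds=2, epochs=5, bottleneck=4, seed=9)
        a = train_grud_ae(ds, cfg)
        b = train_grud_ae(ds, cfg)
        assert a[0].history == b[0].history
        assert np.array_equal(
            a[0].embeddings.filter(like="h_").to_numpy(),
            b[0].embeddings.filter(like="h_").to_numpy(),
        )

    def test_rank1_reconstruction_correlates(self):
        """After training on fully observed rank-1 data the reconstruction
        tracks the (rank-1) post-imputation targets."""
        ds = toy_dataset(n=60, D=4, seed=3, presence=1.0, scale=0.5)
        cfg = TrainConfig(n_folds=2, epochs=600, bottleneck=12, seed=3,
                          batch_size=30, patience=300, lr=2e-2)
        results = train_grud_ae(ds, cfg)
        params = results[0].params
        _, xhat, xbar = grud_forward(params, ds.X, ds.M, ds.Delta, ds.last_obs, ds.x_mean)
        r = np.corrcoef(xhat.ravel(), xbar.ravel())[0, 1]
        assert r >= 0.9


class TestSAE:
    def test_masked_cells_contribute_no_loss(self):
        V = np.array([[1.0, 2.0]])
        vbar = np.array([[5.0, 2.0]])
        assert masked_loss(vbar, V, np.array([[0.0, 1.0]])) == 0.0

    def test_fully_masked_sample_zero_loss(self):
        V = np.ones((1, 3))
        assert masked_loss(V + 7, V, np.zeros((1, 3))) == 0.0

    def test_gradient_zero_for_masked_cell(self):
        rng = np.random.default_rng(0)
        params = init_sae_params(3, 2, seed=1)
        V = rng.normal(size=(4, 3))
        mask = np.ones((4, 3))
        mask[:, 2] = 0.0
        _, grads = _sae_backward(params, V, mask)
        # perturbing a masked target leaves the loss unchanged
        V2 = V.copy()
        V2[:, 2] += 10.0
        _, grads2 = _sae_backward(params, V2, mask)
        assert np.allclose(grads["W2"][:, 2], grads2["W2"][:, 2])

    def test_sae_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        params = init_sae_params(4, 3, seed=2)
        V = rng.normal(size=(5, 4))
        mask = (rng.random((5, 4)) < 0.7).astype(float)
        _, grads = _sae_backward(params, V, mask)
        eps = 1e-6
        for key in params:
            ix = np.unravel_index(rng.integers(params[key].size), params[key].shape)
            orig = params[key][ix]
            params[key][ix] = orig + eps
            lp, _ = _sae_backward(params, V, mask)
            params[key][ix] = orig - eps
            lm, _ = _sae_backward(params, V, mask)
            params[key][ix] = orig
            assert grads[key][ix] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_rank1_static_recovery(self):
        rng = np.random.default_rng(6)
        n, D = 80, 6
        V = rng.normal(size=(n, 1)) @ rng.normal(size=(1, D))
        mask = (rng.random((n, D)) < 0.8).astype(float)
        cfg = TrainConfig(n_folds=2, epochs=80, bottleneck=4, seed=4, batch_size=16, patience=40)
        folds = [np.arange(0, n // 2), np.arange(n // 2, n)]
        results = train_sae(V, mask, cfg, folds, np.arange(n))
        _, vbar = sae_forward(results[0].params, V)
        mse = float(np.sum(mask * (vbar - V) ** 2) / mask.sum())
        assert mse < V[mask == 1].var()
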