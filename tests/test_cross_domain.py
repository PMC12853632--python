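import numpy as np
import pytest

from herbrec.corpus import build_cooccurrence, build_vocabularies
from herbrec.cross_domain import (AutoencoderConfig, AutoencoderParams,
                                  CPMConfig, ObservedVector,
                                  assemble_embeddings, cdl_loss, cpm_loss,
                                  domain_classifier_accuracy, encode_decode,
                                  init_cpm, latent_features, padded_profiles,
                                  read_embeddings_tsv, train_autoencoder,
                                  train_cpm, write_embeddings_tsv)
from conftest import random_records


def vec(values, mask=None, entity="e", domain="source"):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return ObservedVector(values, mask, entity, domain)


def hand_params(alpha=0.0):
    """2-latent autoencoder on 3-dim inputs with hand-set weights."""
    W1 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]])
    b1 = np.array([0.1, -0.2])
    W2 = np.array([[0.5, 0.0, 1.0], [1.0, 0.5, 0.0]])
    b2 = np.array([0.0, 0.1, -0.3])
    return AutoencoderParams(W1, b1, W2, b2, alpha=alpha)


class TestEncodeDecode:
    def test_zero_parameters_give_zero(self):
        p = AutoencoderParams(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 3)), np.zeros(3))
        np.testing.assert_array_equal(encode_decode(np.array([1.0, 2.0, 3.0]), p), 0.0)

    def test_identity_weights_pass_nonnegative_input(self):
        p = AutoencoderParams(np.eye(3), np.zeros(3), np.eye(3), np.zeros(3))
        y = np.array([0.0, 2.0, 5.0])
        np.testing.assert_allclose(encode_decode(y, p), y)

    def test_matches_pencil_and_paper(self):
        p = hand_params()
        y = np.array([1.0, 2.0, 0.5])
        # hand evaluation, scalar by scalar
        h = np.maximum(y @ p.W1 + p.b1, 0.0)
        expected = np.maximum(h @ p.W2 + p.b2, 0.0)
        out = encode_decode(y, p)
        np.testing.assert_allclose(out, expected)
        # first latent unit: 1*1 + 2*0 + 0.5*1 + 0.1 = 1.6
        assert h[0] == pytest.approx(1.6)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            encode_decode(np.ones(4), hand_params())

    def test_output_nonnegative(self):
        rng = np.random.default_rng(0)
        p = AutoencoderParams.init(rng, 6, 3)
        out = encode_decode(rng.normal(size=6), p)
        assert (out >= 0).all()


class TestCdlLoss:
    def test_perfect_reconstruction_zero(self):
        p = AutoencoderParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        assert cdl_loss([vec([1.0, 4.0])], p) == pytest.approx(0.0)

    def test_zero_prediction_observed_three_four(self):
        p = AutoencoderParams(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 2)), np.zeros(2))
        assert cdl_loss([vec([3.0, 4.0])], p) == pytest.approx(25.0)

    def test_matches_brute_force_with_penalty(self):
        rng = np.random.default_rng(1)
        p = hand_params(alpha=0.5)
        batch = [vec(rng.uniform(0, 3, 3), rng.random(3) > 0.3) for _ in range(4)]
        total = 0.0
        for v in batch:
            yhat = encode_decode(v.values, p)
            for j in range(3):
                if v.mask[j]:
                    total += (yhat[j] - v.values[j]) ** 2
        total += 0.5 * (np.sum(p.W1**2) + np.sum(p.W2**2) + np.sum(p.b1**2) + np.sum(p.b2**2))
        assert cdl_loss(batch, p) == pytest.approx(total)

    def test_unobserved_positions_ignored(self):
        p = hand_params()
        base = vec([1.0, 2.0, 3.0], [True, False, True])
        perturbed = vec([1.0, 99.0, 3.0], [True, False, True])
        # only the masked (unobserved) entry differs, but it still feeds the
        # encoder, so zero it on input per the padded-profile convention
        base2 = vec([1.0, 0.0, 3.0], [True, False, True])
        pert2 = vec([1.0, 0.0, 3.0], [True, False, True])
        assert cdl_loss([base2], p) == cdl_loss([pert2], p)
        # and the loss never charges the unobserved coordinate
        yhat = encode_decode(base2.values, p)
        manual = (yhat[0] - 1.0) ** 2 + (yhat[2] - 3.0) ** 2
        assert cdl_loss([base2], p) == pytest.approx(manual)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            hand_params(alpha=-1.0)

    def test_analytic_gradient_matches_finite_differences(self):
        # the training loop's backprop against a central-difference oracle
        rng = np.random.default_rng(2)
        Y = rng.uniform(0, 2, (3, 4))
        O = (rng.random((3, 4)) > 0.3)
        batch = [vec(Y[i] * O[i], O[i]) for i in range(3)]
        p = AutoencoderParams.init(rng, 4, 2, alpha=0.1)

        def loss_at(W1):
            q = AutoencoderParams(W1, p.b1, p.W2, p.b2, p.alpha)
            return cdl_loss(batch, q)

        # analytic gradient of the masked loss wrt W1
        Yb = np.stack([v.values for v in batch])
        Ob = np.stack([v.mask for v in batch]).astype(float)
        h_pre = Yb @ p.W1 + p.b1
        h = np.maximum(h_pre, 0)
        out_pre = h @ p.W2 + p.b2
        out = np.maximum(out_pre, 0)
        d_out = 2 * Ob * (out - Yb) * (out_pre > 0)
        dW1 = Yb.T @ (d_out @ p.W2.T * (h_pre > 0)) + 2 * p.alpha * p.W1
        eps = 1e-6
        for idx in [(0, 0), (1, 1), (3, 0)]:
            Wp, Wm = p.W1.copy(), p.W1.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            numeric = (loss_at(Wp) - loss_at(Wm)) / (2 * eps)
            assert dW1[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-6)


class TestTrainAutoencoder:
    def test_zero_epochs_returns_seeded_init(self):
        batch = [vec([1.0, 2.0, 0.0])]
        cfg = AutoencoderConfig(latent_dim=2, max_epochs=0, seed=5)
        params = train_autoencoder(batch, cfg)
        expected = AutoencoderParams.init(np.random.default_rng(5), 3, 2)
        np.testing.assert_array_equal(params.W1, expected.W1)

    def test_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0.5, 2.0, 8)
        v = rng.uniform(0.5, 2.0, 6)
        M = np.outer(u, v)
        batch = [vec(M[i]) for i in range(8)]
        cfg = AutoencoderConfig(latent_dim=2, lr=1e-2, max_epochs=2000, patience=200, seed=3)
        params = train_autoencoder(batch, cfg)
        mse = cdl_loss(batch, params)
        zero_loss = float(np.sum(M**2))
        assert mse < 0.10 * zero_loss

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        batch = [vec(rng.uniform(0, 2, 5)) for _ in range(6)]
        cfg = AutoencoderConfig(latent_dim=2, max_epochs=50, seed=9)
        a = train_autoencoder(batch, cfg)
        b = train_autoencoder(batch, cfg)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_training_never_exceeds_initial_loss(self):
        rng = np.random.default_rng(6)
        batch = [vec(rng.uniform(0, 2, 5)) for _ in range(6)]
        cfg0 = AutoencoderConfig(latent_dim=2, max_epochs=0, seed=2)
        cfg = AutoencoderConfig(latent_dim=2, max_epochs=100, seed=2)
        init_loss = cdl_loss(batch, train_autoencoder(batch, cfg0))
        final_loss = cdl_loss(batch, train_autoencoder(batch, cfg))
        assert final_loss <= init_loss


class TestLatentFeatures:
    def test_zero_weights(self):
        p = hand_params()
        p.W1[...] = 0.0
        p.b1[...] = 0.0
        np.testing.assert_array_equal(latent_features(np.ones(3), p), 0.0)

    def test_hand_computation(self):
        p = hand_params()
        y = np.array([2.0, 0.0, 1.0])
        # W1.T y + b1 = [2+1+0.1, 0-1-0.2] -> relu -> [3.1, 0]
        np.testing.assert_allclose(latent_features(y, p), [3.1, 0.0])

    def test_nonnegative(self):
        rng = np.random.default_rng(7)
        p = AutoencoderParams.init(rng, 5, 3)
        assert (latent_features(rng.normal(size=5), p) >= 0).all()


class TestCPM:
    def _params(self, mu=0.0, lam=0.0, dim=4, seed=0):
        cfg = CPMConfig(mu=mu, lam=lam, hidden=8)
        return init_cpm(np.random.default_rng(seed), dim, dim, cfg)

    def test_mu_lam_zero_equals_prediction_loss(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 4))
        labels = ["source"] * 3 + ["target"] * 3
        p = self._params()
        f = p.extractor(X)
        expected = float(np.sum((p.predictor(f) - X) ** 2))
        assert cpm_loss(X, X, labels, p) == pytest.approx(expected)

    def test_brute_force_term_by_term(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 4))
        T = rng.normal(size=(4, 4))
        labels = ["source", "target", "target", "source"]
        p = self._params(mu=0.7, lam=0.3)
        f = p.extractor(X)
        pred = float(np.sum((p.predictor(f) - T) ** 2))
        logits = p.classifier(f).ravel()
        y = np.array([0.0, 1.0, 1.0, 0.0])
        probs = 1 / (1 + np.exp(-logits))
        ce = float(-np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
        reg = p.sq_norm()
        assert cpm_loss(X, T, labels, p) == pytest.approx(pred - 0.7 * ce + 0.3 * reg)

    def test_bad_label_rejected(self):
        p = self._params()
        with pytest.raises(ValueError, match="middle"):
            cpm_loss(np.ones((1, 4)), np.ones((1, 4)), ["middle"], p)

    def test_zero_epochs_passthrough(self):
        rng = np.random.default_rng(10)
        Fs, Ft = rng.normal(size=(5, 4)), rng.normal(size=(6, 4))
        cfg = CPMConfig(max_epochs=0, hidden=8, seed=1)
        rs, rt, params = train_cpm(Fs, Ft, cfg)
        # features pass through standardization and the initial extractor only
        X = np.vstack([Fs, Ft])
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_array_equal(rs, params.extractor(Z[:5]))
        np.testing.assert_array_equal(rt, params.extractor(Z[5:]))

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        Fs, Ft = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        cfg = CPMConfig(max_epochs=30, hidden=8, seed=2)
        a = train_cpm(Fs, Ft, cfg)[0]
        b = train_cpm(Fs, Ft, cfg)[0]
        np.testing.assert_array_equal(a, b)

    def test_adversarial_training_confuses_domains(self):
        # features drawn from shifted Gaussians: trivially separable before,
        # much less so after adversarial refinement
        rng = np.random.default_rng(12)
        d = 8
        Fs = rng.normal(size=(80, d)) + 1.5
        Ft = rng.normal(size=(80, d)) - 1.5
        cfg = CPMConfig(mu=1.0, hidden=32, lr=1e-2, max_epochs=400,
                        patience=400, seed=3)
        rs, rt, params = train_cpm(Fs, Ft, cfg)
        acc_after = domain_classifier_accuracy(params, Fs, Ft)
        # before: classifier trained alone (extractor frozen at init)
        cfg_clf_only = CPMConfig(mu=0.0, hidden=32, lr=1e-2, max_epochs=400,
                                 patience=400, seed=3)
        _, _, p0 = train_cpm(Fs, Ft, cfg_clf_only)
        acc_before = domain_classifier_accuracy(p0, Fs, Ft)
        assert abs(acc_after - 0.5) < abs(acc_before - 0.5)


class TestAssembleEmbeddings:
    def test_single_domain_verbatim(self):
        v = np.array([1.0, 2.0])
        E, prov = assemble_embeddings({}, {"h1": v}, ["h1"])
        np.testing.assert_array_equal(E[0], v)
        assert prov == ["target"]

    def test_mean_is_idempotent_on_identical_vectors(self):
        v = np.array([1.0, 2.0])
        E, prov = assemble_embeddings({"h": v}, {"h": v}, ["h"])
        np.testing.assert_array_equal(E[0], v)
        assert prov == ["both"]

    def test_mean_of_distinct_vectors(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        E, _ = assemble_embeddings({"h": u}, {"h": v}, ["h"])
        np.testing.assert_allclose(E[0], [0.5, 1.0])

    def test_concat_policy_doubles_width(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        E, _ = assemble_embeddings({"h": u}, {"h": v}, ["h"], policy="concat")
        np.testing.assert_allclose(E[0], [1.0, 0.0, 0.0, 2.0])

    def test_missing_term_errors(self):
        with pytest.raises(KeyError, match="ghost"):
            assemble_embeddings({}, {}, ["ghost"])


class TestProfilesAndIO:
    def test_padded_profiles_share_width(self):
        rng = np.random.default_rng(13)
        recs = random_records(rng, n=14)
        sv, hv = build_vocabularies(recs)
        cs = build_cooccurrence(recs, sv, hv, "source")
        ct = build_cooccurrence(recs, sv, hv, "target")
        profiles = padded_profiles(cs, ct, "herb")
        widths = {len(v.values) for v in profiles}
        assert len(widths) == 1
        assert widths.pop() == max(len(cs.col_terms), len(ct.col_terms))
        for v in profiles:
            np.testing.assert_array_equal(v.mask, v.values > 0)

    def test_embeddings_tsv_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(14)
        terms = ["甘草", "t2", "t3"]
        M = rng.normal(size=(3, 4))
        path = tmp_path / "emb.tsv"
        write_embeddings_tsv(terms, M, path)
        terms2, M2 = read_embeddings_tsv(path)
        assert terms2 == terms
        np.testing.assert_array_equal(M2, M)  # exact at 17 significant digits
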