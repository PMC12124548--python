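"""Model assembly, gradient reversal, training mechanics and prediction."""

import numpy as np
import pytest

import mdann as M
from mdann import mdann_core as core


@pytest.fixture(scope="module")
def tiny_setup():
    spec = M.BiasSpec(n=60, image_size=(16, 16),
                      attributes=[M.AttributeSpec("sex", 3.0, 0.5),
                                  M.AttributeSpec("hand", 2.0, 0.5)], seed=2)
    cohort = M.generate_cohort(spec)
    cae_cfg = M.CAEConfig(depth=2, base_channels=4, input_size=(16, 16), epochs=2)
    cae = M.pretrain_cae(cohort, cae_cfg, seed=0)
    return cohort, cae_cfg, cae


class TestAveragedGradientReversal:
    def test_mean_and_scale(self):
        fwd = np.zeros(2)
        g1, g2 = np.array([2.0, 0.0]), np.array([0.0, 2.0])
        out, rev = M.averaged_gradient_reversal(fwd, [g1, g2], lam=1.0)
        np.testing.assert_array_equal(out, fwd)
        np.testing.assert_array_equal(rev, [-1.0, -1.0])

    def test_zero_lambda_inert(self):
        _, rev = M.averaged_gradient_reversal(np.zeros(3), [np.ones(3)], lam=0.0)
        np.testing.assert_array_equal(rev, np.zeros(3))

    def test_single_component_is_classical_reversal(self):
        g = np.array([0.5, -1.5])
        _, rev = M.averaged_gradient_reversal(np.zeros(2), [g], lam=1.0)
        np.testing.assert_array_equal(rev, -g)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            M.averaged_gradient_reversal(np.zeros(2),
                                         [np.zeros(2), np.zeros(3)], 1.0)


class TestBuild:
    def test_embedding_dim_is_bottleneck_channels(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=2)
        model = M.build_mdann(cfg, cae, seed=0)
        assert model.embedding_dim == 8  # base 4, depth 2
        e = M.embed(model, cohort.images[:5])
        assert e.shape == (5, 8)

    def test_same_seed_identical_weights(self, tiny_setup):
        _, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=1)
        m1 = M.build_mdann(cfg, cae, seed=9)
        m2 = M.build_mdann(cfg, cae, seed=9)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_config_mismatch_rejected(self, tiny_setup):
        _, cae_cfg, cae = tiny_setup
        other = M.CAEConfig(depth=1, base_channels=4, input_size=(16, 16))
        with pytest.raises(ValueError, match="does not match"):
            M.build_mdann(M.MDANNConfig(encoder=other), cae, seed=0)

    def test_encoder_initialized_from_cae(self, tiny_setup):
        _, cae_cfg, cae = tiny_setup
        model = M.build_mdann(M.MDANNConfig(encoder=cae_cfg), cae, seed=0)
        for p_new, p_old in zip(model.encoder.params(), cae.encoder.params()):
            np.testing.assert_array_equal(p_new.value, p_old.value)


class TestGradientContract:
    @pytest.mark.parametrize("n_adversarial", [1, 2, 3])
    def test_encoder_gradient_decomposition(self, n_adversarial, rng):
        """Total encoder gradient is dL_pred/denc - lam/K * sum dL_AC/denc,
        checked against central finite differences on a toy encoder."""
        lam = 0.7
        cae_cfg = M.CAEConfig(depth=1, base_channels=2, input_size=(8, 8))
        cae = M.build_cae(cae_cfg, seed=n_adversarial)
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=n_adversarial,
                            ac_hidden=4, predictor_hidden=(5, 3),
                            reversal_lambda=lam)
        model = M.build_mdann(cfg, cae, seed=n_adversarial)
        x = rng.uniform(0, 1, (6, 8, 8))
        labels = np.array([1, 0, 1, 0, 1, 0])
        attrs = rng.integers(0, 2, (6, n_adversarial))
        attrs[0], attrs[1] = 1, 0
        for head in [model.predictor] + model.acs:
            head.p = 0.4
        grad = M.encoder_gradient(model, x, labels, attrs, lam=lam)

        h = 1e-5
        k = 0
        for p in model.encoder.params():
            flat = p.value.ravel()
            for i in range(flat.size):
                flat[i] += h
                up_p, up_ac = M.head_losses(model, x, labels, attrs)
                flat[i] -= 2 * h
                dn_p, dn_ac = M.head_losses(model, x, labels, attrs)
                flat[i] += h
                fd = ((up_p - lam * np.mean(up_ac))
                      - (dn_p - lam * np.mean(dn_ac))) / (2 * h)
                assert abs(fd - grad[k]) <= 1e-5 * max(abs(fd), 1e-3)
                k += 1
        assert k == grad.size


class TestTrainingMechanics:
    def test_lambda_zero_matches_k_zero_trajectory(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        idx = np.arange(cohort.n)
        runs = []
        for n_adv, lam in ((0, 0.0), (2, 0.0)):
            cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=n_adv,
                                reversal_lambda=lam, epochs=3)
            model = M.build_mdann(cfg, cae, seed=4)
            M.train_mdann(model, cohort, idx, seed=4)
            runs.append([p.value.copy() for p in model.encoder.params()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_single_class_batch_skipped(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=0,
                            predictor_loss="minimax")
        model = M.build_mdann(cfg, cae, seed=0)
        out = M.train_step(model, cohort.images[:4], np.ones(4, dtype=int))
        assert out is None
        assert model.skipped_batches == 1

    def test_history_lengths_match_epochs(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=2, epochs=4)
        model = M.build_mdann(cfg, cae, seed=0)
        M.train_mdann(model, cohort, np.arange(48), val_idx=np.arange(48, 60),
                      seed=0)
        for key in ("predictor_loss", "val_AUC", "ac0_AUC", "ac1_AUC"):
            assert len(model.history[key]) == 4

    def test_training_learns_signal(self):
        """With no adversary, held-out AUC beats chance on a learnable cohort."""
        spec = M.BiasSpec(n=120, image_size=(16, 16), label_amplitude=0.3,
                          attributes=[M.AttributeSpec("sex", 3.0, 0.8)], seed=3)
        cohort = M.generate_cohort(spec)
        cae_cfg = M.CAEConfig(depth=2, base_channels=4, input_size=(16, 16),
                              epochs=3)
        cae = M.pretrain_cae(cohort, cae_cfg, seed=1)
        folds = M.stratified_kfold(cohort.labels, cohort.coded_attributes, 5, 1)
        tr, te = np.flatnonzero(folds != 0), np.flatnonzero(folds == 0)
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=0, epochs=15)
        model = M.build_mdann(cfg, cae, seed=1)
        M.train_mdann(model, cohort, tr, val_idx=te, seed=1)
        assert model.history["val_AUC"][-1] > 0.6

    def test_adversary_pushes_ac_auc_toward_chance(self):
        """Relative to a reversal-free control, adversarial training drifts
        the AC's held-out AUC on its attribute toward 0.5 (seed-averaged)."""
        drifts = []
        for seed in range(3):
            spec = M.BiasSpec(n=160, image_size=(32, 32),
                              attributes=[M.AttributeSpec("sex", 3.0, 0.5)],
                              seed=seed)
            cohort = M.generate_cohort(spec)
            folds = M.stratified_kfold(cohort.labels, cohort.coded_attributes,
                                       5, seed)
            tr, te = np.flatnonzero(folds != 0), np.flatnonzero(folds == 0)
            cae_cfg = M.CAEConfig(depth=2, base_channels=8,
                                  input_size=(32, 32), epochs=8)
            cae = M.pretrain_cae(cohort.subset(tr), cae_cfg, seed=seed)
            auc = {}
            for lam in (0.0, 3.0):
                cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=1,
                                    epochs=25, reversal_lambda=lam,
                                    reversal_norm_cap=1.5)
                model = M.build_mdann(cfg, cae, seed=seed)
                M.train_mdann(model, cohort, tr, val_idx=te, seed=seed)
                auc[lam] = model.history["ac0_AUC"][-1]
            drifts.append(abs(auc[0.0] - 0.5) - abs(auc[3.0] - 0.5))
        assert np.mean(drifts) > 0

    def test_too_many_acs_rejected(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=3)
        model = M.build_mdann(cfg, cae, seed=0)
        with pytest.raises(ValueError, match="attribute"):
            M.train_mdann(model, cohort, np.arange(40), seed=0)


class TestPredict:
    def test_deterministic_and_bounded(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        model = M.build_mdann(M.MDANNConfig(encoder=cae_cfg), cae, seed=0)
        s1, y1 = M.predict(model, cohort.images[:10])
        s2, y2 = M.predict(model, cohort.images[:10])
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(y1, y2)
        assert ((0 <= s1) & (s1 <= 1)).all()

    def test_threshold_semantics(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        model = M.build_mdann(M.MDANNConfig(encoder=cae_cfg), cae, seed=0)
        _, y_hat = M.predict(model, cohort.images[:10], threshold=0.0)
        assert (y_hat == 1).all()

    def test_invalid_threshold_rejected(self, tiny_setup):
        cohort, cae_cfg, cae = tiny_setup
        model = M.build_mdann(M.MDANNConfig(encoder=cae_cfg), cae, seed=0)
        with pytest.raises(ValueError, match="threshold"):
            M.predict(model, cohort.images[:5], threshold=1.5)


class TestCheckpointing:
    def test_round_trip(self, tiny_setup, tmp_path):
        cohort, cae_cfg, cae = tiny_setup
        cfg = M.MDANNConfig(encoder=cae_cfg, n_adversarial=1, epochs=2)
        model = M.build_mdann(cfg, cae, seed=0)
        M.train_mdann(model, cohort, np.arange(48), seed=0)
        M.save_mdann(model, tmp_path)
        back = M.load_mdann(tmp_path)
        s1, _ = M.predict(model, cohort.images[:8])
        s2, _ = M.predict(back, cohort.images[:8])
        np.testing.assert_array_equal(s1, s2)
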