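import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vaemarker as vm
from vaemarker import _nn
from vaemarker.vaejmlp import _VaeMlpNet, kl_gaussian


class TestLossPrimitives:
    def test_reparameterization_identity(self):
        # zero noise passes mu through; unit scale passes noise through
        assert vm.reparameterize(0.5, np.array([0.1]), 0.0) == 0.5
        e = np.array([1.7, -0.3])
        assert np.allclose(vm.reparameterize(np.zeros(2), np.ones(2), e), e)
        assert vm.reparameterize(1.0, np.array([2.0]), -0.5) == 0.0

    def test_reparameterize_requires_positive_sigma(self):
        with pytest.raises(vm.ValidationError):
            vm.reparameterize(0.0, np.array([0.0]), 1.0)

    def test_kl_closed_form_values(self):
        assert kl_gaussian(np.zeros(4), np.ones(4)) == 0.0
        # single unit, mu=1, sigma=1: 0.5*(1 + 1 - 0 - 1) = 0.5
        assert kl_gaussian(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6),
           st.lists(st.floats(0.05, 5), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kl_nonnegative_with_equality_iff_standard(self, mu, sigma):
        k = min(len(mu), len(sigma))
        mu, sigma = np.array(mu[:k]), np.array(sigma[:k])
        kl = kl_gaussian(mu, sigma)
        assert kl >= -1e-12
        if np.allclose(mu, 0) and np.allclose(sigma, 1):
            assert kl == pytest.approx(0.0, abs=1e-12)
        elif np.abs(mu).max() > 1e-3 or np.abs(sigma - 1).max() > 1e-3:
            assert kl > 0

    def test_vae_loss_components(self):
        x = np.array([[0.3, 0.8]])
        total, bce, kl = vm.vae_loss(x, x, np.zeros((1, 2)), np.ones((1, 2)))
        entropy = -(0.3 * np.log(0.3) + 0.7 * np.log(0.7)
                    + 0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert kl == pytest.approx(0.0)
        assert bce == pytest.approx(entropy)
        assert total == pytest.approx(bce + kl)

    def test_vae_loss_rejects_out_of_range_reconstruction(self):
        with pytest.raises(vm.ValidationError, match="sigmoid"):
            vm.vae_loss(np.array([[0.5]]), np.array([[1.2]]),
                        np.zeros((1, 1)), np.ones((1, 1)))

    def test_joint_loss_weighting(self):
        assert vm.joint_loss(10.0, 0.7, 0.001) == pytest.approx(0.71)
        assert vm.joint_loss(123.0, 0.7, 0.0) == 0.7
        assert vm.joint_loss(0.0, 0.7, 0.5) == 0.7

    @given(st.floats(0, 100), st.floats(0, 10), st.floats(0, 1),
           st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_joint_loss_linear_in_each_argument(self, lv, lm, lam, c):
        base = vm.joint_loss(lv, lm, lam)
        assert vm.joint_loss(c * lv, lm, lam) == pytest.approx(
            base + (c - 1) * lam * lv, rel=1e-9, abs=1e-9)
        assert vm.joint_loss(lv, c * lm, lam) == pytest.approx(
            base + (c - 1) * lm, rel=1e-9, abs=1e-9)


class TestArchitecture:
    def test_decoder_mirrors_encoder(self):
        arch = vm.ArchitectureSpec(input_dim=500)
        assert arch.decoder_widths == tuple(reversed(arch.encoder_widths))

    def test_scaled_keeps_ratio_with_floor(self):
        arch = vm.ArchitectureSpec.scaled(300)
        latent = arch.latent_dim
        assert arch.encoder_widths == (8 * latent, 8 * latent, 4 * latent,
                                       latent)
        tiny = vm.ArchitectureSpec.scaled(10)
        assert tiny.latent_dim == 8  # floor

    def test_schedule_phase_sum_validated(self):
        bad = vm.TrainingSchedule(total_epochs=250, vae_only_epochs=50,
                                  mlp_only_epochs=50, joint_epochs=100)
        with pytest.raises(vm.ValidationError, match="sum"):
            bad.validate()
        vm.TrainingSchedule().validate()  # defaults are consistent


def _tiny_sched(**kw):
    base = dict(total_epochs=6, vae_only_epochs=2, mlp_only_epochs=2,
                joint_epochs=2, batch_size=16, seed=0)
    base.update(kw)
    return vm.TrainingSchedule(**base)


def _tiny_setup(sim300, n_genes=30):
    counts, labels, truth = sim300
    genes = list(truth.biomarker_gene_ids) \
        + [g for g in counts.gene_ids if g not in set(truth.de_gene_ids)][:20]
    sub = counts.subset_genes(genes[:n_genes])
    train_ids, test_ids = vm.vaejmlp.stratified_split(labels, 0.2, 0)
    scaled = vm.minmax_scale(sub, train_ids, log2=True)
    return scaled, labels, (train_ids, test_ids)


class TestTraining:
    def test_phase_isolation(self, sim300):
        """VAE-only epochs leave the classifier untouched and vice versa."""
        scaled, labels, split = _tiny_setup(sim300)
        arch = vm.ArchitectureSpec.scaled(30)
        init_net = _VaeMlpNet(arch, np.random.default_rng(0))

        vae_only = vm.train(scaled, labels, arch, _tiny_sched(
            total_epochs=3, vae_only_epochs=3, mlp_only_epochs=0,
            joint_epochs=0), split=split)
        for got, init in zip(vae_only.net.mlp_parameters(),
                             init_net.mlp_parameters()):
            assert np.array_equal(got.value, init.value)
        assert any(not np.array_equal(g.value, i.value)
                   for g, i in zip(vae_only.net.vae_parameters(),
                                   init_net.vae_parameters()))

        mlp_only = vm.train(scaled, labels, arch, _tiny_sched(
            total_epochs=3, vae_only_epochs=0, mlp_only_epochs=3,
            joint_epochs=0), split=split)
        for got, init in zip(mlp_only.net.vae_parameters(),
                             init_net.vae_parameters()):
            assert np.array_equal(got.value, init.value)
        assert any(not np.array_equal(g.value, i.value)
                   for g, i in zip(mlp_only.net.mlp_parameters(),
                                   init_net.mlp_parameters()))

    def test_deterministic_under_seed(self, sim300):
        scaled, labels, split = _tiny_setup(sim300)
        arch = vm.ArchitectureSpec.scaled(30)
        a = vm.train(scaled, labels, arch, _tiny_sched(), split=split)
        b = vm.train(scaled, labels, arch, _tiny_sched(), split=split)
        assert a.loss_trace[-1] == b.loss_trace[-1]
        assert a.metrics == b.metrics

    def test_vae_phase_loss_decreases(self, trained_toy):
        model, _, _, _ = trained_toy
        vae_trace = [e["vae"] for e in model.loss_trace if e["phase"] == "vae"]
        assert vae_trace[-1] < vae_trace[0]

    def test_kl_trace_nonnegative(self, trained_toy):
        model, _, _, _ = trained_toy
        assert all(e["kl"] >= 0 for e in model.loss_trace)
        assert all(np.isfinite(e["total"]) for e in model.loss_trace)

    def test_separable_data_reaches_high_auc(self, trained_toy):
        model, _, _, _ = trained_toy
        assert model.metrics["auc"] >= 0.95

    def test_input_dim_mismatch_rejected(self, sim300):
        scaled, labels, split = _tiny_setup(sim300)
        with pytest.raises(vm.ValidationError, match="input_dim"):
            vm.train(scaled, labels, vm.ArchitectureSpec.scaled(99),
                     _tiny_sched(), split=split)


class TestEvaluateEncode:
    def test_metric_definitions_on_toy_model(self, trained_toy):
        model, scaled, labels, _ = trained_toy
        metrics = vm.evaluate(model, scaled, labels, split="test")
        for key in ("auc", "accuracy", "precision", "recall"):
            assert 0 <= metrics[key] <= 1

    def test_encode_deterministic_and_duplicate_rows(self, trained_toy):
        model, scaled, _, _ = trained_toy
        z1 = vm.encode(model, scaled)
        z2 = vm.encode(model, scaled)
        assert np.array_equal(z1, z2)
        assert z1.shape == (len(scaled.sample_ids), model.arch.latent_dim)

    def test_encode_matches_manual_forward_pass(self):
        """Hand-set two-layer encoder agrees with explicit matrix algebra."""
        arch = vm.ArchitectureSpec(input_dim=2, encoder_widths=(3,),
                                   latent_dim=2, mlp_widths=(2,))
        net = _VaeMlpNet(arch, np.random.default_rng(0))
        w1 = np.arange(6, dtype=float).reshape(2, 3) / 10
        b1 = np.array([0.1, -0.2, 0.3])
        w_mu = np.ones((3, 2))
        net.enc_hidden.layers[0].W.value[...] = w1
        net.enc_hidden.layers[0].b.value[...] = b1
        net.mu_head.W.value[...] = w_mu
        net.mu_head.b.value[...] = 0.0
        x = np.array([[1.0, -1.0]])
        h = x @ w1 + b1
        h = np.where(h > 0, h, 0.01 * h)  # LeakyReLU
        assert np.allclose(net.encode_mu(x), h @ w_mu)

    def test_checkpoint_round_trip(self, trained_toy, tmp_path):
        model, scaled, _, _ = trained_toy
        vm.vaejmlp.save_checkpoint(model, tmp_path / "ckpt")
        back = vm.vaejmlp.load_checkpoint(tmp_path / "ckpt")
        assert np.allclose(vm.encode(back, scaled), vm.encode(model, scaled))
        assert back.metrics == model.metrics
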