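import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latemix._nn import leaky_relu
from latemix.autoencoder import (SSAEArchitecture, SemiSupervisedAutoencoder,
                                 TrainConfig, build_ssae, corrupt,
                                 count_parameters, select_architecture,
                                 ssae_loss, train_ssae, train_usae_matched)


def _low_rank_data(n=400, p_in=30, rank=3, noise=0.05, seed=0):
    """Planted low-rank block plus targets that are linear in the factors.
    Columns are z-scored, as scaled omic blocks entering the SSAE would be."""
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, rank))
    W = rng.standard_normal((rank, p_in))
    X = F @ W + noise * rng.standard_normal((n, p_in))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Y = F @ rng.standard_normal((rank, 5)) + noise * rng.standard_normal((n, 5))
    return X, Y


class TestCorrupt:
    def test_sigma_zero_is_identity(self):
        X = np.arange(12.0).reshape(3, 4)
        out = corrupt(X, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, X)
        assert out is not X

    def test_noise_law(self):
        rng = np.random.default_rng(1)
        X = np.zeros((1000, 1000))
        delta = corrupt(X, 0.1, rng) - X
        assert abs(delta.std() - 0.1) < 0.001
        assert abs(delta.mean()) < 0.001

    def test_fixed_rng_reproducible(self):
        X = np.ones((5, 5))
        a = corrupt(X, 0.3, np.random.default_rng(2))
        b = corrupt(X, 0.3, np.random.default_rng(2))
        np.testing.assert_array_equal(a, b)


class TestLoss:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(3).standard_normal((4, 6))
        Y = np.random.default_rng(4).standard_normal((4, 2))
        for alpha in (0.0, 0.3, 1.0):
            assert ssae_loss(X, X, Y, Y, alpha) == 0.0

    def test_endpoints_recover_single_terms(self):
        rng = np.random.default_rng(5)
        X, Xp = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        Y, Yp = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        assert ssae_loss(X, Xp, Y, Yp, 1.0) == pytest.approx(
            np.mean((X - Xp) ** 2))
        assert ssae_loss(X, Xp, Y, Yp, 0.0) == pytest.approx(
            np.mean((Y - Yp) ** 2))

    def test_hand_example(self):
        # recon MSE = mean((1,0)-(0,0))^2 = 0.5; supervised MSE = 1
        assert ssae_loss([1.0, 0.0], [0.0, 0.0], [1.0], [0.0],
                         0.5) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.0, 1.0))
    def test_linear_in_alpha(self, alpha):
        rng = np.random.default_rng(6)
        X, Xp = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        Y, Yp = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        l0 = ssae_loss(X, Xp, Y, Yp, 0.0)
        l1 = ssae_loss(X, Xp, Y, Yp, 1.0)
        assert ssae_loss(X, Xp, Y, Yp, alpha) == pytest.approx(
            alpha * l1 + (1 - alpha) * l0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ssae_loss(np.zeros(3), np.zeros(4), np.zeros(2), np.zeros(2), 0.5)


class TestArchitecture:
    def test_parameter_count_closed_form(self):
        assert count_parameters(10, 4, 2, 5) == 137
        model = build_ssae(SSAEArchitecture(10, 4, 2, t=5), seed=0)
        assert model.n_parameters_ == 137
        # enumeration over the actual weight tensors
        total = sum(lay.W.size + lay.b.size for lay in model._all_layers())
        assert total == 137

    def test_leaky_relu_definition(self):
        assert leaky_relu(np.array(-2.0), 0.1) == pytest.approx(-0.2)
        assert leaky_relu(np.array(3.0), 0.1) == pytest.approx(3.0)

    def test_same_seed_same_initial_weights(self):
        a = build_ssae(SSAEArchitecture(8, 4, 2), seed=3)
        b = build_ssae(SSAEArchitecture(8, 4, 2), seed=3)
        for la, lb in zip(a._all_layers(), b._all_layers()):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            SSAEArchitecture(4, 8, 2)   # p > p_in
        with pytest.raises(ValueError):
            SSAEArchitecture(8, 4, 5)   # l > p
        with pytest.raises(ValueError):
            SSAEArchitecture(8, 4, 2, alpha=1.5)


class TestEncode:
    def test_linear_slope_network_is_matrix_product(self):
        model = build_ssae(SSAEArchitecture(6, 4, 3, r=0.0, leaky_slope=1.0),
                           seed=1)
        X = np.random.default_rng(7).standard_normal((10, 6))
        W1, W2 = (lay.W for lay in model.encoder_layers_)
        b1, b2 = (lay.b for lay in model.encoder_layers_)
        np.testing.assert_allclose(model.transform(X), (X @ W1 + b1) @ W2 + b2,
                                   atol=1e-6)

    def test_hand_forward_pass(self):
        # 2 -> 2 -> 1 with hand-set weights, slope 0.1
        model = build_ssae(SSAEArchitecture(2, 2, 1, leaky_slope=0.1), seed=0)
        e1, e2 = model.encoder_layers_
        e1.W[:] = [[1.0, -1.0], [2.0, 0.5]]
        e1.b[:] = [0.0, 1.0]
        e2.W[:] = [[1.0], [-2.0]]
        e2.b[:] = [0.5]
        x = np.array([[1.0, 2.0]])
        h = np.array([leaky_relu(np.array(5.0), 0.1),
                      leaky_relu(np.array(1.0), 0.1)])  # (5, 1)
        z_expected = leaky_relu(h[0] * 1.0 + h[1] * -2.0 + 0.5, 0.1)  # 3.5
        assert model.transform(x)[0, 0] == pytest.approx(z_expected)

    def test_width_mismatch_raises(self):
        model = build_ssae(SSAEArchitecture(6, 4, 3), seed=0)
        with pytest.raises(ValueError, match="width"):
            model.transform(np.zeros((2, 5)))


class TestTraining:
    def test_reconstruction_improves_on_planted_low_rank_data(self):
        wins = 0
        for seed in range(5):
            X, Y = _low_rank_data(seed=seed)
            model = SemiSupervisedAutoencoder(
                hidden_width=12, bottleneck_width=3, alpha=0.9,
                dropout_rate=0.1, corruption_sd=0.05, decay=0.98,
                learning_rate=3e-3, min_epochs=5, stop_window=5,
                max_epochs=40, random_state=seed)
            model.fit(X, Y)
            hist = model.history_["val_recon_mse"]
            if hist[-1] < 0.5 * hist[0]:
                wins += 1
        assert wins == 5

    def test_alpha_one_leaves_head_untrained(self):
        X, Y = _low_rank_data(n=150)
        model = SemiSupervisedAutoencoder(
            hidden_width=8, bottleneck_width=3, alpha=1.0, dropout_rate=0.0,
            corruption_sd=0.05, min_epochs=3, stop_window=3, max_epochs=6,
            random_state=0)
        ref = SemiSupervisedAutoencoder(**model.get_params())
        ref.initialize(X.shape[1], t=5)
        model.fit(X, Y)
        for trained, init in zip(model.head_layers_, ref.head_layers_):
            np.testing.assert_array_equal(trained.W, init.W)

    def test_stopping_rule_mechanics(self):
        # zero learning rate + no corruption: validation loss is constant, so
        # the moving-average rule must fire at exactly min_epochs + 1
        X, Y = _low_rank_data(n=120)
        model = SemiSupervisedAutoencoder(
            hidden_width=8, bottleneck_width=3, alpha=0.9, dropout_rate=0.0,
            corruption_sd=0.0, learning_rate=0.0, min_epochs=4, stop_window=1,
            max_epochs=50, random_state=0)
        model.fit(X, Y)
        assert model.n_epochs_ == 5
        assert model.stopped_reason_ == "early_stop"

    def test_requires_targets_when_supervised(self):
        with pytest.raises(ValueError, match="requires a target"):
            SemiSupervisedAutoencoder(alpha=0.5).fit(np.zeros((20, 4)))


class TestMatchedControl:
    def test_vacuous_target_stops_after_first_epoch(self):
        X, _ = _low_rank_data(n=120)
        arch = SSAEArchitecture(X.shape[1], 8, 3, r=0.0)
        cfg = TrainConfig(corruption_sd=0.05, min_epochs=2, stop_window=2,
                          max_epochs=10, seed=0)
        usae = train_usae_matched(arch, X, np.inf, cfg)
        assert usae.n_epochs_ == 1

    def test_unreachable_target_raises(self):
        X, _ = _low_rank_data(n=120, noise=0.3)
        arch = SSAEArchitecture(X.shape[1], 8, 3, r=0.0)
        cfg = TrainConfig(corruption_sd=0.1, min_epochs=2, stop_window=2,
                          max_epochs=5, seed=0)
        with pytest.raises(RuntimeError, match="not reached"):
            train_usae_matched(arch, X, 0.0, cfg)

    def test_paired_runs_match_within_one_epoch_increment(self):
        for seed in range(3):
            X, Y = _low_rank_data(seed=seed)
            arch = SSAEArchitecture(X.shape[1], 12, 3, r=0.1, alpha=0.9)
            cfg = TrainConfig(corruption_sd=0.05, min_epochs=5, stop_window=5,
                              max_epochs=40, seed=seed)
            ssae = train_ssae(arch, X, Y, cfg)
            usae = train_usae_matched(arch, X, ssae.val_recon_mse_,
                                      TrainConfig(corruption_sd=0.05,
                                                  min_epochs=5, stop_window=5,
                                                  max_epochs=120, seed=seed))
            hist = usae.history_["val_recon_mse"]
            assert usae.val_recon_mse_ <= ssae.val_recon_mse_
            if len(hist) > 1:
                # the previous epoch had not yet reached the target
                assert hist[-2] > ssae.val_recon_mse_


class TestArchitectureSelection:
    def test_smallest_feasible_candidate_wins(self):
        X, Y = _low_rank_data(n=300, p_in=20, rank=2, noise=0.02, seed=1)
        cfg = TrainConfig(corruption_sd=0.02, decay=0.98, learning_rate=3e-3,
                          min_epochs=4, stop_window=4, max_epochs=30, seed=0)
        grid = [(10, 2), (16, 4)]
        arch, model = select_architecture(grid, X, Y, cfg, mse_cap=1.5,
                                          corr_cap=1.0)
        assert (arch.p, arch.l) == (10, 2)
        assert count_parameters(20, 10, 2, 5) < count_parameters(20, 16, 4, 5)

    def test_infeasible_caps_raise_with_diagnostics(self):
        X, Y = _low_rank_data(n=150, p_in=10, rank=2, seed=2)
        cfg = TrainConfig(corruption_sd=0.02, min_epochs=2, stop_window=2,
                          max_epochs=4, seed=0)
        with pytest.raises(RuntimeError, match="no feasible"):
            select_architecture([(6, 2)], X, Y, cfg, mse_cap=-1.0, corr_cap=0.0)
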