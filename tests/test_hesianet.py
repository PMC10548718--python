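"""Siamese network architecture, losses, gradients and training behavior."""

import numpy as np
import pytest

from hesiagraph.dataset import FeatureBlock, LabelledPair
from hesiagraph.hesianet import (ChannelConfig, ModelConfig, TrainConfig,
                                 _loss_and_grads, bce_loss, channel_kl,
                                 expected_param_count, forward, init_model,
                                 load_model, predict_pairs, save_model, train)
from hesiagraph.synthetic import make_separable_fixture

SMALL = ModelConfig(channel=ChannelConfig(input_dim=8, layer_widths=(10, 6),
                                          dropout_rate=0.0), head_width=4)


class TestArchitecture:
    def test_default_heterogeneous_param_count(self):
        cfg = ModelConfig()
        model = init_model(cfg, seed=0)
        # independent oracle: sum of in*out + out over dense layers
        assert expected_param_count(cfg) == 2 * 697_280 + 2_113 == 1_396_673
        assert model.num_params() == 1_396_673

    def test_default_homogeneous_param_count(self):
        cfg = ModelConfig(weight_mode="homogeneous")
        model = init_model(cfg, seed=0)
        assert expected_param_count(cfg) == 697_280 + 2_113 == 699_393
        assert model.num_params() == 699_393

    def test_param_identity_small_config(self):
        hetero = init_model(SMALL, seed=1)
        homo = init_model(SMALL.replace(weight_mode="homogeneous"), seed=1)
        channel = sum(l.n_params for l in hetero.channel_f)
        head = hetero.head_hidden.n_params + hetero.head_out.n_params
        assert hetero.num_params() == 2 * channel + head
        assert homo.num_params() == channel + head

    def test_seeded_init_reproducible(self):
        x = np.random.default_rng(0).standard_normal(8)
        p1 = forward(init_model(SMALL, seed=7), x, x)[0]
        p2 = forward(init_model(SMALL, seed=7), x, x)[0]
        assert p1 == p2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ChannelConfig(layer_widths=(16, 0))
        with pytest.raises(ValueError):
            ModelConfig(head_width=0)
        with pytest.raises(ValueError):
            ModelConfig(weight_mode="diagonal")


class TestForward:
    def test_homogeneous_identical_inputs_zero_merge(self):
        model = init_model(SMALL.replace(weight_mode="homogeneous"), seed=2)
        x = np.random.default_rng(1).standard_normal(8)
        prob, eps_r, eps_p = forward(model, x, x)
        np.testing.assert_array_equal(eps_r, eps_p)
        assert 0 < prob < 1

    def test_heterogeneous_identical_inputs_differ(self):
        model = init_model(SMALL, seed=2)
        x = np.random.default_rng(1).standard_normal(8)
        _, eps_r, eps_p = forward(model, x, x)
        assert not np.array_equal(eps_r, eps_p)

    def test_merge_symmetry_of_absolute_difference(self):
        model = init_model(SMALL, seed=3)
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 8))
        # |eps_r - eps_p| is symmetric, so swapping the *channel outputs*
        # leaves the head input unchanged; check via the homogeneous model
        homo = init_model(SMALL.replace(weight_mode="homogeneous"), seed=3)
        assert forward(homo, a, b)[0] == pytest.approx(forward(homo, b, a)[0])

    def test_probability_in_open_interval(self):
        model = init_model(SMALL, seed=5)
        rng = np.random.default_rng(6)
        probs, _, _ = model.forward_batch(rng.standard_normal((20, 8)),
                                          rng.standard_normal((20, 8)))
        assert np.all((probs > 0) & (probs < 1))

    def test_shape_mismatch(self):
        model = init_model(SMALL, seed=0)
        with pytest.raises(ValueError):
            model.forward_batch(np.zeros((2, 5)), np.zeros((2, 8)))


class TestLosses:
    def test_bce_closed_forms(self):
        assert bce_loss(1, 0.5) == pytest.approx(np.log(2), rel=1e-9)
        assert bce_loss(0, 0.5) == pytest.approx(np.log(2), rel=1e-9)
        assert bce_loss(1, 1.0 - 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_bce_domain_error(self):
        with pytest.raises(ValueError):
            bce_loss(1, 1.5)
        with pytest.raises(ValueError):
            bce_loss(0, -0.1)

    def test_channel_kl_properties(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 12))
        assert channel_kl(a, a) == pytest.approx(0.0, abs=1e-12)
        assert channel_kl(a, b) > 0
        assert channel_kl(a, b) == pytest.approx(channel_kl(b, a))
        # invariant to a constant shift (softmax normalization)
        assert channel_kl(a + 3.0, b) == pytest.approx(channel_kl(a, b))

    def test_loss_affine_in_lambda(self):
        rng = np.random.default_rng(1)
        Xr, Xp = rng.standard_normal((2, 16, 8))
        y = rng.integers(0, 2, 16)
        losses = {}
        for lam in (0.0, 0.1, 1.0):
            model = init_model(SMALL.replace(kl_weight=lam), seed=4)
            losses[lam], bce, kl, _ = _loss_and_grads(model, Xr, Xp, y)
        # same seed -> same weights -> total(lam) = bce + lam * kl
        slope = losses[1.0] - losses[0.0]
        assert losses[0.1] == pytest.approx(losses[0.0] + 0.1 * slope, rel=1e-9)

    def test_lambda_zero_is_pure_bce(self):
        rng = np.random.default_rng(2)
        Xr, Xp = rng.standard_normal((2, 10, 8))
        y = rng.integers(0, 2, 10)
        model = init_model(SMALL.replace(kl_weight=0.0), seed=4)
        total, bce, kl, _ = _loss_and_grads(model, Xr, Xp, y)
        probs, _, _ = model.forward_batch(Xr, Xp)
        manual = np.mean([bce_loss(yi, pi) for yi, pi in zip(y, probs)])
        assert total == pytest.approx(bce) == pytest.approx(manual, rel=1e-9)

    def test_gradients_match_finite_differences(self):
        model = init_model(SMALL.replace(kl_weight=0.3), seed=3)
        rng = np.random.default_rng(0)
        Xr, Xp = rng.standard_normal((2, 7, 8))
        y = rng.integers(0, 2, 7)
        _, _, _, grads = _loss_and_grads(model, Xr, Xp, y)
        h = 1e-6
        for layer in model.layers():
            for arr, g in zip((layer.W, layer.b), grads[id(layer)]):
                flat = arr.reshape(-1)
                for i in range(0, flat.size, max(1, flat.size // 5)):
                    old = flat[i]
                    flat[i] = old + h
                    lp = _loss_and_grads(model, Xr, Xp, y)[0]
                    flat[i] = old - h
                    lm = _loss_and_grads(model, Xr, Xp, y)[0]
                    flat[i] = old
                    assert g.reshape(-1)[i] == pytest.approx(
                        (lp - lm) / (2 * h), rel=1e-4, abs=1e-7)


@pytest.fixture(scope="module")
def separable():
    return make_separable_fixture(n=200, dim=16, margin=2.0, seed=8)


class TestTraining:
    def test_fits_separable_fixture_to_perfect_accuracy(self, separable):
        cfg = ModelConfig(channel=ChannelConfig(input_dim=16,
                                                layer_widths=(24, 12),
                                                dropout_rate=0.0),
                          head_width=8, kl_weight=0.0)
        model = init_model(cfg, seed=1)
        model, hist = train(model, separable, separable,
                            TrainConfig(learning_rate=3e-3, max_epochs=200,
                                        early_stop_patience=200, seed=1))
        assert hist["train_acc"].max() == 1.0

    def test_early_stopping_triggers(self, separable):
        cfg = ModelConfig(channel=ChannelConfig(input_dim=16,
                                                layer_widths=(8,),
                                                dropout_rate=0.0),
                          head_width=4)
        model = init_model(cfg, seed=0)
        # learning rate so small the validation accuracy never improves
        model, hist = train(model, separable, separable,
                            TrainConfig(learning_rate=1e-12, max_epochs=100,
                                        early_stop_patience=2, seed=0))
        assert len(hist) <= 4

    def test_lr_reduction_recorded(self, separable):
        cfg = ModelConfig(channel=ChannelConfig(input_dim=16,
                                                layer_widths=(8,),
                                                dropout_rate=0.0),
                          head_width=4)
        model = init_model(cfg, seed=0)
        model, hist = train(model, separable, separable,
                            TrainConfig(learning_rate=1e-12, max_epochs=100,
                                        early_stop_patience=9,
                                        lr_reduce_patience=3,
                                        lr_reduce_factor=0.5, seed=0))
        assert hist["lr"].min() < 1e-12

    def test_training_deterministic_under_seed(self, separable):
        cfg = ModelConfig(channel=ChannelConfig(input_dim=16,
                                                layer_widths=(12, 6)),
                          head_width=4)
        hists = []
        for _ in range(2):
            model = init_model(cfg, seed=5)
            _, hist = train(model, separable, separable,
                            TrainConfig(learning_rate=1e-3, max_epochs=8,
                                        early_stop_patience=20, seed=5))
            hists.append(hist)
        assert hists[0]["train_loss"].tolist() == hists[1]["train_loss"].tolist()

    def test_single_class_training_rejected(self, separable):
        bad = FeatureBlock(separable.X[separable.y == 1],
                           separable.y[separable.y == 1])
        model = init_model(ModelConfig(channel=ChannelConfig(
            input_dim=16, layer_widths=(8,))), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, bad, separable, TrainConfig())


class TestPredictPairs:
    def test_threshold_strictly_greater(self, random_table):
        cfg = ModelConfig(channel=ChannelConfig(input_dim=8,
                                                layer_widths=(6, 4),
                                                dropout_rate=0.0),
                          head_width=3)
        model = init_model(cfg, seed=2)
        pairs = [LabelledPair("r0", "p0", 1)]
        (drug, dis, prob, label), = predict_pairs(model, pairs, random_table)
        # at threshold exactly equal to the score the call must be negative
        (_, _, _, at_thr), = predict_pairs(model, pairs, random_table,
                                           threshold=prob)
        assert at_thr == 0
        (_, _, _, below), = predict_pairs(model, pairs, random_table,
                                          threshold=prob - 1e-9)
        assert below == 1

    def test_empty_and_deterministic(self, random_table):
        model = init_model(ModelConfig(channel=ChannelConfig(
            input_dim=8, layer_widths=(6,))), seed=3)
        assert predict_pairs(model, [], random_table) == []
        pairs = [LabelledPair(f"r{i}", "p1", 0) for i in range(4)]
        assert predict_pairs(model, pairs, random_table) == \
            predict_pairs(model, pairs, random_table)


def test_save_load_roundtrip(tmp_path):
    model = init_model(SMALL.replace(kl_weight=0.2), seed=9)
    rng = np.random.default_rng(0)
    Xr, Xp = rng.standard_normal((2, 5, 8))
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    np.testing.assert_array_equal(model.forward_batch(Xr, Xp)[0],
                                  back.forward_batch(Xr, Xp)[0])
    assert back.config == model.config
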