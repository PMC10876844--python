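"""Classifier contracts: parameter formula, shapes, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bayeshead as bh
from bayeshead.errors import DivergedTrainingError
from bayeshead.layers import PReLU, ResidualBlock, SeparableConv3d, cross_entropy


class TestSeparableParamCount:
    @pytest.mark.parametrize(
        "C,K,O,expected",
        [(1, 3, 8, 35), (16, 3, 16, 688), (4, 1, 4, 20)],
    )
    def test_formula_examples(self, C, K, O, expected):
        assert bh.count_separable_params(C, K, O) == expected

    @given(
        C=st.integers(1, 16),
        K=st.sampled_from([1, 3, 5]),
        O=st.integers(1, 16),
    )
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_implemented_layer_matches_formula(self, C, K, O):
        layer = SeparableConv3d(C, O, K, stride=1, rng=np.random.default_rng(0))
        weights_only = sum(
            p.value.size for p in [layer.depthwise.weight, layer.pointwise.weight]
        )
        assert weights_only == bh.count_separable_params(C, K, O)
        assert layer.n_params() == bh.count_separable_params(C, K, O, with_bias=True)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            bh.count_separable_params(0, 3, 4)


class TestBuildNetwork:
    def test_halving_and_flatten_arithmetic(self):
        spec = bh.NetworkSpec(input_shape=(96, 96, 96), block_channels=(8, 16, 32))
        assert spec.flatten_size == 32 * 12**3 == 55_296

    def test_logit_shape_contract(self, tiny_net, rng):
        x = rng.normal(size=(3, 1, 8, 8, 8))
        assert tiny_net.forward(x).shape == (3, 2)

    def test_total_params_match_hand_count(self):
        """Independent tally of one small spec from the separable formula."""
        spec = bh.NetworkSpec(input_shape=(16, 16, 16), block_channels=(2, 4, 4))
        net = bh.build_network(spec, seed=0)
        expected = 0
        chans = (1, 2, 4, 4)
        for cin, cout in zip(chans[:-1], chans[1:]):
            expected += bh.count_separable_params(cin, 3, cout, with_bias=True)  # sep1
            expected += bh.count_separable_params(cout, 3, cout, with_bias=True)  # sep2
            expected += 2  # two PReLU slopes
            expected += cin * cout  # strided projection, no bias
        expected += 4 * 2**3 * 2 + 2  # head weights + biases
        assert net.n_params() == expected

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            bh.NetworkSpec(input_shape=(20, 20, 20))

    def test_init_deterministic(self):
        spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 2, 2))
        a = bh.build_network(spec, seed=7)
        b = bh.build_network(spec, seed=7)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_net, rng):
        x = rng.normal(size=(2, 1, 8, 8, 8))
        y = np.array([0, 1])
        loss, g = cross_entropy(tiny_net.forward(x), y)
        for p in tiny_net.params():
            p.zero_grad()
        gx = tiny_net.backward(g)
        eps = 1e-6
        # a spread of parameters: first depthwise weight, a PReLU slope, head
        params = tiny_net.params()
        for p in (params[0], params[4], params[-2], params[-1]):
            idx = tuple(0 for _ in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            l1, _ = cross_entropy(tiny_net.forward(x), y)
            p.value[idx] = orig - eps
            l2, _ = cross_entropy(tiny_net.forward(x), y)
            p.value[idx] = orig
            assert p.grad[idx] == pytest.approx((l1 - l2) / (2 * eps), abs=1e-6)
        i = (0, 0, 3, 4, 5)
        orig = x[i]
        x[i] = orig + eps
        l1, _ = cross_entropy(tiny_net.forward(x), y)
        x[i] = orig - eps
        l2, _ = cross_entropy(tiny_net.forward(x), y)
        x[i] = orig
        assert gx[i] == pytest.approx((l1 - l2) / (2 * eps), abs=1e-6)


class TestResidualBlock:
    def test_zeroed_convs_and_unit_slope_give_identity(self, rng):
        block = ResidualBlock(3, 3, kernel=3, stride=1, rng=np.random.default_rng(0))
        assert block.proj is None
        for sep in (block.sep1, block.sep2):
            for p in sep.params():
                p.value[...] = 0.0
        block.act1.slope.value[...] = 1.0
        block.act2.slope.value[...] = 1.0
        x = rng.normal(size=(2, 3, 8, 8, 8))
        assert np.allclose(block.forward(x), x)

    def test_stride2_block_halves_sides(self, rng):
        block = ResidualBlock(1, 4, kernel=3, stride=2, rng=np.random.default_rng(0))
        out = block.forward(rng.normal(size=(1, 1, 16, 16, 16)))
        assert out.shape == (1, 4, 8, 8, 8)


class TestTraining:
    def test_overfits_a_separable_batch(self):
        """Capacity check: many epochs on 8 easy volumes reach accuracy 1."""
        cfg = bh.SynthConfig(
            n_subjects=8, shape=(8, 8, 8), effect_size=0.8, noise_sd=0.01,
            ambiguous_fraction=0.0, subject_sd=0.0, seed=5,
        )
        ds = bh.generate_dataset(cfg)
        ds.meta["split"] = "train"
        spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 4, 4))
        net = bh.train(
            bh.build_network(spec, seed=5),
            ds,
            bh.TrainConfig(epochs=60, batch_size=8, seed=5),
        )
        assert net.training_log[-1]["accuracy"] == 1.0

    def test_loss_decreases_on_separable_data(self, small_trained):
        log = small_trained.training_log
        assert log[-1]["loss"] < log[0]["loss"]

    def test_permuted_labels_give_chance_accuracy(self):
        """Null-label control: no signal to learn, test accuracy near 0.5."""
        accs = []
        for seed in range(3):
            cfg = bh.SynthConfig(
                n_subjects=40, shape=(8, 8, 8), effect_size=0.5, noise_sd=0.02,
                ambiguous_fraction=0.0, seed=seed,
            )
            ds = bh.generate_dataset(cfg)
            perm_rng = np.random.default_rng(100 + seed)
            ds.labels = perm_rng.permutation(ds.labels)
            ds.meta["label"] = ds.labels
            ds = bh.split_dataset(ds, 0.8, seed)
            spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 4, 4))
            net = bh.train(bh.build_network(spec, seed=seed), ds, bh.TrainConfig(seed=seed))
            test = ds.partition("test")
            accs.append((net.forward(test.stack()).argmax(axis=1) == test.labels).mean())
        assert abs(np.mean(accs) - 0.5) < 0.3

    def test_training_deterministic(self, small_dataset):
        spec = bh.NetworkSpec(input_shape=(16, 16, 16), block_channels=(2, 4, 4))
        outs = []
        for _ in range(2):
            net = bh.train(
                bh.build_network(spec, seed=2), small_dataset, bh.TrainConfig(epochs=2, seed=2)
            )
            outs.append(np.concatenate([p.value.ravel() for p in net.params()]))
        assert np.array_equal(outs[0], outs[1])

    def test_empty_train_split_rejected(self):
        ds = bh.generate_dataset(bh.SynthConfig(n_subjects=4, shape=(8, 8, 8), seed=0))
        spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 2, 2))
        with pytest.raises(ValueError, match="train split"):
            bh.train(bh.build_network(spec, seed=0), ds, bh.TrainConfig())

    def test_diverged_training_names_epoch(self):
        ds = bh.generate_dataset(bh.SynthConfig(n_subjects=8, shape=(8, 8, 8), seed=0))
        ds.meta["split"] = "train"
        spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 2, 2))
        net = bh.build_network(spec, seed=0)
        net.head.weight.value[...] = np.nan  # corrupt weights -> non-finite loss
        with pytest.raises(DivergedTrainingError, match="epoch 0"):
            bh.train(net, ds, bh.TrainConfig(epochs=1))


class TestCheckpoint:
    def test_round_trip_bit_exact(self, small_trained, tmp_path, rng):
        path = tmp_path / "ckpt.npz"
        bh.save_checkpoint(small_trained, path)
        loaded = bh.load_checkpoint(path)
        for pa, pb in zip(small_trained.params(), loaded.params()):
            assert np.array_equal(pa.value, pb.value)
        assert loaded.training_log == small_trained.training_log
        x = rng.normal(size=(2, 1, 16, 16, 16))
        assert np.array_equal(small_trained.forward(x), loaded.forward(x))
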