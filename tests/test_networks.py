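"""Architectures, attention, one-hot encoding, checkpointing, ensembling."""

import numpy as np
import pytest

from polphen.encoding import encode_mutants, one_hot_encode
from polphen.io import parse_mutant_id
from polphen.landscape import STANDARD_AAS
from polphen.nn import (AttentionDenseNet, DenseNet, Ensemble, SequenceNet,
                        Tensor, TrainConfig, self_attention,
                        select_best_checkpoint, train_with_checkpoints,
                        transfer_combine)
from polphen.nn.layers import attention_weights
from polphen.nn.train import Checkpoint, selection_score
from polphen.metrics import RegressionReport


class TestOneHot:
    def test_all_single_mutants_valid(self, wt_seq):
        # every substitution at every position: 31 x 19 library
        mutants = []
        for i, wt_aa in enumerate(wt_seq):
            for aa in STANDARD_AAS:
                if aa != wt_aa:
                    mutants.append(parse_mutant_id(f"{wt_aa}{1076 + i}{aa}"))
        X = encode_mutants(wt_seq, mutants)
        assert X.shape == (31 * 19, 31, 21)
        assert np.array_equal(np.unique(X), [0.0, 1.0])
        assert np.allclose(X.sum(axis=2), 1.0)

    def test_protonated_his_channel(self, wt_seq):
        X = encode_mutants(wt_seq, [parse_mutant_id("WT")])
        row = X[0, 1085 - 1076]
        assert row[20] == 1.0          # protonated channel
        assert row[6] == 0.0           # ordinary H channel ('H' is index 6)

    def test_substituted_his_leaves_protonated_channel(self, wt_seq):
        X = encode_mutants(wt_seq, [parse_mutant_id("H1085Q")])
        assert X[0, 1085 - 1076, 20] == 0.0

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode(list("B" * 31))

    def test_injective_over_alphabet(self, wt_seq, mutant_library):
        X = encode_mutants(wt_seq, mutant_library)
        flat = {x.tobytes() for x in X}
        assert len(flat) == len(mutant_library)


class TestArchitectures:
    def test_fitness_geometry(self, rng):
        net = DenseNet(63, (256, 128, 64), rng)
        shapes = [(l.W.shape, l.b.shape) for l in net.all_layers]
        assert shapes == [((63, 256), (256,)), ((256, 128), (128,)),
                          ((128, 64), (64,)), ((64, 1), (1,))]

    def test_sequence_geometry_and_position_wise_hidden(self, rng):
        net = SequenceNet(rng=rng)
        assert net.flat_width == 992
        x = Tensor.const(np.random.default_rng(0).random((2, 31, 21)))
        h = x
        for layer in net.layers:
            h = layer(h).relu()
        assert h.shape == (2, 31, 32)
        assert net.post_flatten.W.shape == (992, 32)
        assert net.head.W.shape == (32, 1)

    def test_md_attention_geometry(self, rng):
        net = AttentionDenseNet(62, (128, 64), rng=rng)
        assert [l.W.shape for l in net.layers] == [(62, 128), (128, 64)]
        assert net.head.W.shape == (64, 1)

    def test_weight_roundtrip(self, rng):
        net = DenseNet(10, (8, 4), rng)
        w = net.get_weights()
        net2 = DenseNet(10, (8, 4), np.random.default_rng(99))
        net2.set_weights(w)
        x = np.random.default_rng(1).random((3, 10))
        assert np.allclose(net.predict(x), net2.predict(x))


class TestSelfAttention:
    def test_constant_vector_is_fixed_point(self):
        h = Tensor.const(np.full((1, 8), 3.14))
        out = self_attention(h)
        assert np.allclose(out.value, h.value)

    def test_matches_bruteforce_on_toy(self):
        vals = np.array([[1.0, 3.0]])
        out = self_attention(Tensor.const(vals)).value
        # row i: softmax([h_i*h_1, h_i*h_2]) . [h_1, h_2]
        expected = []
        for hi in (1.0, 3.0):
            sims = np.array([hi * 1.0, hi * 3.0])
            w = np.exp(sims - sims.max())
            w /= w.sum()
            expected.append(w @ np.array([1.0, 3.0]))
        assert np.allclose(out.ravel(), expected)

    def test_weight_rows_normalised(self, rng):
        W = attention_weights(rng.standard_normal((4, 16)))
        assert np.allclose(W.sum(axis=-1), 1.0, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            self_attention(Tensor.const(np.array([[np.nan, 1.0]])))


class TestTrainingProtocol:
    def test_checkpoint_count_matches_interval(self, rng):
        net = DenseNet(5, (8,), rng)
        X = rng.standard_normal((12, 5))
        y = X @ rng.standard_normal(5)
        cfg = TrainConfig(max_epochs=200, checkpoint_interval=50,
                          learning_rate=1e-3, seed=0)
        res = train_with_checkpoints(net, X, y, cfg)
        assert [c.epoch for c in res.checkpoints] == [50, 100, 150, 200]
        assert len(res.loss_trajectory) == 200

    def test_interval_must_divide_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=1000, checkpoint_interval=300)

    def test_learnable_linear_target(self, rng):
        net = DenseNet(6, (32, 16), rng)
        X = rng.standard_normal((40, 6))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 2.0, -0.5])
        cfg = TrainConfig(max_epochs=400, checkpoint_interval=400,
                          learning_rate=1e-3, seed=1)
        res = train_with_checkpoints(net, X, y, cfg)
        assert res.loss_trajectory[-1] < 1e-2

    def test_fixed_seed_reproducible_trajectory(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        trajs = []
        for _ in range(2):
            net = DenseNet(4, (8,), np.random.default_rng(3))
            cfg = TrainConfig(max_epochs=50, checkpoint_interval=50,
                              learning_rate=1e-3, seed=5)
            trajs.append(train_with_checkpoints(net, X, y, cfg).loss_trajectory)
        assert trajs[0] == trajs[1]

    def test_selection_prefers_calibrated_model(self):
        # R2=0.9, slope=1.0 beats R2=0.95, slope=0.2 under R2 - |slope-1|
        a = RegressionReport(r2=0.9, slope=1.0, intercept=0.0, mse=0.1)
        b = RegressionReport(r2=0.95, slope=0.2, intercept=0.0, mse=0.1)
        assert selection_score(a) > selection_score(b)

    def test_select_best_checkpoint_ties_and_singleton(self, rng):
        net = DenseNet(3, (4,), rng)
        X = rng.standard_normal((8, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        w = net.get_weights()
        cks = [Checkpoint(epoch=500, weights=w, train_loss=1.0),
               Checkpoint(epoch=1000, weights=w, train_loss=1.0)]
        best = select_best_checkpoint(net, cks, X, y)
        assert best.epoch == 500            # identical scores: earliest epoch
        only = select_best_checkpoint(net, cks[:1], X, y)
        assert only.epoch == 500
        with pytest.raises(ValueError):
            select_best_checkpoint(net, [], X, y)


class TestEnsemble:
    class _Stub:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)

    def test_mean_of_members(self):
        ens = Ensemble([self._Stub(0.5), self._Stub(1.5)])
        assert np.allclose(ens.predict(np.zeros((4, 1))), 1.0)

    def test_degenerate_ensemble(self, rng):
        net = DenseNet(4, (8,), rng)
        X = rng.standard_normal((5, 4))
        ens = Ensemble([net] * 10)
        assert np.allclose(ens.predict(X), net.predict(X))

    def test_matches_independent_mean(self, rng):
        nets = [DenseNet(4, (8,), np.random.default_rng(i)) for i in range(3)]
        X = rng.standard_normal((6, 4))
        manual = np.mean([n.predict(X) for n in nets], axis=0)
        assert np.allclose(Ensemble(nets).predict(X), manual)


class TestTransferCombine:
    def test_frozen_weights_unchanged_after_training(self, rng):
        pre = DenseNet(6, (16, 8), rng)
        branch = DenseNet(4, (8, 8), np.random.default_rng(1))
        combined = transfer_combine(pre, branch, "feed-last",
                                    rng=np.random.default_rng(2))
        before = [w.copy() for w in pre.get_weights()]
        X1 = rng.standard_normal((20, 6))
        X2 = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        from polphen.nn.autodiff import Adam
        from polphen.nn.losses import combined_loss
        opt = Adam(combined.parameters(trainable_only=True), lr=1e-3)
        for _ in range(100):
            pred = combined.forward((X1, X2))
            loss = combined_loss(Tensor.const(y.reshape(-1, 1)), pred, kl=False)
            opt.zero_grad()
            loss.backward()
            opt.step()
        after = pre.get_weights()
        for b, a in zip(before, after):
            assert np.array_equal(b, a)   # bitwise unchanged

    def test_feed_last_zero_branch_reproduces_pretrained(self, rng):
        pre = DenseNet(6, (16, 8), rng)
        branch = DenseNet(4, (8, 8), np.random.default_rng(1))
        combined = transfer_combine(pre, branch, "feed-last",
                                    rng=np.random.default_rng(2))
        X1 = rng.standard_normal((7, 6))
        X2 = rng.standard_normal((7, 4))
        assert np.allclose(combined.predict((X1, X2)), pre.predict(X1))

    def test_concat_junction_width(self, rng):
        pre = DenseNet(6, (16, 8), rng)
        branch = DenseNet(4, (8, 4), np.random.default_rng(1))
        combined = transfer_combine(pre, branch, "concat-last",
                                    rng=np.random.default_rng(2))
        assert combined.head.W.shape == (8 + 4, 1)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            transfer_combine(DenseNet(4, (4,), rng), DenseNet(4, (4,), rng),
                             "stack")
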