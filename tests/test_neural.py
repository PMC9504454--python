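import numpy as np
import pytest

import ctxpred as cp
from ctxpred.neural import (
    ArchitectureSpec,
    ContextLSTM,
    TrainingConfig,
    build_network,
    load_neural_results,
    sample_training_positions,
)
from ctxpred.nn import BiLSTM, softmax_xent


class TestArchitecture:
    def test_bilstm_parameter_count_matches_formula(self):
        # 2 directions x 4 gates x (H*(D+H) + H) with D=4, H=8
        layer = BiLSTM(4, 8, np.random.default_rng(0))
        assert layer.n_parameters == 832

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError, match="3 or 4"):
            ArchitectureSpec(flank_size=5, conv_layers=[(16, 5)], lstm_layers=[8])

    def test_flank_size_does_not_change_lstm_parameters(self):
        rng = np.random.default_rng(0)
        n50 = build_network(ArchitectureSpec(flank_size=50, conv_layers=[(8, 3)],
                                             lstm_layers=[8]), rng).n_parameters
        n100 = build_network(ArchitectureSpec(flank_size=100, conv_layers=[(8, 3)],
                                              lstm_layers=[8]), rng).n_parameters
        assert n50 == n100  # recurrent weight sharing: only sequence length grows

    def test_gradients_match_numerical_derivatives(self):
        rng = np.random.default_rng(0)
        net = build_network(ArchitectureSpec(flank_size=3, conv_layers=[(6, 3)],
                                             lstm_layers=[5], dense_units=7), rng)
        x = rng.random((3, 6, 4))
        y = np.array([0, 1, 2])
        _, _, dlogits = softmax_xent(net.forward(x), y)
        net.backward(dlogits)
        grads = [g.copy() for g in net.grads]
        eps = 1e-6
        for pi, p in enumerate(net.params):
            flat = p.reshape(-1)
            for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp, _, _ = softmax_xent(net.forward(x), y)
                flat[j] = old - eps
                lm, _, _ = softmax_xent(net.forward(x), y)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert grads[pi].reshape(-1)[j] == pytest.approx(num, abs=1e-7, rel=1e-4)


class TestSampling:
    @pytest.fixture
    def masked_genome(self):
        rng = np.random.default_rng(3)
        g = cp.GenomeSequence("g", rng.integers(0, 4, size=2010).astype(np.uint8))
        return g, cp.build_position_mask(g, 5)

    def test_fraction_one_returns_all_qualified(self, masked_genome):
        g, mask = masked_genome
        pos = sample_training_positions(g, mask, 1.0, seed=0)
        np.testing.assert_array_equal(pos, mask.qualified_positions)

    def test_deterministic_given_seed(self, masked_genome):
        g, mask = masked_genome
        a = sample_training_positions(g, mask, 0.3, seed=7)
        b = sample_training_positions(g, mask, 0.3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_half_fraction_counts_and_membership(self, masked_genome):
        g, mask = masked_genome
        pos = sample_training_positions(g, mask, 0.5, seed=1)
        assert pos.size == round(0.5 * mask.qualified_positions.size)
        assert not mask.disqualified[pos].any()
        assert np.unique(pos).size == pos.size

    def test_empty_pool_rejected(self):
        g = cp.GenomeSequence.from_string("g", "NNNNNN")
        mask = cp.build_position_mask(g, 1)
        with pytest.raises(ValueError, match="no qualified"):
            sample_training_positions(g, mask, 0.5, seed=0)


def _tiny_config(**kw):
    defaults = dict(sample_fraction=1.0, rounds=2, batches_per_round=10,
                    batch_size=32, validation_size=64, learning_rate=1e-2, seed=0)
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestTraining:
    def test_constant_genome_reaches_perfect_validation(self):
        g = cp.GenomeSequence.from_string("g", "A" * 400)
        res = ContextLSTM(g, ArchitectureSpec.tiny(3), _tiny_config(rounds=3)).fit()
        assert res.training_log.val_accuracy[-1] == 1.0

    def test_log_has_one_row_per_round(self):
        g = cp.GenomeSequence.from_string("g", "ACGT" * 100)
        res = ContextLSTM(g, ArchitectureSpec.tiny(3), _tiny_config(rounds=3)).fit()
        assert res.training_log.n_rounds == 3
        assert list(res.training_log.to_frame()["round"]) == [1, 2, 3]

    def test_identical_seeds_reproduce_log(self):
        g = cp.GenomeSequence.from_string("g", "ACGTTGCA" * 60)
        log1 = ContextLSTM(g, ArchitectureSpec.tiny(3), _tiny_config()).fit().training_log
        log2 = ContextLSTM(g, ArchitectureSpec.tiny(3), _tiny_config()).fit().training_log
        assert log1.train_loss == log2.train_loss
        assert log1.val_loss == log2.val_loss

    def test_chromosome_split_gives_disjoint_pools(self):
        rng = np.random.default_rng(0)
        ga = cp.GenomeSequence("a", rng.integers(0, 4, 500).astype(np.uint8))
        gb = cp.GenomeSequence("b", rng.integers(0, 4, 500).astype(np.uint8))
        model = ContextLSTM([ga, gb], ArchitectureSpec.tiny(3),
                            _tiny_config(train_chromosomes=["a"],
                                         validation_chromosomes=["b"]))
        train_pool, val_pool = model._pools()
        assert set(train_pool[:, 0]) == {0} and set(val_pool[:, 0]) == {1}

    def test_validation_cross_entropy_decreases_on_learnable_structure(self):
        chain = cp.MarkovChain.random(1, seed=2, concentration=0.3)
        spec = cp.SyntheticGenomeSpec(length=40_000, order=1,
                                      transition_table=chain.table, seed=6)
        g, _ = cp.generate_genome(spec)
        cfg = _tiny_config(rounds=3, batches_per_round=60, batch_size=128,
                           validation_size=1024)
        res = ContextLSTM(g, ArchitectureSpec.tiny(3), cfg).fit()
        assert res.training_log.val_loss[-1] < res.training_log.val_loss[0]
        # the floor is the chain's conditional entropy
        assert res.training_log.val_loss[-1] > chain.conditional_entropy("both") - 0.05


@pytest.fixture(scope="module")
def trained_tiny():
    g = cp.GenomeSequence.from_string("g", "ACGTTGCA" * 60)
    return g, ContextLSTM(g, ArchitectureSpec.tiny(3), _tiny_config()).fit()


class TestPredictContract:
    def test_outputs_are_distributions(self, trained_tiny):
        g, res = trained_tiny
        pos = cp.build_position_mask(g, 3).qualified_positions[:50]
        probs = res.predict_positions(g, pos)
        assert (probs > 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicated_context_gives_identical_outputs(self, trained_tiny):
        g, res = trained_tiny
        ctx = cp.extract_context(g, 10, 3)
        probs = res.predict_batch([ctx, ctx])
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_flank_mismatch_rejected(self, trained_tiny):
        g, res = trained_tiny
        with pytest.raises(ValueError, match="flank"):
            res.predict_batch([cp.extract_context(g, 10, 4)])

    def test_bidirectional_outputs_are_distributions(self, trained_tiny):
        g, res = trained_tiny
        probs = res.predict_positions(g, np.arange(5, 15), bidirectional=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_checkpoint_roundtrip(self, trained_tiny, tmp_path):
        g, res = trained_tiny
        path = tmp_path / "model.npz"
        res.save(path)
        back = load_neural_results(path)
        pos = np.arange(5, 15)
        np.testing.assert_allclose(back.predict_positions(g, pos),
                                   res.predict_positions(g, pos), atol=1e-12)
        assert back.training_log.val_loss == res.training_log.val_loss
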