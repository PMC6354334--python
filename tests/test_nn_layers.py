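"""Neural layers against independent oracles, plus training behaviour."""

import math

import numpy as np
import pytest

from medtimeline.features import CategoryTables
from medtimeline.nn import layers
from medtimeline.nn.encoding import (
    PAD_ID,
    PairEncoder,
    SentenceEncoding,
    Vocabulary,
    batch_arrays,
)
from medtimeline.nn.model import (
    RELATIONS,
    EncodedPair,
    ModelConfig,
    RelationClassifier,
    train_model,
)

import oracles

RNG = np.random.default_rng(20260920)


def zero_lstm_params(D, H, dtype=np.float64):
    return dict(
        Wx=np.zeros((D, 4 * H), dtype=dtype),
        Wh=np.zeros((H, 4 * H), dtype=dtype),
        Wci=np.zeros((H, H), dtype=dtype),
        Wcf=np.zeros((H, H), dtype=dtype),
        Wco=np.zeros((H, H), dtype=dtype),
        b=np.zeros(4 * H, dtype=dtype),
    )


def random_lstm_params(D, H, rng, dtype=np.float64):
    p = zero_lstm_params(D, H, dtype)
    for key in p:
        p[key] = rng.uniform(-0.5, 0.5, size=p[key].shape).astype(dtype)
    return p


class TestLstm:
    def test_zero_weights_force_zero_outputs(self):
        """Gates sit at 0.5 and tanh(0)=0, so h_t = 0 for every step."""
        X = RNG.normal(size=(2, 5, 3))
        mask = np.ones((2, 5))
        H, h_fin, _ = layers.lstm_dir_forward(X, mask, **zero_lstm_params(3, 4))
        assert np.allclose(H, 0.0)
        assert np.allclose(h_fin, 0.0)

    def test_scalar_cell_matches_hand_evaluated_gate_arithmetic(self):
        """1-unit cell, hand-set weights, 2 steps, evaluated by hand.

        i1 = s(.6*.5+.3*0+.1)=s(.4); f1 = s(-.4*.5-.2*0+.2)=s(0)=.5
        c1 = f1*0 + i1*tanh(.7*.5); o1 = s(.3*.5+.5*c1-.1); h1 = o1*tanh(c1)
        then the same recurrences at step 2 with x2 = -0.3.
        """
        s, th = oracles.ref_sigmoid, math.tanh
        i1 = s(0.6 * 0.5 + 0.1)
        f1 = s(-0.4 * 0.5 + 0.2)
        c1 = i1 * th(0.7 * 0.5)
        o1 = s(0.3 * 0.5 + 0.5 * c1 - 0.1)
        h1 = o1 * th(c1)
        i2 = s(0.6 * -0.3 + 0.2 * h1 + 0.3 * c1 + 0.1)
        f2 = s(-0.4 * -0.3 + 0.5 * h1 - 0.2 * c1 + 0.2)
        c2 = f2 * c1 + i2 * th(0.7 * -0.3 - 0.6 * h1)
        o2 = s(0.3 * -0.3 + 0.4 * h1 + 0.5 * c2 - 0.1)
        h2 = o2 * th(c2)

        p = dict(
            Wx=np.array([[0.6, -0.4, 0.7, 0.3]]),
            Wh=np.array([[0.2, 0.5, -0.6, 0.4]]),
            Wci=np.array([[0.3]]),
            Wcf=np.array([[-0.2]]),
            Wco=np.array([[0.5]]),
            b=np.array([0.1, 0.2, 0.0, -0.1]),
        )
        X = np.array([[[0.5], [-0.3]]])
        H, h_fin, _ = layers.lstm_dir_forward(X, np.ones((1, 2)), **p)
        assert H[0, 0, 0] == pytest.approx(h1, abs=1e-6)
        assert H[0, 1, 0] == pytest.approx(h2, abs=1e-6)
        assert h_fin[0, 0] == pytest.approx(h2, abs=1e-6)

    def test_vector_cell_matches_reference_loop(self):
        """Random 3-unit cell over 4 steps vs the pure-Python reference."""
        D, H_size, T = 4, 3, 4
        p = random_lstm_params(D, H_size, np.random.default_rng(5))
        X = np.random.default_rng(6).normal(size=(1, T, D))
        H, _, _ = layers.lstm_dir_forward(X, np.ones((1, T)), **p)
        W = oracles.split_joint_weights(
            p["Wx"].tolist(), p["Wh"].tolist(), p["Wci"].tolist(),
            p["Wcf"].tolist(), p["Wco"].tolist(), p["b"].tolist(),
        )
        ref = oracles.ref_lstm_sequence(X[0].tolist(), W, H_size)
        assert np.allclose(H[0], np.array(ref), atol=1e-6)

    def test_backward_direction_equals_forward_on_reversed_input(self):
        D, H_size, T = 3, 2, 6
        p = random_lstm_params(D, H_size, np.random.default_rng(7))
        X = np.random.default_rng(8).normal(size=(2, T, D))
        mask = np.ones((2, T))
        H_rev, fin_rev, _ = layers.lstm_dir_forward(X, mask, **p, reverse=True)
        H_fwd, fin_fwd, _ = layers.lstm_dir_forward(
            X[:, ::-1].copy(), mask, **p, reverse=False
        )
        assert np.allclose(H_rev, H_fwd[:, ::-1], atol=1e-12)
        assert np.allclose(fin_rev, fin_fwd, atol=1e-12)

    def test_pad_steps_carry_state_unchanged(self):
        D, H_size = 3, 2
        p = random_lstm_params(D, H_size, np.random.default_rng(9))
        X = np.random.default_rng(10).normal(size=(1, 4, D))
        X_padded = np.concatenate([X, np.zeros((1, 3, D))], axis=1)
        mask = np.concatenate([np.ones((1, 4)), np.zeros((1, 3))], axis=1)
        H_short, fin_short, _ = layers.lstm_dir_forward(X, np.ones((1, 4)), **p)
        H_long, fin_long, _ = layers.lstm_dir_forward(X_padded, mask, **p)
        assert np.allclose(H_long[:, :4], H_short, atol=1e-12)
        assert np.allclose(fin_long, fin_short, atol=1e-12)


class TestConvMaxpool:
    def test_window_count_is_n_minus_k_plus_1(self):
        B, n, d, L, k = 1, 10, 4, 2, 3
        H = RNG.normal(size=(B, n, d))
        W = RNG.normal(size=(k * d, L))
        pooled, cache = layers.conv_maxpool_forward(
            H, np.array([n]), W, np.zeros(L), k
        )
        assert cache.windows.shape[1] == n - k + 1 == 8

    def test_zero_filters_pool_to_one_half(self):
        """sigma(0) = 0.5 for every window, so every pooled value is 0.5."""
        H = RNG.normal(size=(2, 9, 3))
        pooled, _ = layers.conv_maxpool_forward(
            H, np.array([9, 9]), np.zeros((9, 4)), np.zeros(4), 3
        )
        assert np.allclose(pooled, 0.5)

    @pytest.mark.parametrize("k", [3, 5])
    def test_matches_brute_force_window_loop(self, k):
        B, n, d, L = 3, 6, 4, 2
        rng = np.random.default_rng(11)
        H = rng.normal(size=(B, n, d))
        W = rng.normal(size=(k * d, L))
        b = rng.normal(size=L)
        pooled, _ = layers.conv_maxpool_forward(
            H, np.full(B, n), W, b, k
        )
        for i in range(B):
            ref = oracles.ref_conv_maxpool(H[i].tolist(), W.tolist(), b.tolist(), k)
            assert np.allclose(pooled[i], ref, atol=1e-6)

    def test_windows_beyond_real_length_are_excluded(self):
        """A huge activation hidden in the padded tail never wins the pool."""
        d, L, k = 2, 1, 3
        H = np.zeros((1, 8, d))
        H[0, 6] = 100.0  # inside PAD region (real length 5)
        W = np.ones((k * d, L))
        pooled_short, _ = layers.conv_maxpool_forward(
            H[:, :5], np.array([5]), W, np.zeros(L), k
        )
        pooled_padded, _ = layers.conv_maxpool_forward(
            H, np.array([5]), W, np.zeros(L), k
        )
        assert np.allclose(pooled_short, pooled_padded, atol=1e-12)

    def test_sentence_shorter_than_width_keeps_single_window(self):
        H = RNG.normal(size=(1, 7, 3))
        pooled, cache = layers.conv_maxpool_forward(
            H, np.array([2]), RNG.normal(size=(21, 2)), np.zeros(2), 7
        )
        assert np.all(cache.argmax == 0)


class TestOutputLayer:
    def test_softmax_rows_are_probability_vectors(self):
        logits = RNG.normal(size=(6, 4)) * 10
        probs = layers.softmax(logits)
        assert np.all(probs > 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_class_order_is_the_four_relations(self):
        assert tuple(r.value for r in RELATIONS) == (
            "NONE", "SIMULTANEOUS", "BEFORE", "AFTER",
        )


# ---------------------------------------------------------------------------
# Whole-model behaviour
# ---------------------------------------------------------------------------


def tiny_setup(max_len=12):
    vocab = Vocabulary()
    for tok in list("abcdefghij"):
        vocab.add(tok)
    tables = CategoryTables.fit([])
    return PairEncoder(vocab, max_len=max_len), tables


def random_pair(rng, vocab_size, tables, label=None, n_lo=3, n_hi=9):
    def sent():
        n = int(rng.integers(n_lo, n_hi))
        k = int(rng.integers(0, n))
        return SentenceEncoding(
            token_ids=rng.integers(2, vocab_size, n),
            positions=np.arange(n) - k,
            target=k,
        )

    offs, acc = [], 0
    for size in tables.sizes():
        offs.append(acc + int(rng.integers(0, size)))
        acc += size
    return EncodedPair(me=sent(), te=sent(), features=np.array(offs), label=label)


def tiny_config(variant, **kw):
    defaults = dict(
        word_dim=5, position_dim=3, feature_dim=2, lstm_units=4,
        filter_widths=(2, 3), filters_per_width=3, max_len=12,
        dropout=0.0, batch_size=4, epochs=1, variant=variant,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestModelDefaults:
    def test_default_config_echoes_reference_hyperparameters(self):
        cfg = ModelConfig()
        assert cfg.word_dim == 50
        assert cfg.position_dim == 30
        assert cfg.feature_dim == 20
        assert cfg.lstm_units == 50
        assert cfg.filter_widths == (3, 5, 7)
        assert cfg.filters_per_width == 100
        assert cfg.max_len == 100
        assert cfg.dropout == 0.5
        assert cfg.batch_size == 32
        assert cfg.epochs == 20

    def test_input_row_width_is_word_plus_position_dim(self):
        assert ModelConfig().input_dim == 80

    def test_feature_representation_width_is_200(self):
        cfg = ModelConfig()
        assert cfg.n_features * cfg.feature_dim == 200


class TestEncodeInput:
    def test_positions_are_signed_offsets_with_zero_at_target(self):
        enc, _ = tiny_setup()
        se = enc.encode_sentence(list("abcdefg"), target=3)
        assert list(se.positions) == [-3, -2, -1, 0, 1, 2, 3]
        assert se.positions[se.target] == 0

    def test_representation_equals_direct_table_lookup(self):
        """x_t must equal [E_w row of w_t, E_d row of d_t], elementwise."""
        enc, tables = tiny_setup()
        cfg = tiny_config("cnn")
        model = RelationClassifier(cfg, enc, tables, seed=3, dtype=np.float64)
        words = list("abcdefg")
        se = enc.encode_sentence(words, target=3)
        ids, pos, mask, lens = batch_arrays(
            [se], enc.pad_position_row, enc.max_len - 1, min_len=3
        )
        X = np.concatenate(
            [model.params["E_w"][ids], model.params["E_d"][pos]], axis=2
        )
        for t, w in enumerate(words):
            row = np.concatenate([
                model.params["E_w"][enc.vocab.get(w)],
                model.params["E_d"][(t - 3) + enc.max_len - 1],
            ])
            assert np.allclose(X[0, t], row)

    def test_long_sentence_truncates_to_window_around_target(self):
        enc, _ = tiny_setup(max_len=5)
        se = enc.encode_sentence(list("abcdefghij"), target=7)
        assert len(se.token_ids) == 5
        assert se.positions[se.target] == 0

    def test_empty_sentence_is_an_error(self):
        enc, _ = tiny_setup()
        with pytest.raises(ValueError):
            enc.encode_sentence([], target=0)

    def test_pad_rows_are_frozen_at_zero(self):
        enc, tables = tiny_setup()
        model = RelationClassifier(tiny_config("rnn-cnn"), enc, tables, seed=4)
        assert np.allclose(model.params["E_w"][PAD_ID], 0.0)
        assert np.allclose(model.params["E_d"][enc.pad_position_row], 0.0)

    def test_unk_vector_is_mean_of_word_vectors(self):
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config("cnn"), enc, tables, seed=5, dtype=np.float64
        )
        assert np.allclose(
            model.params["E_w"][1], model.params["E_w"][2:].mean(axis=0)
        )


class TestEmbedFeatures:
    def test_one_hot_selection_equals_row_lookup(self):
        """z_i = E_g . g_i picks exactly row r when g_i selects category r."""
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config("cnn"), enc, tables, seed=6, dtype=np.float64
        )
        rng = np.random.default_rng(12)
        pair = random_pair(rng, len(enc.vocab), tables)
        both, feats, _ = model._assemble([pair])
        _, cache = model._forward(both, feats, train=False)
        Z = model.params["E_g"][feats].reshape(1, -1)
        manual = np.concatenate(
            [model.params["E_g"][i] for i in pair.features]
        )
        assert np.allclose(Z[0], manual)


class TestClassifyPair:
    @pytest.mark.parametrize("variant", ["rnn-cnn", "cnn", "rnn"])
    def test_probabilities_lie_on_the_simplex(self, variant):
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config(variant), enc, tables, seed=7, dtype=np.float64
        )
        rng = np.random.default_rng(13)
        pairs = [random_pair(rng, len(enc.vocab), tables) for _ in range(5)]
        probs = model.predict_proba(pairs)
        assert probs.shape == (5, 4)
        assert np.all(probs > 0) and np.all(probs < 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_variant_is_an_error(self):
        with pytest.raises(ValueError):
            tiny_config("transformer")

    def test_rnn_cnn_forward_equals_composed_layer_oracles(self):
        """Y == softmax(W_o [C_M, C_T, Z] + b_o) with C computed by the
        pure-Python LSTM and convolution references, to 1e-6."""
        enc, tables = tiny_setup()
        cfg = tiny_config("rnn-cnn")
        model = RelationClassifier(cfg, enc, tables, seed=8, dtype=np.float64)
        rng = np.random.default_rng(14)
        pair = random_pair(rng, len(enc.vocab), tables, n_lo=4, n_hi=5)
        # both sentences length 4 > max width 3, equal length: no padding
        probs = model.predict_proba([pair])[0]

        p = model.params
        reps = []
        for se in (pair.me, pair.te):
            X = np.concatenate([
                p["E_w"][se.token_ids],
                p["E_d"][se.positions + enc.max_len - 1],
            ], axis=1)
            Wf = oracles.split_joint_weights(
                p["lstm_f_Wx"].tolist(), p["lstm_f_Wh"].tolist(),
                p["lstm_f_Wci"].tolist(), p["lstm_f_Wcf"].tolist(),
                p["lstm_f_Wco"].tolist(), p["lstm_f_b"].tolist(),
            )
            Wb = oracles.split_joint_weights(
                p["lstm_b_Wx"].tolist(), p["lstm_b_Wh"].tolist(),
                p["lstm_b_Wci"].tolist(), p["lstm_b_Wcf"].tolist(),
                p["lstm_b_Wco"].tolist(), p["lstm_b_b"].tolist(),
            )
            Hf = oracles.ref_lstm_sequence(X.tolist(), Wf, cfg.lstm_units)
            Hb = oracles.ref_lstm_sequence(X[::-1].tolist(), Wb, cfg.lstm_units)[::-1]
            H = [hf + hb for hf, hb in zip(Hf, Hb)]
            pooled = []
            for k in cfg.filter_widths:
                pooled += oracles.ref_conv_maxpool(
                    H, p[f"conv_k{k}_W"].tolist(), p[f"conv_k{k}_b"].tolist(), k
                )
            reps.append(pooled)
        Z = np.concatenate([p["E_g"][i] for i in pair.features])
        A = np.concatenate([reps[0], reps[1], Z])
        ref = oracles.ref_softmax((A @ p["out_W"] + p["out_b"]).tolist())
        assert np.allclose(probs, ref, atol=1e-6)

    @pytest.mark.parametrize("variant", ["rnn-cnn", "cnn", "rnn"])
    def test_appending_pad_never_changes_probabilities(self, variant):
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config(variant), enc, tables, seed=9, dtype=np.float64
        )
        rng = np.random.default_rng(15)
        short = random_pair(rng, len(enc.vocab), tables, n_lo=4, n_hi=5)
        base = model.predict_proba([short])[0]
        longer_pair = random_pair(rng, len(enc.vocab), tables, n_lo=10, n_hi=11)
        # batching `short` with a longer pair forces PAD onto `short`
        padded = model.predict_proba([short, longer_pair])[0]
        assert np.allclose(base, padded, atol=1e-6)


class TestTraining:
    def test_single_small_step_decreases_batch_loss(self):
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config("rnn-cnn"), enc, tables, seed=10, dtype=np.float64
        )
        rng = np.random.default_rng(16)
        batch = [
            random_pair(rng, len(enc.vocab), tables, label=int(rng.integers(0, 4)))
            for _ in range(6)
        ]
        before = model.loss(batch)
        model.sgd_step(batch, lr=0.01)
        assert model.loss(batch) < before

    def test_separable_pairs_are_learned_to_high_accuracy(self):
        """200 trivially separable pairs (label readable off the ME token)
        reach >= 0.99 training accuracy within 20 epochs."""
        enc, tables = tiny_setup()
        rng = np.random.default_rng(17)
        pairs = []
        for _ in range(200):
            label = int(rng.integers(0, 4))
            me = SentenceEncoding(
                token_ids=np.array([2 + label] * 5), positions=np.arange(5) - 2,
                target=2,
            )
            te = SentenceEncoding(
                token_ids=np.array([7, 8, 9, 7, 8]), positions=np.arange(5) - 2,
                target=2,
            )
            offs, acc = [], 0
            for size in tables.sizes():
                offs.append(acc)
                acc += size
            pairs.append(EncodedPair(me=me, te=te, features=np.array(offs),
                                     label=label))
        cfg = tiny_config("rnn-cnn", epochs=20, batch_size=16)
        model = RelationClassifier(cfg, enc, tables, seed=11, dtype=np.float64)
        train_model(model, pairs, seed=11)
        preds = model.predict_proba(pairs).argmax(axis=1)
        accuracy = np.mean(preds == [p.label for p in pairs])
        assert accuracy >= 0.99

    def test_label_outside_class_set_is_an_error(self):
        enc, tables = tiny_setup()
        model = RelationClassifier(tiny_config("cnn"), enc, tables, seed=12)
        rng = np.random.default_rng(18)
        bad = [random_pair(rng, len(enc.vocab), tables, label=7)]
        with pytest.raises(ValueError):
            train_model(model, bad, seed=0)

    def test_empty_pair_set_is_an_error(self):
        enc, tables = tiny_setup()
        model = RelationClassifier(tiny_config("cnn"), enc, tables, seed=13)
        with pytest.raises(ValueError):
            train_model(model, [], seed=0)

    def test_same_seed_reproduces_parameters_bitwise(self):
        enc, tables = tiny_setup()
        rng = np.random.default_rng(19)
        pairs = [
            random_pair(rng, len(enc.vocab), tables, label=int(rng.integers(0, 4)))
            for _ in range(24)
        ]
        runs = []
        for _ in range(2):
            cfg = tiny_config("rnn-cnn", epochs=2, dropout=0.5)
            model = RelationClassifier(cfg, enc, tables, seed=21)
            train_model(model, pairs, seed=21)
            runs.append({k: v.copy() for k, v in model.params.items()})
        for key in runs[0]:
            assert np.array_equal(runs[0][key], runs[1][key])


class TestPersistence:
    def test_save_load_restores_identical_predictions(self, tmp_path):
        enc, tables = tiny_setup()
        model = RelationClassifier(
            tiny_config("rnn-cnn"), enc, tables, seed=14, dtype=np.float64
        )
        rng = np.random.default_rng(20)
        pairs = [random_pair(rng, len(enc.vocab), tables) for _ in range(4)]
        before = model.predict_proba(pairs)
        model.save(tmp_path / "bundle")
        restored = RelationClassifier.load(tmp_path / "bundle")
        after = restored.predict_proba(pairs)
        assert np.array_equal(before, after)
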