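import numpy as np
import pytest

import mortcode as mc
from mortcode.certificate import Certificate
from mortcode.coder import (
    ModelConfig,
    OptParams,
    build_model,
    load_coder,
    predict_proba,
    predict_proba_batch,
    predict_topk,
    save_coder,
    train,
)


@pytest.fixture(scope="module")
def tiny_vocab():
    return mc.make_synthetic_vocabulary(3, 6, seed=2)


@pytest.fixture(scope="module")
def tiny_config(tiny_vocab):
    return ModelConfig(V=tiny_vocab.size, embed_dim=8, conv_spec=((3, 3, 12),), seed=5)


@pytest.fixture(scope="module")
def tiny_model(tiny_vocab):
    return mc.make_cause_model(tiny_vocab, seed=2)


def _cert(vocab, codes, **kw):
    defaults = dict(id="t", year=2005, sex=0, age_value=70, age_unit="years")
    defaults.update(kw)
    return Certificate.build(part1=[[c] for c in codes], part2=[], **defaults)


class TestModelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(embed_dim=0),
            dict(conv_spec=()),
            dict(conv_spec=((7, 3, 8),)),     # kernel taller than the grid
            dict(conv_spec=((3, 21, 8),)),    # kernel wider than the grid
            dict(pooling="avg"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(V=10, **kwargs)


class TestBuildModel:
    def test_same_seed_identical_parameters(self, tiny_config, tiny_vocab):
        a = build_model(tiny_config, tiny_vocab)
        b = build_model(tiny_config, tiny_vocab)
        assert set(a.params) == set(b.params)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_vocab_size_mismatch_rejected(self, tiny_vocab):
        with pytest.raises(ValueError, match="does not match"):
            build_model(ModelConfig(V=tiny_vocab.size + 1), tiny_vocab)

    def test_gender_ablation_removes_parameters(self, tiny_vocab):
        cfg = ModelConfig(V=tiny_vocab.size, embed_dim=8, conv_spec=((3, 3, 8),),
                          use_gender=False)
        coder = build_model(cfg, tiny_vocab)
        assert "gender_embed" not in coder.params

    def test_pad_embedding_is_zero(self, tiny_config, tiny_vocab):
        coder = build_model(tiny_config, tiny_vocab)
        np.testing.assert_array_equal(
            coder.params["code_embed"][tiny_vocab.pad_index], 0.0
        )

    def test_onehot_times_projection_equals_lookup(self, tiny_config, tiny_vocab):
        """The dummy-variable formulation (one-hot x projection matrix) and
        the embedding lookup are the same linear map, for all four inputs."""
        coder = build_model(tiny_config, tiny_vocab)
        for name, n_states in [
            ("code_embed", tiny_vocab.size + 2),
            ("age_embed", 25),
            ("year_embed", tiny_config.Y),
            ("gender_embed", 2),
        ]:
            table = coder.params[name]
            for idx in range(n_states):
                onehot = np.zeros(n_states, dtype=table.dtype)
                onehot[idx] = 1.0
                np.testing.assert_allclose(onehot @ table, table[idx], atol=1e-6)


class TestPredict:
    def test_distributions_normalize(self, tiny_config, tiny_vocab, tiny_model):
        coder = build_model(tiny_config, tiny_vocab)
        certs = mc.generate_dataset(tiny_model, 40, seed=3)
        probs = predict_proba_batch(coder, certs, tiny_vocab)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_initialized_head_gives_uniform_distribution(
        self, tiny_config, tiny_vocab, tiny_model
    ):
        coder = build_model(tiny_config, tiny_vocab)
        cert = mc.generate_dataset(tiny_model, 1, seed=4)[0]
        probs = predict_proba(coder, cert, tiny_vocab)
        np.testing.assert_allclose(probs, 1.0 / tiny_vocab.size, atol=1e-7)

    def test_fingerprint_mismatch_rejected(self, tiny_config, tiny_vocab, tiny_model):
        coder = build_model(tiny_config, tiny_vocab)
        other = mc.make_synthetic_vocabulary(3, 6, seed=99)
        cert = mc.generate_dataset(tiny_model, 1, seed=4)[0]
        with pytest.raises(ValueError, match="fingerprint"):
            predict_proba(coder, cert, other)


class TestTopK:
    def test_topk_contract(self, desk_run):
        vocab = desk_run.model.vocab
        cert = desk_run.test_set[0]
        full = predict_topk(desk_run.coder, cert, vocab, k=vocab.size)
        assert sorted(c for c, _ in full) == sorted(vocab.codes)
        probs = [p for _, p in full]
        assert probs == sorted(probs, reverse=True)
        top1 = predict_topk(desk_run.coder, cert, vocab, k=1)
        assert top1[0][0] == vocab.code_at(
            int(np.argmax(predict_proba(desk_run.coder, cert, vocab)))
        )
        top2 = predict_topk(desk_run.coder, cert, vocab, k=2)
        assert top2[0] == top1[0]

    def test_k_out_of_range(self, tiny_config, tiny_vocab, tiny_model):
        coder = build_model(tiny_config, tiny_vocab)
        cert = mc.generate_dataset(tiny_model, 1, seed=4)[0]
        for k in (0, tiny_vocab.size + 1):
            with pytest.raises(ValueError):
                predict_topk(coder, cert, tiny_vocab, k)


class TestTrain:
    def test_memorization_reduces_loss(self, tiny_config, tiny_vocab, tiny_model):
        certs = mc.generate_dataset(tiny_model, 10, seed=5)
        coder = build_model(tiny_config, tiny_vocab)
        out = train(coder, certs, certs, tiny_vocab,
                    OptParams(epochs=3, batch_size=10, lr=1e-2))
        # batch losses are recorded before each update, so epoch 0 reflects
        # the uniform zero-initialized head (exactly ln V) and later epochs
        # must sit strictly below it
        init_loss = np.log(tiny_vocab.size)
        assert out.history["train_loss"][0] == pytest.approx(init_loss)
        assert out.history["train_loss"][1] < init_loss
        assert out.history["train_loss"][-1] < out.history["train_loss"][1]

    def test_training_is_deterministic(self, tiny_config, tiny_vocab, tiny_model):
        certs = mc.generate_dataset(tiny_model, 60, seed=6)
        runs = []
        for _ in range(2):
            coder = build_model(tiny_config, tiny_vocab)
            out = train(coder, certs[:40], certs[40:], tiny_vocab,
                        OptParams(epochs=2, batch_size=16, seed=9))
            runs.append(out.history)
        assert runs[0] == runs[1]

    def test_empty_train_set_rejected(self, tiny_config, tiny_vocab):
        coder = build_model(tiny_config, tiny_vocab)
        with pytest.raises(ValueError, match="empty"):
            train(coder, [], [], tiny_vocab)

    def test_label_outside_vocab_rejected(self, tiny_config, tiny_vocab, tiny_model):
        certs = mc.generate_dataset(tiny_model, 5, seed=7)
        bad = [certs[0].with_gold("Z99", False)] + certs[1:]
        coder = build_model(tiny_config, tiny_vocab)
        with pytest.raises(ValueError, match="outside the vocabulary"):
            train(coder, bad, [], tiny_vocab, OptParams(epochs=1))


class TestCheckpoint:
    def test_round_trip_bit_identical_predictions(
        self, tmp_path, tiny_config, tiny_vocab, tiny_model
    ):
        certs = mc.generate_dataset(tiny_model, 30, seed=8)
        coder = train(build_model(tiny_config, tiny_vocab), certs[:20], certs[20:],
                      tiny_vocab, OptParams(epochs=1))
        path = tmp_path / "coder.npz"
        save_coder(coder, path)
        back = load_coder(path, tiny_vocab)
        assert back.config == coder.config
        a = predict_proba(coder, certs[0], tiny_vocab)
        b = predict_proba(back, certs[0], tiny_vocab)
        np.testing.assert_array_equal(a, b)

    def test_load_against_wrong_vocabulary_rejected(
        self, tmp_path, tiny_config, tiny_vocab
    ):
        coder = build_model(tiny_config, tiny_vocab)
        path = tmp_path / "coder.npz"
        save_coder(coder, path)
        with pytest.raises(ValueError, match="fingerprint"):
            load_coder(path, mc.make_synthetic_vocabulary(3, 6, seed=99))

    def test_untrained_checkpoint_reproduces_seeded_init(
        self, tmp_path, tiny_config, tiny_vocab
    ):
        coder = build_model(tiny_config, tiny_vocab)
        path = tmp_path / "init.npz"
        save_coder(coder, path)
        back = load_coder(path)
        rebuilt = build_model(tiny_config, tiny_vocab)
        for k in rebuilt.params:
            np.testing.assert_array_equal(back.params[k], rebuilt.params[k])


class TestStructuralSensitivity:
    def test_part_placement_changes_prediction(self, desk_run):
        """Moving a promotion trigger from Part II into Part I must be able to
        change the output: the model is not row-permutation invariant, because
        the promotion rule depends on which part a condition is written in."""
        model = desk_run.model
        vocab = model.vocab
        trigger, pattern, _ = model.promotion_pairs[0]
        root = next(
            c for c, _ in model.ucd_prior if pattern in model.descendants(c)
        )
        in_part2 = Certificate.build(
            id="a", part1=[[pattern], [root]], part2=[[trigger]],
            year=2005, sex=0, age_value=70, age_unit="years",
        )
        in_part1 = Certificate.build(
            id="b", part1=[[pattern], [root], [trigger]], part2=[],
            year=2005, sex=0, age_value=70, age_unit="years",
        )
        p2 = predict_proba(desk_run.coder, in_part2, vocab)
        p1 = predict_proba(desk_run.coder, in_part1, vocab)
        assert int(p2.argmax()) != int(p1.argmax()) or not np.allclose(p2, p1, atol=1e-3)
        # the trained coder honours the promotion rule
        assert vocab.code_at(int(p2.argmax())) == trigger
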