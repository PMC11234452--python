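"""Tokenizer, transformer decoder training, sampling and persistence."""

import math

import numpy as np
import pytest

from gelgen import FixtureConfig, make_corpus
from gelgen.lm import DESK_PROFILE, SmilesGPT, Vocabulary, tokenize
from gelgen.metrics import novelty, validity

TOY = ["CCO", "CCN", "CCC", "CC(=O)O", "c1ccccc1", "CCOC", "CNC", "CC(C)O", "OCCO", "CCCN"]


def tiny_model(**kw):
    kw.setdefault("n_layers", 2)
    kw.setdefault("d_model", 48)
    kw.setdefault("n_heads", 12)
    kw.setdefault("d_ff", 256)
    kw.setdefault("context_window", 64)
    kw.setdefault("learning_rate", 3e-3)
    kw.setdefault("batch_size", 8)
    kw.setdefault("n_epochs", 50)
    kw.setdefault("seed", 0)
    return SmilesGPT(**kw)


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", ["C", "C", "O"]),
            ("c1ccccc1Cl", ["c", "1", "c", "c", "c", "c", "c", "1", "Cl"]),
            ("[nH]", ["[nH]"]),
            ("BrCC%10CC%10", ["Br", "C", "C", "%10", "C", "C", "%10"]),
            ("C/C=C\\C", ["C", "/", "C", "=", "C", "\\", "C"]),
        ],
    )
    def test_multicharacter_tokens_kept_whole(self, smiles, expected):
        assert tokenize(smiles) == expected

    def test_unknown_character_named(self):
        with pytest.raises(ValueError, match="cannot tokenize"):
            tokenize("C!C")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tokenize("")

    def test_round_trip_on_generated_corpus(self, small_corpus):
        smiles = small_corpus.smiles()
        vocab = Vocabulary.from_corpus(smiles)
        assert all(vocab.decode(vocab.encode(s)) == s for s in smiles)


class TestVocabulary:
    def test_specials_present_once_and_dense(self):
        vocab = Vocabulary.from_corpus(["CCO"])
        assert sorted(vocab.index.values()) == list(range(len(vocab)))
        assert vocab.pad_id != vocab.start_id != vocab.end_id

    def test_out_of_vocabulary_token_named(self):
        vocab = Vocabulary.from_corpus(["CCO"])
        with pytest.raises(ValueError, match="'N'"):
            vocab.encode("CCN")

    def test_encode_has_sentinels(self):
        vocab = Vocabulary.from_corpus(["CCO"])
        ids = vocab.encode("CCO")
        assert ids[0] == vocab.start_id and ids[-1] == vocab.end_id


class TestTraining:
    def test_untrained_model_predicts_uniformly(self, quiet_stderr):
        m = tiny_model(n_epochs=0).fit(TOY)
        assert m.nll(TOY) == pytest.approx(math.log(len(m.vocab_)), abs=1e-3)

    def test_overfits_toy_corpus(self, quiet_stderr):
        m = tiny_model(n_epochs=200).fit(TOY)
        run = m.history_[-1]
        assert run.epoch_nll[-1] < 0.1
        # on-average non-increasing NLL
        first, last = np.mean(run.epoch_nll[:5]), np.mean(run.epoch_nll[-5:])
        assert last < first

    def test_finetune_lowers_nll_on_new_corpus(self, quiet_stderr):
        pretrain = ["CCO", "CCN", "CCC", "COC", "CNC"]
        finetune = ["OCCO", "OCCN", "NCCN", "OCCC", "NCCC"]
        vocab = Vocabulary.from_corpus(pretrain + finetune)
        m = tiny_model(n_epochs=60).fit(pretrain, vocab=vocab)
        before = m.nll(finetune)
        m.finetune(finetune, n_epochs=60)
        assert m.nll(finetune) < before
        assert m.fitted_phase_ == "finetune"
        assert [r.phase for r in m.history_] == ["pretrain", "finetune"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tiny_model().fit([])

    def test_training_deterministic_given_seed(self, quiet_stderr):
        a = tiny_model(n_epochs=10).fit(TOY)
        b = tiny_model(n_epochs=10).fit(TOY)
        assert a.history_[-1].epoch_nll == b.history_[-1].epoch_nll


class TestSampling:
    def test_memorizes_single_molecule(self, quiet_stderr):
        m = tiny_model(n_epochs=400).fit(["CCO"])
        assert m.history_[-1].epoch_nll[-1] < 0.01  # genuinely overfit
        samples = m.sample(100, seed=5)
        assert sum(s == "CCO" for s in samples) >= 95

    def test_same_seed_identical(self, quiet_stderr):
        m = tiny_model(n_epochs=30).fit(TOY)
        assert m.sample(25, seed=9) == m.sample(25, seed=9)

    def test_zero_samples(self, quiet_stderr):
        m = tiny_model(n_epochs=1).fit(TOY)
        assert m.sample(0) == []

    def test_bad_temperature(self, quiet_stderr):
        m = tiny_model(n_epochs=1).fit(TOY)
        with pytest.raises(ValueError):
            m.sample(5, temperature=0.0)

    def test_incremental_decoder_matches_batch_forward(self, quiet_stderr):
        m = tiny_model(n_epochs=20).fit(TOY)
        ids = m.vocab_.encode("CC(=O)O")
        full = m.sequence_logits(ids)
        h, dh = m.n_heads, m.d_model // m.n_heads
        kc = [np.zeros((1, h, 64, dh), np.float32) for _ in range(m.n_layers)]
        vc = [np.zeros((1, h, 64, dh), np.float32) for _ in range(m.n_layers)]
        inc = np.stack(
            [m._step_logits(np.array([t]), i, kc, vc)[0] for i, t in enumerate(ids)]
        )
        assert np.allclose(full, inc, atol=1e-4)


class TestCausality:
    def test_future_tokens_do_not_change_past_logits(self, quiet_stderr):
        m = tiny_model(n_epochs=10).fit(TOY)
        ids = np.array(m.vocab_.encode("CC(=O)O"))
        base = m.sequence_logits(ids)
        cut = 3
        perturbed = ids.copy()
        perturbed[cut + 1 :] = m.vocab_.encode("c1ccccc1")[1 : len(ids) - cut]
        probe = m.sequence_logits(perturbed)
        assert np.allclose(base[: cut + 1], probe[: cut + 1], atol=1e-5)
        assert not np.allclose(base[cut + 1 :], probe[cut + 1 :], atol=1e-5)


class TestCheckpoint:
    def test_round_trip_preserves_sampling(self, tmp_path, quiet_stderr):
        m = tiny_model(n_epochs=30).fit(TOY)
        path = str(tmp_path / "model.npz")
        m.save(path)
        loaded = SmilesGPT.load(path)
        assert loaded.sample(20, seed=4) == m.sample(20, seed=4)
        assert loaded.vocab_.tokens == m.vocab_.tokens

    def test_version_mismatch_fails_loudly(self, tmp_path, quiet_stderr):
        import json

        m = tiny_model(n_epochs=1).fit(TOY)
        path = str(tmp_path / "model.npz")
        m.save(path)
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(str(arrays["meta"]))
        meta["version"] = "other-v9"
        arrays["meta"] = np.asarray(json.dumps(meta))
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="version"):
            SmilesGPT.load(path)


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            SmilesGPT(d_model=50, n_heads=12).fit(TOY)

    def test_context_window_minimum(self):
        with pytest.raises(ValueError):
            SmilesGPT(context_window=1).fit(TOY)

    def test_full_scale_defaults(self):
        m = SmilesGPT()
        assert (m.n_layers, m.d_model, m.n_heads, m.d_ff, m.context_window) == (
            18, 48, 12, 512, 128,
        )
        assert DESK_PROFILE.n_layers == 4


class TestDistributionLearning:
    def test_desk_profile_learns_corpus_distribution(self, quiet_stderr):
        """A reduced model pretrained on a synthetic corpus emits mostly
        valid SMILES while still memorizing part of the training set."""
        corpus = make_corpus(FixtureConfig(seed=7, n_molecules=600))
        smiles = corpus.smiles()
        m = SmilesGPT(
            n_layers=4, d_model=48, n_heads=12, d_ff=512, context_window=64,
            learning_rate=3e-3, batch_size=32, n_epochs=200, seed=0,
        )
        m.fit(smiles)
        samples = m.sample(300, seed=1)
        assert validity(samples) >= 80.0
        assert novelty(samples, corpus) < 100.0
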