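import numpy as np
import pytest

from cpinet import autodiff as ad
from cpinet.seq2seq import (EncoderConfig, PretrainConfig, decode_teacher_forced,
                            encode, init_autoencoder, pretrain,
                            reconstruction_accuracy, sequences_to_ids,
                            trim_to_longest)
from cpinet.synthetic import gen_compounds
from cpinet.vocab import build_vocabulary, tokenize


@pytest.fixture(scope="module")
def corpus():
    smiles = gen_compounds(24, seed=42)
    vocab = build_vocabulary(smiles, "smiles")
    tokens = [tokenize(s, vocab, 24) for s in smiles]
    return smiles, vocab, tokens


def test_thought_vector_dims_match_channel_defaults(corpus):
    """Compound channel latent is 128-dimensional, protein channel 256."""
    _, vocab, tokens = corpus
    ids = sequences_to_ids(tokens[:4])
    for dim in (128, 256):
        cfg = EncoderConfig(vocab_size=vocab.size, dim=dim)
        params = init_autoencoder(cfg, seed=0)
        _, thought, _ = encode(params, "ae", cfg, ids, vocab.pad_id)
        assert thought.shape == (4, dim)


def test_thought_dim_independent_of_sequence_length(corpus):
    _, vocab, tokens = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=16)
    params = init_autoencoder(cfg, seed=0)
    for t in tokens[:6]:
        _, thought, _ = encode(params, "ae", cfg, sequences_to_ids([t]), vocab.pad_id)
        assert thought.shape == (1, 16)


def test_padding_does_not_change_thought_vector(corpus):
    smiles, vocab, _ = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=16)
    params = init_autoencoder(cfg, seed=0)
    short = sequences_to_ids([tokenize(smiles[0], vocab, 20)])
    long = sequences_to_ids([tokenize(smiles[0], vocab, 48)])
    _, t1, _ = encode(params, "ae", cfg, short, vocab.pad_id)
    _, t2, _ = encode(params, "ae", cfg, long, vocab.pad_id)
    np.testing.assert_allclose(t1.data, t2.data, atol=1e-12)


def test_decoder_scores_normalise_and_mask_pads(corpus):
    _, vocab, tokens = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=16)
    params = init_autoencoder(cfg, seed=0)
    ids = trim_to_longest(sequences_to_ids(tokens[:3]), vocab.pad_id)
    enc_out, thought, mask = encode(params, "ae", cfg, ids, vocab.pad_id)
    logits = decode_teacher_forced(params, "ae", cfg, enc_out, thought, mask,
                                   ids, vocab.pad_id)
    probs = ad.softmax(logits, axis=1).data
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-10)
    # pad positions are excluded from the loss by the target mask
    targets = ids[:, 1:].T.ravel()
    assert (targets == vocab.pad_id).any()


def test_untrained_accuracy_is_chance_level(corpus):
    """Random parameters reconstruct uniform random sequences at chance."""
    _, vocab, _ = corpus
    rng = np.random.default_rng(0)
    symbols = list(vocab.non_special())
    uniform = [[symbols[i] for i in rng.integers(0, len(symbols), 20)]
               for _ in range(30)]
    tokens = [tokenize(u, vocab, 24) for u in uniform]
    cfg = EncoderConfig(vocab_size=vocab.size, dim=16)
    params = init_autoencoder(cfg, seed=7)
    acc = reconstruction_accuracy(params, "ae", cfg, tokens, vocab.pad_id)
    assert acc < 3.0 / len(symbols) + 0.15  # far below learned performance


def test_pretrain_learns_and_is_seed_deterministic(corpus):
    _, vocab, tokens = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=24, attention_dim=12)
    pcfg = PretrainConfig(epochs=8, batch_size=12, learning_rate=2e-3, seed=5)
    params1, hist1 = pretrain(tokens, vocab, cfg, pcfg)
    params2, hist2 = pretrain(tokens, vocab, cfg, pcfg)
    assert hist1 == hist2  # bitwise-identical training under a fixed seed
    for key in params1:
        np.testing.assert_array_equal(params1[key].data, params2[key].data)
    assert hist1[-1]["loss"] < hist1[0]["loss"]
    from cpinet.seq2seq import init_autoencoder
    untrained = reconstruction_accuracy(init_autoencoder(cfg, seed=5), "ae", cfg,
                                        tokens, vocab.pad_id)
    trained = reconstruction_accuracy(params1, "ae", cfg, tokens, vocab.pad_id)
    assert trained > untrained + 0.1  # clearly learning, not drifting


def test_single_sequence_overfit_reproduces_input(corpus):
    smiles, vocab, _ = corpus
    tokens = [tokenize(smiles[0], vocab, 16)]
    cfg = EncoderConfig(vocab_size=vocab.size, dim=24, attention_dim=12)
    params, _ = pretrain(tokens, vocab, cfg,
                         PretrainConfig(epochs=60, batch_size=1,
                                        learning_rate=5e-3, seed=0))
    assert reconstruction_accuracy(params, "ae", cfg, tokens, vocab.pad_id) == 1.0


def test_empty_corpus_rejected(corpus):
    _, vocab, _ = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=8)
    with pytest.raises(ValueError, match="empty corpus"):
        pretrain([], vocab, cfg, PretrainConfig(epochs=1, batch_size=4, seed=0))
    params = init_autoencoder(cfg, seed=0)
    with pytest.raises(ValueError, match="empty corpus"):
        reconstruction_accuracy(params, "ae", cfg, [], vocab.pad_id)


def test_sgd_decay_scheme_runs(corpus):
    _, vocab, tokens = corpus
    cfg = EncoderConfig(vocab_size=vocab.size, dim=12)
    params, hist = pretrain(tokens[:8], vocab, cfg,
                            PretrainConfig(epochs=2, batch_size=8, seed=0,
                                           scheme="sgd-decay", learning_rate=0.5))
    assert len(hist) == 2 and np.isfinite(hist[-1]["loss"])
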