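import numpy as np
import pytest

from cpinet import autodiff as ad
from cpinet import nn
from cpinet.autodiff import Tensor
from cpinet.dataset import CPISample
from cpinet.model import ModelConfig, TrainConfig, UnifiedModel, train_unified
from cpinet.seq2seq import EncoderConfig, PretrainConfig, pretrain
from cpinet.vocab import tokenize
from conftest import SMALL_MODEL_KW


def test_channel_config_validation():
    with pytest.raises(ValueError, match="compound channel"):
        ModelConfig(channels=("sps",))
    with pytest.raises(ValueError, match="protein channel"):
        ModelConfig(channels=("smiles", "graph"))
    with pytest.raises(ValueError, match="unknown channel"):
        ModelConfig(channels=("smiles", "sps", "bogus"))


def test_channel_order_is_canonical():
    cfg = ModelConfig(channels=("graph", "sps", "smiles"))
    assert cfg.channels == ("smiles", "sps", "graph")


def test_attention_weights_sum_to_one_over_real_positions(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    model = small_model
    source = model.prepare(cpi.samples[:6])
    # recompute the smiles-channel attention by hand on one batch
    from cpinet.seq2seq import encode, trim_to_longest
    vocab = model.vocabs["smiles"]
    ids = trim_to_longest(source.ids["smiles"][:6], vocab.pad_id)
    enc_cfg = model.config.encoder_config("smiles", vocab.size)
    outputs, _, mask = encode(model.params, "smiles", enc_cfg, ids, vocab.pad_id)
    flat = ad.concat(outputs, axis=0)
    scores = nn.attention_scores(model.params, "smiles.att", flat)
    alpha = ad.softmax(ad.reshape(scores, (ids.shape[1], ids.shape[0])),
                       axis=0, mask=mask.T)
    np.testing.assert_allclose(alpha.data.sum(axis=0), np.ones(6), rtol=1e-10)
    assert (alpha.data.T[mask == 0] == 0).all()


def test_conv1d_matches_nested_loop_oracle(rng):
    batch, length, d_in, filters, kernel = 2, 10, 3, 4, 4
    params = {}
    nn.init_conv1d(params, "c", rng, d_in, filters, kernel)
    x = rng.normal(size=(batch * length, d_in))
    out, out_len = nn.conv1d(params, "c", Tensor(x), batch, length, kernel)
    assert out_len == length - kernel + 1
    xs = x.reshape(batch, length, d_in)
    expected = np.zeros((batch, out_len, filters))
    for b in range(batch):
        for t in range(out_len):
            acc = params["c.b"].data.copy()
            for k in range(kernel):
                acc = acc + xs[b, t + k] @ params[f"c.K{k}"].data
            expected[b, t] = acc
    np.testing.assert_allclose(out.data.reshape(batch, out_len, filters),
                               expected, rtol=1e-10)


def test_conv1d_rejects_short_sequences(rng):
    params = {}
    nn.init_conv1d(params, "c", rng, 3, 4, kernel=4)
    with pytest.raises(ValueError, match="shorter than kernel"):
        nn.conv1d(params, "c", Tensor(np.zeros((2 * 2, 3))), 2, 2, 4)


def test_constant_input_single_averaging_kernel(rng):
    """An averaging kernel over a constant sequence returns the constant."""
    params = {}
    kernel, d = 4, 3
    nn.init_conv1d(params, "c", rng, d, d, kernel)
    for k in range(kernel):
        params[f"c.K{k}"] = Tensor(np.eye(d) / kernel, requires_grad=True)
    params["c.b"] = Tensor(np.zeros(d), requires_grad=True)
    const = np.tile([1.0, 2.0, 3.0], (6, 1))
    out, _ = nn.conv1d(params, "c", Tensor(const), 1, 6, kernel)
    np.testing.assert_allclose(out.data, np.tile([1.0, 2.0, 3.0], (3, 1)))


def test_appending_pads_leaves_channel_vector_unchanged(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    model = small_model
    s = cpi.samples[0]
    vocab = model.vocabs["smiles"]
    short = np.array([tokenize(s.smiles, vocab, 30).indices])
    long = np.array([tokenize(s.smiles, vocab, 40).indices])
    v1 = model._sequence_channel("smiles", short, train=False, rng=None)
    v2 = model._sequence_channel("smiles", long, train=False, rng=None)
    np.testing.assert_allclose(v1.data, v2.data, atol=1e-12)


def test_fusion_dimension_and_order(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    model = small_model
    cfg = model.config
    source = model.prepare(cpi.samples[:4])
    pred = model.forward_batch(source.ids, source.graphs[:4] if source.graphs else None)
    assert pred.shape == (4, 1)
    head_in = model.params["head.fc1.W"].shape[0]
    assert head_in == 2 * cfg.conv_filters + cfg.graph_hidden  # smiles + sps + graph


def test_graph_only_compound_fusion(tiny_vocabs, tiny_dataset):
    _, cpi = tiny_dataset
    cfg = ModelConfig(channels=("graph", "sps"), **SMALL_MODEL_KW)
    model = UnifiedModel.initialize(cfg, {"sps": tiny_vocabs["sps"]}, seed=0)
    assert model.params["head.fc1.W"].shape[0] == (cfg.graph_hidden + cfg.conv_filters)
    pred = model.predict(cpi.samples[:3])
    assert pred.shape == (3,) and np.isfinite(pred).all()


def test_forward_deterministic_in_eval_mode(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    p1 = small_model.predict(cpi.samples[:5])
    p2 = small_model.predict(cpi.samples[:5])
    np.testing.assert_array_equal(p1, p2)


def test_forward_finite_on_many_random_samples(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    pred = small_model.predict(cpi.samples)
    assert np.isfinite(pred).all()


def test_missing_channel_data_raises(tiny_vocabs, tiny_dataset):
    _, cpi = tiny_dataset
    cfg = ModelConfig(channels=("smiles", "sps", "graph", "amino"), **SMALL_MODEL_KW)
    model = UnifiedModel.initialize(cfg, tiny_vocabs, seed=0)
    s = cpi.samples[0]
    sample = CPISample(smiles=s.smiles, sps=s.sps, label=1.0, amino=None)
    with pytest.raises(ValueError, match="amino"):
        model.prepare([sample])


def test_four_channel_variant_runs(tiny_vocabs, tiny_dataset):
    _, cpi = tiny_dataset
    cfg = ModelConfig(channels=("smiles", "sps", "graph", "amino"), **SMALL_MODEL_KW)
    model = UnifiedModel.initialize(cfg, tiny_vocabs, seed=0)
    pred = model.predict(cpi.samples[:4])
    assert np.isfinite(pred).all()
    # amino channel is bidirectional: conv consumes 2*dim features
    assert model.params["amino.conv.K0"].shape[0] == 2 * cfg.amino_dim


def test_single_step_decreases_batch_loss(small_model, tiny_dataset):
    """End-to-end differentiability: a small enough step reduces the loss."""
    _, cpi = tiny_dataset
    model = small_model
    source = model.prepare(cpi.samples[:16])
    batch = source.subset(np.arange(16))

    def batch_loss():
        pred = model.forward_batch(batch.ids, batch.graphs)
        return float(np.mean((pred.data.ravel() - batch.labels) ** 2))

    base = batch_loss()
    decreased = False
    for lr in (1e-2, 1e-3, 1e-4, 1e-5):
        saved = nn.copy_params(model.params)
        pred = model.forward_batch(batch.ids, batch.graphs)
        err = ad.add(pred, Tensor(-batch.labels[:, None]))
        loss = ad.mean(ad.mul(err, err))
        for p in model.params.values():
            p.grad = None
        loss.backward()
        for p in model.params.values():
            if p.grad is not None:
                p.data -= lr * p.grad
        if batch_loss() < base:
            decreased = True
            model.params = saved
            break
        model.params = saved
    assert decreased


def test_training_history_bookkeeping(small_model, tiny_dataset):
    _, cpi = tiny_dataset
    _, hist = train_unified(small_model, cpi, None,
                            TrainConfig(epochs=3, batch_size=16,
                                        learning_rate=1e-3, seed=0))
    assert len(hist) == 3
    assert all("train_rmse" in h for h in hist)


def test_empty_train_set_rejected(small_model):
    from cpinet.dataset import CPIDataset
    with pytest.raises(ValueError, match="empty"):
        train_unified(small_model, CPIDataset([]), None, TrainConfig(epochs=1, seed=0))


def test_checkpoint_roundtrip_preserves_predictions(small_model, tiny_dataset, tmp_path):
    _, cpi = tiny_dataset
    model = small_model
    train_unified(model, cpi, None,
                  TrainConfig(epochs=1, batch_size=16, learning_rate=1e-3, seed=0))
    before = model.predict(cpi.samples[:6])
    model.save(tmp_path / "ckpt")
    loaded = UnifiedModel.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(before, loaded.predict(cpi.samples[:6]))


def test_warm_start_copies_pretrained_weights_exactly(tiny_vocabs, tiny_dataset):
    synth, _ = tiny_dataset
    vocab = tiny_vocabs["smiles"]
    tokens = [tokenize(s, vocab, 40) for s in synth.compounds]
    enc_cfg = EncoderConfig(vocab_size=vocab.size, dim=16, attention_dim=8)
    warm, _ = pretrain(tokens, vocab, enc_cfg,
                       PretrainConfig(epochs=2, batch_size=8, seed=1),
                       prefix="ae_smiles")
    cfg = ModelConfig(channels=("smiles", "sps", "graph"), **SMALL_MODEL_KW)
    model = UnifiedModel.initialize(cfg, tiny_vocabs, seed=0, warm=warm,
                                    warm_prefixes={"smiles": "ae_smiles"})
    np.testing.assert_array_equal(model.params["smiles.emb.E"].data,
                                  warm["ae_smiles.emb.E"].data)
    np.testing.assert_array_equal(model.params["smiles.enc.l1.fwd.Un"].data,
                                  warm["ae_smiles.enc.l1.fwd.Un"].data)
    # decoder-side weights must not leak into the unified model
    assert not any(k.startswith("smiles.dec") for k in model.params)


def test_warm_started_training_learns(tiny_vocabs, tiny_dataset):
    synth, cpi = tiny_dataset
    vocab = tiny_vocabs["smiles"]
    tokens = [tokenize(s, vocab, 40) for s in synth.compounds]
    enc_cfg = EncoderConfig(vocab_size=vocab.size, dim=16, attention_dim=8)
    warm, _ = pretrain(tokens, vocab, enc_cfg,
                       PretrainConfig(epochs=2, batch_size=8, seed=1),
                       prefix="ae_smiles")
    cfg = ModelConfig(channels=("smiles", "sps", "graph"), **SMALL_MODEL_KW)
    model = UnifiedModel.initialize(cfg, tiny_vocabs, seed=0, warm=warm,
                                    warm_prefixes={"smiles": "ae_smiles"})
    _, hist = train_unified(model, cpi, None,
                            TrainConfig(epochs=4, batch_size=16,
                                        learning_rate=1e-3, seed=0))
    assert hist[-1]["train_rmse"] < hist[0]["train_rmse"]
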