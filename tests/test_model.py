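"""Architecture contracts of the attention network."""

import numpy as np
import pytest

from pathdrug.model import (
    DrugResponseModel,
    ModelConfig,
    SUBNETWORK_NAMES,
)
from pathdrug.nn import Tensor

from conftest import TINY_MODEL


def test_default_embedding_is_256_by_16():
    cfg = ModelConfig(vocab_size=40)
    model = DrugResponseModel(cfg)
    codes = np.zeros((1, 256), dtype=int)
    codes[0, -5:] = [1, 2, 3, 2, 1]
    emb = model.embedding(codes)
    assert emb.shape == (1, 256, 16)


def test_embedding_is_a_lookup(tiny_model):
    codes = np.array([[0, 0, 1, 4, 1, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 4]])
    emb = tiny_model.embedding(codes).data[0]
    assert np.array_equal(emb[2], emb[4])   # same token, different positions
    assert np.array_equal(emb[3], emb[15])
    assert np.array_equal(emb[0], emb[1])   # shared pad row


def test_five_representations_share_sequence_length(tiny_model, tiny_inputs):
    codes, _ = tiny_inputs
    reps = tiny_model.encode_smiles(codes)
    assert len(reps) == 5
    for rep in reps:
        assert rep.shape[:2] == (5, 16)


def test_multiscale_conv_output_shapes():
    cfg = ModelConfig(vocab_size=40)
    model = DrugResponseModel(cfg)
    emb = model.embedding(np.zeros((2, 256), dtype=int))
    for conv, k in zip(model.convs, (3, 5, 11)):
        out = conv(emb)
        assert out.shape == (2, 256, 16)


def test_transformer_is_position_sensitive(tiny_model):
    codes = np.zeros((1, 16), dtype=int)
    codes[0, -4:] = [1, 2, 3, 4]
    swapped = codes.copy()
    swapped[0, -4:] = [2, 1, 3, 4]
    tiny_model.eval()
    r1 = tiny_model.encode_smiles(codes)[4].data
    r2 = tiny_model.encode_smiles(swapped)[4].data
    assert not np.allclose(r1, r2)


def test_attention_weights_normalized_nonnegative(tiny_model, tiny_inputs):
    codes, omics = tiny_inputs
    tiny_model.eval()
    _, att = tiny_model.forward(codes, omics)
    assert set(att.smiles_alpha) == {"expression"}
    for alphas in (att.smiles_alpha["expression"], att.pathway_alpha["expression"]):
        assert len(alphas) == 5
        for a in alphas:
            assert (a >= 0).all()
            assert a.sum(axis=1) == pytest.approx(np.ones(len(a)), abs=1e-6)


def test_constant_rows_make_context_equal_row():
    from pathdrug.model import SmilesAttentionLayer
    rng = np.random.default_rng(0)
    layer = SmilesAttentionLayer(channels=4, seq_len=6, omics_dim=3,
                                 attn_dim=5, rng=rng)
    row = rng.normal(size=4)
    seq = Tensor(np.tile(row, (2, 6, 1)))
    ctx, alpha = layer(seq, Tensor(rng.normal(size=(2, 3))))
    assert ctx.data == pytest.approx(np.tile(row, (2, 1)))


def test_zero_scoring_vector_gives_uniform_attention():
    from pathdrug.model import SmilesAttentionLayer
    rng = np.random.default_rng(1)
    layer = SmilesAttentionLayer(channels=4, seq_len=6, omics_dim=3,
                                 attn_dim=5, rng=rng)
    layer.V.data[:] = 0.0
    seq = Tensor(rng.normal(size=(2, 6, 4)))
    ctx, alpha = layer(seq, Tensor(rng.normal(size=(2, 3))))
    assert alpha.data == pytest.approx(np.full((2, 6), 1 / 6))
    assert ctx.data == pytest.approx(seq.data.mean(axis=1))


def test_zero_omics_vector_gives_zero_gated_output():
    from pathdrug.model import OmicsAttentionLayer
    rng = np.random.default_rng(2)
    layer = OmicsAttentionLayer(channels=4, seq_len=6, omics_dim=3,
                                attn_dim=5, rng=rng)
    gated, alpha = layer(Tensor(rng.normal(size=(2, 6, 4))), Tensor(np.zeros((2, 3))))
    assert np.all(gated.data == 0.0)
    assert alpha.data.sum(axis=1) == pytest.approx(np.ones(2), abs=1e-6)


def test_head_width_bookkeeping():
    cfg = ModelConfig(seed=0, **TINY_MODEL)
    # five contexts of width C plus five gated omics vectors of width O
    assert cfg.head_width() == 5 * 8 + 5 * 6
    two = dict(TINY_MODEL, omics_dims={"expression": 6, "mutation": 9})
    cfg2 = ModelConfig(seed=0, **two)
    assert cfg2.head_width() == (5 * 8 + 5 * 6) + (5 * 8 + 5 * 9)


def test_eval_mode_is_deterministic(tiny_model, tiny_inputs):
    codes, omics = tiny_inputs
    p1 = tiny_model.predict(codes, omics)
    p2 = tiny_model.predict(codes, omics)
    assert np.array_equal(p1, p2)


def test_output_invariant_to_omics_argument_order(tiny_inputs):
    codes, omics = tiny_inputs
    rng = np.random.default_rng(5)
    cfg = dict(TINY_MODEL, omics_dims={"expression": 6, "mutation": 9})
    model = DrugResponseModel(ModelConfig(seed=4, **cfg))
    om = {"expression": omics["expression"], "mutation": rng.normal(size=(5, 9)) ** 2}
    p1 = model.predict(codes, om)
    p2 = model.predict(codes, dict(reversed(list(om.items()))))
    assert np.array_equal(p1, p2)


def test_missing_required_omics_kind_errors(tiny_model, tiny_inputs):
    codes, _ = tiny_inputs
    with pytest.raises(KeyError, match="expression"):
        tiny_model.forward(codes, {})


def test_classifier_head_outputs_probabilities(tiny_inputs):
    codes, omics = tiny_inputs
    cfg = ModelConfig(seed=6, head="classifier", **TINY_MODEL)
    model = DrugResponseModel(cfg)
    out = model.predict(codes, omics)
    assert ((out > 0) & (out < 1)).all()


def test_gradient_reaches_every_parameter_group(tiny_model, tiny_inputs):
    codes, omics = tiny_inputs
    out, _ = tiny_model.forward(codes, omics, return_attention=False)
    target = Tensor(np.linspace(-1, 1, len(codes)))
    loss = ((out - target) ** 2.0).mean()
    loss.backward()
    for name, p in tiny_model.named_parameters():
        assert p.grad is not None, name
        assert np.abs(p.grad).sum() > 0 or "bias" in name, name


def test_omics_input_is_not_dead(tiny_inputs):
    codes, omics = tiny_inputs
    changed = 0
    for seed in range(5):
        model = DrugResponseModel(ModelConfig(seed=seed, **TINY_MODEL))
        base = model.predict(codes, omics)
        bumped = {"expression": omics["expression"].copy()}
        bumped["expression"][:, 2] *= 2.0
        changed += not np.allclose(model.predict(codes, bumped), base)
    assert changed >= 4  # doubling one pathway moves the prediction


def test_subnetwork_names_cover_three_kinds():
    assert SUBNETWORK_NAMES == {
        "expression": "SGAN", "cnv": "SCAN", "mutation": "SMAN"
    }


def test_checkpoint_round_trip(tmp_path, tiny_model, tiny_inputs):
    codes, omics = tiny_inputs
    ref = tiny_model.predict(codes, omics)
    path = tmp_path / "model.npz"
    tiny_model.save(path, vocab_hash="deadbeef")
    loaded, vocab_hash = DrugResponseModel.load(path)
    assert vocab_hash == "deadbeef"
    assert np.array_equal(loaded.predict(codes, omics), ref)
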