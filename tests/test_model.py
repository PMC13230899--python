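"""Correction-network contracts: group independence, gating, decoder
residual wiring, attention arithmetic, head behaviour, determinism."""

import numpy as np
import pytest

from snvpurify.autograd import Tensor
from snvpurify.features import GROUP_DIMS, GROUP_NAMES
from snvpurify.model import CorrectionModel, FeatureScaler, ModelConfig


def tiny_config(**kw):
    kw.setdefault("d_model", 16)
    kw.setdefault("n_heads", 2)
    kw.setdefault("n_blocks", 2)
    kw.setdefault("seed", 5)
    return ModelConfig(**kw)


def random_groups(rng, batch=3):
    return {g: rng.normal(size=(batch, GROUP_DIMS[g])) for g in GROUP_NAMES}


@pytest.fixture
def model():
    return CorrectionModel(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def test_d_model_must_divide_heads():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(d_model=10, n_heads=4)


def test_group_dim_mismatch_names_group(model, rng):
    groups = random_groups(rng)
    groups["purity_basic"] = rng.normal(size=(3, 7))
    with pytest.raises(ValueError, match="purity_basic"):
        model.encode_groups(groups)


def test_perturbing_one_group_changes_only_its_token(model, rng):
    groups = random_groups(rng)
    base = [t.data.copy() for t in model.encode_groups(groups)]
    groups2 = {g: m.copy() for g, m in groups.items()}
    groups2["repeat_region"] += 1.0
    perturbed = [t.data.copy() for t in model.encode_groups(groups2)]
    target_idx = GROUP_NAMES.index("repeat_region")
    for i, (a, b) in enumerate(zip(base, perturbed)):
        if i == target_idx:
            assert not np.allclose(a, b)
        else:
            np.testing.assert_array_equal(a, b)


def test_zero_input_token_is_bias_plus_position(model):
    groups = {g: np.zeros((1, GROUP_DIMS[g])) for g in GROUP_NAMES}
    tokens = model.encode_groups(groups)
    for g, tok in zip(GROUP_NAMES, tokens):
        expected = (np.tanh(model.params[f"enc.{g}.b"].data)
                    + model.params[f"pos.{g}"].data)
        np.testing.assert_allclose(tok.data[0], expected, atol=1e-14)


def test_gate_saturation_and_midpoint(model, rng):
    tokens = model.encode_groups(random_groups(rng))
    for g in GROUP_NAMES:
        model.params[f"gate.{g}.w"].data[:] = 0.0
        model.params[f"gate.{g}.b"].data[:] = 0.0
    _, gates = model.apply_gates(tokens)
    np.testing.assert_allclose(gates, 0.5)  # pre-activation 0 -> sigmoid 0.5
    for g in GROUP_NAMES:
        model.params[f"gate.{g}.b"].data[:] = 50.0  # saturated
    _, gates = model.apply_gates(tokens)
    np.testing.assert_allclose(gates, 1.0, atol=1e-12)


def test_gates_strictly_inside_unit_interval(model, rng):
    gated, gates = model.apply_gates(model.encode_groups(random_groups(rng, batch=16)))
    assert np.all(gates > 0.0) and np.all(gates < 1.0)


def test_decoder_residual_path_with_zeroed_weights(model, rng):
    """With attention output and FFN weights zeroed, each block reduces to
    its two LayerNorms applied to the residual stream."""
    for blk in range(model.config.n_blocks):
        for nm in ("Wo", "bo"):
            model.params[f"blk{blk}.attn.{nm}"].data[:] = 0.0
        model.params[f"blk{blk}.ffn.W2"].data[:] = 0.0
        model.params[f"blk{blk}.ffn.b2"].data[:] = 0.0
    tokens = model.encode_groups(random_groups(rng))
    out = model.concat_and_decode(model.apply_gates(tokens)[0]).data

    def ln(x, g, b, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    gated, _ = model.apply_gates(tokens)
    x = np.stack([t.data for t in gated], axis=1)
    for blk in range(model.config.n_blocks):
        x = ln(x, model.params[f"blk{blk}.ln1.g"].data, model.params[f"blk{blk}.ln1.b"].data)
        x = ln(x, model.params[f"blk{blk}.ln2.g"].data, model.params[f"blk{blk}.ln2.b"].data)
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_single_head_attention_matches_hand_computation(rng):
    """One block, one head, hand-set projections: the attention output must
    equal softmax(q k^T / sqrt(d)) v re-derived independently."""
    cfg = ModelConfig(d_model=4, n_heads=1, n_blocks=1, seed=1)
    model = CorrectionModel(cfg)
    Wq = rng.normal(size=(4, 4))
    Wk = rng.normal(size=(4, 4))
    Wv = rng.normal(size=(4, 4))
    model.params["blk0.attn.Wq"].data = Wq
    model.params["blk0.attn.Wk"].data = Wk
    model.params["blk0.attn.Wv"].data = Wv
    model.params["blk0.attn.Wo"].data = np.eye(4)
    for nm in ("bq", "bk", "bv", "bo"):
        model.params[f"blk0.attn.{nm}"].data[:] = 0.0
    x = rng.normal(size=(1, 2, 4))  # batch 1, two tokens
    got = model._attention(Tensor(x), 0).data[0]

    q, k, v = x[0] @ Wq, x[0] @ Wk, x[0] @ Wv
    scores = q @ k.T / np.sqrt(4)
    weights = np.exp(scores - scores.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(got, weights @ v, atol=1e-12)


def test_decoder_permutation_equivariant_without_positions(model, rng):
    gated, _ = model.apply_gates(model.encode_groups(random_groups(rng)))
    perm = [3, 0, 4, 1, 2]
    out = model.concat_and_decode(gated).data
    out_perm = model.concat_and_decode([gated[i] for i in perm]).data
    np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-10)


def test_constant_head_outputs_softplus_bias(model, rng):
    model.params["head.w"].data[:] = 0.0
    model.params["head.b"].data[:] = 1.3
    out = model.forward(random_groups(rng, batch=8)).data
    np.testing.assert_allclose(out, np.log1p(np.exp(1.3)), atol=1e-12)


def test_predictions_nonnegative_and_finite(model, rng):
    preds = model.predict(random_groups(rng, batch=1000))
    assert np.all(preds >= 0.0) and np.all(np.isfinite(preds))


def test_same_seed_same_weights_and_outputs(rng):
    groups = random_groups(rng)
    a, b = CorrectionModel(tiny_config()), CorrectionModel(tiny_config())
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
    np.testing.assert_array_equal(a.forward(groups).data, b.forward(groups).data)


def test_batch_size_invariance(model, rng):
    groups = random_groups(rng, batch=5)
    full = model.predict(groups)
    singles = np.concatenate([
        model.predict({g: m[i:i + 1] for g, m in groups.items()}) for i in range(5)
    ])
    np.testing.assert_allclose(full, singles, atol=1e-10)


def test_parameter_count_deterministic_function_of_config():
    assert (CorrectionModel(tiny_config()).parameter_count()
            == CorrectionModel(tiny_config()).parameter_count())
    assert (CorrectionModel(tiny_config(d_model=32)).parameter_count()
            > CorrectionModel(tiny_config()).parameter_count())


def independent_forward(blob: dict, groups: dict) -> np.ndarray:
    """A from-scratch numpy re-implementation of the forward pass reading
    only the exported checkpoint dict (the oracle for save/load + forward)."""
    P = {k: np.array(v) for k, v in blob["params"].items()}
    cfg = blob["config"]
    mean = {g: np.array(v) for g, v in blob["scaler"]["mean"].items()}
    std = {g: np.array(v) for g, v in blob["scaler"]["std"].items()}
    names = list(mean)
    toks = []
    for g in names:
        x = (groups[g] - mean[g]) / std[g]
        tok = np.tanh(x @ P[f"enc.{g}.W"] + P[f"enc.{g}.b"]) + P[f"pos.{g}"]
        gate = 1 / (1 + np.exp(-(tok @ P[f"gate.{g}.w"] + P[f"gate.{g}.b"])))
        toks.append(tok * gate)
    x = np.stack(toks, axis=1)
    H = cfg["n_heads"]
    d = cfg["d_model"]
    dh = d // H

    def ln(v, g, b, eps=1e-5):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * g + b

    for blk in range(cfg["n_blocks"]):
        p = f"blk{blk}"
        B, T, _ = x.shape
        qkv = []
        for nm in ("q", "k", "v"):
            y = x @ P[f"{p}.attn.W{nm}"] + P[f"{p}.attn.b{nm}"]
            qkv.append(y.reshape(B, T, H, dh).transpose(0, 2, 1, 3))
        q, k, v = qkv
        s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        w = np.exp(s - s.max(-1, keepdims=True))
        w /= w.sum(-1, keepdims=True)
        ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        a = ctx @ P[f"{p}.attn.Wo"] + P[f"{p}.attn.bo"]
        x = ln(x + a, P[f"{p}.ln1.g"], P[f"{p}.ln1.b"])
        h = np.maximum(x @ P[f"{p}.ffn.W1"] + P[f"{p}.ffn.b1"], 0.0)
        h = h @ P[f"{p}.ffn.W2"] + P[f"{p}.ffn.b2"]
        x = ln(x + h, P[f"{p}.ln2.g"], P[f"{p}.ln2.b"])
    pooled = x.mean(axis=1)
    z = (pooled @ P["head.w"] + P["head.b"]).ravel()
    z = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)  # softplus
    return np.expm1(z) if cfg["log1p_target"] else z


def test_checkpoint_round_trip_and_forward_oracle(tmp_path, rng):
    import json

    model = CorrectionModel(tiny_config())
    # non-trivial scaler, as after training
    groups = random_groups(rng, batch=64)
    model.scaler = FeatureScaler.fit(groups)
    path = tmp_path / "model.ckpt.json"
    model.save(path)
    reloaded = CorrectionModel.load(path)
    test_groups = random_groups(rng, batch=4)
    np.testing.assert_allclose(reloaded.predict(test_groups),
                               model.predict(test_groups), atol=1e-12)
    blob = json.loads(path.read_text())
    np.testing.assert_allclose(independent_forward(blob, test_groups),
                               model.predict(test_groups), atol=1e-5)


def test_checkpoint_config_mismatch_rejected(tmp_path, rng):
    import json

    model = CorrectionModel(tiny_config())
    path = tmp_path / "model.ckpt.json"
    model.save(path)
    blob = json.loads(path.read_text())
    blob["config"]["d_model"] = 32  # silently re-shaping would be a bug
    path.write_text(json.dumps(blob))
    with pytest.raises(ValueError, match="shape"):
        CorrectionModel.load(path)
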