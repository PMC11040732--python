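"""Encoder blocks, attention, pairwise module, heads, loss and the
assembled network's invariances."""

import numpy as np
import pytest

from aldele.autograd import Tensor
from aldele.chem import FingerprintDictionary, assign_subgraph_ids, parse_smiles
from aldele.config import ModelConfig, PRESETS
from aldele.model import (AldeleNetwork, ANNEncoder, AttentionPool, CNNEncoder,
                          GNNEncoder, PairFeatures, PairwiseInteraction,
                          PredictionHead, loss)


RNG = np.random.default_rng(0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_presets_match_published_combinations():
    expected = {"M1": {2, 3}, "M2": {2, 4}, "M3": {2, 3, 4},
                "M4": {1, 2, 3}, "M5": {1, 2, 3, 4}, "M6": {1, 2, 3, 4, 5}}
    assert {k: set(v) for k, v in PRESETS.items()} == expected
    for name in expected:
        cfg = ModelConfig.from_preset(name)
        assert set(cfg.toolkits) == expected[name]


def test_mode_toolkit_validation():
    with pytest.raises(ValueError):
        ModelConfig(toolkits={3}, mode="cpi")           # no compound toolkit
    with pytest.raises(ValueError):
        ModelConfig(toolkits={2}, mode="cpi")           # no protein toolkit
    with pytest.raises(ValueError):
        ModelConfig(toolkits={2, 3}, mode="protein_only")
    with pytest.raises(ValueError):
        ModelConfig(toolkits={3, 4}, mode="compound_only")
    ModelConfig(toolkits={3, 4}, mode="protein_only")   # valid
    ModelConfig(toolkits={1, 2}, mode="compound_only")  # valid


def test_default_hyperparameters():
    cfg = ModelConfig()
    assert (cfg.r, cfg.n, cfg.w, cfg.dim) == (2, 3, 21, 10)
    assert (cfg.layers_gnn, cfg.layers_cnn, cfg.layers_nn) == (3, 3, 3)


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def _graph(smiles, r=2, d=None):
    g = parse_smiles(smiles)
    return assign_subgraph_ids(g, r, d or FingerprintDictionary())


def test_gnn_zero_layers_returns_raw_embeddings():
    g = _graph("CCO")
    enc = GNNEncoder(np.random.default_rng(1), 10, 10, 4, layers=0)
    V = enc(g)
    expected = enc.vertex_emb.data[np.asarray(g.vertex_subgraph_ids)]
    assert np.allclose(V.data, expected)


def test_gnn_single_atom():
    g = _graph("C")
    enc = GNNEncoder(np.random.default_rng(1), 10, 10, 4, layers=2)
    assert enc(g).shape == (1, 4)


def test_gnn_benzene_symmetry():
    g = _graph("c1ccccc1")
    enc = GNNEncoder(np.random.default_rng(2), 10, 10, 6, layers=3)
    V = enc(g).data
    assert np.allclose(V, V[0])


def test_gnn_rejects_out_of_dictionary_ids():
    g = _graph("CCO")
    enc = GNNEncoder(np.random.default_rng(1), 2, 2, 4, layers=1)
    with pytest.raises(ValueError, match="dictionary"):
        enc(g)


def test_cnn_preserves_length_and_zero_maps_to_zero():
    enc = CNNEncoder(np.random.default_rng(3), 5, layers=3)
    for L in (1, 2, 7):
        out = enc(Tensor(np.random.default_rng(4).normal(size=(L, 5))))
        assert out.shape == (L, 5)
    out = enc(Tensor(np.zeros((6, 5))))
    assert np.allclose(out.data, 0.0)
    with pytest.raises(ValueError):
        enc(Tensor(np.zeros((0, 5))))


def test_cnn_identity_kernel_reproduces_input():
    enc = CNNEncoder(np.random.default_rng(5), 4, layers=1, kernel=3)
    for i, dense in enumerate(enc.layers[0]):
        dense.W.data = np.eye(4) if i == 1 else np.zeros((4, 4))
        dense.b.data = np.zeros(4)
    x = np.abs(np.random.default_rng(6).normal(size=(5, 4)))  # ReLU-transparent
    out = enc(Tensor(x))
    assert np.allclose(out.data, x)


def test_ann_contracts():
    enc = ANNEncoder(np.random.default_rng(7), 10, 6, layers=2)
    out1 = enc(Tensor(np.ones(10)))
    out2 = enc(Tensor(np.ones(10)))
    assert np.allclose(out1.data, out2.data)
    for d in enc.dense:
        d.b.data[:] = 0.0
    assert np.allclose(enc(Tensor(np.zeros(10))).data, 0.0)
    with pytest.raises(ValueError):
        enc(Tensor(np.zeros(200)))


# ---------------------------------------------------------------------------
# attention / pairwise / head / loss
# ---------------------------------------------------------------------------

def test_attention_identical_positions_pool_to_that_vector():
    att = AttentionPool(np.random.default_rng(8), 6)
    att.w.data = np.random.default_rng(9).normal(size=(6, 1))
    h = np.tile(np.random.default_rng(10).normal(size=6), (5, 1))
    pooled, alpha, _ = att(Tensor(h))
    assert np.isclose(alpha.data.sum(), 1.0)
    assert np.allclose(pooled.data, h[0])
    assert np.allclose(alpha.data, 0.2)


def test_attention_single_position_and_empty():
    att = AttentionPool(np.random.default_rng(11), 4)
    h = np.random.default_rng(12).normal(size=(1, 4))
    pooled, alpha, _ = att(Tensor(h))
    assert np.allclose(pooled.data, h[0]) and np.isclose(alpha.data[0, 0], 1.0)
    with pytest.raises(ValueError):
        att(Tensor(np.zeros((0, 4))))


def test_pairwise_contracts():
    pw = PairwiseInteraction(np.random.default_rng(13), 4)
    rng = np.random.default_rng(14)
    P, summary = pw(Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(7, 4))))
    assert P.shape == (3, 7) and summary.shape == (4,)
    assert np.all((P.data > 0) & (P.data < 1))
    # orthogonal (zero) projections give sigma(0) = 0.5
    pw.Wc.W.data[:] = 0; pw.Wc.b.data[:] = 0
    pw.Wp.W.data[:] = 0; pw.Wp.b.data[:] = 0
    P, _ = pw(Tensor(rng.normal(size=(1, 4))), Tensor(rng.normal(size=(1, 4))))
    assert P.shape == (1, 1) and np.isclose(P.data[0, 0], 0.5)


def test_head_outputs():
    head = PredictionHead(np.random.default_rng(15), 8, 6, "classification", 4)
    probs = head(Tensor(np.random.default_rng(16).normal(size=(1, 8))))
    assert probs.shape == (1, 4)
    assert np.isclose(probs.data.sum(), 1.0)
    reg = PredictionHead(np.random.default_rng(17), 8, 6, "regression")
    out = reg(Tensor(np.random.default_rng(18).normal(size=(1, 8))))
    assert out.shape == (1,)
    with pytest.raises(ValueError):
        reg(Tensor(np.zeros((1, 5))))


def test_loss_zero_cases_and_penalty_isolation():
    from aldele.autograd import Parameter
    pred = Tensor(np.array([1.0, 2.0]))
    assert loss(pred, [1.0, 2.0], [], 0.0).data == 0.0
    probs = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert np.isclose(loss(probs, [0, 1], [], 0.0, task="classification").data, 0.0,
                      atol=1e-10)
    theta = Parameter(np.array([2.0, 1.0]))
    val = loss(pred, [1.0, 2.0], [theta], 0.5).data
    assert np.isclose(val, 0.5 * 5.0)
    with pytest.raises(ValueError):
        loss(Tensor(np.array([np.nan])), [0.0], [], 0.0)


# ---------------------------------------------------------------------------
# assembled network
# ---------------------------------------------------------------------------

def _m1_features(smiles, word_ids, d, vocab_n):
    return PairFeatures(graph=_graph(smiles, 2, d), word_ids=np.asarray(word_ids))


def test_prediction_invariant_to_atom_ordering():
    cfg = ModelConfig.from_preset("M1", seed=3)
    d = FingerprintDictionary()
    words = np.array([1, 2, 3, 1])
    feats_a = PairFeatures(graph=_graph("OCC", 2, d), word_ids=words)
    feats_b = PairFeatures(graph=_graph("CCO", 2, d), word_ids=words)
    net = AldeleNetwork(cfg, n_vertex_ids=d.n_vertex_ids,
                        n_edge_ids=d.n_edge_ids, n_words=5)
    assert np.allclose(net.predict(feats_a), net.predict(feats_b))


def test_one_step_decreases_single_pair_loss():
    cfg = ModelConfig.from_preset("M1", seed=4, learning_rate=1e-3)
    d = FingerprintDictionary()
    feats = PairFeatures(graph=_graph("CCO", 2, d), word_ids=np.array([1, 2, 1]))
    net = AldeleNetwork(cfg, d.n_vertex_ids, d.n_edge_ids, n_words=4)
    opt = net.make_optimizer()
    def current_loss():
        pred = net.forward(feats)["prediction"]
        return loss(pred, [2.0], net.params, cfg.lambda_l2)
    before = current_loss()
    before.backward()
    opt.step()
    after = current_loss()
    assert after.data < before.data


def test_stronger_l2_shrinks_weight_norm():
    from aldele.synthetic import SyntheticSpec, build_dataset
    from aldele.train import train_model
    ds, _ = build_dataset(SyntheticSpec(n_pairs=25, n_proteins=5, n_compounds=5,
                                        seq_length=(20, 25), seed=5))
    norms = []
    for lam in (0.0, 1e-2, 1.0):
        cfg = ModelConfig.from_preset("M1", seed=5, epochs=3, lambda_l2=lam)
        ckpt, _ = train_model(cfg, ds)
        norms.append(sum(float((a ** 2).sum()) for a in ckpt.state))
    assert norms[0] > norms[1] > norms[2]


def test_one_dimension_modes_ignore_other_side():
    cfg = ModelConfig(toolkits={3}, mode="protein_only", seed=6)
    net = AldeleNetwork(cfg, n_words=6)
    feats = PairFeatures(word_ids=np.array([1, 2, 3]))
    out1 = net.predict(feats)
    feats_with_graph = PairFeatures(word_ids=np.array([1, 2, 3]),
                                    graph=_graph("CCO"))
    assert np.allclose(net.predict(feats_with_graph), out1)
    cfg_c = ModelConfig(toolkits={2}, mode="compound_only", seed=6)
    d = FingerprintDictionary()
    g = _graph("CCO", 2, d)
    net_c = AldeleNetwork(cfg_c, d.n_vertex_ids, d.n_edge_ids)
    p1 = net_c.predict(PairFeatures(graph=g))
    p2 = net_c.predict(PairFeatures(graph=g, word_ids=np.array([1, 1])))
    assert np.allclose(p1, p2)
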