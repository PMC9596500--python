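"""Graph-attention layer semantics: hand-worked weights, limits, gradients."""

import numpy as np
import pytest

from kgetm.autodiff import Tensor
from kgetm.gat import (GATConfig, GATLayerParams, GATNetwork,
                       attention_weights, gat_forward, gat_layer_forward)
from kgetm.graph import CrossLinkSet, load_hierarchy, merge_knowledge_graph

from conftest import check_gradient


def _graph(tmp_path, icd_lines, atc_lines, links=()):
    icd_p = tmp_path / "icd.tsv"
    icd_p.write_text("\n".join(icd_lines) + "\n")
    atc_p = tmp_path / "atc.tsv"
    atc_p.write_text("\n".join(atc_lines) + "\n")
    ls = CrossLinkSet()
    for a, b in links:
        ls.add(a, b)
    return merge_knowledge_graph(load_hierarchy(icd_p, "icd"),
                                 load_hierarchy(atc_p, "atc"), ls)


@pytest.fixture
def path_graph(tmp_path):
    # merged node order: 100, 200, 300 (icd) then A, A01 (atc)
    return _graph(tmp_path, ["200\t100", "300\t200"], ["A01\tA"],
                  links=[("300", "A01")])


def _identity_layer(dim, a_values=None):
    """Single-head layer with W = I and a configurable attention vector."""
    a = np.zeros(2 * dim) if a_values is None else np.asarray(a_values, float)
    return GATLayerParams(W=[Tensor(np.eye(dim), requires_grad=True)],
                          a=[Tensor(a, requires_grad=True)])


def test_attention_weights_hand_worked_two_logits():
    """Scalar embeddings, W=1, a=(0,1): logits over {self, neighbour} are
    (0, 1), so the weights are softmax(0, 1) = (0.2689, 0.7311)."""
    layer = _identity_layer(1, a_values=[0.0, 1.0])
    weights = attention_weights(layer, head=0, code="x",
                                embeddings={"x": np.array([0.0]),
                                            "b": np.array([1.0])},
                                adjacency={"x": ["b"], "b": ["x"]})
    assert set(weights) == {"x", "b"}
    assert weights["x"] == pytest.approx(0.26894142, abs=1e-6)
    assert weights["b"] == pytest.approx(0.73105858, abs=1e-6)
    assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)


def test_zero_attention_layer_is_neighbourhood_average(path_graph):
    """With a = 0 and W = I every logit is 0, so the layer output is the
    plain average of the node itself and its neighbours."""
    dim = 3
    rng = np.random.default_rng(0)
    h0 = rng.standard_normal((len(path_graph), dim))
    layer = _identity_layer(dim)
    tgt, src = path_graph.edge_arrays()
    out = gat_layer_forward(layer, Tensor(h0), tgt, src, len(path_graph),
                            GATConfig(num_layers=1, num_heads=1)).data
    for i, code in enumerate(path_graph.nodes):
        group = [i] + sorted(path_graph.node_index[n]
                             for n in path_graph.graph.neighbors(code))
        assert np.allclose(out[i], h0[group].mean(axis=0), atol=1e-10)


def test_batched_layer_matches_reference_attention(path_graph):
    """The vectorised layer reproduces the per-node reference evaluation."""
    dim = 4
    rng = np.random.default_rng(1)
    h0 = rng.standard_normal((len(path_graph), dim))
    layer = GATLayerParams.random(dim, num_heads=1, rng=rng)
    tgt, src = path_graph.edge_arrays()
    out = gat_layer_forward(layer, Tensor(h0), tgt, src, len(path_graph),
                            GATConfig(num_layers=1, num_heads=1)).data
    emb = {c: h0[i] for i, c in enumerate(path_graph.nodes)}
    adj = {c: list(path_graph.graph.neighbors(c)) for c in path_graph.nodes}
    W = layer.W[0].data
    for i, code in enumerate(path_graph.nodes):
        w = attention_weights(layer, 0, code, emb, adj)
        expected = sum(wj * (W @ emb[j]) for j, wj in w.items())
        assert np.allclose(out[i], expected, atol=1e-10)


def test_attention_weights_always_sum_to_one(path_graph):
    rng = np.random.default_rng(2)
    emb = {c: rng.standard_normal(3) for c in path_graph.nodes}
    adj = {c: list(path_graph.graph.neighbors(c)) for c in path_graph.nodes}
    for trial in range(20):
        layer = GATLayerParams.random(3, num_heads=2, rng=rng)
        for head in range(2):
            for code in path_graph.nodes:
                w = attention_weights(layer, head, code, emb, adj)
                assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(v >= 0 for v in w.values())


def test_forward_invariant_to_node_insertion_order(tmp_path):
    g1 = _graph(tmp_path, ["200\t100", "300\t200"], ["A01\tA"])
    # same taxonomy content written in a different line order
    (tmp_path / "icd2.tsv").write_text("300\t200\n200\t100\n")
    (tmp_path / "atc2.tsv").write_text("A01\tA\n")
    from kgetm.graph import load_hierarchy as lh
    g2 = merge_knowledge_graph(lh(tmp_path / "icd2.tsv", "icd"),
                               lh(tmp_path / "atc2.tsv", "atc"),
                               CrossLinkSet())
    assert g1.nodes == g2.nodes
    net = GATNetwork(3, GATConfig(num_layers=2, num_heads=2), seed=0)
    h0 = np.random.default_rng(0).standard_normal((len(g1), 3))
    out1 = net.forward(Tensor(h0), g1).data
    out2 = net.forward(Tensor(h0), g2).data
    assert np.allclose(out1, out2)


def test_max_pool_and_head_combining_shapes(path_graph):
    h0 = np.random.default_rng(0).standard_normal((len(path_graph), 4))
    for combine in ("average", "concat-project"):
        net = GATNetwork(4, GATConfig(num_layers=3, num_heads=2,
                                      head_combine=combine), seed=1)
        out = net.forward(Tensor(h0), path_graph)
        assert out.shape == (len(path_graph), 4)
    # max-pool dominates: pooled output >= each layer output elementwise
    net = GATNetwork(4, GATConfig(num_layers=2, num_heads=1), seed=2)
    tgt, src = path_graph.edge_arrays()
    h1 = gat_layer_forward(net.layers[0], Tensor(h0), tgt, src,
                           len(path_graph), net.config)
    h2 = gat_layer_forward(net.layers[1], h1, tgt, src, len(path_graph),
                           net.config)
    pooled = net.forward(Tensor(h0), path_graph).data
    assert np.all(pooled >= h1.data - 1e-12)
    assert np.all(pooled >= h2.data - 1e-12)


def test_gat_layer_gradient_matches_finite_differences(path_graph):
    dim = 3
    rng = np.random.default_rng(3)
    h = Tensor(rng.standard_normal((len(path_graph), dim)),
               requires_grad=True)
    layer = GATLayerParams.random(dim, num_heads=2, rng=rng)
    tgt, src = path_graph.edge_arrays()
    weights = rng.standard_normal((len(path_graph), dim))

    def loss():
        out = gat_layer_forward(layer, h, tgt, src, len(path_graph),
                                GATConfig(num_layers=1, num_heads=2))
        return (out * Tensor(weights)).sum()

    for param in [h, *layer.parameters()]:
        check_gradient(loss, param, rtol=1e-4)


def test_gat_forward_extracts_vocabulary_rows(path_graph):
    net = GATNetwork(3, GATConfig(num_layers=1, num_heads=1), seed=0)
    h0 = np.random.default_rng(0).standard_normal((len(path_graph), 3))
    emb = gat_forward(net, h0, path_graph, ["100", "300"], ["A01"])
    full = net.forward(Tensor(h0), path_graph).data
    assert np.allclose(emb.rho_icd[1], full[path_graph.node_index["300"]])
    assert np.allclose(emb.rho_atc[0], full[path_graph.node_index["A01"]])
    with pytest.raises(KeyError):
        gat_forward(net, h0, path_graph, ["100", "MISSING"], ["A01"])


def test_config_validation():
    with pytest.raises(ValueError):
        GATConfig(num_layers=0)
    with pytest.raises(ValueError):
        GATConfig(head_combine="sum")
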