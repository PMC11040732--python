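"""Molecular graph construction, r-radius subgraph identifiers and the
descriptor pipeline."""

import numpy as np
import networkx as nx
import pytest

from aldele.chem import (FingerprintDictionary, assign_subgraph_ids,
                         compute_descriptors, filter_and_select, parse_smiles,
                         DESCRIPTOR_NAMES)

SMALL_MOLECULES = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CC(C)(C)C", "CCO", "OCCO", "CCN",
    "CC(N)C(=O)O", "CC=O", "C=CC=C", "C#N", "CC#N", "c1ccccc1", "c1ccncc1",
    "c1ccoc1", "c1ccsc1", "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1",
    "C1CCOC1", "C1CCNC1", "CC(=O)O", "CC(=O)N", "COC", "CSC", "CS(=O)C",
    "CCl", "CBr", "CF", "C(F)(F)F", "CC(F)F", "OC(=O)C(=O)O", "NC(=O)N",
    "CNC", "CN(C)C", "CCOC(C)=O", "CC(O)C", "OCC(O)CO", "C=O", "OC=O",
    "CCS", "NCCO", "C1=CC(=O)C=CC1=O", "Cc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "CC(C)O",
]


def test_parse_smiles_counts():
    g = parse_smiles("CCO")
    assert g.n_vertices == 3 and g.n_edges == 2
    assert [t[0] for t in g.atom_types] == ["C", "C", "O"]
    g = parse_smiles("C")
    assert g.n_vertices == 1 and g.n_edges == 0
    g = parse_smiles("c1ccccc1")
    assert g.n_vertices == 6 and g.n_edges == 6


@pytest.mark.parametrize("bad", ["", "not_a_smiles", "C(("])
def test_parse_smiles_rejects_invalid(bad):
    with pytest.raises(ValueError):
        parse_smiles(bad)


def test_benzene_single_id_at_each_radius():
    for r in (1, 2):
        g = assign_subgraph_ids(parse_smiles("c1ccccc1"), r)
        assert len(set(g.vertex_subgraph_ids)) == 1


def test_ethanol_three_distinct_ids_at_r1():
    g = assign_subgraph_ids(parse_smiles("CCO"), 1)
    assert len(set(g.vertex_subgraph_ids)) == 3


def test_radius_zero_is_atom_type_partition():
    for smi in ("CCO", "c1ccccc1", "CC(=O)O"):
        g = assign_subgraph_ids(parse_smiles(smi), 0)
        by_type = {}
        for t, i in zip(g.atom_types, g.vertex_subgraph_ids):
            by_type.setdefault(t, set()).add(i)
        # bijection between atom types and ids
        assert all(len(v) == 1 for v in by_type.values())
        assert len({next(iter(v)) for v in by_type.values()}) == len(by_type)


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        assign_subgraph_ids(parse_smiles("CC"), -1)


def _ball_partition(graph, r):
    """Oracle: group vertices by rooted-ball isomorphism (VF2)."""
    G = nx.Graph()
    for i, t in enumerate(graph.atom_types):
        G.add_node(i, t=t)
    for i, j, bt in graph.bonds:
        G.add_edge(i, j, bt=bt)
    balls = []
    for v in G.nodes:
        dist = nx.single_source_shortest_path_length(G, v, cutoff=r)
        sub = G.subgraph(dist).copy()
        for n in sub.nodes:
            sub.nodes[n]["center"] = n == v
        balls.append(sub)
    nm = nx.algorithms.isomorphism.categorical_node_match(["t", "center"], [None, None])
    em = nx.algorithms.isomorphism.categorical_edge_match("bt", None)
    classes = []
    labels = np.empty(len(balls), dtype=int)
    for v, ball in enumerate(balls):
        for ci, rep in enumerate(classes):
            if nx.is_isomorphic(ball, rep, node_match=nm, edge_match=em):
                labels[v] = ci
                break
        else:
            classes.append(ball)
            labels[v] = len(classes) - 1
    return labels


@pytest.mark.parametrize("r", [1, 2])
def test_subgraph_ids_match_ball_isomorphism_oracle(r):
    """Vertices receive equal ids exactly when their r-neighborhoods are
    graph-isomorphic (brute-force VF2 oracle, molecules <=10 heavy atoms)."""
    checked = 0
    for smi in SMALL_MOLECULES:
        g = parse_smiles(smi)
        if g.n_vertices > 10:
            continue
        assign_subgraph_ids(g, r)
        mine = np.asarray(g.vertex_subgraph_ids)
        oracle = _ball_partition(g, r)
        # partitions equal up to renaming
        pairs = {(a, b) for a, b in zip(mine, oracle)}
        assert len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs}), smi
        checked += 1
    assert checked >= 50


def test_subgraph_ids_permutation_invariant():
    rng = np.random.default_rng(0)
    for smi in ("CC(N)C(=O)O", "c1ccncc1", "CCOC(C)=O"):
        g = parse_smiles(smi)
        perm = rng.permutation(g.n_vertices)
        inv = np.argsort(perm)
        g2 = parse_smiles(smi)
        g2.atom_types = [g.atom_types[perm[i]] for i in range(g.n_vertices)]
        g2.bonds = [tuple(sorted((int(inv[i]), int(inv[j])))) + (bt,)
                    for i, j, bt in g.bonds]
        d = FingerprintDictionary()
        assign_subgraph_ids(g, 2, d)
        assign_subgraph_ids(g2, 2, d)
        assert sorted(g.vertex_subgraph_ids) == sorted(g2.vertex_subgraph_ids)


def test_radius_refinement_is_monotone():
    """The partition at radius r+1 refines the partition at radius r."""
    for smi in SMALL_MOLECULES[:20]:
        ids = {}
        for r in (0, 1, 2):
            g = assign_subgraph_ids(parse_smiles(smi), r)
            ids[r] = g.vertex_subgraph_ids
        for r in (0, 1):
            # same id at r+1 implies same id at r
            for i in range(len(ids[r])):
                for j in range(i + 1, len(ids[r])):
                    if ids[r + 1][i] == ids[r + 1][j]:
                        assert ids[r][i] == ids[r][j], smi


def test_unknown_fingerprints_map_to_reserved_id():
    d = FingerprintDictionary()
    assign_subgraph_ids(parse_smiles("CCO"), 2, d)
    d.frozen = True
    g = assign_subgraph_ids(parse_smiles("c1ccsc1"), 2, d)
    assert set(g.vertex_subgraph_ids) == {0}


def test_descriptors_basic_structure():
    v = compute_descriptors("c1ccccc1")
    names = dict(zip(v.names, v.values))
    assert names["HeavyAtomCount"] == 6
    assert names["RingCount"] == 1
    v1 = compute_descriptors("CCO")
    v2 = compute_descriptors("CCO")
    assert np.array_equal(v1.values, v2.values, equal_nan=True)


def test_filter_and_select_contracts():
    rng = np.random.default_rng(1)
    n, p = 40, 30
    X = rng.normal(size=(n, p))
    X[:, 5] = 7.0                      # invariant column
    X[:, 6] = np.inf                   # non-finite column
    y = rng.normal(size=n)
    X[:, 3] = y                        # perfect predictor
    names = [f"d{i:02d}" for i in range(p)]
    sel = filter_and_select(X, y, k=10, names=names)
    assert len(sel) == 10
    assert 5 not in sel and 6 not in sel
    assert sel[0] == 3                 # label-equal column ranked first
    with pytest.raises(ValueError):
        filter_and_select(X[:10], y, k=10, names=names)
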