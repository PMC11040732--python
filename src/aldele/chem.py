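"""Compound featurization: molecular graphs with r-radius subgraph ids and
whole-molecule descriptor vectors.

Two complementary views of a substrate are produced:

* a heavy-atom molecular graph whose vertices carry discrete *r-radius
  subgraph* identifiers — the induced neighborhood of each atom within
  graph distance ``r``, hashed by iterative Weisfeiler–Lehman-style
  relabeling so that graph-isomorphic neighborhoods share one identifier.
  The identifiers index learned embedding tables downstream.
* a vector of ~200 conformation-independent RDKit descriptors
  (compositional counts, topology, computed logP, ...), filtered for
  invariant/non-finite columns and reduced to the top-k most
  label-informative descriptors by tree-ensemble importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit import RDLogger
from sklearn.ensemble import ExtraTreesClassifier, ExtraTreesRegressor

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeGraph",
    "DescriptorVector",
    "FingerprintDictionary",
    "parse_smiles",
    "assign_subgraph_ids",
    "compute_descriptors",
    "filter_and_select",
]

UNKNOWN_ID = 0  # reserved embedding slot for fingerprints unseen at fit time


@dataclass
class MoleculeGraph:
    """Heavy-atom graph of one compound.

    ``bonds`` stores each undirected bond once with i < j.  ``atom_types``
    are hashable per-vertex codes (symbol, aromatic flag, total H count,
    formal charge); the H-count channel distinguishes e.g. terminal from
    internal carbons already at radius 0.
    """

    smiles: str
    atom_types: list
    bonds: list  # (i, j, bond_type_code)
    vertex_subgraph_ids: list[int] | None = None
    edge_subgraph_ids: list[int] | None = None
    radius: int | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.atom_types)

    @property
    def n_edges(self) -> int:
        return len(self.bonds)


class FingerprintDictionary:
    """Dataset-level mapping from subgraph fingerprints to integer ids.

    Grown while featurizing training molecules, then frozen; fingerprints
    first seen at inference map to the reserved unknown id (0) so the
    embedding vocabulary stays closed.
    """

    def __init__(self):
        self.vertex: dict = {}
        self.edge: dict = {}
        self.frozen = False

    def vertex_id(self, key) -> int:
        if key in self.vertex:
            return self.vertex[key]
        if self.frozen:
            return UNKNOWN_ID
        idx = len(self.vertex) + 1  # 0 reserved
        self.vertex[key] = idx
        return idx

    def edge_id(self, key) -> int:
        if key in self.edge:
            return self.edge[key]
        if self.frozen:
            return UNKNOWN_ID
        idx = len(self.edge) + 1
        self.edge[key] = idx
        return idx

    @property
    def n_vertex_ids(self) -> int:
        return len(self.vertex) + 1

    @property
    def n_edge_ids(self) -> int:
        return len(self.edge) + 1


def parse_smiles(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a heavy-atom :class:`MoleculeGraph`.

    Hydrogens stay implicit; aromaticity uses RDKit's perception and
    aromatic bonds get their own bond-type code.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    atom_types = [
        (a.GetSymbol(), a.GetIsAromatic(), a.GetTotalNumHs(), a.GetFormalCharge())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j, str(b.GetBondType())))
    return MoleculeGraph(smiles=smiles, atom_types=atom_types, bonds=bonds)


def assign_subgraph_ids(
    graph: MoleculeGraph, r: int, dictionary: FingerprintDictionary | None = None
) -> MoleculeGraph:
    """Assign r-radius subgraph identifiers to every vertex and edge.

    Runs ``r`` rounds of simultaneous relabeling: a vertex label becomes the
    hash of (its label, the sorted multiset of (incident-edge label, neighbor
    label) pairs); an edge label becomes (its bond type, the unordered pair
    of endpoint labels).  At radius 0 the vertex ids are exactly the
    atom-type partition.  Final labels are interned in `dictionary` (a fresh
    one if omitted).
    """
    if r < 0:
        raise ValueError("radius r must be non-negative")
    if dictionary is None:
        dictionary = FingerprintDictionary()
    n = graph.n_vertices
    v_labels = list(graph.atom_types)
    e_labels = [bt for (_, _, bt) in graph.bonds]
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]  # vertex -> (edge idx, neighbor)
    for e_idx, (i, j, _) in enumerate(graph.bonds):
        adj[i].append((e_idx, j))
        adj[j].append((e_idx, i))
    for _ in range(r):
        new_v = [
            (v_labels[i], tuple(sorted((e_labels[e], v_labels[nb]) for e, nb in adj[i])))
            for i in range(n)
        ]
        new_e = [
            (graph.bonds[e][2], tuple(sorted((v_labels[i], v_labels[j]))))
            for e, (i, j, _) in enumerate(graph.bonds)
        ]
        v_labels, e_labels = new_v, new_e
    graph.vertex_subgraph_ids = [dictionary.vertex_id(("v", r, lab)) for lab in v_labels]
    graph.edge_subgraph_ids = [dictionary.edge_id(("e", r, lab)) for lab in e_labels]
    graph.radius = r
    return graph


# ---------------------------------------------------------------------------
# Toolkit 1: whole-molecule descriptors
# ---------------------------------------------------------------------------

_DESCRIPTOR_FUNCS = sorted(Descriptors.descList, key=lambda nf: nf[0])
DESCRIPTOR_NAMES = [name for name, _ in _DESCRIPTOR_FUNCS]


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list[str] = field(default_factory=lambda: list(DESCRIPTOR_NAMES))
    selected_indices: np.ndarray | None = None


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the full conformation-independent RDKit descriptor vector.

    Entries the descriptor engine cannot evaluate come back as NaN and are
    excluded later by :func:`filter_and_select`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    values = np.empty(len(_DESCRIPTOR_FUNCS))
    n_bad = 0
    for k, (_, fn) in enumerate(_DESCRIPTOR_FUNCS):
        try:
            values[k] = float(fn(mol))
        except Exception:
            values[k] = np.nan
            n_bad += 1
    if n_bad == len(values):
        raise ValueError(f"descriptor engine returned no values for {smiles!r}")
    return DescriptorVector(values=values)


def filter_and_select(
    descriptor_matrix: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    task: str = "regression",
    names: list[str] | None = None,
    random_state: int = 0,
) -> np.ndarray:
    """Drop invariant/non-finite descriptor columns and keep the top-k.

    Survivors are ranked by feature importance from a small randomized-tree
    ensemble fit on the (training-fold) labels, ties broken by descriptor
    name so the selection is deterministic.  Returns the retained column
    indices into the original matrix; exactly ``min(k, n_surviving)`` of
    them.
    """
    X = np.asarray(descriptor_matrix, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("descriptor matrix rows and labels length differ")
    if k < 1:
        raise ValueError("k must be positive")
    names = names if names is not None else DESCRIPTOR_NAMES
    finite = np.isfinite(X).all(axis=0)
    with np.errstate(invalid="ignore"):
        varying = np.nanstd(X, axis=0) > 0
    surviving = np.flatnonzero(finite & varying)
    if surviving.size < 1:
        raise ValueError("no descriptor column survives the invariant/finite filter")
    est_cls = ExtraTreesRegressor if task == "regression" else ExtraTreesClassifier
    est = est_cls(n_estimators=64, random_state=random_state, n_jobs=1)
    est.fit(X[:, surviving], y)
    imp = est.feature_importances_
    order = sorted(range(surviving.size), key=lambda i: (-imp[i], names[surviving[i]]))
    return surviving[order[: min(k, surviving.size)]]  # best-ranked first
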