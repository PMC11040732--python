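"""The ALDELE network: encoder blocks per toolkit, two-phase attention,
the pairwise interaction module, prediction heads and the training loss.

Architecture sketch (cpi mode)::

    compound side                         protein side
    ------------------                    -------------------
    T2 graph --GNN--> vertex vectors V    T3 words --CNN--> C
    T1 descriptors --ANN--> r             T4 PSSM  --CNN--> M
            |                                  |
     attention phase C over V (+r)      attention phase P over C++M
            |                                  |
       pooled compound vector        pooled protein vector (++ T5 energy
            |                           readout, joined after attention)
            +------ pairwise P_ij = sigmoid(f(Wc v_i) . f(Wp c_j)) ------+
                                |
              combined descriptor --> MLP head --> activity / classes

All parameters (dense weights, embedding tables for subgraph vertices,
edges and n-gram words) are trained jointly by backpropagation with L2
regularization.
"""

from __future__ import annotations

import numpy as np

from .autograd import Adam, Parameter, Tensor, concat, softmax
from .chem import MoleculeGraph
from .config import ModelConfig

__all__ = [
    "AldeleNetwork", "GNNEncoder", "CNNEncoder", "ANNEncoder",
    "AttentionPool", "PairwiseInteraction", "PredictionHead", "loss",
]


def _init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Uniform init scaled by fan-in."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _init_embedding(rng: np.random.Generator, n_rows: int, dim: int) -> np.ndarray:
    """Embedding-table init: each row scaled by the embedding dimension
    (the table's row count is a vocabulary size, not a fan-in)."""
    bound = 1.0 / np.sqrt(dim)
    return rng.uniform(-bound, bound, size=(n_rows, dim))


class Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Parameter(_init(rng, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class GNNEncoder:
    """Message-passing encoder over r-radius subgraph embeddings.

    Each layer updates vertices from their incident edge embeddings and
    edges from their endpoint vertices, simultaneously, through ReLU
    transforms; with zero layers the raw embedding lookup is returned.
    """

    def __init__(self, rng, n_vertex_ids: int, n_edge_ids: int, dim: int, layers: int):
        self.dim = dim
        self.layers = layers
        self.n_vertex_ids = n_vertex_ids
        self.n_edge_ids = n_edge_ids
        self.vertex_emb = Parameter(_init_embedding(rng, n_vertex_ids, dim))
        self.edge_emb = Parameter(_init_embedding(rng, n_edge_ids, dim))
        self.W_v = [Dense(rng, dim, dim) for _ in range(layers)]
        self.W_e = [Dense(rng, dim, dim) for _ in range(layers)]

    def __call__(self, graph: MoleculeGraph) -> Tensor:
        if graph.vertex_subgraph_ids is None:
            raise ValueError("graph has no subgraph ids assigned")
        v_ids = np.asarray(graph.vertex_subgraph_ids)
        if v_ids.max(initial=0) >= self.n_vertex_ids:
            raise ValueError("vertex subgraph id outside the embedding dictionary")
        V = self.vertex_emb[v_ids]
        n = graph.n_vertices
        if graph.n_edges:
            e_ids = np.asarray(graph.edge_subgraph_ids)
            if e_ids.max(initial=0) >= self.n_edge_ids:
                raise ValueError("edge subgraph id outside the embedding dictionary")
            E = self.edge_emb[e_ids]
            B = np.zeros((n, graph.n_edges))  # vertex-edge incidence
            for k, (i, j, _) in enumerate(graph.bonds):
                B[i, k] = 1.0
                B[j, k] = 1.0
            Bt = Tensor(B)
            for Wv, We in zip(self.W_v, self.W_e):
                V_new = Wv(V + Bt @ E).relu()
                E_new = We(E + Bt.T @ V).relu()
                V, E = V_new, E_new
        else:
            for Wv in self.W_v:
                V = Wv(V).relu()
        return V

    @property
    def params(self):
        out = [self.vertex_emb, self.edge_emb]
        for d in self.W_v + self.W_e:
            out += d.params
        return out


class CNNEncoder:
    """Stack of length-preserving 1-D convolutions with ReLU.

    Each layer computes f(W_conv . window + b_conv) per position; the input
    is zero-padded so the number of positions never changes.
    """

    def __init__(self, rng, dim: int, layers: int, kernel: int = 3):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        self.kernel = kernel
        self.offsets = list(range(-(kernel // 2), kernel // 2 + 1))
        self.layers = [
            ([Dense(rng, dim, dim) for _ in self.offsets]) for _ in range(layers)
        ]

    @staticmethod
    def _shift(x: Tensor, offset: int) -> Tensor:
        """Rows shifted by `offset` positions, zero-filled at the boundary."""
        if offset == 0:
            return x
        L, d = x.shape
        if abs(offset) >= L:
            return Tensor(np.zeros((L, d)))
        pad = Tensor(np.zeros((abs(offset), d)))
        if offset > 0:
            return concat([pad, x[: L - offset]], axis=0)
        return concat([x[-offset:], pad], axis=0)

    def __call__(self, rows: Tensor) -> Tensor:
        if rows.shape[0] < 1:
            raise ValueError("CNN input must contain at least one position")
        h = rows
        for taps in self.layers:
            acc = None
            for off, dense in zip(self.offsets, taps):
                term = self._shift(h, off) @ dense.W
                acc = term if acc is None else acc + term
            acc = acc + taps[self.kernel // 2].b
            h = acc.relu()
        return h

    @property
    def params(self):
        out = []
        for taps in self.layers:
            for d in taps:
                out += d.params
        return out


class ANNEncoder:
    """Dense ReLU stack over the selected whole-compound descriptors."""

    def __init__(self, rng, d_in: int, dim: int, layers: int):
        self.d_in = d_in
        dims = [d_in] + [dim] * layers
        self.dense = [Dense(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(
                f"descriptor input has length {x.shape[-1]}, expected the "
                f"selected length {self.d_in}")
        h = x
        for d in self.dense:
            h = d(h).relu()
        return h

    @property
    def params(self):
        out = []
        for d in self.dense:
            out += d.params
        return out


class AttentionPool:
    """Neural attention pooling over a set of position vectors.

    Per-position scores are ReLU(W.h_i + b); softmax normalization turns
    them into convex pooling weights (summing to 1), and the raw scores are
    kept for interpretation (hotspot profiles min-max rescale them).
    """

    def __init__(self, rng, dim: int):
        # zero scoring vector + positive bias: scores start uniform and in
        # the active ReLU regime, so the attention direction is set by the
        # training gradients instead of by initialization noise
        self.w = Parameter(np.zeros((dim, 1)))
        self.b = Parameter(np.ones(1))

    def __call__(self, hidden: Tensor) -> tuple[Tensor, Tensor, np.ndarray]:
        if hidden.shape[0] < 1:
            raise ValueError("attention pooling needs at least one position")
        scores = (hidden @ self.w + self.b).relu()       # (L, 1)
        alpha = softmax(scores, axis=0)                  # (L, 1), sums to 1
        pooled = (alpha * hidden).sum(axis=0)            # (dim,)
        return pooled, alpha, scores.data.ravel().copy()

    @property
    def params(self):
        return [self.w, self.b]


class PairwiseInteraction:
    """Sigmoid-normalized bilinear scores between compound atoms and
    protein positions, plus a fixed-length summary of the score matrix.

    P_ij = sigmoid(f(Wc v_i) . f(Wp c_j)); the combined descriptor keeps
    the hot-pair signal through order-invariant summaries: mean row max,
    overall mean, mean column max, overall max.
    """

    def __init__(self, rng, dim: int):
        self.Wc = Dense(rng, dim, dim)
        self.Wp = Dense(rng, dim, dim)

    def __call__(self, compound_vectors: Tensor, protein_vectors: Tensor
                 ) -> tuple[Tensor, Tensor]:
        if compound_vectors.shape[1] != protein_vectors.shape[1]:
            raise ValueError("compound and protein vectors have mismatched dimensionality")
        U = self.Wc(compound_vectors).relu()
        C = self.Wp(protein_vectors).relu()
        P = (U @ C.T).sigmoid()
        s_row_max = P.max(axis=1).mean()
        s_mean = P.mean()
        s_col_max = P.max(axis=0).mean()
        s_max = P.max()
        summary = concat([s.reshape(1) for s in (s_row_max, s_mean, s_col_max, s_max)])
        return P, summary

    @property
    def params(self):
        return self.Wc.params + self.Wp.params


class PredictionHead:
    """MLP head: scalar for regression, softmax probabilities for
    classification."""

    def __init__(self, rng, d_in: int, dim: int, task: str, num_classes: int = 4):
        self.task = task
        d_out = 1 if task == "regression" else num_classes
        self.hidden = Dense(rng, d_in, dim)
        self.out = Dense(rng, dim, d_out)
        self.d_in = d_in

    def __call__(self, combined: Tensor) -> Tensor:
        if combined.shape[-1] != self.d_in:
            raise ValueError(
                f"combined descriptor has length {combined.shape[-1]}, expected {self.d_in}")
        h = self.hidden(combined).relu()
        z = self.out(h)
        if self.task == "regression":
            return z.reshape(1)[0:1]
        return softmax(z, axis=-1)

    @property
    def params(self):
        return self.hidden.params + self.out.params


def loss(predictions: Tensor, labels: np.ndarray, params: list[Parameter],
         lambda_l2: float, task: str = "regression") -> Tensor:
    """Training objective: MSE (regression) or cross-entropy
    (classification), plus lambda * ||Theta||^2 over every weight matrix,
    bias and embedding table."""
    if not np.isfinite(predictions.data).all():
        raise ValueError("NaN or infinite value in predictions")
    if task == "regression":
        y = Tensor(np.asarray(labels, dtype=float).ravel())
        data_term = ((predictions - y) ** 2.0).mean()
    else:
        y = np.asarray(labels, dtype=int).ravel()
        probs = predictions  # (n, n_classes) softmax outputs
        eps = Tensor(1e-12)
        picked = probs[np.arange(y.size), y]
        data_term = -((picked + eps).log().mean())
    if lambda_l2 > 0:
        reg = None
        for p in params:
            term = (p ** 2.0).sum()
            reg = term if reg is None else reg + term
        return data_term + lambda_l2 * reg
    return data_term


class PairFeatures:
    """Featurized inputs for one compound-protein pair."""

    def __init__(self, graph=None, descriptors=None, word_ids=None,
                 pssm_scaled=None, energy_reduced=None, compound_id=None,
                 protein_id=None):
        self.graph = graph
        self.descriptors = descriptors
        self.word_ids = word_ids
        self.pssm_scaled = pssm_scaled
        self.energy_reduced = energy_reduced
        self.compound_id = compound_id
        self.protein_id = protein_id


class AldeleNetwork:
    """The assembled model for one toolkit combination and mode."""

    def __init__(self, config: ModelConfig, n_vertex_ids: int = 1,
                 n_edge_ids: int = 1, n_words: int = 1):
        self.config = config
        rng = np.random.default_rng(config.seed)
        T = config.toolkits
        dim = config.dim
        self.gnn = GNNEncoder(rng, n_vertex_ids, n_edge_ids, dim, config.layers_gnn) if 2 in T else None
        self.ann = ANNEncoder(rng, config.k_descriptors, dim, config.layers_nn) if 1 in T else None
        self.word_emb = Parameter(_init_embedding(rng, n_words, dim)) if 3 in T else None
        self.cnn_words = CNNEncoder(rng, dim, config.layers_cnn, config.cnn_kernel) if 3 in T else None
        self.pssm_proj = Dense(rng, 20, dim) if 4 in T else None
        self.cnn_pssm = CNNEncoder(rng, dim, config.layers_cnn, config.cnn_kernel) if 4 in T else None
        self.energy_proj = Dense(rng, config.k_energy, dim) if 5 in T else None
        self.attn_compound = AttentionPool(rng, dim) if (T & {1, 2}) else None
        self.attn_protein = AttentionPool(rng, dim) if (T & {3, 4}) else None
        # joins sequence-attended and structure readouts into one protein vector
        self.protein_join = Dense(rng, 2 * dim, dim) if 5 in T and (T & {3, 4}) else None
        self.pairwise = PairwiseInteraction(rng, dim) if config.mode == "cpi" else None
        if config.mode == "cpi":
            d_comb = 2 * dim + 4
        else:
            d_comb = dim
        self.head = PredictionHead(rng, d_comb, dim, config.task, config.num_classes)

    # ------------------------------------------------------------------
    @property
    def params(self) -> list[Parameter]:
        out = []
        for comp in (self.gnn, self.ann, self.cnn_words, self.cnn_pssm,
                     self.attn_compound, self.attn_protein, self.pairwise,
                     self.head):
            if comp is not None:
                out += comp.params
        for dense in (self.pssm_proj, self.energy_proj, self.protein_join):
            if dense is not None:
                out += dense.params
        if self.word_emb is not None:
            out.append(self.word_emb)
        return out

    # ------------------------------------------------------------------
    def _compound_positions(self, feats: PairFeatures) -> tuple[Tensor, list]:
        blocks, prov = [], []
        if self.gnn is not None:
            V = self.gnn(feats.graph)
            blocks.append(V)
            prov += [("atom", i) for i in range(feats.graph.n_vertices)]
        if self.ann is not None:
            if feats.descriptors is None:
                raise ValueError("toolkit 1 enabled but pair has no descriptor vector")
            r = self.ann(Tensor(np.asarray(feats.descriptors, dtype=float)))
            blocks.append(r.reshape(1, -1))
            prov.append(("descriptor", 0))
        return concat(blocks, axis=0), prov

    def _protein_positions(self, feats: PairFeatures) -> tuple[Tensor, list]:
        blocks, prov = [], []
        if self.cnn_words is not None:
            if feats.word_ids is None:
                raise ValueError("toolkit 3 enabled but pair has no word ids")
            emb = self.word_emb[np.asarray(feats.word_ids)]
            C = self.cnn_words(emb)
            blocks.append(C)
            prov += [("word", i) for i in range(len(feats.word_ids))]
        if self.cnn_pssm is not None:
            if feats.pssm_scaled is None:
                raise ValueError("toolkit 4 enabled but pair has no PSSM")
            M = self.cnn_pssm(self.pssm_proj(Tensor(feats.pssm_scaled)).relu())
            blocks.append(M)
            prov += [("residue", i) for i in range(feats.pssm_scaled.shape[0])]
        return concat(blocks, axis=0), prov

    def forward(self, feats: PairFeatures) -> dict:
        """Run one pair through the network; returns the prediction plus the
        attention scores and pairwise matrix needed for interpretation."""
        cfg = self.config
        out: dict = {}
        compound_vec = protein_vec = None
        if cfg.mode in ("cpi", "compound_only"):
            Vc, prov_c = self._compound_positions(feats)
            compound_vec, _, scores_c = self.attn_compound(Vc)
            out["attention_compound"] = scores_c
            out["compound_provenance"] = prov_c
            compound_positions = Vc
        if cfg.mode in ("cpi", "protein_only"):
            if cfg.toolkits & {3, 4}:
                Vp, prov_p = self._protein_positions(feats)
                seq_vec, _, scores_p = self.attn_protein(Vp)
                out["attention_protein"] = scores_p
                out["protein_provenance"] = prov_p
                protein_positions = Vp
            else:
                seq_vec = protein_positions = prov_p = None
            if self.energy_proj is not None:
                if feats.energy_reduced is None:
                    raise ValueError("toolkit 5 enabled but pair has no energy features")
                y_energy = self.energy_proj(
                    Tensor(np.asarray(feats.energy_reduced, dtype=float))).relu()
                if seq_vec is not None:
                    protein_vec = self.protein_join(
                        concat([seq_vec, y_energy], axis=0).reshape(1, -1))[0].relu()
                    protein_vec = protein_vec.reshape(-1)
                else:
                    protein_vec = y_energy
            else:
                protein_vec = seq_vec
        if cfg.mode == "cpi":
            if protein_positions is None:
                # energy-only protein side: the joined vector is the single position
                protein_positions = protein_vec.reshape(1, -1)
            P, summary = self.pairwise(compound_positions, protein_positions)
            out["pairwise"] = P.data.copy()
            combined = concat([compound_vec, protein_vec, summary], axis=0)
        elif cfg.mode == "compound_only":
            combined = compound_vec
        else:
            combined = protein_vec
        out["prediction"] = self.head(combined.reshape(1, -1))
        return out

    def predict(self, feats: PairFeatures) -> np.ndarray:
        return self.forward(feats)["prediction"].data.copy()

    def make_optimizer(self) -> Adam:
        return Adam(self.params, lr=self.config.learning_rate)

    # ---- checkpoint (de)serialization --------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        mine = self.params
        if len(state) != len(mine):
            raise ValueError("state does not match the network's parameter list")
        for p, arr in zip(mine, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch while loading state")
            p.data = arr.copy()
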