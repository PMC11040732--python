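"""Dataset assembly, label preprocessing, cross-validated training and
metric computation.

The training protocol follows the published recipe: shuffle, split into
k (default 5) folds, and for each fold fit *every* data-dependent
component — the subgraph fingerprint dictionary, the n-gram vocabulary,
descriptor selection and scaling, and the energy PCA basis — on the
training portion only.  The held-out fold is split 50/50 into a
validation half (which picks the epoch with minimal r.m.s.e.) and a test
half (which produces the reported metrics).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .chem import (FingerprintDictionary, assign_subgraph_ids,
                   compute_descriptors, filter_and_select, parse_smiles)
from .config import ModelConfig
from .model import AldeleNetwork, PairFeatures, loss as model_loss
from .protein import NgramVocabulary, smooth_pssm, split_ngrams, parse_psiblast_pssm, PSSM
from .structure import EnergyMatrix, EnergyReducer, normalize_vs_wildtype

__all__ = [
    "CPIDataset", "MetricsReport", "Checkpoint", "Featurizer",
    "preprocess_labels", "kfold_split", "train_model", "cross_validate",
    "compute_metrics",
]

CHECKPOINT_SCHEMA = 1


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def preprocess_labels(raw, scheme: str, bounds=None) -> np.ndarray:
    """Apply a dataset's preprocessing scheme to raw activity values.

    Schemes: ``percentage`` (identity), ``log2``, ``log10``,
    ``cutoff:<theta>`` (binary by raw >= theta), ``multiclass`` (ordinal
    classes from ``bounds``; default 0 -> class 0, tertiles of the nonzero
    values -> classes 1..3).
    """
    raw = np.asarray(raw, dtype=float)
    if scheme == "percentage":
        return raw.copy()
    if scheme in ("log2", "log10"):
        bad = np.flatnonzero(raw <= 0)
        if bad.size:
            raise ValueError(
                f"{scheme} scheme requires positive values; offending pair rows: {bad.tolist()}")
        return np.log2(raw) if scheme == "log2" else np.log10(raw)
    if scheme.startswith("cutoff"):
        theta = float(scheme.split(":", 1)[1]) if ":" in scheme else 0.0
        return (raw >= theta).astype(float)
    if scheme == "multiclass":
        if bounds is None:
            nonzero = raw[raw > 0]
            if nonzero.size == 0:
                return np.zeros_like(raw)
            bounds = np.quantile(nonzero, [1 / 3, 2 / 3])
        labels = np.zeros(raw.shape, dtype=float)
        labels[raw > 0] = 1
        labels[raw > bounds[0]] = 2
        labels[raw > bounds[1]] = 3
        return labels
    raise ValueError(f"unknown preprocessing scheme {scheme!r}")


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded shuffle into k near-equal disjoint folds; returns the fold
    index of every pair."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pairs n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class CPIDataset:
    """Aligned (compound, protein, label) triples plus raw inputs.

    ``compounds`` maps compound id -> SMILES; ``proteins`` maps protein id
    -> sequence.  PSSMs and energy tables are optional and referenced per
    protein id.
    """

    pairs: list  # (compound_id, protein_id, raw_label)
    compounds: dict
    proteins: dict
    scheme: str = "percentage"
    pssms: dict | None = None            # protein_id -> PSSM | path
    energies: dict | None = None         # protein_id -> EnergyMatrix
    wt_ensemble: list | None = None      # list[EnergyMatrix]
    bounds: tuple | None = None
    labels: np.ndarray = field(init=False)

    def __post_init__(self):
        missing = [
            (c, p) for c, p, _ in self.pairs
            if c not in self.compounds or p not in self.proteins
        ]
        if missing:
            raise ValueError(f"pairs reference unknown records: {missing[:5]}")
        self.labels = preprocess_labels(
            [lab for _, _, lab in self.pairs], self.scheme, self.bounds)

    def __len__(self):
        return len(self.pairs)


# ---------------------------------------------------------------------------
# featurization (fitted on training folds only)
# ---------------------------------------------------------------------------

class Featurizer:
    """Turns raw dataset records into :class:`PairFeatures`.

    ``fit`` grows the fingerprint dictionary, n-gram vocabulary,
    descriptor selection/scaling and the energy PCA basis from the
    training pairs only, then freezes them; ``transform`` maps any pair
    through the frozen state (unseen fingerprints/words go to the
    reserved unknown ids).
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.fingerprints = FingerprintDictionary()
        self.vocabulary = NgramVocabulary(n=config.n)
        self.selected: np.ndarray | None = None
        self.desc_mean: np.ndarray | None = None
        self.desc_std: np.ndarray | None = None
        self.reducer: EnergyReducer | None = None
        self._graphs: dict = {}
        self._descriptors: dict = {}
        self._words: dict = {}
        self._pssm: dict = {}
        self._energy: dict = {}

    # -- helpers -----------------------------------------------------------
    def _graph(self, dataset: CPIDataset, cid):
        if cid not in self._graphs:
            g = parse_smiles(dataset.compounds[cid])
            assign_subgraph_ids(g, self.config.r, self.fingerprints)
            self._graphs[cid] = g
        return self._graphs[cid]

    def _full_descriptors(self, dataset: CPIDataset, cid):
        if cid not in self._descriptors:
            self._descriptors[cid] = compute_descriptors(dataset.compounds[cid]).values
        return self._descriptors[cid]

    def _word_ids(self, dataset: CPIDataset, pid):
        if pid not in self._words:
            ws = split_ngrams(dataset.proteins[pid], self.config.n, self.vocabulary)
            self._words[pid] = ws.word_ids
        return self._words[pid]

    def _pssm_scaled(self, dataset: CPIDataset, pid):
        if pid not in self._pssm:
            src = dataset.pssms[pid]
            pssm = src if isinstance(src, PSSM) else parse_psiblast_pssm(
                src, dataset.proteins[pid])
            smooth_pssm(pssm, self.config.w)
            self._pssm[pid] = pssm.scaled
        return self._pssm[pid]

    def _energy_reduced(self, dataset: CPIDataset, pid):
        if pid not in self._energy:
            rec: EnergyMatrix = dataset.energies[pid]
            if rec.normalized is None and dataset.wt_ensemble:
                normalize_vs_wildtype(rec, dataset.wt_ensemble)
            self._energy[pid] = self.reducer.transform(rec).reduced
        return self._energy[pid]

    # -- fit / transform ---------------------------------------------------
    def fit(self, dataset: CPIDataset, train_idx) -> "Featurizer":
        cfg = self.config
        T = cfg.toolkits
        train_idx = np.asarray(train_idx)
        cids = {dataset.pairs[i][0] for i in train_idx}
        pids = {dataset.pairs[i][1] for i in train_idx}
        if 2 in T and cfg.mode != "protein_only":
            for cid in sorted(cids, key=str):
                self._graph(dataset, cid)
        if 3 in T and cfg.mode != "compound_only":
            for pid in sorted(pids, key=str):
                self._word_ids(dataset, pid)
        self.fingerprints.frozen = True
        self.vocabulary.frozen = True
        if 1 in T and cfg.mode != "protein_only":
            rows = np.stack([
                self._full_descriptors(dataset, dataset.pairs[i][0]) for i in train_idx])
            labels = dataset.labels[train_idx]
            task = "regression" if cfg.task == "regression" else "classification"
            self.selected = filter_and_select(
                rows, labels, k=cfg.k_descriptors, task=task, random_state=cfg.seed)
            sel = rows[:, self.selected]
            self.desc_mean = sel.mean(axis=0)
            self.desc_std = sel.std(axis=0)
            self.desc_std[self.desc_std == 0] = 1.0
        if 5 in T and cfg.mode != "compound_only":
            if dataset.energies is None:
                raise ValueError("toolkit 5 requires per-protein energy tables")
            records = []
            for pid in sorted(pids, key=str):
                rec = dataset.energies[pid]
                if rec.normalized is None and dataset.wt_ensemble:
                    normalize_vs_wildtype(rec, dataset.wt_ensemble)
                records.append(rec)
            k = min(self.config.k_energy, len(records))
            self.reducer = EnergyReducer(k=k).fit(records)
        return self

    def transform_pair(self, dataset: CPIDataset, i: int) -> PairFeatures:
        cfg = self.config
        T = cfg.toolkits
        cid, pid, _ = dataset.pairs[i]
        feats = PairFeatures(compound_id=cid, protein_id=pid)
        if cfg.mode != "protein_only":
            if 2 in T:
                feats.graph = self._graph(dataset, cid)
            if 1 in T:
                full = self._full_descriptors(dataset, cid)[self.selected]
                feats.descriptors = (full - self.desc_mean) / self.desc_std
        if cfg.mode != "compound_only":
            if 3 in T:
                feats.word_ids = self._word_ids(dataset, pid)
            if 4 in T:
                feats.pssm_scaled = self._pssm_scaled(dataset, pid)
            if 5 in T:
                feats.energy_reduced = self._energy_reduced(dataset, pid)
        return feats

    @property
    def vocab_sizes(self) -> dict:
        return {
            "n_vertex_ids": self.fingerprints.n_vertex_ids,
            "n_edge_ids": self.fingerprints.n_edge_ids,
            "n_words": self.vocabulary.size,
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    rmse: float | None = None
    r_squared: float | None = None
    pearson_r: float | None = None
    r2_undefined: bool = False
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    learning_curve: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rmse", "r_squared", "pearson_r", "r2_undefined",
                 "precision", "recall", "f1", "learning_curve")}


def compute_metrics(pred, truth, task: str = "regression") -> MetricsReport:
    """r.m.s.e., R^2 and Pearson r for regression; macro-averaged
    precision / recall / F1 for classification.

    R^2 = 1 - sum((y_p - y_e)^2) / sum((y_e - mean(y_e))^2); a zero-variance
    truth vector makes R^2 undefined and is flagged rather than reported.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if task == "regression":
        pred = pred.ravel()
        truth = truth.ravel().astype(float)
        if pred.shape != truth.shape:
            raise ValueError("prediction and truth vectors are misaligned")
        if truth.size < 2:
            raise ValueError("need at least 2 points for regression metrics")
        resid = pred - truth
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        ss_tot = float(np.sum((truth - truth.mean()) ** 2))
        if ss_tot == 0.0:
            return MetricsReport(rmse=rmse, r_squared=None, pearson_r=None,
                                 r2_undefined=True)
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        if np.std(pred) == 0.0:
            r = 0.0
        else:
            r = float(stats.pearsonr(pred, truth)[0])
        return MetricsReport(rmse=rmse, r_squared=r2, pearson_r=r)
    if pred.ndim == 2:  # probability rows
        pred = pred.argmax(axis=1)
    pred = pred.ravel().astype(int)
    truth = truth.ravel().astype(int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors are misaligned")
    p, r, f1, _ = precision_recall_fscore_support(
        truth, pred, average="macro", zero_division=0)
    return MetricsReport(precision=float(p), recall=float(r), f1=float(f1))


# ---------------------------------------------------------------------------
# checkpoint
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Single-file archive of everything needed to re-run a trained model."""

    schema_version: int
    config: dict
    vocab_sizes: dict
    featurizer: Featurizer
    state: list
    label_mean: float = 0.0
    label_std: float = 1.0

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "Checkpoint":
        with open(path, "rb") as fh:
            ckpt = pickle.load(fh)
        if ckpt.schema_version != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {ckpt.schema_version}")
        return ckpt

    def build_network(self) -> AldeleNetwork:
        net = AldeleNetwork(ModelConfig.from_dict(self.config), **self.vocab_sizes)
        net.load_state_dict(self.state)
        return net

    def predict_pairs(self, dataset: CPIDataset, indices=None) -> np.ndarray:
        net = self.build_network()
        idx = range(len(dataset)) if indices is None else indices
        preds = []
        for i in idx:
            feats = self.featurizer.transform_pair(dataset, i)
            out = net.predict(feats)
            preds.append(out)
        preds = np.vstack(preds)
        if ModelConfig.from_dict(self.config).task == "regression":
            return preds.ravel() * self.label_std + self.label_mean
        return preds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_batch(net: AldeleNetwork, feats_list):
    from .autograd import concat as t_concat
    outs = [net.forward(f)["prediction"] for f in feats_list]
    if net.config.task == "regression":
        return t_concat(outs, axis=0)
    return t_concat([o.reshape(1, -1) for o in outs], axis=0)


def train_model(
    config: ModelConfig,
    dataset: CPIDataset,
    train_idx=None,
    val_idx=None,
    test_idx=None,
    verbose: bool = False,
) -> tuple[Checkpoint, MetricsReport]:
    """Train one model and return (checkpoint at minimal validation
    r.m.s.e., test metrics with the per-epoch learning curve).

    With no explicit split, pairs are shuffled into 5 folds with the
    config seed; fold 0 is held out and split 50/50 into validation and
    test halves.
    """
    n = len(dataset)
    if train_idx is None:
        folds = kfold_split(n, k=5, seed=config.seed)
        held = np.flatnonzero(folds == 0)
        train_idx = np.flatnonzero(folds != 0)
        val_idx = held[: held.size // 2]
        test_idx = held[held.size // 2 :]
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx) if val_idx is not None else np.array([], dtype=int)
    test_idx = np.asarray(test_idx) if test_idx is not None else np.array([], dtype=int)

    featurizer = Featurizer(config).fit(dataset, train_idx)
    # materialize features up front; missing inputs fail before training
    feats = {int(i): featurizer.transform_pair(dataset, int(i))
             for i in np.concatenate([train_idx, val_idx, test_idx])}

    net = AldeleNetwork(config, **featurizer.vocab_sizes)
    opt = net.make_optimizer()

    y = dataset.labels
    if config.task == "regression":
        mu = float(y[train_idx].mean())
        sd = float(y[train_idx].std()) or 1.0
    else:
        mu, sd = 0.0, 1.0
    y_scaled = (y - mu) / sd if config.task == "regression" else y

    rng = np.random.default_rng(config.seed)
    curve = []
    best_state = net.state_dict()
    best_val = np.inf

    def eval_rmse(idx) -> float:
        preds = np.array([net.predict(feats[int(i)]).ravel()[0] for i in idx]) \
            if config.task == "regression" else None
        if preds is None:
            return np.nan
        return float(np.sqrt(np.mean((preds * sd + mu - y[idx]) ** 2)))

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            preds = _forward_batch(net, [feats[int(i)] for i in batch])
            batch_loss = model_loss(preds, y_scaled[batch], net.params,
                                    config.lambda_l2, task=config.task)
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            batch_loss.backward()
            opt.step()
            epoch_loss += float(batch_loss.data)
            n_batches += 1
        val_rmse = eval_rmse(val_idx) if val_idx.size else np.nan
        curve.append({"epoch": epoch,
                      "train_loss": epoch_loss / max(n_batches, 1),
                      "val_rmse": val_rmse})
        if verbose:
            print(f"epoch {epoch}  train_loss {curve[-1]['train_loss']:.4f}  "
                  f"val_rmse {val_rmse:.4f}")
        if val_idx.size and val_rmse < best_val:
            best_val = val_rmse
            best_state = net.state_dict()
        elif not val_idx.size:
            best_state = net.state_dict()

    net.load_state_dict(best_state)
    ckpt = Checkpoint(
        schema_version=CHECKPOINT_SCHEMA,
        config=config.to_dict(),
        vocab_sizes=featurizer.vocab_sizes,
        featurizer=featurizer,
        state=best_state,
        label_mean=mu,
        label_std=sd,
    )
    if test_idx.size:
        preds = ckpt.predict_pairs(dataset, test_idx)
        report = compute_metrics(preds, y[test_idx], task=config.task)
    else:
        report = MetricsReport()
    report.learning_curve = curve
    return ckpt, report


def cross_validate(config: ModelConfig, dataset: CPIDataset, k: int = 5,
                   seed: int | None = None) -> list[MetricsReport]:
    """Full k-fold cross-validation; each held-out fold is split 50/50
    into validation and test halves.  Returns one report per fold."""
    seed = config.seed if seed is None else seed
    folds = kfold_split(len(dataset), k=k, seed=seed)
    reports = []
    for f in range(k):
        held = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        val_idx = held[: held.size // 2]
        test_idx = held[held.size // 2 :]
        _, rep = train_model(config, dataset, train_idx, val_idx, test_idx)
        reports.append(rep)
    return reports
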