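"""Structure-derived featurization: per-residue weighted energy-term
matrices for protein variants, normalized against a relaxed wild-type
ensemble and reduced to a fixed length by principal component analysis.

A variant structure is summarized as an N x (F+1) table: one integer
amino-acid code column (A=1 ... Y=20, alphabetical) plus F weighted
energy score terms per residue.  Normalization z-scores each (residue,
term) cell against the wild-type ensemble; records of different length
are zero-padded to the dataset maximum before a PCA basis (fit on
training records only) projects each record to a k-dimensional vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .protein import AMINO_ACIDS

__all__ = ["EnergyMatrix", "EnergyReducer", "load_energy_table",
           "normalize_vs_wildtype", "reduce_dims"]

_AA_CODE = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class EnergyMatrix:
    residue_codes: np.ndarray  # N ints in 1..20
    energies: np.ndarray       # N x F
    term_names: list[str]
    normalized: np.ndarray | None = None
    reduced: np.ndarray | None = None

    @property
    def combined(self) -> np.ndarray:
        """The N x (F+1) matrix: codes column followed by the energy block."""
        return np.hstack([self.residue_codes[:, None].astype(float), self.energies])


def load_energy_table(path) -> EnergyMatrix:
    """Read a per-residue energy table (TSV, header row).

    Expected columns: residue index, residue one-letter code, then F named
    energy-term columns.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if len(header) < 3:
        raise ValueError(f"{path}: expected at least 3 columns (index, residue, terms)")
    term_names = header[2:]
    codes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(header):
            raise ValueError(f"{path}: ragged row at line {lineno}")
        aa = cols[1].upper()
        if aa not in _AA_CODE:
            raise ValueError(f"{path}: unknown residue letter {aa!r} at line {lineno}")
        codes.append(_AA_CODE[aa])
        rows.append([float(c) for c in cols[2:]])
    return EnergyMatrix(
        residue_codes=np.asarray(codes, dtype=np.int64),
        energies=np.asarray(rows, dtype=float),
        term_names=term_names,
    )


def normalize_vs_wildtype(variant: EnergyMatrix, wt_ensemble: list[EnergyMatrix]) -> EnergyMatrix:
    """z-score variant energies per (residue, term) cell against the
    wild-type relaxed ensemble; cells with zero ensemble deviation map
    to 0.  Shift-invariant by construction."""
    if len(wt_ensemble) < 2:
        raise ValueError("wild-type ensemble must contain at least 2 members")
    shapes = {m.energies.shape for m in wt_ensemble} | {variant.energies.shape}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between variant and ensemble members: {shapes}")
    stack = np.stack([m.energies for m in wt_ensemble])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (variant.energies - mean) / std
    z[~np.isfinite(z)] = 0.0
    z[std == 0] = 0.0
    variant.normalized = z
    return variant


class EnergyReducer:
    """PCA reduction of variable-length energy records to fixed k-vectors.

    Records are zero-padded to the training set's maximum residue count
    and flattened before fitting; the fitted basis (and padding length)
    is reused verbatim at inference.
    """

    def __init__(self, k: int = 32):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.max_len: int | None = None
        self.n_terms: int | None = None
        self.pca: PCA | None = None

    def _flat(self, record: EnergyMatrix) -> np.ndarray:
        block = record.normalized if record.normalized is not None else record.energies
        n, f = block.shape
        if f != self.n_terms:
            raise ValueError("energy-term count differs from the fitted records")
        padded = np.zeros((self.max_len, self.n_terms))
        padded[: min(n, self.max_len)] = block[: self.max_len]
        return padded.ravel()

    def fit(self, records: list[EnergyMatrix]) -> "EnergyReducer":
        if not records:
            raise ValueError("no records to fit the reduction basis on")
        self.max_len = max(r.energies.shape[0] for r in records)
        self.n_terms = records[0].energies.shape[1]
        X = np.stack([self._flat(r) for r in records])
        max_rank = min(X.shape)
        if self.k > max_rank:
            raise ValueError(f"k={self.k} exceeds available rank {max_rank}")
        self.pca = PCA(n_components=self.k, svd_solver="full", random_state=0)
        self.pca.fit(X)
        return self

    def transform(self, record: EnergyMatrix) -> EnergyMatrix:
        if self.pca is None:
            raise ValueError("reduction basis has not been fitted")
        record.reduced = self.pca.transform(self._flat(record)[None, :])[0]
        return record


def reduce_dims(records: list[EnergyMatrix], k: int, basis: EnergyReducer | None = None
                ) -> tuple[list[EnergyMatrix], EnergyReducer]:
    """Project energy records onto a top-k principal-component basis.

    With ``basis=None`` a new basis is fitted on `records` (training
    mode); otherwise the given fitted basis is applied unchanged.
    """
    if basis is None:
        basis = EnergyReducer(k=k).fit(records)
    return [basis.transform(r) for r in records], basis
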