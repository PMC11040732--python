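"""Readers for the on-disk input formats: pairs tables, FASTA, SMILES
lists and the PSSM / energy manifests."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .structure import load_energy_table

__all__ = ["load_fasta", "load_smiles_file", "load_pairs_table",
           "load_manifest", "assemble_dataset"]


def load_fasta(path) -> dict:
    """Multi-record FASTA (wrapped lines fine) -> {id: sequence}."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def load_smiles_file(path) -> dict:
    """SMILES one per line, optionally followed by an id column."""
    compounds = {}
    for k, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        cols = line.split()
        cid = cols[1] if len(cols) > 1 else f"C{k:04d}"
        compounds[cid] = cols[0]
    if not compounds:
        raise ValueError(f"{path}: no SMILES entries found")
    return compounds


def load_pairs_table(path, smiles_col: str | None = None):
    """TSV/CSV with header: compound_id, protein_id, label (and optionally
    an inline SMILES column).  Returns (pairs, inline_compounds)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"compound_id", "protein_id", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pairs table needs columns {sorted(required)}")
    pairs = list(zip(df["compound_id"], df["protein_id"], df["label"].astype(float)))
    compounds = None
    if smiles_col is not None:
        compounds = dict(zip(df["compound_id"], df[smiles_col]))
    return pairs, compounds


def load_manifest(path) -> dict:
    """Two-column TSV mapping record id -> file path (relative to the
    manifest's directory)."""
    base = Path(path).parent
    mapping = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rid, rel = line.split("\t")[:2]
        mapping[rid] = base / rel
    return mapping


def assemble_dataset(pairs_path, fasta_path, smiles_path=None, smiles_col=None,
                     pssm_manifest=None, energy_manifest=None,
                     wt_dir=None, scheme: str = "percentage"):
    """Build a :class:`aldele.train.CPIDataset` from on-disk inputs."""
    from .train import CPIDataset

    pairs, inline = load_pairs_table(pairs_path, smiles_col)
    proteins = load_fasta(fasta_path)
    if inline is not None:
        compounds = inline
    elif smiles_path is not None:
        compounds = load_smiles_file(smiles_path)
    else:
        raise ValueError("supply either --smiles-col or a SMILES file")
    pssms = {pid: str(p) for pid, p in load_manifest(pssm_manifest).items()} \
        if pssm_manifest else None
    energies = None
    wt_ensemble = None
    if energy_manifest:
        energies = {pid: load_energy_table(p)
                    for pid, p in load_manifest(energy_manifest).items()}
        if wt_dir:
            wt_ensemble = [load_energy_table(p) for p in sorted(Path(wt_dir).glob("*.tsv"))]
    return CPIDataset(pairs=pairs, compounds=compounds, proteins=proteins,
                      scheme=scheme, pssms=pssms, energies=energies,
                      wt_ensemble=wt_ensemble)
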