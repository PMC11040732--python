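"""Self-contained synthetic datasets with planted, recoverable signal.

The generator emulates every input the pipeline consumes — protein
sequences (FASTA), compound SMILES, PSI-BLAST ASCII PSSMs, per-residue
energy tables with a wild-type relaxed ensemble, and a pairs table —
without any external download.  Signal is planted twice over:

* a fixed amino-acid *motif* inserted at a recorded position into a
  "positive" subset of proteins (PSSM columns are boosted and energy
  terms shifted at the same positions);
* a phosphate-like *functional group* appended to a "positive" subset
  of compound scaffolds.

Labels follow the stated effect model
``label = beta0 + beta1 * motif_present * group_present + eps`` with
``eps ~ Normal(0, sigma^2)``, so only pairs where both plants co-occur are
active — mirroring a decoy-substrate contrast where removing the group
abolishes predicted activity.  The seed fully determines every emitted
byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .protein import AMINO_ACIDS, PSIBLAST_ORDER, PSSM
from .structure import EnergyMatrix, _AA_CODE

__all__ = ["SyntheticSpec", "generate", "build_dataset", "make_decoy_sets",
           "write_pssm"]

PHOSPHATE = "OP(=O)(O)O"


@dataclass
class SyntheticSpec:
    n_pairs: int = 200
    n_proteins: int = 20
    n_compounds: int = 20
    seq_length: tuple = (50, 80)
    motif: str = "CWHWKEYR"
    group_smiles: str = PHOSPHATE
    beta0: float = 10.0
    beta1: float = 50.0
    sigma: float = 1.0
    positive_fraction: float = 0.5
    n_energy_terms: int = 6
    wt_ensemble_size: int = 4
    inject_x: bool = False   # sprinkle nonstandard X residues to exercise masking
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seq_length"] = list(self.seq_length)
        return d


def _random_scaffold(rng: np.random.Generator) -> str:
    """Small random alkyl/hydroxyl scaffold, e.g. 'CC(O)CCO'."""
    length = int(rng.integers(3, 8))
    parts = []
    for i in range(length):
        parts.append("C")
        if rng.random() < 0.4 and i < length - 1:
            parts.append("(O)")
    if rng.random() < 0.5:
        parts.append("O")
    return "".join(parts)


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _sample(spec: SyntheticSpec) -> dict:
    """Draw the full synthetic study: records, plants and labels."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seq_length
    n_pos_p = int(round(spec.n_proteins * spec.positive_fraction))
    n_pos_c = int(round(spec.n_compounds * spec.positive_fraction))

    proteins, motif_pos = {}, {}
    for k in range(spec.n_proteins):
        pid = f"P{k:03d}"
        seq = _random_sequence(rng, lo, hi)
        if k < n_pos_p:
            pos = int(rng.integers(0, len(seq) - len(spec.motif) + 1))
            seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif):]
            motif_pos[pid] = pos
        if spec.inject_x:
            j = int(rng.integers(0, len(seq)))
            seq = seq[:j] + "X" + seq[j + 1:]
        proteins[pid] = seq

    compounds, has_group = {}, {}
    for k in range(spec.n_compounds):
        cid = f"C{k:03d}"
        scaffold = _random_scaffold(rng)
        if k < n_pos_c:
            smi = scaffold + spec.group_smiles
        else:
            smi = scaffold
        if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - scaffolds are valid
            smi = "CCO"
        compounds[cid] = smi
        has_group[cid] = k < n_pos_c

    n_combos = spec.n_proteins * spec.n_compounds
    if spec.n_pairs > n_combos:
        raise ValueError("n_pairs exceeds the number of distinct combinations")
    chosen = rng.choice(n_combos, size=spec.n_pairs, replace=False)
    pairs = []
    for flat in chosen:
        pid = f"P{int(flat) // spec.n_compounds:03d}"
        cid = f"C{int(flat) % spec.n_compounds:03d}"
        active = (pid in motif_pos) and has_group[cid]
        eps = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
        label = spec.beta0 + spec.beta1 * float(active) + eps
        pairs.append((cid, pid, float(label)))

    # PSSM-like matrices: Normal(0, 2) background, motif columns boosted
    pssms = {}
    for pid, seq in proteins.items():
        L = len(seq)
        scores = rng.normal(0.0, 2.0, size=(L, 20))
        if pid in motif_pos:
            start = motif_pos[pid]
            for off, aa in enumerate(spec.motif):
                scores[start + off, AMINO_ACIDS.index(aa)] += 8.0
        pssms[pid] = np.round(scores).astype(int)

    # per-residue energy tables + a wild-type relaxed ensemble per protein
    energies, wt_ensembles = {}, {}
    F = spec.n_energy_terms
    for pid, seq in proteins.items():
        L = len(seq)
        base = rng.normal(0.0, 1.0, size=(L, F))
        if pid in motif_pos:
            start = motif_pos[pid]
            base[start : start + len(spec.motif)] += 2.0
        codes = np.array([_AA_CODE.get(aa, 1) for aa in seq])
        term_names = [f"term{t+1}" for t in range(F)]
        energies[pid] = EnergyMatrix(residue_codes=codes, energies=base,
                                     term_names=term_names)
        members = []
        for _ in range(spec.wt_ensemble_size):
            members.append(EnergyMatrix(
                residue_codes=codes.copy(),
                energies=rng.normal(0.0, 1.0, size=(L, F)),
                term_names=term_names))
        wt_ensembles[pid] = members

    return {
        "proteins": proteins, "motif_pos": motif_pos,
        "compounds": compounds, "has_group": has_group,
        "pairs": pairs, "pssms": pssms,
        "energies": energies, "wt_ensembles": wt_ensembles,
    }


def write_pssm(path, sequence: str, scores_alphabetical: np.ndarray) -> None:
    """Write an L x 20 score matrix in the PSI-BLAST `-out_ascii_pssm`
    ASCII dialect (header lines, then position / residue / 20 log-odds)."""
    perm = [AMINO_ACIDS.index(aa) for aa in PSIBLAST_ORDER]
    block = np.asarray(scores_alphabetical)[:, perm]
    lines = ["", "Last position-specific scoring matrix computed, weighted observed percentages rounded down"]
    lines.append("            " + "  ".join(PSIBLAST_ORDER))
    for i, aa in enumerate(sequence):
        vals = " ".join(f"{int(v):3d}" for v in block[i])
        lines.append(f"{i+1:5d} {aa} {vals}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_energy_table(path, record: EnergyMatrix) -> None:
    inv_code = {v: k for k, v in _AA_CODE.items()}
    header = "residue_index\tresidue\t" + "\t".join(record.term_names)
    rows = [header]
    for i, (code, vals) in enumerate(zip(record.residue_codes, record.energies)):
        cells = "\t".join(f"{v:.4f}" for v in vals)
        rows.append(f"{i+1}\t{inv_code[int(code)]}\t{cells}")
    Path(path).write_text("\n".join(rows) + "\n")


def build_dataset(spec: SyntheticSpec, with_pssm: bool = False,
                  with_energy: bool = False):
    """In-memory dataset assembly: returns (CPIDataset, truth dict).

    Energy records are pre-normalized against each protein's own wild-type
    ensemble before entering the dataset.
    """
    from .structure import normalize_vs_wildtype
    from .train import CPIDataset

    data = _sample(spec)
    pssms = None
    if with_pssm:
        pssms = {pid: PSSM(scores=data["pssms"][pid].astype(float), residues=seq)
                 for pid, seq in data["proteins"].items()}
    energies = None
    if with_energy:
        energies = {}
        for pid, rec in data["energies"].items():
            normalize_vs_wildtype(rec, data["wt_ensembles"][pid])
            energies[pid] = rec
    dataset = CPIDataset(
        pairs=data["pairs"],
        compounds=data["compounds"],
        proteins=data["proteins"],
        scheme="percentage",
        pssms=pssms,
        energies=energies,
    )
    truth = {
        "motif": spec.motif,
        "motif_positions": data["motif_pos"],
        "positive_proteins": sorted(data["motif_pos"]),
        "group_compounds": sorted(c for c, g in data["has_group"].items() if g),
        "spec": spec.to_dict(),
    }
    return dataset, truth


def generate(spec: SyntheticSpec, out_dir) -> dict:
    """Write the complete synthetic file set; returns the paths written.

    Layout: ``seqs.fasta``, ``compounds.smi``, ``pairs.tsv``,
    ``pssm/<pid>.pssm``, ``energy/<pid>.tsv``, ``energy/wt/<pid>_<k>.tsv``
    and ``truth.json``.  Same spec + seed -> byte-identical outputs.
    """
    out = Path(out_dir)
    try:
        (out / "pssm").mkdir(parents=True, exist_ok=True)
        (out / "energy" / "wt").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    data = _sample(spec)

    fasta = []
    for pid in sorted(data["proteins"]):
        fasta.append(f">{pid}")
        seq = data["proteins"][pid]
        fasta += [seq[i : i + 60] for i in range(0, len(seq), 60)]
    (out / "seqs.fasta").write_text("\n".join(fasta) + "\n")

    smi_lines = [f"{data['compounds'][cid]}\t{cid}" for cid in sorted(data["compounds"])]
    (out / "compounds.smi").write_text("\n".join(smi_lines) + "\n")

    rows = ["compound_id\tprotein_id\tlabel"]
    rows += [f"{c}\t{p}\t{lab:.6f}" for c, p, lab in data["pairs"]]
    (out / "pairs.tsv").write_text("\n".join(rows) + "\n")

    for pid, seq in sorted(data["proteins"].items()):
        write_pssm(out / "pssm" / f"{pid}.pssm", seq, data["pssms"][pid])
        _write_energy_table(out / "energy" / f"{pid}.tsv", data["energies"][pid])
        for k, member in enumerate(data["wt_ensembles"][pid]):
            _write_energy_table(out / "energy" / "wt" / f"{pid}_{k}.tsv", member)

    truth = {
        "motif": spec.motif,
        "motif_positions": data["motif_pos"],
        "positive_proteins": sorted(data["motif_pos"]),
        "group_compounds": sorted(c for c, g in data["has_group"].items() if g),
        "spec": spec.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"root": out, "truth": truth}


def make_decoy_sets(spec: SyntheticSpec, n_each: int, max_retries: int = 50
                    ) -> tuple[list[str], list[str]]:
    """Paired decoy lists: each "with" entry carries the functional group,
    the matching "without" entry is the same SMILES with the group token
    removed (revalidated by the parser)."""
    if n_each < 1:
        raise ValueError("n_each must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    with_group, without_group = [], []
    for _ in range(n_each):
        for attempt in range(max_retries):
            scaffold = _random_scaffold(rng)
            w = scaffold + spec.group_smiles
            wo = w.replace(spec.group_smiles, "")
            if Chem.MolFromSmiles(w) is not None and Chem.MolFromSmiles(wo) is not None:
                with_group.append(w)
                without_group.append(wo)
                break
        else:
            raise ValueError("could not build a valid decoy pair within the retry budget")
    return with_group, without_group
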