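"""Attention-weight interpretation: hotspot profiles for proteins and
substrate atoms, annotation export, and decoy-substrate contrasts.

Attention scores from a trained checkpoint are mapped back onto residues
(n-gram word scores redistributed uniformly over the n residues each word
covers) or onto atoms (one graph vertex per heavy atom), min-max rescaled
to [0, 1] for reporting.  Positions above a threshold are called *hot
spots* — by convention 0.5 for protein residues and 0.7 for substrate
atom subgroups, with the argmax atom marked as the subgroup peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .train import Checkpoint, CPIDataset

__all__ = ["AttentionProfile", "protein_profile", "compound_profile",
           "export_annotations", "decoy_contrast"]


@dataclass
class AttentionProfile:
    target: str                      # "protein" | "compound"
    positions: np.ndarray            # 1-based residue / atom indices
    labels: list                     # residue letters or atom symbols
    weights: np.ndarray              # rescaled to [0, 1]
    hotspot_class: list              # "peak" | "high" | "background"
    flat: bool = False               # constant raw scores; rescale degenerate
    raw_scores: np.ndarray = field(default=None, repr=False)

    def __len__(self):
        return len(self.positions)


def _rescale(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-12:
        return np.zeros_like(raw), True
    return (raw - lo) / (hi - lo), False


def protein_profile(checkpoint: Checkpoint, dataset: CPIDataset, pair_index: int,
                    threshold: float = 0.5) -> AttentionProfile:
    """Per-residue attention profile for one pair.

    Word-level scores contribute equally to each of the n residues a word
    covers; the per-residue weight is the mean over covering positions.
    A constant raw profile is emitted as all-zero with ``flat=True``
    instead of rescaled noise.
    """
    cfg_mode = checkpoint.config["mode"]
    if cfg_mode == "compound_only":
        raise ValueError("compound_only checkpoints carry no protein attention")
    net = checkpoint.build_network()
    feats = checkpoint.featurizer.transform_pair(dataset, pair_index)
    out = net.forward(feats)
    if "attention_protein" not in out:
        raise ValueError("checkpoint's toolkit set yields no protein attention")
    scores = out["attention_protein"]
    prov = out["protein_provenance"]
    _, pid, _ = dataset.pairs[pair_index]
    seq = dataset.proteins[pid]
    n = checkpoint.config["n"]
    contributions: list[list[float]] = [[] for _ in range(len(seq))]
    for (kind, i), s in zip(prov, scores):
        if kind == "word":
            for j in range(i, min(i + n, len(seq))):
                contributions[j].append(float(s))
        else:  # direct per-residue position (PSSM row)
            contributions[i].append(float(s))
    raw = np.array([np.mean(c) if c else 0.0 for c in contributions])
    weights, flat = _rescale(raw)
    classes = ["background" if flat or w <= threshold else "high" for w in weights]
    return AttentionProfile(
        target="protein",
        positions=np.arange(1, len(seq) + 1),
        labels=list(seq),
        weights=weights,
        hotspot_class=classes,
        flat=flat,
        raw_scores=raw,
    )


def compound_profile(checkpoint: Checkpoint, dataset: CPIDataset, pair_index: int,
                     threshold: float = 0.7) -> AttentionProfile:
    """Per-atom attention profile (SMILES heavy-atom order).

    Classes: the argmax atom is the subgroup ``peak``, atoms above the
    threshold are ``high``, the rest ``background``.
    """
    if checkpoint.config["mode"] == "protein_only":
        raise ValueError("protein_only checkpoints carry no compound attention")
    if 2 not in checkpoint.config["toolkits"]:
        raise ValueError("compound profiles require toolkit 2 (molecular graph)")
    net = checkpoint.build_network()
    feats = checkpoint.featurizer.transform_pair(dataset, pair_index)
    out = net.forward(feats)
    scores = out["attention_compound"]
    prov = out["compound_provenance"]
    atom_scores = np.array([float(s) for (kind, _), s in zip(prov, scores)
                            if kind == "atom"])
    weights, flat = _rescale(atom_scores)
    classes = ["background"] * len(weights)
    if not flat:
        for i, w in enumerate(weights):
            if w > threshold:
                classes[i] = "high"
        classes[int(np.argmax(weights))] = "peak"
    symbols = [t[0] for t in feats.graph.atom_types]
    return AttentionProfile(
        target="compound",
        positions=np.arange(1, len(weights) + 1),
        labels=symbols,
        weights=weights,
        hotspot_class=classes,
        flat=flat,
        raw_scores=atom_scores,
    )


def export_annotations(profile: AttentionProfile, path, pdb_in=None, pdb_out=None,
                       residue_mapping: dict | None = None) -> Path:
    """Write a profile as TSV (position, label, weight, class); optionally
    copy a user PDB with weights*100 in the B-factor column.

    ``residue_mapping`` maps profile positions (1-based) to PDB residue
    numbers when the numbering differs.
    """
    path = Path(path)
    lines = ["position\tlabel\tweight\tclass"]
    for pos, lab, w, cls in zip(profile.positions, profile.labels,
                                profile.weights, profile.hotspot_class):
        lines.append(f"{pos}\t{lab}\t{w:.6f}\t{cls}")
    path.write_text("\n".join(lines) + "\n")
    if pdb_in is not None:
        _write_pdb_bfactors(profile, pdb_in, pdb_out or path.with_suffix(".pdb"),
                            residue_mapping)
    return path


def _write_pdb_bfactors(profile, pdb_in, pdb_out, residue_mapping):
    weight_by_resnum = {}
    if residue_mapping is None:
        residue_mapping = {int(p): int(p) for p in profile.positions}
    for pos, w in zip(profile.positions, profile.weights):
        weight_by_resnum[residue_mapping[int(pos)]] = w
    text = Path(pdb_in).read_text().splitlines()
    pdb_resnums = {
        int(line[22:26]) for line in text if line.startswith(("ATOM", "HETATM"))
    }
    unmapped = pdb_resnums - set(weight_by_resnum)
    if unmapped:
        raise ValueError(
            f"PDB residues {sorted(unmapped)[:5]}... have no profile weight; "
            "supply a residue mapping")
    out_lines = []
    for line in text:
        if line.startswith(("ATOM", "HETATM")):
            resnum = int(line[22:26])
            b = round(weight_by_resnum[resnum] * 100.0, 2)
            line = line[:60] + f"{b:6.2f}" + line[66:]
        out_lines.append(line)
    Path(pdb_out).write_text("\n".join(out_lines) + "\n")


def decoy_contrast(checkpoint: Checkpoint, substrates_with: list[str],
                   substrates_without: list[str], protein_sequence: str,
                   pssm=None, energy=None) -> dict:
    """Predict activity for two substrate lists against one fixed protein
    and test whether the group-containing list scores higher.

    Returns per-list predictions and means, their difference, and a
    one-sided Wilcoxon rank-sum p-value for mean(with) > mean(without).
    """
    if not substrates_with or not substrates_without:
        raise ValueError("both substrate lists must be non-empty")
    from rdkit import Chem
    bad = [s for s in substrates_with + substrates_without
           if Chem.MolFromSmiles(s) is None]
    if bad:
        raise ValueError(f"unparsable SMILES entries: {bad}")
    pid = "_decoy_protein"
    compounds = {f"W{i}": s for i, s in enumerate(substrates_with)}
    compounds.update({f"O{i}": s for i, s in enumerate(substrates_without)})
    pairs = [(cid, pid, 0.0) for cid in compounds]
    ds = CPIDataset(pairs=pairs, compounds=compounds,
                    proteins={pid: protein_sequence}, scheme="percentage",
                    pssms={pid: pssm} if pssm is not None else None,
                    energies={pid: energy} if energy is not None else None)
    preds = checkpoint.predict_pairs(ds).ravel()
    n_w = len(substrates_with)
    pred_with, pred_without = preds[:n_w], preds[n_w:]
    if np.allclose(pred_with, pred_without[: len(pred_with)]) and \
            len(pred_with) == len(pred_without):
        p_value = 1.0
    else:
        p_value = float(stats.mannwhitneyu(
            pred_with, pred_without, alternative="greater")[1])
    return {
        "predictions_with": pred_with,
        "predictions_without": pred_without,
        "mean_with": float(pred_with.mean()),
        "mean_without": float(pred_without.mean()),
        "difference": float(pred_with.mean() - pred_without.mean()),
        "p_value": p_value,
    }
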