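"""Protein sequence featurization: overlapping n-gram words and smoothed,
logistically scaled position-specific scoring matrices (PSSMs).

An amino-acid sequence is tokenized into overlapping n-grams (stride 1),
each mapped to an id in a vocabulary grown on training data and frozen
afterwards; unknown words map to a reserved id.  PSSMs produced by
PSI-BLAST (`-out_ascii_pssm` dialect) are parsed, smoothed by a centered
window-sum of width w (zero padding at the ends), and squashed into (0, 1)
by the standard logistic 1/(1+e^-x) before entering the convolutional
encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "WordSequence",
    "PSSM",
    "NgramVocabulary",
    "split_ngrams",
    "parse_psiblast_pssm",
    "smooth_pssm",
    "scale_logistic",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # canonical alphabetical order
# column order PSI-BLAST prints in ASCII PSSMs
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
NONSTANDARD = set("BZXUO")
UNKNOWN_WORD = 0


@dataclass
class WordSequence:
    sequence: str
    n: int
    word_ids: np.ndarray


class NgramVocabulary:
    """n-gram word vocabulary; id 0 is reserved for unknown words."""

    def __init__(self, n: int = 3):
        self.n = n
        self.words: dict[str, int] = {}
        self.frozen = False

    def word_id(self, word: str) -> int:
        if word in self.words:
            return self.words[word]
        if self.frozen:
            return UNKNOWN_WORD
        idx = len(self.words) + 1
        self.words[word] = idx
        return idx

    @property
    def size(self) -> int:
        return len(self.words) + 1


def split_ngrams(
    sequence: str,
    n: int,
    vocabulary: NgramVocabulary | None = None,
    policy: str = "mask",
) -> WordSequence:
    """Tokenize a sequence into |S|-n+1 overlapping n-gram words.

    Nonstandard residue letters (B, Z, X, U, O) either raise under the
    ``strict`` policy or send every n-gram containing them to the unknown
    id under ``mask`` (the default, since real FASTA files contain X).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sequence = sequence.upper()
    if len(sequence) < n:
        raise ValueError(f"sequence of length {len(sequence)} shorter than n={n}: {sequence!r}")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        illegal = bad - NONSTANDARD
        if illegal:
            raise ValueError(f"illegal residue letters {sorted(illegal)} in sequence")
        if policy == "strict":
            raise ValueError(f"nonstandard residue letters {sorted(bad)} under strict policy")
    if vocabulary is None:
        vocabulary = NgramVocabulary(n=n)
    ids = np.empty(len(sequence) - n + 1, dtype=np.int64)
    for i in range(ids.size):
        word = sequence[i : i + n]
        if set(word) & NONSTANDARD:
            ids[i] = UNKNOWN_WORD
        else:
            ids[i] = vocabulary.word_id(word)
    return WordSequence(sequence=sequence, n=n, word_ids=ids)


@dataclass
class PSSM:
    scores: np.ndarray  # L x 20, alphabetical amino-acid column order
    residues: str
    smoothed: np.ndarray | None = None
    scaled: np.ndarray | None = None
    window: int | None = None


def parse_psiblast_pssm(path, sequence: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM into an L x 20 log-odds matrix.

    Reads the first (log-odds) score block and remaps its columns from
    PSI-BLAST's printing order to canonical alphabetical order.  If
    ``sequence`` is given, the per-row residue letters are cross-checked
    against it.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for idx, line in enumerate(lines):
        cols = line.split()
        if len(cols) >= 20 and all(c in PSIBLAST_ORDER and len(c) == 1 for c in cols[:20]):
            header_idx = idx
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM column-header line found")
    file_order = "".join(lines[header_idx].split()[:20])
    rows, residues = [], []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            break
        cols = line.split()
        if len(cols) < 22 or not cols[0].isdigit():
            raise ValueError(f"{path}: malformed PSSM row at line {lineno}")
        residues.append(cols[1])
        try:
            rows.append([float(c) for c in cols[2:22]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric score at line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: PSSM contains no residue rows")
    raw = np.asarray(rows)
    perm = [file_order.index(aa) for aa in AMINO_ACIDS]
    scores = raw[:, perm]
    res_str = "".join(residues)
    if sequence is not None and res_str != sequence.upper():
        raise ValueError(f"{path}: PSSM residue letters do not match the paired sequence")
    return PSSM(scores=scores, residues=res_str)


def smooth_pssm(pssm: PSSM, w: int = 21) -> PSSM:
    """Window-sum smoothing: row i becomes the sum of rows within the
    centered window of width w, with out-of-range rows treated as zero."""
    if w < 1 or w % 2 == 0:
        raise ValueError("window w must be an odd positive integer")
    half = (w - 1) // 2
    L = pssm.scores.shape[0]
    padded = np.zeros((L + 2 * half, pssm.scores.shape[1]))
    padded[half : half + L] = pssm.scores
    # centered window-sum via sliding view; window row i covers raw rows
    # i-half .. i+half with zeros outside the sequence
    smoothed = np.vstack([padded[i : i + w].sum(axis=0) for i in range(L)])
    pssm.smoothed = smoothed
    pssm.scaled = scale_logistic(smoothed)
    pssm.window = w
    return pssm


def scale_logistic(matrix: np.ndarray) -> np.ndarray:
    """Elementwise standard logistic 1/(1+e^-x); output strictly in (0,1).

    For |x| beyond ~37 the logistic saturates to exactly 0.0/1.0 in double
    precision; outputs are clamped to the nearest representable values
    inside the open interval so the (0,1) contract holds.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite entries in matrix passed to logistic scaling")
    out = 1.0 / (1.0 + np.exp(-matrix))
    return np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
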