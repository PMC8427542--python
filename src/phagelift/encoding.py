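"""Numeric sequence representations: one-hot matrices and k-mer frequencies.

The one-hot convention maps A, C, G, T to the indicator rows
[0,0,0,1], [0,0,1,0], [0,1,0,0], [1,0,0,0] respectively, i.e. column order
(T, G, C, A). Ambiguous IUPAC codes become all-zero rows, so they contribute
nothing to any convolutional kernel response; right-padding to a model input
length likewise uses all-zero rows.
"""

from __future__ import annotations

import numpy as np

from .seqio import NucleotideSequence

# column index of the 1 for each unambiguous base
_BASE_COL = {"T": 0, "G": 1, "C": 2, "A": 3}
_COL_BASE = "TGCA"

# 256-entry byte lookup: base -> one-hot column, 4 for ambiguous/other
_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_COL.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c

# lexicographic digit (A=0 < C=1 < G=2 < T=3) for k-mer indexing
_KMER_DIGIT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _KMER_DIGIT[ord(_b)] = _i
    _KMER_DIGIT[ord(_b.lower())] = _i


def _bases_of(seq: NucleotideSequence | str) -> str:
    return seq.bases if isinstance(seq, NucleotideSequence) else seq


def one_hot_encode(seq: NucleotideSequence | str, target_length: int | None = None) -> np.ndarray:
    """Encode a sequence as an L×4 (or target_length×4) 0/1 float matrix.

    Rows beyond the sequence end (3' zero-padding up to ``target_length``) and
    rows for ambiguous bases are all zero.
    """
    bases = _bases_of(seq)
    L = len(bases)
    if target_length is not None and target_length < L:
        raise ValueError(f"target_length {target_length} < sequence length {L}")
    out_len = L if target_length is None else target_length
    cols = _LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    mat = np.zeros((out_len, 5), dtype=np.float32)
    mat[np.arange(L), cols] = 1.0
    return mat[:, :4]  # 5th column absorbed ambiguous bases


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to 'N'."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an L×4 matrix, got shape {matrix.shape}")
    nonzero = matrix != 0
    counts = nonzero.sum(axis=1)
    if np.any(counts > 1):
        bad = int(np.argmax(counts > 1))
        raise ValueError(f"row {bad} has more than one nonzero entry")
    out = []
    for row, n in zip(nonzero, counts):
        out.append("N" if n == 0 else _COL_BASE[int(np.argmax(row))])
    return "".join(out)


def kmer_frequencies(seq: NucleotideSequence | str, k: int) -> np.ndarray:
    """Frequencies of all 4^k k-mers in lexicographic order (AA..A first).

    Windows containing any ambiguous base are skipped; counts are normalised
    by the number of valid windows. A sequence with no valid window yields the
    all-zero vector.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    bases = _bases_of(seq)
    n_bins = 4**k
    digits = _KMER_DIGIT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    L = len(digits)
    if L < k:
        return np.zeros(n_bins, dtype=np.float64)
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(n_bins, dtype=np.float64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return counts / counts.sum()
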