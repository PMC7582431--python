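"""k-mer composition vectors and the entropy density profile (EDP).

A sequence of length m yields m-k+1 overlapping k-mers (step 1).  The k-mer
frequency vector has 4^k components in lexicographic order (A < C < G < U)
and sums to 1.  The EDP transform re-expresses a frequency vector f as

    S_i = -(1/H) f_i log f_i,   H = -sum_i f_i log f_i,

the per-symbol share of the Shannon entropy; components sum to 1.  Natural
logarithms are used throughout (the base cancels in the ratio).  For k = 8
the raw vector has 65,536 components and is stored sparsely: a transcript of
a few kb touches at most m-7 of them.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import DegenerateInputError
from .seq_io import NucleotideSequence, RNA_ALPHABET

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_CODE_TABLE = np.full(128, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE_TABLE[ord(_b)] = _i


def encode_residues(residues: str) -> np.ndarray:
    """Residues as integer codes A=0, C=1, G=2, U=3."""
    codes = _CODE_TABLE[np.frombuffer(residues.encode(), dtype=np.uint8)]
    if codes.min(initial=0) < 0:
        raise ValueError("sequence contains non-ACGU symbols")
    return codes


def kmer_index(word: str) -> int:
    """Lexicographic index of a k-mer (A<C<G<U), base-4 positional code."""
    idx = 0
    for c in word:
        idx = idx * 4 + _BASE_INDEX[c]
    return idx


def kmer_word(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(RNA_ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return [kmer_word(i, k) for i in range(4 ** k)]


def _window_codes(codes: np.ndarray, k: int, step: int = 1) -> np.ndarray:
    """Base-4 codes of all k-windows at the given step."""
    m = codes.size
    if m < k:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(m - k + 1, dtype=np.int64)
    for i in range(k):
        vals = vals * 4 + codes[i:m - k + 1 + i]
    return vals[::step]


def kmer_counts(seq: NucleotideSequence | str, k: int, step: int = 1) -> np.ndarray:
    """Integer count of each of the 4^k words (dense array of length 4^k)."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    vals = _window_codes(encode_residues(residues), k, step)
    return np.bincount(vals, minlength=4 ** k)


def kmer_frequencies(seq: NucleotideSequence | str, k: int) -> np.ndarray:
    """Sliding-window k-mer frequencies; all-zero (with a warning) if m < k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if len(residues) < k:
        warnings.warn(
            f"sequence shorter than k={k}; returning an all-zero vector",
            stacklevel=2,
        )
        return np.zeros(4 ** k)
    counts = kmer_counts(residues, k)
    return counts / counts.sum()


def kmer_count_matrix(
    seqs: Sequence[NucleotideSequence], k: int = 8
) -> sparse.csr_matrix:
    """Sparse n x 4^k matrix of raw k-mer occurrence counts.

    This is the raw 8-mer block (fea.Tuple) at the default k; binomial
    feature selection operates on these counts directly.
    """
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for s in seqs:
        vals = _window_codes(encode_residues(s.residues), k)
        idx, cnt = np.unique(vals, return_counts=True)
        indices.append(idx)
        data.append(cnt)
        indptr.append(indptr[-1] + idx.size)
    return sparse.csr_matrix(
        (
            np.concatenate(data) if data else np.empty(0),
            np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
            np.array(indptr),
        ),
        shape=(len(seqs), 4 ** k),
    )


def edp_from_frequencies(freq: np.ndarray) -> np.ndarray:
    """Entropy density profile of a frequency vector (0 log 0 := 0).

    Degenerate input (fewer than two nonzero components, H = 0) falls back
    to the uniform vector with a warning.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    nz = f > 0
    if nz.sum() < 2:
        warnings.warn(
            "entropy is zero (single-symbol distribution); returning the "
            "uniform profile",
            stacklevel=2,
        )
        return np.full(f.size, 1.0 / f.size)
    plogp = np.zeros_like(f)
    plogp[nz] = f[nz] * np.log(f[nz])
    h = -plogp.sum()
    return -plogp / h


def edp_2mer(seq: NucleotideSequence | str) -> np.ndarray:
    """16-component EDP of the dinucleotide composition."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if len(residues) < 2:
        raise DegenerateInputError("EDP of 2-mers needs length >= 2")
    return edp_from_frequencies(kmer_frequencies(residues, 2))
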