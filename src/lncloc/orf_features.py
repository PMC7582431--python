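"""ORF detection and the coding-potential feature family.

Covers the longest open reading frame (forward strand, three frames, AUG to
the first in-frame stop, stop codon included in the length), its coverage,
the amino-acid entropy density profile of the ORF, hexamer usage bias
(in-frame log-likelihood ratio against a class background), whole-sequence
hexamer log-distances to the cytoplasm and nucleus reference profiles,
UTR coverage/GC statistics, and the 8-component Fickett position/composition
vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .errors import DegenerateInputError
from .kmer_features import edp_from_frequencies, kmer_counts
from .seq_io import LabeledDataset, NucleotideSequence, RNA_ALPHABET

START_CODON = "AUG"
STOP_CODONS = ("UAG", "UAA", "UGA")
#: Amino-acid order of the 20-component ORF EDP.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
N_HEXAMERS = 4096
#: Additive per-cell pseudocount (total pseudomass 1 over the 4096 cells),
#: giving a scale-free frequency floor of about 1/(4096 * total).
HEX_PSEUDOCOUNT = 1.0 / N_HEXAMERS


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest forward-frame ORF; ``end`` is exclusive and past the stop."""

    start: int = 0
    end: int = 0
    found: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def find_longest_orf(seq: NucleotideSequence) -> OrfAnnotation:
    """Longest AUG..stop span over the three forward frames.

    The stop codon is included in the length; ties go to the smallest start.
    """
    s = seq.residues
    m = len(s)
    best_len, best_start, best_end = 0, -1, -1
    for frame in range(3):
        augs = []
        stops = []
        for pos in range(frame, m - 2, 3):
            codon = s[pos:pos + 3]
            if codon == START_CODON:
                augs.append(pos)
            elif codon in STOP_CODONS:
                stops.append(pos)
        if not augs or not stops:
            continue
        stops_arr = np.array(stops)
        for aug in augs:
            j = np.searchsorted(stops_arr, aug + 1)
            if j == len(stops_arr):
                continue
            end = int(stops_arr[j]) + 3
            length = end - aug
            if length > best_len or (length == best_len and aug < best_start):
                best_len, best_start, best_end = length, aug, end
    if best_len == 0:
        return OrfAnnotation()
    return OrfAnnotation(best_start, best_end, True)


def orf_coverage(seq: NucleotideSequence, orf: OrfAnnotation) -> float:
    """ORF length over sequence length; 0 when no ORF was found."""
    if not orf.found:
        return 0.0
    return orf.length / seq.length


def edp_orf(seq: NucleotideSequence, orf: OrfAnnotation) -> np.ndarray:
    """20-component amino-acid EDP of the translated ORF (stop excluded).

    Without a complete ORF of at least two sense codons the vector is zero.
    """
    if not orf.found or orf.length < 6:
        return np.zeros(20)
    coding = seq.residues[orf.start:orf.end - 3]
    aa = str(Seq(coding).translate())
    counts = np.zeros(20)
    for a in aa:
        counts[_AA_INDEX[a]] += 1
    return edp_from_frequencies(counts / counts.sum())


def _inframe_hexamer_counts(s: str, start: int, end: int) -> np.ndarray:
    """Counts of step-3 hexamer windows over the coding part of an ORF.

    Windows start at the ORF start and stay inside [start, end-3): the stop
    codon does not contribute hexamers.
    """
    region = s[start:end - 3]
    if len(region) < 6:
        return np.zeros(N_HEXAMERS, dtype=np.int64)
    return kmer_counts(region, 6, step=3)


def _normalize(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return (counts + HEX_PSEUDOCOUNT) / (total + 1.0)


@dataclass
class HexamerTable:
    """Per-class hexamer frequency references fitted on training data.

    ``inframe_freq``: in-frame (step 3 from the ORF start) frequencies per
    class; ``background_freq``: the same quantity pooled over all *other*
    classes; ``seq_freq``: step-1 whole-sequence hexamer frequencies per
    class, used by the log-distance features.  All tables carry the additive
    pseudocount, so every entry is strictly positive.
    """

    classes: tuple[str, ...]
    inframe_freq: dict[str, np.ndarray]
    background_freq: dict[str, np.ndarray]
    seq_freq: dict[str, np.ndarray]


def build_hexamer_tables(train: LabeledDataset) -> HexamerTable:
    """Fit in-frame, background, and whole-sequence hexamer tables.

    A class without any complete ORF falls back to a uniform in-frame table
    (with a warning) so that downstream log ratios stay defined.
    """
    classes = tuple(sorted(set(train.labels.values())))
    inframe: dict[str, np.ndarray] = {c: np.zeros(N_HEXAMERS, dtype=np.int64) for c in classes}
    seqlevel: dict[str, np.ndarray] = {c: np.zeros(N_HEXAMERS, dtype=np.int64) for c in classes}
    for s in train.sequences:
        cls = train.labels[s.id]
        if s.length >= 6:
            seqlevel[cls] += kmer_counts(s.residues, 6)
        orf = find_longest_orf(s)
        if orf.found:
            inframe[cls] += _inframe_hexamer_counts(s.residues, orf.start, orf.end)
    inframe_freq, background_freq, seq_freq = {}, {}, {}
    for c in classes:
        if inframe[c].sum() == 0:
            warnings.warn(
                f"class {c!r} has no in-frame hexamers; using a uniform table",
                stacklevel=2,
            )
            inframe_freq[c] = np.full(N_HEXAMERS, 1.0 / N_HEXAMERS)
        else:
            inframe_freq[c] = _normalize(inframe[c])
        rest = sum(
            (inframe[o] for o in classes if o != c),
            np.zeros(N_HEXAMERS, dtype=np.int64),
        )
        if rest.sum() == 0:
            background_freq[c] = np.full(N_HEXAMERS, 1.0 / N_HEXAMERS)
        else:
            background_freq[c] = _normalize(rest)
        seq_freq[c] = _normalize(seqlevel[c])
    return HexamerTable(classes, inframe_freq, background_freq, seq_freq)


def hexamer_bias(
    seq: NucleotideSequence,
    orf: OrfAnnotation,
    tables: HexamerTable,
    cls: str,
) -> float:
    """Mean in-frame log-likelihood ratio mu(s) = mean log(F_j / F).

    Averaged over the ORF's in-frame hexamers; 0 when no ORF was found.
    """
    if not orf.found or orf.length < 6:
        return 0.0
    counts = _inframe_hexamer_counts(seq.residues, orf.start, orf.end)
    idx = np.nonzero(counts)[0]
    n = counts[idx].sum()
    if n == 0:
        return 0.0
    ratios = np.log(tables.inframe_freq[cls][idx] / tables.background_freq[cls][idx])
    return float((counts[idx] * ratios).sum() / n)


def hexamer_log_distances(
    seq: NucleotideSequence,
    tables: HexamerTable,
    cyto: str = "cytoplasm",
    nuc: str = "nucleus",
) -> tuple[float, float, float]:
    """(logDistCyto, logDistNuc, RatioDist) of whole-sequence hexamers.

    Step-1 hexamer frequencies of the sequence are compared against the two
    largest class profiles; the sum runs over observed hexamers and is
    normalized by the total number of hexamer windows.  A zero nucleus
    distance makes the ratio 1 (with a warning).
    """
    if seq.length < 6:
        raise DegenerateInputError("hexamer log-distances need length >= 6")
    counts = kmer_counts(seq.residues, 6)
    n = seq.length - 5
    freq_seq = (counts + HEX_PSEUDOCOUNT) / (n + 1.0)
    idx = np.nonzero(counts)[0]
    d_cyto = float(np.log(freq_seq[idx] / tables.seq_freq[cyto][idx]).sum() / n)
    d_nuc = float(np.log(freq_seq[idx] / tables.seq_freq[nuc][idx]).sum() / n)
    if d_nuc == 0.0:
        if d_cyto != 0.0:
            warnings.warn("zero nucleus log-distance; ratio set to 1", stacklevel=2)
        ratio = 1.0
    else:
        ratio = d_cyto / d_nuc
    return d_cyto, d_nuc, ratio


def _gc_fraction(region: str) -> float:
    if not region:
        return 0.0
    return (region.count("G") + region.count("C")) / len(region)


def utr_features(
    seq: NucleotideSequence, orf: OrfAnnotation
) -> tuple[float, float, float, float, float]:
    """(cov5, cov3, gc5, gc3, gcNonOrf) of the regions flanking the ORF.

    All five are 0 when no ORF was found; an empty region has GC 0.
    """
    if not orf.found:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    s = seq.residues
    utr5 = s[: orf.start]
    utr3 = s[orf.end:]
    m = seq.length
    return (
        len(utr5) / m,
        len(utr3) / m,
        _gc_fraction(utr5),
        _gc_fraction(utr3),
        _gc_fraction(utr5 + utr3),
    )


def fickett_vector(seq: NucleotideSequence) -> np.ndarray:
    """Fickett position values and composition percentages (8 components).

    For each base B, B1/B2/B3 count occurrences in the three codon phases
    over the whole sequence and B_pos = MAX(B1,B2,B3)/(MIN(B1,B2,B3)+1);
    composition is 100 * count(B)/m.  Order: Apos, Cpos, Gpos, Upos,
    A%, C%, G%, U%.
    """
    if seq.length < 3:
        raise DegenerateInputError("Fickett features need length >= 3")
    s = seq.residues
    out = np.empty(8)
    for bi, base in enumerate(RNA_ALPHABET):
        phase = [s[off::3].count(base) for off in range(3)]
        out[bi] = max(phase) / (min(phase) + 1)
        out[4 + bi] = 100.0 * s.count(base) / len(s)
    return out
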