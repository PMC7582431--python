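"""Secondary-structure prediction, SSE annotation, and derived sequences.

Structures are pseudoknot-free dot-bracket strings.  Two folding engines are
provided: ``external_mfe`` shells out to ViennaRNA's ``RNAfold`` (true
minimum-free-energy folding), and ``nussinov`` is a built-in base-pair
maximization (Watson-Crick + GU wobble, minimum hairpin loop 3) whose
pseudo-MFE is -1.0 per pair.  The Nussinov engine exists so the pipeline is
deterministic and dependency-free; its traceback breaks ties toward the
smaller 5' index.

Every position of a structure gets a secondary-structure-element (SSE)
label: paired positions are stems ``s``; an unpaired run directly enclosed
by its own pair is a hairpin loop ``h``; a run interrupting a helix on one
side only is a bulge ``b``; all remaining unpaired runs (interior loops,
multiloops, exterior regions) are loops ``l``.  These rules are frozen as
the package's definition.

From sequence + structure six derived sequences are built (SSE full,
SSE abbreviated, paired/unpaired, acguD, acguS, acgu-ACGU), and per-class
k-mer profiles of the derived sequences yield log-distance features in the
same form as the hexamer log-distances.
"""

from __future__ import annotations

import re
import subprocess
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit

from .errors import (
    DegenerateInputError,
    EngineUnavailableError,
    NotFittedError,
    StructureParseError,
)
from .kmer_features import encode_residues
from .seq_io import NucleotideSequence

#: Derived-sequence types and their alphabet sizes (for pseudocounting).
DERIVED_TYPES = {
    "sse_full": 4,
    "sse_abbr": 4,
    "paired_unpaired": 2,
    "acguD": 5,
    "acguS": 5,
    "acgu_ACGU": 8,
}

_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):  # AU, CG, GU
    _CAN_PAIR[_a, _b] = True


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket string plus (pseudo-)minimum free energy in kcal/mol."""

    dotbracket: str
    mfe: float
    engine: str = "nussinov"

    def __post_init__(self) -> None:
        parse_pairs(self.dotbracket)  # validates balance and symbols

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    def pairs(self) -> np.ndarray:
        return parse_pairs(self.dotbracket)


def parse_pairs(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired); rejects pseudoknots."""
    bad = set(dotbracket) - set("().")
    if bad:
        raise StructureParseError(
            f"unsupported structure symbols {sorted(bad)} (pseudoknots are rejected)"
        )
    partner = np.full(len(dotbracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureParseError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise StructureParseError(f"unclosed '(' at position {stack[-1]}")
    return partner


@njit(cache=True)
def _nussinov_fill(codes, can_pair, min_loop):  # pragma: no cover - numba
    n = codes.size
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for l in range(i + min_loop + 1, j + 1):
                if can_pair[codes[i], codes[l]]:
                    cand = 1 + dp[i + 1, l - 1]
                    if l < j:
                        cand += dp[l + 1, j]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def _nussinov_traceback(codes: np.ndarray, dp: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.size
    partner = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i, j] == dp[i + 1, j]:  # ties resolved toward i unpaired
            stack.append((i + 1, j))
            continue
        for l in range(i + min_loop + 1, j + 1):
            if not _CAN_PAIR[codes[i], codes[l]]:
                continue
            cand = 1 + dp[i + 1, l - 1] + (dp[l + 1, j] if l < j else 0)
            if cand == dp[i, j]:  # smallest valid 5'-most partner wins
                partner[i], partner[l] = l, i
                stack.append((i + 1, l - 1))
                if l < j:
                    stack.append((l + 1, j))
                break
    return partner


def fold_nussinov(seq: NucleotideSequence | str, min_loop: int = 3) -> SecondaryStructure:
    """Base-pair maximization fallback folder (pseudo-MFE = -1 per pair)."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    codes = encode_residues(residues)
    if codes.size <= min_loop + 1:
        return SecondaryStructure("." * codes.size, 0.0, "nussinov")
    dp = _nussinov_fill(codes, _CAN_PAIR, min_loop)
    partner = _nussinov_traceback(codes, dp, min_loop)
    db = "".join(
        "(" if (p > i) else (")" if p >= 0 else ".")
        for i, p in enumerate(partner)
    )
    n_pairs = int((partner >= 0).sum()) // 2
    return SecondaryStructure(db, -1.0 * n_pairs, "nussinov")


_RNAFOLD_ENERGY = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def fold_external(seq: NucleotideSequence | str) -> SecondaryStructure:
    """Fold with ViennaRNA's ``RNAfold`` and parse its dot-bracket output."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=residues + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        raise EngineUnavailableError(
            "RNAfold is not available or failed; use engine='nussinov' as a fallback"
        ) from exc
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise StructureParseError(f"unexpected RNAfold output: {proc.stdout!r}")
    struct_line = lines[1]
    db = struct_line.split(None, 1)[0]
    match = _RNAFOLD_ENERGY.search(struct_line)
    if match is None or len(db) != len(residues):
        raise StructureParseError(f"cannot parse RNAfold line: {struct_line!r}")
    return SecondaryStructure(db, float(match.group(1)), "external_mfe")


def fold(
    seq: NucleotideSequence | str,
    engine: str = "nussinov",
    fold_window: int | None = None,
) -> SecondaryStructure:
    """Predict a secondary structure with the chosen engine.

    ``fold_window`` caps the folded span to the 5'-most window of that many
    nucleotides (the remainder is reported unpaired); folding cost grows
    cubically with length, and the cap keeps multi-kilobase transcripts
    tractable.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    tail = ""
    if fold_window is not None and len(residues) > fold_window:
        tail = "." * (len(residues) - fold_window)
        residues = residues[:fold_window]
    if engine == "nussinov":
        ss = fold_nussinov(residues)
    elif engine == "external_mfe":
        ss = fold_external(residues)
    else:
        raise ValueError(f"unknown folding engine {engine!r}")
    if tail:
        ss = SecondaryStructure(ss.dotbracket + tail, ss.mfe, ss.engine)
    return ss


def annotate_sse(ss: SecondaryStructure | str) -> str:
    """Per-position SSE labels: stem ``s``, bulge ``b``, loop ``l``, hairpin ``h``."""
    db = ss.dotbracket if isinstance(ss, SecondaryStructure) else ss
    partner = parse_pairs(db)
    n = len(db)
    labels = ["s" if partner[i] >= 0 else "?" for i in range(n)]
    i = 0
    while i < n:
        if partner[i] >= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and partner[j + 1] < 0:
            j += 1
        left, right = i - 1, j + 1
        if left >= 0 and right < n:
            if partner[left] == right:
                lab = "h"
            elif partner[left] == partner[right] + 1:
                lab = "b"  # helix interrupted on this side only
            else:
                lab = "l"
        else:
            lab = "l"  # exterior region
        for pos in range(i, j + 1):
            labels[pos] = lab
        i = j + 1
    return "".join(labels)


@dataclass(frozen=True)
class DerivedSequences:
    """The six structure-derived sequences of one transcript."""

    sse_full: str
    sse_abbr: str
    paired_unpaired: str
    acguD: str
    acguS: str
    acgu_ACGU: str

    def get(self, kind: str) -> str:
        return getattr(self, kind)


def derive_sequences(
    seq: NucleotideSequence | str,
    ss: SecondaryStructure | str,
    sse: str | None = None,
) -> DerivedSequences:
    """Per-position mappings of (sequence, structure) onto derived strings.

    paired/unpaired: '.'->U, bracket->P; acguD: unpaired->'D'; acguS:
    paired->'D'; acgu-ACGU: paired->uppercase, unpaired->lowercase;
    SSE full: the SSE label; SSE abbreviated: runs of equal labels collapsed.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    db = ss.dotbracket if isinstance(ss, SecondaryStructure) else ss
    if len(residues) != len(db):
        raise ValueError(
            f"sequence length {len(residues)} != structure length {len(db)}"
        )
    if sse is None:
        sse = annotate_sse(db)
    if len(sse) != len(db):
        raise ValueError("SSE annotation length mismatch")
    unpaired = [c == "." for c in db]
    pu = "".join("U" if u else "P" for u in unpaired)
    acgud = "".join("D" if u else r for u, r in zip(unpaired, residues))
    acgus = "".join(r if u else "D" for u, r in zip(unpaired, residues))
    acgu_acgu = "".join(
        r.lower() if u else r.upper() for u, r in zip(unpaired, residues)
    )
    abbr = "".join(c for i, c in enumerate(sse) if i == 0 or sse[i - 1] != c)
    return DerivedSequences(sse, abbr, pu, acgud, acgus, acgu_acgu)


def _string_kmer_counts(s: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


@dataclass
class StructureProfiles:
    """Per-class k-mer frequency profiles of the derived sequences.

    Fitted on training data only.  ``logdist(derived, kind, k, cls)``
    computes the mean log ratio of the sequence's derived k-mer frequencies
    to the class profile, in the same form as the hexamer log-distances but
    over the derived alphabet.
    """

    ks: tuple[int, ...] = (1, 4)
    kinds: tuple[str, ...] = tuple(DERIVED_TYPES)
    _tables: dict = field(default_factory=dict, repr=False)
    _totals: dict = field(default_factory=dict, repr=False)
    classes: tuple[str, ...] = ()

    @property
    def fitted(self) -> bool:
        return bool(self._tables)

    def fit(
        self,
        derived_by_id: Mapping[str, DerivedSequences],
        labels: Mapping[str, str],
    ) -> "StructureProfiles":
        self.classes = tuple(sorted(set(labels.values())))
        self._tables = {}
        self._totals = {}
        for cls in self.classes:
            ids = [i for i, c in labels.items() if c == cls]
            for kind in self.kinds:
                for k in self.ks:
                    counts: dict[str, int] = {}
                    total = 0
                    for sid in ids:
                        for w, c in _string_kmer_counts(
                            derived_by_id[sid].get(kind), k
                        ).items():
                            counts[w] = counts.get(w, 0) + c
                            total += c
                    self._tables[(kind, k, cls)] = counts
                    self._totals[(kind, k, cls)] = total
        return self

    def _class_freq(self, kind: str, k: int, cls: str, word: str) -> float:
        v = DERIVED_TYPES[kind] ** k
        # A class absent from training falls back to a uniform profile.
        counts = self._tables.get((kind, k, cls), {})
        total = self._totals.get((kind, k, cls), 0)
        return (counts.get(word, 0) + 1.0 / v) / (total + 1.0)

    def logdist(self, derived: str, kind: str, k: int, cls: str) -> float:
        if not self.fitted:
            raise NotFittedError("structure profiles are not fitted")
        n = len(derived) - k + 1
        if n < 1:
            raise DegenerateInputError(f"derived sequence shorter than k={k}")
        v = DERIVED_TYPES[kind] ** k
        acc = 0.0
        for w, c in _string_kmer_counts(derived, k).items():
            fs = (c + 1.0 / v) / (n + 1.0)
            acc += np.log(fs / self._class_freq(kind, k, cls, w))
        return acc / n

    def logdist_triple(
        self,
        derived: str,
        kind: str,
        k: int,
        cyto: str = "cytoplasm",
        nuc: str = "nucleus",
    ) -> tuple[float, float, float]:
        d_c = self.logdist(derived, kind, k, cyto)
        d_n = self.logdist(derived, kind, k, nuc)
        if d_n == 0.0:
            if d_c != 0.0:
                warnings.warn(
                    "zero nucleus structure log-distance; ratio set to 1",
                    stacklevel=2,
                )
            ratio = 1.0
        else:
            ratio = d_c / d_n
        return d_c, d_n, ratio


def structure_feature_vector(
    derived: DerivedSequences,
    profiles: StructureProfiles,
    mfe: float,
    length: int,
    kinds: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Six log-distance values per derived-sequence type plus MFE features.

    For each type: (logDistCyto, logDistNuc, RatioDist) at each fitted k
    (default k = 1 and 4), followed by the raw MFE and MFE per nucleotide.
    """
    if not profiles.fitted:
        raise NotFittedError("structure profiles are not fitted")
    kinds = kinds or profiles.kinds
    out: list[float] = []
    for kind in kinds:
        for k in profiles.ks:
            out.extend(profiles.logdist_triple(derived.get(kind), kind, k))
    out.extend([mfe, mfe / length])
    return np.array(out)
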