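"""Global pairwise amino-acid alignment scores and the clonotype distance.

The clonotype-defining distance between two CDR3 sequences is

    d(a, b) = min(S(a, a), S(b, b)) - S(a, b)

where S is the optimal end-to-end (global) alignment score under a
substitution matrix (BLOSUM62 by default) with affine gap costs: a gap of
length L costs ``gap_open + gap_extend * L``.  This makes d(a, a) = 0,
d symmetric and non-negative, so an integer cutoff in score units is
directly interpretable.

The scoring kernel is a numba-compiled Gotoh dynamic program; the
all-pairs driver prunes pairs whose distance provably exceeds the cutoff
from sequence lengths and self-scores alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_NEG = np.int32(-(10**8))


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for CDR3 alignment distances.

    cutoff is the maximum distance (in score units) at which two CDR3s are
    considered clonally related.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    cutoff: int = 10

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")


@lru_cache(maxsize=None)
def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """20x20 integer substitution matrix over AA_ALPHABET order."""
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix

    alph = ProteinSequence.alphabet
    if name.upper() == "BLOSUM62":
        mat = SubstitutionMatrix.std_protein_matrix()
    else:
        mat = SubstitutionMatrix(alph, alph, name.upper())
    out = np.zeros((20, 20), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = mat.get_score(a, b)
    return out


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices into AA_ALPHABET."""
    if not seq:
        raise ValueError("empty sequence")
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"invalid residue {ch!r} at position {i} in {seq!r}")
        out[i] = idx
    return out


@njit(cache=True)
def _gotoh_score(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Optimal global alignment score; gap of length L costs open + extend*L."""
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = np.full((m + 1,), _NEG, dtype=np.int32)
    X = np.full((m + 1,), _NEG, dtype=np.int32)  # gap in b (vertical)
    Y = np.full((m + 1,), _NEG, dtype=np.int32)  # gap in a (horizontal)
    M[0] = 0
    for j in range(1, m + 1):
        Y[j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        prev_M = M[0]
        prev_X = X[0]
        prev_Y = Y[0]
        M[0] = _NEG
        X[0] = -(gap_open + gap_extend * i)
        Y[0] = _NEG
        for j in range(1, m + 1):
            diag_best = prev_M
            if prev_X > diag_best:
                diag_best = prev_X
            if prev_Y > diag_best:
                diag_best = prev_Y
            prev_M = M[j]
            prev_X = X[j]
            prev_Y = Y[j]
            M[j] = diag_best + sub[a[i - 1], b[j - 1]]
            # X: gap in b, comes from row above (stored prev_* of column j)
            x_open = prev_M - open_cost
            x_ext = prev_X - gap_extend
            x_from_y = prev_Y - open_cost
            best = x_open
            if x_ext > best:
                best = x_ext
            if x_from_y > best:
                best = x_from_y
            X[j] = best
            # Y: gap in a, comes from current row, column j-1
            y_open = M[j - 1] - open_cost
            y_ext = Y[j - 1] - gap_extend
            y_from_x = X[j - 1] - open_cost
            best = y_open
            if y_ext > best:
                best = y_ext
            if y_from_x > best:
                best = y_from_x
            Y[j] = best
    best = M[m]
    if X[m] > best:
        best = X[m]
    if Y[m] > best:
        best = Y[m]
    return best


@njit(cache=True)
def _distance_row(
    i, flat, offsets, lengths, self_scores, sub, gap_open, gap_extend, cutoff
):  # pragma: no cover - jitted
    """Distances of sequence i against all j > i, pruned against cutoff.

    Entries that provably exceed the cutoff are reported as cutoff + 1
    without running the dynamic program: with diagonal-dominant matrices a
    cross score can never exceed the smaller self-score minus the minimal
    cost of aligning unequal lengths, so
    d >= min(S_ii, S_jj) - S_shorter + gap_open + gap_extend * |len_i - len_j|.
    """
    n = len(lengths)
    out = np.empty(n - i - 1, dtype=np.int32)
    a = flat[offsets[i] : offsets[i] + lengths[i]]
    for k in range(i + 1, n):
        dlen = lengths[i] - lengths[k]
        if dlen < 0:
            dlen = -dlen
        smin = self_scores[i] if self_scores[i] < self_scores[k] else self_scores[k]
        if dlen > 0:
            sshort = self_scores[i] if lengths[i] < lengths[k] else self_scores[k]
            bound = smin - sshort + gap_open + gap_extend * dlen
            if bound > cutoff:
                out[k - i - 1] = cutoff + 1
                continue
        b = flat[offsets[k] : offsets[k] + lengths[k]]
        s = _gotoh_score(a, b, sub, gap_open, gap_extend)
        out[k - i - 1] = smin - s
    return out


def global_alignment_score(a: str, b: str, params: AlignmentParams | None = None) -> int:
    """Optimal global alignment score of two amino-acid strings."""
    params = params or AlignmentParams()
    sub = substitution_matrix(params.substitution_matrix)
    ea, eb = encode_sequence(a), encode_sequence(b)
    return int(_gotoh_score(ea, eb, sub, params.gap_open, params.gap_extend))


def self_score(a: str, params: AlignmentParams | None = None) -> int:
    """Score of a sequence against itself (sum of diagonal entries)."""
    params = params or AlignmentParams()
    sub = substitution_matrix(params.substitution_matrix)
    ea = encode_sequence(a)
    return int(sub[ea, ea].sum())


def receptor_distance(a: str, b: str, params: AlignmentParams | None = None) -> int:
    """Alignment-score distance d(a,b) = min(S_aa, S_bb) - S_ab."""
    params = params or AlignmentParams()
    return min(self_score(a, params), self_score(b, params)) - global_alignment_score(
        a, b, params
    )


def _pack(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in seqs], dtype=np.int32)
    offsets = np.zeros(len(seqs), dtype=np.int64)
    np.cumsum(lengths[:-1], out=offsets[1:])
    flat = np.empty(int(lengths.sum()), dtype=np.int8)
    for s, off in zip(seqs, offsets):
        flat[off : off + len(s)] = encode_sequence(s)
    return flat, offsets, lengths


def neighbor_pairs(
    seqs: list[str], params: AlignmentParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered pairs (i, j, d) of sequences with distance <= cutoff.

    Verifies that the substitution matrix is diagonally dominant (every
    diagonal entry is a row maximum), which the pruning bound relies on.
    """
    params = params or AlignmentParams()
    sub = substitution_matrix(params.substitution_matrix)
    if np.any(sub.max(axis=1) > np.diag(sub)):
        raise ValueError(
            "substitution matrix is not diagonally dominant; "
            "the pruned all-pairs search would be lossy"
        )
    flat, offsets, lengths = _pack(seqs)
    self_scores = np.array(
        [int(sub[flat[o : o + l], flat[o : o + l]].sum()) for o, l in zip(offsets, lengths)],
        dtype=np.int32,
    )
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    dd: list[np.ndarray] = []
    for i in range(len(seqs) - 1):
        row = _distance_row(
            i, flat, offsets, lengths, self_scores,
            sub, params.gap_open, params.gap_extend, params.cutoff,
        )
        hit = np.where(row <= params.cutoff)[0]
        if hit.size:
            ii.append(np.full(hit.size, i, dtype=np.int64))
            jj.append(hit + i + 1)
            dd.append(row[hit])
    if not ii:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=np.int32)
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(dd)
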