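"""Dynamic-programming pairwise alignment and percent identity.

The engine is a Gotoh affine-gap aligner (global Needleman-Wunsch or local
Smith-Waterman) with a deterministic traceback. Conventions, fixed for
reproducibility:

* a gap of length k costs ``gap_open + k * gap_extend`` (defaults 11 and 1);
* traceback ties are broken diagonal > up (gap in b) > left (gap in a);
* ambiguous residues (X for protein, N and ``-`` for nucleotide) score 0
  against everything and never count as identical;
* percent identity uses core columns by default, i.e. terminal-gap overhangs
  of a global alignment are excluded from the denominator.

The protein substitution matrix is BLOSUM62 (X row/column zeroed); the
nucleotide scoring is match +2 / mismatch -3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .core import (
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    SequenceRecord,
    ambiguous_residues,
)
from .errors import AlignmentError

__all__ = [
    "Scoring",
    "default_scoring",
    "AlignmentResult",
    "align_pair",
    "percent_identity",
    "encode",
]

GAP = "-"
_NEG = -1e30


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties over a fixed alphabet."""

    alphabet: str
    matrix: np.ndarray  # (L, L) float64, symmetric
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        L = len(self.alphabet)
        if self.matrix.shape != (L, L):
            raise AlignmentError("scoring matrix shape does not match alphabet")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be non-negative")


@lru_cache(maxsize=4)
def default_scoring(alphabet: str = PROTEIN_ALPHABET) -> Scoring:
    """The default scoring for an alphabet: BLOSUM62 or +2/-3 nucleotide."""
    if alphabet == PROTEIN_ALPHABET:
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        ambiguous = ambiguous_residues(alphabet)
        L = len(alphabet)
        mat = np.zeros((L, L))
        for i, x in enumerate(alphabet):
            for j, y in enumerate(alphabet):
                if x in ambiguous or y in ambiguous:
                    mat[i, j] = 0.0
                else:
                    mat[i, j] = float(blosum[x][y])
        return Scoring(alphabet, mat)
    if alphabet == NUCLEOTIDE_ALPHABET:
        ambiguous = ambiguous_residues(alphabet)
        L = len(alphabet)
        mat = np.full((L, L), -3.0)
        np.fill_diagonal(mat, 2.0)
        for i, x in enumerate(alphabet):
            for j, y in enumerate(alphabet):
                if x in ambiguous or y in ambiguous:
                    mat[i, j] = 0.0
        return Scoring(alphabet, mat)
    raise AlignmentError(f"no default scoring for alphabet {alphabet!r}")


def encode(residues: str, alphabet: str) -> np.ndarray:
    """Encode residues as int8 indices into ``alphabet``."""
    lookup = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lookup[ord(c)] = i
    codes = lookup[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise AlignmentError("sequence contains residues outside the alphabet")
    return codes


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _score_only(a, b, S, oe, ext, local):  # pragma: no cover - jitted
    """Best alignment score with O(min-row) memory.

    ``oe`` is gap_open + gap_extend (the cost of the first gap residue).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.empty(m + 1)  # current/previous row of the main state
    F = np.empty(m + 1)  # vertical (gap-in-b) state, carried down columns
    H[0] = 0.0
    for j in range(1, m + 1):
        H[j] = 0.0 if local else -(oe + (j - 1) * ext)
        F[j] = _NEG
    best = 0.0 if local else _NEG
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = 0.0 if local else -(oe + (i - 1) * ext)
        e = _NEG  # horizontal (gap-in-a) state, reset per row
        for j in range(1, m + 1):
            e = max(H[j - 1] - oe, e - ext)
            F[j] = max(H[j] - oe, F[j] - ext)
            h = diag + S[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if F[j] > h:
                h = F[j]
            if local and h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            if local and h > best:
                best = h
    if not local:
        best = H[m]
    return best


@njit(cache=True)
def _fill_full(a, b, S, oe, ext, local):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1))
    E = np.empty((n + 1, m + 1))
    F = np.empty((n + 1, m + 1))
    H[0, 0] = 0.0
    E[0, 0] = _NEG
    F[0, 0] = _NEG
    for j in range(1, m + 1):
        E[0, j] = _NEG if local else -(oe + (j - 1) * ext)
        H[0, j] = 0.0 if local else E[0, j]
        F[0, j] = _NEG
    for i in range(1, n + 1):
        F[i, 0] = _NEG if local else -(oe + (i - 1) * ext)
        H[i, 0] = 0.0 if local else F[i, 0]
        E[i, 0] = _NEG
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - oe, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - oe, F[i - 1, j] - ext)
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if local and h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _traceback(a, b, S, H, E, F, oe, ext, local):  # pragma: no cover - jitted
    """Deterministic traceback: diagonal > up (gap in b) > left (gap in a).

    Returns (score, ai, bi, length) where ai/bi hold 0-based residue indices
    per column (-1 for a gap), written back-to-front into fixed buffers.
    """
    n, m = a.shape[0], b.shape[0]
    if local:
        best = 0.0
        bi_, bj_ = 0, 0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if H[i, j] > best:
                    best = H[i, j]
                    bi_, bj_ = i, j
        i, j = bi_, bj_
        score = best
    else:
        i, j = n, m
        score = H[n, m]
    cap = n + m
    ai = np.empty(cap, dtype=np.int64)
    bi = np.empty(cap, dtype=np.int64)
    k = cap
    while i > 0 or j > 0:
        if local and H[i, j] == 0.0:
            break
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
            k -= 1
            ai[k] = i - 1
            bi[k] = j - 1
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == F[i, j]:
            while True:
                opened = F[i, j] == H[i - 1, j] - oe
                k -= 1
                ai[k] = i - 1
                bi[k] = -1
                i -= 1
                if opened:
                    break
        elif j > 0 and H[i, j] == E[i, j]:
            while True:
                opened = E[i, j] == H[i, j - 1] - oe
                k -= 1
                ai[k] = -1
                bi[k] = j - 1
                j -= 1
                if opened:
                    break
        else:
            break
    return score, ai[k:], bi[k:]


@njit(cache=True)
def _all_pairs_scores(cat_a, off_a, cat_b, off_b, S, oe, ext, local):  # pragma: no cover
    """Score every sequence of A against every sequence of B in one call."""
    na = off_a.shape[0] - 1
    nb = off_b.shape[0] - 1
    out = np.empty((na, nb))
    for i in range(na):
        sa = cat_a[off_a[i] : off_a[i + 1]]
        for j in range(nb):
            sb = cat_b[off_b[j] : off_b[j + 1]]
            out[i, j] = _score_only(sa, sb, S, oe, ext, local)
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with identity and coverage bookkeeping.

    ``n_core_columns`` excludes terminal-gap overhangs (relevant for global
    alignments; local alignments have no overhangs by construction).
    Coverage is the fraction of each input sequence lying inside the core
    aligned region.
    """

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_columns: int
    n_core_columns: int
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")
        if not (0 <= self.n_identical <= self.n_core_columns <= self.n_columns):
            raise AlignmentError("inconsistent column counts")


def _core_slice(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Column range excluding terminal gap runs of either sequence."""
    ncol = len(aligned_a)
    start, end = 0, ncol
    while start < ncol and (aligned_a[start] == GAP or aligned_b[start] == GAP):
        start += 1
    while end > start and (aligned_a[end - 1] == GAP or aligned_b[end - 1] == GAP):
        end -= 1
    return start, end


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str = "global",
    scoring: Scoring | None = None,
) -> AlignmentResult:
    """Optimal affine-gap alignment of two records.

    ``mode`` is ``"global"`` or ``"local"``. The two records must share an
    alphabet; the default scoring is chosen from it.
    """
    if mode not in ("global", "local"):
        raise AlignmentError(f"unknown alignment mode {mode!r}")
    if a.alphabet != b.alphabet:
        raise AlignmentError(
            f"alphabet mismatch between {a.id!r} and {b.id!r}"
        )
    if scoring is None:
        scoring = default_scoring(a.alphabet)
    ca = encode(a.residues, scoring.alphabet)
    cb = encode(b.residues, scoring.alphabet)
    oe = scoring.gap_open + scoring.gap_extend
    local = mode == "local"
    H, E, F = _fill_full(ca, cb, scoring.matrix, oe, scoring.gap_extend, local)
    score, ai, bi = _traceback(
        ca, cb, scoring.matrix, H, E, F, oe, scoring.gap_extend, local
    )
    cols_a = "".join(a.residues[i] if i >= 0 else GAP for i in ai)
    cols_b = "".join(b.residues[j] if j >= 0 else GAP for j in bi)
    return _build_result(a, b, cols_a, cols_b, float(score))


def _build_result(
    a: SequenceRecord, b: SequenceRecord, cols_a: str, cols_b: str, score: float
) -> AlignmentResult:
    start, end = _core_slice(cols_a, cols_b)
    ambiguous = ambiguous_residues(a.alphabet)
    n_core = end - start
    ident = 0
    res_a = 0
    res_b = 0
    for x, y in zip(cols_a[start:end], cols_b[start:end]):
        if x != GAP:
            res_a += 1
        if y != GAP:
            res_b += 1
        if x == y and x not in ambiguous and x != GAP:
            ident += 1
    return AlignmentResult(
        aligned_a=cols_a,
        aligned_b=cols_b,
        score=score,
        n_identical=ident,
        n_columns=len(cols_a),
        n_core_columns=n_core,
        coverage_a=res_a / len(a),
        coverage_b=res_b / len(b),
    )


def percent_identity(result: AlignmentResult, convention: str = "core") -> float:
    """Fraction of identical residues under a denominator convention.

    ``core`` divides by columns excluding terminal-gap overhangs (the common
    16S-identity convention); ``all_columns`` divides by every alignment
    column.
    """
    if convention == "core":
        denom = result.n_core_columns
    elif convention == "all_columns":
        denom = result.n_columns
    else:
        raise AlignmentError(f"unknown identity convention {convention!r}")
    if denom == 0:
        raise AlignmentError("zero-length (core) alignment has no identity")
    return result.n_identical / denom
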