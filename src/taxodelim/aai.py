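"""Average amino-acid identity (AAI) from reciprocal best hits.

AAI between two proteomes is the unweighted arithmetic mean of the percent
identities of their reciprocal-best-hit (RBH) protein pairs: a pair (a, b)
is an RBH when b is a's best-scoring local alignment in the other proteome
and vice versa. Weak pairs are filtered after RBH selection (defaults:
identity >= 0.30 and >= 70% coverage of the shorter protein — conventional
orthology filters, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import LabeledMatrix, Proteome
from .errors import AlignmentError, InvariantError
from .pairwise import (
    AlignmentResult,
    Scoring,
    _all_pairs_scores,
    align_pair,
    default_scoring,
    encode,
    percent_identity,
)

__all__ = ["AaiParams", "RbhPair", "AaiResult", "reciprocal_best_hits", "aai", "aai_matrix"]


@dataclass(frozen=True)
class AaiParams:
    """Hit-selection parameters for RBH-AAI."""

    min_identity: float = 0.30
    min_coverage_short: float = 0.70
    mode: str = "local"

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 1:
            raise InvariantError("min_identity must be in [0, 1]")
        if not 0 < self.min_coverage_short <= 1:
            raise InvariantError("min_coverage_short must be in (0, 1]")
        if self.mode not in ("local", "global"):
            raise InvariantError(f"unknown alignment mode {self.mode!r}")


@dataclass(frozen=True)
class RbhPair:
    """A mutual best-scoring protein pair with its identity and coverage."""

    id_a: str
    id_b: str
    identity: float
    coverage_short: float
    score: float


@dataclass(frozen=True)
class AaiResult:
    taxon_a: str
    taxon_b: str
    aai: float
    n_rbh: int
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.aai <= 1:
            raise InvariantError("aai must be in [0, 1]")
        if self.n_rbh > min(self.n_a, self.n_b):
            raise InvariantError("more RBH pairs than proteins in the smaller proteome")


def _encoded(p: Proteome, scoring: Scoring) -> tuple[np.ndarray, np.ndarray]:
    codes = [encode(rec.residues, scoring.alphabet) for rec in p.records]
    offsets = np.zeros(len(codes) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(c) for c in codes])
    return np.concatenate(codes).astype(np.int8), offsets


def _score_table(
    A: Proteome, B: Proteome, params: AaiParams, scoring: Scoring
) -> np.ndarray:
    cat_a, off_a = _encoded(A, scoring)
    cat_b, off_b = _encoded(B, scoring)
    return _all_pairs_scores(
        cat_a,
        off_a,
        cat_b,
        off_b,
        scoring.matrix,
        scoring.gap_open + scoring.gap_extend,
        scoring.gap_extend,
        params.mode == "local",
    )


def _align(A: Proteome, i: int, B: Proteome, j: int, params: AaiParams) -> AlignmentResult:
    return align_pair(A.records[i], B.records[j], mode=params.mode)


def _identity_of(r: AlignmentResult) -> float:
    if r.n_core_columns == 0:
        return 0.0
    return percent_identity(r, "core")


def _best_with_ties(
    scores: np.ndarray, A: Proteome, B: Proteome, params: AaiParams, axis: int
) -> np.ndarray:
    """Best-hit index along ``axis`` with deterministic tie-breaking.

    Ties in best score are broken by higher identity, then lexicographically
    smaller partner id (identities are computed lazily, only on ties).
    """
    n = scores.shape[0] if axis == 1 else scores.shape[1]
    best = np.empty(n, dtype=np.int64)
    for i in range(n):
        row = scores[i, :] if axis == 1 else scores[:, i]
        top = row.max()
        cands = np.flatnonzero(row == top)
        if len(cands) == 1:
            best[i] = cands[0]
            continue
        keyed = []
        for j in cands:
            if axis == 1:
                ident = _identity_of(_align(A, i, B, int(j), params))
                pid = B.records[int(j)].id
            else:
                ident = _identity_of(_align(A, int(j), B, i, params))
                pid = A.records[int(j)].id
            keyed.append((-ident, pid, int(j)))
        best[i] = min(keyed)[2]
    return best


def reciprocal_best_hits(
    A: Proteome, B: Proteome, params: AaiParams | None = None
) -> list[RbhPair]:
    """Mutual best-scoring protein pairs between two proteomes.

    Identity/coverage filters are applied after RBH selection, so a weak
    mutual pair is dropped rather than replaced by the runner-up.
    """
    params = params or AaiParams()
    scoring = default_scoring(A.records[0].alphabet)
    scores = _score_table(A, B, params, scoring)
    best_ab = _best_with_ties(scores, A, B, params, axis=1)
    best_ba = _best_with_ties(scores, A, B, params, axis=0)
    pairs: list[RbhPair] = []
    for i, j in enumerate(best_ab):
        if best_ba[j] != i:
            continue
        if scores[i, j] <= 0 and params.mode == "local":
            continue  # no positive-scoring segment: not a conserved comparison
        result = _align(A, i, B, int(j), params)
        if result.n_core_columns == 0:
            continue
        identity = percent_identity(result, "core")
        cov_short = (
            result.coverage_a if len(A.records[i]) <= len(B.records[int(j)]) else result.coverage_b
        )
        if identity < params.min_identity or cov_short < params.min_coverage_short:
            continue
        pairs.append(
            RbhPair(
                id_a=A.records[i].id,
                id_b=B.records[int(j)].id,
                identity=identity,
                coverage_short=cov_short,
                score=float(scores[i, j]),
            )
        )
    return pairs


def aai(A: Proteome, B: Proteome, params: AaiParams | None = None) -> AaiResult:
    """Unweighted mean RBH identity between two proteomes."""
    pairs = reciprocal_best_hits(A, B, params)
    if not pairs:
        raise AlignmentError(
            f"no conserved comparison between {A.taxon_id!r} and {B.taxon_id!r} "
            "(zero reciprocal best hits survive the filters)"
        )
    return AaiResult(
        taxon_a=A.taxon_id,
        taxon_b=B.taxon_id,
        aai=float(np.mean([p.identity for p in pairs])),
        n_rbh=len(pairs),
        n_a=len(A),
        n_b=len(B),
    )


def aai_matrix(
    proteomes: list[Proteome],
    params: AaiParams | None = None,
    missing: str = "fail",
) -> LabeledMatrix:
    """All-vs-all AAI as a symmetric similarity matrix (fraction scale).

    The diagonal is fixed at 1.0. ``missing`` controls what happens when a
    pair has no conserved comparison: ``"fail"`` (default) raises, ``"nan"``
    records a NaN entry (which downstream delineation treats as failing any
    threshold).
    """
    if len(proteomes) < 2:
        raise InvariantError("need at least two proteomes")
    ids = [p.taxon_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise InvariantError("duplicate taxon ids among proteomes")
    if missing not in ("fail", "nan"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    n = len(proteomes)
    values = np.eye(n)
    # pairs are computed in sorted-id order so input order cannot affect values
    order = sorted(range(n), key=lambda k: ids[k])
    for a_pos, b_pos in combinations(order, 2):
        try:
            res = aai(proteomes[a_pos], proteomes[b_pos], params)
            values[a_pos, b_pos] = values[b_pos, a_pos] = res.aai
        except AlignmentError:
            if missing == "fail":
                raise
            values[a_pos, b_pos] = values[b_pos, a_pos] = np.nan
    return LabeledMatrix(ids, values, kind="similarity", scale="fraction")
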