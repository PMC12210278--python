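"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different from the
package implementation: exhaustive alignment enumeration, a top-down
memoized three-state DP, numerical quadrature of the t density, the
contingency-table ARI formula, mutual-argmax RBH selection, and stepwise
enumeration of all unrooted topologies on a small leaf set.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import integrate

from taxodelim.core import TreeNode


# ---------------------------------------------------------------------------
# Alignment oracles
# ---------------------------------------------------------------------------

def enumerate_alignment_score(
    s1: str, s2: str, S: np.ndarray, index: dict, gap_open: float, gap_extend: float,
    mode: str = "global",
) -> float:
    """True brute force: enumerate every gapped alignment and score gap runs.

    Exponential; only for very short sequences. For local mode, maximizes
    over all substring pairs (including the empty alignment, score 0).
    """

    def score_all(a: str, b: str) -> float:
        best = -math.inf

        def rec(i: int, j: int, score: float, last: str) -> None:
            nonlocal best
            if i == len(a) and j == len(b):
                best = max(best, score)
                return
            if i < len(a) and j < len(b):
                rec(i + 1, j + 1, score + S[index[a[i]], index[b[j]]], "M")
            if i < len(a):
                cost = gap_extend if last == "A" else gap_open + gap_extend
                rec(i + 1, j, score - cost, "A")
            if j < len(b):
                cost = gap_extend if last == "B" else gap_open + gap_extend
                rec(i, j + 1, score - cost, "B")

        rec(0, 0, 0.0, "M")
        return best

    if mode == "global":
        return score_all(s1, s2)
    best = 0.0
    for i1 in range(len(s1) + 1):
        for i2 in range(i1, len(s1) + 1):
            for j1 in range(len(s2) + 1):
                for j2 in range(j1, len(s2) + 1):
                    if i2 == i1 and j2 == j1:
                        continue
                    best = max(best, score_all(s1[i1:i2], s2[j1:j2]))
    return best


def dp_align_score(
    s1: str, s2: str, S: np.ndarray, index: dict, gap_open: float, gap_extend: float,
    mode: str = "global",
) -> float:
    """Top-down memoized three-state affine DP (independent formulation)."""
    oe = gap_open + gap_extend
    n, m = len(s1), len(s2)

    @functools.lru_cache(maxsize=None)
    def best_from(i: int, j: int, last: str) -> float:
        """Best score of aligning the suffixes s1[i:], s2[j:]."""
        if i == n and j == m:
            return 0.0
        out = -math.inf
        if i < n and j < m:
            out = max(out, S[index[s1[i]], index[s2[j]]] + best_from(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if last == "A" else oe
            out = max(out, -cost + best_from(i + 1, j, "A"))
        if j < m:
            cost = gap_extend if last == "B" else oe
            out = max(out, -cost + best_from(i, j + 1, "B"))
        return out

    if mode == "global":
        result = best_from(0, 0, "M")
        best_from.cache_clear()
        return result

    @functools.lru_cache(maxsize=None)
    def local_from(i: int, j: int, last: str) -> float:
        """Best score of an alignment starting exactly at (i, j)."""
        out = 0.0 if last == "M" else -math.inf  # may end here (not inside a gap)
        if i < n and j < m:
            out = max(out, S[index[s1[i]], index[s2[j]]] + local_from(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if last == "A" else oe
            out = max(out, -cost + local_from(i + 1, j, "A"))
        if j < m:
            cost = gap_extend if last == "B" else oe
            out = max(out, -cost + local_from(i, j + 1, "B"))
        return out

    best = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            best = max(best, local_from(i, j, "M"))
    local_from.cache_clear()
    return best


def rbh_oracle(A, B, align, min_identity: float, min_coverage: float):
    """Exhaustive mutual-argmax RBH selection over precomputed alignments.

    ``align(i, j)`` returns (score, identity, coverage_short) for A's i-th
    vs B's j-th protein. Ties broken by (higher identity, lexicographic id).
    """
    na, nb = len(A.records), len(B.records)
    table = {(i, j): align(i, j) for i in range(na) for j in range(nb)}

    def best_j(i: int) -> int:
        return min(
            range(nb),
            key=lambda j: (-table[i, j][0], -table[i, j][1], B.records[j].id),
        )

    def best_i(j: int) -> int:
        return min(
            range(na),
            key=lambda i: (-table[i, j][0], -table[i, j][1], A.records[i].id),
        )

    pairs = set()
    for i in range(na):
        j = best_j(i)
        if best_i(j) != i:
            continue
        score, identity, coverage = table[i, j]
        if score <= 0:
            continue
        if identity < min_identity or coverage < min_coverage:
            continue
        pairs.add((A.records[i].id, B.records[j].id))
    return pairs


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def t_two_sided_p(t: float, df: float) -> float:
    """Two-sided p from numerical quadrature of the t density."""

    def pdf(x: float) -> float:
        logc = (
            math.lgamma((df + 1) / 2)
            - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi)
        )
        return math.exp(logc - ((df + 1) / 2) * math.log1p(x * x / df))

    tail, _err = integrate.quad(pdf, abs(t), math.inf, epsabs=1e-14, epsrel=1e-12)
    return min(1.0, 2.0 * tail)


def ari_oracle(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency-table formula."""
    from collections import Counter

    n = len(labels_a)
    contingency = Counter(zip(labels_a, labels_b))
    a_sizes = Counter(labels_a)
    b_sizes = Counter(labels_b)
    sum_comb = sum(math.comb(c, 2) for c in contingency.values())
    sum_a = sum(math.comb(c, 2) for c in a_sizes.values())
    sum_b = sum(math.comb(c, 2) for c in b_sizes.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


def threshold_scan_oracle(intra, inter, direction: str, resolution: int = 20001):
    """Dense-grid scan for the misclassification-minimizing cutoff count.

    The scan covers the open interval between the pooled extremes — the same
    space the midpoint-of-order-statistics candidates span (a cutoff outside
    it degenerately declares every value one class).
    """
    lo = min(np.min(intra), np.min(inter))
    hi = max(np.max(intra), np.max(inter))
    grid = np.linspace(lo + 1e-9, hi - 1e-9, resolution)
    best = None
    intra = np.asarray(intra)
    inter = np.asarray(inter)
    for c in grid:
        if direction == "similarity":
            miss = int((intra < c).sum() + (inter >= c).sum())
        else:
            miss = int((intra > c).sum() + (inter <= c).sum())
        if best is None or miss < best:
            best = miss
    return best


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def enumerate_topologies(labels: list[str]):
    """All distinct unrooted topologies over the labels by stepwise addition.

    Yields rooted representations (TreeNode roots, trifurcating root) whose
    unrooted shapes enumerate the (2L-5)!! possibilities exactly once.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")

    def clone(node: TreeNode) -> TreeNode:
        new = TreeNode(node.label)
        for c in node.children:
            new.add_child(clone(c))
        return new

    def attachment_points(root: TreeNode) -> list[TreeNode]:
        return [n for n in root.preorder() if n is not root]

    root = TreeNode()
    for lab in labels[:3]:
        root.add_child(TreeNode(label=lab))
    partial = [root]
    for lab in labels[3:]:
        grown = []
        for tree in partial:
            n_points = len(attachment_points(tree))
            for k in range(n_points):
                t = clone(tree)
                target = attachment_points(t)[k]
                parent = target.parent
                new_internal = TreeNode()
                parent.children[parent.children.index(target)] = new_internal
                new_internal.parent = parent
                new_internal.add_child(target)
                target.parent = new_internal
                new_internal.add_child(TreeNode(label=lab))
                grown.append(t)
        partial = grown
    return partial
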