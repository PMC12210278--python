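"""Threshold- and monophyly-driven delineation of taxa into ranked groups.

Given a rooted phylogenomic tree and taxon-by-taxon relatedness matrices
(AAI as similarity, evolutionary distance as distance), a rank is delineated
by a greedy maximal-clade traversal: walking from the root, a clade is
emitted as a group as soon as every intra-clade pair satisfies every
threshold rule (minimum pairwise AAI above the cutoff, maximum pairwise ED
below it) and the clade's root is supported; otherwise the walk descends.
This yields the coarsest partition consistent with the thresholds and
monophyly. Families and genera are delineated hierarchically (genus rules
must be strictly tighter), so the genus partition refines the family
partition by construction.

The module also provides the separation statistics used to justify
thresholds: intra- vs inter-group value samples, Welch's unequal-variance
t-test (with the conventional "< 2.2e-16" reporting floor), and a
misclassification-minimizing threshold derived from the two samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .core import LabeledMatrix, PhyloTree, TreeNode
from .errors import DelineationError, InvariantError

__all__ = [
    "ThresholdRule",
    "TaxonPartition",
    "SeparationReport",
    "WelchResult",
    "P_FLOOR",
    "intra_inter_split",
    "welch_t_test",
    "derive_threshold",
    "delineate_rank",
    "hierarchical_delineate",
    "compare_partitions",
]

#: reporting floor for vanishingly small p-values, as commonly printed by R
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ThresholdRule:
    """One metric's cutoff: intra >= cutoff (similarity) or <= (distance)."""

    metric: str
    direction: str  # "similarity" | "distance"
    cutoff: float

    def __post_init__(self) -> None:
        if self.direction not in ("similarity", "distance"):
            raise InvariantError(f"unknown rule direction {self.direction!r}")

    def intra_ok(self, values: np.ndarray) -> bool:
        """Whether every intra-clade pair value satisfies the rule."""
        if values.size == 0:
            return True
        if np.isnan(values).any():
            return False  # missing relatedness: fail safe toward descending
        if self.direction == "similarity":
            return bool(values.min() >= self.cutoff)
        return bool(values.max() <= self.cutoff)

    def tighter_than(self, other: "ThresholdRule") -> bool:
        if self.direction != other.direction:
            raise InvariantError("cannot compare rules of different directions")
        if self.direction == "similarity":
            return self.cutoff > other.cutoff
        return self.cutoff < other.cutoff


@dataclass
class TaxonPartition:
    """Disjoint grouping of leaves into named groups at one rank."""

    rank: str
    groups: dict[str, frozenset]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for name, members in self.groups.items():
            if not members:
                raise InvariantError(f"group {name!r} is empty")
            if seen & members:
                raise InvariantError(f"group {name!r} overlaps another group")
            seen |= members

    @property
    def leaf_universe(self) -> frozenset:
        return frozenset().union(*self.groups.values()) if self.groups else frozenset()

    def group_of(self) -> dict[str, str]:
        return {leaf: name for name, members in self.groups.items() for leaf in members}

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @classmethod
    def from_mapping(cls, rank: str, mapping: Mapping[str, str]) -> "TaxonPartition":
        groups: dict[str, set] = {}
        for leaf, group in mapping.items():
            groups.setdefault(group, set()).add(leaf)
        return cls(rank, {g: frozenset(m) for g, m in groups.items()})


# ---------------------------------------------------------------------------
# Separation statistics
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    """Intra/inter value samples with per-group summaries."""

    intra: np.ndarray
    inter: np.ndarray
    group_summaries: dict[str, dict]
    all_singletons: bool
    t: float | None = None
    df: float | None = None
    p: float | None = None


def intra_inter_split(matrix: LabeledMatrix, partition: TaxonPartition) -> SeparationReport:
    """Split a matrix's unordered off-diagonal pairs by co-membership.

    Singleton groups contribute no intra pairs; their summaries report
    ``n = 0``. The intra and inter sample sizes always add up to the number
    of unordered pairs over the partition's leaves.
    """
    missing = sorted(partition.leaf_universe - set(matrix.labels))
    if missing:
        raise InvariantError(f"partition labels not in matrix: {missing}")
    membership = partition.group_of()
    labels = sorted(partition.leaf_universe)
    intra: list[float] = []
    inter: list[float] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            v = matrix.value(a, b)
            (intra if membership[a] == membership[b] else inter).append(v)
    summaries: dict[str, dict] = {}
    for name, members in sorted(partition.groups.items()):
        vals = matrix.pairs(sorted(members))
        if vals.size:
            summaries[name] = {
                "n": int(vals.size),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
        else:
            summaries[name] = {"n": 0, "mean": None, "median": None, "min": None, "max": None}
    return SeparationReport(
        intra=np.asarray(intra, dtype=float),
        inter=np.asarray(inter, dtype=float),
        group_summaries=summaries,
        all_singletons=not intra,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float  #: two-sided, floored at P_FLOOR
    floored: bool

    @property
    def p_display(self) -> str:
        return f"< {P_FLOOR:g}" if self.floored else f"{self.p:g}"


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test with the Satterthwaite degrees of freedom.

    p-values below 2.2e-16 are floored there and flagged, mirroring the
    conventional reporting of vanishingly small p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvariantError("Welch test needs at least two values per sample")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) != np.mean(y):
        # zero-variance samples with distinct means: t is infinite
        return WelchResult(t=math.inf, df=float(len(x) + len(y) - 2), p=P_FLOOR, floored=True)
    if np.var(x) == 0 and np.var(y) == 0:
        return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0, floored=False)
    res = stats.ttest_ind(x, y, equal_var=False)
    p_raw = float(res.pvalue)
    floored = p_raw < P_FLOOR
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=max(p_raw, P_FLOOR),
        floored=floored,
    )


def derive_threshold(
    intra: Sequence[float], inter: Sequence[float], direction: str = "similarity"
) -> dict:
    """Data-driven cutoff separating intra- from inter-group values.

    Candidate cutoffs are the midpoints of adjacent pooled order statistics;
    the one minimizing total misclassification wins, ties broken by maximal
    margin to the nearest sample value (then by the smaller cutoff). With
    perfectly separable samples this is the midpoint of the gap.
    """
    if direction not in ("similarity", "distance"):
        raise InvariantError(f"unknown direction {direction!r}")
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise InvariantError("both samples must be non-empty")
    pooled = np.unique(np.concatenate([intra, inter]))
    if pooled.size == 1:
        return {"cutoff": float(pooled[0]), "misclassified": int(min(intra.size, inter.size))}
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    best: tuple | None = None
    for c in candidates:
        if direction == "similarity":
            miss = int((intra < c).sum() + (inter >= c).sum())
        else:
            miss = int((intra > c).sum() + (inter <= c).sum())
        margin = float(np.min(np.abs(pooled - c)))
        key = (miss, -margin, c)
        if best is None or key < best:
            best = key
    assert best is not None
    return {"cutoff": float(best[2]), "misclassified": int(best[0])}


# ---------------------------------------------------------------------------
# Rank delineation
# ---------------------------------------------------------------------------

def _clade_leaves(node: TreeNode) -> list[str]:
    return [n.label for n in node.leaves()]  # type: ignore[misc]


def delineate_rank(
    tree: PhyloTree,
    rules: Sequence[ThresholdRule],
    matrices: Mapping[str, LabeledMatrix],
    support_min: float = 70.0,
    rank: str = "group",
    group_prefix: str = "G",
) -> TaxonPartition:
    """Greedy maximal-clade partition of a rooted tree under threshold rules.

    Walking preorder from the root, a clade is emitted when every rule holds
    for all intra-clade pairs and its root support is at least
    ``support_min`` (the tree root is exempt, and so are leaves, which
    become singleton groups when reached without emission). Every group is a
    clade of the input tree by construction.
    """
    if not rules:
        raise DelineationError("at least one threshold rule is required")
    leaf_set = set(tree.leaf_labels())
    for rule in rules:
        if rule.metric not in matrices:
            raise DelineationError(f"no matrix supplied for metric {rule.metric!r}")
        missing = leaf_set - set(matrices[rule.metric].labels)
        if missing:
            raise DelineationError(
                f"matrix {rule.metric!r} lacks leaves {sorted(missing)}"
            )

    groups: dict[str, frozenset] = {}
    provenance: dict[str, dict] = {}

    def emit(node: TreeNode, leaves: list[str]) -> None:
        name = f"{group_prefix}{len(groups) + 1:03d}"
        groups[name] = frozenset(leaves)
        prov: dict = {"n_leaves": len(leaves), "root_support": node.support}
        for rule in rules:
            vals = matrices[rule.metric].pairs(leaves)
            if vals.size:
                prov[f"min_intra_{rule.metric}"] = float(np.min(vals))
                prov[f"max_intra_{rule.metric}"] = float(np.max(vals))
        provenance[name] = prov

    def eligible(node: TreeNode, leaves: list[str]) -> bool:
        if node.is_leaf:
            return True
        if node is not tree.root:
            if node.support is None or node.support < support_min:
                return False
        return all(
            rule.intra_ok(matrices[rule.metric].pairs(leaves)) for rule in rules
        )

    def walk(node: TreeNode) -> None:
        leaves = _clade_leaves(node)
        if eligible(node, leaves):
            emit(node, leaves)
            return
        for child in node.children:
            walk(child)

    walk(tree.root)
    return TaxonPartition(rank, groups, provenance)


def _subtree_rooted_at(node: TreeNode) -> PhyloTree:
    def clone(n: TreeNode) -> TreeNode:
        new = TreeNode(n.label, n.length, n.support)
        for c in n.children:
            new.add_child(clone(c))
        return new

    root = clone(node)
    root.length = None
    return PhyloTree(root, normalize=False)


def _find_clade_node(tree: PhyloTree, members: frozenset) -> TreeNode:
    for node in tree.root.preorder():
        if frozenset(_clade_leaves(node)) == members:
            return node
    raise DelineationError("group is not a clade of the tree")


def hierarchical_delineate(
    tree: PhyloTree,
    family_rules: Sequence[ThresholdRule],
    genus_rules: Sequence[ThresholdRule],
    matrices: Mapping[str, LabeledMatrix],
    support_min: float = 70.0,
) -> dict[str, TaxonPartition]:
    """Families first, then genera independently inside each family subtree.

    Genus rules must be at least as tight as family rules metric by metric
    (a looser genus rule is rejected as non-nested), which guarantees every
    genus group nests in exactly one family group. With equal rule sets the
    genus partition reproduces the family partition. The root of each family
    subtree is support-exempt in the genus pass (it already qualified as a
    family).
    """
    fam_by_metric = {r.metric: r for r in family_rules}
    gen_by_metric = {r.metric: r for r in genus_rules}
    if set(fam_by_metric) != set(gen_by_metric):
        raise DelineationError("family and genus rules must cover the same metrics")
    for metric, grule in gen_by_metric.items():
        if fam_by_metric[metric].tighter_than(grule):
            raise DelineationError(
                f"genus rule for {metric!r} is looser than the family rule (non-nested)"
            )
    families = delineate_rank(
        tree, family_rules, matrices, support_min, rank="family", group_prefix="F"
    )
    genus_groups: dict[str, frozenset] = {}
    genus_prov: dict[str, dict] = {}
    for fam_name in sorted(families.groups):
        members = families.groups[fam_name]
        node = _find_clade_node(tree, members)
        sub = _subtree_rooted_at(node)
        part = delineate_rank(
            sub,
            genus_rules,
            matrices,
            support_min,
            rank="genus",
            group_prefix=f"{fam_name}_g",
        )
        for gname in sorted(part.groups):
            genus_groups[gname] = part.groups[gname]
            prov = dict(part.provenance.get(gname, {}))
            prov["family"] = fam_name
            genus_prov[gname] = prov
    genera = TaxonPartition("genus", genus_groups, genus_prov)
    return {"family": families, "genus": genera}


def compare_partitions(p: TaxonPartition, q: TaxonPartition) -> dict:
    """Adjusted Rand index and raw pair-agreement count between partitions."""
    if p.leaf_universe != q.leaf_universe:
        raise InvariantError("partitions cover different leaf universes")
    leaves = sorted(p.leaf_universe)
    pm, qm = p.group_of(), q.group_of()
    lab_p = [pm[leaf] for leaf in leaves]
    lab_q = [qm[leaf] for leaf in leaves]
    n_agree = 0
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            same_p = lab_p[i] == lab_p[j]
            same_q = lab_q[i] == lab_q[j]
            n_agree += same_p == same_q
    if p.n_groups == 1 and q.n_groups == 1:
        ari = 1.0  # both trivial: identical partitions
    else:
        ari = float(adjusted_rand_score(lab_p, lab_q))
    return {"ari": ari, "n_agree_pairs": n_agree}
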