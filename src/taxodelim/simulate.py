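"""Synthetic data with planted family/genus structure.

The generator builds a three-tier rooted tree (family stems off the root,
genus stems inside families, species tips inside genera) whose patristic
distances land in configured bands, then evolves a root proteome down the
tree under a 20-state Jukes-Cantor substitution process whose rate is
calibrated so that expected tip-pair identity tracks the configured AAI
bands. Branch support values are drawn from a configurable distribution.

Tier placement. The intra- and inter-family distance bands are treated as
envelopes; within them the three kinds of leaf pairs are drawn from
narrower corridors (within-genus, cross-genus-within-family, and
between-family) positioned so that the planted ranks are separable by the
standard genus (AAI 0.7 / ED 0.4) and family (AAI 0.6 / ED 0.5) boundaries,
with the realized AAI gap centred near the family AAI boundary. A few
distances are anchored at corridor edges (the closest family pair at the
between-family corridor floor, the widest family at the cross-genus
ceiling) so every tier of the planted structure is exercised in every
replicate. Infeasible band/corridor combinations fail loudly.

Substitution model. On a branch of length d each site mutates independently
with probability p(d) = (19/20)(1 - exp(-k d)), jumping to a uniformly
chosen different residue; this is the exact 20-state Jukes-Cantor
transition, so the expected identity of two tips at patristic distance D is
I(D) = 1/20 + (19/20) exp(-k D). The rate k is calibrated from that closed
form so that I maps the distance-corridor gap onto the AAI band gap (minus
a small terminal-trim allowance, since local alignments clip low-scoring
ends and measure slightly above per-site identity). No indels and no gene
gain/loss: every proteome keeps the root's gene count.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .core import LabeledMatrix, PhyloTree, Proteome, SequenceRecord, TreeNode
from .errors import SimulationError

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "simulate_tree",
    "evolve_proteomes",
    "perturb_tree",
    "random_resolved_tree",
    "synthetic_ogri_matrices",
    "substitution_rate",
    "expected_identity",
]

_N_AA = 20
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: measured local-alignment identity sits slightly above per-site identity
#: because terminal mismatch columns get trimmed; the calibration aims this
#: far below the nominal AAI-gap midpoint to compensate (~I*t/L for t≈1-2
#: trimmed columns at protein length ≈300).
TRIM_ALLOWANCE = 0.005


@dataclass(frozen=True)
class SimParams:
    """Parameters of the planted-structure simulation.

    Band defaults follow the reported intra/inter family AAI and ED ranges
    for the order under study; corridors position the three distance tiers
    inside those envelopes (see the module docstring).
    """

    n_families: int = 13
    genera_per_family: tuple[int, int] = (1, 2)
    species_per_genus: tuple[int, int] = (1, 2)
    intra_family_ed_band: tuple[float, float] = (0.16, 0.57)
    inter_family_ed_band: tuple[float, float] = (0.50, 1.22)
    target_intra_family_aai_band: tuple[float, float] = (0.62, 0.84)
    target_inter_family_aai_band: tuple[float, float] = (0.51, 0.60)
    within_genus_ed: tuple[float, float] = (0.17, 0.30)
    cross_genus_ed: tuple[float, float] = (0.42, 0.44)
    between_family_ed: tuple[float, float] = (0.57, 1.20)
    n_proteins: int = 10
    protein_length: tuple[int, int] = (280, 320)
    support_distribution: tuple = ("constant", 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        def band(name: str, lo_hi: tuple[float, float]) -> None:
            lo, hi = lo_hi
            if not lo < hi:
                raise SimulationError(f"{name} must be ordered lo < hi, got {lo_hi}")

        band("intra_family_ed_band", self.intra_family_ed_band)
        band("inter_family_ed_band", self.inter_family_ed_band)
        band("target_intra_family_aai_band", self.target_intra_family_aai_band)
        band("target_inter_family_aai_band", self.target_inter_family_aai_band)
        band("within_genus_ed", self.within_genus_ed)
        band("cross_genus_ed", self.cross_genus_ed)
        band("between_family_ed", self.between_family_ed)
        if self.inter_family_ed_band[1] <= self.intra_family_ed_band[0]:
            raise SimulationError("inter-family ED band must extend above the intra band")
        for name, corridor, env in (
            ("within_genus_ed", self.within_genus_ed, self.intra_family_ed_band),
            ("cross_genus_ed", self.cross_genus_ed, self.intra_family_ed_band),
            ("between_family_ed", self.between_family_ed, self.inter_family_ed_band),
        ):
            if corridor[0] < env[0] or corridor[1] > env[1]:
                raise SimulationError(
                    f"{name} corridor {corridor} escapes its band envelope {env}"
                )
        if not self.within_genus_ed[1] < self.cross_genus_ed[0]:
            raise SimulationError("within-genus distances must stay below cross-genus ones")
        if not self.cross_genus_ed[1] < self.between_family_ed[0]:
            raise SimulationError(
                "cross-genus distances must stay below between-family ones "
                "(infeasible bands: no separable branch-length assignment exists)"
            )
        if self.n_families < 1:
            raise SimulationError("need at least one family")
        for name, rng_ in (
            ("genera_per_family", self.genera_per_family),
            ("species_per_genus", self.species_per_genus),
        ):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise SimulationError(f"{name} range must be ordered and >= 1")
        if self.n_proteins < 1:
            raise SimulationError("need at least one protein")
        if self.protein_length[0] < 1 or self.protein_length[1] < self.protein_length[0]:
            raise SimulationError("protein_length range must be ordered and >= 1")
        kind = self.support_distribution[0]
        if kind not in ("constant", "uniform"):
            raise SimulationError(f"unknown support distribution {kind!r}")
        s_aai = self._aai_separatrix()
        if s_aai <= 1.0 / _N_AA:
            raise SimulationError("AAI bands sit below the random-identity floor")

    def _aai_separatrix(self) -> float:
        return (
            self.target_intra_family_aai_band[0] + self.target_inter_family_aai_band[1]
        ) / 2.0 - TRIM_ALLOWANCE

    def _ed_separatrix(self) -> float:
        return (self.cross_genus_ed[1] + self.between_family_ed[0]) / 2.0


def expected_identity(distance: float, rate: float) -> float:
    """Expected per-site identity of two tips at a patristic distance."""
    return 1.0 / _N_AA + (1.0 - 1.0 / _N_AA) * math.exp(-rate * distance)


def substitution_rate(params: SimParams) -> float:
    """Calibrated rate k mapping the ED corridor gap onto the AAI gap.

    Solves I(s_ed) = s_aai in the closed form above, where s_ed is the
    midpoint between the cross-genus ceiling and the between-family floor
    and s_aai is the midpoint of the AAI band gap minus the trim allowance.
    """
    s_aai = params._aai_separatrix()
    s_ed = params._ed_separatrix()
    return -math.log((s_aai - 1.0 / _N_AA) / (1.0 - 1.0 / _N_AA)) / s_ed


@dataclass
class SyntheticTruth:
    """A simulated tree plus the planted partitions that generated it."""

    tree: PhyloTree
    family_partition: "TaxonPartition"
    genus_partition: "TaxonPartition"
    params: SimParams


def _draw_support(params: SimParams, rng: np.random.Generator) -> float:
    dist = params.support_distribution
    if dist[0] == "constant":
        return float(dist[1])
    return float(rng.uniform(dist[1], dist[2]))


def simulate_tree(params: SimParams) -> SyntheticTruth:
    """Build the planted three-tier tree (see the module docstring)."""
    from .delineate import TaxonPartition

    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[0])
    F = params.n_families
    g_lo, g_hi = params.genera_per_family
    s_lo, s_hi = params.species_per_genus

    n_genera = [g_hi if f == 0 else int(rng.integers(g_lo, g_hi + 1)) for f in range(F)]
    n_species = [
        [
            s_hi if (f == 0 and g == 0) else int(rng.integers(s_lo, s_hi + 1))
            for g in range(n_genera[f])
        ]
        for f in range(F)
    ]

    wg_lo, wg_hi = params.within_genus_ed
    cg_lo, cg_hi = params.cross_genus_ed
    bf_lo, bf_hi = params.between_family_ed
    h_root = bf_lo / 2.0
    eps_max = (bf_hi - bf_lo) / 2.0
    # anchors: the two first families sit at the corridor floor; with >= 4
    # families the last two sit at its ceiling
    eps = np.array([float(rng.uniform(0.0, eps_max)) for _ in range(F)])
    eps[0] = 0.0
    if F >= 2:
        eps[1] = 0.0
    if F >= 4:
        eps[-1] = eps_max
        eps[-2] = eps_max

    root = TreeNode()
    fam_map: dict[str, str] = {}
    gen_map: dict[str, str] = {}
    for f in range(F):
        fam_id = f"F{f + 1:02d}"
        # the widest family (the anchor, index 0) pins the cross-genus ceiling
        d_cross = cg_hi if f == 0 else float(rng.uniform(cg_lo, cg_hi))
        h_fam = d_cross / 2.0
        tip_depth = h_root + eps[f]
        genus_nodes: list[TreeNode] = []
        for g in range(n_genera[f]):
            gen_id = f"{fam_id}G{g + 1:02d}"
            S = n_species[f][g]
            d_within = float(rng.uniform(wg_lo, wg_hi))
            h_gen = d_within / 2.0
            tips = []
            for s in range(S):
                label = f"{gen_id}S{s + 1:02d}"
                fam_map[label] = fam_id
                gen_map[label] = gen_id
                tips.append(TreeNode(label=label))
            if S == 1:
                genus_nodes.append(tips[0])
            else:
                gnode = TreeNode(support=_draw_support(params, rng))
                for tip in tips:
                    tip.length = h_gen
                    gnode.add_child(tip)
                genus_nodes.append(gnode)
        if len(genus_nodes) == 1:
            sub = genus_nodes[0]
            sub.length = tip_depth if sub.is_leaf else tip_depth - _node_height(sub)
            root.add_child(sub)
        else:
            fnode = TreeNode(support=_draw_support(params, rng), length=tip_depth - h_fam)
            for sub in genus_nodes:
                sub.length = h_fam if sub.is_leaf else h_fam - _node_height(sub)
                fnode.add_child(sub)
            root.add_child(fnode)

    tree = PhyloTree(root, normalize=False)
    return SyntheticTruth(
        tree=tree,
        family_partition=TaxonPartition.from_mapping("family", fam_map),
        genus_partition=TaxonPartition.from_mapping("genus", gen_map),
        params=params,
    )


def _node_height(node: TreeNode) -> float:
    """Height of an ultrametric subtree above its tips."""
    h = 0.0
    n = node
    while not n.is_leaf:
        child = n.children[0]
        h += child.length or 0.0
        n = child
    return h


def evolve_proteomes(truth: SyntheticTruth, params: SimParams | None = None) -> list[Proteome]:
    """Evolve a random root proteome down the tree; one proteome per leaf."""
    params = params or truth.params
    if not truth.tree.has_branch_lengths():
        raise SimulationError("tree must have branch lengths on every edge")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[1])
    rate = substitution_rate(params)
    lo, hi = params.protein_length
    lengths = rng.integers(lo, hi + 1, size=params.n_proteins)
    root_seqs = [rng.integers(0, _N_AA, size=int(n)).astype(np.int8) for n in lengths]

    proteomes: list[Proteome] = []

    def mutate(seq: np.ndarray, d: float) -> np.ndarray:
        p = (1.0 - 1.0 / _N_AA) * (1.0 - math.exp(-rate * d))
        mask = rng.random(seq.shape[0]) < p
        out = seq.copy()
        n_mut = int(mask.sum())
        if n_mut:
            jumps = rng.integers(1, _N_AA, size=n_mut).astype(np.int8)
            out[mask] = (out[mask] + jumps) % _N_AA
        return out

    def walk(node: TreeNode, seqs: list[np.ndarray]) -> None:
        if node.length is not None:
            seqs = [mutate(s, node.length) for s in seqs]
        if node.is_leaf:
            records = tuple(
                SequenceRecord(
                    f"{node.label}_p{i + 1:03d}",
                    "".join(_AA[c] for c in seq),
                )
                for i, seq in enumerate(seqs)
            )
            proteomes.append(Proteome(node.label, records))
            return
        for child in node.children:
            walk(child, seqs)

    walk(truth.tree.root, root_seqs)
    return proteomes


def perturb_tree(tree: PhyloTree, n_nni: int, seed: int) -> PhyloTree:
    """Apply random nearest-neighbor interchanges to a fully resolved tree."""
    if n_nni < 0:
        raise SimulationError("n_nni must be >= 0")
    if not tree.is_binary():
        raise SimulationError("perturb_tree requires a fully resolved (binary) tree")
    out = tree.copy()
    rng = np.random.default_rng(seed)
    for _ in range(n_nni):
        internal_edges = [
            v
            for v in out.root.preorder()
            if not v.is_leaf and v.parent is not None
        ]
        if not internal_edges:
            break
        v = internal_edges[int(rng.integers(len(internal_edges)))]
        u = v.parent
        assert u is not None
        siblings = [c for c in u.children if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        u.children[u.children.index(s)] = c
        v.children[v.children.index(c)] = s
        c.parent, s.parent = u, v
    return PhyloTree(out.root, normalize=False)


def random_resolved_tree(
    labels: list[str],
    seed: int,
    support: float = 100.0,
    length_range: tuple[float, float] = (0.05, 0.3),
) -> PhyloTree:
    """A random binary tree over the labels (test substrate for CD studies)."""
    if len(labels) < 2:
        raise SimulationError("need at least two labels")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(label=lab, length=float(rng.uniform(*length_range))) for lab in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = TreeNode(length=float(rng.uniform(*length_range)), support=support)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].length = None
    return PhyloTree(nodes[0], normalize=False)


def synthetic_ogri_matrices(
    labels: list[str],
    n_synonym_pairs: int,
    seed: int,
    ani_background: tuple[float, float] = (75.0, 92.0),
    ddh_background: tuple[float, float] = (20.0, 55.0),
    ani_synonym: tuple[float, float] = (96.5, 99.5),
    ddh_synonym: tuple[float, float] = (71.0, 92.0),
) -> tuple[LabeledMatrix, LabeledMatrix, set[frozenset]]:
    """Synthetic ANI/dDDH percent matrices with planted same-species pairs.

    Background pairs sit clearly below the species boundaries, planted pairs
    clearly above both; returns (ani, ddh, planted pair set).
    """
    n = len(labels)
    if n_synonym_pairs * 2 > n:
        raise SimulationError("not enough labels for that many disjoint synonym pairs")
    rng = np.random.default_rng(seed)
    ani = np.zeros((n, n))
    ddh = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    ani[iu] = rng.uniform(*ani_background, size=len(iu[0]))
    ddh[iu] = rng.uniform(*ddh_background, size=len(iu[0]))
    order = rng.permutation(n)
    planted: set[frozenset] = set()
    for k in range(n_synonym_pairs):
        i, j = int(order[2 * k]), int(order[2 * k + 1])
        a, b = min(i, j), max(i, j)
        ani[a, b] = rng.uniform(*ani_synonym)
        ddh[a, b] = rng.uniform(*ddh_synonym)
        planted.add(frozenset((labels[i], labels[j])))
    ani = ani + ani.T
    ddh = ddh + ddh.T
    np.fill_diagonal(ani, 100.0)
    np.fill_diagonal(ddh, 100.0)
    return (
        LabeledMatrix(labels, ani, kind="similarity", scale="percent"),
        LabeledMatrix(labels, ddh, kind="similarity", scale="percent"),
        planted,
    )


def params_dict(params: SimParams) -> dict:
    """JSON-serializable view of the parameters."""
    return asdict(params)
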