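"""Core in-memory containers: sequences, proteomes, trees and labeled matrices.

These types are deliberately small and strict: every invariant the pipeline
relies on (unique ids, symmetric matrices, non-negative branch lengths,
support scales) is checked at construction time so that downstream code can
assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import InvariantError

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
NUCLEOTIDE_ALPHABET = "ACGTN-"

#: residues that never count as identical and score zero against everything
PROTEIN_AMBIGUOUS = frozenset("X")
NUCLEOTIDE_AMBIGUOUS = frozenset("N-")


def ambiguous_residues(alphabet: str) -> frozenset:
    """The ambiguity characters of an alphabet (X for protein, N/- for DNA)."""
    return NUCLEOTIDE_AMBIGUOUS if alphabet == NUCLEOTIDE_ALPHABET else PROTEIN_AMBIGUOUS

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence over a declared alphabet."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise InvariantError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise InvariantError(f"sequence {self.id!r} has no residues")
        allowed = set(self.alphabet)
        bad = sorted(set(self.residues) - allowed)
        if bad:
            raise InvariantError(
                f"sequence {self.id!r} contains residues outside its alphabet: {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Proteome:
    """An ordered collection of protein sequences belonging to one taxon."""

    taxon_id: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.taxon_id or any(c.isspace() for c in self.taxon_id):
            raise InvariantError(f"taxon_id must be a non-empty token, got {self.taxon_id!r}")
        if not self.records:
            raise InvariantError(f"proteome {self.taxon_id!r} is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise InvariantError(
                    f"proteome {self.taxon_id!r} has duplicate record id {rec.id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


class TreeNode:
    """A node of a rooted phylogenetic tree.

    ``support`` is stored on the [0, 100] scale; ``recovery`` is an optional
    integer annotation used by the majority-rule consensus (how many input
    trees contained the node's bipartition).
    """

    __slots__ = ("parent", "children", "label", "length", "support", "recovery")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.label = label
        self.length = length
        self.support = support
        self.recovery: int | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class PhyloTree:
    """A rooted tree with unique leaf labels, branch lengths and supports.

    Normalization suppresses unary internal nodes (concatenating branch
    lengths) and validates leaf-label uniqueness and non-negative lengths.
    """

    def __init__(self, root: TreeNode, normalize: bool = True) -> None:
        self.root = root
        if normalize:
            self._suppress_unary()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _suppress_unary(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.root.preorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    if child.length is not None and node.length is not None:
                        child.length += node.length
                    self.root = child
                else:
                    parent = node.parent
                    assert parent is not None
                    idx = parent.children.index(node)
                    if child.length is None:
                        child.length = node.length
                    elif node.length is not None:
                        child.length += node.length
                    child.parent = parent
                    parent.children[idx] = child
                changed = True
                break

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.root.preorder():
            if node.is_leaf:
                if not node.label:
                    raise InvariantError("leaf without a label")
                if any(c.isspace() for c in node.label):
                    raise InvariantError(f"leaf label contains whitespace: {node.label!r}")
                labels.append(node.label)
            if node.length is not None and node.length < 0:
                raise InvariantError(
                    f"negative branch length {node.length} at {node.label or 'internal node'}"
                )
            if node.support is not None and not (0 <= node.support <= 100):
                raise InvariantError(f"support {node.support} outside [0, 100]")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise InvariantError(f"duplicate leaf labels: {sorted(dupes)}")

    # -- queries --------------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self, include_root: bool = True) -> list[TreeNode]:
        nodes = [n for n in self.root.preorder() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.root.preorder() if n is not self.root
        )

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length, node.support)
            new.recovery = node.recovery
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), normalize=False)


@dataclass
class LabeledMatrix:
    """A symmetric taxon-by-taxon matrix of similarities or distances.

    ``kind`` is ``"similarity"`` (AAI, ANI, dDDH; diagonal at the scale
    maximum) or ``"distance"`` (ED; zero diagonal, unbounded above).
    ``scale`` is ``"fraction"`` or ``"percent"``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"
    scale: str = "fraction"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("similarity", "distance"):
            raise InvariantError(f"unknown matrix kind {self.kind!r}")
        if self.scale not in ("fraction", "percent"):
            raise InvariantError(f"unknown matrix scale {self.scale!r}")
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvariantError("matrix labels are not unique")
        if self.values.shape != (n, n):
            raise InvariantError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if np.isinf(self.values).any():
            raise InvariantError("matrix contains infinite entries")
        # NaN marks a recorded-missing pair (see aai_matrix's missing policy);
        # the NaN pattern must itself be symmetric.
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL, rtol=0, equal_nan=True):
            raise InvariantError("matrix is not symmetric within 1e-9")
        diag = np.diag(self.values)
        top = 1.0 if self.scale == "fraction" else 100.0
        if self.kind == "similarity":
            if not np.allclose(diag, top, atol=_SYMMETRY_TOL):
                raise InvariantError(f"similarity diagonal must equal {top}")
            with np.errstate(invalid="ignore"):
                if (
                    np.nanmin(self.values) < -_SYMMETRY_TOL
                    or np.nanmax(self.values) > top + _SYMMETRY_TOL
                ):
                    raise InvariantError(f"similarity entries outside [0, {top}]")
        else:
            if not np.allclose(diag, 0.0, atol=_SYMMETRY_TOL):
                raise InvariantError("distance diagonal must be zero")
            if np.nanmin(self.values) < -_SYMMETRY_TOL:
                raise InvariantError("negative distance entries")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def submatrix(self, labels: Sequence[str]) -> "LabeledMatrix":
        idx = [self._index[lab] for lab in labels]
        return LabeledMatrix(
            list(labels), self.values[np.ix_(idx, idx)], kind=self.kind, scale=self.scale
        )

    def pairs(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Off-diagonal values over all unordered pairs of ``labels``."""
        labs = self.labels if labels is None else list(labels)
        idx = np.array([self._index[lab] for lab in labs])
        sub = self.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(labs), k=1)
        return sub[iu]

    def to_scale(self, scale: str) -> "LabeledMatrix":
        if scale == self.scale:
            return self
        factor = 100.0 if scale == "percent" else 0.01
        return LabeledMatrix(self.labels, self.values * factor, kind=self.kind, scale=scale)
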