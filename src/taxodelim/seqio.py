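"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (protein and nucleotide), single-tree Newick, PHYLIP-square
distance matrices (the IQ-TREE ``mldist`` dialect), long-format TSV matrices
and a TSV taxonomy mapping (leaf_label, taxon_name, genus, family).

All readers validate strictly and raise :class:`~taxodelim.errors.FormatError`
with enough context to locate the offending line.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import (
    LabeledMatrix,
    PhyloTree,
    Proteome,
    SequenceRecord,
    TreeNode,
    PROTEIN_ALPHABET,
)
from .errors import FormatError, InvariantError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_proteome",
    "read_proteome_dir",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_square_matrix",
    "write_matrix",
    "read_taxonomy_mapping",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = PROTEIN_ALPHABET) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order.

    Residues are upper-cased before alphabet validation. Duplicate ids,
    illegal residues and empty files are format errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, desc, chunks
        if header is None:
            return
        residues = "".join(chunks)
        try:
            rec = SequenceRecord(header, residues, desc, alphabet)
        except InvariantError as exc:
            raise FormatError(f"{path}: near line {line_no}: {exc}") from exc
        records.append(rec)
        header, desc, chunks = None, "", []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(i - 1)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"{path}: line {i}: empty FASTA header")
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = i
                if header in seen:
                    raise FormatError(f"{path}: line {i}: duplicate id {header!r}")
                seen.add(header)
            else:
                if header is None:
                    raise FormatError(f"{path}: line {i}: sequence data before first header")
                bad = set(line.upper()) - set(alphabet)
                if bad:
                    raise FormatError(
                        f"{path}: line {i}: illegal residues {sorted(bad)} in {header!r}"
                    )
                chunks.append(line.upper())
    flush(header_line)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as standard FASTA, wrapping sequence lines at ``wrap``."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for start in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[start : start + wrap] + "\n")


def read_proteome(
    path: str | Path, taxon_id: str | None = None, alphabet: str = PROTEIN_ALPHABET
) -> Proteome:
    """Read one FASTA file as the proteome of a single taxon.

    The taxon id defaults to the file stem.
    """
    path = Path(path)
    tid = taxon_id if taxon_id is not None else path.stem
    return Proteome(tid, tuple(read_fasta(path, alphabet)))


def read_proteome_dir(directory: str | Path) -> list[Proteome]:
    """Read every ``*.faa``/``*.fasta``/``*.fa`` file in a directory."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in (".faa", ".fasta", ".fa")
    )
    if not paths:
        raise FormatError(f"{directory}: no FASTA files found")
    return [read_proteome(p) for p in paths]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _support_from_label(label: str | None, where: str) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        raise FormatError(
            f"{where}: internal node label {label!r} is not a numeric support "
            "(plain numeric labels only)"
        ) from None


def read_newick(source: str | Path, is_string: bool = False) -> PhyloTree:
    """Read a single-tree Newick file (or string) into a normalized tree.

    Support values must be plain internal-node labels. Values on [0, 1] are
    interpreted as posterior probabilities and rescaled to [0, 100];
    ``[&...]`` annotation comments are rejected.
    """
    if is_string:
        text = str(source)
        where = "<string>"
    else:
        text = Path(source).read_text()
        where = str(source)
    if "[&" in text:
        raise FormatError(f"{where}: [&...] annotation comments are not supported")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"{where}: malformed newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.is_leaf():
            if dnode.taxon is None:
                raise FormatError(f"{where}: leaf without a label")
            node = TreeNode(label=dnode.taxon.label)
        else:
            node = TreeNode(support=_support_from_label(dnode.label, where))
        node.length = None if dnode.edge.length is None else float(dnode.edge.length)
        if node.length is not None and node.length < 0:
            raise FormatError(f"{where}: negative branch length {node.length}")
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length carries no information here

    # auto-detect posterior-scale supports and rescale to [0, 100]
    supports = [
        n.support for n in root.preorder() if n.children and n.support is not None
    ]
    if supports and max(supports) <= 1.0:
        for n in root.preorder():
            if n.children and n.support is not None:
                n.support *= 100.0
    try:
        return PhyloTree(root)
    except InvariantError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def newick_string(
    tree: PhyloTree, supports: bool = True, recovery_as_label: bool = False
) -> str:
    """Serialize a tree to a Newick string.

    Internal nodes carry their support (or, for consensus trees, their
    recovery count when ``recovery_as_label`` is set) as plain labels.
    """

    def fmt_len(node: TreeNode) -> str:
        return "" if node.length is None else f":{node.length:.6g}"

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}{fmt_len(node)}"
        inner = ",".join(fmt(c) for c in node.children)
        label = ""
        if recovery_as_label and node.recovery is not None:
            label = str(node.recovery)
        elif supports and node.support is not None:
            label = f"{node.support:g}"
        return f"({inner}){label}{fmt_len(node)}"

    return fmt(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | Path, **kwargs) -> None:
    Path(path).write_text(newick_string(tree, **kwargs) + "\n")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

_ASYM_TOL = 1e-6


def _read_mldist(path: Path, kind: str, scale: str) -> LabeledMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FormatError(f"{path}: empty matrix file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise FormatError(f"{path}: first token must be the taxon count") from None
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise FormatError(
            f"{path}: expected {n} rows of a label plus {n} values "
            f"({expected} tokens), found {len(tokens)}"
        )
    labels: list[str] = []
    values = np.empty((n, n))
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        pos += 1
        try:
            row = [float(t) for t in tokens[pos : pos + n]]
        except ValueError as exc:
            raise FormatError(f"{path}: row {labels[-1]!r}: non-numeric value") from exc
        values[i] = row
        pos += n
    return _finish_matrix(path, labels, values, kind, scale)


def _read_tsv_long(
    path: Path,
    kind: str,
    scale: str,
    labels: Sequence[str] | None,
) -> LabeledMatrix:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: tsv_long rows need (label_a, label_b, value)")
    # tolerate a single header row
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    universe: list[str]
    if labels is not None:
        universe = list(labels)
        known = set(universe)
    else:
        seen: dict[str, None] = {}
        for lab in pd.concat([df[0], df[1]]):
            seen.setdefault(str(lab))
        universe = list(seen)
        known = set(universe)
    index = {lab: i for i, lab in enumerate(universe)}
    n = len(universe)
    values = np.full((n, n), np.nan)
    top = 1.0 if scale == "fraction" else 100.0
    np.fill_diagonal(values, top if kind == "similarity" else 0.0)
    for _, (a, b, v, *_rest) in df.iterrows():
        a, b = str(a), str(b)
        if a not in known or b not in known:
            missing = a if a not in known else b
            raise FormatError(f"{path}: unknown label {missing!r}")
        try:
            val = float(v)
        except ValueError:
            raise FormatError(f"{path}: non-numeric value {v!r} for ({a}, {b})") from None
        i, j = index[a], index[b]
        for r, c in ((i, j), (j, i)):
            if not math.isnan(values[r, c]) and abs(values[r, c] - val) > _ASYM_TOL:
                raise FormatError(
                    f"{path}: conflicting entries for ({a}, {b}): "
                    f"{values[r, c]} vs {val}"
                )
        values[i, j] = values[j, i] = val
    if np.isnan(values).any():
        missing = int(np.isnan(values).sum() // 2)
        raise FormatError(f"{path}: {missing} unordered pairs missing from tsv_long file")
    return _finish_matrix(path, universe, values, kind, scale)


def _finish_matrix(
    path: Path, labels: list[str], values: np.ndarray, kind: str, scale: str
) -> LabeledMatrix:
    if not np.allclose(values, values.T, atol=_ASYM_TOL, rtol=0):
        raise FormatError(f"{path}: matrix not symmetric within {_ASYM_TOL}")
    values = (values + values.T) / 2.0
    try:
        return LabeledMatrix(labels, values, kind=kind, scale=scale)
    except InvariantError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_square_matrix(
    path: str | Path,
    dialect: str = "mldist",
    kind: str = "distance",
    scale: str = "fraction",
    labels: Sequence[str] | None = None,
) -> LabeledMatrix:
    """Read a symmetric labeled matrix.

    ``dialect`` is ``"mldist"`` (PHYLIP square, as written by IQ-TREE: first
    line the taxon count, then one label plus n whitespace-separated reals
    per row) or ``"tsv_long"`` (rows of ``label_a<TAB>label_b<TAB>value``;
    missing reciprocal entries are filled by symmetry, conflicts beyond 1e-6
    rejected). ``labels``, when supplied for tsv_long, fixes the label
    universe and makes unknown labels an error.
    """
    path = Path(path)
    if dialect == "mldist":
        return _read_mldist(path, kind, scale)
    if dialect == "tsv_long":
        return _read_tsv_long(path, kind, scale, labels)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def write_matrix(matrix: LabeledMatrix, path: str | Path, dialect: str = "mldist") -> None:
    """Write a matrix in ``mldist`` or ``tsv_long`` dialect.

    Label order follows the matrix; values are rendered with 6 decimals.
    """
    path = Path(path)
    n = len(matrix.labels)
    buf = io.StringIO()
    if dialect == "mldist":
        buf.write(f"{n}\n")
        width = max(len(lab) for lab in matrix.labels) + 2
        for i, lab in enumerate(matrix.labels):
            row = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(n))
            buf.write(f"{lab:<{width}}{row}\n")
    elif dialect == "tsv_long":
        for i in range(n):
            for j in range(i + 1, n):
                buf.write(
                    f"{matrix.labels[i]}\t{matrix.labels[j]}\t{matrix.values[i, j]:.6f}\n"
                )
    else:
        raise ValueError(f"unknown matrix dialect {dialect!r}")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Taxonomy mapping
# ---------------------------------------------------------------------------

def read_taxonomy_mapping(path: str | Path) -> pd.DataFrame:
    """Read the leaf->taxonomy mapping TSV.

    Columns: leaf_label, taxon_name, genus, family (header optional).
    Returns a DataFrame indexed by leaf_label.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: mapping needs 4 columns (leaf, taxon, genus, family)")
    if df.iloc[0, 0] in ("leaf_label", "leaf"):
        df = df.iloc[1:]
    df = df.iloc[:, :4]
    df.columns = ["leaf_label", "taxon_name", "genus", "family"]
    if df["leaf_label"].duplicated().any():
        dupes = sorted(df.loc[df["leaf_label"].duplicated(), "leaf_label"])
        raise FormatError(f"{path}: duplicate leaf labels {dupes}")
    return df.set_index("leaf_label")
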