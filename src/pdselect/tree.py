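"""Rooted phylogenetic trees with branch lengths, read and written as newick.

The tree is the substrate for all phylogenetic-diversity (PD) arithmetic, so
parsing is strict: every edge must carry a non-negative, finite branch length
(PD is meaningless without lengths, and silently defaulting them would corrupt
every downstream score), leaf labels must be unique and non-empty, and every
internal node — including the root — must have out-degree at least two.
Multifurcations are allowed; zero-length branches are allowed (they are common
in 16S rRNA trees wherever sequences are identical).

Newick conventions: single- and double-quoted labels are supported, underscores
in unquoted labels are literal characters (never spaces), and labels are
compared as exact strings after trimming surrounding whitespace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .errors import NewickParseError, TreeValidationError

__all__ = ["PhyloTree", "parse_newick", "read_newick", "total_branch_length", "write_leaf_list"]

# characters that force quoting when serializing a label
_NEEDS_QUOTE = set("()[]{}/\\,;:=*'\"`<> \t\n")


@dataclass
class PhyloTree:
    """A rooted tree over integer node ids ``0 .. n_nodes-1`` with node 0 as root.

    ``parent[v]`` is the parent of non-root node ``v`` (``parent[0]`` is None);
    ``branch_length[v]`` is the length of the edge above ``v`` (0.0 stored for
    the root, which has no edge); ``leaf_label`` maps leaf ids to taxon names.
    Child order is preserved from the source newick so serialization
    round-trips byte-identically.
    """

    parent: list
    branch_length: list
    children: list
    leaf_label: dict
    root: int = 0
    _label_to_node: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._label_to_node:
            self._label_to_node = {lab: v for v, lab in self.leaf_label.items()}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leaves(self) -> Iterator[int]:
        return iter(self.leaf_label)

    def node_for_label(self, label: str) -> int:
        return self._label_to_node[label]

    def has_label(self, label: str) -> bool:
        return label in self._label_to_node

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children[v]))

    def postorder(self) -> Iterator[int]:
        return reversed(list(self.preorder()))

    def depths(self) -> list:
        """Cumulative branch length from the root to each node."""
        d = [0.0] * self.n_nodes
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.branch_length[v]
        return d

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Serialize preserving child order and full branch-length precision."""
        parts: dict[int, str] = {}
        for v in self.postorder():
            if self.is_leaf(v):
                body = _quote_label(self.leaf_label[v])
            else:
                body = "(" + ",".join(parts.pop(c) for c in self.children[v]) + ")"
            if v == self.root:
                parts[v] = body
            else:
                parts[v] = f"{body}:{self.branch_length[v]!r}"
        return parts[self.root] + ";"

    def _signature(self):
        """Canonical (child-order-independent) structural signature."""
        sig: dict[int, tuple] = {}
        for v in self.postorder():
            bl = self.branch_length[v] if v != self.root else None
            if self.is_leaf(v):
                sig[v] = (bl, self.leaf_label[v])
            else:
                sig[v] = (bl, tuple(sorted(sig.pop(c) for c in self.children[v])))
        return sig[self.root]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self._signature() == other._signature()


def _quote_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick statement into a validated :class:`PhyloTree`.

    Raises :class:`NewickParseError` for malformed syntax (the message carries
    the reader's position) and :class:`TreeValidationError` for structurally
    invalid trees: missing or negative branch lengths, duplicate or empty leaf
    labels, unary nodes, or a root with fewer than two children.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            # keep leaf labels as plain node labels so duplicate-label
            # detection (a validation concern) stays in our hands
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy's reader errors carry position info
        raise NewickParseError(f"malformed newick: {_position_message(exc)}") from None
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _position_message(exc: Exception) -> str:
    line = getattr(exc, "line_num", None)
    col = getattr(exc, "col_num", None)
    msg = getattr(exc, "message", None) or str(exc)
    if line is not None and col is not None:
        return f"line {line}, column {col}: {msg}"
    return msg


def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    ids: dict = {}
    parent: list = []
    blen: list = []
    children: list = []
    leaf_label: dict = {}

    for nd in dtree.preorder_node_iter():
        v = len(parent)
        ids[nd] = v
        if nd.parent_node is None:
            parent.append(None)
            blen.append(0.0)
        else:
            p = ids[nd.parent_node]
            parent.append(p)
            length = nd.edge.length
            if length is None:
                raise TreeValidationError(
                    "edge without a branch length; trees without computed branch "
                    "lengths are rejected (PD requires lengths)"
                )
            length = float(length)
            if length < 0:
                raise TreeValidationError(f"negative branch length {length!r}")
            if not math.isfinite(length):
                raise TreeValidationError(f"non-finite branch length {length!r}")
            blen.append(length)
            children[p].append(v)
        children.append([])
        if nd.is_leaf():
            raw = nd.taxon.label if nd.taxon is not None else nd.label
            label = raw.strip() if raw else ""
            if not label:
                raise TreeValidationError("leaf with empty label")
            leaf_label[v] = label

    seen: dict = {}
    for v, lab in leaf_label.items():
        if lab in seen:
            raise TreeValidationError(f"duplicate leaf label {lab!r}")
        seen[lab] = v

    for v, ch in enumerate(children):
        if ch and len(ch) < 2:
            where = "root" if parent[v] is None else "internal node"
            raise TreeValidationError(
                f"{where} with out-degree {len(ch)} (< 2); unary nodes are not allowed"
            )
    if len(parent) == 1:
        raise TreeValidationError("tree has a single node; at least two leaves required")

    return PhyloTree(parent=parent, branch_length=blen, children=children, leaf_label=leaf_label)


def total_branch_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths — the denominator of every coverage fraction."""
    return float(sum(tree.branch_length[v] for v in range(tree.n_nodes) if v != tree.root))


def write_leaf_list(tree: PhyloTree) -> list:
    """All leaf labels in deterministic (lexicographic) order."""
    return sorted(tree.leaf_label.values())
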