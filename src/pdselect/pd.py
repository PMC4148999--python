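"""Phylogenetic diversity (PD) of taxon subsets and PD-maximizing selection.

PD of a taxon set is the total branch length spanned by the set:

* **rooted** mode — the union of the paths from the root to every member
  (Faith's PD including the root path).  The PD of a single taxon is its
  root-path length, so the first greedy pick is well defined.
* **unrooted** mode — the minimal connected subgraph (Steiner tree) spanning
  the members; the PD of zero or one taxon is 0.

``greedy_select`` picks, at every step, the eligible leaf with the largest
marginal PD gain given everything already covered.  On rooted trees this
stepwise rule attains the optimal PD at every intermediate size — the property
the exhaustive ``brute_force_select`` oracle verifies on small instances.  The
implementation is a lazy-greedy (priority queue of stale upper bounds,
re-evaluated on pop), valid because PD is submodular: a leaf's marginal gain
can only shrink as the covered set grows.  Ties are broken lexicographically
by taxon name everywhere so runs are reproducible across platforms.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from .errors import OracleRefusalError, SelectionError, UnknownTaxonError
from .tree import PhyloTree, total_branch_length

__all__ = [
    "pd",
    "unique_contribution",
    "greedy_select",
    "brute_force_select",
    "pd_coverage",
    "SelectionStep",
    "SelectionResult",
    "CoverageReport",
]

MODES = ("rooted", "unrooted")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _resolve(tree: PhyloTree, taxa: Iterable[str]) -> list:
    nodes = []
    for name in taxa:
        if not tree.has_label(name):
            raise UnknownTaxonError(name)
        nodes.append(tree.node_for_label(name))
    return nodes


def pd(tree: PhyloTree, taxa: Iterable[str], mode: str = "rooted") -> float:
    """PD of ``taxa`` on ``tree``; ``pd(all leaves)`` equals the total branch
    length in both modes and ``pd(∅)`` is 0."""
    _check_mode(mode)
    nodes = _resolve(tree, set(taxa))
    if not nodes:
        return 0.0
    covered = bytearray(tree.n_nodes)
    total = 0.0
    for v in nodes:
        while v != tree.root and not covered[v]:
            covered[v] = 1
            total += tree.branch_length[v]
            v = tree.parent[v]
    if mode == "unrooted":
        total -= _lca_depth(tree, nodes)
    return total


def _lca_depth(tree: PhyloTree, nodes: list) -> float:
    """Branch length from the root down to the LCA of ``nodes``."""
    depths = tree.depths()
    level = [0] * tree.n_nodes
    for v in tree.preorder():
        if v != tree.root:
            level[v] = level[tree.parent[v]] + 1
    lca = nodes[0]
    for v in nodes[1:]:
        a, b = lca, v
        while level[a] > level[b]:
            a = tree.parent[a]
        while level[b] > level[a]:
            b = tree.parent[b]
        while a != b:
            a = tree.parent[a]
            b = tree.parent[b]
        lca = a
    return depths[lca]


def unique_contribution(tree: PhyloTree, taxon: str, mode: str = "rooted") -> float:
    """PD lost if ``taxon`` is dropped: ``pd(L) − pd(L ∖ {taxon})``.

    Equals the pendant branch length whenever the taxon's sibling subtree
    still contains a leaf; it exceeds the pendant length when the taxon is the
    sole representative of a deeper clade.
    """
    if not tree.has_label(taxon):
        raise UnknownTaxonError(taxon)
    labels = set(tree.leaf_label.values())
    return pd(tree, labels, mode) - pd(tree, labels - {taxon}, mode)


@dataclass(frozen=True)
class SelectionStep:
    """One accepted greedy pick: the taxon, its marginal PD gain, and the
    cumulative PD after the pick (preselected PD included)."""

    taxon: str
    marginal_gain: float
    cumulative_pd: float


@dataclass
class SelectionResult:
    """An ordered greedy selection with its provenance.

    ``preselected_pd`` is the PD already covered before the first step (the
    already-sequenced fraction); ``total_pd`` is the whole-tree PD, kept so
    cumulative coverage fractions are recoverable from the result alone.
    """

    steps: list
    preselected_pd: float
    mode: str
    total_pd: float = 0.0

    @property
    def selected_taxa(self) -> list:
        return [s.taxon for s in self.steps]

    @property
    def final_pd(self) -> float:
        return self.steps[-1].cumulative_pd if self.steps else self.preselected_pd

    def to_rows(self) -> list:
        """Rows (taxon, rank, marginal_gain, cumulative_pd, cumulative_fraction)."""
        out = []
        for rank, s in enumerate(self.steps, start=1):
            frac = s.cumulative_pd / self.total_pd if self.total_pd > 0 else 0.0
            out.append((s.taxon, rank, s.marginal_gain, s.cumulative_pd, frac))
        return out


@dataclass
class CoverageReport:
    """PD and coverage fraction for named taxon sets against the whole tree."""

    total_pd: float
    entries: list = field(default_factory=list)  # (name, pd, fraction)
    mode: str = "rooted"

    def fraction(self, name: str) -> float:
        for n, _, f in self.entries:
            if n == name:
                return f
        raise KeyError(name)

    def to_json_obj(self) -> dict:
        return {
            "mode": self.mode,
            "total_pd": self.total_pd,
            "sets": [
                {"name": n, "pd": p, "fraction": f} for n, p, f in self.entries
            ],
        }


class _GreedyState:
    """Covered-edge bookkeeping shared by both PD modes.

    ``covered[v]`` flags the edge above node ``v`` as already spanned; in
    unrooted mode ``in_tree`` flags nodes of the current Steiner tree and
    ``top`` is its rootmost node (the LCA of everything selected so far).
    """

    def __init__(self, tree: PhyloTree, mode: str):
        self.tree = tree
        self.mode = mode
        self.covered = bytearray(tree.n_nodes)
        self.in_tree = bytearray(tree.n_nodes)
        self.top: int | None = None
        self.pd = 0.0

    def add_leaf(self, leaf: int) -> float:
        """Cover the leaf's connecting path; return the PD gained."""
        tree = self.tree
        if self.mode == "rooted":
            gain = 0.0
            v = leaf
            while v != tree.root and not self.covered[v]:
                self.covered[v] = 1
                gain += tree.branch_length[v]
                v = tree.parent[v]
            self.pd += gain
            return gain
        # unrooted: attach to the current Steiner tree (or seed it)
        if self.top is None:
            self.in_tree[leaf] = 1
            self.top = leaf
            return 0.0
        gain, attach, acc = self._attachment(leaf)
        v = leaf
        while v != attach:
            self.covered[v] = 1
            self.in_tree[v] = 1
            v = tree.parent[v]
        self.in_tree[attach] = 1
        if attach in acc:
            # attachment above the old top: cover old-top→attach as well
            w = self.top
            while w != attach:
                self.covered[w] = 1
                self.in_tree[w] = 1
                w = tree.parent[w]
            self.top = attach
        self.pd += gain
        return gain

    def gain(self, leaf: int) -> float:
        """Marginal PD gain of adding ``leaf`` to the current covered set."""
        tree = self.tree
        if self.mode == "rooted":
            g = 0.0
            v = leaf
            while v != tree.root and not self.covered[v]:
                g += tree.branch_length[v]
                v = tree.parent[v]
            return g
        if self.top is None:
            return 0.0
        g, _, _ = self._attachment(leaf)
        return g

    def _attachment(self, leaf: int):
        """Find where ``leaf`` joins the Steiner tree.

        Returns ``(gain, attach_node, acc)``; ``acc`` maps each ancestor of
        ``leaf`` visited to its distance from the leaf.  ``attach_node in acc``
        signals the join happened above the tree's current top (the LCA of the
        selection dropped rootwards), so the top→attach path is added too.
        """
        tree = self.tree
        acc: dict = {}
        dist = 0.0
        v = leaf
        while True:
            if self.in_tree[v]:
                return dist, v, acc
            acc[v] = dist
            if v == tree.root:
                break
            dist += tree.branch_length[v]
            v = tree.parent[v]
        # no ancestor of leaf is in the tree: the join is at LCA(leaf, top)
        w = self.top
        climb = 0.0
        while w not in acc:
            climb += tree.branch_length[w]
            w = tree.parent[w]
        return acc[w] + climb, w, acc


def _validate_selection_inputs(tree, preselected, excluded):
    pre = set(preselected)
    exc = set(excluded)
    overlap = pre & exc
    if overlap:
        raise SelectionError(
            f"preselected and excluded overlap: {sorted(overlap)[:5]}"
        )
    _resolve(tree, pre)
    _resolve(tree, exc)
    return pre, exc


def _eligible_labels(tree, pre, exc):
    return sorted(set(tree.leaf_label.values()) - pre - exc)


def greedy_select(
    tree: PhyloTree,
    k: int,
    preselected: Iterable[str] = (),
    excluded: Iterable[str] = (),
    mode: str = "rooted",
) -> SelectionResult:
    """Select ``k`` leaves by largest marginal PD gain, lexicographic ties.

    ``preselected`` taxa count as already covered (their PD is the baseline);
    ``excluded`` taxa are never picked but still contribute to total tree PD.
    """
    _check_mode(mode)
    pre, exc = _validate_selection_inputs(tree, preselected, excluded)
    eligible = _eligible_labels(tree, pre, exc)
    if k < 0:
        raise SelectionError("k must be non-negative")
    if k > len(eligible):
        raise SelectionError(
            f"k={k} exceeds the eligible pool of {len(eligible)} leaves"
        )

    state = _GreedyState(tree, mode)
    for name in sorted(pre):
        state.add_leaf(tree.node_for_label(name))
    pre_pd = state.pd

    steps = []
    cumulative = pre_pd
    remaining = k
    if mode == "unrooted" and state.top is None and k > 0:
        # every single-taxon unrooted PD is 0, so the first pick is the
        # lexicographic tie-break; it seeds the Steiner tree, after which
        # marginal gains are positive and submodular (lazy heap is valid)
        seed = eligible.pop(0)
        state.add_leaf(tree.node_for_label(seed))
        steps.append(SelectionStep(taxon=seed, marginal_gain=0.0, cumulative_pd=cumulative))
        remaining -= 1

    # all gains flow through state.gain so stored bounds and recomputed
    # values use identical summation order
    heap = [
        (-state.gain(tree.node_for_label(name)), name, tree.node_for_label(name))
        for name in eligible
    ]
    heapq.heapify(heap)

    for _ in range(remaining):
        # lazy greedy: stored gains are upper bounds (submodularity), so a
        # popped entry whose gain is still fresh is the true maximum
        while True:
            neg_g, name, leaf = heapq.heappop(heap)
            g = state.gain(leaf)
            if g != -neg_g:
                heapq.heappush(heap, (-g, name, leaf))
                continue
            break
        gained = state.add_leaf(leaf)
        cumulative += gained
        steps.append(SelectionStep(taxon=name, marginal_gain=gained, cumulative_pd=cumulative))

    return SelectionResult(
        steps=steps,
        preselected_pd=pre_pd,
        mode=mode,
        total_pd=total_branch_length(tree),
    )


def brute_force_select(
    tree: PhyloTree,
    k: int,
    preselected: Iterable[str] = (),
    excluded: Iterable[str] = (),
    mode: str = "rooted",
):
    """Exhaustive PD-optimal ``k``-subset; the verification oracle.

    Enumerates every ``k``-subset of the eligible leaves and returns
    ``(subset, pd)`` maximizing ``pd(subset ∪ preselected)``; among ties the
    lexicographically smallest subset wins.  Refuses pools larger than 20
    leaves (combinatorial explosion guard).
    """
    _check_mode(mode)
    pre, exc = _validate_selection_inputs(tree, preselected, excluded)
    eligible = _eligible_labels(tree, pre, exc)
    if len(eligible) > 20:
        raise OracleRefusalError(
            f"eligible pool of {len(eligible)} leaves exceeds the oracle limit of 20"
        )
    if k > len(eligible):
        raise SelectionError(
            f"k={k} exceeds the eligible pool of {len(eligible)} leaves"
        )
    best_set = None
    best_pd = 0.0
    for combo in combinations(eligible, k):  # lexicographic order
        value = pd(tree, pre | set(combo), mode)
        if best_set is None or value > best_pd:
            best_pd = value
            best_set = frozenset(combo)
    if best_set is None:  # k == 0
        return frozenset(), pd(tree, pre, mode)
    return best_set, best_pd


def pd_coverage(
    tree: PhyloTree,
    named_sets: Mapping[str, Iterable[str]],
    mode: str = "rooted",
) -> CoverageReport:
    """PD and coverage fraction for each named taxon set.

    The denominator is the PD of the entire tree, which equals the total
    branch length in both modes.
    """
    _check_mode(mode)
    if tree.n_leaves == 0:
        raise SelectionError("empty tree")
    total = total_branch_length(tree)
    entries = []
    for name, taxa in named_sets.items():
        value = pd(tree, taxa, mode)
        frac = value / total if total > 0 else 0.0
        entries.append((name, value, frac))
    return CoverageReport(total_pd=total, entries=entries, mode=mode)
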