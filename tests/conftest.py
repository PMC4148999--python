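import pytest

from pdselect import PhyloTree, parse_newick

# the worked 4-leaf example used throughout: total branch length 10
FOUR_LEAF_NEWICK = "((A:1,B:2):1,(C:3,D:1):2);"


@pytest.fixture
def four_leaf_tree() -> PhyloTree:
    return parse_newick(FOUR_LEAF_NEWICK)


def star_newick(n: int, length: float = 1.0) -> str:
    leaves = ",".join(f"L{i:03d}:{length!r}" for i in range(n))
    return f"({leaves});"


def oracle_pd(tree: PhyloTree, taxa, mode: str = "rooted") -> float:
    """Independent PD oracle by whole-edge classification.

    The edge above node v is spanned by a taxon set S iff v's subtree contains
    a member of S (rooted), and additionally some member lies outside v's
    subtree (unrooted / Steiner).  This never walks root paths, so it shares
    no code path with the implementation under test.
    """
    members = {tree.node_for_label(t) for t in taxa}
    below: dict = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            below[v] = frozenset({v} & members)
        else:
            acc = frozenset()
            for c in tree.children[v]:
                acc |= below[c]
            below[v] = acc
    total = 0.0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        has_inside = bool(below[v])
        if mode == "rooted":
            if has_inside:
                total += tree.branch_length[v]
        else:
            if has_inside and below[v] != frozenset(members):
                total += tree.branch_length[v]
    return total
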