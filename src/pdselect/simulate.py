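"""Seeded synthetic trees and taxon-record tables.

The generator emulates the inputs of a diversity-driven target-selection
study: a large rooted binary tree over type strains (a stand-in for a curated
16S rRNA reference tree with ~8,000 leaves) and a per-strain status table
(genome project complete / ongoing / none, growability, phylum membership).

Trees are grown by the Yule pure-birth process: every extant lineage splits at
rate ``birth_rate``, branch lengths are the inter-event exposure times, and
growth starts from two crown lineages and stops at the event that would create
``n_leaves + 1`` lineages.  Under that convention the expected total branch
length is ``(n_leaves − 1) / birth_rate`` (the stage with ``j`` lineages lasts
``Exp(j·birth_rate)`` and exposes ``j`` branches, contributing ``1/birth_rate``
in expectation for each of the ``n − 1`` stages ``j = 2 … n``).

Phyla are assigned by cutting the tree into ``n_phyla`` monophyletic clades,
splitting the largest clade first, so per-phylum PD summaries remain
interpretable.  All randomness flows from the single integer ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PdSelectError
from .ledger import TaxonRecord
from .tree import PhyloTree

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "assign_records",
    "simulate_dataset",
    "records_from_phylum_counts",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the mid-2011 study conditions: a 8,029-leaf type-strain
    tree of which 13% carry a known genome project (7% with complete/draft
    sequence data, 6% ongoing), spread over 33 phyla.  ``frac_nongrowable``
    defaults to 0.10: no census of unculturable-at-scale type strains exists,
    and a ~10% failure-to-grow allowance is a realistic planning figure for
    collection-held strains.
    """

    n_leaves: int
    seed: int
    birth_rate: float = 1.0
    frac_sequenced: float = 0.07
    frac_ongoing: float = 0.06
    frac_nongrowable: float = 0.10
    n_phyla: int = 33

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise PdSelectError("n_leaves must be ≥ 2")
        if self.birth_rate <= 0:
            raise PdSelectError("birth_rate must be > 0")
        for name in ("frac_sequenced", "frac_ongoing", "frac_nongrowable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PdSelectError(f"{name} must be in [0, 1]")
        if self.frac_sequenced + self.frac_ongoing > 1.0:
            raise PdSelectError("frac_sequenced + frac_ongoing must be ≤ 1")
        if self.n_phyla < 1:
            raise PdSelectError("n_phyla must be ≥ 1")


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # distinct, reproducible streams per stage, all derived from one seed
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def simulate_yule_tree(spec: SimulationSpec) -> PhyloTree:
    """Grow a rooted binary Yule tree with ``spec.n_leaves`` leaves.

    Leaf labels are ``T000001 …`` in left-to-right tree order; the same spec
    and seed always produce the identical tree (byte-identical newick).
    """
    rng = _rng(spec, 0)
    n = spec.n_leaves
    lam = spec.birth_rate

    parent = [None, 0, 0]
    birth = [0.0, 0.0, 0.0]
    children: list = [[1, 2], [], []]
    active = [1, 2]  # extant lineages, candidates for the next split
    t = 0.0
    while True:
        j = len(active)
        t += rng.exponential(1.0 / (j * lam))
        if j == n:
            break
        idx = rng.integers(j)
        v = active[idx]
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([v, v])
        birth.extend([t, t])
        children[v] = [c1, c2]
        children.extend([[], []])
        active[idx] = c1
        active.append(c2)

    blen = [0.0] * len(parent)
    for v in range(1, len(parent)):
        end = birth[children[v][0]] if children[v] else t
        blen[v] = end - birth[v]

    # label leaves in deterministic left-to-right (preorder) order
    leaf_label: dict = {}
    stack = [0]
    while stack:
        v = stack.pop()
        if not children[v]:
            leaf_label[v] = f"T{len(leaf_label) + 1:06d}"
        else:
            stack.extend(reversed(children[v]))

    return PhyloTree(parent=parent, branch_length=blen, children=children, leaf_label=leaf_label)


def expected_yule_total_length(n_leaves: int, birth_rate: float) -> float:
    """Analytic expectation of the total branch length under the growth
    convention above: (n − 1) / birth_rate."""
    return (n_leaves - 1) / birth_rate


def _clade_partition(tree: PhyloTree, n_phyla: int) -> dict:
    """Cut the tree into ``n_phyla`` monophyletic groups, splitting the clade
    with the most leaves first; returns leaf node → phylum index."""
    n_leaf = [0] * tree.n_nodes
    for v in tree.postorder():
        n_leaf[v] = 1 if tree.is_leaf(v) else sum(n_leaf[c] for c in tree.children[v])

    clades = [tree.root]
    while len(clades) < n_phyla:
        splittable = [c for c in clades if not tree.is_leaf(c)]
        if not splittable:
            raise PdSelectError(
                f"cannot cut the tree into {n_phyla} clades: only "
                f"{len(clades)} leaves/clades available"
            )
        big = max(splittable, key=lambda c: (n_leaf[c], -c))
        clades.remove(big)
        clades.extend(tree.children[big])

    assignment: dict = {}
    for i, top in enumerate(sorted(clades)):
        stack = [top]
        while stack:
            v = stack.pop()
            if tree.is_leaf(v):
                assignment[v] = i
            else:
                stack.extend(tree.children[v])
    return assignment


def assign_records(tree: PhyloTree, spec: SimulationSpec) -> list:
    """Draw a taxon-record table for the tree's leaves.

    Every leaf is a type strain; genome status is complete with probability
    ``frac_sequenced``, ongoing with ``frac_ongoing``, otherwise none;
    growability fails with ``frac_nongrowable``.  Phyla are the clade cut.
    """
    if spec.n_phyla > tree.n_leaves:
        raise PdSelectError(
            f"n_phyla={spec.n_phyla} exceeds the number of leaves ({tree.n_leaves})"
        )
    rng = _rng(spec, 1)
    phylum_of = _clade_partition(tree, spec.n_phyla)
    width = len(str(spec.n_phyla))

    records = []
    for v in sorted(tree.leaf_label):
        label = tree.leaf_label[v]
        u = rng.random()
        if u < spec.frac_sequenced:
            status = "complete"
        elif u < spec.frac_sequenced + spec.frac_ongoing:
            status = "ongoing"
        else:
            status = "none"
        growable = rng.random() >= spec.frac_nongrowable
        records.append(
            TaxonRecord(
                taxon_name=label,
                phylum=f"P{phylum_of[v] + 1:0{width}d}",
                species_or_subspecies_id=f"sp-{label}",
                is_type_strain=True,
                genome_status=status,
                genome_is_type=status != "none",
                growable=growable,
                proposed=False,
            )
        )
    return records


def simulate_dataset(spec: SimulationSpec):
    """Convenience: ``(tree, records)`` for one spec."""
    tree = simulate_yule_tree(spec)
    return tree, assign_records(tree, spec)


def records_from_phylum_counts(counts, growable: bool = True) -> list:
    """Expand a per-phylum count table into a synthetic record list whose
    aggregation reproduces those counts exactly.

    ``counts`` is a DataFrame with columns phylum, type_strains,
    species_subsp, type_genomes, nontype_genomes, proposed (the packaged
    :func:`pdselect.datasets.phylum_counts_2011` table has this shape).  For
    each phylum the expansion creates one row per type strain (distinct
    species ids), extra homotypic-synonym rows for the species/subsp excess,
    genome projects on the first ``type_genomes`` type rows, non-type genome
    projects on additional strains of existing species, and ``proposed`` flags
    on type rows without a genome project.
    """
    records = []
    for row in counts.itertuples(index=False):
        ph = row.phylum
        ts, sp = int(row.type_strains), int(row.species_subsp)
        tg, ntg, prop = int(row.type_genomes), int(row.nontype_genomes), int(row.proposed)
        if not (tg <= ts <= sp and tg + prop <= ts):
            raise PdSelectError(f"phylum {ph!r}: inconsistent counts")
        for i in range(ts):
            has_genome = i < tg
            records.append(
                TaxonRecord(
                    taxon_name=f"{ph}-t{i + 1:05d}",
                    phylum=ph,
                    species_or_subspecies_id=f"{ph}-sp{i + 1:05d}",
                    is_type_strain=True,
                    genome_status="complete" if has_genome else "none",
                    genome_is_type=has_genome,
                    growable=growable,
                    proposed=tg <= i < tg + prop,
                )
            )
        for i in range(sp - ts):  # homotypic synonyms: extra names, no new strains
            records.append(
                TaxonRecord(
                    taxon_name=f"{ph}-syn{i + 1:05d}",
                    phylum=ph,
                    species_or_subspecies_id=f"{ph}-synsp{i + 1:05d}",
                    is_type_strain=False,
                    genome_status="none",
                    genome_is_type=False,
                    growable=growable,
                )
            )
        for i in range(ntg):  # sequenced non-type strains of existing species
            records.append(
                TaxonRecord(
                    taxon_name=f"{ph}-nt{i + 1:05d}",
                    phylum=ph,
                    species_or_subspecies_id=f"{ph}-sp{i + 1:05d}",
                    is_type_strain=False,
                    genome_status="complete",
                    genome_is_type=False,
                    growable=growable,
                )
            )
    return records
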