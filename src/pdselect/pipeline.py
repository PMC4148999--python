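"""End-to-end sequencing-target selection.

The pipeline joins a branch-length tree with a taxon-record table, splits the
leaves into three pools, and runs one greedy PD-maximizing pass:

* **preselected** — strains whose genome project is already registered
  (ongoing or complete).  Their diversity counts as covered, so they anchor
  the greedy baseline rather than being deleted from the tree: deletion would
  distort every marginal gain and the coverage denominator.
* **excluded** — strains failing the type-strain or growability requirement;
  they can never be picked but their branches still belong to the total tree
  PD that coverage fractions are measured against.
* **eligible** — everything else; the primary targets are the first
  ``n_primary`` greedy picks and the backup list is the continuation of the
  same run for ``n_backup`` further picks (backups are next-best scorers,
  meant as drop-in substitutes when a primary fails to yield DNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import SelectionError
from .ledger import TaxonRecord
from .pd import CoverageReport, SelectionResult, greedy_select, pd_coverage
from .tree import PhyloTree

__all__ = [
    "SelectionConfig",
    "JoinResult",
    "FilterResult",
    "PipelineResult",
    "join_tree_records",
    "filter_candidates",
    "run_selection",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of one selection run.

    Defaults are the classic study configuration: 1,000 primary targets plus
    685 backups, rooted PD, type strains only, growable strains only, and
    strains with ongoing or complete genome projects treated as covered.
    """

    n_primary: int = 1000
    n_backup: int = 685
    pd_mode: str = "rooted"
    require_type_strain: bool = True
    require_growable: bool = True
    exclude_statuses: frozenset = frozenset({"ongoing", "complete"})

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise SelectionError("n_primary must be ≥ 1")
        if self.n_backup < 0:
            raise SelectionError("n_backup must be ≥ 0")
        bad = set(self.exclude_statuses) - {"ongoing", "complete"}
        if bad:
            raise SelectionError(f"exclude_statuses may only contain ongoing/complete, got {bad}")


@dataclass
class JoinResult:
    matched: dict  # leaf label -> TaxonRecord
    unmatched_leaves: list
    unmatched_records: list


def join_tree_records(tree: PhyloTree, records: Sequence[TaxonRecord]) -> JoinResult:
    """Exact-string join (whitespace-trimmed) of leaf labels and record names.

    Non-joins are reported, never dropped: unmatched leaves keep contributing
    to total tree PD but cannot be selected; unmatched records are data-entry
    signals for the caller.
    """
    by_name: dict = {}
    for r in records:
        by_name.setdefault(r.taxon_name.strip(), r)
    matched = {}
    unmatched_leaves = []
    for label in sorted(tree.leaf_label.values()):
        key = label.strip()
        if key in by_name:
            matched[label] = by_name[key]
        else:
            unmatched_leaves.append(label)
    leaf_keys = {lab.strip() for lab in tree.leaf_label.values()}
    unmatched_records = sorted(name for name in by_name if name not in leaf_keys)
    return JoinResult(matched, unmatched_leaves, unmatched_records)


@dataclass
class FilterResult:
    eligible: set
    preselected: set
    excluded_detail: dict  # leaf label -> reason

    @property
    def excluded(self) -> set:
        return set(self.excluded_detail)


def filter_candidates(matched: Mapping[str, TaxonRecord], config: SelectionConfig) -> FilterResult:
    """Partition matched leaves into eligible / preselected / excluded.

    Already-sequenced strains take precedence (their PD is covered whatever
    their other flags); the remaining leaves must pass the type-strain and
    growability requirements to stay eligible.
    """
    if not matched:
        raise SelectionError("no matched leaves to filter")
    eligible: set = set()
    preselected: set = set()
    excluded: dict = {}
    for label, rec in matched.items():
        if rec.genome_status in config.exclude_statuses:
            preselected.add(label)
        elif config.require_type_strain and not rec.is_type_strain:
            excluded[label] = "not a type strain"
        elif config.require_growable and not rec.growable:
            excluded[label] = "non-growable"
        else:
            eligible.add(label)
    if not eligible:
        raise SelectionError("empty eligible set after filtering")
    return FilterResult(eligible=eligible, preselected=preselected, excluded_detail=excluded)


@dataclass
class PipelineResult:
    primary: SelectionResult
    backup: SelectionResult
    coverage: CoverageReport
    join: JoinResult
    filter: FilterResult
    config: SelectionConfig = field(default=None)


def run_selection(
    tree: PhyloTree,
    records: Sequence[TaxonRecord],
    config: SelectionConfig = SelectionConfig(),
) -> PipelineResult:
    """Join, filter, select primaries and backups, and report coverage.

    The backup list is the continuation of the primary greedy run, so the
    concatenation of the two equals a single greedy run of size
    ``n_primary + n_backup``.
    """
    join = join_tree_records(tree, records)
    filt = filter_candidates(join.matched, config)

    # unmatched leaves are never selectable but stay in the tree/denominator
    hard_excluded = filt.excluded | set(join.unmatched_leaves)
    k_total = config.n_primary + config.n_backup
    pool = len(filt.eligible)
    if k_total > pool:
        raise SelectionError(
            f"requested {k_total} targets but only {pool} eligible leaves "
            f"(shortfall of {k_total - pool})"
        )

    full = greedy_select(
        tree,
        k=k_total,
        preselected=filt.preselected,
        excluded=hard_excluded,
        mode=config.pd_mode,
    )
    primary = SelectionResult(
        steps=full.steps[: config.n_primary],
        preselected_pd=full.preselected_pd,
        mode=full.mode,
        total_pd=full.total_pd,
    )
    backup = SelectionResult(
        steps=full.steps[config.n_primary :],
        preselected_pd=primary.final_pd,
        mode=full.mode,
        total_pd=full.total_pd,
    )

    type_strains = {lab for lab, rec in join.matched.items() if rec.is_type_strain}
    named_sets = {
        "preselected": set(filt.preselected),
        "preselected+primary": set(filt.preselected) | set(primary.selected_taxa),
        "preselected+primary+backup": set(filt.preselected) | set(full.selected_taxa),
        "type_strains": type_strains,
    }
    coverage = pd_coverage(tree, named_sets, mode=config.pd_mode)
    return PipelineResult(
        primary=primary, backup=backup, coverage=coverage, join=join, filter=filt, config=config
    )
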