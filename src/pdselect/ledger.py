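"""Per-phylum bookkeeping of type strains, synonyms and genome projects.

A :class:`TaxonRecord` is one nomenclatural entry: a species or subspecies
name together with the strain that typifies it, its phylum, whether the row is
the type-strain entry itself or an additional name/strain attached to it
(homotypic synonyms make species/subspecies names outnumber type strains), the
genome-project status registered for the strain, and whether it can be grown
to the cell mass a sequencing project needs.

``summarize_by_phylum`` aggregates records into the classic per-phylum summary
table: type-strain and species/subspecies counts, percent synonyms, type and
non-type genome-sequence counts, genome coverage of the type strains, and the
number of proposed sequencing targets — plus a totals row recomputed from the
summed counts.

Counting rules
--------------
* type strains         — rows flagged ``is_type_strain``
* species/subsp.       — distinct ``species_or_subspecies_id`` values
* % synonyms           — 100 × (species/subsp − type strains) / species/subsp
* type genomes         — rows with a genome project where the sequenced strain
                         is the type strain
* non-type genomes     — rows with a genome project on a non-type strain
* coverage             — 100 × type genomes / type strains; for the totals row
                         a second, clearly labelled variant additionally counts
                         non-type genomes in the numerator (the two variants
                         genuinely differ and neither is silently preferred)

Percentages are kept at full precision and rounded half-up to one decimal only
for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .errors import RecordValidationError, SchemaError

__all__ = [
    "TaxonRecord",
    "PhylumSummary",
    "PhylumSummaryTable",
    "CandidatePool",
    "load_records",
    "write_records",
    "summarize_by_phylum",
    "candidate_pool_report",
    "round_half_up",
]

GENOME_STATUSES = ("none", "ongoing", "complete")

RECORD_COLUMNS = [
    "taxon_name",
    "phylum",
    "species_or_subspecies_id",
    "is_type_strain",
    "genome_status",
    "genome_is_type",
    "growable",
    "proposed",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 → 0.1), the convention of printed
    percentage tables; Python's built-in ``round`` is half-even."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TaxonRecord:
    taxon_name: str
    phylum: str
    species_or_subspecies_id: str
    is_type_strain: bool
    genome_status: str  # none | ongoing | complete
    genome_is_type: bool
    growable: bool
    proposed: bool = False

    def __post_init__(self) -> None:
        if not self.phylum:
            raise RecordValidationError(f"record {self.taxon_name!r}: empty phylum")
        if self.genome_status not in GENOME_STATUSES:
            raise RecordValidationError(
                f"record {self.taxon_name!r}: unknown genome_status "
                f"{self.genome_status!r} (expected one of {GENOME_STATUSES})"
            )
        if self.genome_is_type and self.genome_status == "none":
            raise RecordValidationError(
                f"record {self.taxon_name!r}: genome_is_type set but genome_status is 'none'"
            )

    @property
    def has_genome_project(self) -> bool:
        return self.genome_status != "none"


def _parse_bool(token: str, column: str, row: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise RecordValidationError(f"row {row}: column {column!r}: invalid boolean {token!r}")


def load_records(path) -> list:
    """Read a taxon-record TSV; every row is validated and errors carry the
    1-based data row number."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        status = getattr(row, "genome_status").strip().lower()
        if status not in GENOME_STATUSES:
            raise RecordValidationError(
                f"row {i}: unknown genome_status token {getattr(row, 'genome_status')!r}"
            )
        try:
            records.append(
                TaxonRecord(
                    taxon_name=getattr(row, "taxon_name").strip(),
                    phylum=getattr(row, "phylum").strip(),
                    species_or_subspecies_id=getattr(row, "species_or_subspecies_id").strip(),
                    is_type_strain=_parse_bool(getattr(row, "is_type_strain"), "is_type_strain", i),
                    genome_status=status,
                    genome_is_type=_parse_bool(getattr(row, "genome_is_type"), "genome_is_type", i),
                    growable=_parse_bool(getattr(row, "growable"), "growable", i),
                    proposed=_parse_bool(getattr(row, "proposed"), "proposed", i),
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"row {i}: {exc}") from None
    return records


def write_records(path, records: Iterable[TaxonRecord]) -> None:
    rows = [
        {
            "taxon_name": r.taxon_name,
            "phylum": r.phylum,
            "species_or_subspecies_id": r.species_or_subspecies_id,
            "is_type_strain": str(r.is_type_strain).lower(),
            "genome_status": r.genome_status,
            "genome_is_type": str(r.genome_is_type).lower(),
            "growable": str(r.growable).lower(),
            "proposed": str(r.proposed).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class PhylumSummary:
    """One summary-table row; percentages are stored at full precision."""

    phylum: str
    n_type_strains: int
    n_species_subsp: int
    pct_synonyms: float
    n_type_genomes: int
    n_nontype_genomes: int
    coverage_pct: float
    n_proposed: int


@dataclass
class PhylumSummaryTable:
    rows: list
    totals: PhylumSummary
    totals_coverage_incl_nontype_pct: float

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Tabular form in the fixed column order, totals row last.

        ``rounded=True`` applies the one-decimal half-up presentation
        rounding; the default keeps full precision for machine output.
        """
        data = []
        for s in [*self.rows, self.totals]:
            data.append(
                {
                    "phylum": s.phylum,
                    "type_strains": s.n_type_strains,
                    "species_subsp": s.n_species_subsp,
                    "pct_synonyms": round_half_up(s.pct_synonyms) if rounded else s.pct_synonyms,
                    "type_genomes": s.n_type_genomes,
                    "nontype_genomes": s.n_nontype_genomes,
                    "coverage_pct": round_half_up(s.coverage_pct) if rounded else s.coverage_pct,
                    "proposed": s.n_proposed,
                }
            )
        return pd.DataFrame(data)

    def to_json_obj(self) -> dict:
        obj = self.to_frame().to_dict(orient="records")
        return {
            "phyla": obj[:-1],
            "totals": obj[-1],
            "totals_coverage_incl_nontype_pct": self.totals_coverage_incl_nontype_pct,
        }


def _summarize_group(phylum: str, records: Sequence[TaxonRecord]) -> PhylumSummary:
    n_type = sum(r.is_type_strain for r in records)
    n_sp = len({r.species_or_subspecies_id for r in records})
    n_tg = sum(r.has_genome_project and r.genome_is_type for r in records)
    n_ntg = sum(r.has_genome_project and not r.genome_is_type for r in records)
    n_prop = sum(r.proposed for r in records)
    pct_syn = 100.0 * (n_sp - n_type) / n_sp if n_sp > 0 else 0.0
    cov = 100.0 * n_tg / n_type if n_type > 0 else 0.0
    return PhylumSummary(phylum, n_type, n_sp, pct_syn, n_tg, n_ntg, cov, n_prop)


def summarize_by_phylum(records: Sequence[TaxonRecord]) -> PhylumSummaryTable:
    """Aggregate records into per-phylum rows (input first-occurrence order)
    plus a totals row whose percentages are recomputed from the summed counts."""
    if not records:
        raise RecordValidationError("no records to summarize")
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(r.phylum, []).append(r)
    rows = [_summarize_group(ph, rs) for ph, rs in groups.items()]

    t_type = sum(s.n_type_strains for s in rows)
    t_sp = sum(s.n_species_subsp for s in rows)
    t_tg = sum(s.n_type_genomes for s in rows)
    t_ntg = sum(s.n_nontype_genomes for s in rows)
    t_prop = sum(s.n_proposed for s in rows)
    totals = PhylumSummary(
        phylum="Total",
        n_type_strains=t_type,
        n_species_subsp=t_sp,
        pct_synonyms=100.0 * (t_sp - t_type) / t_sp if t_sp > 0 else 0.0,
        n_type_genomes=t_tg,
        n_nontype_genomes=t_ntg,
        coverage_pct=100.0 * t_tg / t_type if t_type > 0 else 0.0,
        n_proposed=t_prop,
    )
    incl = 100.0 * (t_tg + t_ntg) / t_type if t_type > 0 else 0.0
    return PhylumSummaryTable(rows=rows, totals=totals, totals_coverage_incl_nontype_pct=incl)


@dataclass
class CandidatePool:
    """Partition of the type strains by genome-project existence."""

    n_type_strains: int
    n_with_project: int
    n_without_project: int

    @property
    def pct_with_project(self) -> float:
        if self.n_type_strains == 0:
            return 0.0
        return 100.0 * self.n_with_project / self.n_type_strains

    @property
    def pct_with_project_rounded(self) -> float:
        return round_half_up(self.pct_with_project)


def candidate_pool_report(records: Sequence[TaxonRecord]) -> CandidatePool:
    """How much of the type-strain pool already has a genome project of any
    status — the headline candidate-pool fraction."""
    types = [r for r in records if r.is_type_strain]
    with_proj = sum(r.has_genome_project for r in types)
    return CandidatePool(
        n_type_strains=len(types),
        n_with_project=with_proj,
        n_without_project=len(types) - with_proj,
    )
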