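"""Shared record factory for pipeline/CLI tests."""

from pdselect import TaxonRecord


def make_record(name: str, status: str = "none", growable: bool = True,
                type_strain: bool = True, proposed: bool = False) -> TaxonRecord:
    return TaxonRecord(
        taxon_name=name,
        phylum="P1",
        species_or_subspecies_id=f"sp-{name.strip()}",
        is_type_strain=type_strain,
        genome_status=status,
        genome_is_type=status != "none" and type_strain,
        growable=growable,
        proposed=proposed,
    )
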