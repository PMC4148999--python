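"""Small packaged reference tables."""

from importlib import resources

import pandas as pd

__all__ = ["phylum_counts_2011"]


def phylum_counts_2011() -> pd.DataFrame:
    """Per-phylum counts of bacterial/archaeal type strains, species and
    subspecies names, registered genome-sequencing projects (type and
    non-type strains) and proposed sequencing targets, as of mid-2011
    (NamesforLife nomenclature export joined with GOLD project statuses).

    Columns: phylum, type_strains, species_subsp, type_genomes,
    nontype_genomes, proposed.  Only raw counts are stored; every derived
    quantity (percent synonyms, coverage) is recomputed by the ledger.
    """
    with resources.files(__package__).joinpath("phylum_counts_2011.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
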