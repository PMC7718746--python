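"""Bundled reference datasets (plain-text transcriptions of published
phenotype-scoring tables and the de-repressed gene table)."""

from importlib import resources

import pandas as pd

from ..phenotype import PhenotypeTable


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_adult_eversion() -> PhenotypeTable:
    """Adult eversion outcomes per driver/RNAi genotype (percentages)."""
    df = _read("adult_eversion.tsv").set_index("genotype")
    return PhenotypeTable.from_percentages(df.drop(columns="n"), df["n"])


def load_rescue_eversion() -> PhenotypeTable:
    """Eversion outcomes for knockdown-rescue genotypes (percentages)."""
    df = _read("rescue_eversion.tsv").set_index("genotype")
    return PhenotypeTable.from_percentages(df.drop(columns="n"), df["n"])


def load_disc_culture() -> pd.DataFrame:
    """Ex-vivo disc culture outcomes: assay, genotype, success %, n."""
    return _read("disc_culture.tsv")


def load_derepressed_genes() -> pd.DataFrame:
    """De-repressed gene table: per-locus log2 ratio (best isoform) and FDR."""
    return _read("derepressed_genes.tsv")
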