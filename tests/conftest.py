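import numpy as np
import pandas as pd
import pytest

from ascgenotype import (
    GermlineAllele,
    GermlineReference,
    KeyTable,
    RearrangementTable,
    cluster_reference,
    collapse_identical,
)
from ascgenotype.simulate import SimulationConfig, make_toy_germline


def make_ref(seqs: dict[str, str], gapped: bool = True) -> GermlineReference:
    """Small in-memory germline reference from name -> sequence."""
    return GermlineReference(
        alleles=[
            GermlineAllele(
                iuis_name=n,
                sequence=s.replace(".", ""),
                gapped_sequence=s if gapped else None,
                functionality="functional",
            )
            for n, s in seqs.items()
        ]
    )


def make_table(rows: list[dict], subject_id: str = "subj") -> RearrangementTable:
    df = pd.DataFrame(rows)
    if "sequence_id" not in df.columns:
        df.insert(0, "sequence_id", [f"S{i}" for i in range(len(df))])
    return RearrangementTable(df=df, subject_id=subject_id)


@pytest.fixture(scope="session")
def toy_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7, n_genes=4, alleles_per_gene=3,
                            duplicated_allele_pairs=1, n_sequences=2000)


@pytest.fixture(scope="session")
def toy_germline(toy_cfg):
    return make_toy_germline(toy_cfg)


@pytest.fixture(scope="session")
def toy_asc(toy_germline):
    """Collapsed + clustered toy reference with its key table."""
    unique, mapping = collapse_identical(toy_germline)
    asc_ref, tree = cluster_reference(unique, collapse_mapping=mapping)
    return asc_ref, tree, KeyTable.from_reference(asc_ref), mapping
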