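import numpy as np
import pandas as pd
import pytest

from chemgen import (
    CellLineAnnotation,
    Dataset,
    IC50Matrix,
    SyntheticConfig,
    assemble_instances,
    generate_dataset,
)
from chemgen.containers import DrugDescriptorTable, GenomicFeatureTable


def make_annotation(cell_id, genes, msi="stable", cnv=None, seq=None, tissue="T0"):
    """Annotation helper: all-wildtype unless overridden per gene."""
    cnv = cnv or {}
    seq = seq or {}
    return CellLineAnnotation(
        cell_line_id=cell_id,
        msi_status=msi,
        copy_number={g: cnv.get(g, "wildtype") for g in genes},
        sequence_variant={g: seq.get(g, "wildtype") for g in genes},
        tissue=tissue,
    )


@pytest.fixture
def toy_dataset():
    """3 cell lines x 2 drugs with 4 observed IC50s and tiny feature tables."""
    ic50 = IC50Matrix(
        pd.DataFrame(
            [[0.5, np.nan], [2.0, 8.0], [np.nan, 0.125]],
            index=["C1", "C2", "C3"],
            columns=["D1", "D2"],
        )
    )
    genomic = GenomicFeatureTable(
        pd.DataFrame(
            {"cnv:G1": [0, -1, 1], "seq:G1": [1, 0, 0], "msi": [0, 1, 0]},
            index=["C1", "C2", "C3"],
            dtype=float,
        )
    )
    descriptors = DrugDescriptorTable(
        pd.DataFrame(
            {"mw": [300.0, 450.0], "logp": [1.2, -0.4], "fp1": [0.0, 1.0]},
            index=["D1", "D2"],
        )
    )
    tissues = {"C1": "lung", "C2": "lung", "C3": "breast"}
    return Dataset(ic50=ic50, genomic=genomic, descriptors=descriptors, tissues=tissues)


@pytest.fixture(scope="session")
def default_synthetic():
    """One draw of the default synthetic screen plus its ground truth."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_instances(default_synthetic):
    dataset, _ = default_synthetic
    return assemble_instances(dataset)
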