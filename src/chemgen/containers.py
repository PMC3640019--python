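"""Domain containers for the drug-sensitivity imputation pipeline.

The screen's response data live in a sparse cell-line x drug IC50 matrix
(raw concentrations in uM, missing entries allowed).  Cell lines carry a
categorical genomic annotation (microsatellite status, per-gene copy-number
category, per-gene sequence-variant flag, tissue label) which is later encoded
into a {-1, 0, 1} feature matrix; drugs carry a numeric chemical-descriptor
table.  All containers validate their invariants on construction and keep a
canonical (sorted-id) orientation so downstream results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MSI_CATEGORIES",
    "CNV_CATEGORIES",
    "SEQ_CATEGORIES",
    "CellLineAnnotation",
    "IC50Matrix",
    "GenomicFeatureTable",
    "DrugDescriptorTable",
    "Dataset",
]

MSI_CATEGORIES = ("stable", "unstable", "missing")
CNV_CATEGORIES = ("deletion", "wildtype", "amplification", "missing")
SEQ_CATEGORIES = ("wildtype", "variant", "missing")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass(frozen=True)
class CellLineAnnotation:
    """Raw genomic state of one cell line.

    ``copy_number`` and ``sequence_variant`` map every gene of the panel to a
    category; the gene set must be identical across the cohort.
    """

    cell_line_id: str
    msi_status: str
    copy_number: Mapping[str, str]
    sequence_variant: Mapping[str, str]
    tissue: str = "unknown"

    def __post_init__(self) -> None:
        if self.msi_status not in MSI_CATEGORIES:
            raise ValidationError(
                f"{self.cell_line_id}: msi_status {self.msi_status!r} not in {MSI_CATEGORIES}"
            )
        for gene, cat in self.copy_number.items():
            if cat not in CNV_CATEGORIES:
                raise ValidationError(
                    f"{self.cell_line_id}/{gene}: copy-number category {cat!r} not in {CNV_CATEGORIES}"
                )
        for gene, cat in self.sequence_variant.items():
            if cat not in SEQ_CATEGORIES:
                raise ValidationError(
                    f"{self.cell_line_id}/{gene}: sequence-variant category {cat!r} not in {SEQ_CATEGORIES}"
                )
        if set(self.copy_number) != set(self.sequence_variant):
            raise ValidationError(
                f"{self.cell_line_id}: copy-number and sequence-variant gene sets differ"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.copy_number))

    def n_missing_slots(self) -> int:
        """Count missing encoded feature slots (per-gene cnv + per-gene seq + msi)."""
        n = sum(1 for c in self.copy_number.values() if c == "missing")
        n += sum(1 for c in self.sequence_variant.values() if c == "missing")
        n += 1 if self.msi_status == "missing" else 0
        return n


def _check_unique_sorted(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} ids: {dupes}")
    return sorted(ids)


@dataclass
class IC50Matrix:
    """Sparse cell-line x drug response matrix in raw concentration units (uM).

    Stored as a DataFrame with cell lines on rows, drugs on columns, and NaN
    for unmeasured combinations.  Every stored value must be strictly positive.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        rows = _check_unique_sorted(df.index.astype(str), "cell line")
        cols = _check_unique_sorted(df.columns.astype(str), "drug")
        df = df.astype(float).reindex(index=rows, columns=cols)
        bad = df.le(0.0)
        if bad.any().any():
            cell, drug = next(
                (c, d) for c in df.index for d in df.columns if bad.at[c, d]
            )
            raise ValidationError(
                f"IC50 for cell line {cell!r}, drug {drug!r} is {df.at[cell, drug]}; "
                "has to be a positive number greater than zero"
            )
        self.values = df

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().sum().sum())

    @property
    def fill_fraction(self) -> float:
        return self.n_observed / self.values.size

    def observed_entries(self) -> list[tuple[str, str]]:
        """All measured (cell line, drug) pairs, in canonical row-major order."""
        mask = self.values.notna()
        return [
            (c, d)
            for c in self.values.index
            for d in self.values.columns
            if mask.at[c, d]
        ]

    def subset_cells(self, cells: Iterable[str]) -> "IC50Matrix":
        keep = sorted(set(cells) & set(self.values.index))
        return IC50Matrix(self.values.loc[keep])


@dataclass
class GenomicFeatureTable:
    """Encoded {-1, 0, 1} genomic features, cell lines on rows.

    Feature ids follow the ``cnv:<gene>`` / ``seq:<gene>`` / ``msi`` naming.
    After curation no missing values remain; copy-number features take values
    in {-1, 0, 1} and sequence/msi features in {0, 1}.
    """

    values: pd.DataFrame
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        rows = _check_unique_sorted(df.index.astype(str), "cell line")
        df = df.reindex(index=rows)
        if df.isna().any().any():
            offenders = sorted(df.columns[df.isna().any()])
            raise ValidationError(f"genomic features with missing values: {offenders}")
        allowed = {-1.0, 0.0, 1.0}
        vals = set(np.unique(df.to_numpy()))
        if not vals <= allowed:
            raise ValidationError(f"genomic feature values outside {{-1,0,1}}: {sorted(vals - allowed)}")
        for col in df.columns:
            if not str(col).startswith("cnv:") and df[col].min() < 0:
                raise ValidationError(f"non-cnv feature {col!r} takes value -1")
        self.values = df

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DrugDescriptorTable:
    """Filtered chemical-descriptor matrix, drugs on rows.

    Holds continuous physicochemical descriptors and 0/1 fingerprint bits; no
    missing values and no column constant across all drugs.
    """

    values: pd.DataFrame
    dropped_missing: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        rows = _check_unique_sorted(df.index.astype(str), "drug")
        df = df.reindex(index=rows)
        if not np.isfinite(df.to_numpy()).all():
            offenders = sorted(df.columns[~np.isfinite(df).all()])
            raise ValidationError(f"descriptors with missing/non-finite values: {offenders}")
        if len(df) > 1:
            constant = sorted(df.columns[(df.nunique() <= 1)])
            if constant:
                raise ValidationError(f"descriptors constant across all drugs: {constant}")
        self.values = df

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dataset:
    """Validated bundle of response matrix, genomic features, descriptors and tissues.

    Every observed IC50 entry is guaranteed to have both a genomic feature row
    (its cell line) and a descriptor row (its drug).
    """

    ic50: IC50Matrix
    genomic: GenomicFeatureTable
    descriptors: DrugDescriptorTable
    tissues: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells_resp = set(self.ic50.cell_line_ids)
        cells_geno = set(self.genomic.cell_line_ids)
        drugs_resp = set(self.ic50.drug_ids)
        drugs_desc = set(self.descriptors.drug_ids)
        missing_cells = sorted(cells_resp - cells_geno)
        if missing_cells:
            raise ValidationError(
                f"cell lines in IC50 matrix lacking genomic features: {missing_cells}"
            )
        missing_drugs = sorted(drugs_resp - drugs_desc)
        if missing_drugs:
            raise ValidationError(
                f"drugs in IC50 matrix lacking chemical descriptors: {missing_drugs}"
            )
        if not self.tissues:
            self.tissues = {c: "unknown" for c in self.ic50.cell_line_ids}
        missing_tissue = sorted(cells_resp - set(self.tissues))
        if missing_tissue:
            raise ValidationError(f"cell lines without tissue label: {missing_tissue}")

    @property
    def n_cells(self) -> int:
        return len(self.ic50.cell_line_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.ic50.drug_ids)

    @property
    def n_observed(self) -> int:
        return self.ic50.n_observed
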