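"""Feature engineering: genomic encoding, table filtering, response normalization.

The genomic annotation of each cell line is encoded into ternary feature slots
in a fixed order -- one copy-number slot per gene (amplification -> +1,
wild type -> 0, deletion -> -1), one sequence-variant slot per gene (any
protein-changing variant -> 1), and a single microsatellite-instability slot
(unstable -> 1).  A panel of G genes therefore yields 2*G + 1 slots.  Slots
missing for any cell line of the cohort are removed conservatively, as are
chemical descriptors that are missing for any drug or constant across drugs.

Because the regression network ends in a sigmoid unit, raw IC50 concentrations
(not their logarithms) are mapped into (0, 1) with a logistic curve

    f(x) = 1 / (1 + (x / m) ** (-k)),

where ``m`` is the midpoint concentration (f(m) = 0.5, default 1 uM) and ``k``
the slope.  The map is strictly increasing on (0, inf) and exactly invertible,
so predictions in normalized space convert back to concentrations and to the
log10 IC50 scale used for all reported metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CellLineAnnotation,
    Dataset,
    DrugDescriptorTable,
    GenomicFeatureTable,
    ValidationError,
)

__all__ = [
    "LogisticNormalizer",
    "InstanceSet",
    "curate_cell_lines",
    "encode_genomic_profile",
    "encode_cohort",
    "filter_genomic_features",
    "filter_chemical_features",
    "log10_ic50",
    "assemble_instances",
    "categorize_copy_number",
]

#: copies above which a gene counts as amplified; 0 copies is a deletion
AMPLIFICATION_COPIES = 7


def categorize_copy_number(copies: float) -> str:
    """Map a raw copy number to its category (deletion / wildtype / amplification)."""
    if np.isnan(copies):
        return "missing"
    if copies < 0:
        raise ValidationError(f"negative copy number {copies}")
    if copies == 0:
        return "deletion"
    if copies > AMPLIFICATION_COPIES:
        return "amplification"
    return "wildtype"


def curate_cell_lines(
    annotations: Iterable[CellLineAnnotation], max_missing_features: int = 15
) -> list[CellLineAnnotation]:
    """Drop cell lines with more than ``max_missing_features`` missing feature slots.

    Missingness is counted over the 2*G + 1 encoded slots (per-gene copy number,
    per-gene sequence variant, microsatellite status).  Idempotent and
    order-independent; raises if no cell line survives.
    """
    if max_missing_features < 0:
        raise ValueError("max_missing_features must be >= 0")
    kept = [a for a in annotations if a.n_missing_slots() <= max_missing_features]
    if not kept:
        raise ValidationError("curation removed every cell line")
    return kept


_CNV_CODE = {"deletion": -1.0, "wildtype": 0.0, "amplification": 1.0, "missing": np.nan}
_SEQ_CODE = {"wildtype": 0.0, "variant": 1.0, "missing": np.nan}
_MSI_CODE = {"stable": 0.0, "unstable": 1.0, "missing": np.nan}


def encode_genomic_profile(
    annotation: CellLineAnnotation, gene_list: Sequence[str]
) -> pd.Series:
    """Encode one cell line into its 2*G + 1 raw feature slots.

    Slot order is fixed: all copy-number slots (gene_list order), then all
    sequence-variant slots, then the msi slot.  Missing annotation states are
    encoded as NaN and resolved by :func:`filter_genomic_features`.
    """
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    absent = [g for g in gene_list if g not in annotation.copy_number]
    if absent:
        raise ValidationError(
            f"{annotation.cell_line_id}: genes absent from annotation schema: {absent}"
        )
    index = (
        [f"cnv:{g}" for g in gene_list]
        + [f"seq:{g}" for g in gene_list]
        + ["msi"]
    )
    values = (
        [_CNV_CODE[annotation.copy_number[g]] for g in gene_list]
        + [_SEQ_CODE[annotation.sequence_variant[g]] for g in gene_list]
        + [_MSI_CODE[annotation.msi_status]]
    )
    return pd.Series(values, index=index, name=annotation.cell_line_id, dtype=float)


def encode_cohort(
    annotations: Iterable[CellLineAnnotation], gene_list: Sequence[str] | None = None
) -> pd.DataFrame:
    """Raw slot matrix (cells x 2*G+1 slots, NaN where the annotation is missing)."""
    annotations = list(annotations)
    if not annotations:
        raise ValidationError("empty cohort")
    if gene_list is None:
        gene_list = annotations[0].genes
    rows = [encode_genomic_profile(a, gene_list) for a in annotations]
    return pd.DataFrame(rows).sort_index()


def filter_genomic_features(raw_slots: pd.DataFrame) -> GenomicFeatureTable:
    """Keep exactly the feature slots with no missing value across the cohort."""
    missing = raw_slots.isna().any()
    dropped = sorted(raw_slots.columns[missing])
    kept = raw_slots.loc[:, ~missing]
    if kept.shape[1] == 0:
        raise ValidationError("every genomic feature slot has a missing value")
    return GenomicFeatureTable(kept, dropped_features=dropped)


def filter_chemical_features(descriptors: pd.DataFrame) -> DrugDescriptorTable:
    """Apply the universality then constancy filters to a raw descriptor table.

    A descriptor missing (NaN / non-finite) for any drug is dropped first; a
    descriptor with the same value across all remaining drugs is dropped next.
    """
    df = descriptors.astype(float)
    finite = df.apply(np.isfinite).all()
    dropped_missing = sorted(df.columns[~finite])
    df = df.loc[:, finite]
    if len(df) > 1:
        constant = df.nunique() <= 1
    else:
        constant = pd.Series(False, index=df.columns)
    dropped_constant = sorted(df.columns[constant])
    df = df.loc[:, ~constant]
    if df.shape[1] == 0:
        raise ValidationError("no chemical descriptor survived filtering")
    return DrugDescriptorTable(
        df, dropped_missing=dropped_missing, dropped_constant=dropped_constant
    )


@dataclass(frozen=True)
class LogisticNormalizer:
    """Invertible logistic map between raw IC50 concentrations and (0, 1).

    Parameters
    ----------
    midpoint_um:
        Concentration mapped to 0.5.
    slope:
        Steepness; the map is f(x) = 1 / (1 + (x/midpoint)**(-slope)), i.e. a
        standard logistic applied to slope * ln(x / midpoint).
    """

    midpoint_um: float = 1.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.midpoint_um <= 0 or self.slope <= 0:
            raise ValueError("midpoint_um and slope must be positive")

    def normalize(self, ic50_um):
        x = np.asarray(ic50_um, dtype=float)
        if np.any(x <= 0):
            raise ValidationError(
                "IC50 has to be a positive number greater than zero"
            )
        out = 1.0 / (1.0 + (x / self.midpoint_um) ** (-self.slope))
        return out if out.ndim else float(out)

    def denormalize(self, y):
        y = np.asarray(y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValidationError("normalized response must lie strictly inside (0, 1)")
        out = self.midpoint_um * (y / (1.0 - y)) ** (1.0 / self.slope)
        return out if out.ndim else float(out)

    # sklearn-flavoured aliases so the normalizer slots into pipelines
    def transform(self, X):
        return self.normalize(X)

    def inverse_transform(self, X):
        return self.denormalize(X)


def log10_ic50(ic50_um):
    """Base-10 logarithm of a (strictly positive) raw IC50."""
    x = np.asarray(ic50_um, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("IC50 has to be a positive number greater than zero")
    out = np.log10(x)
    return out if out.ndim else float(out)


@dataclass
class InstanceSet:
    """Vectorized model instances: one row per observed (cell line, drug) entry.

    ``X`` concatenates [genomic features | chemical descriptors]; ``y`` is the
    normalized response in (0, 1) and ``log10`` the base-10 log of the raw
    IC50, the scale on which performance is reported.
    """

    cells: np.ndarray  # (n,) object/str
    drugs: np.ndarray
    X: np.ndarray  # (n, g + c) float
    y: np.ndarray  # (n,) normalized target in (0, 1)
    log10: np.ndarray  # (n,) log10 raw IC50
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.y)

    def select(self, idx) -> "InstanceSet":
        idx = np.asarray(idx)
        return InstanceSet(
            self.cells[idx], self.drugs[idx], self.X[idx], self.y[idx],
            self.log10[idx], self.feature_names,
        )

    def index_of(self, entries: Iterable[tuple[str, str]]) -> np.ndarray:
        lookup = {(c, d): i for i, (c, d) in enumerate(zip(self.cells, self.drugs))}
        try:
            return np.array([lookup[e] for e in entries], dtype=int)
        except KeyError as err:  # pragma: no cover - defensive
            raise KeyError(f"entry {err.args[0]} has no assembled instance") from None


def assemble_instances(
    dataset: Dataset, normalizer: LogisticNormalizer | None = None
) -> InstanceSet:
    """Build one training instance per observed IC50 entry.

    Feature vectors concatenate the cell line's genomic features with the
    drug's chemical descriptors in the declared column orders; the result is
    independent of input row ordering because both tables are kept in
    canonical sorted-id orientation.
    """
    normalizer = normalizer or LogisticNormalizer()
    entries = dataset.ic50.observed_entries()
    feature_names = list(dataset.genomic.feature_ids) + list(
        dataset.descriptors.descriptor_ids
    )
    g = dataset.genomic.values
    d = dataset.descriptors.values
    cells = np.array([c for c, _ in entries], dtype=object)
    drugs = np.array([dr for _, dr in entries], dtype=object)
    n = len(entries)
    X = np.empty((n, g.shape[1] + d.shape[1]))
    if n:
        cell_rows = g.index.get_indexer(cells)
        drug_rows = d.index.get_indexer(drugs)
        X[:, : g.shape[1]] = g.to_numpy()[cell_rows]
        X[:, g.shape[1]:] = d.to_numpy()[drug_rows]
        raw = np.array([dataset.ic50.values.at[c, dr] for c, dr in entries])
    else:
        raw = np.empty(0)
    y = normalizer.normalize(raw) if n else np.empty(0)
    lg = log10_ic50(raw) if n else np.empty(0)
    return InstanceSet(cells, drugs, X, np.atleast_1d(y), np.atleast_1d(lg), feature_names)
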