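"""Delimited-file readers and writers.

All tables are comma-separated with a header row and the id in the first
column.  The IC50 matrix has cell lines on rows and drugs on columns; missing
entries may be written as an empty field or as ``NA`` (``NA`` is written).
The genomic table is accepted in two forms: an *annotation* table with
categorical tokens (msi ``stable``/``unstable``, per-gene ``cnv:<gene>``
columns holding ``deletion``/``wildtype``/``amplification`` or raw copy
counts, per-gene ``seq:<gene>`` columns holding ``wildtype``/``variant``, and
an optional ``tissue`` column), or an already *encoded* numeric table of
{-1, 0, 1} slots.  Ids are opaque, case-sensitive strings; sorted order
defines the canonical matrix orientation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CellLineAnnotation, Dataset, IC50Matrix, ValidationError
from .features import (
    LogisticNormalizer,
    categorize_copy_number,
    curate_cell_lines,
    encode_cohort,
    filter_chemical_features,
    filter_genomic_features,
)

__all__ = [
    "load_ic50_matrix",
    "load_genomic_table",
    "load_dataset",
    "save_predictions",
    "load_predictions",
    "read_smiles",
    "write_dataset_csvs",
]

logger = logging.getLogger("chemgen")

_NA_TOKENS = ("", "NA", "NaN", "nan")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=list(_NA_TOKENS), keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_ic50_matrix(path) -> IC50Matrix:
    df = _read_csv(path)
    try:
        return IC50Matrix(df)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def _cnv_token(tok) -> str:
    if pd.isna(tok):
        return "missing"
    s = str(tok).strip()
    try:
        return categorize_copy_number(float(s))
    except ValueError:
        return s


def _seq_token(tok) -> str:
    return "missing" if pd.isna(tok) else str(tok).strip()


def load_genomic_table(path) -> tuple[list[CellLineAnnotation] | None, pd.DataFrame | None, dict[str, str]]:
    """Read the genomic CSV; returns (annotations, encoded_slots, tissues).

    Exactly one of ``annotations`` / ``encoded_slots`` is non-None depending on
    whether the file holds categorical tokens or numeric slots.
    """
    df = _read_csv(path)
    tissues: dict[str, str] = {}
    if "tissue" in df.columns:
        tissues = {c: str(t) for c, t in df["tissue"].items() if not pd.isna(t)}
        df = df.drop(columns=["tissue"])
    if "msi" not in df.columns:
        raise ValidationError(f"{path}: genomic table lacks an 'msi' column")
    msi_numeric = pd.to_numeric(df["msi"], errors="coerce").notna() | df["msi"].isna()
    if msi_numeric.all():
        # encoded slot matrix
        return None, df.apply(pd.to_numeric, errors="raise"), tissues
    cnv_cols = [c for c in df.columns if c.startswith("cnv:")]
    seq_cols = [c for c in df.columns if c.startswith("seq:")]
    genes_cnv = sorted(c.split(":", 1)[1] for c in cnv_cols)
    genes_seq = sorted(c.split(":", 1)[1] for c in seq_cols)
    if genes_cnv != genes_seq:
        raise ValidationError(f"{path}: cnv and seq gene sets differ")
    annotations = []
    for cell, row in df.iterrows():
        msi = "missing" if pd.isna(row["msi"]) else str(row["msi"]).strip()
        annotations.append(
            CellLineAnnotation(
                cell_line_id=str(cell),
                msi_status=msi,
                copy_number={g: _cnv_token(row[f"cnv:{g}"]) for g in genes_cnv},
                sequence_variant={g: _seq_token(row[f"seq:{g}"]) for g in genes_cnv},
                tissue=tissues.get(str(cell), "unknown"),
            )
        )
    return annotations, None, tissues


def load_dataset(
    ic50_path,
    genomic_path,
    descriptor_path,
    tissue_path=None,
    *,
    max_missing_features: int = 15,
) -> Dataset:
    """Load, curate and validate the three input tables into a :class:`Dataset`.

    Cell lines with more than ``max_missing_features`` missing genomic feature
    slots are removed (together with their IC50 rows); feature slots missing
    for any retained cell line and chemical descriptors that are missing for
    any drug or constant across drugs are dropped.  A cell line or drug with
    responses but no corresponding genomic/descriptor row is an error.
    """
    ic50 = load_ic50_matrix(ic50_path)
    annotations, encoded, tissues = load_genomic_table(genomic_path)

    if annotations is not None:
        kept = curate_cell_lines(annotations, max_missing_features)
        dropped = sorted({a.cell_line_id for a in annotations} - {a.cell_line_id for a in kept})
        slots = encode_cohort(kept)
    else:
        n_missing = encoded.isna().sum(axis=1)
        keep_mask = n_missing <= max_missing_features
        dropped = sorted(encoded.index[~keep_mask])
        slots = encoded.loc[keep_mask]
        if slots.empty:
            raise ValidationError("curation removed every cell line")
    if dropped:
        logger.info("curation dropped %d cell line(s): %s", len(dropped), dropped)

    genomic_cells = set(slots.index)
    unknown_cells = sorted(set(ic50.cell_line_ids) - genomic_cells - set(dropped))
    if unknown_cells:
        raise ValidationError(
            f"cell lines in IC50 matrix absent from genomic table: {unknown_cells}"
        )
    ic50 = ic50.subset_cells(genomic_cells)
    slots = slots.loc[sorted(set(ic50.cell_line_ids))]
    genomic = filter_genomic_features(slots)

    descriptors_raw = _read_csv(descriptor_path)
    unknown_drugs = sorted(set(ic50.drug_ids) - set(descriptors_raw.index.astype(str)))
    if unknown_drugs:
        raise ValidationError(
            f"drugs in IC50 matrix absent from descriptor table: {unknown_drugs}"
        )
    descriptors = filter_chemical_features(descriptors_raw.loc[list(ic50.drug_ids)])

    if tissue_path is not None:
        tdf = pd.read_csv(tissue_path, dtype=str)
        tissues = dict(zip(tdf.iloc[:, 0], tdf.iloc[:, 1]))
    tissues = {c: tissues.get(c, "unknown") for c in ic50.cell_line_ids}

    ds = Dataset(ic50=ic50, genomic=genomic, descriptors=descriptors, tissues=tissues)
    logger.info(
        "loaded dataset: %d cell lines x %d drugs, %d observed IC50s (%.1f%% filled), "
        "%d genomic features, %d chemical descriptors",
        ds.n_cells, ds.n_drugs, ds.n_observed, 100 * ds.ic50.fill_fraction,
        len(ds.genomic.feature_ids), len(ds.descriptors.descriptor_ids),
    )
    return ds


PREDICTION_COLUMNS = ["cell_line", "drug", "y_norm", "log10_ic50", "model_id", "rotation"]


def save_predictions(predictions: pd.DataFrame, path) -> None:
    """Write predicted responses with provenance, lossless to 10 significant digits."""
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise ValidationError(f"prediction table lacks columns: {missing}")
    predictions[PREDICTION_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def load_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_line": str, "drug": str, "model_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: prediction table lacks columns: {missing}")
    return df


def read_smiles(path) -> dict[str, str]:
    """Two-column (drug_id, SMILES) list, kept for provenance only."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_dataset_csvs(
    ic50: pd.DataFrame,
    genomic: pd.DataFrame,
    descriptors: pd.DataFrame,
    tissues: Mapping[str, str],
    outdir,
) -> dict[str, Path]:
    """Write the three input tables (+ tissues) in the dialects ``load_dataset`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ic50": outdir / "ic50.csv",
        "genomic": outdir / "genomic.csv",
        "descriptors": outdir / "descriptors.csv",
        "tissues": outdir / "tissues.csv",
    }
    ic50.to_csv(paths["ic50"], na_rep="NA", float_format="%.10g")
    genomic.to_csv(paths["genomic"], na_rep="NA")
    descriptors.to_csv(paths["descriptors"], float_format="%.10g")
    pd.DataFrame(
        {"cell_line": list(tissues), "tissue": [tissues[c] for c in tissues]}
    ).to_csv(paths["tissues"], index=False)
    return paths
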