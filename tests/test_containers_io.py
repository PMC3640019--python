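"""Container validation, dataset loading and prediction round-trips."""

import numpy as np
import pandas as pd
import pytest

from chemgen import IC50Matrix, curate_cell_lines, load_dataset
from chemgen.containers import ValidationError
from chemgen.io import (
    load_predictions,
    read_smiles,
    save_predictions,
    write_dataset_csvs,
)

from conftest import make_annotation

GENES = ["G1", "G2", "G3"]


class TestIC50Matrix:
    def test_counts_and_order(self, toy_dataset):
        m = toy_dataset.ic50
        assert m.n_observed == 4
        assert m.cell_line_ids == ["C1", "C2", "C3"]
        assert m.observed_entries() == [
            ("C1", "D1"), ("C2", "D1"), ("C2", "D2"), ("C3", "D2")
        ]

    @pytest.mark.parametrize("bad", [0.0, -1.5])
    def test_nonpositive_value_rejected_with_location(self, bad):
        df = pd.DataFrame([[1.0, bad]], index=["C1"], columns=["D1", "D2"])
        with pytest.raises(ValidationError, match=r"C1.*D2|D2.*C1"):
            IC50Matrix(df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["C1", "C1"], columns=["D1"])
        with pytest.raises(ValidationError, match="duplicate"):
            IC50Matrix(df)


class TestCuration:
    def _with_missing(self, cell_id, n_missing, genes):
        """Annotation over len(genes) genes with exactly n_missing missing slots."""
        cnv, seq, msi = {}, {}, "stable"
        slots = [("cnv", g) for g in genes] + [("seq", g) for g in genes]
        take = slots[:n_missing] if n_missing <= len(slots) else slots
        for kind, g in take:
            (cnv if kind == "cnv" else seq)[g] = "missing"
        if n_missing > len(slots):
            msi = "missing"
        return make_annotation(cell_id, genes, msi=msi, cnv=cnv, seq=seq)

    def test_threshold_boundary(self):
        genes = [f"G{i}" for i in range(10)]  # 21 slots
        at = self._with_missing("at", 15, genes)
        over = self._with_missing("over", 16, genes)
        kept = curate_cell_lines([at, over], max_missing_features=15)
        assert [a.cell_line_id for a in kept] == ["at"]

    def test_counts_enumeration(self):
        genes = [f"G{i}" for i in range(11)]  # 23 slots: up to 22 w/o msi
        cohort = [
            self._with_missing(f"c{n}", n, genes) for n in (0, 10, 15, 16, 20)
        ]
        kept = curate_cell_lines(cohort, max_missing_features=15)
        assert len(kept) == 3

    def test_idempotent_and_order_independent(self):
        genes = [f"G{i}" for i in range(10)]
        cohort = [self._with_missing(f"c{n}", n, genes) for n in (0, 16, 3)]
        once = curate_cell_lines(cohort, 15)
        assert curate_cell_lines(once, 15) == once
        rev = curate_cell_lines(cohort[::-1], 15)
        assert {a.cell_line_id for a in rev} == {a.cell_line_id for a in once}

    def test_empty_survivor_set_is_error(self):
        genes = [f"G{i}" for i in range(10)]
        with pytest.raises(ValidationError):
            curate_cell_lines([self._with_missing("c", 16, genes)], 15)


class TestLoadDataset:
    def _write_inputs(self, tmp_path, ic50=None, drop_cell=None):
        cells = ["C1", "C2", "C3"]
        if ic50 is None:
            ic50 = pd.DataFrame(
                [[0.5, np.nan], [2.0, 8.0], [np.nan, 0.125]],
                index=cells, columns=["D1", "D2"],
            )
        genomic = pd.DataFrame(
            {
                "msi": ["stable", "unstable", "stable"],
                "tissue": ["lung", "lung", "breast"],
                "cnv:G1": ["wildtype", "deletion", "amplification"],
                "seq:G1": ["variant", "wildtype", "wildtype"],
            },
            index=pd.Index(cells, name="cell_line"),
        )
        if drop_cell:
            genomic = genomic.drop(index=drop_cell)
        descriptors = pd.DataFrame(
            {"mw": [300.0, 450.0], "logp": [1.2, -0.4]},
            index=pd.Index(["D1", "D2"], name="drug"),
        )
        ic50.to_csv(tmp_path / "ic50.csv", na_rep="NA")
        genomic.to_csv(tmp_path / "genomic.csv")
        descriptors.to_csv(tmp_path / "descriptors.csv")
        return tmp_path

    def test_toy_load(self, tmp_path):
        d = self._write_inputs(tmp_path)
        ds = load_dataset(d / "ic50.csv", d / "genomic.csv", d / "descriptors.csv")
        assert ds.n_observed == 4
        assert ds.tissues["C3"] == "breast"
        assert ds.genomic.values.loc["C2", "cnv:G1"] == -1

    def test_zero_ic50_rejected(self, tmp_path):
        ic50 = pd.DataFrame([[0.0, 1.0]], index=["C1"], columns=["D1", "D2"])
        d = self._write_inputs(tmp_path, ic50=ic50)
        with pytest.raises(ValidationError, match="positive number greater than zero"):
            load_dataset(d / "ic50.csv", d / "genomic.csv", d / "descriptors.csv")

    def test_missing_cell_line_is_id_mismatch(self, tmp_path):
        d = self._write_inputs(tmp_path, drop_cell="C2")
        with pytest.raises(ValidationError, match="C2"):
            load_dataset(d / "ic50.csv", d / "genomic.csv", d / "descriptors.csv")

    def test_raw_copy_numbers_accepted(self, tmp_path):
        d = self._write_inputs(tmp_path)
        genomic = pd.read_csv(d / "genomic.csv", index_col=0)
        genomic["cnv:G1"] = [2, 0, 9]  # wildtype, deletion, amplification
        genomic.to_csv(d / "genomic.csv")
        ds = load_dataset(d / "ic50.csv", d / "genomic.csv", d / "descriptors.csv")
        assert list(ds.genomic.values["cnv:G1"]) == [0, -1, 1]


class TestPredictionRoundTrip:
    def _frame(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "cell_line": [f"C{i%7}" for i in range(n)],
                "drug": [f"D{i%5}" for i in range(n)],
                "y_norm": rng.uniform(1e-6, 1 - 1e-6, n),
                "log10_ic50": rng.normal(0, 2, n),
                "model_id": [f"mlp:{i%8}" for i in range(n)],
                "rotation": [i % 8 for i in range(n)],
            }
        )

    def test_values_survive_at_10_significant_digits(self, tmp_path):
        df = self._frame(100)
        save_predictions(df, tmp_path / "p.csv")
        back = load_predictions(tmp_path / "p.csv")
        np.testing.assert_allclose(back["log10_ic50"], df["log10_ic50"], rtol=1e-9)
        np.testing.assert_allclose(back["y_norm"], df["y_norm"], rtol=1e-9)

    def test_provenance_preserved_per_row(self, tmp_path):
        df = self._frame(30)
        save_predictions(df, tmp_path / "p.csv")
        back = load_predictions(tmp_path / "p.csv")
        for col in ("cell_line", "drug", "model_id", "rotation"):
            assert list(back[col]) == list(df[col])

    def test_empty_set_gives_header_only(self, tmp_path):
        save_predictions(self._frame(0), tmp_path / "p.csv")
        back = load_predictions(tmp_path / "p.csv")
        assert len(back) == 0 and list(back.columns) == [
            "cell_line", "drug", "y_norm", "log10_ic50", "model_id", "rotation"
        ]


def test_dataset_csv_round_trip(tmp_path, default_synthetic):
    """Generated tables written to CSV load back into an equivalent dataset."""
    dataset, truth = default_synthetic
    paths = write_dataset_csvs(
        dataset.ic50.values, truth.annotation_table, dataset.descriptors.values,
        dataset.tissues, tmp_path,
    )
    ds2 = load_dataset(
        paths["ic50"], paths["genomic"], paths["descriptors"], paths["tissues"]
    )
    assert ds2.n_observed == dataset.n_observed
    pd.testing.assert_frame_equal(ds2.genomic.values, dataset.genomic.values)
    pd.testing.assert_frame_equal(
        ds2.ic50.values, dataset.ic50.values, rtol=1e-9
    )


def test_smiles_list_parsed_for_provenance(tmp_path):
    (tmp_path / "smiles.csv").write_text("drug,smiles\nD1,CCO\nD2,c1ccccc1\n")
    assert read_smiles(tmp_path / "smiles.csv") == {"D1": "CCO", "D2": "c1ccccc1"}
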