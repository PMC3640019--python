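"""Fold-plan construction: disjointness, coverage, rotation and downsampling."""

import numpy as np
import pytest

from chemgen import (
    downsample_training,
    make_cellline_disjoint_folds,
    make_random_folds,
    make_tissue_holdout,
)


def grid_entries(n_cells, n_drugs):
    return [(f"C{i}", f"D{j}") for i in range(n_cells) for j in range(n_drugs)]


def assert_plan_invariants(plan, entries):
    """Roles disjoint per rotation; bins disjoint; test sets partition all entries."""
    universe = set(entries)
    assert set(plan.entries) == universe
    test_union = []
    for rot in plan.rotations:
        tr, ct, te = set(rot.train), set(rot.crosstrain), set(rot.test)
        assert not (tr & ct or tr & te or ct & te)
        assert tr | ct | te <= universe
        test_union.extend(rot.test)
    if plan.scheme in ("random", "stringent_cellline"):
        assert sorted(test_union) == sorted(universe)


class TestRandomFolds:
    def test_16_entries_8_bins_of_2(self):
        plan = make_random_folds(grid_entries(4, 4), k=8, seed=5)
        assert all(len(b) == 2 for b in plan.bins)
        assert_plan_invariants(plan, grid_entries(4, 4))

    def test_k_rotations_one_test_and_one_crosstrain_each(self):
        plan = make_random_folds(grid_entries(10, 5), k=8, seed=0)
        assert len(plan.rotations) == 8
        tests = [rot.test for rot in plan.rotations]
        crosstrains = [rot.crosstrain for rot in plan.rotations]
        assert sorted(map(sorted, tests)) == sorted(map(sorted, plan.bins))
        assert sorted(map(sorted, crosstrains)) == sorted(map(sorted, plan.bins))

    def test_seed_determinism(self):
        e = grid_entries(9, 7)
        assert make_random_folds(e, 8, seed=3) == make_random_folds(e, 8, seed=3)
        other = make_random_folds(e, 8, seed=4)
        assert other != make_random_folds(e, 8, seed=3)
        assert sorted(len(b) for b in other.bins) == sorted(
            len(b) for b in make_random_folds(e, 8, seed=3).bins
        )

    def test_near_equal_bins(self):
        plan = make_random_folds(grid_entries(13, 3), k=8, seed=1)
        sizes = [len(b) for b in plan.bins]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_entries(self):
        with pytest.raises(ValueError):
            make_random_folds(grid_entries(1, 5), k=8)
        with pytest.raises(ValueError):
            make_random_folds(grid_entries(4, 4), k=2)


class TestCellLineDisjointFolds:
    def test_cell_line_entries_share_a_bin(self):
        entries = [("C1", "D1"), ("C1", "D2"), ("C1", "D3")] + grid_entries(9, 2)
        plan = make_cellline_disjoint_folds(entries, k=3, seed=0)
        bins_with_c1 = [i for i, b in enumerate(plan.bins) if any(c == "C1" for c, _ in b)]
        assert len(bins_with_c1) == 1

    def test_8_cells_8_bins_one_each(self):
        plan = make_cellline_disjoint_folds(grid_entries(8, 3), k=8, seed=2)
        for b in plan.bins:
            assert len({c for c, _ in b}) == 1

    def test_no_cell_line_spans_two_roles(self):
        plan = make_cellline_disjoint_folds(grid_entries(50, 4), k=8, seed=11)
        for rot in plan.rotations:
            roles = [
                {c for c, _ in rot.train},
                {c for c, _ in rot.crosstrain},
                {c for c, _ in rot.test},
            ]
            assert not (roles[0] & roles[1] or roles[0] & roles[2] or roles[1] & roles[2])

    def test_fewer_cells_than_k(self):
        with pytest.raises(ValueError):
            make_cellline_disjoint_folds(grid_entries(5, 4), k=8)


class TestTissueHoldout:
    def _tissues(self, n_cells, counts):
        """counts: dict tissue -> count, assigned in order."""
        out, i = {}, 0
        for t, cnt in counts.items():
            for _ in range(cnt):
                out[f"C{i}"] = t
                i += 1
        return out

    def test_test_set_is_exactly_held_out_tissue(self):
        tissues = self._tissues(9, {"T1": 3, "T2": 3, "T3": 3})
        entries = grid_entries(9, 4)
        plan = make_tissue_holdout(entries, tissues, "T2", seed=0)
        te_cells = {c for c, _ in plan.rotations[0].test}
        assert te_cells == {c for c, t in tissues.items() if t == "T2"}
        assert set(plan.rotations[0].test) == {e for e in entries if e[0] in te_cells}

    def test_remaining_entries_cover_other_tissues(self):
        tissues = self._tissues(18, {"lung": 3, "other": 15})  # ~17% held out
        entries = grid_entries(18, 5)
        plan = make_tissue_holdout(entries, tissues, "lung", seed=0)
        rot = plan.rotations[0]
        rest = set(rot.train) | set(rot.crosstrain)
        assert rest == {e for e in entries if tissues[e[0]] != "lung"}
        assert len(rest) / len(entries) == pytest.approx(15 / 18)

    def test_crosstrain_is_cellline_disjoint_from_train(self):
        tissues = self._tissues(40, {"T1": 10, "T2": 30})
        plan = make_tissue_holdout(grid_entries(40, 3), tissues, "T1", seed=4)
        rot = plan.rotations[0]
        assert not ({c for c, _ in rot.train} & {c for c, _ in rot.crosstrain})

    def test_absent_or_empty_tissue_is_error(self):
        tissues = self._tissues(4, {"T1": 4})
        with pytest.raises(ValueError):
            make_tissue_holdout(grid_entries(4, 2), tissues, "T9")
        tissues["C9"] = "empty"  # labelled but no observed entries
        with pytest.raises(ValueError):
            make_tissue_holdout(grid_entries(4, 2), tissues, "empty")


class TestDownsampling:
    def test_fraction_one_is_identity(self):
        plan = make_random_folds(grid_entries(10, 10), k=8, seed=0)
        assert downsample_training(plan, 1.0, seed=9) == plan

    def test_exact_retained_count(self):
        plan = make_random_folds(grid_entries(40, 25), k=8, seed=0)  # 1000 entries
        sub = downsample_training(plan, 0.2, seed=1)
        for rot in sub.rotations:
            kept = len(rot.train) + len(rot.crosstrain)
            assert kept == round(0.2 * (1000 - len(rot.test)))

    def test_test_sets_never_touched(self):
        plan = make_random_folds(grid_entries(12, 8), k=8, seed=0)
        for frac in (0.1, 0.5, 0.9):
            sub = downsample_training(plan, frac, seed=2)
            for rot, orig in zip(sub.rotations, plan.rotations):
                assert rot.test == orig.test

    def test_retained_entries_keep_their_roles(self):
        plan = make_random_folds(grid_entries(12, 8), k=8, seed=0)
        sub = downsample_training(plan, 0.5, seed=3)
        for rot, orig in zip(sub.rotations, plan.rotations):
            assert set(rot.train) <= set(orig.train)
            assert set(rot.crosstrain) <= set(orig.crosstrain)

    @pytest.mark.parametrize("frac", [0.0, -0.2, 1.5])
    def test_invalid_fraction(self, frac):
        plan = make_random_folds(grid_entries(4, 4), k=4, seed=0)
        with pytest.raises(ValueError):
            downsample_training(plan, frac)


def test_fold_plan_audit_frame():
    plan = make_random_folds(grid_entries(6, 4), k=4, seed=0)
    df = plan.to_frame()
    assert set(df["role"]) == {"train", "crosstrain", "test"}
    # every rotation accounts for every entry exactly once
    assert (df.groupby("rotation").size() == 24).all()
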