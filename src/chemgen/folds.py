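"""Fold plans for the three validation schemes and training-set downsampling.

The main scheme distributes all observed (cell line, drug) entries at random
into ``k`` near-equal bins and rotates roles so that each bin serves once as
the test set, once as the cross-train set (used only to pick the network
architecture and stopping iteration) and otherwise as training data.  The
*stringent* variant partitions cell lines instead of entries, so that no cell
line ever contributes to two roles of the same rotation -- this measures
generalization to entirely unseen cell lines.  The *tissue hold-out* scheme
reserves every entry of one tissue's cell lines as the single test set.

Downsampling removes a random subset of the train/cross-train entries of each
rotation while leaving the test sets untouched, emulating a sparser screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Entry",
    "Rotation",
    "FoldPlan",
    "make_random_folds",
    "make_cellline_disjoint_folds",
    "make_tissue_holdout",
    "downsample_training",
]

Entry = tuple[str, str]  # (cell line id, drug id)


@dataclass(frozen=True)
class Rotation:
    """Role assignment of one model: disjoint train / cross-train / test entry sets."""

    train: tuple[Entry, ...]
    crosstrain: tuple[Entry, ...]
    test: tuple[Entry, ...]

    def __post_init__(self) -> None:
        tr, ct, te = set(self.train), set(self.crosstrain), set(self.test)
        if tr & ct or tr & te or ct & te:
            raise ValueError("rotation roles are not disjoint")


@dataclass(frozen=True)
class FoldPlan:
    scheme: str
    k: int
    bins: tuple[tuple[Entry, ...], ...]
    rotations: tuple[Rotation, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        all_entries = [e for b in self.bins for e in b]
        if len(set(all_entries)) != len(all_entries):
            raise ValueError("bins are not pairwise disjoint")

    @property
    def entries(self) -> tuple[Entry, ...]:
        return tuple(e for b in self.bins for e in b)

    def to_frame(self) -> pd.DataFrame:
        """Serialize (entry, bin, rotation, role) rows for audit."""
        bin_of = {e: i for i, b in enumerate(self.bins) for e in b}
        rows = []
        for r, rot in enumerate(self.rotations):
            for role, entries in (
                ("train", rot.train), ("crosstrain", rot.crosstrain), ("test", rot.test)
            ):
                for c, d in entries:
                    rows.append((c, d, bin_of.get((c, d), -1), r, role))
        return pd.DataFrame(
            rows, columns=["cell_line", "drug", "bin", "rotation", "role"]
        )


def _canonical_entries(observed_entries: Iterable[Entry]) -> list[Entry]:
    entries = sorted(set(map(tuple, observed_entries)))
    if not entries:
        raise ValueError("no observed entries")
    return entries


def _rotate(bins: Sequence[tuple[Entry, ...]], scheme: str, k: int, seed) -> FoldPlan:
    """Canonical rotation schedule: bin i tests in rotation i, bin i+1 cross-trains."""
    rotations = []
    for i in range(k):
        ct = (i + 1) % k
        train = tuple(
            e for j, b in enumerate(bins) if j not in (i, ct) for e in b
        )
        rotations.append(Rotation(train=train, crosstrain=bins[ct], test=bins[i]))
    return FoldPlan(scheme=scheme, k=k, bins=tuple(bins), rotations=tuple(rotations), seed=seed)


def make_random_folds(observed_entries: Iterable[Entry], k: int = 8, seed: int = 0) -> FoldPlan:
    """Distribute observed entries at random into ``k`` near-equal bins and rotate roles."""
    entries = _canonical_entries(observed_entries)
    if k < 3:
        raise ValueError("k must be >= 3 (train, cross-train and test roles)")
    if len(entries) < k:
        raise ValueError(f"{len(entries)} entries cannot fill {k} bins")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    bins = tuple(
        tuple(entries[j] for j in sorted(order[i::k])) for i in range(k)
    )
    return _rotate(bins, "random", k, seed)


def make_cellline_disjoint_folds(
    observed_entries: Iterable[Entry], k: int = 8, seed: int = 0
) -> FoldPlan:
    """Partition *cell lines* into ``k`` bins; entries inherit their cell line's bin."""
    entries = _canonical_entries(observed_entries)
    if k < 3:
        raise ValueError("k must be >= 3 (train, cross-train and test roles)")
    cells = sorted({c for c, _ in entries})
    if len(cells) < k:
        raise ValueError(f"{len(cells)} cell lines cannot fill {k} bins")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    cell_bin = {cells[j]: i for i in range(k) for j in order[i::k]}
    bins = tuple(
        tuple(e for e in entries if cell_bin[e[0]] == i) for i in range(k)
    )
    return _rotate(bins, "stringent_cellline", k, seed)


def make_tissue_holdout(
    observed_entries: Iterable[Entry],
    tissues: Mapping[str, str],
    held_out_tissue: str,
    train_crosstrain_ratio: int = 7,
    seed: int = 0,
) -> FoldPlan:
    """Hold out every entry of one tissue for testing; split the rest by cell line.

    The remaining cell lines are split ``train_crosstrain_ratio``:1 into train
    and cross-train (cell-line-disjoint), mirroring the 6-train + 1-cross-train
    of 8 bins proportion of the main scheme.
    """
    entries = _canonical_entries(observed_entries)
    if held_out_tissue not in set(tissues.values()):
        raise ValueError(f"tissue {held_out_tissue!r} absent from tissue map")
    test = tuple(e for e in entries if tissues.get(e[0]) == held_out_tissue)
    if not test:
        raise ValueError(f"tissue {held_out_tissue!r} has no observed entries")
    rest = [e for e in entries if tissues.get(e[0]) != held_out_tissue]
    cells = sorted({c for c, _ in rest})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    n_ct = max(1, round(len(cells) / (train_crosstrain_ratio + 1)))
    ct_cells = {cells[j] for j in order[:n_ct]}
    crosstrain = tuple(e for e in rest if e[0] in ct_cells)
    train = tuple(e for e in rest if e[0] not in ct_cells)
    rotation = Rotation(train=train, crosstrain=crosstrain, test=test)
    return FoldPlan(
        scheme="tissue_holdout", k=1, bins=(train, crosstrain, test),
        rotations=(rotation,), seed=seed,
    )


def downsample_training(plan: FoldPlan, fraction: float, seed: int = 0) -> FoldPlan:
    """Retain a random ``fraction`` of each rotation's train+cross-train entries.

    Sampling is without replacement within the pooled train/cross-train roles of
    each rotation; each role keeps its own sampled members and test sets are
    never touched.  ``fraction = 1`` returns the plan unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return plan
    rng = np.random.default_rng(seed)
    rotations = []
    for rot in plan.rotations:
        pool = list(rot.train) + list(rot.crosstrain)
        n_keep = round(fraction * len(pool))
        idx = rng.choice(len(pool), size=n_keep, replace=False)
        keep = {pool[i] for i in idx}
        rotations.append(
            Rotation(
                train=tuple(e for e in rot.train if e in keep),
                crosstrain=tuple(e for e in rot.crosstrain if e in keep),
                test=rot.test,
            )
        )
    return FoldPlan(
        scheme=plan.scheme, k=plan.k, bins=plan.bins,
        rotations=tuple(rotations), seed=plan.seed,
    )
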