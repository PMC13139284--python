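"""Dataset partitioning: random 8:1:1, Bemis-Murcko scaffold-disjoint,
and k-fold cross-validation splits, with repeated-run support.

Scaffold splitting assigns whole scaffold groups (largest first) to the
partition furthest below its target fraction, guaranteeing that no
scaffold crosses a partition boundary -- the leakage-free evaluation
regime for structure-activity models.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

DEFAULT_RATIO = (8, 1, 1)


@dataclasses.dataclass
class Split:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    method: str                 # "random" | "scaffold" | "fold"
    seed: int
    run_index: int = 1

    def __post_init__(self):
        parts = [np.asarray(p, dtype=int) for p in
                 (self.train, self.validation, self.test)]
        self.train, self.validation, self.test = parts
        all_idx = np.concatenate(parts)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("partitions are not disjoint")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    def to_frame(self, compound_ids: Sequence | None = None) -> pd.DataFrame:
        rows = []
        for name, idx in (("train", self.train), ("validation", self.validation),
                          ("test", self.test)):
            for i in idx:
                cid = compound_ids[i] if compound_ids is not None else i
                rows.append(dict(compound_id=cid, index=int(i), partition=name,
                                 run_index=self.run_index, method=self.method,
                                 seed=self.seed))
        return pd.DataFrame(rows)


def _partition_sizes(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    total = sum(ratio)
    n_val = int(n * ratio[1] / total)
    n_test = int(n * ratio[2] / total)
    n_train = n - n_val - n_test  # rounding surplus goes to train
    return n_train, n_val, n_test


def random_split(
    n: int, ratio: tuple[int, int, int] = DEFAULT_RATIO, seed: int = 0,
    run_index: int = 1,
) -> Split:
    """Uniform random partition at the given ratio (default 8:1:1)."""
    n_train, n_val, n_test = _partition_sizes(n, ratio)
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small to populate all three partitions")
    perm = np.random.default_rng(seed).permutation(n)
    return Split(
        train=perm[:n_train],
        validation=perm[n_train:n_train + n_val],
        test=perm[n_train + n_val:],
        method="random", seed=seed, run_index=run_index,
    )


def murcko_scaffold(structure: str) -> str:
    """Bemis-Murcko scaffold (ring systems + linkers, side chains
    removed) as canonical SMILES; acyclic molecules map to ''."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(
    structures: Sequence[str], ratio: tuple[int, int, int] = DEFAULT_RATIO,
    seed: int = 0, run_index: int = 1,
) -> Split:
    """Scaffold-disjoint partition by greedy balanced assignment.

    Scaffold groups are sorted by size descending (ties broken by a
    seeded shuffle) and each group is placed whole into the partition
    currently furthest below its target count, so no scaffold ever spans
    two partitions.
    """
    scaffolds: dict[str, list[int]] = {}
    for i, smi in enumerate(structures):
        scaffolds.setdefault(murcko_scaffold(smi), []).append(i)
    if len(scaffolds) < 3:
        raise ValueError(
            f"need >= 3 distinct scaffolds, found {len(scaffolds)}"
        )
    rng = np.random.default_rng(seed)
    groups = list(scaffolds.values())
    rng.shuffle(groups)
    groups.sort(key=len, reverse=True)  # stable: ties keep shuffled order

    n = len(structures)
    targets = _partition_sizes(n, ratio)
    parts: list[list[int]] = [[], [], []]
    for group in groups:
        deficits = [targets[j] - len(parts[j]) for j in range(3)]
        j = int(np.argmax(deficits))  # tie -> train first, then val, test
        parts[j].extend(group)
    return Split(train=np.array(parts[0]), validation=np.array(parts[1]),
                 test=np.array(parts[2]), method="scaffold", seed=seed,
                 run_index=run_index)


def kfold(n: int, k: int = 5, seed: int = 0) -> list[Split]:
    """k random folds; each fold serves once as the test set (validation
    is empty for fold splits)."""
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    splits = []
    for i, fold in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        splits.append(Split(train=train, validation=np.array([], dtype=int),
                            test=fold, method="fold", seed=seed,
                            run_index=i + 1))
    return splits


def repeat_runs(
    splitter: Callable[[int, int], Split], n_runs: int = 5, base_seed: int = 0
) -> list[Split]:
    """Repeat a splitter with seeds base_seed + 1 .. base_seed + n_runs.

    ``splitter(seed, run_index)`` must return a Split; provenance
    (seed, run_index) is recorded on each returned Split.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [splitter(base_seed + r, r) for r in range(1, n_runs + 1)]


def check_scaffold_disjoint(structures: Sequence[str], split: Split) -> bool:
    """True iff no Bemis-Murcko scaffold occurs in two partitions."""
    sets = []
    for idx in (split.train, split.validation, split.test):
        sets.append({murcko_scaffold(structures[i]) for i in idx})
    return (
        not (sets[0] & sets[1]) and not (sets[0] & sets[2])
        and not (sets[1] & sets[2])
    )
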