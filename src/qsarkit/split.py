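"""External train/test partitioning.

Four strategies: seeded random, stratified (categorical targets),
Bemis-Murcko scaffold (whole scaffold groups never straddle the boundary)
and Butina exclusion-sphere clustering on fingerprint Tanimoto distances
(whole clusters kept together).  Membership, group keys and all parameters
are persisted so a split can be reloaded bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import MoleculeRecord

__all__ = [
    "Partition",
    "bemis_murcko_scaffold",
    "scaffold_split",
    "butina_cluster",
    "random_or_stratified_split",
]


class StructureError(ValueError):
    pass


class DegenerateSplitWarning(UserWarning):
    pass


@dataclass
class Partition:
    """A train/test membership with its provenance (strategy, params, groups)."""

    train_ids: list[str]
    test_ids: list[str]
    strategy: str
    params: dict
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        rows = [(i, "train", self.group_map.get(i, "")) for i in self.train_ids]
        rows += [(i, "test", self.group_map.get(i, "")) for i in self.test_ids]
        pd.DataFrame(rows, columns=["id", "subset", "group_key"]).to_csv(
            csv_path, index=False
        )
        with open(json_path, "w") as fh:
            json.dump({"strategy": self.strategy, "params": self.params}, fh, indent=2)

    @classmethod
    def load(cls, csv_path: str | Path, json_path: str | Path) -> "Partition":
        df = pd.read_csv(csv_path, dtype={"id": str, "group_key": str}, keep_default_na=False)
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            train_ids=df.loc[df.subset == "train", "id"].tolist(),
            test_ids=df.loc[df.subset == "test", "id"].tolist(),
            strategy=meta["strategy"],
            params=meta["params"],
            group_map={r.id: r.group_key for r in df.itertuples() if r.group_key},
        )


def bemis_murcko_scaffold(smiles_canonical: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold (rings + linkers).

    Acyclic molecules return the empty string.
    """
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise StructureError(f"invalid SMILES: {smiles_canonical!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def _greedy_group_split(
    ids: list[str], groups: list[str], test_fraction: float, strategy: str, params: dict
) -> Partition:
    """Greedy bin fill: groups by size descending (ties: first occurrence),
    assigned to train until it holds ceil((1-f)*N), remainder to test."""
    order: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for idx, (i, g) in enumerate(zip(ids, groups)):
        if g not in order:
            order[g] = idx
            members[g] = []
        members[g].append(i)
    ranked = sorted(members, key=lambda g: (-len(members[g]), order[g]))
    n_train_target = int(np.ceil((1.0 - test_fraction) * len(ids)))
    train, test = [], []
    for g in ranked:
        if len(train) < n_train_target:
            train.extend(members[g])
        else:
            test.extend(members[g])
    if not test:
        warnings.warn(
            "all records fall in one group; test set is empty",
            DegenerateSplitWarning,
            stacklevel=3,
        )
    return Partition(
        train_ids=train,
        test_ids=test,
        strategy=strategy,
        params=params,
        group_map=dict(zip(ids, groups)),
    )


def scaffold_split(
    records: list[MoleculeRecord], test_fraction: float = 0.2
) -> Partition:
    """Bemis-Murcko scaffold split: whole scaffold groups, largest first to
    train until the train quota is met; the remaining groups form the test set."""
    ok = [r for r in records if r.status == "ok"]
    ids = [r.id for r in ok]
    groups = [bemis_murcko_scaffold(r.smiles_canonical) for r in ok]
    return _greedy_group_split(
        ids, groups, test_fraction, "scaffold", {"test_fraction": test_fraction}
    )


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances between binary fingerprint rows."""
    fps = np.asarray(fps)
    if not np.isin(fps, (0, 1)).all():
        raise TypeError("fingerprint matrix must be binary")
    fps = fps.astype(np.float64)
    inter = fps @ fps.T
    pop = fps.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    return 1.0 - sim


def butina_cluster(fingerprints: np.ndarray, cutoff: float) -> np.ndarray:
    """Butina exclusion-sphere clustering; returns one label per row.

    Neighbors are rows at Tanimoto distance <= cutoff.  Candidates are ranked
    by neighbor count descending (ties: ascending row index); the top
    unassigned candidate becomes a centroid and claims its unassigned
    neighbors, so every member lies within the cutoff of its centroid.
    """
    dist = tanimoto_distance_matrix(fingerprints)
    n = dist.shape[0]
    neigh = [np.flatnonzero(dist[i] <= cutoff) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-len(neigh[i]), i))
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for c in order:
        if labels[c] >= 0:
            continue
        labels[c] = next_label
        for j in neigh[c]:
            if labels[j] < 0:
                labels[j] = next_label
        next_label += 1
    return labels


def butina_split(
    records: list[MoleculeRecord],
    fingerprints: np.ndarray,
    test_fraction: float = 0.2,
    cutoff: float = 0.35,
) -> Partition:
    """Cluster-aware split: Butina clusters as groups, greedy fill as in
    :func:`scaffold_split`."""
    ok = [r for r in records if r.status == "ok"]
    labels = butina_cluster(fingerprints, cutoff)
    if len(labels) != len(ok):
        raise ValueError("fingerprint rows must align with ok records")
    return _greedy_group_split(
        [r.id for r in ok],
        [str(l) for l in labels],
        test_fraction,
        "butina",
        {"test_fraction": test_fraction, "cutoff": cutoff},
    )


def random_or_stratified_split(
    records: list[MoleculeRecord],
    test_fraction: float,
    seed: int,
    stratify: bool = False,
) -> Partition:
    """Seeded shuffle split; stratified mode preserves per-class proportions
    within one item per class.  Singleton classes go to train with a warning."""
    ok = [r for r in records if r.status == "ok"]
    ids = np.array([r.id for r in ok])
    rng = np.random.default_rng(seed)
    params = {"test_fraction": test_fraction, "seed": seed, "stratify": stratify}
    if not stratify:
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test = ids[perm[:n_test]]
        train = ids[perm[n_test:]]
        return Partition(list(train), list(test), "random", params)
    labels = np.array([r.target for r in ok])
    train, test = [], []
    for cls in pd.unique(labels):
        members = ids[labels == cls]
        if len(members) == 1:
            warnings.warn(
                f"class {cls!r} has a single member; placed in train",
                DegenerateSplitWarning,
                stacklevel=2,
            )
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_test = int(round(test_fraction * len(members)))
        test.extend(members[perm[:n_test]])
        train.extend(members[perm[n_test:]])
    return Partition(list(train), list(test), "stratified", params)
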