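"""Cross-validation split construction and label-shuffling controls.

Split modes
-----------
warm
    Record-level k-fold: pairs are assigned to folds directly, so test
    proteins and ligands generally also appear in training.
cold_protein / cold_drug
    Entity-level k-fold: whole proteins (or ligands) are held out, so every
    test record involves an unseen protein (or ligand).
cold_pair
    Proteins and ligands are folded independently; fold i's test set is the
    records whose protein AND ligand both fall in fold i, so both entities
    are unseen in training.  Records with mixed fold membership belong to
    neither side of that fold.
group_holdout
    A named protein group (e.g. all variants of one target such as HIV-1
    protease) forms a single test set; everything touching it is excluded
    from training.

Label-shuffling straw-model controls: S1 permutes affinity values within
train and within test, S2 within train only, S3 within test only.  A model
with genuine signal collapses to concordance ~0.5 under S1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .records import AffinityDataset

MODES = ("warm", "cold_protein", "cold_drug", "cold_pair", "group_holdout")


class SplitConfigError(ValueError):
    """Impossible or inconsistent split request."""


@dataclass(frozen=True)
class SplitSpec:
    mode: str
    n_folds: int = 5
    seed: int = 0
    holdout_group: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SplitConfigError(f"unknown split mode {self.mode!r}")
        if self.mode == "group_holdout":
            if not self.holdout_group:
                raise SplitConfigError("group_holdout requires a nonempty holdout_group")
        else:
            if self.n_folds < 2:
                raise SplitConfigError("cross-validation requires n_folds >= 2")
            if self.holdout_group:
                raise SplitConfigError("holdout_group only valid for group_holdout mode")


def _fold_assignment(items: list[str], n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    """Shuffle items, then deal them into n_folds near-equal chunks."""
    items = list(items)
    order = rng.permutation(len(items))
    assignment = {}
    for k, idx in enumerate(order):
        assignment[items[idx]] = k % n_folds
    return assignment


def make_splits(ds: AffinityDataset, spec: SplitSpec) -> list[tuple[list[int], list[int]]]:
    """Build (train_indices, test_indices) pairs over ``ds.records``.

    Deterministic under ``spec.seed``; train and test are disjoint in every
    fold, and test folds partition the eligible records.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(ds.records)
    protein_ids = [p.id for p in ds.proteins]
    ligand_ids = [l.id for l in ds.ligands]

    if spec.mode == "group_holdout":
        unknown = set(spec.holdout_group) - set(protein_ids)
        if unknown:
            raise SplitConfigError(f"holdout proteins not in dataset: {sorted(unknown)}")
        held = set(spec.holdout_group)
        test = [i for i, r in enumerate(ds.records) if r.protein_id in held]
        train = [i for i in range(n) if i not in set(test)]
        return [(train, test)]

    k = spec.n_folds
    if spec.mode == "warm":
        if n < k:
            raise SplitConfigError(f"{n} records cannot form {k} folds")
        fold_of = _fold_assignment([str(i) for i in range(n)], k, rng)
        rec_fold = [fold_of[str(i)] for i in range(n)]
        folds = []
        for f in range(k):
            test = [i for i in range(n) if rec_fold[i] == f]
            train = [i for i in range(n) if rec_fold[i] != f]
            folds.append((train, test))
        return folds

    if spec.mode == "cold_protein":
        if len(protein_ids) < k:
            raise SplitConfigError(f"{len(protein_ids)} proteins cannot form {k} folds")
        pf = _fold_assignment(protein_ids, k, rng)
        folds = []
        for f in range(k):
            test = [i for i, r in enumerate(ds.records) if pf[r.protein_id] == f]
            train = [i for i, r in enumerate(ds.records) if pf[r.protein_id] != f]
            folds.append((train, test))
        return folds

    if spec.mode == "cold_drug":
        if len(ligand_ids) < k:
            raise SplitConfigError(f"{len(ligand_ids)} ligands cannot form {k} folds")
        lf = _fold_assignment(ligand_ids, k, rng)
        folds = []
        for f in range(k):
            test = [i for i, r in enumerate(ds.records) if lf[r.ligand_id] == f]
            train = [i for i, r in enumerate(ds.records) if lf[r.ligand_id] != f]
            folds.append((train, test))
        return folds

    # cold_pair
    if len(protein_ids) < k or len(ligand_ids) < k:
        raise SplitConfigError("not enough proteins or ligands for cold_pair folds")
    pf = _fold_assignment(protein_ids, k, rng)
    lf = _fold_assignment(ligand_ids, k, rng)
    folds = []
    for f in range(k):
        test = [
            i for i, r in enumerate(ds.records)
            if pf[r.protein_id] == f and lf[r.ligand_id] == f
        ]
        train = [
            i for i, r in enumerate(ds.records)
            if pf[r.protein_id] != f and lf[r.ligand_id] != f
        ]
        folds.append((train, test))
    return folds


def shuffle_labels(
    ds: AffinityDataset,
    setting: str,
    folds: list[tuple[list[int], list[int]]],
    seed: int = 0,
) -> list[tuple[AffinityDataset, AffinityDataset]]:
    """Apply a straw-model label permutation per fold.

    Returns per-fold (train_dataset, test_dataset).  ``setting``:
    'S1' shuffles values within train and within test, 'S2' train only,
    'S3' test only, 'none' leaves both intact.  Sequences are untouched;
    only the pairing of affinity values to records is broken.
    """
    if setting not in ("S1", "S2", "S3", "none"):
        raise ValueError(f"unknown straw setting {setting!r}")
    rng = np.random.default_rng(seed)
    out = []
    for train_idx, test_idx in folds:
        train_ds = ds.subset_records(train_idx)
        test_ds = ds.subset_records(test_idx)
        if setting in ("S1", "S2") and len(train_ds):
            values = np.array([r.value for r in train_ds.records])
            train_ds = train_ds.with_values(values[rng.permutation(len(values))])
        if setting in ("S1", "S3") and len(test_ds):
            values = np.array([r.value for r in test_ds.records])
            test_ds = test_ds.with_values(values[rng.permutation(len(values))])
        out.append((train_ds, test_ds))
    return out


def write_split_manifest(path, spec: SplitSpec, folds) -> None:
    payload = {
        "mode": spec.mode,
        "seed": spec.seed,
        "n_folds": spec.n_folds,
        "holdout_group": list(spec.holdout_group),
        "folds": [{"train": list(tr), "test": list(te)} for tr, te in folds],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_split_manifest(path) -> tuple[SplitSpec, list[tuple[list[int], list[int]]]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    spec = SplitSpec(
        mode=payload["mode"],
        n_folds=payload["n_folds"],
        seed=payload["seed"],
        holdout_group=tuple(payload.get("holdout_group", ())),
    )
    folds = [(f["train"], f["test"]) for f in payload["folds"]]
    return spec, folds
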