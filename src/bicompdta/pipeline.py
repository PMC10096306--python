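"""Config-driven experiment orchestration.

``run_experiment`` ties the modules together: load or synthesize a
dataset, build splits (warm / cold / group holdout), optionally apply a
straw-model label shuffle, encode proteins against the training panel and
ligands against the training vocabulary, train the two-branch regressor
per fold, and evaluate.  Every run writes a provenance manifest (config
snapshot, input fingerprints, seeds, which partitions were permuted) next
to its metric files.

The default config is available from :func:`reference_config`; user
configs are dictionaries (or YAML files) with the same sections and are
merged over the defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .encoder import BiCompProteinEncoder, SmilesLabelEncoder
from .metrics import aggregate_folds, evaluate_fold
from .model import BiCompDTARegressor
from .records import AffinityDataset
from .splits import SplitSpec, make_splits, shuffle_labels, write_split_manifest
from .synthetic import SyntheticSpec, generate_dataset
from . import data_io


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


def reference_config() -> dict:
    """The fully explicit default configuration."""
    return {
        "data": {
            "source": "synthetic",           # or "files"
            "synthetic": {
                "n_families": 6, "members_per_family": 10,
                "protein_length": 240, "mutation_rate": 0.1,
                "n_ligands": 40, "ligand_length_range": [20, 45],
                "noise_sd": 0.3, "seed": 0,
            },
            "files": {
                "proteins": None, "ligands": None, "affinities": None,
                "format": "triples_tsv", "measure": "pre-transformed",
                "proteins_as_rows": True,
            },
            "harmonize_policy": "max",
        },
        "split": {"mode": "warm", "n_folds": 5, "seed": 0,
                  "holdout_group": [], "max_folds": None},
        "straw": {"setting": "none", "seed": 0},
        "encoder": {"combiner": "product", "weight_w": None, "max_len": None},
        "model": {
            "n_filters": 32, "filter_length": 4, "embedding_dim": 32,
            "protein_fc_sizes": [128, 128, 64],
            "predictor_fc_sizes": [128, 64, 32],
            "dropout": 0.1, "learning_rate": 1e-3, "batch_size": 64,
            "epochs": 30, "seed": 0, "drug_branch": "cnn_sep",
            "patience": 15, "validation_fraction": 0.1,
        },
        "metrics": {"aupr_threshold": 7.0},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(value, dict) and isinstance(out[key], dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(source) -> dict:
    """Merge a dict or YAML file over :func:`reference_config`."""
    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        with open(source, encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
    return _merge(reference_config(), override)


def _file_fingerprint(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_data(cfg: dict) -> tuple[AffinityDataset, dict]:
    """Dataset plus provenance fingerprints from the data section."""
    data_cfg = cfg["data"]
    if data_cfg["source"] == "synthetic":
        syn = dict(data_cfg["synthetic"])
        syn["ligand_length_range"] = tuple(syn["ligand_length_range"])
        spec = SyntheticSpec(**syn)
        ds, _ = generate_dataset(spec)
        prov = {"source": "synthetic", "spec": syn}
    elif data_cfg["source"] == "files":
        files = data_cfg["files"]
        for key in ("proteins", "ligands", "affinities"):
            if not files.get(key) or not Path(files[key]).exists():
                raise ConfigError(f"data file for {key!r} missing")
        ds = data_io.load_affinity_dataset(
            files["proteins"], files["ligands"], files["affinities"],
            format=files["format"], measure=files["measure"],
            proteins_as_rows=files["proteins_as_rows"],
        )
        prov = {
            "source": "files",
            "fingerprints": {k: _file_fingerprint(files[k])
                             for k in ("proteins", "ligands", "affinities")},
        }
    else:
        raise ConfigError(f"unknown data source {data_cfg['source']!r}")
    ds = data_io.harmonize_duplicates(ds, policy=data_cfg["harmonize_policy"])
    return ds, prov


def run_fold(
    train_ds: AffinityDataset,
    test_ds: AffinityDataset,
    encoder_cfg: dict,
    model_cfg: dict,
    aupr_threshold: float = 7.0,
) -> tuple[dict, BiCompDTARegressor]:
    """Encode, train and evaluate one fold; returns (fold metrics, model).

    The protein reference panel and the SMILES vocabulary come from the
    training records only, so cold-start folds never leak test identities
    into the representation.
    """
    train_pids = {r.protein_id for r in train_ds.records}
    train_lids = {r.ligand_id for r in train_ds.records}
    panel = [p for p in train_ds.proteins if p.id in train_pids]
    train_ligands = [l for l in train_ds.ligands if l.id in train_lids]
    if not panel or not train_ligands:
        raise ConfigError("training fold has no proteins or no ligands")

    enc = BiCompProteinEncoder(
        combiner=encoder_cfg["combiner"], weight_w=encoder_cfg["weight_w"]
    ).fit(panel)
    smi = SmilesLabelEncoder(max_len=encoder_cfg["max_len"]).fit(train_ligands)

    def matrices(ds: AffinityDataset):
        pidx = ds.protein_index
        lidx = ds.ligand_index
        uniq_p = sorted({r.protein_id for r in ds.records})
        uniq_l = sorted({r.ligand_id for r in ds.records})
        pvec = dict(zip(uniq_p, enc.transform([pidx[i] for i in uniq_p])))
        lvec = dict(zip(uniq_l, smi.transform([lidx[i] for i in uniq_l])))
        P = np.stack([pvec[r.protein_id] for r in ds.records])
        D = np.stack([lvec[r.ligand_id] for r in ds.records])
        y = np.array([r.value for r in ds.records])
        return P, D, y

    Pt, Dt, yt = matrices(train_ds)
    Pe, De, ye = matrices(test_ds)

    est = BiCompDTARegressor(
        **model_cfg, vocab_size=smi.vocab_.n_codes
    )
    est.fit((Pt, Dt), yt)
    pred = est.predict((Pe, De))
    fold = evaluate_fold(ye, pred, aupr_threshold)
    return fold, est


def run_experiment(config=None, out_dir=None) -> dict:
    """Run a full protocol and return the aggregate results dictionary.

    ``config`` may be a path to a YAML file, a dict of overrides, or None
    for the reference configuration.  If ``out_dir`` is given, fold
    manifests, per-fold metrics, the aggregate report and the provenance
    manifest are written there.
    """
    t0 = time.time()
    cfg = load_config(config)
    ds, provenance = load_data(cfg)

    split_cfg = cfg["split"]
    spec = SplitSpec(
        mode=split_cfg["mode"], n_folds=split_cfg["n_folds"],
        seed=split_cfg["seed"],
        holdout_group=tuple(split_cfg["holdout_group"] or ()),
    )
    folds = make_splits(ds, spec)
    setting = cfg["straw"]["setting"]
    fold_datasets = shuffle_labels(ds, setting, folds, seed=cfg["straw"]["seed"])
    max_folds = split_cfg.get("max_folds")
    if max_folds:
        fold_datasets = fold_datasets[:max_folds]

    mc = dict(cfg["model"])
    mc["protein_fc_sizes"] = tuple(mc["protein_fc_sizes"])
    mc["predictor_fc_sizes"] = tuple(mc["predictor_fc_sizes"])

    per_fold = []
    for train_ds, test_ds in fold_datasets:
        fold, _ = run_fold(
            train_ds, test_ds, cfg["encoder"], mc,
            aupr_threshold=cfg["metrics"]["aupr_threshold"],
        )
        per_fold.append(fold)
    report = aggregate_folds(per_fold)

    manifest = {
        "config": cfg,
        "data": provenance,
        "split": {"mode": spec.mode, "seed": spec.seed, "n_folds": spec.n_folds},
        "shuffled_partitions": {
            "train": setting in ("S1", "S2"),
            "test": setting in ("S1", "S3"),
            "setting": setting,
        },
        "n_records": len(ds.records),
        "wall_time_s": None,
        "outputs": [],
    }
    results = {"metrics": report.to_dict(), "manifest": manifest}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_split_manifest(out / "splits.json", spec, folds)
        report.to_json(out / "metrics.json")
        manifest["outputs"] = ["splits.json", "metrics.json", "manifest.json"]
        manifest["wall_time_s"] = round(time.time() - t0, 3)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return results


def run_ablation(config=None, combiners=("product", "sw_only", "ncd_only"), out_dir=None) -> dict:
    """Run the same protocol once per combiner (feature ablation)."""
    results = {}
    for combiner in combiners:
        cfg = load_config(config)
        cfg["encoder"]["combiner"] = combiner
        if combiner != "weighted_sum":
            cfg["encoder"]["weight_w"] = None
        sub_out = Path(out_dir) / combiner if out_dir else None
        results[combiner] = run_experiment(cfg, out_dir=sub_out)
    return results
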