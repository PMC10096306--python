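"""Flat-file readers/writers, affinity transforms and harmonization.

Input conventions (all UTF-8, ``#`` comment lines ignored):

* proteins: FASTA, or two-column TSV ``id<TAB>sequence``
* ligands: two-column TSV ``id<TAB>smiles``
* affinities: three-column TSV ``protein_id<TAB>ligand_id<TAB>value``, or a
  dense CSV matrix with protein row labels and ligand column headers
  (missing cells empty/NaN), the layout used by kinase-panel datasets.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    AffinityDataset,
    AffinityRecord,
    DataIntegrityError,
    LigandRecord,
    ProteinRecord,
)

logger = logging.getLogger(__name__)


def kd_to_pkd(kd: float) -> float:
    """Transform a dissociation constant in nanomolar to pKd.

    pKd = -log10(Kd / 1e9), i.e. the negative decadic log of the molar
    Kd; monotone decreasing in Kd (stronger binders score higher).
    """
    if not math.isfinite(kd) or kd <= 0:
        raise ValueError(f"Kd must be finite and positive, got {kd!r}")
    return -math.log10(kd / 1e9)


def pkd_to_kd(pkd: float) -> float:
    """Inverse of :func:`kd_to_pkd`: pKd back to nanomolar Kd."""
    return 1e9 * 10.0 ** (-pkd)


def _data_lines(path) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((i, line))
    return out


def read_proteins(path) -> list[ProteinRecord]:
    """Read a protein panel from FASTA or ``id<TAB>sequence`` TSV."""
    path = Path(path)
    first = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.startswith(">"):
        return [
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    records = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>sequence'")
        records.append(ProteinRecord(id=parts[0], sequence=parts[1].upper()))
    return records


def read_ligands(path) -> list[LigandRecord]:
    """Read ligands from a two-column ``id<TAB>smiles`` TSV."""
    records = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>smiles'")
        records.append(LigandRecord(id=parts[0], smiles=parts[1]))
    return records


def _read_affinities_triples(path, measure) -> list[AffinityRecord]:
    records = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'protein_id<TAB>ligand_id<TAB>value'"
            )
        try:
            value = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad affinity value {parts[2]!r}") from exc
        records.append(
            AffinityRecord(protein_id=parts[0], ligand_id=parts[1], value=value, measure=measure)
        )
    return records


def _read_affinities_dense(path, measure, proteins_as_rows=True) -> list[AffinityRecord]:
    df = pd.read_csv(path, index_col=0, comment="#")
    if not proteins_as_rows:
        df = df.T
    records = []
    for pid, row in df.iterrows():
        for lid, value in row.items():
            if pd.isna(value):
                continue
            records.append(
                AffinityRecord(
                    protein_id=str(pid), ligand_id=str(lid), value=float(value), measure=measure
                )
            )
    return records


def load_affinity_dataset(
    protein_path,
    ligand_path,
    affinity_path,
    format: str = "triples_tsv",
    measure: str = "pre-transformed",
    proteins_as_rows: bool = True,
) -> AffinityDataset:
    """Load a referentially intact dataset from flat files.

    ``format`` is ``triples_tsv`` or ``dense_matrix``.  A dense matrix is
    flattened to triples, dropping missing cells.  Rows are proteins and
    columns ligands by default; pass ``proteins_as_rows=False`` for the
    transposed layout.
    """
    proteins = read_proteins(protein_path)
    ligands = read_ligands(ligand_path)
    if format == "triples_tsv":
        records = _read_affinities_triples(affinity_path, measure)
    elif format == "dense_matrix":
        records = _read_affinities_dense(affinity_path, measure, proteins_as_rows)
    else:
        raise ValueError(f"unknown affinity format {format!r}")
    return AffinityDataset(proteins=proteins, ligands=ligands, records=records)


def write_dataset(ds: AffinityDataset, protein_path, ligand_path, affinity_path) -> None:
    """Write a dataset back out in the TSV flat-file layout."""
    with open(protein_path, "w", encoding="utf-8") as fh:
        for p in ds.proteins:
            fh.write(f"{p.id}\t{p.sequence}\n")
    with open(ligand_path, "w", encoding="utf-8") as fh:
        for l in ds.ligands:
            fh.write(f"{l.id}\t{l.smiles}\n")
    with open(affinity_path, "w", encoding="utf-8") as fh:
        for r in ds.records:
            fh.write(f"{r.protein_id}\t{r.ligand_id}\t{r.value!r}\n")


def harmonize_duplicates(ds: AffinityDataset, policy: str = "max") -> AffinityDataset:
    """Collapse duplicate (protein, ligand) pairs and redundant SMILES.

    ``policy='max'`` keeps the maximum affinity per pair (the
    harmonization rule used for Kd-type bioactivity aggregation);
    ``'mean'`` averages (appropriate for already-aggregated KIBA scores);
    ``'error'`` raises on the first duplicate.  Ligand ids that map to
    multiple distinct SMILES strings keep the first occurrence; the rest
    are dropped with a logged warning.
    """
    if policy not in ("max", "mean", "error"):
        raise ValueError(f"unknown policy {policy!r}")

    seen_smiles: dict[str, str] = {}
    ligands = []
    for l in ds.ligands:
        if l.id in seen_smiles:
            if l.smiles != seen_smiles[l.id]:
                logger.warning(
                    "ligand %s has multiple SMILES; keeping first, dropping %r",
                    l.id, l.smiles,
                )
            continue
        seen_smiles[l.id] = l.smiles
        ligands.append(l)

    grouped: dict[tuple[str, str], list[AffinityRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in ds.records:
        key = (r.protein_id, r.ligand_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        elif policy == "error":
            raise DataIntegrityError(f"duplicate affinity pair {key}")
        grouped[key].append(r)

    records = []
    for key in order:
        group = grouped[key]
        first = group[0]
        if len(group) == 1:
            records.append(first)
            continue
        values = [g.value for g in group]
        value = max(values) if policy == "max" else float(np.mean(values))
        records.append(
            AffinityRecord(
                protein_id=first.protein_id,
                ligand_id=first.ligand_id,
                value=value,
                measure=first.measure,
            )
        )
    return AffinityDataset(proteins=list(ds.proteins), ligands=ligands, records=records)


def deduplicate_proteins(ds: AffinityDataset, similarity, threshold: float) -> AffinityDataset:
    """Drop near-redundant proteins using a precomputed similarity matrix.

    Greedy in dataset order: a protein is removed when its similarity to an
    already-kept protein is >= ``threshold``; its affinity records go with
    it.  Deterministic by construction.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    ids = list(similarity.ids)
    pos = {pid: k for k, pid in enumerate(ids)}
    for p in ds.proteins:
        if p.id not in pos:
            raise DataIntegrityError(f"protein {p.id!r} missing from similarity matrix")
    kept: list[ProteinRecord] = []
    for p in ds.proteins:
        i = pos[p.id]
        if any(similarity.values[i, pos[q.id]] >= threshold for q in kept):
            continue
        kept.append(p)
    kept_ids = {p.id for p in kept}
    records = [r for r in ds.records if r.protein_id in kept_ids]
    return AffinityDataset(proteins=kept, ligands=list(ds.ligands), records=records)
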