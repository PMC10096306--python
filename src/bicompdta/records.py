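"""Core dataset containers: proteins, ligands, affinity records.

A dataset ties together a protein panel (amino-acid sequences), a ligand
panel (SMILES strings) and a list of affinity records referencing both by
id.  Affinity values are dimensionless log-scale labels (pKd, pKi or KIBA
scores); the ``measure`` tag records their provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

VALID_MEASURES = ("Kd", "Ki", "IC50", "KIBA", "pre-transformed")


class DataIntegrityError(ValueError):
    """Referential or structural inconsistency in a dataset."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by ``id`` with an amino-acid ``sequence``.

    The sequence must be nonempty over the 20 standard residues plus 'X'.
    Optional ``family`` metadata is used by the synthetic generator.
    """

    id: str
    sequence: str
    family: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class LigandRecord:
    """A ligand identified by ``id`` with a SMILES string."""

    id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"ligand {self.id!r}: empty SMILES")
        if not self.smiles.isprintable():
            raise ValueError(f"ligand {self.id!r}: non-printable SMILES")


@dataclass(frozen=True)
class AffinityRecord:
    """One (protein, ligand, affinity) triple.

    ``value`` is a finite log-scale affinity; ``measure`` tags its origin.
    """

    protein_id: str
    ligand_id: str
    value: float
    measure: str = "Kd"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(
                f"affinity ({self.protein_id},{self.ligand_id}): "
                f"non-finite value {self.value!r}"
            )
        if self.measure not in VALID_MEASURES:
            raise ValueError(f"unknown affinity measure {self.measure!r}")


@dataclass
class AffinityDataset:
    """Proteins, ligands and the affinity records linking them."""

    proteins: list[ProteinRecord] = field(default_factory=list)
    ligands: list[LigandRecord] = field(default_factory=list)
    records: list[AffinityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pids = [p.id for p in self.proteins]
        lids = [l.id for l in self.ligands]
        if len(set(pids)) != len(pids):
            raise DataIntegrityError("duplicate protein ids")
        # duplicate ligand ids are tolerated here: raw inputs may list one id
        # with several SMILES strings, resolved by harmonize_duplicates
        pset, lset = set(pids), set(lids)
        for r in self.records:
            if r.protein_id not in pset:
                raise DataIntegrityError(f"unknown protein id {r.protein_id!r}")
            if r.ligand_id not in lset:
                raise DataIntegrityError(f"unknown ligand id {r.ligand_id!r}")

    @property
    def protein_index(self) -> dict[str, ProteinRecord]:
        return {p.id: p for p in self.proteins}

    @property
    def ligand_index(self) -> dict[str, LigandRecord]:
        out: dict[str, LigandRecord] = {}
        for l in self.ligands:  # first occurrence wins, matching harmonization
            out.setdefault(l.id, l)
        return out

    def subset_records(self, indices) -> "AffinityDataset":
        """A view-like copy keeping only ``records[i] for i in indices``."""
        recs = [self.records[i] for i in indices]
        return AffinityDataset(
            proteins=list(self.proteins), ligands=list(self.ligands), records=recs
        )

    def with_values(self, values) -> "AffinityDataset":
        """Copy with record values replaced positionally (same pairs)."""
        if len(values) != len(self.records):
            raise DataIntegrityError("value vector length mismatch")
        recs = [replace(r, value=float(v)) for r, v in zip(self.records, values)]
        return AffinityDataset(
            proteins=list(self.proteins), ligands=list(self.ligands), records=recs
        )

    def __len__(self) -> int:
        return len(self.records)
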