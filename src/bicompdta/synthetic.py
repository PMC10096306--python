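"""Synthetic dataset generator with the structure the method assumes.

Proteins come in planted families: each family has a random ancestor
sequence and members are i.i.d.-substituted copies, so both alignment and
compression similarity carry family signal.  Ligands are random
SMILES-like strings.  Affinity decomposes additively into a protein-family
effect plus a ligand character-composition effect plus Gaussian noise,
then is shifted/scaled into a pKd-like range -- so the protein branch
must recover the family structure from panel similarities and the drug
branch the composition from character codes; neither branch alone
suffices for top accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AMINO_ACIDS, AffinityDataset, AffinityRecord, LigandRecord, ProteinRecord

#: SMILES-plausible characters without any chemistry semantics
DEFAULT_LIGAND_ALPHABET = "CNOSP=#()12c"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_families: int = 3
    members_per_family: int = 10
    protein_length: int = 400
    mutation_rate: float = 0.1
    n_ligands: int = 20
    ligand_length_range: tuple[int, int] = (20, 45)
    ligand_alphabet: str = DEFAULT_LIGAND_ALPHABET
    noise_sd: float = 0.3
    seed: int = 0
    affinity_range: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.protein_length,
               self.n_ligands) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        lo, hi = self.ligand_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid ligand_length_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.ligand_alphabet:
            raise ValueError("ligand_alphabet must be nonempty")


def _protein_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1])


def _ligand_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 2])


def _affinity_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 3])


def generate_proteins(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Family ancestors plus point-mutated members; family id in metadata."""
    rng = _protein_rng(spec)
    aa = np.array(list(AMINO_ACIDS))
    proteins = []
    for fam in range(spec.n_families):
        ancestor = rng.integers(0, len(aa), size=spec.protein_length)
        for m in range(spec.members_per_family):
            seq = ancestor.copy()
            mutate = rng.random(spec.protein_length) < spec.mutation_rate
            # draw substitutions for every site, use only the mutated ones,
            # so member sequences stay aligned with the ancestor
            subs = rng.integers(0, len(aa), size=spec.protein_length)
            seq[mutate] = subs[mutate]
            proteins.append(
                ProteinRecord(
                    id=f"F{fam}_P{m}",
                    sequence="".join(aa[seq]),
                    family=fam,
                )
            )
    return proteins


def generate_ligands(spec: SyntheticSpec) -> list[LigandRecord]:
    """Uniform random strings over the ligand alphabet."""
    rng = _ligand_rng(spec)
    chars = np.array(list(spec.ligand_alphabet))
    lo, hi = spec.ligand_length_range
    ligands = []
    for i in range(spec.n_ligands):
        length = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, len(chars), size=length)
        ligands.append(LigandRecord(id=f"L{i}", smiles="".join(chars[idx])))
    return ligands


@dataclass
class SyntheticTruth:
    """The generative parameters behind an affinity table."""

    family_effects: np.ndarray
    char_weights: dict[str, float]
    scale: float
    offset: float
    noise_sd: float

    def noiseless_affinity(self, protein: ProteinRecord, ligand: LigandRecord) -> float:
        """The exact generative mean for one pair (the oracle predictor)."""
        fam = protein.family
        comp = sum(
            self.char_weights[c] * ligand.smiles.count(c) / len(ligand.smiles)
            for c in self.char_weights
        )
        raw = self.family_effects[fam] + comp
        return self.offset + self.scale * raw

    def to_dict(self) -> dict:
        return {
            "family_effects": self.family_effects.tolist(),
            "char_weights": self.char_weights,
            "scale": self.scale, "offset": self.offset, "noise_sd": self.noise_sd,
        }


def generate_affinities(
    proteins: list[ProteinRecord],
    ligands: list[LigandRecord],
    spec: SyntheticSpec,
) -> tuple[AffinityDataset, SyntheticTruth]:
    """Full protein x ligand affinity grid plus the generative truth.

    affinity(p, l) = family_effect(p) + sum_c w_c * freq(c in l) + noise,
    affinely mapped into ``spec.affinity_range``.
    """
    if not proteins or not ligands:
        raise ValueError("need nonempty proteins and ligands")
    rng = _affinity_rng(spec)
    fam_effects = rng.normal(0.0, 1.0, size=spec.n_families)
    weights = {c: float(rng.normal(0.0, 1.0)) for c in spec.ligand_alphabet}

    raw = np.empty((len(proteins), len(ligands)))
    for i, p in enumerate(proteins):
        for j, l in enumerate(ligands):
            comp = sum(
                weights[c] * l.smiles.count(c) / len(l.smiles) for c in weights
            )
            raw[i, j] = fam_effects[p.family] + comp

    lo, hi = spec.affinity_range
    rmin, rmax = raw.min(), raw.max()
    span = rmax - rmin if rmax > rmin else 1.0
    scale = (hi - lo) / span
    offset = lo - scale * rmin
    truth = SyntheticTruth(
        family_effects=fam_effects, char_weights=weights,
        scale=scale, offset=offset, noise_sd=spec.noise_sd,
    )

    noise = rng.normal(0.0, spec.noise_sd, size=raw.shape) if spec.noise_sd > 0 else 0.0
    values = offset + scale * raw + noise
    records = [
        AffinityRecord(
            protein_id=p.id, ligand_id=l.id,
            value=float(values[i, j]), measure="pre-transformed",
        )
        for i, p in enumerate(proteins)
        for j, l in enumerate(ligands)
    ]
    ds = AffinityDataset(proteins=list(proteins), ligands=list(ligands), records=records)
    return ds, truth


def generate_dataset(spec: SyntheticSpec) -> tuple[AffinityDataset, SyntheticTruth]:
    """Proteins + ligands + full affinity grid in one call."""
    proteins = generate_proteins(spec)
    ligands = generate_ligands(spec)
    return generate_affinities(proteins, ligands, spec)
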