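"""Seeded generators for molecules, proteins and affinity labels.

Every stage of the pipeline can be exercised without external data:

* molecules are assembled atom by atom (C/N/O/S, single/double bonds,
  3–6 rings, optional fused benzene) under RDKit valence rules, so all
  emitted SMILES parse back into valid graphs;
* proteins are uniform-random sequences over the 20-residue alphabet,
  or periodic repeats when ``repeat_period`` is set, giving the MLM and
  CPC pretraining objectives learnable local structure;
* affinity labels come from a documented deterministic function of
  simple physicochemical descriptors plus optional Gaussian noise. The
  coupling term (molecule size × hydrophobic fraction) makes the label
  depend jointly on both modalities, so neither encoder alone can
  explain all the variance.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chem import smiles_to_graph
from .errors import ConfigError
from .prot_encoder import AMINO_ACIDS

__all__ = [
    "SyntheticSpec", "gen_molecules", "gen_proteins", "gen_affinity",
    "noiseless_affinity", "gen_dataset", "write_dta_csv", "write_fasta",
    "HYDROPHOBIC_RESIDUES", "AFFINITY_COEFFS",
]

# residues counted as hydrophobic in the label function
HYDROPHOBIC_RESIDUES = frozenset("AVLIFMWC")

# label = a*heavy + b*aromatic_rings + g*hydro_frac + d*heavy*hydro_frac
AFFINITY_COEFFS = {"alpha": 0.25, "beta": 0.5, "gamma": 2.0, "delta": 0.05}


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic draw.

    Defaults mirror the pretraining corpus this module emulates
    (protein lengths 70–1000); tests and the toy pipeline pass smaller
    ranges explicitly.
    """

    n_pairs: int = 500
    mol_atom_range: tuple[int, int] = (4, 12)
    prot_len_range: tuple[int, int] = (70, 1000)
    noise_sd: float = 0.1
    seed: int = 0
    repeat_period: int | None = None

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.mol_atom_range[0] < 1 or self.mol_atom_range[0] > self.mol_atom_range[1]:
            raise ConfigError("invalid mol_atom_range")
        if self.prot_len_range[0] < 1 or self.prot_len_range[0] > self.prot_len_range[1]:
            raise ConfigError("invalid prot_len_range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.repeat_period is not None and self.repeat_period < 1:
            raise ConfigError("repeat_period must be >= 1")


_ELEMENTS = ["C", "C", "C", "C", "C", "N", "O", "S"]
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def _free_valence(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return _MAX_VALENCE[atom.GetSymbol()] - used


def _random_molecule(rng: np.random.Generator, n_atoms: int) -> str | None:
    """One attempt at a random valid molecule with exactly n_atoms heavy atoms."""
    if n_atoms >= 7 and rng.random() < 0.35:
        # start from a benzene core and grow the remainder onto it
        mol = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
    else:
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom("C"))
    while mol.GetNumAtoms() < n_atoms:
        anchors = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) >= 1]
        if not anchors:
            return None
        anchor = int(rng.choice(anchors))
        symbol = str(rng.choice(_ELEMENTS))
        new_idx = mol.AddAtom(Chem.Atom(symbol))
        double = (rng.random() < 0.15 and _free_valence(mol, anchor) >= 2
                  and _MAX_VALENCE[symbol] >= 2
                  and not mol.GetAtomWithIdx(anchor).GetIsAromatic())
        mol.AddBond(anchor, new_idx,
                    Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)
    # occasionally close an aliphatic ring of size 3-6
    if mol.GetNumAtoms() >= 3 and rng.random() < 0.4:
        dmat = Chem.GetDistanceMatrix(mol.GetMol(), force=True)
        pairs = [(i, j) for i in range(mol.GetNumAtoms())
                 for j in range(i + 1, mol.GetNumAtoms())
                 if 2 <= dmat[i, j] <= 5
                 and _free_valence(mol, i) >= 1 and _free_valence(mol, j) >= 1
                 and mol.GetBondBetweenAtoms(i, j) is None]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(i, j, Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    smiles = Chem.MolToSmiles(out)
    return smiles or None


def gen_molecules(spec: SyntheticSpec,
                  rng: np.random.Generator | None = None) -> list[str]:
    """Generate ``spec.n_pairs`` valid SMILES strings (deterministic per seed)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.mol_atom_range
    out: list[str] = []
    while len(out) < spec.n_pairs:
        n_atoms = int(rng.integers(lo, hi + 1))
        smiles = _random_molecule(rng, n_atoms)
        if smiles is None:
            continue
        try:
            smiles_to_graph(smiles)
        except Exception:
            continue
        out.append(smiles)
    return out


def gen_proteins(spec: SyntheticSpec,
                 rng: np.random.Generator | None = None) -> list[str]:
    """Random or periodic sequences with lengths uniform on the given range."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.prot_len_range
    seqs = []
    letters = np.array(list(AMINO_ACIDS))
    for _ in range(spec.n_pairs):
        length = int(rng.integers(lo, hi + 1))
        if spec.repeat_period:
            unit = rng.choice(letters, size=spec.repeat_period)
            reps = math.ceil(length / spec.repeat_period)
            seq = "".join(np.tile(unit, reps)[:length])
        else:
            seq = "".join(rng.choice(letters, size=length))
        seqs.append(seq)
    return seqs


def _descriptors(smiles: str, sequence: str) -> tuple[float, float, float]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigError(f"label function got invalid SMILES {smiles!r}")
    heavy = float(mol.GetNumAtoms())
    rings = float(rdMolDescriptors.CalcNumAromaticRings(mol))
    hydro = sum(1 for aa in sequence if aa in HYDROPHOBIC_RESIDUES) / len(sequence)
    return heavy, rings, hydro


def noiseless_affinity(smiles: str, sequence: str) -> float:
    """The deterministic part of the synthetic label function."""
    heavy, rings, hydro = _descriptors(smiles, sequence)
    c = AFFINITY_COEFFS
    return (c["alpha"] * heavy + c["beta"] * rings
            + c["gamma"] * hydro + c["delta"] * heavy * hydro)


def gen_affinity(smiles: str, sequence: str, noise_sd: float,
                 rng: np.random.Generator | int) -> float:
    """Noiseless label plus Gaussian(0, noise_sd) measurement noise."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    label = noiseless_affinity(smiles, sequence)
    if noise_sd > 0:
        label += float(rng.normal(0.0, noise_sd))
    return float(label)


def gen_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Paired (smiles, sequence, affinity) table, fully seeded by the spec."""
    rng = np.random.default_rng(spec.seed)
    molecules = gen_molecules(spec, rng)
    proteins = gen_proteins(spec, rng)
    rows = [
        {"smiles": s, "sequence": p,
         "affinity": gen_affinity(s, p, spec.noise_sd, rng)}
        for s, p in zip(molecules, proteins)
    ]
    return pd.DataFrame(rows)


def write_dta_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_fasta(sequences: list[str], path: str | Path,
                prefix: str = "synthetic") -> Path:
    """Write a pretraining corpus; records are named `{prefix}_{i}`."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=f"{prefix}_{i}", description="")
               for i, s in enumerate(sequences)]
    path = Path(path)
    seqio_write(records, str(path), "fasta")
    return path
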