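"""SMILES parsing and molecular-graph featurization.

Molecules are heavy-atom graphs (implicit hydrogens) with undirected
bonds stored once. Besides plain adjacency, the graph carries the two
incidence structures message passing needs: atom -> incident bonds and
bond -> neighbouring bonds (bonds sharing exactly one endpoint).

Atom and bond descriptors are the conventional one-hot sets used by
message-passing chemistry models: element, degree, formal charge,
attached hydrogens and hybridisation for atoms (plus an aromaticity
bit); bond order, conjugation and ring membership for bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import DataError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolecularGraph", "smiles_to_graph", "featurize_atom", "featurize_bond",
    "read_smiles_file", "ATOM_FEATURE_DIM", "BOND_FEATURE_DIM",
]

# one-hot vocabularies; the final element slot is the catch-all "other"
_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "other"]
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-2, -1, 0, 1, 2]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
    "other",
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FEATURE_DIM = (len(_ELEMENTS) + len(_DEGREES) + len(_CHARGES)
                    + len(_NUM_HS) + len(_HYBRID) + 1)
BOND_FEATURE_DIM = len(_BOND_TYPES) + 2


def _one_hot(value, choices: list) -> list[float]:
    """One-hot with the last slot as fallback when value is unlisted."""
    vec = [0.0] * len(choices)
    idx = choices.index(value) if value in choices else len(choices) - 1
    vec[idx] = 1.0
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Binary descriptor row for one atom (a row of x_v)."""
    feats = (
        _one_hot(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(atom.GetDegree(), _DEGREES)
        + _one_hot(atom.GetFormalCharge(), _CHARGES)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        + _one_hot(atom.GetHybridization(), _HYBRID)
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.array(feats)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Binary descriptor row for one bond (a row of x_e)."""
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
    )
    return np.array(feats)


@dataclass
class MolecularGraph:
    """Undirected featurized molecular graph.

    ``bond_neighbors[b]`` lists bonds sharing exactly one endpoint atom
    with ``b`` (never ``b`` itself); ``endpoints[b]`` is the unordered
    atom pair of bond ``b``.
    """

    n_atoms: int
    n_bonds: int
    atom_features: np.ndarray            # [n_atoms, d_atom]
    bond_features: np.ndarray            # [n_bonds, d_bond]
    atom_neighbors: list[set[int]]
    incident_bonds: list[set[int]]
    bond_neighbors: list[set[int]]
    endpoints: list[tuple[int, int]]
    smiles: str = ""
    _packed: dict = field(default_factory=dict, repr=False, compare=False)

    def packed_adjacency(self) -> dict[str, np.ndarray]:
        """Padded index/mask arrays for vectorised neighbourhood pooling.

        Returns int index matrices and {0,1} masks, one pair per
        adjacency map; padded slots point at index 0 and are masked out.
        """
        if self._packed:
            return self._packed

        def pack(sets: list[set[int]]):
            k = max((len(s) for s in sets), default=0)
            k = max(k, 1)
            idx = np.zeros((len(sets), k), dtype=np.intp)
            mask = np.zeros((len(sets), k))
            for i, s in enumerate(sets):
                for j, m in enumerate(sorted(s)):
                    idx[i, j] = m
                    mask[i, j] = 1.0
            return idx, mask

        for name, sets in (("incident", self.incident_bonds),
                           ("neighbors", self.atom_neighbors),
                           ("bond_nbrs", self.bond_neighbors)):
            self._packed[name + "_idx"], self._packed[name + "_mask"] = pack(sets)
        return self._packed


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized :class:`MolecularGraph`.

    Raises :class:`DataError` for empty input and
    :class:`SmilesParseError` for unparseable strings.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise DataError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)

    n_atoms = mol.GetNumAtoms()
    n_bonds = mol.GetNumBonds()
    atom_features = np.stack([featurize_atom(a) for a in mol.GetAtoms()])
    bond_features = (np.stack([featurize_bond(b) for b in mol.GetBonds()])
                     if n_bonds else np.zeros((0, BOND_FEATURE_DIM)))

    atom_neighbors = [set() for _ in range(n_atoms)]
    incident_bonds = [set() for _ in range(n_atoms)]
    endpoints: list[tuple[int, int]] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        e = b.GetIdx()
        atom_neighbors[i].add(j)
        atom_neighbors[j].add(i)
        incident_bonds[i].add(e)
        incident_bonds[j].add(e)
        endpoints.append((min(i, j), max(i, j)))

    bond_neighbors = [set() for _ in range(n_bonds)]
    for e, (i, j) in enumerate(endpoints):
        for v in (i, j):
            for other in incident_bonds[v]:
                if other != e:
                    bond_neighbors[e].add(other)

    return MolecularGraph(
        n_atoms=n_atoms, n_bonds=n_bonds,
        atom_features=atom_features, bond_features=bond_features,
        atom_neighbors=atom_neighbors, incident_bonds=incident_bonds,
        bond_neighbors=bond_neighbors, endpoints=endpoints, smiles=smiles,
    )


def read_smiles_file(path: str | Path) -> list[MolecularGraph]:
    """Parse a text file of one SMILES per line (blank lines skipped)."""
    graphs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s:
            continue
        try:
            graphs.append(smiles_to_graph(s))
        except SmilesParseError as exc:
            raise SmilesParseError(s, f"line {lineno}: {exc}") from exc
    return graphs
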