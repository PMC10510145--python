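"""Undirected communicative message passing over molecular graphs.

Atoms and bonds carry hidden vectors of a common width d. Each layer
exchanges messages along three undirected routes — bond→atom,
atom→atom and bond→bond — where every neighbourhood is pooled as

    F(set) = elementwise-max(set) ⊙ elementwise-sum(set)

(⊙ = Hadamard product; an empty neighbourhood pools to the zero
vector). The pooled message gates the receiver's own hidden state, the
atom state accumulates all three self/neighbour terms additively, and
the bond state passes through a learned linear map, ReLU and dropout
with a residual connection. After L layers the final atom states are
concatenated with the last layer's two aggregated atom terms, passed
through a communicate map (affine 3d→d + ReLU) and sum-pooled into the
molecule embedding E_m, which is invariant to atom renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Linear, ParamModule, dropout, glorot
from .chem import MolecularGraph
from .errors import ConfigError, StateError

__all__ = [
    "LayerState", "MolEncoder",
    "aggregate_bonds_to_atom", "aggregate_atoms_to_atom",
    "aggregate_bonds_to_bond",
]


@dataclass
class LayerState:
    """Hidden atom/bond features after `layer_index` message-passing layers."""

    h_atoms: Tensor                      # [n_atoms, d]
    h_bonds: Tensor                      # [n_bonds, d]
    layer_index: int
    aux: dict | None = field(default=None, repr=False)


def _as_data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _pool_set(hidden: np.ndarray, members: set[int], width: int) -> np.ndarray:
    """max ⊙ sum over a neighbourhood; zero vector when the set is empty."""
    if not members:
        return np.zeros(width)
    rows = hidden[sorted(members)]
    return rows.max(axis=0) * rows.sum(axis=0)


def aggregate_bonds_to_atom(state: LayerState, graph: MolecularGraph,
                            v: int) -> np.ndarray:
    """Pooled message from the bonds incident to atom ``v``."""
    h = _as_data(state.h_bonds)
    return _pool_set(h, graph.incident_bonds[v], _as_data(state.h_atoms).shape[1])


def aggregate_atoms_to_atom(state: LayerState, graph: MolecularGraph,
                            v: int) -> np.ndarray:
    """Pooled message from the atoms adjacent to atom ``v``."""
    h = _as_data(state.h_atoms)
    return _pool_set(h, graph.atom_neighbors[v], h.shape[1])


def aggregate_bonds_to_bond(state: LayerState, graph: MolecularGraph,
                            e: int) -> np.ndarray:
    """Pooled message from the bonds sharing one endpoint with bond ``e``."""
    h = _as_data(state.h_bonds)
    return _pool_set(h, graph.bond_neighbors[e], _as_data(state.h_atoms).shape[1])


def _pool_packed(h: Tensor, idx: np.ndarray, mask: np.ndarray) -> Tensor:
    """Vectorised max ⊙ sum over padded neighbourhoods (mask rows of zeros
    yield exactly the zero vector)."""
    g = h.take(idx)                                  # [n, k, d]
    m = Tensor(mask[:, :, None])
    s = (g * m).sum(axis=1)
    # push padded slots to -inf-like values before the max
    mx = (g * m + Tensor((mask[:, :, None] - 1.0) * 1e30)).max(axis=1)
    has = Tensor((mask.sum(axis=1) > 0).astype(np.float64)[:, None])
    return mx * s * has


class MolEncoder(ParamModule):
    """Undirected-CMPNN molecule encoder.

    Parameters
    ----------
    rng : numpy Generator used for weight initialisation.
    atom_dim, bond_dim : widths of the featurizer output rows.
    hidden_dim : common hidden width d of atom and bond states.
    depth : number of message-passing layers L (>= 1).
    dropout_rate : bond-update dropout probability in [0, 1).
    """

    def __init__(self, rng: np.random.Generator, atom_dim: int, bond_dim: int,
                 hidden_dim: int = 128, depth: int = 3,
                 dropout_rate: float = 0.1):
        if depth < 1:
            raise ConfigError("encoder depth must be >= 1")
        if not 0.0 <= dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        self.atom_dim = atom_dim
        self.bond_dim = bond_dim
        self.hidden_dim = hidden_dim
        self.depth = depth
        self.dropout_rate = dropout_rate
        self.init_linear_atom = Linear(rng, atom_dim, hidden_dim)
        self.init_linear_bond = Linear(rng, bond_dim, hidden_dim)
        # per-layer bond-update weight W (no bias: the residual carries h_e)
        self.bond_update_weight = [
            Tensor(glorot(rng, hidden_dim, hidden_dim), requires_grad=True)
            for _ in range(depth)
        ]
        self.communicate_map = Linear(rng, 3 * hidden_dim, hidden_dim)

    # ------------------------------------------------------------------ init
    def init_hidden(self, graph: MolecularGraph) -> LayerState:
        """ReLU-activated affine encodings of the raw atom/bond descriptors."""
        if graph.atom_features.shape[1] != self.atom_dim:
            raise ConfigError(
                f"atom feature width {graph.atom_features.shape[1]} does not "
                f"match encoder atom_dim {self.atom_dim}")
        if graph.n_bonds and graph.bond_features.shape[1] != self.bond_dim:
            raise ConfigError(
                f"bond feature width {graph.bond_features.shape[1]} does not "
                f"match encoder bond_dim {self.bond_dim}")
        h_v = self.init_linear_atom(Tensor(graph.atom_features)).relu()
        if graph.n_bonds:
            h_e = self.init_linear_bond(Tensor(graph.bond_features)).relu()
        else:
            h_e = Tensor(np.zeros((0, self.hidden_dim)))
        return LayerState(h_atoms=h_v, h_bonds=h_e, layer_index=0)

    # ----------------------------------------------------------------- layer
    def layer_forward(self, state: LayerState, graph: MolecularGraph,
                      training: bool = False,
                      rng: np.random.Generator | None = None) -> LayerState:
        """One message-passing layer l-1 -> l.

        The returned state carries, in ``aux``, the two aggregated atom
        terms (bond→atom and atom→atom messages gated by the previous
        atom state) that the readout of the final layer consumes.
        """
        if state.layer_index >= self.depth:
            raise StateError(
                f"state is already at depth {state.layer_index} of {self.depth}")
        packed = graph.packed_adjacency()
        h_v, h_e = state.h_atoms, state.h_bonds
        zero_atoms = Tensor(np.zeros((graph.n_atoms, self.hidden_dim)))

        if graph.n_bonds:
            f_ev = _pool_packed(h_e, packed["incident_idx"],
                                packed["incident_mask"])
        else:
            f_ev = zero_atoms
        if graph.n_atoms > 1 and any(graph.atom_neighbors):
            f_vv = _pool_packed(h_v, packed["neighbors_idx"],
                                packed["neighbors_mask"])
        else:
            f_vv = zero_atoms

        h_ev = h_v * f_ev                     # bond→atom message, gated
        h_vv = h_v * f_vv                     # atom→atom message, gated
        new_h_v = h_ev + h_vv + h_v

        if graph.n_bonds:
            f_ee = _pool_packed(h_e, packed["bond_nbrs_idx"],
                                packed["bond_nbrs_mask"])
            h_ee = h_e * f_ee                 # bond→bond message, gated
            W = self.bond_update_weight[state.layer_index]
            new_h_e = (h_ee @ W + h_e).relu()
            new_h_e = dropout(new_h_e, self.dropout_rate, rng, training)
        else:
            new_h_e = h_e

        return LayerState(h_atoms=new_h_v, h_bonds=new_h_e,
                          layer_index=state.layer_index + 1,
                          aux={"h_ev": h_ev, "h_vv": h_vv})

    # --------------------------------------------------------------- readout
    def readout(self, final_state: LayerState, graph: MolecularGraph) -> Tensor:
        """Communicate-and-pool: [h_v, h_vv, h_ev] → affine+ReLU → sum over atoms."""
        if final_state.layer_index != self.depth:
            raise StateError(
                f"readout expects a depth-{self.depth} state, got layer "
                f"{final_state.layer_index}")
        if final_state.aux is None:
            raise StateError("final state lacks the aggregated atom terms")
        cat = concat([final_state.h_atoms, final_state.aux["h_vv"],
                      final_state.aux["h_ev"]], axis=1)
        per_atom = self.communicate_map(cat).relu()
        return per_atom.sum(axis=0)

    # ------------------------------------------------------------------- all
    def encode(self, graph: MolecularGraph, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Full pass: init, L message-passing layers, readout → E_m (width d)."""
        state = self.init_hidden(graph)
        for _ in range(self.depth):
            state = self.layer_forward(state, graph, training=training, rng=rng)
        return self.readout(state, graph)
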