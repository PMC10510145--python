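"""Message passing encoder: hand-worked examples, the scalar-loop oracle,
permutation invariance and gradient correctness."""

import numpy as np
import pytest

from dtakit._autodiff import Tensor
from dtakit.chem import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, smiles_to_graph
from dtakit.errors import ConfigError, StateError
from dtakit.mol_encoder import (LayerState, MolEncoder, aggregate_atoms_to_atom,
                                aggregate_bonds_to_atom, aggregate_bonds_to_bond)
from dtakit.synthetic import SyntheticSpec, gen_molecules
from rdkit import Chem

from oracles import cmpnn_scalar, encoder_weights_as_lists, \
    finite_difference_grads, max_relative_error


def _state(graph, h_atoms, h_bonds, layer=0):
    return LayerState(h_atoms=Tensor(np.asarray(h_atoms, dtype=float)),
                      h_bonds=Tensor(np.asarray(h_bonds, dtype=float)),
                      layer_index=layer)


# ------------------------------------------------------------ initialization
def test_init_hidden_zero_weights_gives_zero_state(tiny_encoder, cyclopropane):
    for p in tiny_encoder.init_linear_atom.parameters().values():
        p.data[...] = 0.0
    for p in tiny_encoder.init_linear_bond.parameters().values():
        p.data[...] = 0.0
    s = tiny_encoder.init_hidden(cyclopropane)
    assert not np.any(s.h_atoms.data) and not np.any(s.h_bonds.data)


def test_init_hidden_relu_clamps_negative_bias(rng, cyclopropane):
    enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, hidden_dim=8,
                     depth=1, dropout_rate=0.0)
    enc.init_linear_atom.W.data[...] = 0.0
    enc.init_linear_atom.b.data[...] = -1.0
    s = enc.init_hidden(cyclopropane)
    assert np.all(s.h_atoms.data == 0.0)
    assert np.all(s.h_atoms.data >= 0) and np.all(s.h_bonds.data >= 0)


def test_init_hidden_matches_scalar_affine(tiny_encoder, propane):
    s = tiny_encoder.init_hidden(propane)
    W = tiny_encoder.init_linear_atom.W.data
    b = tiny_encoder.init_linear_atom.b.data
    for v in range(propane.n_atoms):
        expect = np.maximum(propane.atom_features[v] @ W + b, 0.0)
        np.testing.assert_allclose(s.h_atoms.data[v], expect, atol=1e-12)


def test_init_hidden_dimension_mismatch(rng, cyclopropane):
    enc = MolEncoder(rng, atom_dim=5, bond_dim=3, hidden_dim=8, depth=1)
    with pytest.raises(ConfigError):
        enc.init_hidden(cyclopropane)


def test_depth_zero_rejected(rng):
    with pytest.raises(ConfigError):
        MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, depth=0)


# -------------------------------------------------------------- aggregations
def test_single_incident_bond_squares_elementwise():
    g = smiles_to_graph("CC")
    s = _state(g, [[0.0, 0.0], [0.0, 0.0]], [[2.0, 3.0]])
    np.testing.assert_allclose(aggregate_bonds_to_atom(s, g, 0), [4.0, 9.0])


def test_two_incident_bonds_max_times_sum(propane):
    # centre atom of propane touches both bonds: hiddens [1,0] and [0,1]
    s = _state(propane, np.zeros((3, 2)), [[1.0, 0.0], [0.0, 1.0]])
    np.testing.assert_allclose(aggregate_bonds_to_atom(s, propane, 1),
                               [1.0, 1.0])


def test_isolated_atom_aggregates_to_zero():
    g = smiles_to_graph("C")
    s = _state(g, [[1.0, 2.0]], np.zeros((0, 2)))
    np.testing.assert_allclose(aggregate_bonds_to_atom(s, g, 0), [0.0, 0.0])
    np.testing.assert_allclose(aggregate_atoms_to_atom(s, g, 0), [0.0, 0.0])


def test_single_neighbor_atom_squares_elementwise():
    g = smiles_to_graph("CC")
    s = _state(g, [[0.0, 0.0], [-1.0, 2.0]], [[0.0, 0.0]])
    np.testing.assert_allclose(aggregate_atoms_to_atom(s, g, 0), [1.0, 4.0])


def test_two_neighbor_atoms_max_times_sum(propane):
    s = _state(propane, [[1.0, 2.0], [0.0, 0.0], [3.0, 0.0]], np.zeros((2, 2)))
    # neighbours of the centre: max [3,2] ⊙ sum [4,2] = [12,4]
    np.testing.assert_allclose(aggregate_atoms_to_atom(s, propane, 1),
                               [12.0, 4.0])


def test_bond_with_no_neighbor_bonds_gives_zero():
    g = smiles_to_graph("CC")
    s = _state(g, np.zeros((2, 2)), [[5.0, 7.0]])
    np.testing.assert_allclose(aggregate_bonds_to_bond(s, g, 0), [0.0, 0.0])


def test_cyclopropane_bond_neighbors_pool(cyclopropane):
    h_bonds = np.zeros((3, 2))
    h_bonds[1] = [1.0, 1.0]
    h_bonds[2] = [2.0, 0.0]
    s = _state(cyclopropane, np.zeros((3, 2)), h_bonds)
    # neighbours of bond 0 are bonds 1 and 2: max [2,1] ⊙ sum [3,1] = [6,1]
    np.testing.assert_allclose(aggregate_bonds_to_bond(s, cyclopropane, 0),
                               [6.0, 1.0])
    # the bond's own hidden state never participates
    s.h_bonds.data[0] = [100.0, 100.0]
    np.testing.assert_allclose(aggregate_bonds_to_bond(s, cyclopropane, 0),
                               [6.0, 1.0])


# -------------------------------------------------------------- layer update
def test_layer_forward_zero_state_stays_zero(tiny_encoder, cyclopropane):
    s = _state(cyclopropane, np.zeros((3, 8)), np.zeros((3, 8)))
    out = tiny_encoder.layer_forward(s, cyclopropane)
    assert not np.any(out.h_atoms.data) and not np.any(out.h_bonds.data)
    assert out.layer_index == 1


def test_layer_forward_edgeless_graph_keeps_atom_state(tiny_encoder):
    g = smiles_to_graph("C.C")
    s = _state(g, np.ones((2, 8)), np.zeros((0, 8)))
    out = tiny_encoder.layer_forward(s, g)
    np.testing.assert_array_equal(out.h_atoms.data, np.ones((2, 8)))


def test_layer_forward_past_depth_raises(tiny_encoder, cyclopropane):
    s = _state(cyclopropane, np.zeros((3, 8)), np.zeros((3, 8)), layer=3)
    with pytest.raises(StateError):
        tiny_encoder.layer_forward(s, cyclopropane)


def test_encoder_matches_scalar_loop_oracle(rng):
    """Random 4-atom ring and other small molecules: vectorised encoder
    equals the independent scalar recurrence within 1e-6."""
    for smiles in ["C1CCC1", "CC(C)=O", "c1ccccc1", "CC"]:
        g = smiles_to_graph(smiles)
        enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM,
                         hidden_dim=8, depth=3, dropout_rate=0.0)
        got = enc.encode(g).data
        want = cmpnn_scalar(g, encoder_weights_as_lists(enc), enc.depth)
        np.testing.assert_allclose(got, want, atol=1e-6, rtol=1e-9)


def test_dropout_disabled_outside_training(tiny_encoder, cyclopropane, rng):
    enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, hidden_dim=8,
                     depth=2, dropout_rate=0.5)
    a = enc.encode(cyclopropane).data
    b = enc.encode(cyclopropane).data
    np.testing.assert_array_equal(a, b)
    c = enc.encode(cyclopropane, training=True,
                   rng=np.random.default_rng(0)).data
    assert not np.array_equal(a, c)


# ------------------------------------------------------------------- readout
def test_readout_single_atom_is_pool_of_one(tiny_encoder):
    g = smiles_to_graph("C")
    em = tiny_encoder.encode(g).data
    state = tiny_encoder.init_hidden(g)
    for _ in range(tiny_encoder.depth):
        state = tiny_encoder.layer_forward(state, g)
    cat = np.concatenate([state.h_atoms.data[0], state.aux["h_vv"].data[0],
                          state.aux["h_ev"].data[0]])
    expect = np.maximum(cat @ tiny_encoder.communicate_map.W.data
                        + tiny_encoder.communicate_map.b.data, 0.0)
    np.testing.assert_allclose(em, expect, atol=1e-12)


def test_readout_zero_communicate_map_gives_zero(rng, cyclopropane):
    enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, hidden_dim=8,
                     depth=1, dropout_rate=0.0)
    enc.communicate_map.W.data[...] = 0.0
    enc.communicate_map.b.data[...] = 0.0
    np.testing.assert_array_equal(enc.encode(cyclopropane).data, np.zeros(8))


def test_readout_is_additive_over_disconnected_copies(tiny_encoder):
    one = tiny_encoder.encode(smiles_to_graph("CCO")).data
    two = tiny_encoder.encode(smiles_to_graph("CCO.CCO")).data
    np.testing.assert_allclose(two, 2 * one, rtol=1e-9)


def test_depth_one_encoder_is_finite_everywhere(rng):
    enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, hidden_dim=8,
                     depth=1, dropout_rate=0.0)
    for smiles in ["C", "CC", "C1CC1", "c1ccccc1", "CC(=O)O"]:
        assert np.all(np.isfinite(enc.encode(smiles_to_graph(smiles)).data))


# ------------------------------------------------------ invariance / gradients
def test_permutation_invariance_of_embedding(rng, tiny_encoder):
    spec = SyntheticSpec(n_pairs=10, mol_atom_range=(3, 8), seed=5)
    for smiles in gen_molecules(spec):
        mol = Chem.MolFromSmiles(smiles)
        scrambled = Chem.MolToSmiles(mol, canonical=False, doRandom=True)
        a = tiny_encoder.encode(smiles_to_graph(smiles)).data
        b = tiny_encoder.encode(smiles_to_graph(scrambled)).data
        assert max_relative_error(a, b) < 1e-5


def test_gradient_matches_finite_differences(rng):
    """∂E_m/∂params on a 3-atom molecule agrees with central differences."""
    g = smiles_to_graph("CCO")
    enc = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM, hidden_dim=4,
                     depth=2, dropout_rate=0.0)
    direction = np.random.default_rng(0).normal(size=4)

    def scalar():
        return float(enc.encode(g).data @ direction)

    out = (enc.encode(g) * Tensor(direction)).sum()
    out.backward()
    params = [p for p in enc.parameters().values()]
    fd = finite_difference_grads(scalar, params)
    for p, g_fd in zip(params, fd):
        got = p.grad if p.grad is not None else np.zeros_like(p.data)
        assert max_relative_error(got, g_fd, floor=1e-3) < 1e-4
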