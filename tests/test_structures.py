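"""Molecule identification, component typing, monomer extraction, k-grids."""

import itertools

import numpy as np
import pytest

from deltagap.structures import (
    ComponentEntry,
    ComponentLibrary,
    MoleculeIdentificationError,
    PeriodicStructure,
    assign_component_types,
    extract_monomer,
    identify_molecules,
    kpoint_grid,
)

from conftest import water_box


def brute_force_partition(structure, tolerance=1.2):
    """Oracle: cluster atoms in an explicit 3x3x3 supercell, then fold the
    connected component containing each central-cell atom back to indices."""
    from deltagap.structures import COVALENT_RADII

    n = structure.n_atoms
    shifts = list(itertools.product((-1, 0, 1), repeat=3))
    coords = np.vstack([structure.positions + np.array(s) @ structure.cell for s in shifts])
    species = list(structure.species) * len(shifts)
    radii = np.array([COVALENT_RADII[s] for s in species])
    cut = tolerance * (radii[:, None] + radii[None, :])
    d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=-1)
    adj = (d <= cut) & (d > 1e-12)
    # union-find over the supercell
    parent = list(range(len(coords)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(*np.nonzero(adj)):
        pi, pj = find(i), find(j)
        if pi != pj:
            parent[pi] = pj
    # collect, for every component containing a central-cell atom, the base
    # (mod n) indices of all its members
    central_offset = shifts.index((0, 0, 0)) * n
    members = {}
    for k in range(len(coords)):
        members.setdefault(find(k), set()).add(k % n)
    groups = {}
    for i in range(n):
        groups.setdefault(find(central_offset + i), members[find(central_offset + i)])
    return {frozenset(g) for g in groups.values()}


class TestIdentifyMolecules:
    def test_two_waters_in_cubic_cell(self):
        units = identify_molecules(water_box(), 1.2)
        assert len(units) == 2
        assert all(len(u.atom_indices) == 3 for u in units)

    def test_single_atom(self):
        s = PeriodicStructure(("O",), [[5.0, 5.0, 5.0]], np.eye(3) * 10)
        units = identify_molecules(s)
        assert len(units) == 1
        assert np.all(units[0].image_shifts == 0)

    def test_boundary_crossing_diatomic_matches_supercell_oracle(self):
        cell = np.eye(3) * 9.0
        s = PeriodicStructure(("N", "N"), [[0.98 * 9, 4, 4], [0.02 * 9, 4, 4]], cell)
        units = identify_molecules(s)
        assert len(units) == 1
        pos = s.positions[units[0].atom_indices] + units[0].image_shifts @ cell
        bond = np.linalg.norm(pos[1] - pos[0])
        assert bond == pytest.approx(0.04 * 9, abs=1e-10)
        assert {frozenset(u.atom_indices) for u in units} == brute_force_partition(s)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_supercell_oracle_on_random_crystals(self, library, seed):
        from deltagap.toyverse import generate_trial_crystals

        s = generate_trial_crystals(library, [{"active": 3, "n2o": 3}], 1, seed=seed)[0]
        units = identify_molecules(s)
        assert {frozenset(u.atom_indices) for u in units} == brute_force_partition(s)

    def test_translation_and_permutation_invariance(self, rng):
        s = water_box()
        units0 = {frozenset(u.atom_indices) for u in identify_molecules(s)}
        shifted = PeriodicStructure(s.species, s.positions + rng.uniform(-4, 4, 3), s.cell)
        assert {frozenset(u.atom_indices) for u in identify_molecules(shifted)} == units0
        perm = rng.permutation(s.n_atoms)
        permuted = PeriodicStructure(
            tuple(s.species[i] for i in perm), s.positions[perm], s.cell
        )
        # permuted atom j is original atom perm[j]: unit membership must map back
        got = {
            frozenset(int(perm[i]) for i in u.atom_indices)
            for u in identify_molecules(permuted)
        }
        assert got == units0

    def test_partition_covers_all_atoms_once(self, toy_crystals):
        for s in toy_crystals:
            units = identify_molecules(s)
            all_idx = np.concatenate([u.atom_indices for u in units])
            assert sorted(all_idx) == list(range(s.n_atoms))

    def test_periodic_polymer_raises(self):
        # chain of C atoms spanning the cell through its own image
        cell = np.eye(3) * 3.0
        s = PeriodicStructure(("C", "C"), [[0, 0, 0], [1.5, 0, 0]], cell)
        with pytest.raises(MoleculeIdentificationError):
            identify_molecules(s)

    def test_unknown_element_raises(self):
        s = PeriodicStructure(("Xx",), [[0, 0, 0]], np.eye(3) * 5)
        with pytest.raises(ValueError, match="unknown element"):
            identify_molecules(s)


class TestComponentTyping:
    def test_water_vs_ammonia_library(self):
        lib = ComponentLibrary()
        lib.add("water", ComponentEntry(("O", "H", "H"), ((0, 1), (0, 2)),
                                        [[0, 0, 0], [0.76, 0.59, 0], [-0.76, 0.59, 0]]))
        lib.add("ammonia", ComponentEntry(("N", "H", "H", "H"), ((0, 1), (0, 2), (0, 3)),
                                          [[0, 0, 0], [0.94, 0.38, 0], [-0.47, 0.38, 0.81],
                                           [-0.47, 0.38, -0.81]]))
        s = water_box()
        units = assign_component_types(identify_molecules(s), s, lib)
        assert all(u.component_type == "water" for u in units)

    def test_empty_library_gives_unknown(self):
        s = water_box()
        units = assign_component_types(identify_molecules(s), s, ComponentLibrary())
        assert all(u.component_type == "unknown" for u in units)

    def test_structural_isomers_distinct(self):
        # same formula C2H2O2, different bond graphs
        lib = ComponentLibrary()
        lib.add("chain", ComponentEntry(("O", "C", "C", "O", "H", "H"),
                                        ((0, 1), (1, 2), (2, 3), (1, 4), (2, 5)),
                                        np.zeros((6, 3))))
        lib.add("branch", ComponentEntry(("O", "C", "C", "O", "H", "H"),
                                         ((0, 1), (1, 2), (1, 3), (2, 4), (2, 5)),
                                         np.zeros((6, 3))))
        g1, g2 = lib["chain"].graph(), lib["branch"].graph()
        import networkx as nx

        assert not nx.is_isomorphic(g1, g2, node_match=lambda a, b: a["element"] == b["element"])

    def test_isomorphic_duplicate_rejected(self):
        lib = ComponentLibrary()
        lib.add("a", ComponentEntry(("N", "N"), ((0, 1),), [[0, 0, 0], [1.1, 0, 0]]))
        with pytest.raises(ValueError, match="isomorphic"):
            lib.add("b", ComponentEntry(("N", "N"), ((0, 1),), [[0, 0, 0], [1.2, 0, 0]]))

    def test_generated_crystal_types_roundtrip(self, library, toy_crystals):
        from collections import Counter

        s = toy_crystals[0]  # active:3 n2:3
        units = assign_component_types(identify_molecules(s), s, library)
        assert Counter(u.component_type for u in units) == {"active": 3, "n2": 3}


class TestExtractMonomer:
    def test_interior_unit_keeps_coordinates(self):
        s = water_box()
        u = identify_molecules(s)[0]
        mono = extract_monomer(s, u)
        assert not mono.periodic
        np.testing.assert_allclose(mono.positions, s.positions[u.atom_indices])

    def test_boundary_unit_restores_bond_length(self):
        cell = np.eye(3) * 9.0
        s = PeriodicStructure(("N", "N"), [[0.98 * 9, 4, 4], [0.02 * 9, 4, 4]], cell)
        mono = extract_monomer(s, identify_molecules(s)[0])
        assert np.linalg.norm(mono.positions[1] - mono.positions[0]) == pytest.approx(0.36)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_distance_matrix_invariant_to_wrapping(self, rng, seed):
        s = water_box()
        u0 = identify_molecules(s)[0]
        ref = extract_monomer(s, u0).positions
        ref_d = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        # rewrap with random lattice translations per atom
        shifts = np.random.default_rng(seed).integers(-2, 3, (s.n_atoms, 3))
        wrapped = PeriodicStructure(s.species, s.positions + shifts @ s.cell, s.cell)
        u = next(
            un for un in identify_molecules(wrapped) if set(un.atom_indices) == set(u0.atom_indices)
        )
        pos = extract_monomer(wrapped, u).positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.testing.assert_allclose(np.sort(d.ravel()), np.sort(ref_d.ravel()), atol=1e-10)

    def test_invalid_indices_raise(self):
        s = water_box()
        u = identify_molecules(s)[0]
        u.atom_indices = np.array([0, 99])
        u.image_shifts = np.zeros((2, 3), dtype=int)
        with pytest.raises(ValueError):
            extract_monomer(s, u)


class TestKpointGrid:
    @pytest.mark.parametrize(
        "lengths, x, expected",
        [
            ((10, 10, 10), 30, (3, 3, 3)),
            ((7, 31, 15), 30, (5, 1, 2)),
            ((30, 30, 30), 30, (1, 1, 1)),
        ],
    )
    def test_smallest_integer_rule(self, lengths, x, expected):
        assert kpoint_grid(np.diag(lengths), x) == expected

    def test_rule_property(self, rng):
        for _ in range(50):
            lengths = rng.uniform(2, 40, 3)
            x = rng.uniform(5, 60)
            n = kpoint_grid(np.diag(lengths), x)
            for ni, a in zip(n, lengths):
                assert ni * a >= x - 1e-9
                assert ni == 1 or (ni - 1) * a < x

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            kpoint_grid(np.diag([1, 1, 1]), -5)
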