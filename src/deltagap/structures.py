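"""Periodic crystal structures, molecule identification, and cell utilities.

Coordinates are Cartesian angstroms throughout; unit cells are row-major
(rows are lattice vectors).  Fractional coordinates appear only internally.
Molecules are recovered from a crystal by partitioning the periodic bond
graph: two atoms are bonded iff any minimum-image distance is below
``tolerance * (r_cov_i + r_cov_j)``.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "COVALENT_RADII",
    "ComponentEntry",
    "ComponentLibrary",
    "EFSResult",
    "MolecularUnit",
    "MoleculeIdentificationError",
    "PeriodicStructure",
    "rescale_cell",
    "assign_component_types",
    "extract_monomer",
    "identify_molecules",
    "kpoint_grid",
]

# Single-bond covalent radii (A), Cordero et al. values for the organic set
# plus a few common heteroatoms.
COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39,
}

# Standard atomic weights (amu), pinned in-code for reproducible densities.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Br": 79.904, "I": 126.90447,
}

AMU_TO_GRAM = 1.66053906660e-24
ANG3_TO_CM3 = 1.0e-24


class MoleculeIdentificationError(RuntimeError):
    """Raised when the periodic bond graph cannot be partitioned into
    finite molecules (e.g. a component bonds to its own periodic image)."""


@dataclass
class EFSResult:
    """Energy (eV), per-atom forces (eV/A) and optional 3x3 virial (eV).

    The virial follows the convention ``virial = -dE/d(strain)``; stress is
    ``-virial / volume`` with tension negative.
    """

    energy: float
    forces: np.ndarray
    virial: np.ndarray | None = None
    local_energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must have shape (n_atoms, 3)")
        if self.virial is not None:
            self.virial = np.asarray(self.virial, dtype=float)
            if self.virial.shape != (3, 3):
                raise ValueError("virial must be 3x3")
            if not np.allclose(self.virial, self.virial.T, atol=1e-10):
                raise ValueError("virial must be symmetric within 1e-10 eV")

    def validate_for(self, structure: "PeriodicStructure") -> None:
        if len(self.forces) != structure.n_atoms:
            raise ValueError("forces shape does not match atom count")


@dataclass
class PeriodicStructure:
    """A (possibly periodic) collection of atoms.

    Attributes
    ----------
    species : tuple of element symbols, one per atom.
    positions : (N, 3) Cartesian coordinates in A.
    cell : (3, 3) lattice vectors as rows, in A.
    pbc : three booleans.
    labels : optional :class:`EFSResult` attached to this geometry.
    provenance : free-text tag recording how the structure was made.
    """

    species: tuple[str, ...]
    positions: np.ndarray
    cell: np.ndarray
    pbc: tuple[bool, bool, bool] = (True, True, True)
    labels: EFSResult | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        self.positions = np.array(self.positions, dtype=float).reshape(-1, 3)
        self.cell = np.array(self.cell, dtype=float).reshape(3, 3)
        self.pbc = tuple(bool(b) for b in self.pbc)
        if len(self.species) != len(self.positions):
            raise ValueError("positions length must equal species length")
        if all(self.pbc) and np.linalg.det(self.cell) <= 0:
            raise ValueError("cell must have strictly positive determinant")
        if self.labels is not None:
            self.labels.validate_for(self)

    # -- basic geometry -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def periodic(self) -> bool:
        return any(self.pbc)

    def volume(self) -> float:
        return float(abs(np.linalg.det(self.cell)))

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[s] for s in self.species])
        except KeyError as exc:  # pragma: no cover - message only
            raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc

    def density(self) -> float:
        """Mass density in g/cm^3 (periodic structures only)."""
        if not self.periodic:
            raise ValueError("density requires a periodic cell")
        mass_g = self.masses().sum() * AMU_TO_GRAM
        return mass_g / (self.volume() * ANG3_TO_CM3)

    def formula(self) -> Counter:
        return Counter(self.species)

    def cell_heights(self) -> np.ndarray:
        """Perpendicular distances between opposite cell faces."""
        vol = abs(np.linalg.det(self.cell))
        cross = np.cross(np.roll(self.cell, -1, axis=0), np.roll(self.cell, -2, axis=0))
        return vol / np.linalg.norm(cross, axis=1)

    def fractional(self) -> np.ndarray:
        return self.positions @ np.linalg.inv(self.cell)

    def wrapped(self) -> "PeriodicStructure":
        """Copy with all positions translated into the [0,1) unit cell."""
        if not self.periodic:
            return self.copy()
        frac = self.fractional() % 1.0
        out = self.copy()
        out.positions = frac @ self.cell
        return out

    def copy(self) -> "PeriodicStructure":
        return PeriodicStructure(
            self.species,
            self.positions.copy(),
            self.cell.copy(),
            self.pbc,
            labels=None if self.labels is None else EFSResult(
                self.labels.energy,
                self.labels.forces.copy(),
                None if self.labels.virial is None else self.labels.virial.copy(),
            ),
            provenance=self.provenance,
        )


@dataclass
class MolecularUnit:
    """An intact molecule inside a crystal.

    ``image_shifts`` are integer lattice translations per atom; adding
    ``shift @ cell`` to the stored positions makes the molecule whole.
    """

    atom_indices: np.ndarray
    image_shifts: np.ndarray
    component_type: str = "unknown"

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.image_shifts = np.asarray(self.image_shifts, dtype=int).reshape(-1, 3)
        if len(self.atom_indices) != len(self.image_shifts):
            raise ValueError("image_shifts must match atom_indices length")


@dataclass
class ComponentEntry:
    """Library entry: an element-labeled molecular graph plus a reference
    gas-phase geometry (positions in the same atom order as ``species``)."""

    species: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    reference_positions: np.ndarray

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.reference_positions = np.asarray(self.reference_positions, dtype=float).reshape(-1, 3)
        if len(self.reference_positions) != len(self.species):
            raise ValueError("reference geometry must match species length")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, s in enumerate(self.species):
            g.add_node(i, element=s)
        g.add_edges_from(self.bonds)
        return g


class ComponentLibrary:
    """Map from component identifier to molecular graph + reference geometry.

    No two entries may have isomorphic element-labeled graphs.
    """

    def __init__(self, entries: Mapping[str, ComponentEntry] | None = None):
        self.entries: dict[str, ComponentEntry] = {}
        if entries:
            for name, entry in entries.items():
                self.add(name, entry)

    def add(self, name: str, entry: ComponentEntry) -> None:
        g = entry.graph()
        for other_name, other in self.entries.items():
            if nx.is_isomorphic(g, other.graph(), node_match=_element_match):
                raise ValueError(
                    f"component {name!r} is graph-isomorphic to existing entry {other_name!r}"
                )
        self.entries[name] = entry

    def __getitem__(self, name: str) -> ComponentEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)


def _element_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"]


def _pair_cutoffs(species: tuple[str, ...], tolerance: float) -> np.ndarray:
    try:
        radii = np.array([COVALENT_RADII[s] for s in species])
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc
    return tolerance * (radii[:, None] + radii[None, :])


def _bond_images(structure: PeriodicStructure, tolerance: float):
    """Find all bonded pairs and the lattice shifts realizing each bond.

    Returns a dict ``(i, j) -> shift`` with i < j, where the bond vector is
    ``pos[j] + shift @ cell - pos[i]``.  Raises if an atom bonds to its own
    periodic image or a pair is bonded through two distinct images (both
    indicate a structure that wraps onto itself through the cell).
    """
    n = structure.n_atoms
    pos = structure.positions
    cut = _pair_cutoffs(structure.species, tolerance)

    if not structure.periodic:
        diff = pos[None, :, :] - pos[:, None, :]
        dist = np.linalg.norm(diff, axis=-1)
        bonds = {}
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] <= cut[i, j]:
                    bonds[(i, j)] = np.zeros(3, dtype=int)
        return bonds

    heights = structure.cell_heights()
    max_cut = float(cut.max())
    reach = np.maximum(1, np.ceil(max_cut / heights).astype(int))
    shifts = np.array(list(itertools.product(*[range(-r, r + 1) for r in reach])))
    cart_shifts = shifts @ structure.cell

    # dist[s, i, j] = |pos_j + shift_s - pos_i|
    diff = pos[None, None, :, :] + cart_shifts[:, None, None, :] - pos[None, :, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    within = dist <= cut[None, :, :]

    bonds: dict[tuple[int, int], np.ndarray] = {}
    for s_idx, i, j in zip(*np.nonzero(within)):
        shift = shifts[s_idx]
        if i == j:
            if np.any(shift != 0):
                raise MoleculeIdentificationError(
                    f"atom {i} ({structure.species[i]}) bonds to its own periodic "
                    "image: structure wraps onto itself through the cell"
                )
            continue
        if i > j:
            continue
        key = (int(i), int(j))
        if key in bonds:
            if np.any(bonds[key] != shift):
                raise MoleculeIdentificationError(
                    f"atoms {i}-{j} are bonded through two distinct periodic "
                    "images: structure wraps onto itself through the cell"
                )
        else:
            bonds[key] = shift.copy()
    return bonds


def identify_molecules(structure: PeriodicStructure, tolerance: float = 1.2) -> list[MolecularUnit]:
    """Partition a structure into molecules via its periodic bond graph.

    Atoms i, j are bonded iff any minimum-image distance is at most
    ``tolerance * (r_cov(i) + r_cov(j))``.  The returned units carry integer
    ``image_shifts`` that unwrap each molecule into a contiguous object.
    """
    if structure.n_atoms < 1:
        raise ValueError("structure must contain at least one atom")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    # detect bonds on wrapped positions so the image search stays local even
    # for structures whose stored coordinates drifted far outside the cell
    if structure.periodic:
        wrap = -np.floor(structure.fractional()).astype(int)
        work = PeriodicStructure(
            structure.species, structure.positions + wrap @ structure.cell, structure.cell,
            structure.pbc,
        )
    else:
        wrap = np.zeros((structure.n_atoms, 3), dtype=int)
        work = structure
    bonds = _bond_images(work, tolerance)
    adj: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(structure.n_atoms)}
    for (i, j), shift in bonds.items():
        adj[i].append((j, shift))
        adj[j].append((i, -shift))

    units: list[MolecularUnit] = []
    seen = np.full(structure.n_atoms, False)
    for start in range(structure.n_atoms):
        if seen[start]:
            continue
        shift_of = {start: np.zeros(3, dtype=int)}
        queue = deque([start])
        seen[start] = True
        while queue:
            a = queue.popleft()
            for b, shift in adj[a]:
                want = shift_of[a] + shift
                if b in shift_of:
                    if np.any(shift_of[b] != want):
                        raise MoleculeIdentificationError(
                            f"component containing atom {start} wraps onto itself "
                            "through the cell (periodic polymer)"
                        )
                else:
                    shift_of[b] = want
                    seen[b] = True
                    queue.append(b)
        idx = np.array(sorted(shift_of), dtype=int)
        total = {i: shift_of[i] + wrap[i] for i in shift_of}
        ref = total[int(idx[0])]
        shifts = np.array([total[int(i)] - ref for i in idx], dtype=int)
        units.append(MolecularUnit(idx, shifts))
    return units


def _unit_graph(structure: PeriodicStructure, unit: MolecularUnit, tolerance: float) -> nx.Graph:
    pos = structure.positions[unit.atom_indices] + unit.image_shifts @ structure.cell
    sub = tuple(structure.species[i] for i in unit.atom_indices)
    cut = _pair_cutoffs(sub, tolerance)
    g = nx.Graph()
    for k, s in enumerate(sub):
        g.add_node(k, element=s)
    dist = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    for a in range(len(sub)):
        for b in range(a + 1, len(sub)):
            if dist[a, b] <= cut[a, b]:
                g.add_edge(a, b)
    return g


def assign_component_types(
    units: list[MolecularUnit],
    structure: PeriodicStructure,
    library: ComponentLibrary,
    tolerance: float = 1.2,
) -> list[MolecularUnit]:
    """Label each unit by element-labeled graph isomorphism against the library.

    Unmatched units get ``component_type="unknown"``; that is a valid outcome,
    not an error.
    """
    out = []
    for unit in units:
        g = _unit_graph(structure, unit, tolerance)
        found = "unknown"
        for name in library.names():
            if nx.is_isomorphic(g, library[name].graph(), node_match=_element_match):
                found = name
                break
        out.append(replace(unit, component_type=found))
    return out


def match_to_reference(
    structure: PeriodicStructure,
    unit: MolecularUnit,
    entry: ComponentEntry,
    tolerance: float = 1.2,
) -> dict[int, int]:
    """Atom mapping ``local index -> reference index`` for a typed unit.

    Deterministic: the VF2 search iterates nodes in sorted order.
    """
    g = _unit_graph(structure, unit, tolerance)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        entry.graph(), g, node_match=_element_match
    )
    for mapping in matcher.isomorphisms_iter():
        # mapping: reference index -> local index
        return {local: ref for ref, local in mapping.items()}
    raise ValueError("unit does not match the given component entry")


def extract_monomer(structure: PeriodicStructure, unit: MolecularUnit) -> PeriodicStructure:
    """Extract a unit as a non-periodic structure at unwrapped coordinates."""
    idx = unit.atom_indices
    if len(idx) == 0 or idx.min() < 0 or idx.max() >= structure.n_atoms:
        raise ValueError("unit atom indices are invalid for this structure")
    pos = structure.positions[idx] + unit.image_shifts @ structure.cell
    span = pos.max(axis=0) - pos.min(axis=0)
    box = np.diag(span + 20.0)  # generous padding; cell unused when pbc False
    return PeriodicStructure(
        tuple(structure.species[i] for i in idx),
        pos,
        box,
        pbc=(False, False, False),
        provenance=(structure.provenance + ":monomer").lstrip(":"),
    )


def rescale_cell(structure: PeriodicStructure, scale: float,
                 tolerance: float = 1.1) -> PeriodicStructure:
    """Isotropically rescale the cell, moving molecules rigidly.

    Molecular centers of mass scale with the cell while internal geometries
    stay fixed — the natural way to compress or expand a molecular crystal
    without distorting its building blocks.  The slightly tight bond
    tolerance keeps compressed intermolecular contacts from being read as
    bonds.
    """
    units = identify_molecules(structure, tolerance)
    cell = structure.cell * scale
    pos = structure.positions.copy()
    for u in units:
        up = structure.positions[u.atom_indices] + u.image_shifts @ structure.cell
        com = up.mean(axis=0)
        pos[u.atom_indices] = up - com + com * scale - u.image_shifts @ cell
    return PeriodicStructure(
        structure.species, pos, cell, structure.pbc,
        provenance=(structure.provenance + f":rescaled{scale:g}").lstrip(":"),
    )


def kpoint_grid(cell: np.ndarray, x: float) -> tuple[int, int, int]:
    """k-point counts per direction: smallest n with n * a >= x.

    ``a`` is the length of the cell vector along each direction.
    """
    cell = np.asarray(cell, dtype=float).reshape(3, 3)
    lengths = np.linalg.norm(cell, axis=1)
    if np.any(lengths <= 0) or x <= 0:
        raise ValueError("cell lengths and x must be positive")
    return tuple(max(1, int(math.ceil(x / a - 1e-9))) for a in lengths)
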