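"""Desk-scale fixture universe: toy components, analytic calculators, and
random trial-crystal generation.

The toy universe emulates the screening setting of a molecular co-crystal
study: one "active" bent triatomic (water-like, two species) plus four
co-formers (homonuclear and heteronuclear diatomics and a linear
triatomic), packed into random periodic cells at a range of
stoichiometries.

Two analytic calculators play the roles of the cheap baseline and the
expensive target method.  Both are sums of intramolecular harmonic terms
(all atom pairs within a molecule, stiff for bonded pairs and softer for
1-3 pairs, equilibria taken from the component reference geometry) and
smoothly truncated intermolecular Lennard-Jones pair terms sharing one
repulsive wall.  They differ by a smooth, short-ranged function of local
geometry — the baseline's r^-6 attraction is 30% too strong and its bonds
stiffer with contracted equilibria, while the target alone carries a weak
extra attractive tail — so the baseline systematically over-binds
intermolecular contacts (contracted cells, too-negative lattice energies)
and a short-ranged correction can in principle learn the difference
exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .delta import Calculator
from .structures import (
    ComponentEntry,
    ComponentLibrary,
    EFSResult,
    PeriodicStructure,
    assign_component_types,
    identify_molecules,
    match_to_reference,
    rescale_cell,
)

__all__ = [
    "ToyCalculator",
    "ToyPotentialParams",
    "generate_trial_crystals",
    "make_toy_components",
    "perturb_structure",
    "rescale_cell",
    "toy_baseline",
    "toy_baseline_params",
    "toy_calculator",
    "toy_target",
    "toy_target_params",
]

COULOMB_EV_A = 14.399645  # e^2 / (4 pi eps0), in eV * A


def make_toy_components() -> ComponentLibrary:
    """Deterministic library: one active component and four co-formers."""
    half = math.radians(104.5 / 2.0)
    r_oh = 0.97
    lib = ComponentLibrary()
    lib.add(
        "active",
        ComponentEntry(
            ("O", "H", "H"),
            ((0, 1), (0, 2)),
            [
                [0.0, 0.0, 0.0],
                [r_oh * math.sin(half), r_oh * math.cos(half), 0.0],
                [-r_oh * math.sin(half), r_oh * math.cos(half), 0.0],
            ],
        ),
    )
    lib.add("n2", ComponentEntry(("N", "N"), ((0, 1),), [[0, 0, 0], [1.10, 0, 0]]))
    lib.add("o2", ComponentEntry(("O", "O"), ((0, 1),), [[0, 0, 0], [1.21, 0, 0]]))
    lib.add("no", ComponentEntry(("N", "O"), ((0, 1),), [[0, 0, 0], [1.15, 0, 0]]))
    lib.add(
        "n2o",
        ComponentEntry(
            ("N", "N", "O"),
            ((0, 1), (1, 2)),
            [[-1.13, 0, 0], [0, 0, 0], [1.19, 0, 0]],
        ),
    )
    return lib


@dataclass
class ToyPotentialParams:
    """Parameters of the analytic toy potential.

    bond_k        harmonic constant for bonded (1-2) intramolecular pairs (eV/A^2)
    bond_k_13     harmonic constant for non-bonded intramolecular pairs (eV/A^2)
    bond_r0_scale multiplier on reference-geometry pair distances (equilibria)
    pair_epsilon  Lennard-Jones well depth per species pair (eV)
    pair_sigma    Lennard-Jones length scale per species pair (A)
    cutoff        intermolecular cutoff (A); must stay below half the
                  smallest cell height (strict minimum image)
    switch_width  width of the smooth truncation window (A)
    tail_strength relative magnitude of the extra attractive r^-6 tail
    charge        optional per-species point charges (e) for a wrapped,
                  smoothly truncated Coulomb term
    """

    bond_k: float = 35.0
    bond_k_13: float = 8.0
    bond_r0_scale: float = 1.0
    pair_epsilon: Mapping[tuple[str, str], float] = field(default_factory=dict)
    pair_sigma: Mapping[tuple[str, str], float] = field(default_factory=dict)
    attraction_scale: float = 1.0
    cutoff: float = 3.0
    switch_width: float = 0.6
    tail_strength: float = 0.15
    charge: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.bond_k < 0 or self.bond_k_13 < 0:
            raise ValueError("bond constants must be non-negative")
        if any(s <= 0 for s in self.pair_sigma.values()):
            raise ValueError("pair_sigma must be positive")


# radii chosen so the cutoff sits at ~1.7 sigma: the attractive well and the
# nearest part of the second shell are inside the interaction range, so the
# equilibrium crystal is a normal close-packed LJ solid rather than a
# coordination-maximizing collapse against the repulsive walls
_SPECIES_EPS = {"H": 0.014, "N": 0.028, "O": 0.032}
_SPECIES_SIG = {"H": 1.70, "N": 1.85, "O": 1.80}


def _combine(eps_scale: float, sig_scale: float):
    eps, sig = {}, {}
    for a, b in itertools.combinations_with_replacement(sorted(_SPECIES_EPS), 2):
        key = (a, b)
        eps[key] = eps_scale * math.sqrt(_SPECIES_EPS[a] * _SPECIES_EPS[b])
        sig[key] = sig_scale * 0.5 * (_SPECIES_SIG[a] + _SPECIES_SIG[b])
    return eps, sig


def toy_target_params() -> ToyPotentialParams:
    eps, sig = _combine(1.0, 1.0)
    return ToyPotentialParams(
        bond_k=35.0, bond_k_13=8.0, bond_r0_scale=1.0, pair_epsilon=eps, pair_sigma=sig
    )


def toy_baseline_params() -> ToyPotentialParams:
    """Over-binding variant: the r^-6 attraction is 30% too strong (the
    repulsive wall is shared with the target), pulling contacts closer and
    lattice energies lower; bonds are stiffer with equilibria contracted by
    3%.  The resulting target-minus-baseline difference is a smooth,
    bounded, short-ranged function of local geometry."""
    eps, sig = _combine(1.0, 1.0)
    return ToyPotentialParams(
        bond_k=45.0, bond_k_13=5.5, bond_r0_scale=0.97,
        pair_epsilon=eps, pair_sigma=sig, attraction_scale=1.30,
    )


def _switch(r: np.ndarray, rc: float, width: float):
    t = np.clip((r - (rc - width)) / width, 0.0, 1.0)
    f = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    df = np.where((r > rc - width) & (r < rc), -(30 * t**2 - 60 * t**3 + 30 * t**4) / width, 0.0)
    return f, df


class ToyCalculator(Calculator):
    """Analytic toy potential with exact forces and virial."""

    def __init__(
        self,
        params: ToyPotentialParams,
        dispersion_tail: bool = False,
        library: ComponentLibrary | None = None,
        name: str = "toy",
        bond_tolerance: float = 1.1,
    ):
        self.params = params
        self.dispersion_tail = bool(dispersion_tail)
        self.library = library if library is not None else make_toy_components()
        self.name = name
        self.bond_tolerance = bond_tolerance
        self._topo_cache: dict = {}

    # -- topology -------------------------------------------------------
    def _topology(self, structure: PeriodicStructure):
        """Fixed molecular topology: partition, pair list and equilibria.

        Bonding is perceived once per species sequence and then held fixed,
        the way a force field fixes its connectivity: during dynamics a
        thermally stretched bond must not transiently re-partition the
        system.  Call :meth:`reset_topology` when the same calculator is
        reused on structures whose identical species sequence carries a
        genuinely different bonding pattern.
        """
        key = structure.species
        hit = self._topo_cache.get(key)
        if hit is not None:
            return hit
        units = identify_molecules(structure, self.bond_tolerance)
        typed = assign_component_types(units, structure, self.library, self.bond_tolerance)
        ii, jj, r0, kk = [], [], [], []
        mol_id = np.empty(structure.n_atoms, dtype=int)
        for mi, u in enumerate(typed):
            mol_id[u.atom_indices] = mi
            if u.component_type == "unknown":
                raise ValueError("toy calculator met a molecule outside its library")
            entry = self.library[u.component_type]
            mapping = match_to_reference(structure, u, entry, self.bond_tolerance)
            ref = entry.reference_positions
            bonded = {tuple(sorted(b)) for b in entry.bonds}
            local = list(range(len(u.atom_indices)))
            for a, b in itertools.combinations(local, 2):
                ra, rb = mapping[a], mapping[b]
                ii.append(u.atom_indices[a])
                jj.append(u.atom_indices[b])
                r0.append(float(np.linalg.norm(ref[ra] - ref[rb])))
                kk.append(
                    self.params.bond_k
                    if tuple(sorted((ra, rb))) in bonded
                    else self.params.bond_k_13
                )
        data = (
            mol_id,
            np.array(ii, dtype=int),
            np.array(jj, dtype=int),
            np.array(r0),
            np.array(kk),
        )
        self._topo_cache[key] = data
        return data

    def reset_topology(self) -> None:
        """Forget cached bonding (see :meth:`_topology`)."""
        self._topo_cache.clear()

    # -- evaluation -----------------------------------------------------
    def evaluate(self, structure: PeriodicStructure) -> EFSResult:
        p = self.params
        n = structure.n_atoms
        pos = structure.positions
        if structure.periodic:
            heights = structure.cell_heights()
            if p.cutoff > heights.min() / 2.0:
                raise ValueError(
                    f"cutoff {p.cutoff} A exceeds half the minimum cell height "
                    f"({heights.min() / 2.0:.3f} A): minimum image invalid"
                )
        mol_id, ii, jj, r0, kk = self._topology(structure)

        energy = 0.0
        forces = np.zeros((n, 3))
        virial = np.zeros((3, 3))

        # intramolecular harmonic terms; minimum image is exact here because
        # molecular extents are below half the (validated) cell heights
        if len(ii):
            R = pos[jj] - pos[ii]
            if structure.periodic:
                frac = R @ np.linalg.inv(structure.cell)
                R = (frac - np.round(frac)) @ structure.cell
            r = np.linalg.norm(R, axis=1)
            dr = r - p.bond_r0_scale * r0
            energy += float(0.5 * np.sum(kk * dr**2))
            dEdR = (kk * dr / r)[:, None] * R
            np.add.at(forces, ii, dEdR)
            np.add.at(forces, jj, -dEdR)
            virial -= dEdR.T @ R

        # intermolecular pair terms, strict minimum image
        ai, aj = np.triu_indices(n, k=1)
        mask = mol_id[ai] != mol_id[aj]
        ai, aj = ai[mask], aj[mask]
        if len(ai):
            R = pos[aj] - pos[ai]
            if structure.periodic:
                inv = np.linalg.inv(structure.cell)
                frac = R @ inv
                R = (frac - np.round(frac)) @ structure.cell
            r = np.linalg.norm(R, axis=1)
            within = r <= p.cutoff
            ai, aj, R, r = ai[within], aj[within], R[within], r[within]
            if len(ai):
                eps = np.array(
                    [
                        p.pair_epsilon[tuple(sorted((structure.species[a], structure.species[b])))]
                        for a, b in zip(ai, aj)
                    ]
                )
                sig = np.array(
                    [
                        p.pair_sigma[tuple(sorted((structure.species[a], structure.species[b])))]
                        for a, b in zip(ai, aj)
                    ]
                )
                sr6 = (sig / r) ** 6
                a = p.attraction_scale
                e_pair = 4.0 * eps * (sr6**2 - a * sr6)
                de_dr = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * a * sr6) / r
                if self.dispersion_tail:
                    e_pair += -4.0 * eps * p.tail_strength * sr6
                    de_dr += 4.0 * eps * p.tail_strength * 6.0 * sr6 / r
                if p.charge:
                    q = np.array(
                        [
                            p.charge.get(structure.species[a], 0.0)
                            * p.charge.get(structure.species[b], 0.0)
                            for a, b in zip(ai, aj)
                        ]
                    )
                    e_pair += COULOMB_EV_A * q / r
                    de_dr += -COULOMB_EV_A * q / r**2
                f, df = _switch(r, p.cutoff, p.switch_width)
                dE = de_dr * f + e_pair * df
                energy += float(np.sum(e_pair * f))
                dEdR = (dE / r)[:, None] * R
                np.add.at(forces, ai, dEdR)
                np.add.at(forces, aj, -dEdR)
                virial -= dEdR.T @ R

        virial = 0.5 * (virial + virial.T)
        return EFSResult(energy, forces, virial)


def toy_calculator(
    params: ToyPotentialParams,
    dispersion_tail: bool = False,
    library: ComponentLibrary | None = None,
    name: str = "toy",
) -> ToyCalculator:
    """Build a toy analytic calculator (spec'd factory form)."""
    return ToyCalculator(params, dispersion_tail, library, name)


def toy_baseline(library: ComponentLibrary | None = None) -> ToyCalculator:
    return ToyCalculator(toy_baseline_params(), False, library, "toy-baseline")


def toy_target(library: ComponentLibrary | None = None) -> ToyCalculator:
    return ToyCalculator(toy_target_params(), True, library, "toy-target")


# --------------------------------------------------------------------------
# trial crystal generation


def _random_cell(rng: np.random.Generator, volume: float, min_height: float) -> np.ndarray:
    for _ in range(200):
        ratios = rng.uniform(0.9, 1.15, 3)
        alpha, beta, gamma = np.radians(rng.uniform(80.0, 100.0, 3))
        a, b, c = ratios / np.cbrt(np.prod(ratios))
        cg, sg = math.cos(gamma), math.sin(gamma)
        cb, ca = math.cos(beta), math.cos(alpha)
        cx = c * cb
        cy = c * (ca - cb * cg) / sg
        cz2 = c**2 - cx**2 - cy**2
        if cz2 <= 0:
            continue
        cell = np.array([[a, 0, 0], [b * cg, b * sg, 0], [cx, cy, math.sqrt(cz2)]])
        cell *= np.cbrt(volume / abs(np.linalg.det(cell)))
        vol = abs(np.linalg.det(cell))
        cross = np.cross(np.roll(cell, -1, axis=0), np.roll(cell, -2, axis=0))
        if (vol / np.linalg.norm(cross, axis=1)).min() >= min_height:
            return cell
    raise RuntimeError("could not draw a cell with acceptable heights")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _min_image_dists(dx: np.ndarray, cell: np.ndarray) -> np.ndarray:
    frac = dx @ np.linalg.inv(cell)
    return np.linalg.norm((frac - np.round(frac)) @ cell, axis=-1)


def generate_trial_crystals(
    library: ComponentLibrary,
    stoichiometries: Sequence[Mapping[str, int]],
    n_per_composition: int,
    seed: int,
    cell_volume_per_molecule: tuple[float, float] = (110.0, 150.0),
    min_dist: float = 2.0,
    min_cell_height: float = 7.0,
) -> list[PeriodicStructure]:
    """Random periodic trial structures spanning the given stoichiometries.

    Molecules are placed at random positions and orientations; a placement
    is rejected whenever any intermolecular atom pair comes below
    ``min_dist``.  Deterministic for a given seed.
    """
    if not stoichiometries:
        raise ValueError("stoichiometries must be non-empty")
    rng = np.random.default_rng(seed)
    out: list[PeriodicStructure] = []
    for comp in stoichiometries:
        comp = {k: int(v) for k, v in comp.items() if v > 0}
        n_mol = sum(comp.values())
        if n_mol == 0:
            raise ValueError("composition has no molecules")
        comp_tag = ",".join(f"{k}:{v}" for k, v in sorted(comp.items()))
        for idx in range(n_per_composition):
            structure = None
            for _attempt in range(60):
                vol = rng.uniform(*cell_volume_per_molecule) * n_mol
                cell = _random_cell(rng, vol, min_cell_height)
                species: list[str] = []
                placed = np.zeros((0, 3))
                ok = True
                for name, count in sorted(comp.items()):
                    entry = library[name]
                    ref = entry.reference_positions - entry.reference_positions.mean(axis=0)
                    for _ in range(count):
                        for _try in range(200):
                            rot = _random_rotation(rng)
                            com = rng.uniform(0, 1, 3) @ cell
                            coords = ref @ rot.T + com
                            if len(placed):
                                d = _min_image_dists(
                                    coords[:, None, :] - placed[None, :, :], cell
                                )
                                if d.min() < min_dist:
                                    continue
                            placed = np.vstack([placed, coords])
                            species.extend(entry.species)
                            break
                        else:
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    structure = PeriodicStructure(
                        tuple(species),
                        placed,
                        cell,
                        provenance=f"toy:{comp_tag}:{idx}",
                    )
                    break
            if structure is None:
                raise RuntimeError(
                    f"placement budget exhausted for composition {comp_tag}; "
                    "increase cell_volume_per_molecule"
                )
            out.append(structure)
    return out


def perturb_structure(
    structure: PeriodicStructure,
    position_amplitude: float,
    cell_amplitude: float,
    seed: int,
    min_dist: float = 0.5,
) -> PeriodicStructure:
    """Gaussian positional noise plus a random symmetric cell strain.

    Resamples (up to a budget) if the perturbation brings any two atoms
    closer than ``min_dist``.
    """
    if position_amplitude < 0 or cell_amplitude < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    for _ in range(60):
        dp = rng.normal(0.0, position_amplitude, structure.positions.shape) if position_amplitude else 0.0
        G = rng.normal(0.0, cell_amplitude, (3, 3)) if cell_amplitude else np.zeros((3, 3))
        strain = 0.5 * (G + G.T)
        D = np.eye(3) + strain
        pos = (structure.positions + dp) @ D
        cell = structure.cell @ D
        if structure.n_atoms > 1:
            ai, aj = np.triu_indices(structure.n_atoms, k=1)
            dx = pos[aj] - pos[ai]
            d = _min_image_dists(dx, cell) if structure.periodic else np.linalg.norm(dx, axis=1)
            if d.min() < min_dist:
                continue
        return PeriodicStructure(
            structure.species,
            pos,
            cell,
            structure.pbc,
            provenance=(structure.provenance + ":perturbed").lstrip(":"),
        )
    raise RuntimeError("perturbation kept creating atom overlaps below the floor")
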