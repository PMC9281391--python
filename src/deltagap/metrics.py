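"""Validation metrics: lattice energies, density deviations, RMSD over
15-molecule clusters, error statistics, and maximum remaining force.

The lattice energy of a crystal containing counts n_t of each component is

    E_lat = ( E_crystal - sum_t n_t E_gas,t ) / sum_t n_t      (eV/molecule)

with E_gas,t the optimized gas-phase energy of component t; a
single-component crystal is the special case with one nonzero count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .structures import (
    ComponentLibrary,
    EFSResult,
    PeriodicStructure,
    assign_component_types,
    identify_molecules,
    match_to_reference,
)

__all__ = [
    "ErrorSummary",
    "density_deviation",
    "error_summary",
    "lattice_energy",
    "max_remaining_force",
    "rmsd15",
]


@dataclass
class ErrorSummary:
    """MAE and population standard deviation of signed errors."""

    mae: float
    std: float
    n: int
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)


def error_summary(predicted, reference) -> ErrorSummary:
    """MAE of |p - r| and STD of signed (p - r), population divisor n."""
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.shape != r.shape or len(p) < 1:
        raise ValueError("predicted and reference must have equal length >= 1")
    e = p - r
    return ErrorSummary(float(np.abs(e).mean()), float(e.std(ddof=0)), len(e), e)


def lattice_energy(
    e_crystal: float,
    gas_refs: Mapping[str, float],
    counts: Mapping[str, int],
) -> float:
    """Lattice energy per molecule (eV)."""
    total = 0
    e_gas = 0.0
    for comp, cnt in counts.items():
        if cnt < 0:
            raise ValueError("counts must be non-negative")
        if cnt == 0:
            continue
        if comp not in gas_refs:
            raise ValueError(f"missing gas reference for component {comp!r}")
        total += cnt
        e_gas += cnt * gas_refs[comp]
    if total == 0:
        raise ValueError("total molecule count must be positive")
    return (e_crystal - e_gas) / total


def density_deviation(
    structure: PeriodicStructure, reference: PeriodicStructure, absolute: bool = False
) -> float:
    """Percentage density deviation 100 (rho - rho_ref) / rho_ref.

    Positive for a denser (more contracted) structure.  ``absolute`` returns
    the magnitude, as plotted in per-structure comparisons.
    """
    if structure.formula() != reference.formula():
        raise ValueError("structures must share a chemical formula per cell")
    dev = 100.0 * (structure.density() - reference.density()) / reference.density()
    return abs(dev) if absolute else dev


def max_remaining_force(efs: EFSResult) -> float:
    """Maximum Euclidean per-atom force norm (eV/A)."""
    if efs.forces is None or len(efs.forces) == 0:
        raise ValueError("forces missing")
    return float(np.linalg.norm(efs.forces, axis=1).max())


# --------------------------------------------------------------------------
# RMSD over 15-molecule clusters


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R and translation t minimizing |P R^T + t - Q|.

    Reflections are excluded (determinant forced to +1).
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - pc @ R.T


def _molecule_records(structure: PeriodicStructure, library: ComponentLibrary, tolerance: float):
    units = assign_component_types(
        identify_molecules(structure, tolerance), structure, library, tolerance
    )
    recs = []
    for u in units:
        if u.component_type == "unknown":
            raise ValueError("structure contains a molecule outside the library")
        entry = library[u.component_type]
        mapping = match_to_reference(structure, u, entry, tolerance)
        order = sorted(range(len(u.atom_indices)), key=lambda k: mapping[k])
        pos = structure.positions[u.atom_indices] + u.image_shifts @ structure.cell
        pos = pos[order]
        species = [structure.species[u.atom_indices[k]] for k in order]
        masses = structure.masses()[u.atom_indices][order]
        com = (pos * masses[:, None]).sum(axis=0) / masses.sum()
        key = tuple(sorted(u.atom_indices))
        recs.append(
            {
                "key": key,
                "type": u.component_type,
                "pos": pos,
                "species": species,
                "com": com,
            }
        )
    return recs


def _cluster(recs, central_idx, cell, n_mol=15, shift_range=3, periodic=True):
    """Central molecule + nearest neighbors by COM distance over images."""
    import itertools as it

    if not periodic:
        shift_range = 0
    center_com = recs[central_idx]["com"]
    cands = []
    for mi, rec in enumerate(recs):
        for shift in it.product(range(-shift_range, shift_range + 1), repeat=3):
            sv = np.array(shift) @ cell
            d = np.linalg.norm(rec["com"] + sv - center_com)
            if mi == central_idx and not any(shift):
                continue
            cands.append((d, mi, sv))
    cands.sort(key=lambda c: (c[0], c[1], tuple(c[2])))
    if len(cands) < n_mol - 1:
        raise ValueError("fewer than 15 molecules obtainable from periodic images")
    cluster = [(central_idx, np.zeros(3))]
    cluster += [(mi, sv) for _d, mi, sv in cands[: n_mol - 1]]
    return cluster


def _cluster_arrays(recs, cluster):
    mols = []
    for mi, sv in cluster:
        rec = recs[mi]
        heavy = np.array([s != "H" for s in rec["species"]])
        mols.append(
            {
                "type": rec["type"],
                "pos": rec["pos"] + sv,
                "heavy": heavy,
                "com": rec["com"] + sv,
            }
        )
    return mols


def _match_and_rmsd(ref_mols, s_mols, R, t, align=True):
    """Greedy same-type molecule assignment by COM distance after applying
    (R, t) to the structure cluster, then a joint heavy-atom superposition."""
    s_coms = np.array([m["com"] @ R.T + t for m in s_mols])
    taken = set()
    pairs = []
    for ri, rm in enumerate(ref_mols):
        ds = [
            (np.linalg.norm(s_coms[si] - rm["com"]), si)
            for si in range(len(s_mols))
            if si not in taken and s_mols[si]["type"] == rm["type"]
        ]
        if not ds:
            raise ValueError("cluster molecule multisets do not match")
        _d, si = min(ds)
        taken.add(si)
        pairs.append((ri, si))
    P = np.vstack([s_mols[si]["pos"][s_mols[si]["heavy"]] for _ri, si in pairs])
    Q = np.vstack([ref_mols[ri]["pos"][ref_mols[ri]["heavy"]] for ri, _si in pairs])
    if align:
        R2, t2 = _kabsch(P, Q)
    else:
        R2, t2 = np.eye(3), np.zeros(3)
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R2.T + t2 - Q) ** 2, axis=1))))
    return rmsd, R2, t2, pairs


def rmsd15(
    structure: PeriodicStructure,
    reference: PeriodicStructure,
    library: ComponentLibrary,
    tolerance: float = 1.2,
    n_mol: int = 15,
    align: bool = True,
) -> float:
    """Heavy-atom RMSD between 15-molecule clusters of two crystals (A).

    For each candidate central molecule of the reference, the cluster of the
    central molecule plus its 14 nearest neighbors (by center-of-mass
    distance, periodic images allowed) is cut from both structures; molecule
    correspondence is seeded by superimposing the central molecules, refined
    once, and all non-hydrogen atoms are superimposed by the optimal proper
    rotation/translation.  The reported value is the minimum over candidate
    centers.  Directional by construction; rmsd15(A, A) = 0.
    """
    ref_recs = _molecule_records(reference, library, tolerance)
    s_recs = _molecule_records(structure, library, tolerance)
    by_key = {r["key"]: i for i, r in enumerate(s_recs)}
    if sorted(r["key"] for r in ref_recs) != sorted(by_key):
        raise ValueError("structures do not decompose into matching molecules")

    best = np.inf
    for ci, ref_rec in enumerate(ref_recs):
        si = by_key[ref_rec["key"]]
        ref_cluster = _cluster_arrays(
            ref_recs, _cluster(ref_recs, ci, reference.cell, n_mol, periodic=reference.periodic)
        )
        s_cluster = _cluster_arrays(
            s_recs, _cluster(s_recs, si, structure.cell, n_mol, periodic=structure.periodic)
        )
        # seed: superimpose the central molecules (heavy atoms, canonical order)
        if not align:
            R, t = np.eye(3), np.zeros(3)
        else:
            # seed on the full central molecules (H included: small molecules
            # may have too few heavy atoms to pin down a rotation)
            R, t = _kabsch(s_cluster[0]["pos"], ref_cluster[0]["pos"])
        rmsd, R, t, pairs = _match_and_rmsd(ref_cluster, s_cluster, R, t, align)
        for _ in range(4):  # refine assignment to a fixed point
            rmsd2, R, t, pairs2 = _match_and_rmsd(ref_cluster, s_cluster, R, t, align)
            stable = pairs2 == pairs
            rmsd, pairs = rmsd2, pairs2
            if stable:
                break
        best = min(best, rmsd)
    return best
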