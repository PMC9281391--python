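"""Variable-cell local relaxation and constant-pressure molecular dynamics.

Relaxation runs a quasi-Newton (L-BFGS-B) minimization over a combined
coordinate of atomic positions and a symmetric cell strain; the strain
gradient comes from the calculator's virial, so any force/virial-capable
:class:`~deltagap.delta.Calculator` can drive it.  Strain components are
bounded (|eps| <= 0.3 by default) so a bad line-search step cannot collapse
the cell outside any calculator's validity domain.

NPT sampling couples a BAOAB Langevin thermostat to an isotropic
Monte-Carlo barostat that rescales molecular centers of mass (internal
geometries ride along rigidly, which keeps acceptance high for stiff
molecules).  Both are driven by a single seeded generator, so trajectories
are reproducible; statistical equality of means is promised under a fixed
seed, bitwise equality across platforms is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .delta import Calculator
from .structures import EFSResult, PeriodicStructure, identify_molecules

__all__ = [
    "RelaxationError",
    "Trajectory",
    "mean_density",
    "relax",
    "relax_volume",
    "run_npt",
]

KB_EV = 8.617333262e-5           # eV/K
EV_PER_A_AMU = 9.648533290731446e-3  # 1 eV/A/amu in A/fs^2
BAR_TO_EV_A3 = 6.241509074460763e-7  # 1 bar in eV/A^3


class RelaxationError(RuntimeError):
    """Non-convergence; carries the last structure and residual force."""

    def __init__(self, message: str, structure: PeriodicStructure, fmax_residual: float):
        super().__init__(message)
        self.structure = structure
        self.fmax_residual = fmax_residual


@dataclass
class Trajectory:
    """MD frames plus per-frame thermodynamic observables."""

    frames: list[PeriodicStructure]
    temperature: np.ndarray   # K
    pressure: np.ndarray      # bar
    density: np.ndarray       # g/cm^3
    energy: np.ndarray        # potential energy, eV

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        n = len(self.frames)
        if any(len(a) != n for a in (self.temperature, self.pressure, self.density, self.energy)):
            raise ValueError("frames and thermo records must have equal length")

    def write_thermo_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "temperature_K", "pressure_bar", "density_g_cm3", "energy_eV"])
            for i in range(len(self.frames)):
                w.writerow([i, self.temperature[i], self.pressure[i], self.density[i], self.energy[i]])


_STRAIN_BASIS = []
for _a in range(3):
    _m = np.zeros((3, 3))
    _m[_a, _a] = 1.0
    _STRAIN_BASIS.append(_m)
for _a, _b in ((0, 1), (0, 2), (1, 2)):
    _m = np.zeros((3, 3))
    _m[_a, _b] = _m[_b, _a] = 1.0
    _STRAIN_BASIS.append(_m)


def _max_force(forces: np.ndarray) -> float:
    return float(np.abs(forces).max())


def relax(
    structure: PeriodicStructure,
    calc: Calculator,
    fmax: float = 0.01,
    relax_cell: bool = False,
    max_steps: int = 200,
    pressure: float = 0.0,
    strain_bound: float = 0.3,
    max_displacement: float | None = None,
    smax: float | None = None,
) -> PeriodicStructure:
    """Minimize energy until every force component is below ``fmax`` (eV/A).

    With ``relax_cell`` the cell relaxes too; the cell convergence measure is
    the strain gradient divided by the cell length scale (same units as
    forces) against ``smax``, which defaults to ``fmax / 4`` — for soft
    molecular crystals the residual-stress criterion must be tighter than
    the force one or the converged density is sloppy.  ``max_displacement`` bounds each
    atomic coordinate to a box around its start (a trust region, useful for
    local refinement with models that extrapolate poorly far from their
    training data).  Deterministic given its inputs.  Raises
    :class:`RelaxationError` after ``max_steps`` iterations.
    """
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    if smax is None:
        smax = fmax / 4.0
    res0 = calc.evaluate(structure)
    if _converged(res0, structure, fmax, relax_cell, smax):
        out = structure.copy()
        out.labels = res0
        return out

    pos0 = structure.positions.copy()
    cell0 = structure.cell.copy()
    L0 = abs(np.linalg.det(cell0)) ** (1.0 / 3.0) if structure.periodic else 1.0
    n = structure.n_atoms
    p_ev = pressure * BAR_TO_EV_A3

    nvar = 3 * n + (6 if relax_cell else 0)

    def unpack(z):
        pos_var = z[: 3 * n].reshape(n, 3)
        if relax_cell:
            eps = sum(z[3 * n + k] / L0 * _STRAIN_BASIS[k] for k in range(6))
            D = np.eye(3) + eps
        else:
            D = np.eye(3)
        return PeriodicStructure(
            structure.species, pos_var @ D, cell0 @ D, structure.pbc,
            provenance=structure.provenance,
        ), pos_var, D

    best = {"energy": np.inf, "z": None, "res": None}

    def objective(z):
        st, pos_var, D = unpack(z)
        try:
            res = calc.evaluate(st)
        except Exception:
            # line-search excursion into a region where the calculator is
            # undefined (broken molecule, cell too small): report a large
            # energy sloping back toward the last accepted point so the
            # optimizer backtracks instead of stalling on a flat plateau
            anchor = best["z"] if best["z"] is not None else z0
            return 1e4 + 1e2 * float(np.sum((z - anchor) ** 2)), 2e2 * (z - anchor)
        vol = st.volume() if structure.periodic else 0.0
        e = res.energy + p_ev * vol
        g = np.empty(nvar)
        g[: 3 * n] = (-(res.forces) @ D).ravel()
        if relax_cell:
            dEdD = -np.linalg.inv(D).T @ res.virial
            if pressure:
                dEdD += p_ev * vol * np.linalg.inv(D).T
            for k in range(6):
                g[3 * n + k] = np.sum(dEdD * _STRAIN_BASIS[k]) / L0
        if e < best["energy"]:
            best.update(energy=e, z=z.copy(), res=res)
        return e, g

    z0 = np.concatenate([pos0.ravel(), np.zeros(6)] if relax_cell else [pos0.ravel()])
    bounds = None
    if relax_cell or max_displacement is not None:
        if max_displacement is None:
            pos_bounds = [(None, None)] * (3 * n)
        else:
            pos_bounds = [(v - max_displacement, v + max_displacement) for v in pos0.ravel()]
        bounds = pos_bounds + (
            [(-strain_bound * L0, strain_bound * L0)] * 6 if relax_cell else []
        )

    class _Done(Exception):
        pass

    def callback(z):
        st, _, _ = unpack(z)
        try:
            res = calc.evaluate(st)
        except Exception:
            return
        if _converged(res, st, fmax, relax_cell, smax):
            best.update(energy=-np.inf, z=z.copy(), res=res)
            raise _Done

    try:
        minimize(
            objective,
            z0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=callback,
            options={"maxiter": max_steps, "maxfun": 5 * max_steps + 100,
                     "ftol": 1e-14, "gtol": 1e-10},
        )
    except _Done:
        pass

    st, _, _ = unpack(best["z"])
    res = calc.evaluate(st)
    st.labels = res
    if not _converged(res, st, fmax, relax_cell, smax):
        raise RelaxationError(
            f"relaxation did not reach fmax={fmax} within {max_steps} steps",
            st,
            _max_force(res.forces),
        )
    return st


def _converged(res: EFSResult, structure: PeriodicStructure, fmax: float,
               relax_cell: bool, smax: float) -> bool:
    if _max_force(res.forces) > fmax:
        return False
    if relax_cell:
        if res.virial is None:
            raise ValueError("cell relaxation requires a virial-capable calculator")
        L = structure.volume() ** (1.0 / 3.0)
        if np.abs(res.virial).max() / L > smax:
            return False
    return True


def relax_volume(
    structure: PeriodicStructure,
    calc: Calculator,
    bounds: tuple[float, float] = (0.82, 1.25),
    min_cell_height: float = 0.0,
    xatol: float = 1e-4,
):
    """Rigid-molecule isotropic volume relaxation.

    Finds the linear scale factor s minimizing the energy of the structure
    with its cell scaled by s and molecular centers of mass scaled along
    (internal geometries fixed).  A scalar, bounded minimization: robust
    against the soft collective modes that make full variable-cell
    relaxation of porous molecular packings wander between basins, which
    makes it the right probe for *density* comparisons between methods.

    Returns ``(rescaled structure with labels, s)``.
    """
    from scipy.optimize import minimize_scalar

    from .structures import rescale_cell

    lo, hi = bounds
    if min_cell_height > 0:
        lo = max(lo, min_cell_height / structure.cell_heights().min())
    if not lo < hi:
        raise ValueError("empty scale interval after the cell-height floor")

    def energy(s):
        return calc.evaluate(rescale_cell(structure, float(s))).energy

    opt = minimize_scalar(energy, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    s = float(opt.x)
    out = rescale_cell(structure, s)
    out.labels = calc.evaluate(out)
    return out, s


# --------------------------------------------------------------------------
# NPT molecular dynamics


def run_npt(
    structure: PeriodicStructure,
    calc: Calculator,
    temperature: float,
    pressure: float = 1.0,
    n_steps: int = 20000,
    timestep: float = 1.0,
    seed: int = 0,
    friction: float = 0.02,
    barostat: bool = True,
    barostat_interval: int = 25,
    barostat_dlnv: float = 0.02,
    sample_interval: int = 20,
    force_bound: float = 60.0,
    min_cell_height: float = 0.0,
    bond_tolerance: float = 1.1,
) -> Trajectory:
    """Langevin (BAOAB) dynamics with an isotropic MC barostat.

    Temperature in K, pressure in bar, timestep in fs, friction in 1/fs.
    Thermo records (instantaneous temperature from 3N kinetic degrees of
    freedom, virial pressure, density, potential energy) are appended every
    ``sample_interval`` steps.  Raises on force blow-up with the offending
    frame attached.
    """
    if temperature < 0 or timestep <= 0:
        raise ValueError("temperature must be >= 0 and timestep > 0")
    rng = np.random.default_rng(seed)
    n = structure.n_atoms
    m = structure.masses()[:, None]
    pos = structure.positions.copy()
    cell = structure.cell.copy()
    kT = KB_EV * temperature
    p_ev = pressure * BAR_TO_EV_A3

    # fixed molecular topology for COM rescaling
    units = identify_molecules(structure, bond_tolerance) if structure.periodic else []

    vel = rng.normal(0.0, 1.0, (n, 3)) * np.sqrt(kT * EV_PER_A_AMU / m) if kT > 0 else np.zeros((n, 3))
    vel -= vel.mean(axis=0, keepdims=True)

    c1 = np.exp(-friction * timestep)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))

    def make_structure():
        return PeriodicStructure(structure.species, pos.copy(), cell.copy(), structure.pbc,
                                 provenance=structure.provenance)

    res = calc.evaluate(make_structure())
    frames, temps, press, dens, epots = [], [], [], [], []
    n_acc = n_try = 0

    for step in range(1, n_steps + 1):
        # B A O A B
        vel += 0.5 * timestep * res.forces / m * EV_PER_A_AMU
        pos += 0.5 * timestep * vel
        if kT > 0:
            vel = c1 * vel + c2 * rng.normal(0.0, 1.0, (n, 3)) * np.sqrt(kT * EV_PER_A_AMU / m)
        pos += 0.5 * timestep * vel
        res = calc.evaluate(make_structure())
        if np.abs(res.forces).max() > force_bound:
            bad = make_structure()
            bad.labels = res
            raise RuntimeError(
                f"force blow-up at step {step}: |F|max = {np.abs(res.forces).max():.2f} eV/A"
            ) from None
        vel += 0.5 * timestep * res.forces / m * EV_PER_A_AMU

        if barostat and structure.periodic and step % barostat_interval == 0:
            n_try += 1
            dlnv = rng.uniform(-barostat_dlnv, barostat_dlnv)
            s = np.exp(dlnv / 3.0)
            new_cell = cell * s
            new_pos = pos.copy()
            for u in units:
                up = pos[u.atom_indices] + u.image_shifts @ cell
                com = up.mean(axis=0)
                new_pos[u.atom_indices] = up - com + com * s - u.image_shifts @ new_cell
            trial = PeriodicStructure(structure.species, new_pos, new_cell, structure.pbc)
            heights_ok = trial.cell_heights().min() >= min_cell_height
            if heights_ok:
                try:
                    trial_res = calc.evaluate(trial)
                except Exception:
                    trial_res = None
                if trial_res is not None:
                    vol = abs(np.linalg.det(cell))
                    dv = abs(np.linalg.det(new_cell)) - vol
                    n_free = max(1, len(units))
                    arg = -(trial_res.energy - res.energy + p_ev * dv) / max(kT, 1e-12) + n_free * dlnv
                    if np.log(max(rng.uniform(), 1e-300)) < arg:
                        pos, cell, res = new_pos, new_cell, trial_res
                        n_acc += 1

        if step % sample_interval == 0:
            ke = 0.5 * float(np.sum(m * vel**2)) / EV_PER_A_AMU
            t_inst = 2.0 * ke / (3.0 * n * KB_EV)
            st = make_structure()
            st.labels = res
            frames.append(st)
            temps.append(t_inst)
            if structure.periodic:
                vol = st.volume()
                w = res.virial if res.virial is not None else np.zeros((3, 3))
                p_inst = (2.0 * ke + np.trace(w)) / (3.0 * vol) / BAR_TO_EV_A3
                press.append(p_inst)
                dens.append(st.density())
            else:
                press.append(0.0)
                dens.append(0.0)
            epots.append(res.energy)

    return Trajectory(frames, temps, press, dens, epots)


def mean_density(traj: Trajectory, discard_fraction: float = 0.2, n_blocks: int = 5):
    """Block-averaged mean density and standard error over retained frames.

    Frames in the first ``discard_fraction`` of the trajectory are treated
    as equilibration and dropped; the rest is split into ``n_blocks``
    contiguous blocks and the standard error estimated from the scatter of
    block means (robust to short-time correlation).
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must lie in [0, 1)")
    data = traj.density[int(np.floor(discard_fraction * len(traj.density))):]
    if len(data) < n_blocks:
        raise ValueError(f"need at least {n_blocks} retained frames, got {len(data)}")
    blocks = np.array_split(data, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return float(data.mean()), se
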