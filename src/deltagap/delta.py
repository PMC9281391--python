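"""The delta-learning composite: baseline + intra corrections + inter correction.

The total energy of a crystal is

    E = E_baseline
      + sum_t sum_{i=1..N_t} dE_intra^t(monomer_i)
      + dE_inter(crystal)

where one intramolecular correction is fitted per component type t and a
single intermolecular correction covers all component combinations.
Corrections apply to energies, forces and virials alike: intra models are
evaluated on unwrapped in-crystal monomer geometries, their forces mapped
back onto the parent atoms and their virials taken from the monomers'
relative-vector gradients (gauge-consistent because intra forces sum to
zero per molecule).

Label generation follows the same bookkeeping.  Intra labels are plain
target-baseline differences on gas-phase monomers.  Inter labels are the
*residual* of the total delta after subtracting the fitted intra-model
predictions, which makes the energy expression exact by construction on the
training data.
"""

from __future__ import annotations

import abc
import logging
from dataclasses import dataclass, field

import numpy as np

from .gap import GapModel, TrainingObservation
from .structures import (
    ComponentLibrary,
    EFSResult,
    PeriodicStructure,
    assign_component_types,
    extract_monomer,
    identify_molecules,
)

__all__ = [
    "Calculator",
    "DeltaModel",
    "GapCalculator",
    "delta_gap_evaluate",
    "label_inter",
    "label_intra",
]

logger = logging.getLogger(__name__)


class Calculator(abc.ABC):
    """Anything that maps a structure to energy/forces/virial.

    Implementations must be deterministic: identical structures give
    identical results.
    """

    name: str = "calculator"

    @abc.abstractmethod
    def evaluate(self, structure: PeriodicStructure) -> EFSResult:
        ...


class GapCalculator(Calculator):
    """A bare GAP model exposed through the calculator interface."""

    def __init__(self, model: GapModel, name: str = "gap"):
        self.model = model
        self.name = name

    def evaluate(self, structure: PeriodicStructure) -> EFSResult:
        return self.model.predict(structure)


@dataclass
class DeltaModel(Calculator):
    """Baseline calculator + per-component intra GAPs + one inter GAP."""

    baseline: Calculator
    intra_models: dict[str, GapModel]
    inter_model: GapModel
    library: ComponentLibrary
    bond_tolerance: float = 1.2
    name: str = "delta-gap"

    def supported_components(self) -> list[str]:
        return list(self.intra_models)

    def decompose(self, structure: PeriodicStructure, forces: bool = True) -> dict:
        """Evaluate every term of the energy expression separately.

        Returns a dict with keys ``baseline``, ``intra`` (map component type
        -> EFSResult in parent-atom indexing, summed over molecules of that
        type), ``inter`` and ``total``.
        """
        units = assign_component_types(
            identify_molecules(structure, self.bond_tolerance),
            structure,
            self.library,
            self.bond_tolerance,
        )
        for u in units:
            if u.component_type not in self.intra_models:
                raise ValueError(
                    f"no intramolecular correction for component {u.component_type!r}"
                )

        base = self.baseline.evaluate(structure)
        n = structure.n_atoms

        intra: dict[str, EFSResult] = {}
        for u in units:
            mono = extract_monomer(structure, u)
            res = self.intra_models[u.component_type].predict(mono, forces=forces)
            f = np.zeros((n, 3))
            f[u.atom_indices] = res.forces
            w = res.virial if res.virial is not None else np.zeros((3, 3))
            prev = intra.get(u.component_type)
            if prev is None:
                intra[u.component_type] = EFSResult(res.energy, f, w)
            else:
                intra[u.component_type] = EFSResult(
                    prev.energy + res.energy, prev.forces + f, prev.virial + w
                )

        inter = self.inter_model.predict(structure, forces=forces)

        total_e = base.energy + sum(r.energy for r in intra.values()) + inter.energy
        total_f = base.forces + sum(r.forces for r in intra.values()) + inter.forces
        total_w = None
        if base.virial is not None and inter.virial is not None:
            total_w = (
                base.virial
                + sum(r.virial for r in intra.values())
                + inter.virial
            )
        return {
            "baseline": base,
            "intra": intra,
            "inter": inter,
            "total": EFSResult(total_e, total_f, total_w),
        }

    def evaluate(self, structure: PeriodicStructure, forces: bool = True) -> EFSResult:
        return self.decompose(structure, forces=forces)["total"]


def delta_gap_evaluate(model: DeltaModel, structure: PeriodicStructure) -> EFSResult:
    """Functional form of :meth:`DeltaModel.evaluate`."""
    return model.evaluate(structure)


def label_intra(
    monomers: list[PeriodicStructure],
    target: Calculator,
    baseline: Calculator,
    weight_class: str = "default",
) -> list[TrainingObservation]:
    """Target-minus-baseline labels on gas-phase monomer geometries.

    A monomer on which either calculator fails is skipped with a logged
    warning; the exclusion is recorded in the observation list's length.
    """
    out: list[TrainingObservation] = []
    for i, mono in enumerate(monomers):
        if mono.periodic:
            raise ValueError("intra labels require non-periodic monomers")
        try:
            t = target.evaluate(mono)
            b = baseline.evaluate(mono)
        except Exception as exc:  # noqa: BLE001 - calculators may fail arbitrarily
            logger.warning("monomer %d excluded from intra labels: %s", i, exc)
            continue
        out.append(
            TrainingObservation(
                mono,
                energy=t.energy - b.energy,
                forces=t.forces - b.forces,
                weight_class=weight_class,
            )
        )
    return out


def label_inter(
    crystals: list[PeriodicStructure],
    target: Calculator,
    baseline: Calculator,
    intra_models: dict[str, GapModel],
    library: ComponentLibrary,
    bond_tolerance: float = 1.2,
    include_virial: bool = False,
    weight_class: str = "default",
) -> list[TrainingObservation]:
    """Residual intermolecular labels after subtracting fitted intra models.

    energy = [E_target - E_baseline] - sum_molecules dE_intra(monomer at the
    in-crystal geometry); forces and (optionally) virials analogously.  By
    construction the composite model then reproduces the target exactly on
    any structure where its own predictions match these labels.
    """
    out: list[TrainingObservation] = []
    for i, crystal in enumerate(crystals):
        try:
            units = assign_component_types(
                identify_molecules(crystal, bond_tolerance), crystal, library, bond_tolerance
            )
            t = target.evaluate(crystal)
            b = baseline.evaluate(crystal)
        except Exception as exc:  # noqa: BLE001
            logger.warning("crystal %d excluded from inter labels: %s", i, exc)
            continue
        de = t.energy - b.energy
        df = t.forces - b.forces
        dw = None
        if include_virial and t.virial is not None and b.virial is not None:
            dw = t.virial - b.virial
        ok = True
        for u in units:
            if u.component_type not in intra_models:
                logger.warning(
                    "crystal %d excluded: unknown component %r", i, u.component_type
                )
                ok = False
                break
            mono = extract_monomer(crystal, u)
            res = intra_models[u.component_type].predict(mono)
            de -= res.energy
            df[u.atom_indices] -= res.forces
            if dw is not None and res.virial is not None:
                dw -= res.virial
        if not ok:
            continue
        out.append(
            TrainingObservation(
                crystal, energy=de, forces=df, virial=dw, weight_class=weight_class
            )
        )
    return out
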