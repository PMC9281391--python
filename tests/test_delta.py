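"""Composite model bookkeeping: additivity, labels, monomer limits."""

import numpy as np
import pytest

from deltagap.delta import DeltaModel, label_inter, label_intra
from deltagap.gap import GapModel, select_sparse_points, TrainingObservation
from deltagap.soap import SoapSpec
from deltagap.structures import (
    EFSResult,
    PeriodicStructure,
    extract_monomer,
    identify_molecules,
)

SPEC = SoapSpec(cutoff=3.0, n_max=3, l_max=2, sigma_atom=0.5,
                species=("H", "N", "O"), zeta=4)


class ConstantPerAtom:
    """Toy target offset: baseline plus c per atom (zero forces)."""

    name = "constant"

    def __init__(self, base, c):
        self.base = base
        self.c = c

    def evaluate(self, s):
        r = self.base.evaluate(s)
        return EFSResult(r.energy + self.c * s.n_atoms, r.forces, r.virial)


def zero_gap_model(structure_or_envs, m=4):
    """A GAP model with all-zero weights and offsets: the null correction."""
    obs = [TrainingObservation(structure_or_envs, energy=0.0)]
    pts = select_sparse_points(obs, m, SPEC, seed=0)
    from deltagap.soap import descriptor_matrix

    return GapModel(SPEC, descriptor_matrix(pts), tuple(p.center_species for p in pts),
                    np.zeros(len(pts)), {}, {})


@pytest.fixture(scope="module")
def null_delta(library):
    from deltagap.toyverse import generate_trial_crystals, toy_baseline

    crystal = generate_trial_crystals(library, [{"active": 3, "n2": 3}], 1, seed=5)[0]
    base = toy_baseline(library)
    null = zero_gap_model(crystal)
    model = DeltaModel(base, {n: null for n in library.names()}, null, library)
    return model, crystal, base


class TestEvaluate:
    def test_null_corrections_reproduce_baseline(self, null_delta):
        model, crystal, base = null_delta
        got = model.evaluate(crystal)
        ref = base.evaluate(crystal)
        assert got.energy == pytest.approx(ref.energy, abs=1e-12)
        np.testing.assert_allclose(got.forces, ref.forces, atol=1e-12)
        np.testing.assert_allclose(got.virial, ref.virial, atol=1e-12)

    def test_decomposition_sums_to_total(self, pilot_study, toy_crystals):
        model = pilot_study.model
        for s in toy_crystals[:4]:
            parts = model.decompose(s)
            total = (
                parts["baseline"].energy
                + sum(r.energy for r in parts["intra"].values())
                + parts["inter"].energy
            )
            assert parts["total"].energy == pytest.approx(total, abs=1e-10)

    def test_single_molecule_monomer_limit(self, pilot_study, library):
        """For an isolated molecule, total - baseline - inter equals the intra
        model's gas-phase prediction exactly."""
        from deltagap.workflow import _gas_monomer

        model = pilot_study.model
        gas = _gas_monomer(library, "active")
        parts = model.decompose(gas)
        intra_direct = model.intra_models["active"].predict(gas)
        residual = parts["total"].energy - parts["baseline"].energy - parts["inter"].energy
        assert residual == pytest.approx(intra_direct.energy, abs=1e-10)

    def test_forces_match_finite_differences(self, pilot_study, toy_crystals):
        model = pilot_study.model
        s = toy_crystals[0]
        res = model.evaluate(s)
        h = 1e-4
        rng = np.random.default_rng(1)
        for a, x in zip(rng.integers(0, s.n_atoms, 4), rng.integers(0, 3, 4)):
            pp, pm = s.positions.copy(), s.positions.copy()
            pp[a, x] += h
            pm[a, x] -= h
            ep = model.evaluate(PeriodicStructure(s.species, pp, s.cell), forces=False).energy
            em = model.evaluate(PeriodicStructure(s.species, pm, s.cell), forces=False).energy
            assert -(ep - em) / (2 * h) == pytest.approx(res.forces[a, x], abs=1e-5)

    def test_unknown_component_raises(self, null_delta):
        model, crystal, _ = null_delta
        model2 = DeltaModel(model.baseline, {}, model.inter_model, model.library)
        with pytest.raises(ValueError, match="intramolecular"):
            model2.evaluate(crystal)


class TestLabelIntra:
    def test_target_equals_baseline_gives_zero(self, library, baseline):
        from deltagap.workflow import _gas_monomer

        monos = [_gas_monomer(library, n) for n in library.names()]
        obs = label_intra(monos, baseline, baseline)
        assert all(o.energy == pytest.approx(0.0, abs=1e-14) for o in obs)
        assert all(np.abs(o.forces).max() < 1e-14 for o in obs)

    def test_constant_per_atom_target(self, library, baseline):
        from deltagap.workflow import _gas_monomer

        target = ConstantPerAtom(baseline, 0.25)
        monos = [_gas_monomer(library, "active"), _gas_monomer(library, "n2o")]
        obs = label_intra(monos, target, baseline)
        for o in obs:
            assert o.energy == pytest.approx(0.25 * o.structure.n_atoms)
            assert np.abs(o.forces).max() < 1e-14

    def test_rotation_invariant_labels(self, library, baseline, target):
        from deltagap.workflow import _gas_monomer
        from test_soap import rotation_matrix

        gas = _gas_monomer(library, "no")
        gas.positions += np.random.default_rng(0).normal(0, 0.05, gas.positions.shape)
        R = rotation_matrix(np.random.default_rng(1))
        rot = PeriodicStructure(gas.species, gas.positions @ R.T, gas.cell, gas.pbc)
        o1 = label_intra([gas], target, baseline)[0]
        o2 = label_intra([rot], target, baseline)[0]
        assert o1.energy == pytest.approx(o2.energy, abs=1e-10)
        np.testing.assert_allclose(o2.forces, o1.forces @ R.T, atol=1e-10)

    def test_periodic_monomer_rejected(self, baseline, toy_crystals):
        with pytest.raises(ValueError):
            label_intra([toy_crystals[0]], baseline, baseline)


class TestLabelInter:
    def test_bookkeeping_identity(self, library, baseline, target, pilot_study, toy_crystals):
        """energy_label + sum(intra predictions) + E_baseline == E_target."""
        intra = pilot_study.model.intra_models
        for s in toy_crystals[:3]:
            obs = label_inter([s], target, baseline, intra, library)[0]
            total = baseline.evaluate(s).energy + obs.energy
            for u in identify_molecules(s):
                pass
            from deltagap.structures import assign_component_types

            units = assign_component_types(identify_molecules(s), s, library)
            for u in units:
                total += intra[u.component_type].predict(extract_monomer(s, u)).energy
            assert total == pytest.approx(target.evaluate(s).energy, abs=1e-10)

    def test_target_equals_baseline_gives_minus_intra(self, library, baseline, pilot_study, toy_crystals):
        intra = pilot_study.model.intra_models
        s = toy_crystals[1]
        obs = label_inter([s], baseline, baseline, intra, library)[0]
        from deltagap.structures import assign_component_types

        units = assign_component_types(identify_molecules(s), s, library)
        intra_sum = sum(
            intra[u.component_type].predict(extract_monomer(s, u)).energy for u in units
        )
        assert obs.energy == pytest.approx(-intra_sum, abs=1e-10)

    def test_isolated_molecules_give_near_zero_labels(self, library, baseline, target, pilot_study):
        """Molecules beyond all interaction ranges: only intra physics left,
        so inter labels shrink to the intra-model fit error."""
        from deltagap.workflow import _gas_monomer

        intra = pilot_study.model.intra_models
        gas = _gas_monomer(library, "active")
        pos = np.vstack([gas.positions + [0, 0, 0], gas.positions + [15.0, 0, 0]])
        far = PeriodicStructure(gas.species * 2, pos + 5.0, np.eye(3) * 40.0)
        obs = label_inter([far], target, baseline, intra, library)[0]
        assert abs(obs.energy) < 5e-3
        assert np.abs(obs.forces).max() < 5e-2
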