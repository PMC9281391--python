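"""Sparse-GP regression: sparse selection, fitting, prediction consistency."""

import numpy as np
import pytest

from deltagap.gap import (
    GapModel,
    TrainingObservation,
    fit_gap,
    predict,
    select_sparse_points,
)
from deltagap.soap import SoapSpec, compute_soap_environments, descriptor_matrix
from deltagap.structures import PeriodicStructure


@pytest.fixture(scope="module")
def spec():
    return SoapSpec(cutoff=3.5, n_max=4, l_max=3, sigma_atom=0.5, species=("H", "O"), zeta=4)


@pytest.fixture(scope="module")
def base_structure():
    rng = np.random.default_rng(1)
    cell = np.diag([7.2, 7.6, 7.0]) + rng.normal(0, 0.1, (3, 3))
    pos = rng.uniform(0, 7, (8, 3))
    return PeriodicStructure(tuple(rng.choice(["H", "O"], 8)), pos, cell)


@pytest.fixture(scope="module")
def random_model(spec, base_structure):
    """A syntactically valid model with random weights: enough to test the
    analytic consistency of prediction (forces, virial, extensivity)."""
    rng = np.random.default_rng(2)
    envs = compute_soap_environments(base_structure, spec).descriptors()
    return GapModel(
        spec,
        descriptor_matrix(envs),
        tuple(e.center_species for e in envs),
        rng.normal(0, 0.05, len(envs)),
        {"H": -0.1, "O": -0.3},
        {},
    )


def perturbed(structure, seed, amp=0.05):
    rng = np.random.default_rng(seed)
    return PeriodicStructure(
        structure.species, structure.positions + rng.normal(0, amp, structure.positions.shape),
        structure.cell, structure.pbc,
    )


class TestSparsePoints:
    def test_all_environments_when_m_equals_pool(self, spec, base_structure):
        obs = [TrainingObservation(base_structure, energy=0.0)]
        pts = select_sparse_points(obs, 8, spec, seed=0)
        assert len(pts) == 8

    def test_m_exceeding_pool_raises(self, spec, base_structure):
        with pytest.raises(ValueError):
            select_sparse_points([TrainingObservation(base_structure, energy=0.0)], 99, spec)

    def test_duplicates_never_before_distinct(self, spec, base_structure):
        obs = [
            TrainingObservation(base_structure, energy=0.0),
            TrainingObservation(base_structure, energy=0.0),  # exact duplicate pool
        ]
        pts = select_sparse_points(obs, 9, spec, seed=3)
        vecs = descriptor_matrix(pts)
        # the first 8 picks must be the 8 distinct environments
        first = vecs[:8]
        assert np.linalg.matrix_rank(first @ first.T > 0.999999) or len(
            np.unique(np.round(first, 8), axis=0)
        ) == 8

    def test_matches_brute_force_greedy_on_1d_family(self, spec):
        """Environments parameterized by one bond length: FPS picks must agree
        with an exhaustive greedy recomputation in descriptor space."""
        structures = [
            PeriodicStructure(("O", "H"), [[0, 0, 0], [0.8 + 0.05 * i, 0, 0]],
                              np.eye(3) * 20, (False,) * 3)
            for i in range(12)
        ]
        obs = [TrainingObservation(s, energy=0.0) for s in structures]
        pts = select_sparse_points(obs, 6, spec, seed=5)

        envs = []
        for s in structures:
            envs.extend(compute_soap_environments(s, spec).descriptors())
        X = descriptor_matrix(envs)
        sp = np.array([e.center_species for e in envs])

        def dist(i, j):
            if sp[i] != sp[j]:
                return np.sqrt(2.0)
            k = min(1.0, max(-1.0, X[i] @ X[j])) ** 4
            return np.sqrt(max(0.0, 2 - 2 * k))

        start = int(np.random.default_rng(5).integers(len(envs)))
        chosen = [start]
        while len(chosen) < 6:
            best, bd = None, -1.0
            for i in range(len(envs)):
                if i in chosen:
                    continue
                d = min(dist(i, c) for c in chosen)
                if d > bd + 1e-15:
                    best, bd = i, d
            chosen.append(best)
        np.testing.assert_allclose(descriptor_matrix(pts), X[chosen], atol=1e-12)


class TestFit:
    def test_interpolation_limit(self, spec, base_structure, random_model):
        obs = []
        for i in range(6):
            s = perturbed(base_structure, i)
            obs.append(TrainingObservation(s, energy=predict(random_model, s, forces=False).energy))
        pts = select_sparse_points(obs, 48, spec, seed=0)
        model = fit_gap(obs, spec, pts, regularization={"sigma_energy": 1e-8})
        for o in obs:
            assert predict(model, o.structure, forces=False).energy == pytest.approx(
                o.energy, abs=1e-6
            )

    def test_offset_absorbs_per_atom_shift(self, spec, base_structure, random_model):
        obs, obs_shift = [], []
        for i in range(6):
            s = perturbed(base_structure, i)
            e = predict(random_model, s, forces=False).energy
            obs.append(TrainingObservation(s, energy=e))
            obs_shift.append(TrainingObservation(s, energy=e + 0.5 * s.n_atoms))
        pts = select_sparse_points(obs, 48, spec, seed=0)
        m1 = fit_gap(obs, spec, pts, regularization={"sigma_energy": 1e-8})
        m2 = fit_gap(obs_shift, spec, pts, regularization={"sigma_energy": 1e-8})
        probe = perturbed(base_structure, 99)
        e1 = predict(m1, probe, forces=False).energy
        e2 = predict(m2, probe, forces=False).energy
        assert e2 - e1 == pytest.approx(0.5 * probe.n_atoms, abs=1e-4)

    def test_force_training_reduces_force_error(self, spec, base_structure, random_model):
        """Monte-Carlo comparison at fixed seed: adding force labels must
        lower held-out force RMSE relative to an energy-only fit."""
        rng = np.random.default_rng(0)
        train = [perturbed(base_structure, i, amp=0.08) for i in range(10)]
        test = [perturbed(base_structure, 100 + i, amp=0.08) for i in range(5)]
        lbl_train = [predict(random_model, s) for s in train]
        lbl_test = [predict(random_model, s) for s in test]
        pts = select_sparse_points(
            [TrainingObservation(s, energy=0.0) for s in train], 40, spec, seed=1
        )
        reg = {"sigma_energy": 1e-4, "sigma_force": 1e-3}
        m_e = fit_gap(
            [
                TrainingObservation(s, energy=l.energy + rng.normal(0, 1e-4))
                for s, l in zip(train, lbl_train)
            ],
            spec, pts, regularization=reg,
        )
        m_ef = fit_gap(
            [
                TrainingObservation(s, energy=l.energy + rng.normal(0, 1e-4), forces=l.forces)
                for s, l in zip(train, lbl_train)
            ],
            spec, pts, regularization=reg,
        )

        def rmse(model):
            errs = [predict(model, s).forces - l.forces for s, l in zip(test, lbl_test)]
            return np.sqrt(np.mean(np.concatenate(errs) ** 2))

        assert rmse(m_ef) < rmse(m_e)

    def test_no_labels_raises(self, base_structure):
        with pytest.raises(ValueError):
            TrainingObservation(base_structure)


class TestPredict:
    def test_isolated_atoms_forces_zero(self, spec, random_model):
        s = PeriodicStructure(("H", "O"), [[0, 0, 0], [15, 0, 0]], np.eye(3) * 40, (False,) * 3)
        res = predict(random_model, s)
        assert np.abs(res.forces).max() == 0.0
        assert res.energy == pytest.approx(res.local_energies.sum())

    def test_forces_match_finite_differences(self, spec, base_structure, random_model):
        res = predict(random_model, base_structure)
        h = 1e-4
        rng = np.random.default_rng(3)
        for a, x in zip(rng.integers(0, 8, 6), rng.integers(0, 3, 6)):
            pp, pm = base_structure.positions.copy(), base_structure.positions.copy()
            pp[a, x] += h
            pm[a, x] -= h
            ep = predict(random_model, PeriodicStructure(base_structure.species, pp, base_structure.cell), forces=False).energy
            em = predict(random_model, PeriodicStructure(base_structure.species, pm, base_structure.cell), forces=False).energy
            assert -(ep - em) / (2 * h) == pytest.approx(res.forces[a, x], abs=1e-5)

    def test_virial_matches_strain_derivative(self, spec, base_structure, random_model):
        res = predict(random_model, base_structure)
        h = 1e-5
        for a in range(3):
            for b in range(a, 3):
                eps = np.zeros((3, 3))
                eps[a, b] = eps[b, a] = h
                def energy_at(sign):
                    D = np.eye(3) + sign * eps
                    s = PeriodicStructure(
                        base_structure.species, base_structure.positions @ D, base_structure.cell @ D
                    )
                    return predict(random_model, s, forces=False).energy
                dE = (energy_at(+1) - energy_at(-1)) / (2 * h)
                expect = -res.virial[a, b] * (2 if a != b else 1)
                assert dE == pytest.approx(expect, abs=1e-5)

    def test_extensivity_doubled_cell(self, spec, base_structure, random_model):
        s = base_structure
        cell2 = s.cell.copy()
        cell2[2] *= 2
        doubled = PeriodicStructure(s.species * 2, np.vstack([s.positions, s.positions + s.cell[2]]), cell2)
        e1 = predict(random_model, s, forces=False).energy
        e2 = predict(random_model, doubled, forces=False).energy
        assert e2 == pytest.approx(2 * e1, abs=1e-8)

    def test_rotation_invariance_and_force_corotation(self, spec, base_structure, random_model):
        from test_soap import rotation_matrix

        rng = np.random.default_rng(4)
        R = rotation_matrix(rng)
        rot = PeriodicStructure(
            base_structure.species, base_structure.positions @ R.T, base_structure.cell @ R.T
        )
        r0 = predict(random_model, base_structure)
        r1 = predict(random_model, rot)
        assert r1.energy == pytest.approx(r0.energy, abs=1e-8)
        np.testing.assert_allclose(r1.forces, r0.forces @ R.T, atol=1e-7)

    def test_species_not_in_model_raises(self, random_model):
        s = PeriodicStructure(("C",), [[0, 0, 0]], np.eye(3) * 10, (False,) * 3)
        with pytest.raises(ValueError):
            predict(random_model, s)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, spec, base_structure, random_model):
        path = tmp_path / "model.npz"
        random_model.save(path)
        loaded = GapModel.load(path)
        assert loaded.spec == random_model.spec
        e0 = predict(random_model, base_structure, forces=False).energy
        e1 = predict(loaded, base_structure, forces=False).energy
        assert e0 == pytest.approx(e1, abs=1e-12)
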