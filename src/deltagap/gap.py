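"""Sparse Gaussian-process regression over summed local SOAP energies.

The total energy of a structure is modeled as a sum of per-atom local
energies, each a kernel expansion over a set of representative ("sparse")
environments:

    E = sum_i [ offset(Z_i) + sum_s w_s k(d_i, x_s) ],   k = (d . x)^zeta

with the kernel defined as zero between environments of different center
species (block structure).  Weights solve a regularized least-squares
problem assembled from energy rows (kernel sums), force rows (chain rule
through the descriptor gradients) and optional virial rows, with the
sparse-point Gram matrix as a Tikhonov prior (jittered Cholesky factor
appended to the design).  This is the standard projected-process / GAP
normal-equation system solved by orthogonal factorization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cholesky, lstsq

from .soap import (
    EnvironmentDescriptor,
    SoapSpec,
    compute_soap_environments,
    descriptor_matrix,
)
from .structures import EFSResult, PeriodicStructure

__all__ = [
    "DEFAULT_REGULARIZATION",
    "GapModel",
    "TrainingObservation",
    "fit_gap",
    "predict",
    "select_sparse_points",
]

# Conventional GAP-style noise levels.
DEFAULT_REGULARIZATION: Mapping[str, float] = {
    "sigma_energy": 0.001,  # eV per atom
    "sigma_force": 0.05,    # eV/A
    "sigma_virial": 0.05,   # eV
}

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingObservation:
    """A labeled structure; at least one of energy/forces/virial present.

    ``weight_class`` selects per-observation regularization strengths, so
    e.g. strongly perturbed far-from-minimum structures can carry looser
    noise levels than near-minimum ones.
    """

    structure: PeriodicStructure
    energy: float | None = None
    forces: np.ndarray | None = None
    virial: np.ndarray | None = None
    weight_class: str = "default"

    def __post_init__(self) -> None:
        if self.energy is None and self.forces is None and self.virial is None:
            raise ValueError("observation must carry at least one label")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if len(self.forces) != self.structure.n_atoms:
                raise ValueError("force label shape mismatch")
        if self.virial is not None:
            self.virial = np.asarray(self.virial, dtype=float).reshape(3, 3)


@dataclass
class GapModel:
    """Fitted sparse-GP correction model."""

    spec: SoapSpec
    sparse_vectors: np.ndarray
    sparse_species: tuple[str, ...]
    weights: np.ndarray
    per_species_offset: dict[str, float]
    regularization: dict[str, float]
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        self.sparse_vectors = np.atleast_2d(np.asarray(self.sparse_vectors, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.sparse_species = tuple(self.sparse_species)
        if len(self.weights) != len(self.sparse_vectors):
            raise ValueError("weights length must equal sparse point count")

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "spec": {
                "cutoff": self.spec.cutoff,
                "n_max": self.spec.n_max,
                "l_max": self.spec.l_max,
                "sigma_atom": self.spec.sigma_atom,
                "species": list(self.spec.species),
                "zeta": self.spec.zeta,
                "smooth_width": self.spec.smooth_width,
            },
            "sparse_species": list(self.sparse_species),
            "per_species_offset": self.per_species_offset,
            "regularization": self.regularization,
            "jitter": self.jitter,
        }
        np.savez(
            path,
            sparse_vectors=self.sparse_vectors,
            weights=self.weights,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GapModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        spec = SoapSpec(**{**meta["spec"], "species": tuple(meta["spec"]["species"])})
        return cls(
            spec,
            data["sparse_vectors"],
            tuple(meta["sparse_species"]),
            data["weights"],
            dict(meta["per_species_offset"]),
            dict(meta["regularization"]),
            float(meta["jitter"]),
        )

    def predict(self, structure: PeriodicStructure, forces: bool = True) -> EFSResult:
        return predict(self, structure, forces=forces)


# --------------------------------------------------------------------------
# sparse-point selection


def select_sparse_points(
    observations: Sequence, m: int, spec: SoapSpec, seed: int = 0
) -> list[EnvironmentDescriptor]:
    """Choose m representative environments by FPS in descriptor space.

    The metric is the kernel-induced distance sqrt(2 - 2 k); environments of
    different center species are maximally distant (cross-species kernel is
    zero), so all species get covered early.
    """
    envs: list[EnvironmentDescriptor] = []
    for obs in observations:
        structure = obs.structure if isinstance(obs, TrainingObservation) else obs
        envs.extend(compute_soap_environments(structure, spec).descriptors())
    if m > len(envs):
        raise ValueError(f"m={m} exceeds environment pool size {len(envs)}")
    X = descriptor_matrix(envs)
    sp = np.array([e.center_species for e in envs])
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(envs)))

    chosen = [start]
    mind = _env_dists(X, sp, start, spec.zeta)
    for _ in range(m - 1):
        cand = mind.copy()
        cand[chosen] = -np.inf
        nxt = int(np.argmax(cand))
        chosen.append(nxt)
        mind = np.minimum(mind, _env_dists(X, sp, nxt, spec.zeta))
    return [envs[i] for i in chosen]


def _env_dists(X: np.ndarray, sp: np.ndarray, idx: int, zeta: int) -> np.ndarray:
    k = np.clip(X @ X[idx], -1.0, 1.0) ** zeta
    k = np.where(sp == sp[idx], k, 0.0)
    return np.sqrt(np.clip(2.0 - 2.0 * k, 0.0, None))


# --------------------------------------------------------------------------
# fitting


def _row_blocks(
    structure: PeriodicStructure,
    spec: SoapSpec,
    S: np.ndarray,
    sp_mask_lookup: dict[str, np.ndarray],
    need_grads: bool,
):
    """Kernel features for one structure.

    Returns (energy_features (m,), force_features (N, 3, m) or None,
    virial_features (3, 3, m) or None, species counts).
    """
    zeta = spec.zeta
    envs = compute_soap_environments(structure, spec, gradients=need_grads)
    X = envs.vectors
    mask = np.vstack([sp_mask_lookup[s] for s in envs.center_species])
    dots = np.clip(X @ S.T, -1.0, 1.0)
    k = (dots**zeta) * mask
    e_feat = k.sum(axis=0)

    f_feat = v_feat = None
    if need_grads:
        n = structure.n_atoms
        coef = zeta * dots ** (zeta - 1) * mask  # (n_env, m)
        dEdx = np.zeros((n, 3, len(S)))
        v_feat = np.zeros((3, 3, len(S)))
        for e, (j_idx, R, grad) in enumerate(envs.neighbors):
            if len(j_idx) == 0:
                continue
            # T[j, s, x] = coef_es * (grad_j . x_s)_x
            T = np.einsum("jdx,md->jmx", grad, S) * coef[e][None, :, None]
            Txm = T.transpose(0, 2, 1)  # (J, 3, m)
            np.add.at(dEdx, j_idx, Txm)
            dEdx[e] -= Txm.sum(axis=0)
            v_feat -= np.einsum("jma,jb->abm", T, R)
        v_feat = 0.5 * (v_feat + v_feat.transpose(1, 0, 2))
        f_feat = -dEdx
    counts = {s: structure.species.count(s) for s in spec.species}
    return e_feat, f_feat, v_feat, counts


def fit_gap(
    observations: Sequence[TrainingObservation],
    spec: SoapSpec,
    sparse_points: Sequence[EnvironmentDescriptor],
    regularization: Mapping[str, float] | None = None,
    class_sigmas: Mapping[str, Mapping[str, float]] | None = None,
    jitter: float = 1e-8,
) -> GapModel:
    """Fit sparse-GP weights and per-species offsets.

    ``regularization`` holds the default noise levels (sigma_energy in
    eV/atom, sigma_force in eV/A, sigma_virial in eV); ``class_sigmas`` maps
    a ``weight_class`` tag to overriding levels.
    """
    if not observations:
        raise ValueError("no observations")
    base = dict(DEFAULT_REGULARIZATION)
    if regularization:
        base.update(regularization)
    class_sigmas = dict(class_sigmas or {})

    S = descriptor_matrix(sparse_points)
    sp_species = tuple(p.center_species for p in sparse_points)
    sp_arr = np.array(sp_species)
    sp_mask_lookup = {s: (sp_arr == s).astype(float) for s in spec.species}
    m = len(S)
    species = list(spec.species)
    n_off = len(species)

    rows, targets = [], []
    for obs in observations:
        for s in obs.structure.species:
            if s not in spec.species:
                raise ValueError(f"species {s!r} not covered by spec")
        sig = dict(base)
        sig.update(class_sigmas.get(obs.weight_class, {}))
        need_grads = obs.forces is not None or obs.virial is not None
        e_feat, f_feat, v_feat, counts = _row_blocks(
            obs.structure, spec, S, sp_mask_lookup, need_grads
        )
        if obs.energy is not None:
            w = 1.0 / (sig["sigma_energy"] * obs.structure.n_atoms)
            row = np.concatenate([e_feat, [counts[s] for s in species]])
            rows.append(w * row)
            targets.append(w * obs.energy)
        if obs.forces is not None:
            w = 1.0 / sig["sigma_force"]
            flat = f_feat.reshape(-1, m)
            for r, y in zip(flat, obs.forces.ravel()):
                rows.append(w * np.concatenate([r, np.zeros(n_off)]))
                targets.append(w * y)
        if obs.virial is not None:
            w = 1.0 / sig["sigma_virial"]
            for a in range(3):
                for b in range(a, 3):
                    rows.append(
                        w * np.concatenate([v_feat[a, b], np.zeros(n_off)])
                    )
                    targets.append(w * obs.virial[a, b])

    K_mm = np.clip(S @ S.T, -1.0, 1.0) ** spec.zeta
    K_mm *= sp_arr[:, None] == sp_arr[None, :]
    try:
        L = cholesky(K_mm + jitter * np.eye(m), lower=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"sparse Gram matrix singular even with jitter {jitter:g}; "
            "condition number too high - reduce m or raise jitter"
        ) from exc
    prior = np.hstack([L, np.zeros((m, n_off))])
    # tiny ridge on the offset columns: keeps near-collinear composition
    # vectors (e.g. all structures sharing one stoichiometry) from pushing
    # offsets along an unconstrained direction
    off_prior = np.hstack([np.zeros((n_off, m)), np.sqrt(1e-8) * np.eye(n_off)])

    A = np.vstack([np.asarray(rows), prior, off_prior])
    y = np.concatenate([np.asarray(targets), np.zeros(m + n_off)])
    sol, *_ = lstsq(A, y, lapack_driver="gelsd")

    offsets = {s: float(sol[m + i]) for i, s in enumerate(species)}
    return GapModel(
        spec, S, sp_species, sol[:m], offsets, base, jitter
    )


# --------------------------------------------------------------------------
# prediction


def predict(model: GapModel, structure: PeriodicStructure, forces: bool = True) -> EFSResult:
    """Energy, forces and virial of a structure under a GAP model.

    Forces are exact negative gradients of the predicted energy; the virial
    is assembled from the per-neighbor displacement gradients,
    ``W_ab = -sum (dE/dR)_a R_b`` (so stress = -virial/volume), which equals
    the negative strain derivative of the energy.
    """
    spec = model.spec
    for s in structure.species:
        if s not in spec.species:
            raise ValueError(f"species {s!r} not covered by model")
    zeta = spec.zeta
    S = model.sparse_vectors
    sp_arr = np.array(model.sparse_species)

    envs = compute_soap_environments(structure, spec, gradients=forces)
    X = envs.vectors
    mask = np.vstack([(sp_arr == s).astype(float) for s in envs.center_species])
    dots = np.clip(X @ S.T, -1.0, 1.0)
    k = (dots**zeta) * mask
    local = np.array(
        [model.per_species_offset.get(s, 0.0) for s in structure.species]
    ) + k @ model.weights
    energy = float(local.sum())

    if not forces:
        return EFSResult(energy, np.zeros((structure.n_atoms, 3)), None, local)

    coefw = zeta * dots ** (zeta - 1) * mask * model.weights[None, :]
    v_env = coefw @ S  # (n_env, dim): d(local energy)/d(descriptor)
    dEdx = np.zeros((structure.n_atoms, 3))
    W = np.zeros((3, 3))
    for e, (j_idx, R, grad) in enumerate(envs.neighbors):
        if len(j_idx) == 0:
            continue
        g = np.einsum("jdx,d->jx", grad, v_env[e])  # dE/dR_j
        np.add.at(dEdx, j_idx, g)
        dEdx[e] -= g.sum(axis=0)
        W -= g.T @ R
    W = 0.5 * (W + W.T)
    return EFSResult(energy, -dEdx, W, local)
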