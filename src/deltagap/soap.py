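"""SOAP power-spectrum descriptors, kernels, and analytic gradients.

An atom's neighborhood density (each neighbor smeared by a Gaussian of width
``sigma_atom``, multiplied by a smooth cutoff function) is expanded in a
radial basis of Gaussians times spherical harmonics.  The rotationally
invariant power spectrum

    p_{s1 s2, n n', l} = sum_m c^{s1}_{nlm} (c^{s2}_{n'lm})*

is evaluated here through the spherical-harmonic addition theorem as a
double sum over neighbor pairs weighted by Legendre polynomials of the
enclosed angle,

    p_{s1 s2, n n', l} = (2l+1)/(4 pi) * sum_{j in s1} sum_{k in s2}
                         A_{nl}(r_j) A_{n'l}(r_k) P_l(cos theta_jk),

which is mathematically identical and yields compact analytic gradients.
The radial channels A_{nl}(r) (radial integral of the smeared neighbor
density against the basis, times the cutoff function) are tabulated by
Gauss-Legendre quadrature and represented as cubic splines; the spline is
the definition of the channel, so its derivative is the exact gradient of
what the forward pass computes.

Descriptors are L2-normalized.  The environment kernel is the dot product
raised to an integer power ``zeta``; the induced metric is
``d = sqrt(2 - 2 k)`` and structure dissimilarity is the symmetric
Hausdorff value of that metric over the two environment sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.interpolate import CubicSpline
from scipy.special import ive

from .structures import PeriodicStructure

__all__ = [
    "EnvironmentDescriptor",
    "SoapSpec",
    "compute_soap",
    "compute_soap_environments",
    "descriptor_matrix",
    "environment_kernel",
    "soap_gradients",
    "structure_dissimilarity",
    "structure_hash",
]


@dataclass(frozen=True)
class SoapSpec:
    """Hyperparameters of the SOAP descriptor.

    cutoff       radial cutoff (A)
    n_max        number of radial basis functions
    l_max        angular momentum limit
    sigma_atom   Gaussian smearing width of the neighbor density (A)
    species      ordered element list the descriptor resolves
    zeta         kernel exponent (integer >= 1)
    smooth_width width of the polynomial cutoff-smoothing region (A)
    """

    cutoff: float = 5.0
    n_max: int = 8
    l_max: int = 4
    sigma_atom: float = 0.5
    species: tuple[str, ...] = ()
    zeta: int = 4
    smooth_width: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.sigma_atom <= 0:
            raise ValueError("cutoff and sigma_atom must be positive")
        if self.n_max < 1 or self.l_max < 0:
            raise ValueError("n_max >= 1 and l_max >= 0 required")
        if int(self.zeta) != self.zeta or self.zeta < 1:
            raise ValueError("zeta must be an integer >= 1")
        if not (0 < self.smooth_width <= self.cutoff):
            raise ValueError("smooth_width must lie in (0, cutoff]")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "zeta", int(self.zeta))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_pairs(self) -> int:
        ns = self.n_species
        return ns * (ns + 1) // 2

    @property
    def dim(self) -> int:
        return self.n_pairs * self.n_max * self.n_max * (self.l_max + 1)

    def species_index(self, symbol: str) -> int:
        try:
            return self.species.index(symbol)
        except ValueError:
            raise ValueError(f"species {symbol!r} not covered by SoapSpec") from None


@dataclass
class EnvironmentDescriptor:
    """Normalized power-spectrum vector of one atomic environment."""

    vector: np.ndarray
    center_species: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()


# --------------------------------------------------------------------------
# radial channel tables

_RADIAL_CACHE: dict[tuple, tuple[CubicSpline, CubicSpline]] = {}


def _radial_splines(spec: SoapSpec) -> tuple[CubicSpline, CubicSpline]:
    key = (spec.cutoff, spec.n_max, spec.l_max, spec.sigma_atom)
    if key in _RADIAL_CACHE:
        return _RADIAL_CACHE[key]

    rc, nmax, lmax, sig = spec.cutoff, spec.n_max, spec.l_max, spec.sigma_atom
    centers = np.linspace(0.0, rc, nmax)
    width = rc / nmax

    # quadrature over the expansion radius r
    xq, wq = np.polynomial.legendre.leggauss(220)
    rmax = rc + 3.0 * max(sig, width)
    r = 0.5 * rmax * (xq + 1.0)
    w = 0.5 * rmax * wq
    gn = np.exp(-((r[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))  # (Q, n)

    rho = np.concatenate([[0.0], np.linspace(1e-4, rc, 500)])
    W = np.zeros((len(rho), nmax, lmax + 1))
    ls = np.arange(lmax + 1)
    for i, p in enumerate(rho):
        if p == 0.0:
            # only l = 0 survives: i_l(0) = delta_l0
            W[i, :, 0] = (w * r**2 * np.exp(-(r**2) / (2 * sig**2))) @ gn
            continue
        x = r * p / sig**2
        # exp-scaled modified spherical Bessel: i_l(x) e^{-x}
        sc = np.sqrt(np.pi / (2 * x))[:, None] * ive(ls[None, :] + 0.5, x[:, None])
        gauss = np.exp(-((r - p) ** 2) / (2 * sig**2))
        for l in ls:
            W[i, :, l] = (w * r**2 * gauss * sc[:, l]) @ gn

    spline = CubicSpline(rho, W, axis=0)
    pair = (spline, spline.derivative())
    _RADIAL_CACHE[key] = pair
    return pair


def _cutoff_fn(r: np.ndarray, rc: float, width: float):
    """C2 polynomial switch: 1 below rc-width, 0 at rc.  Returns (f, df)."""
    r = np.asarray(r, dtype=float)
    t = np.clip((r - (rc - width)) / width, 0.0, 1.0)
    f = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    df = -(30.0 * t**2 - 60.0 * t**3 + 30.0 * t**4) / width
    df = np.where((r > rc - width) & (r < rc), df, 0.0)
    return f, df


# --------------------------------------------------------------------------
# neighbor enumeration

def _neighbor_lists(structure: PeriodicStructure, rc: float):
    """Per atom: (atom indices, displacement vectors, distances) within rc."""
    pos = structure.positions
    n = structure.n_atoms
    if structure.periodic:
        heights = structure.cell_heights()
        reach = [
            int(np.ceil(rc / heights[d])) if structure.pbc[d] else 0 for d in range(3)
        ]
        shifts = np.array(
            list(itertools.product(*[range(-r, r + 1) for r in reach])), dtype=float
        )
        cart = shifts @ structure.cell
    else:
        shifts = np.zeros((1, 3))
        cart = np.zeros((1, 3))
    # images[s, j] = pos_j + cart_s
    images = pos[None, :, :] + cart[:, None, :]
    zero_shift = int(np.flatnonzero(~np.any(shifts, axis=1))[0])

    out = []
    for i in range(n):
        diff = images - pos[i]  # (S, N, 3)
        dist = np.linalg.norm(diff, axis=-1)
        mask = dist <= rc
        mask[zero_shift, i] = False
        mask &= dist > 1e-12
        s_idx, j_idx = np.nonzero(mask)
        out.append((j_idx.astype(int), diff[s_idx, j_idx], dist[s_idx, j_idx]))
    return out


# --------------------------------------------------------------------------
# descriptor assembly


class SoapEnvironments:
    """Descriptors for all atoms of one structure, with optional per-neighbor
    gradients for force/virial assembly.

    Attributes
    ----------
    vectors : (n_atoms, dim) normalized descriptors.
    center_species : list of element symbols.
    neighbors : per env, tuple (atom index array J, displacement vectors
        (J, 3), gradient tensor (J, dim, 3)) of the descriptor w.r.t. each
        neighbor displacement vector; ``None`` when gradients were not
        requested.  Displacement vectors point from the center to the
        neighbor image.
    """

    def __init__(self, spec: SoapSpec, vectors, center_species, neighbors):
        self.spec = spec
        self.vectors = vectors
        self.center_species = center_species
        self.neighbors = neighbors

    def descriptors(self) -> list[EnvironmentDescriptor]:
        return [
            EnvironmentDescriptor(v, s)
            for v, s in zip(self.vectors, self.center_species)
        ]


def compute_soap_environments(
    structure: PeriodicStructure, spec: SoapSpec, gradients: bool = False
) -> SoapEnvironments:
    """Compute descriptors (and optionally neighbor-resolved gradients)."""
    for s in structure.species:
        if s not in spec.species:
            raise ValueError(f"species {s!r} missing from SoapSpec.species")

    nmax, lmax, ns = spec.n_max, spec.l_max, spec.n_species
    pair_list = [(a, b) for a in range(ns) for b in range(a, ns)]
    pair_offset = {p: k * nmax * nmax * (lmax + 1) for k, p in enumerate(pair_list)}
    dim = spec.dim

    spline, dspline = _radial_splines(spec)
    leg_c = [np.eye(lmax + 1)[l] for l in range(lmax + 1)]
    dleg_c = [npleg.legder(c) if l > 0 else np.zeros(1) for l, c in enumerate(leg_c)]
    lnorm = (2.0 * np.arange(lmax + 1) + 1.0) / (4.0 * np.pi)

    nbr_lists = _neighbor_lists(structure, spec.cutoff)
    sp_idx_atoms = np.array([spec.species_index(s) for s in structure.species])

    vectors = np.zeros((structure.n_atoms, dim))
    per_env_nbrs = [] if gradients else None

    for i in range(structure.n_atoms):
        j_idx, R, rho = nbr_lists[i]
        J = len(j_idx)
        # entry 0 is the center's own density contribution (rho = 0)
        rho_all = np.concatenate([[0.0], rho])
        U = np.vstack([[0.0, 0.0, 1.0], R / rho[:, None] if J else np.zeros((0, 3))])
        sp_all = np.concatenate([[sp_idx_atoms[i]], sp_idx_atoms[j_idx]]).astype(int)

        fc, dfc = _cutoff_fn(rho_all, spec.cutoff, spec.smooth_width)
        Wv = spline(rho_all)  # (Jt, n, L+1)
        dWv = dspline(rho_all)
        A = Wv * fc[:, None, None]
        dA = dWv * fc[:, None, None] + Wv * dfc[:, None, None]

        cos = np.clip(U @ U.T, -1.0, 1.0)
        P = [lnorm[l] * npleg.legval(cos, leg_c[l]) for l in range(lmax + 1)]
        dP = [lnorm[l] * npleg.legval(cos, dleg_c[l]) for l in range(lmax + 1)]

        members = [np.flatnonzero(sp_all == s) for s in range(ns)]
        # q[l][s][a, n] = sum_{b in s} P_l[a, b] A[b, n, l]
        q = [
            [P[l][:, members[s]] @ A[members[s], :, l] for s in range(ns)]
            for l in range(lmax + 1)
        ]

        p = np.zeros(dim)
        for (s1, s2) in pair_list:
            base = pair_offset[(s1, s2)]
            for l in range(lmax + 1):
                block = A[members[s1], :, l].T @ q[l][s2][members[s1]]
                p[base + l * nmax * nmax : base + (l + 1) * nmax * nmax] = block.ravel()

        norm = np.linalg.norm(p)
        if norm == 0.0:  # pragma: no cover - self term is always positive
            norm = 1.0
        vectors[i] = p / norm

        if not gradients:
            continue

        # gradients: batched over the neighbors of each species and over l
        grad = np.zeros((J, dim, 3))
        nm = nmax * nmax
        L1 = lmax + 1
        inv_r = 1.0 / rho_all[1:]
        dP_all = np.stack(dP, axis=-1)           # (Jt, Jt, L)
        q_all = [np.stack([q[l][s] for l in range(L1)], axis=-1) for s in range(ns)]
        for sj in range(ns):
            jj_loc = np.flatnonzero(sp_all[1:] == sj)  # true-neighbor indices
            if len(jj_loc) == 0:
                continue
            a_idx = jj_loc + 1
            G = len(jj_loc)
            u_g = U[a_idx]                       # (G, 3)
            Aj = A[a_idx]                        # (G, n, L)
            dAj = dA[a_idx]
            for s2 in range(ns):
                idx2 = members[s2]
                cos_g = cos[a_idx][:, idx2]      # (G, B)
                # d cos(a,b) / dR_a, independent of l
                V = (U[idx2][None, :, :] - cos_g[:, :, None] * u_g[:, None, :]) \
                    * inv_r[jj_loc][:, None, None]
                w = dP_all[a_idx][:, idx2]       # (G, B, L)
                A2 = A[idx2]                     # (B, n, L)
                # t[g, m, x, l] = sum_b w A2 V
                t = np.einsum("gbl,bml,gbx->gmxl", w, A2, V)
                qa = q_all[s2][a_idx]            # (G, n, L)
                if s2 >= sj:  # role as first index of block (sj, s2)
                    base = pair_offset[(sj, s2)]
                    blk = (dAj[:, :, None, None, :] * qa[:, None, :, None, :]) * u_g[:, None, None, :, None]
                    blk += Aj[:, :, None, None, :] * t[:, None, :, :, :]
                    # (G, n, m, 3, L) -> (G, L*nm, 3), l-major block layout
                    add = blk.transpose(0, 4, 1, 2, 3).reshape(G, L1 * nm, 3)
                    grad[jj_loc, base : base + L1 * nm] += add
                if s2 <= sj:  # role as second index of block (s2, sj)
                    base = pair_offset[(s2, sj)]
                    blk = (qa[:, :, None, None, :] * dAj[:, None, :, None, :]) * u_g[:, None, None, :, None]
                    blk += t[:, :, None, :, :] * Aj[:, None, :, None, :]
                    add = blk.transpose(0, 4, 1, 2, 3).reshape(G, L1 * nm, 3)
                    grad[jj_loc, base : base + L1 * nm] += add

        # chain rule through L2 normalization
        d = vectors[i]
        proj = np.einsum("d,jdx->jx", d, grad)
        grad = (grad - d[None, :, None] * proj[:, None, :]) / norm
        per_env_nbrs.append((j_idx, R, grad))

    return SoapEnvironments(spec, vectors, list(structure.species), per_env_nbrs)


def compute_soap(structure: PeriodicStructure, spec: SoapSpec) -> list[EnvironmentDescriptor]:
    """One normalized descriptor per atom."""
    return compute_soap_environments(structure, spec).descriptors()


def soap_gradients(structure: PeriodicStructure, spec: SoapSpec) -> np.ndarray:
    """Derivatives of every descriptor component w.r.t. every atom position.

    Returns an array of shape (n_env, dim, n_atoms, 3).
    """
    envs = compute_soap_environments(structure, spec, gradients=True)
    n = structure.n_atoms
    out = np.zeros((n, spec.dim, n, 3))
    for i, (j_idx, _R, grad) in enumerate(envs.neighbors):
        for jj, j in enumerate(j_idx):
            out[i, :, j, :] += grad[jj]
            out[i, :, i, :] -= grad[jj]
    return out


# --------------------------------------------------------------------------
# kernels and dissimilarity


def descriptor_matrix(envs: Sequence[EnvironmentDescriptor]) -> np.ndarray:
    return np.vstack([e.vector for e in envs])


def environment_kernel(a: EnvironmentDescriptor, b: EnvironmentDescriptor, zeta: int) -> float:
    """SOAP similarity k = (a . b)^zeta for normalized descriptors."""
    va, vb = np.ravel(a.vector), np.ravel(b.vector)
    if va.shape != vb.shape:
        raise ValueError("descriptor lengths do not match")
    if int(zeta) != zeta or zeta < 1:
        raise ValueError("zeta must be an integer >= 1")
    return float(np.clip(va @ vb, -1.0, 1.0) ** int(zeta))


def _distance_matrix(A: np.ndarray, B: np.ndarray, zeta: int) -> np.ndarray:
    K = np.clip(A @ B.T, -1.0, 1.0) ** int(zeta)
    return np.sqrt(np.clip(2.0 - 2.0 * K, 0.0, None))


def structure_dissimilarity(A, B, zeta: int = 4) -> float:
    """Symmetric Hausdorff distance between two environment sets.

    With the kernel-induced environment metric ``d = sqrt(2 - 2 k)``, this is
    ``max(max_i min_j d_ij, max_j min_i d_ij)``; zero iff each environment of
    one set has an exact match in the other.
    """
    MA = A if isinstance(A, np.ndarray) else descriptor_matrix(A)
    MB = B if isinstance(B, np.ndarray) else descriptor_matrix(B)
    if MA.size == 0 or MB.size == 0:
        raise ValueError("environment sets must be non-empty")
    D = _distance_matrix(np.atleast_2d(MA), np.atleast_2d(MB), zeta)
    return float(max(D.min(axis=1).max(), D.min(axis=0).max()))


def structure_hash(structure: PeriodicStructure) -> str:
    """Stable content hash, usable as a descriptor-cache key."""
    import hashlib

    h = hashlib.sha256()
    h.update(",".join(structure.species).encode())
    h.update(np.round(structure.positions, 10).tobytes())
    h.update(np.round(structure.cell, 10).tobytes())
    h.update(bytes(structure.pbc))
    return h.hexdigest()
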