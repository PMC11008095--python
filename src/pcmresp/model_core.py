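"""Gaussian-multipole electrostatics engine.

Monopoles and dipoles are carried as spherical Gaussian densities of
per-atom width ``R_i`` (Å); a width of 0 degenerates to a point multipole.
Every pair interaction is attenuated by the damping kernels

    f_e(s) = erf(s) - (2 s / sqrt(pi)) exp(-s^2)
    f_t(s) = erf(s) - (2 s / sqrt(pi)) (1 + 2 s^2 / 3) exp(-s^2)

with reduced distance ``s = beta_ij * r_ij`` and pair Gaussian exponent
``beta_ij = 1 / sqrt(R_i^2 + R_j^2)``.  ``f_e`` governs charge potentials
and fields, ``f_t`` the anisotropic part of the dipole field tensor; both
approach 1 at large separation so all quantities reduce to the familiar
point-multipole expressions in the far field.

Sign convention (used consistently everywhere):

    T_ij = (f_e / r^3) I - (3 f_t / r^5) r r^T

and the electric field at site *i* produced by a dipole ``p`` at site *j*
is ``-T_ij @ p``.  The interaction energy of two dipoles is
``p_i^T T_ij p_j``.

Public functions accept Å / e / Å³ and return atomic units (Hartree/e for
potentials, Hartree/e/Bohr for fields, e·Bohr for induced dipoles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import erf

from .constants import ANGSTROM_TO_BOHR

__all__ = [
    "MoleculeModel",
    "SurfaceChargeSet",
    "EspGrid",
    "DampedKernels",
    "pair_exponent",
    "damping",
    "dipole_field_tensor",
    "build_A",
    "static_field",
    "field_matrices",
    "solve_induced",
    "model_esp",
    "esp_matrices",
    "surface_potential_matrix",
    "cbv_frame_matrix",
]

_SQRT_PI = np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MoleculeModel:
    """A molecule with per-atom electrostatic parameters.

    Parameters
    ----------
    atom_positions
        (n, 3) coordinates in Å.
    elements
        Length-n element symbols.
    bonds
        Covalent bonds as (i, j) index pairs; used to build the
        covalent-bond-vector (CBV) frame for permanent dipoles.
    total_charge
        Net molecular charge in e.
    charges
        Per-atom Gaussian monopoles q_i (e).  Defaults to zeros.
    polarizabilities
        Per-atom isotropic polarizabilities alpha_i (Å³), >= 0.  Atoms with
        alpha_i == 0 are excluded from the induced-dipole system.
    gauss_radii
        Per-atom Gaussian widths R_i (Å).  R_i == 0 means a point multipole
        (used by the fixed point-charge model).
    cbv_coefficients
        Per-atom list of permanent-dipole coefficients p^loc (e·Å), one per
        incident bond in the canonical slot order (bonded neighbors sorted
        by index).  Empty lists for models without permanent dipoles.
    equivalence_groups
        Partition (list of lists) of atom indices that must share a fitted
        charge; provided as input, never auto-detected.
    """

    atom_positions: np.ndarray
    elements: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    total_charge: float = 0.0
    charges: np.ndarray | None = None
    polarizabilities: np.ndarray | None = None
    gauss_radii: np.ndarray | None = None
    cbv_coefficients: list[list[float]] | None = None
    equivalence_groups: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        if self.atom_positions.ndim != 2 or self.atom_positions.shape[1] != 3:
            raise ValueError("atom_positions must have shape (n, 3)")
        n = self.n_atoms
        if n < 1:
            raise ValueError("a molecule needs at least one atom")
        if len(self.elements) != n:
            raise ValueError("elements length does not match atom count")
        seen: set[tuple[int, int]] = set()
        norm_bonds: list[tuple[int, int]] = []
        for b in self.bonds:
            i, j = int(b[0]), int(b[1])
            if i == j:
                raise ValueError(f"bond ({i},{j}) references one atom twice")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references an invalid atom index")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)
            norm_bonds.append(key)
        self.bonds = norm_bonds
        self.charges = self._per_atom(self.charges, 0.0, "charges")
        self.polarizabilities = self._per_atom(
            self.polarizabilities, 0.0, "polarizabilities"
        )
        if np.any(self.polarizabilities < 0):
            raise ValueError("polarizabilities must be >= 0")
        self.gauss_radii = self._per_atom(self.gauss_radii, 0.0, "gauss_radii")
        if np.any(self.gauss_radii < 0):
            raise ValueError("gauss_radii must be >= 0")
        if self.cbv_coefficients is None:
            self.cbv_coefficients = [[] for _ in range(n)]
        else:
            self.cbv_coefficients = [
                [float(c) for c in row] for row in self.cbv_coefficients
            ]
        if len(self.cbv_coefficients) != n:
            raise ValueError("cbv_coefficients must have one entry per atom")
        degrees = self.bond_degrees()
        for i, row in enumerate(self.cbv_coefficients):
            if row and len(row) != degrees[i]:
                raise ValueError(
                    f"atom {i}: {len(row)} CBV coefficients but {degrees[i]} bonds"
                )
        for grp in self.equivalence_groups:
            for i in grp:
                if not (0 <= int(i) < n):
                    raise ValueError(f"equivalence group index {i} out of range")

    # -- helpers -----------------------------------------------------------

    def _per_atom(self, arr, default, name) -> np.ndarray:
        if arr is None:
            return np.full(self.n_atoms, float(default))
        out = np.asarray(arr, dtype=float).copy()
        if out.shape != (self.n_atoms,):
            raise ValueError(f"{name} must be a length-{self.n_atoms} array")
        return out

    @property
    def n_atoms(self) -> int:
        return self.atom_positions.shape[0]

    def bond_degrees(self) -> list[int]:
        deg = [0] * self.n_atoms
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def bonded_neighbors(self, i: int) -> list[int]:
        """Bonded neighbors of atom i in canonical (sorted) slot order."""
        nb = [j for a, j in self.bonds if a == i] + [a for a, j in self.bonds if j == i]
        return sorted(nb)

    def cbv_slots(self) -> list[tuple[int, int]]:
        """Canonical (atom, neighbor) order of CBV coefficient slots."""
        slots = []
        for i in range(self.n_atoms):
            for j in self.bonded_neighbors(i):
                slots.append((i, j))
        return slots

    @property
    def n_cbv(self) -> int:
        return len(self.cbv_slots())

    def cbv_flat(self) -> np.ndarray:
        """Permanent-dipole coefficients flattened in canonical slot order (e·Å)."""
        out = []
        for i in range(self.n_atoms):
            row = self.cbv_coefficients[i]
            nb = self.bonded_neighbors(i)
            if row:
                out.extend(row)
            else:
                out.extend([0.0] * len(nb))
        return np.asarray(out, dtype=float)

    def set_cbv_flat(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_cbv,):
            raise ValueError("wrong number of CBV coefficients")
        k = 0
        rows: list[list[float]] = []
        for i in range(self.n_atoms):
            d = len(self.bonded_neighbors(i))
            rows.append([float(v) for v in values[k : k + d]])
            k += d
        self.cbv_coefficients = rows

    def polarizable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.polarizabilities > 0)

    def permanent_dipoles(self) -> np.ndarray:
        """Global Cartesian permanent dipoles, (n, 3) in e·Å."""
        F = cbv_frame_matrix(self)
        return (F @ self.cbv_flat()).reshape(self.n_atoms, 3)

    def copy(self) -> "MoleculeModel":
        return MoleculeModel(
            atom_positions=self.atom_positions.copy(),
            elements=list(self.elements),
            bonds=list(self.bonds),
            total_charge=self.total_charge,
            charges=self.charges.copy(),
            polarizabilities=self.polarizabilities.copy(),
            gauss_radii=self.gauss_radii.copy(),
            cbv_coefficients=[list(r) for r in self.cbv_coefficients],
            equivalence_groups=[list(g) for g in self.equivalence_groups],
        )


@dataclass
class SurfaceChargeSet:
    """Continuum-solvent surface charges, static during fitting.

    ``radii`` are per-point Gaussian widths (Å); 0 means a point charge.
    ``weights`` (surface areas or quadrature weights) are carried as
    metadata and never enter the electrostatics.
    """

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        m = self.positions.shape[0]
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if self.charges.shape != (m,):
            raise ValueError("surface charges length mismatch")
        self.radii = (
            np.zeros(m) if self.radii is None else np.asarray(self.radii, dtype=float)
        )
        self.weights = (
            np.ones(m) if self.weights is None else np.asarray(self.weights, dtype=float)
        )
        if self.radii.shape != (m,) or self.weights.shape != (m,):
            raise ValueError("surface radii/weights length mismatch")
        if np.any(self.radii < 0):
            raise ValueError("surface radii must be >= 0")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "SurfaceChargeSet":
        """Gas phase: no surface points."""
        return cls(np.zeros((0, 3)), np.zeros(0))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class EspGrid:
    """ESP sample points with quantum-mechanical reference potentials (a.u.)."""

    points: np.ndarray
    qm_potentials: np.ndarray | None = None
    point_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        g = self.points.shape[0]
        if self.qm_potentials is None:
            self.qm_potentials = np.zeros(g)
        else:
            self.qm_potentials = np.asarray(self.qm_potentials, dtype=float).reshape(-1)
        if self.qm_potentials.shape != (g,):
            raise ValueError("qm_potentials length mismatch")
        if self.point_weights is None:
            self.point_weights = np.ones(g)
        else:
            self.point_weights = np.asarray(self.point_weights, dtype=float).reshape(-1)
        if self.point_weights.shape != (g,):
            raise ValueError("point_weights length mismatch")
        if np.any(self.point_weights <= 0):
            raise ValueError("point_weights must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def check_against_atoms(self, atom_positions: np.ndarray, tol: float = 1e-6) -> None:
        """Reject grid points coinciding with atom centers (QM reference diverges)."""
        atom_positions = np.asarray(atom_positions, dtype=float)
        if self.n_points == 0 or atom_positions.size == 0:
            return
        d = np.linalg.norm(
            self.points[:, None, :] - atom_positions[None, :, :], axis=-1
        )
        if np.min(d) < tol:
            j, i = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"grid point {j} coincides with atom {i} (distance {d[j, i]:.2e} Å)"
            )


@dataclass(frozen=True)
class DampedKernels:
    """Charge (f_e) and dipole-tensor (f_t) damping factors at reduced distance s."""

    f_e: float
    f_t: float
    s: float


# ---------------------------------------------------------------------------
# scalar kernels
# ---------------------------------------------------------------------------


def pair_exponent(R_i: float, R_j: float) -> float:
    """Gaussian exponent of an interacting pair, beta_ij = 1/sqrt(R_i^2 + R_j^2).

    Use ``R_j = 0`` for a point probe (e.g. an ESP grid point).  Units are the
    inverse of whatever the radii are given in.
    """
    if R_i < 0 or R_j < 0:
        raise ValueError("Gaussian radii must be >= 0")
    if R_i == 0 and R_j == 0:
        raise ValueError("pointlike pair has no Gaussian exponent")
    return 1.0 / float(np.hypot(R_i, R_j))


def _fe_ft(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized damping kernels; s may contain inf (point pair -> 1)."""
    s = np.asarray(s, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        g = (2.0 * s / _SQRT_PI) * np.exp(-(s**2))
        fe = erf(s) - g
        ft = erf(s) - g * (1.0 + 2.0 * s**2 / 3.0)
    fe = np.where(np.isfinite(s), fe, 1.0)
    ft = np.where(np.isfinite(s), ft, 1.0)
    return fe, ft


def damping(r: float, beta: float) -> DampedKernels:
    """Damping kernels at separation ``r`` for pair exponent ``beta``.

    These are the unique kernels for which the Gaussian-charge potential
    ``q erf(beta r)/r`` has a consistent field (``q f_e / r^2``) and
    field gradient (dipole tensor with ``f_t``).
    """
    if r < 0:
        raise ValueError("distance must be >= 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    s = beta * r
    fe, ft = _fe_ft(np.asarray(s))
    return DampedKernels(f_e=float(fe), f_t=float(ft), s=float(s))


def dipole_field_tensor(
    r_i: np.ndarray, r_j: np.ndarray, R_i: float, R_j: float
) -> np.ndarray:
    """Damped dipole field tensor T_ij between sites i and j (a.u.).

    Positions in Å, radii in Å; the returned 3x3 tensor is in Bohr^-3.
    Field at i from a dipole p at j is ``-T_ij @ p``; interaction energy of
    two dipoles is ``p_i^T T_ij p_j``.  Symmetric in (i, j).
    """
    r_i = np.asarray(r_i, dtype=float) * ANGSTROM_TO_BOHR
    r_j = np.asarray(r_j, dtype=float) * ANGSTROM_TO_BOHR
    rv = r_i - r_j
    r = np.linalg.norm(rv)
    if r == 0.0:
        raise ValueError("dipole field tensor undefined for coincident points")
    if R_i == 0 and R_j == 0:
        beta = np.inf
    else:
        beta = pair_exponent(R_i * ANGSTROM_TO_BOHR, R_j * ANGSTROM_TO_BOHR)
    fe, ft = _fe_ft(np.asarray(beta * r))
    return (fe / r**3) * np.eye(3) - (3.0 * ft / r**5) * np.outer(rv, rv)


# ---------------------------------------------------------------------------
# vectorized blocks (internal; positions already in Bohr)
# ---------------------------------------------------------------------------


def _pair_geometry(src_b: np.ndarray, dst_b: np.ndarray):
    rv = dst_b[None, :, :] - src_b[:, None, :]  # (nsrc, ndst, 3), src -> dst
    r = np.linalg.norm(rv, axis=-1)  # (nsrc, ndst)
    return rv, r


def _beta_matrix(src_R_b: np.ndarray, dst_R_b: np.ndarray) -> np.ndarray:
    R2 = src_R_b[:, None] ** 2 + dst_R_b[None, :] ** 2
    with np.errstate(divide="ignore"):
        return np.where(R2 > 0, 1.0 / np.sqrt(np.where(R2 > 0, R2, 1.0)), np.inf)


def _charge_potential_block(src_b, src_R_b, dst_b) -> np.ndarray:
    """(ndst, nsrc) potential per unit source charge, at point probes."""
    rv, r = _pair_geometry(src_b, dst_b)
    beta = _beta_matrix(src_R_b, np.zeros(dst_b.shape[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = beta * r
        v = erf(np.where(np.isfinite(s), s, 1.0)) / r
        v = np.where(np.isfinite(s), v, 1.0 / r)
    # finite r -> 0 limit of erf(beta r)/r is 2 beta / sqrt(pi)
    at_center = r == 0
    if np.any(at_center):
        v = np.where(at_center, 2.0 * beta / _SQRT_PI, v)
    return v.T


def _dipole_potential_block(src_b, src_R_b, dst_b) -> np.ndarray:
    """(ndst, 3*nsrc) map from source dipoles (e·Bohr) to potentials (a.u.)."""
    nsrc, ndst = src_b.shape[0], dst_b.shape[0]
    rv, r = _pair_geometry(src_b, dst_b)
    beta = _beta_matrix(src_R_b, np.zeros(ndst))
    s = beta * r
    fe, _ = _fe_ft(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(r > 0, fe / np.where(r > 0, r, 1.0) ** 3, 0.0)
    blk = coef[:, :, None] * rv  # (nsrc, ndst, 3), potential = blk . p
    return blk.transpose(1, 0, 2).reshape(ndst, 3 * nsrc)


def _charge_field_block(src_b, src_R_b, dst_b, dst_R_b, *, exclude_diagonal=False):
    """(3*ndst, nsrc) field at dst sites per unit source charge (a.u.)."""
    nsrc, ndst = src_b.shape[0], dst_b.shape[0]
    rv, r = _pair_geometry(src_b, dst_b)
    beta = _beta_matrix(src_R_b, dst_R_b)
    fe, _ = _fe_ft(beta * r)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(r > 0, fe / np.where(r > 0, r, 1.0) ** 3, 0.0)
    if exclude_diagonal and nsrc == ndst:
        coef = coef * (1.0 - np.eye(nsrc))
    blk = coef[:, :, None] * rv  # (nsrc, ndst, 3)
    return blk.transpose(1, 2, 0).reshape(3 * ndst, nsrc)


def _dipole_tensor_blocks(src_b, src_R_b, dst_b, dst_R_b, *, exclude_diagonal=False):
    """(ndst, nsrc, 3, 3) array of T blocks (zero on excluded diagonal)."""
    nsrc, ndst = src_b.shape[0], dst_b.shape[0]
    rv, r = _pair_geometry(src_b, dst_b)
    beta = _beta_matrix(src_R_b, dst_R_b)
    fe, ft = _fe_ft(beta * r)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv3 = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0) ** 3, 0.0)
        inv5 = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0) ** 5, 0.0)
    eye = np.eye(3)
    T = (fe * inv3)[:, :, None, None] * eye[None, None, :, :] - (
        3.0 * ft * inv5
    )[:, :, None, None] * (rv[:, :, :, None] * rv[:, :, None, :])
    if exclude_diagonal and nsrc == ndst:
        idx = np.arange(nsrc)
        T[idx, idx] = 0.0
    return T.transpose(1, 0, 2, 3)  # (ndst, nsrc, 3, 3)


def _apply_mask(mat_blocks: np.ndarray, mask, src_idx, dst_idx) -> None:
    """Zero (i, j) pairs listed in mask; mask entries are atom index pairs."""
    if not mask:
        return
    pos_s = {a: k for k, a in enumerate(src_idx)}
    pos_d = {a: k for k, a in enumerate(dst_idx)}
    for i, j in mask:
        for a, b in ((i, j), (j, i)):
            if a in pos_d and b in pos_s:
                mat_blocks[pos_d[a], pos_s[b]] = 0.0


# ---------------------------------------------------------------------------
# public assembly
# ---------------------------------------------------------------------------


def build_A(molecule: MoleculeModel, mask=None) -> np.ndarray:
    """Polarization matrix of the induced-dipole system (a.u.).

    Returns the symmetric 3p x 3p matrix over the p atoms with alpha > 0:
    diagonal blocks (1/alpha_i) I, off-diagonal blocks T_ij.  ``mask`` is an
    optional iterable of atom-index pairs whose mutual blocks are zeroed
    (no masking by default: the model keeps all pairs, including bonded ones).
    """
    idx = molecule.polarizable_indices()
    p = idx.size
    if p == 0:
        return np.zeros((0, 0))
    alpha = molecule.polarizabilities[idx] * ANGSTROM_TO_BOHR**3
    if np.any(alpha <= 0):
        raise ValueError("polarizability must be > 0 for atoms in the induced system")
    pos_b = molecule.atom_positions[idx] * ANGSTROM_TO_BOHR
    R_b = molecule.gauss_radii[idx] * ANGSTROM_TO_BOHR
    T = _dipole_tensor_blocks(pos_b, R_b, pos_b, R_b, exclude_diagonal=True)
    _apply_mask(T, mask, idx, idx)
    A = T.transpose(0, 2, 1, 3).reshape(3 * p, 3 * p).copy()
    diag = np.repeat(1.0 / alpha, 3)
    A[np.arange(3 * p), np.arange(3 * p)] = diag
    ev_min = sla.eigvalsh(A, subset_by_index=[0, 0])[0] if p > 0 else 1.0
    if ev_min <= 0:
        warnings.warn(
            f"induced-dipole matrix is not positive definite "
            f"(smallest eigenvalue {ev_min:.3e}); geometry/polarizabilities "
            "are outside the physically stable regime",
            RuntimeWarning,
            stacklevel=2,
        )
    return A


def field_matrices(
    molecule: MoleculeModel, surface: SurfaceChargeSet, mask=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component matrices of the static field at polarizable sites.

    Returns ``(C, D, C_s)`` with the static field ``E = C q + D p + C_s q_s``:
    C maps atomic charges (e), D maps global permanent dipoles (e·Bohr,
    flattened 3n) and C_s maps surface charges (e) to fields (a.u.) at the
    3p polarizable-atom components.  D excludes each atom's own dipole.
    """
    idx = molecule.polarizable_indices()
    n = molecule.n_atoms
    pos_b = molecule.atom_positions * ANGSTROM_TO_BOHR
    R_b = molecule.gauss_radii * ANGSTROM_TO_BOHR
    dst_b, dst_R = pos_b[idx], R_b[idx]
    p = idx.size

    # charge field: exclude self (field of a Gaussian at its own center is 0)
    rv, r = _pair_geometry(pos_b, dst_b)
    beta = _beta_matrix(R_b, dst_R)
    fe, _ = _fe_ft(beta * r)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(r > 0, fe / np.where(r > 0, r, 1.0) ** 3, 0.0)
    if mask:
        pos_s = {a: k for k, a in enumerate(range(n))}
        pos_d = {a: k for k, a in enumerate(idx)}
        for i, j in mask:
            for a, b in ((i, j), (j, i)):
                if a in pos_d and b in pos_s:
                    coef[pos_s[b], pos_d[a]] = 0.0
    C = (coef[:, :, None] * rv).transpose(1, 2, 0).reshape(3 * p, n)

    T = _dipole_tensor_blocks(pos_b, R_b, dst_b, dst_R)
    # zero each polarizable atom's coupling to its own permanent dipole
    for k, a in enumerate(idx):
        T[k, a] = 0.0
    _apply_mask(T, mask, np.arange(n), idx)
    D = -T.transpose(0, 2, 1, 3).reshape(3 * p, 3 * n)

    if surface.n_points:
        Cs = _charge_field_block(
            surface.positions * ANGSTROM_TO_BOHR,
            surface.radii * ANGSTROM_TO_BOHR,
            dst_b,
            dst_R,
        )
    else:
        Cs = np.zeros((3 * p, 0))
    return C, D, Cs


def static_field(molecule: MoleculeModel, surface: SurfaceChargeSet) -> np.ndarray:
    """Static field E = C q + D p + C_s q_s at polarizable sites (a.u., 3p)."""
    C, D, Cs = field_matrices(molecule, surface)
    p_global = molecule.permanent_dipoles().ravel() * ANGSTROM_TO_BOHR
    E = C @ molecule.charges + D @ p_global
    if surface.n_points:
        E = E + Cs @ surface.charges
    return E


def solve_induced(A: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Solve A mu = E for the induced dipoles (e·Bohr) by dense Cholesky."""
    A = np.asarray(A, dtype=float)
    E = np.asarray(E, dtype=float).ravel()
    if A.shape[0] == 0:
        return np.zeros(0)
    try:
        c, low = sla.cho_factor(A, check_finite=False)
    except sla.LinAlgError as exc:
        ev = sla.eigvalsh(A)
        raise np.linalg.LinAlgError(
            "induced-dipole matrix is singular or indefinite "
            f"(smallest eigenvalue {ev[0]:.6e})"
        ) from exc
    mu = sla.cho_solve((c, low), E, check_finite=False)
    resid = np.max(np.abs(A @ mu - E)) if E.size else 0.0
    scale = max(1.0, np.max(np.abs(E)) if E.size else 0.0)
    if resid >= 1e-10 * scale:
        raise np.linalg.LinAlgError(
            f"induced-dipole solve residual {resid:.3e} exceeds tolerance"
        )
    return mu


def esp_matrices(
    molecule: MoleculeModel, grid: EspGrid, *, point_charges: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Charge (X: G x n) and dipole (Y: G x 3n) ESP maps at grid points (a.u.).

    ``point_charges=True`` ignores the Gaussian widths for the monopole
    matrix (the fixed point-charge model); the dipole matrix always uses
    the molecular widths.
    """
    pos_b = molecule.atom_positions * ANGSTROM_TO_BOHR
    R_b = molecule.gauss_radii * ANGSTROM_TO_BOHR
    grid_b = grid.points * ANGSTROM_TO_BOHR
    Rq = np.zeros_like(R_b) if point_charges else R_b
    X = _charge_potential_block(pos_b, Rq, grid_b)
    Y = _dipole_potential_block(pos_b, R_b, grid_b)
    return X, Y


def surface_potential_matrix(surface: SurfaceChargeSet, grid: EspGrid) -> np.ndarray:
    """(G, m) direct Coulomb/Gaussian potential of surface charges at grid points."""
    if surface.n_points == 0:
        return np.zeros((grid.n_points, 0))
    return _charge_potential_block(
        surface.positions * ANGSTROM_TO_BOHR,
        surface.radii * ANGSTROM_TO_BOHR,
        grid.points * ANGSTROM_TO_BOHR,
    )


def model_esp(
    molecule: MoleculeModel,
    mu: np.ndarray,
    surface: SurfaceChargeSet,
    grid: EspGrid,
    include_direct_surface: bool = True,
    *,
    point_charges: bool = False,
) -> np.ndarray:
    """Model electrostatic potential (a.u.) at the grid points.

    ``mu`` are the induced dipoles over the polarizable atoms (3p, e·Bohr)
    as returned by :func:`solve_induced`; pass an empty array when no atom
    is polarizable.  Finite everywhere, including atom centers, where the
    monopole term approaches ``2 q beta / sqrt(pi)``.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    idx = molecule.polarizable_indices()
    if mu.size != 3 * idx.size:
        raise ValueError(
            f"mu has {mu.size} components, expected {3 * idx.size} "
            "(3 per polarizable atom)"
        )
    X, Y = esp_matrices(molecule, grid, point_charges=point_charges)
    dip = molecule.permanent_dipoles().ravel() * ANGSTROM_TO_BOHR
    if idx.size:
        full_mu = np.zeros(3 * molecule.n_atoms)
        for k, a in enumerate(idx):
            full_mu[3 * a : 3 * a + 3] = mu[3 * k : 3 * k + 3]
        dip = dip + full_mu
    V = X @ molecule.charges + Y @ dip
    if include_direct_surface and surface.n_points:
        V = V + surface_potential_matrix(surface, grid) @ surface.charges
    return V


def cbv_frame_matrix(molecule: MoleculeModel) -> np.ndarray:
    """Frame matrix F (3n x B) mapping CBV coefficients to Cartesian dipoles.

    Column (i, k) holds the unit vector from atom i toward its k-th bonded
    neighbor (neighbors in canonical sorted order), placed in rows 3i..3i+2.
    ``p_global = F @ p_loc`` with p_loc in the units of the coefficients.
    """
    slots = molecule.cbv_slots()
    F = np.zeros((3 * molecule.n_atoms, len(slots)))
    for col, (i, j) in enumerate(slots):
        v = molecule.atom_positions[j] - molecule.atom_positions[i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError(f"zero-length bond between atoms {i} and {j}")
        F[3 * i : 3 * i + 3, col] = v / norm
    return F
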