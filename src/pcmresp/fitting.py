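"""Constrained, restrained least-squares fitting of electrostatic parameters.

Three model kinds are supported:

``resp``
    fixed point charges, no polarization (Gaussian widths ignored for the
    monopole kernel),
``pgm-ind``
    Gaussian monopoles plus induced dipoles,
``pgm-perm``
    Gaussian monopoles, induced dipoles, and permanent dipoles expressed as
    covalent-bond-vector (CBV) coefficients.

The objective is a weighted sum of squared ESP residuals over one or more
datasets (media and/or conformations), plus an optional hyperbolic
restraint ``a * sum(sqrt(q^2 + b^2) - b)`` on selected charges, minimized
subject to linear equality constraints (total charge, user charge sums)
via Lagrange multipliers.  Chemical equivalence is imposed by parameter
reduction, not by penalty, so equivalenced parameters are bitwise equal in
the result.

Continuum-surface charges enter in two ways: they polarize the solute
(through the induced-dipole system, a constant ESP offset during the fit)
and they contribute a direct potential at the grid points.  By default the
direct term is subtracted from the QM target; it can instead be added to
the model offset — the two choices give identical residuals.  Reported
RMSE/RRMSE always compare the full model (including the direct surface
potential) against the unmodified QM potentials.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla

from .constants import ANGSTROM_TO_BOHR
from .evaluation import rmse_rrmse
from .model_core import (
    EspGrid,
    MoleculeModel,
    SurfaceChargeSet,
    build_A,
    cbv_frame_matrix,
    esp_matrices,
    field_matrices,
    model_esp,
    solve_induced,
    surface_potential_matrix,
)

__all__ = [
    "EspDataset",
    "RestraintSpec",
    "FitConfiguration",
    "FitResult",
    "MODEL_KINDS",
    "build_design",
    "fit",
    "two_stage_fit",
    "dual_solvent_fit",
    "predict_esp",
]

MODEL_KINDS = ("resp", "pgm-ind", "pgm-perm")


@dataclass
class EspDataset:
    """One medium's ESP data: grid + QM potentials + surface charges."""

    grid: EspGrid
    surface: SurfaceChargeSet
    medium: str = "GAS"
    epsilon: float = 1.0
    atom_positions: np.ndarray | None = None  # Å; conformation consistency checks
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.atom_positions is not None:
            self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        if self.epsilon < 1.0:
            raise ValueError("dielectric constant must be >= 1")


@dataclass
class RestraintSpec:
    """Hyperbolic restraint a * sum(sqrt(q^2 + b^2) - b) toward zero charge.

    Defaults follow the two-stage RESP convention: strength 0.0005 a.u. in
    stage 1, 0.001 a.u. in stage 2, tightness b = 0.1 e, hydrogens
    unrestrained.
    """

    strength: float = 0.0005
    tightness: float = 0.1
    apply_to: str = "non-hydrogen"  # or "all"

    def __post_init__(self) -> None:
        if self.strength < 0 or self.tightness <= 0:
            raise ValueError("restraint strength must be >= 0 and tightness > 0")
        if self.apply_to not in ("non-hydrogen", "all"):
            raise ValueError("apply_to must be 'non-hydrogen' or 'all'")


@dataclass
class FitConfiguration:
    """Everything that defines one fit.

    ``equivalence_groups`` are groups of *parameter* indices (charges are
    parameters 0..n-1, CBV slots follow in canonical order); ``None`` means
    "use the molecule's own atom equivalence groups for charges".
    ``frozen_parameters`` maps parameter index -> fixed value.
    ``charge_constraints`` are (atom index list, required total) pairs in
    addition to the overall total-charge constraint.
    """

    model_kind: str = "resp"
    restraint: RestraintSpec | None = None
    stage: int = 1
    frozen_parameters: dict[int, float] = field(default_factory=dict)
    equivalence_groups: list[list[int]] | None = None
    charge_constraints: list[tuple[list[int], float]] = field(default_factory=list)
    constrain_total_charge: bool = True
    dataset_weights: list[float] | None = None
    max_restraint_iterations: int = 50
    restraint_tolerance: float = 1e-8
    subtract_direct_surface: bool = True
    restrain_dipoles: bool = False

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")

    def config_hash(self) -> str:
        payload = {
            "model_kind": self.model_kind,
            "stage": self.stage,
            "restraint": None
            if self.restraint is None
            else [self.restraint.strength, self.restraint.tightness, self.restraint.apply_to],
            "frozen": sorted((int(k), float(v)) for k, v in self.frozen_parameters.items()),
            "equiv": self.equivalence_groups,
            "constraints": [[list(map(int, a)), float(t)] for a, t in self.charge_constraints],
            "total": self.constrain_total_charge,
            "weights": self.dataset_weights,
            "subtract_surface": self.subtract_direct_surface,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class FitResult:
    """Fitted parameters plus per-dataset quality and solver diagnostics."""

    molecules: list[MoleculeModel]
    model_kind: str
    rmse: list[float]
    rrmse: list[float]
    restraint_iterations: int
    condition: float
    provenance: dict
    stage: int = 1

    @property
    def molecule(self) -> MoleculeModel:
        if len(self.molecules) != 1:
            raise ValueError("FitResult holds multiple molecules")
        return self.molecules[0]

    def parameter_vector(self, molecule_index: int = 0) -> np.ndarray:
        mol = self.molecules[molecule_index]
        if self.model_kind == "pgm-perm":
            return np.concatenate([mol.charges, mol.cbv_flat()])
        return mol.charges.copy()


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def n_parameters(molecule: MoleculeModel, model_kind: str) -> int:
    n = molecule.n_atoms
    return n + molecule.n_cbv if model_kind == "pgm-perm" else n


def _polarized(molecule: MoleculeModel, model_kind: str) -> bool:
    return model_kind != "resp" and molecule.polarizable_indices().size > 0


def _dataset_design(
    molecule: MoleculeModel,
    ds: EspDataset,
    model_kind: str,
    include_direct_surface: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted design matrix (G x P) and constant offset (G) for one dataset."""
    ds.grid.check_against_atoms(molecule.atom_positions)
    if ds.epsilon > 1.0 and ds.surface.n_points == 0:
        raise ValueError(
            f"dataset {ds.medium!r} declares epsilon={ds.epsilon} but has no "
            "surface charges"
        )
    G = ds.grid.n_points
    X, Y = esp_matrices(molecule, ds.grid, point_charges=(model_kind == "resp"))
    offset = np.zeros(G)
    if _polarized(molecule, model_kind):
        idx = molecule.polarizable_indices()
        cols = np.concatenate([np.arange(3 * a, 3 * a + 3) for a in idx])
        YP = Y[:, cols]
        A = build_A(molecule)
        cho = sla.cho_factor(A, check_finite=False)
        C, D, Cs = field_matrices(molecule, ds.surface)
        B_q = X + YP @ sla.cho_solve(cho, C, check_finite=False)
        if ds.surface.n_points:
            offset = offset + YP @ sla.cho_solve(
                cho, Cs @ ds.surface.charges, check_finite=False
            )
        if model_kind == "pgm-perm":
            F = cbv_frame_matrix(molecule)
            B_p = (Y + YP @ sla.cho_solve(cho, D, check_finite=False)) @ F
    else:
        B_q = X
        if model_kind == "pgm-perm":
            B_p = Y @ cbv_frame_matrix(molecule)
    if model_kind == "pgm-perm":
        # CBV coefficients are carried in e·Å; the dipole kernels expect e·Bohr
        B = np.hstack([B_q, B_p * ANGSTROM_TO_BOHR])
    else:
        B = B_q
    if include_direct_surface and ds.surface.n_points:
        offset = offset + surface_potential_matrix(ds.surface, ds.grid) @ ds.surface.charges
    return B, offset


def build_design(
    molecule: MoleculeModel,
    datasets: list[EspDataset],
    model_kind: str = "pgm-ind",
    dataset_weights: list[float] | None = None,
    include_direct_surface: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked linear map from free parameters to model ESP over datasets.

    Rows are scaled by sqrt(point_weight * dataset_weight); the returned
    offset (the surface-induced polarization term, plus the direct surface
    potential if requested) is scaled identically, so that
    ``B @ theta + offset`` lives in the same scaled space as
    ``sqrt(w) * V_qm``.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if dataset_weights is None:
        dataset_weights = [1.0] * len(datasets)
    if len(dataset_weights) != len(datasets):
        raise ValueError("dataset_weights length mismatch")
    if any(w < 0 for w in dataset_weights):
        raise ValueError("dataset weights must be >= 0")
    blocks, offsets = [], []
    for ds, w in zip(datasets, dataset_weights):
        B, off = _dataset_design(molecule, ds, model_kind, include_direct_surface)
        sw = np.sqrt(ds.grid.point_weights * w)
        blocks.append(B * sw[:, None])
        offsets.append(off * sw)
    return np.vstack(blocks), np.concatenate(offsets)


# ---------------------------------------------------------------------------
# forward prediction (shared by fit reporting and transfer evaluation)
# ---------------------------------------------------------------------------


def predict_esp(
    molecule: MoleculeModel, dataset: EspDataset, model_kind: str
) -> np.ndarray:
    """Full model ESP (a.u.) of a parametrized molecule in a dataset's medium.

    Induced dipoles are re-solved against the dataset's own surface charges,
    so the polarization responds to the medium; the direct surface potential
    is always included.
    """
    if _polarized(molecule, model_kind):
        A = build_A(molecule)
        E = static_field_for(molecule, dataset.surface)
        mu = solve_induced(A, E)
    else:
        mu = np.zeros(3 * molecule.polarizable_indices().size)
    return model_esp(
        molecule,
        mu,
        dataset.surface,
        dataset.grid,
        include_direct_surface=True,
        point_charges=(model_kind == "resp"),
    )


def static_field_for(molecule: MoleculeModel, surface: SurfaceChargeSet) -> np.ndarray:
    from .model_core import static_field

    return static_field(molecule, surface)


def _dataset_errors(
    molecule: MoleculeModel, datasets: list[EspDataset], model_kind: str
) -> tuple[list[float], list[float]]:
    rmses, rrmses = [], []
    for ds in datasets:
        V = predict_esp(molecule, ds, model_kind)
        r, rr = rmse_rrmse(V, ds.grid.qm_potentials, ds.grid.point_weights)
        rmses.append(r)
        rrmses.append(rr)
    return rmses, rrmses


# ---------------------------------------------------------------------------
# the constrained, restrained solve
# ---------------------------------------------------------------------------


def _reduction(
    P: int,
    equivalence_groups: list[list[int]],
    frozen: dict[int, float],
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Equivalence/freezing bookkeeping.

    Returns (M, theta_frozen_full, columns) where M is the P x K indicator
    matrix mapping reduced parameters to full ones, theta_frozen_full holds
    frozen values (zeros elsewhere), and columns lists the full indices
    backing each reduced column.
    """
    owner = {}
    for g, grp in enumerate(equivalence_groups):
        for i in grp:
            i = int(i)
            if not (0 <= i < P):
                raise ValueError(f"equivalence index {i} out of range")
            if i in owner:
                raise ValueError(f"parameter {i} appears in two equivalence groups")
            owner[i] = g
    for i in frozen:
        if not (0 <= int(i) < P):
            raise ValueError(f"frozen parameter index {i} out of range")
    frozen_set = set(int(i) for i in frozen)
    for g, grp in enumerate(equivalence_groups):
        members = set(int(i) for i in grp)
        hit = members & frozen_set
        if hit and members - frozen_set:
            raise ValueError(
                f"equivalence group {g} mixes frozen and free parameters {sorted(hit)}"
            )
    columns: list[list[int]] = []
    seen_groups: set[int] = set()
    for i in range(P):
        if i in frozen_set:
            continue
        g = owner.get(i)
        if g is None:
            columns.append([i])
        elif g not in seen_groups:
            seen_groups.add(g)
            columns.append(sorted(int(j) for j in equivalence_groups[g] if int(j) not in frozen_set))
    M = np.zeros((P, len(columns)))
    for k, col in enumerate(columns):
        for i in col:
            M[i, k] = 1.0
    theta_frozen = np.zeros(P)
    for i, v in frozen.items():
        theta_frozen[int(i)] = float(v)
    return M, theta_frozen, columns


def _constraint_rows(
    molecule: MoleculeModel, config: FitConfiguration, P: int
) -> tuple[np.ndarray, np.ndarray]:
    rows, rhs = [], []
    n = molecule.n_atoms
    if config.constrain_total_charge:
        row = np.zeros(P)
        row[:n] = 1.0
        rows.append(row)
        rhs.append(float(molecule.total_charge))
    for atoms, total in config.charge_constraints:
        row = np.zeros(P)
        for a in atoms:
            a = int(a)
            if not (0 <= a < n):
                raise ValueError(f"charge constraint references invalid atom {a}")
            row[a] += 1.0
        rows.append(row)
        rhs.append(float(total))
    if not rows:
        return np.zeros((0, P)), np.zeros(0)
    return np.vstack(rows), np.asarray(rhs)


def _restrained_parameters(
    molecule: MoleculeModel, config: FitConfiguration, P: int
) -> np.ndarray:
    if config.restraint is None or config.restraint.strength == 0.0:
        return np.zeros(0, dtype=int)
    n = molecule.n_atoms
    if config.restraint.apply_to == "all":
        idx = list(range(n))
    else:
        idx = [i for i in range(n) if molecule.elements[i] != "H"]
    if config.restrain_dipoles and P > n:
        idx += list(range(n, P))
    return np.asarray([i for i in idx if i not in config.frozen_parameters], dtype=int)


def _fit_single(
    molecule: MoleculeModel, datasets: list[EspDataset], config: FitConfiguration
) -> tuple[MoleculeModel, int, float]:
    P = n_parameters(molecule, config.model_kind)
    n = molecule.n_atoms
    B, offset = build_design(
        molecule,
        datasets,
        config.model_kind,
        config.dataset_weights,
        include_direct_surface=not config.subtract_direct_surface,
    )
    weights = config.dataset_weights or [1.0] * len(datasets)
    targets = []
    for ds, w in zip(datasets, weights):
        t = ds.grid.qm_potentials.copy()
        if config.subtract_direct_surface and ds.surface.n_points:
            t = t - surface_potential_matrix(ds.surface, ds.grid) @ ds.surface.charges
        targets.append(t * np.sqrt(ds.grid.point_weights * w))
    v = np.concatenate(targets)
    n_free_check = P - len(config.frozen_parameters)
    if B.shape[0] < n_free_check and config.restraint is None:
        import warnings

        warnings.warn(
            f"{B.shape[0]} ESP points for {n_free_check} free parameters: "
            "unrestrained fit is under-determined",
            RuntimeWarning,
            stacklevel=3,
        )

    if config.equivalence_groups is None:
        equivalence_groups = [list(g) for g in molecule.equivalence_groups]
    else:
        equivalence_groups = [list(g) for g in config.equivalence_groups]
    M, theta_frozen, columns = _reduction(P, equivalence_groups, config.frozen_parameters)
    K = M.shape[1]
    G_full, h = _constraint_rows(molecule, config, P)
    Gr = G_full @ M
    hr = h - G_full @ theta_frozen
    # drop constraints that act only on frozen parameters
    keep = []
    for r in range(Gr.shape[0]):
        if np.max(np.abs(Gr[r])) > 1e-12:
            keep.append(r)
        elif abs(hr[r]) > 1e-9:
            raise ValueError(
                f"constraint row {r} is infeasible: fixed parameters sum to "
                f"{h[r] - hr[r]:.12g}, required {h[r]:.12g}"
            )
    Gr, hr = Gr[keep], hr[keep]
    if Gr.shape[0]:
        rank = np.linalg.matrix_rank(Gr, tol=1e-10 * max(1.0, np.abs(Gr).max()))
        if rank < Gr.shape[0]:
            raise ValueError(
                f"constraint rows are linearly dependent (rank {rank} of "
                f"{Gr.shape[0]}); remove redundant constraints"
            )

    BM = B @ M
    r0 = v - offset - B @ theta_frozen
    N = BM.T @ BM
    b = BM.T @ r0
    nc = Gr.shape[0]

    def kkt(Rdiag: np.ndarray) -> np.ndarray:
        Kmat = np.zeros((K + nc, K + nc))
        Kmat[:K, :K] = N + np.diag(Rdiag)
        if nc:
            Kmat[:K, K:] = Gr.T
            Kmat[K:, :K] = Gr
        return Kmat

    sv = np.linalg.svd(kkt(np.zeros(K)), compute_uv=False)
    if sv.size and sv[-1] <= 1e-12 * sv[0]:
        null_dim = int(np.sum(sv <= 1e-12 * sv[0]))
        raise np.linalg.LinAlgError(
            f"rank-deficient constrained system: null-space dimension {null_dim} "
            f"of {K + nc} (collinear or unidentifiable parameters)"
        )
    condition = float(sv[0] / sv[-1]) if sv.size else 1.0

    restrained = _restrained_parameters(molecule, config, P)
    rhs = np.concatenate([b, hr])
    a_str = config.restraint.strength if config.restraint is not None else 0.0
    b_tight = config.restraint.tightness if config.restraint is not None else 0.1
    theta_r = np.zeros(K)
    iterations = 0
    trace: list[float] = []
    max_iter = config.max_restraint_iterations if (a_str > 0 and restrained.size) else 1
    for iterations in range(1, max_iter + 1):
        Rfull = np.zeros(P)
        if a_str > 0 and restrained.size:
            q_cur = (M @ theta_r + theta_frozen)[restrained]
            Rfull[restrained] = a_str / np.sqrt(q_cur**2 + b_tight**2)
        Rdiag = M.T @ (Rfull[:, None] * M)
        sol = sla.solve(kkt(np.diag(Rdiag)), rhs, assume_a="sym")
        new_theta = sol[:K]
        if a_str > 0 and restrained.size:
            delta = np.max(np.abs((M @ (new_theta - theta_r))[restrained]))
            trace.append(float(delta))
            theta_r = new_theta
            if delta < config.restraint_tolerance:
                break
        else:
            theta_r = new_theta
            break
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if a_str > 0 and restrained.size and trace and trace[-1] >= config.restraint_tolerance:
        raise RuntimeError(
            "restraint iteration did not converge in "
            f"{config.max_restraint_iterations} steps; |dq| trace: "
            + ", ".join(f"{d:.3e}" for d in trace[-10:])
        )

    theta = M @ theta_r + theta_frozen
    fitted = molecule.copy()
    fitted.charges = theta[:n].copy()
    if config.model_kind == "pgm-perm":
        fitted.set_cbv_flat(theta[n:])
    return fitted, iterations, condition


def _normalize_inputs(molecules, datasets):
    if isinstance(molecules, MoleculeModel):
        molecules = [molecules]
        datasets = [list(datasets)]
    else:
        molecules = list(molecules)
        datasets = [list(d) for d in datasets]
    if len(molecules) != len(datasets):
        raise ValueError("one dataset list per molecule is required")
    return molecules, datasets


def fit(molecules, datasets, config: FitConfiguration) -> FitResult:
    """Fit charges (and CBV dipoles for pgm-perm) to one or more ESP datasets.

    ``molecules`` may be a single :class:`MoleculeModel` with a flat list of
    datasets, or a list of molecules with a parallel list of dataset lists
    (molecules share no parameters, so they are solved independently).
    """
    molecules, datasets = _normalize_inputs(molecules, datasets)
    fitted_all: list[MoleculeModel] = []
    rmse_all: list[float] = []
    rrmse_all: list[float] = []
    iters = 0
    cond = 0.0
    for mol, ds_list in zip(molecules, datasets):
        fitted, it, c = _fit_single(mol, ds_list, config)
        r, rr = _dataset_errors(fitted, ds_list, config.model_kind)
        fitted_all.append(fitted)
        rmse_all.extend(r)
        rrmse_all.extend(rr)
        iters = max(iters, it)
        cond = max(cond, c)
    provenance = {
        "config_hash": config.config_hash(),
        "datasets": [ds.identifier or ds.medium for dsl in datasets for ds in dsl],
        "model_kind": config.model_kind,
    }
    return FitResult(
        molecules=fitted_all,
        model_kind=config.model_kind,
        rmse=rmse_all,
        rrmse=rrmse_all,
        restraint_iterations=iters,
        condition=cond,
        provenance=provenance,
        stage=config.stage,
    )


def two_stage_fit(
    molecules,
    datasets,
    stage1_config: FitConfiguration,
    stage2_refit_groups: list[list[int]],
    stage2_restraint: RestraintSpec | None = None,
) -> FitResult:
    """Two-stage protocol: fit everything, then refit selected atom groups.

    Stage 1 runs with ``stage1_config`` (typically equivalencing everything
    except the freely rotating methyl/methylene groups).  Stage 2 refits only
    the atoms in ``stage2_refit_groups`` — each group equivalenced internally,
    its CBV slots free for pgm-perm — with every other parameter frozen
    bitwise at its stage-1 value.  An empty refit list returns the stage-1
    result unchanged.
    """
    molecules_n, datasets_n = _normalize_inputs(molecules, datasets)
    if len(molecules_n) != 1:
        raise ValueError("two_stage_fit operates on a single molecule")
    molecule, ds_list = molecules_n[0], datasets_n[0]
    stage1 = fit(molecule, ds_list, stage1_config)
    if not stage2_refit_groups:
        return stage1
    n = molecule.n_atoms
    P = n_parameters(molecule, stage1_config.model_kind)
    refit_atoms: set[int] = set()
    for grp in stage2_refit_groups:
        for a in grp:
            a = int(a)
            if not (0 <= a < n):
                raise ValueError(f"refit group references invalid atom {a}")
            refit_atoms.add(a)
    free: set[int] = set(refit_atoms)
    if stage1_config.model_kind == "pgm-perm":
        for slot, (i, _) in enumerate(stage1.molecule.cbv_slots()):
            if i in refit_atoms:
                free.add(n + slot)
    theta1 = stage1.parameter_vector()
    frozen = {i: float(theta1[i]) for i in range(P) if i not in free}
    for atoms, _total in stage1_config.charge_constraints:
        if any(int(a) not in refit_atoms for a in atoms) and any(
            int(a) in refit_atoms for a in atoms
        ):
            raise ValueError(
                "stage-2 refit group overlaps a charge constraint that also "
                "covers frozen atoms"
            )
    restraint = stage2_restraint
    if restraint is None and stage1_config.restraint is not None:
        restraint = replace(stage1_config.restraint, strength=0.001)
    stage2_config = replace(
        stage1_config,
        stage=2,
        restraint=restraint,
        frozen_parameters=frozen,
        equivalence_groups=[[int(a) for a in grp] for grp in stage2_refit_groups],
    )
    result = fit(molecule, ds_list, stage2_config)
    # frozen parameters must survive bitwise
    theta2 = result.parameter_vector()
    for i, val in frozen.items():
        assert theta2[i] == val
    result.provenance["stage1_config_hash"] = stage1_config.config_hash()
    return result


def dual_solvent_fit(
    molecule: MoleculeModel,
    dataset_A: EspDataset,
    dataset_B: EspDataset,
    config: FitConfiguration,
) -> FitResult:
    """One parameter set fitted jointly to two media (equal weights by default)."""
    for ds in (dataset_A, dataset_B):
        if ds.atom_positions is not None:
            if ds.atom_positions.shape != molecule.atom_positions.shape or np.max(
                np.abs(ds.atom_positions - molecule.atom_positions)
            ) > 1e-6:
                raise ValueError(
                    f"dataset {ds.medium!r} conformation differs from the molecule "
                    "by more than 1e-6 Å"
                )
    if config.dataset_weights is not None and len(config.dataset_weights) != 2:
        raise ValueError("dual_solvent_fit requires exactly two dataset weights")
    return fit(molecule, [dataset_A, dataset_B], config)
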