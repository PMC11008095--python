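"""Tests for the constrained/restrained least-squares fitting machinery."""

from __future__ import annotations

import numpy as np
import pytest

import pcmresp as pr
from pcmresp.fitting import EspDataset, n_parameters
from pcmresp.model_core import EspGrid, SurfaceChargeSet, esp_matrices

from conftest import blank_copy


def _ssr(result: pr.FitResult, datasets) -> float:
    return sum(
        r * r * ds.grid.n_points for r, ds in zip(result.rmse, datasets)
    )


# ---------------------------------------------------------------------------
# build_design
# ---------------------------------------------------------------------------


def test_design_reduces_to_X_without_polarization(gas_wat, truth_molecule):
    gas, _ = gas_wat
    mol = truth_molecule.copy()
    mol.polarizabilities = np.zeros(mol.n_atoms)
    B, offset = pr.build_design(mol, [gas], model_kind="pgm-ind")
    X, _ = esp_matrices(mol, gas.grid)
    assert np.array_equal(B, X)
    assert np.allclose(offset, 0.0)


def test_design_matvec_matches_end_to_end(gas_wat, truth_molecule):
    """Design linearization equals the full nonlinear-path forward model."""
    _, wat = gas_wat
    rng = np.random.default_rng(11)
    for kind in ("resp", "pgm-ind", "pgm-perm"):
        mol = truth_molecule.copy()
        theta = rng.normal(0, 0.3, n_parameters(mol, kind))
        mol.charges = theta[: mol.n_atoms].copy()
        if kind == "pgm-perm":
            mol.set_cbv_flat(theta[mol.n_atoms :])
        else:
            mol.set_cbv_flat(np.zeros(mol.n_cbv))
            theta = theta[: mol.n_atoms]
        B, offset = pr.build_design(
            mol, [wat], model_kind=kind, include_direct_surface=True
        )
        V_design = B @ theta + offset
        V_model = pr.predict_esp(mol, wat, kind)
        assert np.allclose(V_design, V_model, rtol=0, atol=1e-10)


def test_design_duplicate_dataset_half_weight(gas_wat, truth_molecule):
    gas, _ = gas_wat
    mol = truth_molecule
    B1, o1 = pr.build_design(mol, [gas], model_kind="pgm-ind", dataset_weights=[1.0])
    B2, o2 = pr.build_design(
        mol, [gas, gas], model_kind="pgm-ind", dataset_weights=[0.5, 0.5]
    )
    # identical normal equations (up to roundoff in the sqrt-weight scaling)
    assert np.allclose(B2.T @ B2, B1.T @ B1, rtol=1e-12, atol=1e-18)
    assert np.allclose(B2.T @ o2, B1.T @ o1, rtol=1e-12, atol=1e-18)


def test_design_requires_surface_for_solvated_dataset(gas_wat, truth_molecule):
    _, wat = gas_wat
    broken = EspDataset(
        grid=wat.grid, surface=SurfaceChargeSet.empty(), medium="WAT", epsilon=78.3553
    )
    with pytest.raises(ValueError, match="no\\s+surface"):
        pr.build_design(truth_molecule, [broken], model_kind="pgm-ind")


# ---------------------------------------------------------------------------
# fit: recovery, constraints, equivalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kind", ["resp", "pgm-ind", "pgm-perm"])
@pytest.mark.parametrize("medium", ["GAS", "WAT"])
def test_noise_free_recovery(kind, medium):
    spec = pr.benchmark_spec(seed=42)
    spec = type(spec)(**{**spec.__dict__, "model_kind": kind, "media": (("GAS", 1.0), ("WAT", 78.3553))})
    truth = spec.build_molecule()
    ds, _ = pr.forward_esp_dataset(spec, medium)
    config = pr.FitConfiguration(model_kind=kind, restraint=None)
    result = pr.fit(blank_copy(truth), [ds], config)
    assert np.max(np.abs(result.molecule.charges - truth.charges)) < 1e-6
    if kind == "pgm-perm":
        assert np.max(np.abs(result.molecule.cbv_flat() - truth.cbv_flat())) < 1e-6


def test_total_charge_constraint(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp", restraint=pr.RestraintSpec(strength=0.01)
    )
    result = pr.fit(blank_copy(truth_molecule), [gas], config)
    assert abs(np.sum(result.molecule.charges) - truth_molecule.total_charge) < 1e-10


def test_extra_charge_constraint(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp",
        restraint=None,
        charge_constraints=[([1, 2], 0.55)],
    )
    result = pr.fit(blank_copy(truth_molecule), [gas], config)
    assert result.molecule.charges[1] + result.molecule.charges[2] == pytest.approx(
        0.55, abs=1e-10
    )


def test_equivalence_bitwise(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp", restraint=None, equivalence_groups=[[1, 2]]
    )
    result = pr.fit(blank_copy(truth_molecule), [gas], config)
    assert result.molecule.charges[1] == result.molecule.charges[2]  # bitwise


def test_molecule_equivalence_groups_used_by_default(gas_wat, truth_molecule):
    gas, _ = gas_wat
    mol = blank_copy(truth_molecule)
    mol.equivalence_groups = [[1, 2]]
    config = pr.FitConfiguration(model_kind="resp", restraint=None)
    result = pr.fit(mol, [gas], config)
    assert result.molecule.charges[1] == result.molecule.charges[2]


def test_redundant_constraint_rows_rejected(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp",
        restraint=None,
        charge_constraints=[([0, 1, 2], 0.0)],  # duplicates the total-charge row
    )
    with pytest.raises(ValueError, match="dependent"):
        pr.fit(blank_copy(truth_molecule), [gas], config)


def test_frozen_parameters_bitwise(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp", restraint=None, frozen_parameters={0: -0.762}
    )
    result = pr.fit(blank_copy(truth_molecule), [gas], config)
    assert result.molecule.charges[0] == -0.762


def test_frozen_inside_equivalence_group_error(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(
        model_kind="resp",
        restraint=None,
        frozen_parameters={1: 0.3},
        equivalence_groups=[[1, 2]],
    )
    with pytest.raises(ValueError, match="mixes frozen"):
        pr.fit(blank_copy(truth_molecule), [gas], config)


def test_collinear_cbv_rank_deficiency():
    # two bonds from atom 0 pointing in the same direction -> identical
    # frame columns -> unidentifiable CBV coefficients
    mol = pr.MoleculeModel(
        np.array([[0.0, 0, 0], [0, 0, 1.4], [0, 0, 2.8]]),
        ["C", "C", "O"],
        bonds=[(0, 1), (0, 2)],
        charges=[0.1, 0.1, -0.2],
        gauss_radii=[0.8, 0.8, 0.75],
    )
    grid = EspGrid(points=np.random.default_rng(0).uniform(3, 5, (60, 3)))
    ds = EspDataset(grid=grid, surface=SurfaceChargeSet.empty())
    config = pr.FitConfiguration(model_kind="pgm-perm", restraint=None)
    with pytest.raises(np.linalg.LinAlgError, match="null-space"):
        pr.fit(mol, [ds], config)


def test_fit_rotation_invariance(gas_wat, truth_molecule):
    gas, _ = gas_wat
    config = pr.FitConfiguration(model_kind="pgm-perm", restraint=None)
    base = pr.fit(blank_copy(truth_molecule), [gas], config)

    rng = np.random.default_rng(13)
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    mol_r = blank_copy(truth_molecule)
    mol_r.atom_positions = truth_molecule.atom_positions @ Q.T
    gas_r = EspDataset(
        grid=EspGrid(
            points=gas.grid.points @ Q.T,
            qm_potentials=gas.grid.qm_potentials,
            point_weights=gas.grid.point_weights,
        ),
        surface=SurfaceChargeSet.empty(),
        medium="GAS",
        epsilon=1.0,
    )
    rot = pr.fit(mol_r, [gas_r], config)
    assert np.allclose(rot.molecule.charges, base.molecule.charges, atol=1e-8)
    # CBV coefficients are frame-local, hence identical
    assert np.allclose(rot.molecule.cbv_flat(), base.molecule.cbv_flat(), atol=1e-8)


# ---------------------------------------------------------------------------
# restraint behavior
# ---------------------------------------------------------------------------


def test_restraint_never_decreases_ssr(gas_wat, truth_molecule):
    gas, _ = gas_wat
    free = pr.fit(
        blank_copy(truth_molecule), [gas], pr.FitConfiguration("resp", restraint=None)
    )
    tight = pr.fit(
        blank_copy(truth_molecule),
        [gas],
        pr.FitConfiguration("resp", restraint=pr.RestraintSpec(strength=0.01, apply_to="all")),
    )
    assert _ssr(tight, [gas]) >= _ssr(free, [gas]) - 1e-15
    assert tight.restraint_iterations >= 2


def test_restraint_shrinks_single_parameter():
    # one free charge against its own ESP; no constraints
    mol = pr.MoleculeModel(
        np.zeros((1, 3)), ["C"], charges=[0.5], gauss_radii=[0.8], total_charge=0.5
    )
    grid_pts = np.random.default_rng(1).uniform(2, 4, (30, 3))
    grid = EspGrid(points=grid_pts)
    from pcmresp.model_core import model_esp

    V = model_esp(mol, np.zeros(0), SurfaceChargeSet.empty(), grid)
    ds = EspDataset(
        grid=EspGrid(points=grid_pts, qm_potentials=V), surface=SurfaceChargeSet.empty()
    )
    cfg_free = pr.FitConfiguration(
        "pgm-ind", restraint=None, constrain_total_charge=False
    )
    cfg_tight = pr.FitConfiguration(
        "pgm-ind",
        restraint=pr.RestraintSpec(strength=0.05, apply_to="all"),
        constrain_total_charge=False,
    )
    target = mol.copy()
    target.charges = np.zeros(1)
    q_free = pr.fit(target, [ds], cfg_free).molecule.charges[0]
    q_tight = pr.fit(target, [ds], cfg_tight).molecule.charges[0]
    assert abs(q_tight) <= abs(q_free) + 1e-12
    assert abs(q_free - 0.5) < 1e-8


def test_hydrogens_unrestrained_by_default(gas_wat, truth_molecule):
    gas, _ = gas_wat
    cfg = pr.FitConfiguration(
        "resp", restraint=pr.RestraintSpec(strength=0.05, apply_to="non-hydrogen")
    )
    cfg_all = pr.FitConfiguration(
        "resp", restraint=pr.RestraintSpec(strength=0.05, apply_to="all")
    )
    r1 = pr.fit(blank_copy(truth_molecule), [gas], cfg)
    r2 = pr.fit(blank_copy(truth_molecule), [gas], cfg_all)
    # restraining hydrogens too must change the result
    assert not np.allclose(r1.molecule.charges, r2.molecule.charges, atol=1e-12)


# ---------------------------------------------------------------------------
# nested models
# ---------------------------------------------------------------------------


def test_nested_model_residual_ordering(gas_wat, truth_molecule):
    gas, wat = gas_wat
    for ds in (gas, wat):
        r_ind = pr.fit(
            blank_copy(truth_molecule), [ds], pr.FitConfiguration("pgm-ind", restraint=None)
        )
        r_perm = pr.fit(
            blank_copy(truth_molecule), [ds], pr.FitConfiguration("pgm-perm", restraint=None)
        )
        assert _ssr(r_perm, [ds]) <= _ssr(r_ind, [ds]) + 1e-15


# ---------------------------------------------------------------------------
# two-stage fitting
# ---------------------------------------------------------------------------


def _ethane():
    from pcmresp.synthetic_data import build_template

    pos, elements, bonds = build_template("alkane-chain", 2)
    mol = pr.MoleculeModel(
        atom_positions=pos,
        elements=elements,
        bonds=bonds,
        charges=np.zeros(len(elements)),
        gauss_radii=[0.85 if e == "C" else 0.55 for e in elements],
        polarizabilities=[1.0 if e == "C" else 0.3 for e in elements],
    )
    return mol


@pytest.fixture(scope="module")
def ethane_dataset():
    mol = _ethane()
    rng = np.random.default_rng(21)
    truth = mol.copy()
    truth.charges = rng.normal(0, 0.2, mol.n_atoms)
    truth.charges -= truth.charges.mean()
    grid_pts = pr.generate_grid(truth, shell_scales=(1.4, 2.0), density=1.5)
    from pcmresp.model_core import build_A, model_esp, solve_induced, static_field

    mu = solve_induced(build_A(truth), static_field(truth, SurfaceChargeSet.empty()))
    V = model_esp(truth, mu, SurfaceChargeSet.empty(), EspGrid(points=grid_pts))
    ds = EspDataset(
        grid=EspGrid(points=grid_pts, qm_potentials=V), surface=SurfaceChargeSet.empty()
    )
    return mol, ds


def test_two_stage_empty_refit_equals_stage1(ethane_dataset):
    mol, ds = ethane_dataset
    cfg = pr.FitConfiguration("pgm-ind", restraint=pr.RestraintSpec())
    r1 = pr.fit(mol, [ds], cfg)
    r2 = pr.two_stage_fit(mol, [ds], cfg, [])
    assert np.array_equal(r1.molecule.charges, r2.molecule.charges)


def test_two_stage_refit_all_equals_single_stage(ethane_dataset):
    mol, ds = ethane_dataset
    cfg = pr.FitConfiguration("pgm-ind", restraint=None)
    single = pr.fit(
        mol,
        [ds],
        pr.FitConfiguration(
            "pgm-ind", restraint=None, equivalence_groups=[[i] for i in range(mol.n_atoms)]
        ),
    )
    two = pr.two_stage_fit(
        mol, [ds], cfg, [[i] for i in range(mol.n_atoms)], stage2_restraint=None
    )
    assert np.allclose(two.molecule.charges, single.molecule.charges, atol=1e-9)


def test_two_stage_methyl_equivalencing(ethane_dataset):
    mol, ds = ethane_dataset
    h_atoms = [i for i, e in enumerate(mol.elements) if e == "H"]
    assert len(h_atoms) == 6
    cfg = pr.FitConfiguration("pgm-ind", restraint=None)
    result = pr.two_stage_fit(mol, [ds], cfg, [h_atoms], stage2_restraint=None)
    stage1 = pr.fit(mol, [ds], cfg)
    # one shared hydrogen charge, bitwise
    h_charges = result.molecule.charges[h_atoms]
    assert np.all(h_charges == h_charges[0])
    # carbons frozen bitwise at stage-1 values
    c_atoms = [i for i, e in enumerate(mol.elements) if e == "C"]
    assert np.array_equal(
        result.molecule.charges[c_atoms], stage1.molecule.charges[c_atoms]
    )
    # constrained optimum cannot beat the unconstrained stage-1 optimum
    assert _ssr(result, [ds]) >= _ssr(stage1, [ds]) - 1e-15
    assert result.stage == 2


def test_two_stage_invalid_refit_atom(ethane_dataset):
    mol, ds = ethane_dataset
    cfg = pr.FitConfiguration("pgm-ind", restraint=None)
    with pytest.raises(ValueError, match="invalid atom"):
        pr.two_stage_fit(mol, [ds], cfg, [[99]])


# ---------------------------------------------------------------------------
# dual-solvent fitting
# ---------------------------------------------------------------------------


def test_dual_duplicate_equals_single(gas_wat, truth_molecule):
    gas, _ = gas_wat
    cfg = pr.FitConfiguration("pgm-ind", restraint=None)
    single = pr.fit(blank_copy(truth_molecule), [gas], cfg)
    dual = pr.dual_solvent_fit(blank_copy(truth_molecule), gas, gas, cfg)
    assert np.allclose(dual.molecule.charges, single.molecule.charges, atol=1e-10)


def test_dual_shared_truth_recovery(gas_wat, truth_molecule):
    gas, wat = gas_wat
    cfg = pr.FitConfiguration("pgm-perm", restraint=None)
    dual = pr.dual_solvent_fit(blank_copy(truth_molecule), gas, wat, cfg)
    assert np.max(np.abs(dual.molecule.charges - truth_molecule.charges)) < 1e-6
    assert np.max(np.abs(dual.molecule.cbv_flat() - truth_molecule.cbv_flat())) < 1e-6


def test_dual_degenerate_weighting(gas_wat, truth_molecule):
    gas, wat = gas_wat
    cfg = pr.FitConfiguration("pgm-ind", restraint=None, dataset_weights=[1.0, 0.0])
    dual = pr.dual_solvent_fit(blank_copy(truth_molecule), gas, wat, cfg)
    single = pr.fit(
        blank_copy(truth_molecule), [gas], pr.FitConfiguration("pgm-ind", restraint=None)
    )
    assert np.allclose(dual.molecule.charges, single.molecule.charges, atol=1e-10)


def test_dual_conformation_mismatch_error(gas_wat, truth_molecule):
    gas, wat = gas_wat
    shifted = EspDataset(
        grid=wat.grid,
        surface=wat.surface,
        medium="WAT",
        epsilon=wat.epsilon,
        atom_positions=wat.atom_positions + 1e-3,
    )
    cfg = pr.FitConfiguration("pgm-ind", restraint=None)
    with pytest.raises(ValueError, match="conformation"):
        pr.dual_solvent_fit(blank_copy(truth_molecule), gas, shifted, cfg)


# ---------------------------------------------------------------------------
# misc contracts
# ---------------------------------------------------------------------------


def test_under_determined_warns():
    mol = pr.MoleculeModel(
        np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]]),
        ["C", "O", "N"],
        charges=[0.0, 0.0, 0.0],
        gauss_radii=[0.8, 0.75, 0.8],
    )
    grid = EspGrid(points=np.array([[3.0, 3.0, 3.0]]))
    ds = EspDataset(grid=grid, surface=SurfaceChargeSet.empty())
    cfg = pr.FitConfiguration("pgm-ind", restraint=None, constrain_total_charge=False)
    with pytest.warns(RuntimeWarning, match="under-determined"):
        with pytest.raises(np.linalg.LinAlgError):
            pr.fit(mol, [ds], cfg)


def test_multi_molecule_fit(gas_wat, truth_molecule):
    gas, wat = gas_wat
    cfg = pr.FitConfiguration("pgm-perm", restraint=None)
    result = pr.fit(
        [blank_copy(truth_molecule), blank_copy(truth_molecule)],
        [[gas], [wat]],
        cfg,
    )
    assert len(result.molecules) == 2
    assert len(result.rmse) == 2
    for m in result.molecules:
        assert np.max(np.abs(m.charges - truth_molecule.charges)) < 1e-6


def test_fit_result_provenance(gas_wat, truth_molecule):
    gas, _ = gas_wat
    cfg = pr.FitConfiguration("resp", restraint=None)
    result = pr.fit(blank_copy(truth_molecule), [gas], cfg)
    assert result.provenance["config_hash"] == cfg.config_hash()
    assert result.condition > 0
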