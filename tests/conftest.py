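"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pcmresp as pr


@pytest.fixture(scope="session")
def bench_spec() -> pr.SyntheticSpec:
    return pr.benchmark_spec(seed=20240001)


@pytest.fixture(scope="session")
def bench(bench_spec):
    """Truth molecule + five-media datasets of the packaged benchmark."""
    truth, datasets = pr.make_benchmark(bench_spec)
    return truth, datasets


@pytest.fixture(scope="session")
def gas_wat(bench):
    _, datasets = bench
    return datasets["GAS"], datasets["WAT"]


@pytest.fixture(scope="session")
def truth_molecule(bench) -> pr.MoleculeModel:
    return bench[0]


def blank_copy(molecule: pr.MoleculeModel) -> pr.MoleculeModel:
    """Copy with zeroed fit parameters (charges, CBV coefficients)."""
    m = molecule.copy()
    m.charges = np.zeros(m.n_atoms)
    if m.n_cbv:
        m.set_cbv_flat(np.zeros(m.n_cbv))
    return m


@pytest.fixture
def water_like() -> pr.MoleculeModel:
    """Small polarizable 3-atom molecule with permanent dipoles."""
    from pcmresp.synthetic_data import build_template

    pos, elements, bonds = build_template("water-like")
    mol = pr.MoleculeModel(
        atom_positions=pos,
        elements=elements,
        bonds=bonds,
        total_charge=0.0,
        charges=np.array([-0.8, 0.4, 0.4]),
        polarizabilities=np.array([1.0, 0.45, 0.45]),
        gauss_radii=np.array([0.9, 0.7, 0.7]),
        equivalence_groups=[[1, 2]],
    )
    mol.set_cbv_flat(np.array([0.03, 0.03, -0.02, 0.01]))
    return mol


def random_molecule(rng: np.random.Generator, n: int = 4) -> pr.MoleculeModel:
    """Random well-separated polarizable toy molecule."""
    from pcmresp.synthetic_data import build_template, _DEFAULT_ALPHA, _DEFAULT_RADIUS

    pos, elements, bonds = build_template("random", n, rng)
    q = rng.normal(0.0, 0.3, size=n)
    q -= q.mean()
    mol = pr.MoleculeModel(
        atom_positions=pos,
        elements=elements,
        bonds=bonds,
        total_charge=0.0,
        charges=q,
        polarizabilities=np.array([_DEFAULT_ALPHA.get(e, 0.8) for e in elements]),
        gauss_radii=np.array([_DEFAULT_RADIUS.get(e, 0.7) for e in elements]),
    )
    mol.set_cbv_flat(rng.normal(0.0, 0.03, size=mol.n_cbv))
    return mol
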