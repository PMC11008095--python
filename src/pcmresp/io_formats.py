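"""Readers and writers for the native on-disk artifacts.

Three text formats are defined (no binary, no vendor QM logs):

**ESP dataset** (``PCMESP 1``) — a documented stand-in for quantum-chemistry
ESP output, one file per molecule per medium::

    PCMESP 1
    units angstrom            # or "bohr"; normalized to Å on read
    medium WAT
    epsilon 78.3553
    counts <n_atoms> <n_grid> <n_surface>
    atoms                     # element  x y z
    grid                      # V  x y z          (V in a.u.)
    surface                   # q  x y z  radius  weight   (q in e)
    end

**Molecule** — YAML with atoms (element, xyz, charge, polarizability,
gauss_radius), bonds, total_charge, equivalence_groups, and optional CBV
coefficients.

**Parameters** (``PCMRESP-PARAMS 1``) — fitted q / p^loc / alpha / R plus
geometry, equivalence groups, and per-section checksums for tamper
detection; 12 significant digits, fixed column order, losslessly
round-trippable.

External QM output can be plugged in by converting to the PCMESP grammar;
an adapter only needs to emit the blocks above.

All parsers reject malformed input with the offending line number; nothing
is silently coerced.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .constants import BOHR_TO_ANGSTROM
from .fitting import EspDataset, FitConfiguration, FitResult, RestraintSpec
from .model_core import EspGrid, MoleculeModel, SurfaceChargeSet

__all__ = [
    "EspFileRecord",
    "read_esp_dataset",
    "write_esp_dataset",
    "read_molecule",
    "write_molecule",
    "read_parameters",
    "write_parameters",
    "read_fit_config",
]

_F = "%.12g"  # all floats are printed at 12 significant digits


def _fmt(x: float) -> str:
    return _F % float(x)


class FormatError(ValueError):
    """Malformed file content; message carries the line number."""


@dataclass
class EspFileRecord:
    """Parsed contents of one PCMESP file."""

    elements: list[str]
    atom_positions: np.ndarray  # Å
    grid: EspGrid
    surface: SurfaceChargeSet
    medium: str
    epsilon: float
    units: str = "angstrom"

    def to_dataset(self, identifier: str = "") -> EspDataset:
        return EspDataset(
            grid=self.grid,
            surface=self.surface,
            medium=self.medium,
            epsilon=self.epsilon,
            atom_positions=self.atom_positions,
            identifier=identifier,
        )


# ---------------------------------------------------------------------------
# ESP dataset files
# ---------------------------------------------------------------------------


def write_esp_dataset(
    path,
    elements: list[str],
    atom_positions: np.ndarray,
    grid: EspGrid,
    surface: SurfaceChargeSet,
    medium: str = "GAS",
    epsilon: float = 1.0,
) -> None:
    """Write a PCMESP 1 file (coordinates in Å, potentials in a.u.)."""
    atom_positions = np.asarray(atom_positions, dtype=float)
    lines = [
        "PCMESP 1",
        "units angstrom",
        f"medium {medium}",
        f"epsilon {_fmt(epsilon)}",
        f"counts {len(elements)} {grid.n_points} {surface.n_points}",
        "atoms",
    ]
    for e, p in zip(elements, atom_positions):
        lines.append(f"{e} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}")
    lines.append("grid")
    for v, p in zip(grid.qm_potentials, grid.points):
        lines.append(f"{_fmt(v)} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}")
    lines.append("surface")
    for q, p, r, w in zip(
        surface.charges, surface.positions, surface.radii, surface.weights
    ):
        lines.append(
            f"{_fmt(q)} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])} {_fmt(r)} {_fmt(w)}"
        )
    lines.append("end")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _floats(tokens: list[str], lineno: int, expected: int) -> list[float]:
    if len(tokens) != expected:
        raise FormatError(f"line {lineno}: expected {expected} fields, got {len(tokens)}")
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None


def read_esp_dataset(path) -> EspFileRecord:
    """Parse a PCMESP file; coordinates are normalized to Å."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln.split("#")[0].strip()) for i, ln in enumerate(raw)]
    lines = [(no, ln) for no, ln in lines if ln]
    it = iter(lines)

    def next_line():
        try:
            return next(it)
        except StopIteration:
            raise FormatError("unexpected end of file") from None

    no, header = next_line()
    parts = header.split()
    if len(parts) != 2 or parts[0] != "PCMESP":
        raise FormatError(f"line {no}: not a PCMESP file")
    if parts[1] != "1":
        raise FormatError(f"line {no}: unknown PCMESP version {parts[1]!r}")
    meta = {"units": "angstrom", "medium": "GAS", "epsilon": 1.0}
    counts = None
    while True:
        no, ln = next_line()
        key, *rest = ln.split()
        if key == "units":
            if rest[0] not in ("angstrom", "bohr"):
                raise FormatError(f"line {no}: unknown units {rest[0]!r}")
            meta["units"] = rest[0]
        elif key == "medium":
            meta["medium"] = rest[0]
        elif key == "epsilon":
            meta["epsilon"] = _floats(rest, no, 1)[0]
        elif key == "counts":
            if len(rest) != 3:
                raise FormatError(f"line {no}: counts needs 3 integers")
            try:
                counts = tuple(int(t) for t in rest)
            except ValueError:
                raise FormatError(f"line {no}: counts must be integers") from None
        elif key == "atoms":
            break
        else:
            raise FormatError(f"line {no}: unexpected header key {key!r}")
    if counts is None:
        raise FormatError("missing counts line")
    n_atoms, n_grid, n_surface = counts
    scale = BOHR_TO_ANGSTROM if meta["units"] == "bohr" else 1.0

    elements, apos = [], []
    for _ in range(n_atoms):
        no, ln = next_line()
        toks = ln.split()
        if len(toks) != 4:
            raise FormatError(f"line {no}: atom line needs 'element x y z'")
        elements.append(toks[0])
        apos.append(_floats(toks[1:], no, 3))
    no, ln = next_line()
    if ln != "grid":
        raise FormatError(f"line {no}: expected 'grid' (atom count mismatch?)")
    vals, gpos = [], []
    for _ in range(n_grid):
        no, ln = next_line()
        v, x, y, z = _floats(ln.split(), no, 4)
        vals.append(v)
        gpos.append([x, y, z])
    no, ln = next_line()
    if ln != "surface":
        raise FormatError(f"line {no}: expected 'surface' (grid count mismatch?)")
    sq, spos, srad, swt = [], [], [], []
    for _ in range(n_surface):
        no, ln = next_line()
        q, x, y, z, r, w = _floats(ln.split(), no, 6)
        sq.append(q)
        spos.append([x, y, z])
        srad.append(r)
        swt.append(w)
    no, ln = next_line()
    if ln != "end":
        raise FormatError(f"line {no}: expected 'end' (surface count mismatch?)")

    apos_arr = np.asarray(apos, dtype=float).reshape(n_atoms, 3) * scale
    grid = EspGrid(
        points=np.asarray(gpos, dtype=float).reshape(n_grid, 3) * scale,
        qm_potentials=np.asarray(vals, dtype=float),
    )
    grid.check_against_atoms(apos_arr)
    surface = SurfaceChargeSet(
        positions=np.asarray(spos, dtype=float).reshape(n_surface, 3) * scale,
        charges=np.asarray(sq, dtype=float),
        radii=np.asarray(srad, dtype=float) * scale,
        weights=np.asarray(swt, dtype=float),
    )
    return EspFileRecord(
        elements=elements,
        atom_positions=apos_arr,
        grid=grid,
        surface=surface,
        medium=meta["medium"],
        epsilon=float(meta["epsilon"]),
        units="angstrom",
    )


# ---------------------------------------------------------------------------
# molecule files (YAML)
# ---------------------------------------------------------------------------


def write_molecule(path, molecule: MoleculeModel) -> None:
    doc = {
        "pcmresp_molecule": 1,
        "total_charge": float(molecule.total_charge),
        "atoms": [
            {
                "element": e,
                "xyz": [float(x) for x in pos],
                "charge": float(q),
                "polarizability": float(a),
                "gauss_radius": float(r),
            }
            for e, pos, q, a, r in zip(
                molecule.elements,
                molecule.atom_positions,
                molecule.charges,
                molecule.polarizabilities,
                molecule.gauss_radii,
            )
        ],
        "bonds": [[int(i), int(j)] for i, j in molecule.bonds],
        "equivalence_groups": [
            [int(i) for i in g] for g in molecule.equivalence_groups
        ],
        "cbv": [
            {"atom": i, "coefficients": [float(c) for c in row]}
            for i, row in enumerate(molecule.cbv_coefficients)
            if row
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_molecule(path) -> MoleculeModel:
    """Load and validate a molecule definition (invariants checked on load)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("pcmresp_molecule") != 1:
        raise FormatError(f"{path}: not a pcmresp molecule file (version 1)")
    atoms = doc.get("atoms")
    if not atoms:
        raise FormatError(f"{path}: no atoms")
    cbv_rows: list[list[float]] = [[] for _ in atoms]
    for entry in doc.get("cbv") or []:
        i = int(entry["atom"])
        if not (0 <= i < len(atoms)):
            raise FormatError(f"{path}: cbv entry references invalid atom {i}")
        cbv_rows[i] = [float(c) for c in entry["coefficients"]]
    try:
        return MoleculeModel(
            atom_positions=np.array([a["xyz"] for a in atoms], dtype=float),
            elements=[str(a["element"]) for a in atoms],
            bonds=[(int(i), int(j)) for i, j in (doc.get("bonds") or [])],
            total_charge=float(doc.get("total_charge", 0.0)),
            charges=np.array([float(a.get("charge", 0.0)) for a in atoms]),
            polarizabilities=np.array(
                [float(a.get("polarizability", 0.0)) for a in atoms]
            ),
            gauss_radii=np.array([float(a.get("gauss_radius", 0.0)) for a in atoms]),
            cbv_coefficients=cbv_rows,
            equivalence_groups=[
                [int(i) for i in g] for g in (doc.get("equivalence_groups") or [])
            ],
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

_SECTIONS = ("charges", "dipoles", "alphas", "radii")


def _parameter_lines(result: FitResult) -> tuple[list[str], dict[str, list[str]]]:
    lines: list[str] = []
    sections: dict[str, list[str]] = {s: [] for s in _SECTIONS}
    for mi, mol in enumerate(result.molecules):
        lines.append(
            f"molecule {mi} natoms {mol.n_atoms} total_charge {_fmt(mol.total_charge)}"
        )
        for i in range(mol.n_atoms):
            p = mol.atom_positions[i]
            ln = (
                f"atom {mi} {i} {mol.elements[i]} "
                f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])} "
                f"{_fmt(mol.charges[i])} {_fmt(mol.polarizabilities[i])} "
                f"{_fmt(mol.gauss_radii[i])}"
            )
            lines.append(ln)
            sections["charges"].append(_fmt(mol.charges[i]))
            sections["alphas"].append(_fmt(mol.polarizabilities[i]))
            sections["radii"].append(_fmt(mol.gauss_radii[i]))
        for i, j in mol.bonds:
            lines.append(f"bond {mi} {i} {j}")
        flat = mol.cbv_flat()
        for slot, (i, j) in enumerate(mol.cbv_slots()):
            lines.append(f"cbv {mi} {i} {j} {_fmt(flat[slot])}")
            sections["dipoles"].append(_fmt(flat[slot]))
        for grp in mol.equivalence_groups:
            lines.append(f"equiv {mi} " + " ".join(str(int(i)) for i in grp))
    return lines, sections


def _section_hash(values: list[str]) -> str:
    return hashlib.sha256("\n".join(values).encode()).hexdigest()[:12]


def write_parameters(result: FitResult, path) -> None:
    """Serialize fitted parameters losslessly (12 significant digits)."""
    body, sections = _parameter_lines(result)
    lines = [
        "PCMRESP-PARAMS 1",
        f"model_kind {result.model_kind}",
        f"stage {result.stage}",
        f"config_hash {result.provenance.get('config_hash', '-')}",
        f"molecules {len(result.molecules)}",
    ]
    for s in _SECTIONS:
        lines.append(f"checksum {s} {_section_hash(sections[s])}")
    lines.extend(body)
    lines.append("end")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameters(path, verify: bool = False) -> FitResult:
    """Read a parameter file back into a (metrics-free) FitResult.

    With ``verify=True``, per-section checksums are recomputed and a warning
    names any section (charges / dipoles / alphas / radii) whose values no
    longer match the recorded hash.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln.split("#")[0].strip()) for i, ln in enumerate(raw)]
    lines = [(no, ln) for no, ln in lines if ln]
    if not lines or not lines[0][1].startswith("PCMRESP-PARAMS"):
        raise FormatError("not a PCMRESP-PARAMS file")
    version = lines[0][1].split()[1]
    if version != "1":
        raise FormatError(f"unknown parameter-file version {version!r}")
    model_kind, stage, config_hash = "resp", 1, "-"
    checksums: dict[str, str] = {}
    mols: dict[int, dict] = {}
    for no, ln in lines[1:]:
        toks = ln.split()
        key = toks[0]
        if key == "model_kind":
            model_kind = toks[1]
        elif key == "stage":
            stage = int(toks[1])
        elif key == "config_hash":
            config_hash = toks[1]
        elif key == "molecules":
            continue
        elif key == "checksum":
            checksums[toks[1]] = toks[2]
        elif key == "molecule":
            mi = int(toks[1])
            mols[mi] = {
                "natoms": int(toks[3]),
                "total_charge": float(toks[5]),
                "atoms": {},
                "bonds": [],
                "cbv": {},
                "equiv": [],
            }
        elif key == "atom":
            mi, i = int(toks[1]), int(toks[2])
            vals = _floats(toks[4:], no, 6)
            mols[mi]["atoms"][i] = (toks[3], vals)
        elif key == "bond":
            mols[int(toks[1])]["bonds"].append((int(toks[2]), int(toks[3])))
        elif key == "cbv":
            mi = int(toks[1])
            mols[mi]["cbv"][(int(toks[2]), int(toks[3]))] = float(toks[4])
        elif key == "equiv":
            mols[int(toks[1])]["equiv"].append([int(t) for t in toks[2:]])
        elif key == "end":
            break
        else:
            raise FormatError(f"line {no}: unexpected key {key!r}")

    molecules = []
    sections: dict[str, list[str]] = {s: [] for s in _SECTIONS}
    for mi in sorted(mols):
        m = mols[mi]
        n = m["natoms"]
        if sorted(m["atoms"]) != list(range(n)):
            raise FormatError(f"molecule {mi}: atom lines do not match natoms")
        elements = [m["atoms"][i][0] for i in range(n)]
        pos = np.array([m["atoms"][i][1][:3] for i in range(n)])
        q = np.array([m["atoms"][i][1][3] for i in range(n)])
        alpha = np.array([m["atoms"][i][1][4] for i in range(n)])
        radii = np.array([m["atoms"][i][1][5] for i in range(n)])
        mol = MoleculeModel(
            atom_positions=pos,
            elements=elements,
            bonds=m["bonds"],
            total_charge=m["total_charge"],
            charges=q,
            polarizabilities=alpha,
            gauss_radii=radii,
            equivalence_groups=m["equiv"],
        )
        if m["cbv"]:
            flat = np.array([m["cbv"][slot] for slot in mol.cbv_slots()])
            mol.set_cbv_flat(flat)
        molecules.append(mol)
        for i in range(n):
            sections["charges"].append(_fmt(q[i]))
            sections["alphas"].append(_fmt(alpha[i]))
            sections["radii"].append(_fmt(radii[i]))
        for slot in mol.cbv_slots():
            if m["cbv"]:
                sections["dipoles"].append(_fmt(m["cbv"][slot]))
    if verify:
        for s in _SECTIONS:
            if s in checksums and _section_hash(sections[s]) != checksums[s]:
                warnings.warn(
                    f"parameter file {path}: section {s!r} does not match its "
                    "recorded checksum (values were modified after writing)",
                    UserWarning,
                    stacklevel=2,
                )
    return FitResult(
        molecules=molecules,
        model_kind=model_kind,
        rmse=[],
        rrmse=[],
        restraint_iterations=0,
        condition=0.0,
        provenance={"config_hash": config_hash, "source_file": str(path)},
        stage=stage,
    )


# ---------------------------------------------------------------------------
# fit configuration (YAML)
# ---------------------------------------------------------------------------


def read_fit_config(path) -> FitConfiguration:
    """Load a fit configuration from YAML.

    Recognized keys mirror :class:`~pcmresp.fitting.FitConfiguration`;
    ``restraint`` may be ``null`` (no restraint) or a mapping with
    ``strength`` / ``tightness`` / ``apply_to``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: fit config must be a mapping")
    restraint = doc.get("restraint")
    if isinstance(restraint, dict):
        restraint = RestraintSpec(
            strength=float(restraint.get("strength", 0.0005)),
            tightness=float(restraint.get("tightness", 0.1)),
            apply_to=str(restraint.get("apply_to", "non-hydrogen")),
        )
    elif restraint is not None:
        raise FormatError(f"{path}: restraint must be a mapping or null")
    kwargs = dict(
        model_kind=str(doc.get("model_kind", "resp")),
        restraint=restraint,
        stage=int(doc.get("stage", 1)),
        frozen_parameters={
            int(k): float(v) for k, v in (doc.get("frozen_parameters") or {}).items()
        },
        equivalence_groups=(
            None
            if doc.get("equivalence_groups") is None
            else [[int(i) for i in g] for g in doc["equivalence_groups"]]
        ),
        charge_constraints=[
            ([int(i) for i in atoms], float(total))
            for atoms, total in (doc.get("charge_constraints") or [])
        ],
        constrain_total_charge=bool(doc.get("constrain_total_charge", True)),
        dataset_weights=doc.get("dataset_weights"),
        subtract_direct_surface=bool(doc.get("subtract_direct_surface", True)),
    )
    if "max_restraint_iterations" in doc:
        kwargs["max_restraint_iterations"] = int(doc["max_restraint_iterations"])
    if "restraint_tolerance" in doc:
        kwargs["restraint_tolerance"] = float(doc["restraint_tolerance"])
    return FitConfiguration(**kwargs)
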