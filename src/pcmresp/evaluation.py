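"""Fit-quality and cross-solvent transferability metrics.

RMSE is the weighted root-mean-square ESP error in atomic units; RRMSE is
RMSE divided by the weighted root-mean-square of the reference (QM)
potential.  Note: the RRMSE denominator convention (RMS of the reference)
affects comparability of quoted percentages across codes — it is the
standard relative-RMSE convention and is used throughout this package.

Transfer errors re-solve the induced dipoles against the *target* medium's
surface charges (the static monopoles and permanent dipoles are carried
over unchanged), then compare the model ESP with the target's QM data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BOHR_TO_ANGSTROM, EANGSTROM_TO_DEBYE
from .model_core import MoleculeModel

__all__ = [
    "rmse_rrmse",
    "transfer_evaluate",
    "transfer_matrix",
    "TransferReport",
    "molecular_dipole",
    "dipole_statistics",
]


def rmse_rrmse(
    model_esp: np.ndarray,
    qm_esp: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted RMSE (a.u.) and RRMSE (dimensionless fraction).

    RMSE = sqrt(sum w (Vm - Vq)^2 / sum w);
    RRMSE = RMSE / sqrt(sum w Vq^2 / sum w).
    """
    vm = np.asarray(model_esp, dtype=float).ravel()
    vq = np.asarray(qm_esp, dtype=float).ravel()
    if vm.shape != vq.shape or vm.size == 0:
        raise ValueError("model and reference ESP must have equal, nonzero length")
    w = np.ones_like(vq) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape != vq.shape:
        raise ValueError("weights length mismatch")
    wsum = w.sum()
    mse = float(w @ (vm - vq) ** 2 / wsum)
    ref = float(w @ vq**2 / wsum)
    rmse = np.sqrt(mse)
    if ref == 0.0:
        if mse == 0.0:
            return 0.0, 0.0
        raise ValueError("RRMSE undefined: reference ESP is identically zero")
    return rmse, float(rmse / np.sqrt(ref))


def transfer_evaluate(params_from, target_dataset) -> tuple[float, float]:
    """Apply fitted parameters in a (possibly different) medium.

    ``params_from`` is a :class:`~pcmresp.fitting.FitResult` holding a single
    molecule.  Polarization responds to the target surface; when the target
    equals the fitting dataset the returned errors equal the fitting errors.
    """
    from .fitting import predict_esp  # deferred: fitting imports this module

    molecule = params_from.molecule
    if target_dataset.atom_positions is not None:
        if target_dataset.atom_positions.shape != molecule.atom_positions.shape or (
            np.max(np.abs(target_dataset.atom_positions - molecule.atom_positions))
            > 1e-6
        ):
            raise ValueError(
                "target dataset geometry does not match the parametrized molecule"
            )
    V = predict_esp(molecule, target_dataset, params_from.model_kind)
    return rmse_rrmse(
        V, target_dataset.grid.qm_potentials, target_dataset.grid.point_weights
    )


@dataclass
class TransferReport:
    """source medium x target medium grid of fit/transfer errors.

    ``rmse_matrix``/``rrmse_matrix`` rows follow ``source_media`` (the medium
    or media pair the parameters were developed in), columns follow
    ``target_media``.  Cells are unweighted means over molecules; missing
    cells are NaN and excluded from averages.  ``per_molecule`` holds the
    long-format breakdown.
    """

    source_media: list[str]
    target_media: list[str]
    rmse_matrix: np.ndarray
    rrmse_matrix: np.ndarray
    per_molecule: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dataframe(self, metric: str = "rrmse") -> pd.DataFrame:
        m = self.rrmse_matrix if metric == "rrmse" else self.rmse_matrix
        return pd.DataFrame(m, index=self.source_media, columns=self.target_media)

    def averages(
        self, metric: str = "rrmse", exclude: tuple[str, ...] = ()
    ) -> dict[str, object]:
        """Row, column and overall means, optionally excluding media labels."""
        df = self.to_dataframe(metric)
        if exclude:
            df = df.drop(index=[m for m in exclude if m in df.index], errors="ignore")
            df = df.drop(
                columns=[m for m in exclude if m in df.columns], errors="ignore"
            )
        return {
            "per_source": df.mean(axis=1, skipna=True).to_dict(),
            "per_target": df.mean(axis=0, skipna=True).to_dict(),
            "overall": float(np.nanmean(df.to_numpy())) if df.size else float("nan"),
        }

    def write_csv(self, rmse_path, rrmse_path, per_molecule_path=None) -> None:
        self.to_dataframe("rmse").to_csv(rmse_path, index_label="source")
        self.to_dataframe("rrmse").to_csv(rrmse_path, index_label="source")
        if per_molecule_path is not None and len(self.per_molecule):
            self.per_molecule.to_csv(per_molecule_path, index=False)


def transfer_matrix(results_by_medium: dict, datasets_by_medium: dict) -> TransferReport:
    """Full source x target error grid, including the fitting diagonal.

    ``results_by_medium`` maps source labels to FitResults (possibly holding
    several molecules); ``datasets_by_medium`` maps target labels to one
    dataset per molecule (a single dataset or a parallel list).  Missing
    molecule/dataset pairs are recorded as NaN and excluded from averages.
    """
    import logging

    log = logging.getLogger(__name__)
    sources = list(results_by_medium)
    targets = list(datasets_by_medium)
    rmse = np.full((len(sources), len(targets)), np.nan)
    rrmse = np.full((len(sources), len(targets)), np.nan)
    rows = []
    for si, s in enumerate(sources):
        result = results_by_medium[s]
        n_mol = len(result.molecules)
        for ti, t in enumerate(targets):
            ds = datasets_by_medium[t]
            ds_list = [ds] if not isinstance(ds, (list, tuple)) else list(ds)
            if len(ds_list) != n_mol:
                log.warning(
                    "medium %r: %d datasets for %d molecules; cell (%s, %s) absent",
                    t,
                    len(ds_list),
                    n_mol,
                    s,
                    t,
                )
                continue
            cell_rmse, cell_rrmse = [], []
            for mi, d in enumerate(ds_list):
                if d is None:
                    log.warning("missing dataset: molecule %d in medium %r", mi, t)
                    continue
                sub = type(result)(
                    molecules=[result.molecules[mi]],
                    model_kind=result.model_kind,
                    rmse=[],
                    rrmse=[],
                    restraint_iterations=result.restraint_iterations,
                    condition=result.condition,
                    provenance=result.provenance,
                    stage=result.stage,
                )
                r, rr = transfer_evaluate(sub, d)
                cell_rmse.append(r)
                cell_rrmse.append(rr)
                rows.append(
                    {
                        "source": s,
                        "target": t,
                        "molecule": mi,
                        "rmse": r,
                        "rrmse": rr,
                    }
                )
            if cell_rmse:
                rmse[si, ti] = float(np.mean(cell_rmse))
                rrmse[si, ti] = float(np.mean(cell_rrmse))
    return TransferReport(
        source_media=sources,
        target_media=targets,
        rmse_matrix=rmse,
        rrmse_matrix=rrmse,
        per_molecule=pd.DataFrame(rows),
    )


def molecular_dipole(model: MoleculeModel, mu: np.ndarray | None = None) -> np.ndarray:
    """Total molecular dipole moment (Debye, 3-vector).

    Sum of charge moments, permanent dipoles and induced dipoles ``mu``
    (e·Bohr, over polarizable atoms, as returned by the induced solver).
    Origin-independent when the net charge is zero; for charged species the
    moment is taken about the geometric center of the atoms (documented
    convention).
    """
    center = model.atom_positions.mean(axis=0)
    d = (model.charges[:, None] * (model.atom_positions - center)).sum(axis=0)
    d = d + model.permanent_dipoles().sum(axis=0)
    if mu is not None and np.asarray(mu).size:
        mu = np.asarray(mu, dtype=float).reshape(-1, 3)
        d = d + mu.sum(axis=0) * BOHR_TO_ANGSTROM
    return d * EANGSTROM_TO_DEBYE


def dipole_statistics(
    magnitudes: np.ndarray, reference: np.ndarray | None = None
) -> dict[str, float]:
    """AVE / RMS summaries of per-molecule dipole magnitudes (Debye).

    AVE is the plain mean, RMS the root-mean-square magnitude, and RMSD the
    root-mean-square deviation from a reference column when one is given.
    """
    m = np.asarray(magnitudes, dtype=float)
    out = {"ave": float(m.mean()), "rms": float(np.sqrt(np.mean(m**2)))}
    if reference is not None:
        r = np.asarray(reference, dtype=float)
        if r.shape != m.shape:
            raise ValueError("reference length mismatch")
        out["rmsd"] = float(np.sqrt(np.mean((m - r) ** 2)))
    return out
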