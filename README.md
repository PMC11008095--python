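# pcmresp

Restrained, constrained least-squares derivation of atomic monopoles and
permanent dipoles for a fixed point-charge model (`resp`) and two
polarizable Gaussian-multipole models (`pgm-ind`, `pgm-perm`) against
electrostatic potentials (ESPs) computed in dielectric media.
Continuum-solvent surface charges enter the induced-dipole equations as a
fixed external source, so solvent polarization is part of the
parametrization itself. The package also provides the fitting-quality and
cross-solvent transferability evaluation built on top of the fitting
machinery, and a synthetic forward-model generator so that everything is
testable end to end without any external quantum-chemistry data.

## What is implemented

- **`pcmresp.model_core`** — Gaussian-multipole electrostatics engine:
  erf-damped charge/dipole kernels (`f_e`, `f_t`), pair Gaussian exponents
  `beta_ij = 1/sqrt(R_i^2 + R_j^2)`, dipole field tensors, assembly of the
  induced-dipole system (diagonal `1/alpha`, off-diagonal tensors), static
  fields including surface-charge contributions, the dense induced-dipole
  solve, model ESP evaluation (finite everywhere, including atom centers),
  and the covalent-bond-vector (CBV) frame matrix for permanent dipoles.
- **`pcmresp.fitting`** — design-matrix construction
  (`X + Y A^-1 C` charge block, `(Y + Y A^-1 D) F` CBV block, constant
  surface offset `Y A^-1 C_s q_s`), hyperbolic-restraint iteration,
  equality constraints via Lagrange multipliers, chemical equivalence by
  parameter reduction (bitwise-equal results), the two-stage refit
  protocol, and dual-solvent combined fits.
- **`pcmresp.evaluation`** — RMSE/RRMSE, cross-medium transfer evaluation
  (induced dipoles re-solved against the target medium's surface charges),
  full source x target transfer matrices with row/column/overall averages
  (optionally excluding the gas phase), and molecular dipole moments in
  Debye.
- **`pcmresp.io_formats`** — versioned text formats: `PCMESP 1` ESP
  datasets (atoms / grid / surface blocks, Å or Bohr declared in the
  header), YAML molecule definitions, and `PCMRESP-PARAMS 1` parameter
  files with per-section checksums; plus YAML fit configurations.
- **`pcmresp.synthetic_data`** — deterministic Fibonacci-lattice ESP grids
  (default 1.4/1.6/1.8/2.0 x vdW shells at 6 pts/Å²), cavity surfaces
  (5 pts/Å²), a conductor-like continuum stand-in
  (`S q_s = -(eps-1)/eps * Phi`, Gauss's-law checkable), exact coupled
  solute/surface polarization, toy molecule templates, and the packaged
  five-media benchmark (`benchmark_spec`).
- **`pcmresp.cli`** — `pcmresp synth | fit | transfer | eval`.

Units: coordinates in Å, charges in e, polarizabilities in Å³, CBV
coefficients in e·Å; all electrostatics internally in Hartree atomic units
(1 Å = 1.889726124565062 Bohr); dipole moments reported in Debye
(1 e·Å = 4.803204 D).

Note: the RRMSE denominator is the weighted root-mean-square of the
reference ESP. This is the standard relative-RMSE convention, but it
affects comparability of percentages across codes.

## CLI walkthrough

Generate a synthetic five-media benchmark, fit, and evaluate transfer:

```bash
cat > spec.yaml <<EOF
template: water-like
model_kind: pgm-ind
media: [[GAS, 1.0], [ETH, 4.24], [EDC, 10.125], [ACT, 20.493], [WAT, 78.3553]]
grid_density: 2.0
seed: 7
EOF

pcmresp synth spec.yaml -o data/
pcmresp fit data/truth_molecule.yaml data/esp_GAS.txt \
    --model pgm-ind --restraint-strength 0 -o params_gas.txt --report report.json
pcmresp fit data/truth_molecule.yaml data/esp_WAT.txt \
    --model pgm-ind --restraint-strength 0 -o params_wat.txt
pcmresp transfer -p params_gas.txt -p params_wat.txt \
    -e data/esp_GAS.txt -e data/esp_WAT.txt -o transfer/ --heatmap transfer/heat.png
pcmresp eval -p params_gas.txt -e data/esp_WAT.txt
```

`pcmresp fit` also supports `--dual` (combined two-medium fit),
`--stage2-groups "i,j;k,l"` (two-stage refits), and `--config cfg.yaml`
for full fit configurations (restraints, frozen parameters, equivalence
groups, charge constraints, dataset weights).

## File formats

`PCMESP 1` (ESP dataset):

```
PCMESP 1
units angstrom          # or "bohr"
medium WAT
epsilon 78.3553
counts <n_atoms> <n_grid> <n_surface>
atoms                   # element  x y z
grid                    # V(a.u.)  x y z
surface                 # q(e)  x y z  gaussian_radius  area_weight
end
```

Molecule (YAML): `atoms` (element, xyz, charge, polarizability,
gauss_radius), `bonds`, `total_charge`, `equivalence_groups`, optional
`cbv` entries (per-atom coefficient lists, one slot per incident bond in
sorted-neighbor order). External QM output can be used by converting it to
these grammars.
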