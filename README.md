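# pdzlie

Semi-empirical **PB/LIE** binding free energy analysis for PDZ-domain:peptide
complexes, built around the Tiam1 PDZ domain and its Syndecan/Caspr4/CADM1/
Neurexin peptide ligands.

PDZ domains bind the last few residues of a partner protein as an extra
β-strand, and short peptides are convenient model ligands and inhibitor
leads. This package implements a linear-interaction-energy ("LIE") scoring
function for the *relative* binding free energy of such complexes,

```
ΔΔG = α·ΔE_vdW + β·ΔG_elec + γ·ΔA + E_restraint
```

where the inputs are MD-trajectory averages computed per complex: the
protein–peptide van der Waals interaction energy `ΔE_vdW`, a
Poisson–Boltzmann continuum-electrostatic binding term `ΔG_elec`, the change
in molecular surface on binding `ΔA` (Å²; γ is in cal/mol/Å²), and the mean
restraint energy of the simulation. The three weights (α, β, γ) are fitted
to 35 experimental relative affinities by exact least squares; complexes
modelled against a secondary reference (the quadruple-mutant:Caspr4 complex)
receive an additive correction that pins the reference's corrected
prediction to its experimental value. The fit is validated against a
constant-affinity Null model, a 100,000-model scrambled-label ensemble, and
8-fold cross-validation.

Companion modules implement the structure-level quantities these components
derive from — Lazaridis–Karplus gaussian implicit solvation,
solvent-accessible surface area (Shrake–Rupley), Lennard-Jones interaction
energies, backbone φ/ψ torsions with the β-region test for
binding-competent peptide conformations — plus the surrounding estimators:
peptide preorganization free energies `ΔΔG_I = −kT ln(f_i/f_j)` from
unbound-peptide folded fractions, batch-mean uncertainties, the Bennett
Acceptance Ratio (BAR), and the error-decomposition identity
`σ_tot² = δ_exp² + δ_MD² + δ_model²`. A synthetic-data module generates
every input class with known ground truth.

The experimental component tables ship as CSV fixtures
(`src/pdzlie/data/table{1,2,5}.csv`), transcribed verbatim from the
published analysis.

## Worked example

```python
>>> import pdzlie
>>> fit = pdzlie.fit_lie(pdzlie.load_table1())
>>> fit.coefficients
LIECoefficients(alpha=0.016593167452494745, beta=0.258938668907174, gamma=-3.86319039901322, delta=0.0)
>>> [round(x, 4) for x in (fit.report.rmsd, fit.report.mue, fit.report.pearson_r)]
[0.5528, 0.4298, 0.6416]
```

The fitted electrostatic weight β ≈ 0.26 carries most of the signal (the
optimum is shallow in α), and the model reproduces the 35 experimental
relative affinities with an rms deviation of 0.55 kcal/mol, a mean unsigned
error of 0.43 kcal/mol and a Pearson correlation of 0.64 — against 0.52 /
0.44 / none for the Null model (`pdzlie.null_model`). The same numbers are
available from the command line:

```sh
$ pdzlie fit
{
  "coefficients": {
    "alpha": 0.016593167452494745,
    "beta": 0.258938668907174,
    "delta": 0.0,
    "gamma": -3.86319039901322
  },
  "report": {
    "mue": 0.42975001883879793,
    "pearson_r": 0.6416444678204544,
    "rmsd": 0.5528129514678982,
    ...
  }
}
```

`LIERegressor` is a scikit-learn estimator (`fit`/`predict`/`get_params`),
so it composes with sklearn model selection; `pdzlie.fit_lie`,
`pdzlie.evaluate`, `pdzlie.scramble_ensemble` and `pdzlie.crossval` are thin
wrappers over it. Other CLI entry points: `pdzlie data validate`, `pdzlie
eval`, `pdzlie scramble`, `pdzlie crossval`, `pdzlie preorg`, `pdzlie bar`.

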