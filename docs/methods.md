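# Methods

## The LIE scoring function

The package scores the binding free energy of a PDZ:peptide complex
*relative to a reference complex* as a weighted sum of MD-averaged
components:

    ΔΔG = α·ΔE_vdW + β·ΔG_elec + γ·ΔA + E_restraint

The components are produced upstream (explicit-solvent MD plus continuum
electrostatics post-processing) and enter this package as table columns;
running MD or solving the Poisson–Boltzmann equation is out of scope. The
model assumes a *single-trajectory* convention: unbound-state energies are
evaluated on bound-state snapshots with the partners rigidly separated, so
conformational reorganization is treated implicitly through the solute
dielectric. No intercept is fitted — the constant term of the underlying
ansatz cancels in relative free energies. γ is expressed in cal/mol/Å² and
divided by 1000 before multiplying the surface change in Å²; with surface
changes of order ±100 Å² and γ ≈ −4 cal/mol/Å², the surface term
contributes a few tenths of a kcal/mol.

Complexes built on the secondary (quadruple-mutant:Caspr4) backbone have a
systematically different N-terminal conformation and are scored against
that complex instead of the primary reference. Operationally this adds a
correction `ΔΔG_exp(ref) − ΔΔG_model(ref)` to every such prediction, which
pins the reference's corrected prediction to its experimental value. The
correction is recomputed from the current coefficients inside every fit and
evaluation (never frozen at a tabulated value), so cross-validated and
scrambled refits remain self-consistent. Because the corrected prediction
is affine in (α, β, γ), minimising the rms deviation is ordinary least
squares on a 3-column design with the restraint and reference terms
absorbed into an offset; `LIERegressor.fit` solves it exactly via
`numpy.linalg.lstsq` after rejecting rank-deficient designs. A
rank-deficient design (an identically-zero or collinear component column)
raises an error naming the column.

Conventions for error statistics: residuals are computed minus
experimental, so a negative mean signed error means overbound predictions;
the Pearson correlation uses the sample convention over the fitting
records only (reference rows are excluded everywhere — their residuals are
zero by construction); an undefined correlation (constant predictions,
e.g. the Null model) is reported as `None`, never silently zero. Records
whose experimental value is printed only as a lower bound (`ΔΔG ≥ 1.32`)
enter the fit as equality targets at 1.32 kcal/mol, which is how the
source tables tabulate their residuals; prediction-only records (no
experimental value) are excluded from every statistic.

## Validation models

*Null model*: every complex is assigned the mean experimental value of the
fitting set. *Scrambled ensemble*: the 35 experimental values are permuted
uniformly over the 35 complexes (reference complexes stay pinned, since
they define the relative scale), the coefficients are refit in closed form
per permutation, and a scrambled model counts as strictly better only when
its rmsd is lower **and** its correlation higher than the real fit's;
permutations are drawn with replacement across models and the identity is
not excluded (collisions are negligible at 35! possibilities). Independent
resampling of values is available as an option (`mode="resample"`); both
readings of "random reassignment" give indistinguishable ensemble
fractions here. *Cross-validation*: a seeded shuffle splits the records
into k near-equal folds (sizes differ by at most one; 35 records in 8
folds gives folds of 4 or 5); held-out residuals are pooled across folds.
All stochastic routines take an explicit integer seed, record it in their
report, and are bit-reproducible from it.

## Preorganization free energies

The cost of restricting an unbound peptide to its extended,
binding-competent conformation is `ΔΔG_I(i, j) = −kT ln(f_i/f_j)`, with
`f` the fraction of MD frames whose five C-terminal residues all fall in
the β region of the Ramachandran plot — (ψ ≥ 60° or ψ ≤ −150°) and
φ ≤ −30°, bounds inclusive. kT uses T = 298.15 K (kT = 0.5925 kcal/mol,
matching the binding assays at 25 °C) and a natural logarithm. With
duplicate MD runs per peptide, `preorg_ddg` averages **ln f** over runs
(geometric-mean fraction) before taking the ratio; this choice, rather
than arithmetic averaging of the fractions, reproduces all twelve
tabulated duplicate-run values within 0.05 kcal/mol, including peptides
with strongly asymmetric runs (e.g. folded percentages of 8.4 and 0.1),
where arithmetic averaging deviates by up to 0.9 kcal/mol. Arithmetic
averaging remains available (`run_average="linear"`). No formula for the
tabulated uncertainties is published; the package reports the half-range
of `−kT ln(f_i^a/f_j^b)` over all run pairings, which matches most of the
tabulated uncertainties to the printed digit and is documented as the
package's own convention. A zero folded fraction raises an error naming
the peptide rather than returning an infinite value.

## Structure-based terms

These operate on explicit toy structures whose atoms carry their own
parameters; no force-field assignment from topology is performed, and the
default per-element table is a configurable stand-in, not ground truth.

* **Lazaridis–Karplus solvation**: each atom contributes its
  fully-solvated reference free energy minus a screening sum over
  neighbour volumes weighted by a gaussian exclusion density
  `g_i(r) = G_i^free/(2π^{3/2} λ_i r²) · exp(−((r−R_i)/λ_i)²)`. Coincident
  atoms raise a singularity error (the 1/r² density diverges). G^free is
  parameterised so a fully buried atom's net solvation vanishes; the test
  suite verifies this limit on a synthetic quadrature cage within 10%.
* **SASA**: Shrake–Rupley sphere sampling, delegated to biotite, with a
  1.4 Å probe and 960 points/atom by default. The "molecular surface" of
  the scoring function is approximated by the solvent-accessible surface;
  since the surface term carries an empirical weight, the surface
  definition only rescales γ.
* **Binding changes** use the single-trajectory convention: the complex
  and both isolated chains are evaluated at identical coordinates, so the
  surface change is ≤ 0 for contacting chains.
* **Lennard-Jones**: 12-6 with Lorentz–Berthelot combination over
  protein×peptide pairs only; no cutoff by default (an optional cutoff
  exists for parity experiments); coincident inter-chain atoms raise an
  overflow-guard error.
* **Dihedrals**: IUPAC sign convention, degrees, range (−180°, 180°];
  cross-checked against Biopython. Terminal residues yield NaN for the
  geometrically undefined angle, with a warning; the five-residue
  classifier treats a missing angle as not-bound (conservative) and the
  caller decides which residues enter the five-residue rule.

## Other estimators

* **Batch uncertainty**: the trajectory is split into N complete batches;
  σ = sqrt(var(batch means)/(N−1)) with the population variance of the
  batch means, i.e. the standard error of the mean over batches (the
  wording "variance" is ambiguous; this reading is stated explicitly).
  Difference uncertainties add in quadrature.
* **BAR** solves the self-consistent acceptance-ratio equation
  Σ_F f(M + β(W_F − ΔG)) = Σ_R f(−M + β(W_R + ΔG)) (f the Fermi function,
  M = ln N_F/N_R) by Brent root-finding to 1e-10 kcal/mol, bracketed from
  the forward/reverse exponential-average seeds; the uncertainty is the
  standard asymptotic variance from the Fermi weights. Poor
  forward/reverse overlap (mean acceptance < 1e-6) emits a warning with
  the overlap measure.
* **Error decomposition** solves σ_tot² = δ_exp² + δ_MD² + δ_model² for
  the model error; infeasible inputs raise.

## Synthetic data

The generators emulate the statistical structure of the study inputs, with
defaults fixed to the study conditions: 35 fitting records; ground-truth
coefficients (0.020, 0.25, −4); component spreads matched to the fitting
table (PB ~ N(2, 1.5²) kcal/mol, vdW ~ N(1.5, 2.5²) kcal/mol, surface ~
N(0, 40²) Å²); 0.4 kcal/mol gaussian noise on the targets (the order of
the combined model and measurement error); 9/35 of records scored against
the secondary reference. Synthetic reference rows have zero components
(unlike the real secondary reference, whose printed components are nonzero
— the correction removes their effect either way), and restraint energies
are zero. Torsion trajectories are two-state Markov chains with a
prescribed stationary folded probability and mean folded dwell time
(default 10 frames), emitting uniform β-region torsions when folded and
one violating residue otherwise — they model occupancy statistics, not
real torsional dynamics. Work samples are Crooks-consistent gaussians with
closed-form ΔG = μ − σ²β/2. Toy structures include sphere pairs, ideal
strands/helices built by internal-coordinate (NeRF) construction at exact
target torsions, and random dimers; ideal bond lengths/angles are the
standard backbone values and ω is fixed trans.

What passing tests on these generators show — and what they do not: they
verify the estimators' statistical and geometric correctness under known
ground truth, but say nothing about force-field accuracy, sampling
convergence, or conformational effects in real complexes, which enter the
package only through the fixed component tables.

## Numerical choices and problem sizes

Least squares is solved by `lstsq` (SVD); the scrambled ensemble refits
all models in one vectorised closed-form pass (a 100,000-model ensemble
takes about a second). The packaged analyses use the study's own sizes:
35 fitting records, 100,000 scrambled models, 8 folds × 20 seeds for
cross-validation, 10,000 work samples for the BAR checks. The acceptance
script derives all child seeds from a single `--seed`.

## Known limitations

* The per-complex components are fixed inputs; the package cannot
  regenerate them, so the GB-based and LK-based model variants of the
  original analysis (whose per-complex components are not published) are
  not reproducible and are out of scope.
* The scrambled-ensemble "fraction worse" is reproduced at ~99.99% versus
  the published 99.94%; the ~0.05-point offset exceeds binomial noise and
  reflects unrecorded details of the original ensemble procedure.
* The very weak (millimolar) binders are excluded from fitting by
  construction, and the model is not expected to score them.
* The lower-bound affinities are treated as equalities at the common
  bound, which slightly regularises the fit.
* Default atomic parameters for the toy energetics are plausible
  per-element values for testing geometry and limits, not a validated
  solvation parameter set.
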