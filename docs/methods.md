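# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The activity model and its construction

The QSAR model is ordinary multiple linear regression of pIC50
(−log10 molar IC50) on a fixed-size subset of molecular descriptors:

    pIC50 = b0 + Σ_j b_j d_j

**Preprocessing.** Columns with missing values are dropped; then columns
with variance ≤ `variance_floor` (default 1e-8); then, for every pair with
|Pearson r| above `intercorrelation_cap` (default 0.95), the member with the
larger mean absolute correlation to the remaining columns. Both thresholds
are conventional chemometrics defaults and configurable; the removal log
names every dropped column and reason, so the choice is auditable.

**Kennard–Stone split.** Classic max–min selection on Euclidean distance in
descriptor space (autoscaled by default; the raw-space variant is a flag,
since either order is defensible and the field uses both). The two mutually
most distant compounds seed the training set; each step adds the compound
whose minimum distance to the selected set is largest. Exact distance ties
are broken by lexicographic compound-id order — a rule chosen because it
does not depend on row order, which makes the split provably invariant to
shuffling the input. Ties at floating-point exactness essentially occur only
for duplicated points.

**GA descriptor selection.** Chromosomes are descriptor subsets of fixed
size (default 8). Defaults mirror the study conditions: 1000 generations,
crossover probability 1, per-gene replacement mutation probability 0.5,
100 initial subsets, 3 elitist survivors per generation. Offspring come
from single-point crossover of two survivor parents over sorted gene lists,
with duplicate genes repaired by resampling from unused descriptors. The
fitness criterion is selectable (`q2_loo` default, `r2_adj`, `mae`);
LOO Q² is the default because internal cross-validation is what the final
models are judged on. Fitness values are memoized per subset, the
best-fitness trace is monotone non-decreasing under elitism, and runs are
fully reproducible from the config seed. An optional `early_stop_fitness`
halts the search when a known optimum (e.g. Q² = 1 on noiseless data) is
reached; on a noiseless 330 × 564 planted problem the search typically
reaches the optimum within a few thousand generations.

**MLR fit.** Least squares via QR with an intercept; standard errors from
the residual variance RSS/(n − p) (p = terms including intercept) and the
inverse normal-equations matrix. The coefficient uncertainties are reported
as standard errors to mirror the "±" convention of published equation
forms; rank-deficient designs raise an error naming the collinear columns.
With `autoscale`, per-descriptor (mean, SD) pairs are stored in the model so
predictions on raw descriptor values are exactly reproducible.

## Validation battery

* **Internal:** r², adjusted r², SEE with the n − p denominator, PRESS by
  the exact leverage identity `e_i/(1 − h_i)` (equal to n explicit refits to
  machine precision — a property the tests verify by brute force), Q²_LOO =
  1 − PRESS/SS_tot, and the rm² metrics on the LOO predictions.
* **Through-origin statistics:** k = Σy_obs·y_pred / Σy_pred²,
  k′ = Σy_obs·y_pred / Σy_obs²; r0² compares k·y_pred with y_pred against
  y_pred's spread, r0′² symmetrically on y_obs. These coefficients are not
  bounded below by zero for bad fits and are deliberately not clamped.
* **rm² family:** rm² = r²(1 − √(r² − r0²)) and its primed counterpart,
  averaged and differenced. The radical form is used; a radicand pushed
  negative by rounding is clamped at zero and flagged. The "after scaling"
  variant min–max scales observed and predicted values to [0, 1] on their
  combined range — the convention is stated here because published tables
  print only the scaled results. Note the unscaled and scaled values
  coincide whenever both radicands clamp (r0² ≥ r² on both axes).
* **External:** r² (squared Pearson), RMSEP, Q²_f1 = 1 − SSE/Σ(y − ȳ_train)²
  and Q²_f2 with the test mean (the standard definitions; the source table
  labels them without printing formulas), MAE and SD of absolute errors
  after dropping the ⌈5%⌉ largest ("95% data"), with the error-based
  verdict: GOOD iff MAE₉₅ ≤ 0.1·range and MAE₉₅ + 3·SD₉₅ ≤ 0.2·range, BAD
  iff MAE₉₅ > 0.15·range or MAE₉₅ + 3·SD₉₅ > 0.25·range, else MODERATE,
  where range is the training-activity range.
* **Acceptability conditions:** Q² > 0.5; R² > 0.6; the slope/ratio branch
  ((R² − R0²)/R² < 0.1 with 0.85 ≤ k ≤ 1.15, either axis); |R0² − R0′²| <
  0.3; and closeness of R0² or R0′² to R², implemented as the same ratio
  test since no separate numeric threshold is published for it.

**Applicability domain.** Leverages from the training design on the model's
scaling; warning leverage h* = 3p/n; response domain ±3 standardized
residuals. The standardized-residual denominator is the training SEE for
training compounds and the test RMSEP for query compounds — the source
material does not define it, and using each set's own error scale keeps the
±3 band meaningful on both. In-domain ⇔ h ≤ h* and |standardized residual|
≤ 3; the Williams table (id, leverage, std_residual, set, in_domain)
exports as TSV.

## Conceptual-DFT descriptors

ΔE = E_LUMO − E_HOMO, IP = −E_HOMO, EA = −E_LUMO, χ = (IP + EA)/2,
η = (IP − EA)/2, μ = −χ, ω = μ²/2η. Softness is convention-dependent:
the package defaults to ξ = 1/η because that is what the source study's
printed values follow (η = 2.07 eV pairs with ξ = 0.48 eV⁻¹), even though
its text writes ξ = 1/2η; the literal convention is selectable. Inverted
gaps (HOMO ≥ LUMO) are computed with a flag rather than rejected; η = 0
leaves ξ and ω undefined (NaN, flagged).

## MM-GBSA bookkeeping

The end-state decomposition is audited against
ΔG_gas = ΔE_vdW + ΔE_elec, ΔG_solv = ΔE_GB + ΔE_surf,
ΔG_bind = ΔG_gas + ΔG_solv. The default tolerance 0.02 kcal/mol is half a
unit in the last digit on each of three 2-decimal operands; it is
configurable because machine-precision inputs warrant ~1e-9 and tables
printed to 1 decimal need more slack. Reported "±" spreads are carried
through but not propagated into residuals (no error-propagation rule is
published for them). Several rows of the packaged energy table do **not**
close at 0.02 — their printed components are internally inconsistent by up
to 0.64 kcal/mol — and the fixture loader flags exactly those rows rather
than rejecting or correcting them: the fixtures are a record of what was
printed. Per-residue rankings sort ascending by energy (most stabilizing
first) with ties broken by residue number. Entropy terms (−TΔS) are out of
scope, matching the upstream tables.

On the discrepant reference value for ursolic acid (−24.95 vs −23.95
kcal/mol in different source tables): both are retained in their respective
fixtures; the post-dynamics hydrogen-bond correlation reproduces the printed
−0.923 only with −24.95, while the softness correlation reproduces −0.89
with −23.95, so each table is internally consistent with its own value.

## Unit conversions

IC50 [mol/dm³] = 10^(−pIC50); IC50 [μg/ml] = molar × MW × 1000. Recomputing
the printed lead-table columns from the printed (already rounded) pIC50
double-rounds, which can shift the last printed digit by one unit; the
row-by-row checks therefore allow exactly one unit in the last printed
digit. Published model coefficients applied to raw descriptor values do not
reproduce the published predictions — the descriptor scaling behind them is
undisclosed and unrecoverable — so the printed predictions are treated as
reference data, never as a recomputation target, and `apply_model` runs on
raw values without attempting any silent correction. Predictions outside
the model's training activity range are flagged as extrapolations but
returned.

## Dose–response

Percentage inhibition = (A_blank − A_test)/A_blank × 100, scale free in the
absorbance units. IC50 fitting minimizes least squares of inhibition against
log10 concentration under the four-parameter logistic or the normalized
two-parameter variant (bottom 0, top 100 — the default, matching normalized
inhibition plots). Initialization is multistart over the tested
concentration quantiles (25/50/75%) crossed with Hill slopes {0.5, 1, 2};
the best converged start wins, and non-convergence from every start raises
with the best residual. Asymptotic standard errors for IC50 come from the
delta method on log10 IC50. Whether published "normalized" curves were
rescaled to span [0, 100] before fitting is not stated, so both behaviors
are exposed (`rescale_span`). Negative fitted Hill slopes and estimates
outside the tested concentration range are flagged, not silently accepted.

## Synthetic data: what it emulates and what it does not

`gen_qsar_dataset` plants a sparse linear signal (default 8 informative
columns, coefficient magnitudes ~0.7–2.5, intercept 6.0 so activities fall
in a realistic 4–9 pIC50 band, residual SD 0.2 pIC50 units) in a matrix of
standard-normal descriptors, optionally with rho-correlated redundant
copies. Default dimensions 330 × 564 match the study-scale training matrix.
It does **not** emulate the heterogeneous scales, discreteness or heavy
tails of real PaDEL descriptor families (an optional per-column scale
multiplier exists but defaults off, keeping the zero-noise oracle checks
exact). Consequently, passing recovery tests show the pipeline's machinery
is correct and well-calibrated under the assumed linear-plus-noise model;
they do not show that an 8-descriptor linear form suffices for any real
target. `gen_dose_response` assumes Gaussian replicate noise that is
homoscedastic across concentrations, which real plate assays only
approximate. `gen_energy_table` draws components around magnitudes typical
of the study's complexes and computes aggregates exactly, so it cannot
exhibit the printed-rounding inconsistencies real tables carry.

Problem sizes in the test suite follow the study conditions where they are
stated (330/68 splits, equation length 8, GA population 100 with 3
survivors); the noisy GA-recovery check runs 200 generations on a 60-column
matrix over 10 seeds, a size at which pilot runs recover ≥ 6 of 8 planted
descriptors in every seed, and the noiseless full-size (564-column) run
uses early stopping at Q² = 1.

## Known limitations

* The GA is a faithful generic implementation of the published parameter
  settings, not a reimplementation of any specific tool's internals; exact
  selection trajectories will differ.
* Descriptor computation from structures, docking, MD, per-frame MM-GBSA
  and DFT orbital energies are upstream producers; this package consumes
  their tabular outputs only.
* The trimmed-MAE verdict and the Q²_f1/f2 formulas follow the standard
  literature definitions cited above; sources that print only verdicts or
  labels cannot confirm every convention choice.
* Through-origin statistics can be degenerate for constant vectors; these
  raise rather than returning NaN.
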