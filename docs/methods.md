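# Methods

## Model

A molecule is represented by a set of *microstates* — each a specific
tautomer at a specific formal charge — with standard-state free energies
ΔG⁰ⱼₖ (pH 0, kcal/mol) relative to one designated neutral reference
microstate *k*. The pH dependence enters only through the proton count:

    ΔG_jk(pH) = ΔG⁰_jk + Δm_jk · C · pH,   C = RT ln 10,   Δm_jk = q(j) − q(k).

Populations are Boltzmann fractions over all microstates with a defined
ΔG⁰ (the reference contributes ΔG = 0); summing over formal charge gives
titration curves, and the pH where two *adjacent* charge groups are equally
populated is the macroscopic pKa. Because the shared normalization cancels
at a crossing, the same quantity has the closed form
log10(Z_q/Z_{q−1}) with Z_q the pH-0 within-group partition function; for
adjacent charges the population difference has exactly one zero, so
titration and closed form are two routes to one number. The package
computes both and its tests require agreement to 1e-6 pH units.

ΔG⁰ networks can be assembled from microscopic inputs by summing edge
contributions along any path from the reference: a tautomerization edge
contributes m·ΔG (slope factor m, default 1, applied to tautomer edges
only — micro-pKa inputs from regression-corrected methods already carry
their slope), a single deprotonation +C·pKa, a single protonation −C·pKa,
and multi-proton transitions chain single steps. Redundant paths are a
feature, not an error: they encode thermodynamic cycles, which must close
for a consistent method. Path disagreements beyond 1e-6 kcal/mol raise an
error carrying the worst gap, and `cycle_closure_report` quantifies closure
over an independent cycle basis of the edge graph (via networkx) without
raising.

Distribution coefficients assume ionic species do not partition into the
organic phase: logD(pH) = logP + log10(x_neutral). For a monoprotic acid or
base this reduces to the familiar `logP − log10(1 + 10^{±(pH−pKa)})` forms,
and the network route is required to match them to 1e-9. The correction
term is non-negative, so logD ≤ logP always. Experimental logP, pKa and
logD tables are mutually redundant under this model; real measurements are
not perfectly consistent that way, and the package reports such
discrepancies rather than resolving them.

## Numerical choices

* **Thermodynamic constants.** R = 1.98720425e-3 kcal/(mol·K), T = 298.15 K
  by default (configurable in `ThermoContext`); C = RT ln 10 ≈ 1.36434
  kcal/mol per pKa unit.
* **Populations** are computed with max-shift normalization (log-sum-exp),
  so |ΔG/RT| of several hundred — far beyond anything physical — cannot
  overflow; normalization holds to 1e-9.
* **Crossing search.** Charge-fraction differences are scanned on a pH grid
  (default window [−12, 20], step 0.01) for sign changes, each refined by
  Brent bisection to 1e-8 pH. A grid scan is robust to multiple crossings,
  unlike a single root-find from one guess. The window is deliberately
  generous beyond any experimentally plausible range so that badly wrong
  predictions still titrate; a crossing within one grid step of a window
  edge triggers a warning. Only adjacent charge pairs are titrated. A pair
  with no sign change in the window yields no crossing (not an error).
* **Declared-equivalent microstates** (e.g. a reference drawn with
  unspecified stereochemistry and its specified-stereochemistry
  counterpart) are collapsed to a single state before any population
  calculation, keeping the reference's ID, so they are not double-counted
  in partition functions.
* **Identifier conventions** (`SM##` / `SM##_micro###`) are enforced as
  warnings, not errors; the formal-charge window (default −4…+4) is
  configuration, not chemistry.

## Evaluation statistics

Errors are predicted − experimental (positive mean error = overprediction).
R² is the squared Pearson correlation, the convention of blind-challenge
practice; an identity-line coefficient of determination is available
separately since the two differ off the identity line. The slope is the OLS
slope of predicted on experimental. Kendall τ uses the tau-b variant so
tied predictions (common for empirical methods emitting identical values)
are handled. Degenerate inputs (zero variance) yield NaN markers, never
exceptions.

Confidence intervals are percentile bootstrap over molecules, 10,000
resamples and 95% level by default, seeded and bit-reproducible; the
simplest method consistent with bootstrapping-over-molecules practice
(BCa was considered and rejected as an unneeded complication at n ≈ 22).
Resamples that are degenerate for a correlation metric are skipped and
counted. The percentile interval is widened, if necessary, to contain the
full-data point estimate so reports always satisfy ci_low ≤ point ≤
ci_high. At n = 22 the percentile bootstrap is known to undercover
slightly; the acceptance suite measures ~89% empirical coverage of the true
RMSE at the 95% nominal level, within the ±10% band the tests demand.

Predicted macroscopic pKas are paired with experimental ones by
minimum-total-absolute-difference assignment (Hungarian algorithm;
exhaustively verified against brute-force enumeration for all list sizes
≤ 6). Surplus values on either side are reported as unmatched in a
completeness table rather than converted into penalized errors, since no
principled penalty exists.

Consistent-ranking shortlists intersect the top-N methods by ascending
RMSE and MAE with the top-N by descending R² and τ; ties at the boundary
include all tied methods. Null baselines: constant logP 2.66 for every
compound, and equal partitioning (logD 0) for distribution.

Sign-agreement entropy per transition is H = −Σ Pᵢ ln Pᵢ over positive /
negative / exactly-zero predictions with 0·ln 0 = 0. The fractions divide
by the full method cohort by default, so an omitted prediction dilutes all
three fractions (they can sum to less than one) — this is the convention
under which a 10-method cohort splitting 5/4/1-omitted gives H ≈ 0.713.
Dividing by reporting methods only is available behind a flag; treating
omissions as a fourth outcome class was considered and rejected because an
omission is absence of a prediction, not a prediction.

## Synthetic cohorts

The generator emulates a blind challenge: 22 molecules by default, formal
charges spanning a random sub-range of −2…+2 (always including 0), 1–4
tautomers per charge with spreads up to 2 kcal/mol, a 10-method cohort with
0.5 kcal/mol Gaussian free-energy noise, optional per-method bias, a 10%
omission rate, and an optional fraction of exact-zero predictions. True
ΔG⁰ values are constructed by sampling target macroscopic pKas uniformly in
2–12 (bracketing a realistic experimental span) and inverting them through
the partition-function relation — group levels are solved so the analytic
pKa of every adjacent pair equals its target exactly — which guarantees
titratable networks, unlike sampling free energies directly.
`fixed_charge_span=True` makes every molecule span the full charge range
(used for uniformly monoprotic recovery cohorts, where free-energy noise σ
propagates to pKa errors of exactly σ/C). Experimental tables take the
networks' exact macroscopic pKas, logP uniform in 0.58–2.96 (a realistic
measured span for drug-like solutes), and logD derived from logP and the
true speciation at pH 7.4 — so a zero-noise cohort scores exactly zero
error end to end, and that invariant is tested.

All randomness descends from a single integer seed through fixed-lane
`numpy` seed sequences, so networks, method cohorts and experimental tables
are independently reproducible.

What the generator does **not** emulate: real chemistry (SMILES strings are
placeholders), correlated errors between methods, molecule-dependent error
magnitudes, systematic tautomer-enumeration mistakes, or
experiment-internal inconsistency between logP, pKa and logD. Passing
recovery tests therefore demonstrates correctness of the pipeline's
arithmetic and statistics under stated noise models, not predictive skill
on real compounds.

## File formats

Submissions and tables are flat CSV with an optional leading block of
`# key: value` metadata lines (method name, category, ranked flag, unit,
notes). The dialect is this package's own, documented in `macropka.io`;
it mirrors the *fields* of challenge submission templates without claiming
byte compatibility with any historical archive. Free energies are
canonically kcal/mol; kJ/mol and pKa-unit declarations are converted at
read time. Transitions must be defined away from the declared neutral
reference (a directional-convention error otherwise); duplicate
transitions, self-transitions and truncated files (when a row count is
declared) are rejected; a submitted target charge disagreeing with the
microstate table warns by default and fails under `--strict`. Experimental
values outside loose plausibility windows warn but never fail.

## Limitations

* Only adjacent-charge crossings are reported; non-adjacent "crossings"
  have no macroscopic meaning here.
* The intercept parameter of regression-corrected quantum-chemistry
  pipelines has no role when consuming submitted ΔG⁰ values (methods absorb
  it before submission); the closed-form derivation fixes it to zero.
* Ion-pair partitioning and wet-octanol mutual solubility are outside the
  logD model by assumption.
* Microstate enumeration from structures is out of scope: microstate
  tables are inputs.
* Scoring cannot reproduce any real challenge's headline numbers without
  that challenge's submission corpus and experimental tables; the package
  ships simulation-based verification instead.
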