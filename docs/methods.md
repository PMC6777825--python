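# Methods

## The model

A reversibly unfolding protein whose ligand binds the native state melts at
a higher temperature in the ligand's presence. For a two-state transition
the shift obeys the Schellman relation

    ΔTm = Tm − T0 = (Tm·T0·R/ΔH⁰) · ln(1 + [L]/Kd-app)

with [L] the ligand concentration, T0 the ligand-free apparent melting
temperature, ΔH⁰ the van 't Hoff enthalpy of unfolding at T0 (assumed
temperature-independent over the shifts considered), R the gas constant
(1.9872×10⁻³ kcal·mol⁻¹·K⁻¹), and Kd-app the apparent dissociation
constant. Because Tm appears on both sides the relation is implicit, but it
rearranges exactly to

    Tm = T0 / (1 − T0·R·ln(1 + [L]/Kd-app)/ΔH⁰)

valid while the denominator is positive; shifts that would require a
non-positive denominator are outside the model and raise a dedicated
infeasibility error naming the offending term. The closed form is verified
against numeric root-finding of the implicit equation in the test suite.

Assumptions worth stating: unfolding is treated as reversible and two-state;
Kd-app is assumed not to vary over the shift; no ΔCp curvature, no
ligand-depletion correction, and no modeling of the ligand-insensitive first
transition of biphasic curves. These mirror the standard simplifications of
thermal-shift Kd estimation and bound what the numbers mean: Kd-app is an
apparent constant at the (elevated) melting temperature, not a
physiological-temperature affinity.

## Tm calling

Apparent Tm is defined as the temperature of the maximum of dF/dT. The
derivative is computed by a Savitzky–Golay filter (order 2, default window
1.0 °C ≈ 5 samples at the 0.2 °C grid) evaluated with its analytic first
derivative, so linear ramps differentiate to exact constants. The
half-window edge samples are discarded: their extrapolated values carry
inflated noise variance.

Vendor melt-analysis software does not disclose its peak logic, so peak
retention here is explicit and configurable:

* **Noise estimate.** Raw fluorescence noise σ is estimated robustly from
  second differences (MAD-based, insensitive to baselines, transitions and
  quench) and propagated through the known derivative-filter coefficients to
  a derivative-scale σ_f.
* **Detection floor.** A curve whose global derivative maximum is below
  6·σ_f carries no detectable transition (a state, not an exception); pure
  white-noise traces are rejected by this rule across seeds.
* **Peak retention.** A local maximum is retained when its topographic
  prominence is at least `prominence_frac` (default 0.10) of the global
  derivative maximum *and* at least 8·σ_f. The absolute floor matters
  because the rightmost retained peak is the one adopted: a single stray
  noise bump to the right of the true transition would otherwise corrupt the
  call. On the simulator, spurious noise-peak prominences reach ≈7σ_f across
  seeds while genuine secondary transitions sit at ≥10σ_f at default noise,
  which is how the 8σ_f default was placed.
* **Merging.** Peaks closer than `min_separation` (default 2 °C) are merged,
  keeping the higher. Retained peak positions are refined off-grid by a
  quadratic fit through the three samples around each maximum.
* **Adoption.** Two or more retained peaks mark the curve biphasic; the
  rightmost peak is adopted as the apparent Tm, since that is the transition
  that tracks ligand dose in this system. Curves whose derivative maximum
  sits at a grid boundary are flagged unusable rather than extrapolated.

Tm calling is invariant to affine rescaling of fluorescence (both thresholds
are relative; the noise floor scales with the data).

T0 is taken as the mean adopted Tm of the same plate's buffer-only wells
(concentration 0), or a fixed kelvin value by configuration. Downstream of
replicate averaging all temperatures are kelvin; °C appears only at I/O
boundaries.

## Kd estimation

**Dose-series fit.** Replicate-averaged Tm values across ≥4 distinct
concentrations are fitted to the closed form by unweighted least squares
with T0 fixed, (Kd-app, ΔH⁰) free. Positivity is enforced by optimizing in
log space; initialization is a small multistart (Kd₀ = the concentration
nearest half-maximal shift; ΔH⁰ from 40, 70, 100 kcal·mol⁻¹), keeping the
best residual. Standard errors come from the Jacobian covariance at the
optimum via the delta method. Residuals are taken in Tm (identical to ΔTm
residuals at fixed T0). Series whose maximal shift is under 0.5 K are
refused (nothing to fit); non-convergence is reported honestly in the
`converged` flag. Fitting mean Tm unweighted matches the originating assay
convention; s.e.m. weights were considered and left out as the default.

**Single-point inversion.** With Tm = T0 + ΔTm the relation inverts exactly:

    Kd-app = [L] / (exp(ΔTm·ΔH⁰ / (R·Tm·T0)) − 1)

using fixed T0 = 326.1 K and ΔH⁰ = 72.1 kcal·mol⁻¹ (the mean of dose-series
fits). Each estimate is classified by its shift: <0 destabilized, <1 K below
the reporting floor, 6–11 K preferred, 2–11 K acceptable, otherwise out of
range (1, 2, 6, 11 K are named configuration constants — they were set
empirically, not derived). Per ligand, the reported estimate is the lowest
concentration in the preferred window, else the highest concentration in the
acceptable window, else the ligand is excluded (destabilized / below floor),
with the applied rule recorded.

Robustness of the inversion: with the assumed ΔH⁰ off by ±20%, estimates
taken from the preferred window stay within a factor 2 of the true Kd for
shifts up to ≈9.5 K, degrading to ≈2.1 at the 11 K window edge (measured
over a grid of true Kd 10–422 μM). The shift is *not* concave in ln[L]: it
inherits the softplus shape of ln(1+[L]/Kd) — convex below Kd, near-linear
per decade far above — which the property tests assert.

## Receptor response

EC50 is estimated from a single response measurement by inverting a Hill
relation (coefficient fixed at 1 — the underlying relation carries no
exponent) with the maximal response fixed at ΔRFUmax = 104.3:
EC50 = [L]·(ΔRFUmax − ΔRFU)/ΔRFU. Non-positive responses are excluded;
responses at or above the maximum are flagged saturated (the max-defining
ligand cannot yield a finite estimate at that concentration) and are kept
out of downstream correlation. p-scales (pKd, pEC50) are −log₁₀ of the
molar value; the base unit only adds a constant, so correlations are
unaffected by the choice.

## Association

Binding and response tables are inner-joined on ligand id. Raw mode pairs
ΔTm with ΔRFU at a shared concentration (default 10 mM; destabilized ligands
contribute their negative shifts). p-scale mode pairs pKd from usable
adopted estimates with pEC50 from status-ok estimates; every exclusion is
recorded with its reason. Pearson's r is used (the relations examined are
linear on the p-scale); swapping axes or permuting rows cannot change it.

The QSAR stage regresses pKd on every subset of one or two of six side-chain
descriptors by OLS, reporting the multiple correlation r, standard error of
estimate s, overall F and its p-value, with significance at α = 0.05.
Enumeration is capped at two terms, as is standard at n ≈ 15. Near-collinear
subsets (design condition number > 10⁸) are skipped with a log entry. The
number of models tried is reported but no multiplicity correction is
applied, matching classical QSAR practice — a documented caveat: with ~21
correlated models per search, the family-wise chance of a nominally
significant null model is roughly 25–30%, so a single nominal hit in a
search of this size is weak evidence.

## Descriptor table

One row per proteinogenic l-amino acid side chain, six columns from standard
published scales: hydrophobicity (Fauchère–Pliška side-chain π),
hydration (Wolfenden vapor→water transfer free energy, kcal·mol⁻¹),
polarity (Grantham), hydropathy (Kyte–Doolittle), formal side-chain charge
at pH 7 (His neutral), and volume (Zamyatnin residue volume, Å³). Proline is
omitted: its secondary amine leaves the side-chain hydration scale undefined
and it is excluded from the affinity regressions in any case.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
ground truth retrievable for every object:

* **Melt curves.** F(T) = [b₀ + b₁·T + Σᵢ Aᵢ·fᵢ(T)]·exp(−q·(T−(maxTmᵢ+δ))⁺) + ε,
  where fᵢ is the two-state van 't Hoff unfolded fraction (exactly ½ at Tm;
  default transition enthalpy 120 kcal·mol⁻¹, steep as real dye transitions
  are). The exponential quench (default q = 0.01/°C) mimics dye release
  above the last transition; its onset is delayed δ = 3 °C past the last Tm
  because an onset at Tm itself drags the derivative maximum down by up to
  ~0.5 °C, and the quench is meant to shape the curve, not bias Tm. The
  derivative-maximum definition then recovers each tm_true to well within
  one 0.2 °C grid step at zero noise (the residual 1/T² skew of the van 't
  Hoff logistic is ≈0.04 °C at the default enthalpy). Grid: 25→99 °C in
  0.2 °C steps (371 points), the instrument ramp.
* **Plates.** Buffer wells carry one transition at 53.0 °C (the ligand-free
  ground truth). Agonist wells carry the Schellman-shifted second transition
  plus a fixed ligand-insensitive first transition at 50 °C (amplitude 0.6)
  when biphasic mode is on. Destabilizers lower Tm linearly in log dose
  (default −1 K/decade, referenced to 100 μM) — a phenomenological stand-in,
  since no thermodynamic model of destabilization is assumed; inert ligands
  leave the curve unchanged. Plate noise is Gaussian on fluorescence
  (default 0.002 AU = 0.2% of transition amplitude), which puts the Tm-call
  s.e.m. of 7 buffer wells at the 0.07–0.2 °C scale observed in practice
  while keeping biphasic detection reliable.
* **Dose series.** Noise is applied to Tm directly (default σ = 0.3 K).
  Having two distinct noise injection points — fluorescence at the plate
  level, Tm at the series level — keeps caller error and fit error separable
  in tests.
* **Responses.** ΔRFU from the Hill relation plus Gaussian noise; noise may
  push values negative, exercising the exclusion rule.

All randomness flows from explicit integer seeds (per-well seeds are spawned
from one root generator); there is no global random state. What the
generator does *not* emulate: dye-binding kinetics, ΔCp-dependent curvature,
scan-rate dependence, irreversible aggregation, well-position effects, or
any mechanistic model of destabilization — so passing tests demonstrate
correctness of the analysis under the stated model, not robustness to those
real-data phenomena.

## Problem sizes and determinism

The parameter-recovery studies use 200 seeded dose series per regime
(6 replicates at 8 concentrations, or 4 at 9), fitted in a few seconds; the
Monte-Carlo checks of the Tm caller and the null-QSAR tendency use 20–100
seeded repetitions. Identical configuration and seed produce byte-identical
pipeline reports.

## Known limitations

* Kd-app from destabilizing ligands is not defined; they are classified and
  excluded, never quantified.
* The biphasic/monophasic decision depends on the explicit prominence rule;
  vendor software may resolve borderline curves differently.
* The single-point estimator inherits any error in the fixed (T0, ΔH⁰)
  pair; the window rules bound but do not remove this.
* The uncorrected QSAR enumeration overstates nominal significance (see
  above).
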