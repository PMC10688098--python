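# Methods

## Model

A monoprotic ionizable compound is described by three coexisting forms:
the dissolved charged form, the dissolved neutral form and the aggregated
(undissolved) neutral form, the last entering the equilibria through its
*active concentration* — amount of aggregate divided by solution volume,
treated as a thermodynamic species rather than an inert phase of unit
activity.  Mass balance over the three forms,

    C = [N] + [Q] + [N↓],

is coupled to proton dissociation of the single ionizable site,

    Ka = [Q][H+]/[N]          (acids: N protonated, Q the anion)
    Ka = [N][H+]/[Q]          (bases: N deprotonated, Q the cation)

and to the dissolution–aggregation law

    [N↓] = A · C · [N],   A = 1/S.

The aggregation constant A is inversely proportional to the intrinsic
solubility S.  This particular mass-action form has three properties that
motivate it:

1. the dissolved neutral concentration `[N] = C/(1 + Ka/[H+] + A·C)`
   saturates at `1/A = S` as `C → ∞` — S is exactly the saturating
   concentration of the neutral form, i.e. the definition of intrinsic
   solubility;
2. all three forms coexist at every pH and every total concentration (the
   aggregate is not a sharp saturation threshold switched on above S, and
   it participates in every linked equilibrium);
3. speciation is closed-form in (A, C, pH), and at a fixed total
   concentration the full titration curve is *exactly* the no-aggregation
   curve of an apparent constant `Ka_app = Ka/(1 + A·C)`, giving

       pKa_obs = pKa + log10(1 + C/S)   (acids; bases mirrored with −).

   The shift therefore vanishes at infinite dilution, grows without bound
   with C, and equals log10 2 ≈ 0.301 when the total concentration equals
   the intrinsic solubility.

Polarity determines the direction: for acids the aggregation-prone neutral
form is protonated and the shift runs alkaline; for bases it is
deprotonated and the shift runs acidic.  Base compounds use an explicitly
mirrored equation set (pre-acidification with HCl, titration with NaOH),
not sign tricks on the acid code.

Assumptions: one ionizable site (polyprotic compounds out of scope); ideal
solution, activity coefficients 1 even at the 50–175 mM ionic strengths of
universal buffers; equilibrium throughout (no supersaturation kinetics);
temperature fixed (pKw default 13.997, the 25 °C value, configurable).

## pH solver

Unbuffered pH follows from electroneutrality over Na⁺, H⁺, Cl⁻, OH⁻ and
the compound's charged form.  The residual is strictly monotone
(decreasing) in pH for both polarities, so the root on (0, pKw) is unique.
It is found by bracketed bisection — 80 lockstep iterations, vectorized
over whole composition grids, converging to float precision in pH so the
residual of a returned state sits at rounding level (≪ 1e−12 mol/L).  No
derivative iteration is used; robustness was preferred over per-call
speed, and vectorization recovers throughput (a 26-point titration solves
in one call).  A composition whose residual does not change sign on
(0, pKw) — e.g. molar-scale excess strong base — raises a diagnostic error
rather than extrapolating.

A unit test re-derives the implicit titration equation symbolically
(sympy) from the raw system — mass balance, both mass-action laws, the
water product and electroneutrality — and confirms the solver's residual
matches the eliminated form, guarding against transcription error in the
closed-form speciation.

## Titration design and observed pKa

The standard emulated design: 2.5 mL of analyte, the compound pre-charged
with 1.5 equivalents of strong base (acids; strong acid for bases), then
25 aliquots of 10 μL of strong titrant.  The titrant concentration is
chosen so the full schedule delivers 2.5 equivalents, spanning the
transition that runs between 0.5 and 1.5 delivered equivalents; a 10×
titrant (1.0 equivalent total) would end at the half-protonation point.
Dilution is always corrected exactly: moles of Na, Cl and compound are
conserved and divided by the running volume (≈10% cumulative).

"Observed pKa" is operationally defined as the least-squares best-fit pKa
of the A = 0 model re-simulated on the curve's own schedule, pKa the only
free parameter, squared pH residuals (pH is the measured quantity;
delivered volume is controlled), the pre-injection point included.  A
Bjerrum midpoint (pH at 0.5 bound protons per molecule) is the secondary
extraction and agrees with the fit within 0.05 pH on noiseless data; which
extraction a given laboratory uses is rarely reported, so both are
provided.  A fit whose RMSE exceeds a quarter of the curve's pH span is
rejected as "no transition".

Bjerrum plots use `n_bound = ([strong acid] − [strong base] − [H+] +
[OH−])/C + r`, dilution-corrected, with the reference level r = 1 for the
acid protocol and r = 0 for the base protocol so that the fully
deprotonated state maps to zero.  The inverse transform (titrant
equivalents from (pH, n_bound) pairs) is closed-form — the running volume
is linear in delivered titrant — and round-trips to 1e−9; it needs the
setup metadata (pre-added equivalents, titrant concentration, initial
volume), so it takes the `TitrationSetup`, not a bare concentration.

## Spectrophotometry

Samples are centrifuged before measurement, so only the two dissolved
species absorb; generated absorbance is Beer–Lambert (1 cm path) over the
dissolved charged and neutral concentrations only, never the aggregate.
The analysis wavelength defaults to the contrast maximum between the pH
extremes (never an isosbestic point) and can be overridden.  Min–max
normalization across the pH series removes gain and offset; the observed
pKa is the midpoint of the single-site sigmoid `1/(1 + 10^{±(pKa_obs −
pH)})`, with the branch orientation inferred from the data so either
species may be the stronger absorber.

## Fitting

Intrinsic parameters are estimated in `(pKa, log10 S)` space (positivity
and conditioning) by bounded trust-region least squares with a fixed set
of 5 deterministic restarts.  Raw-curve fits share one (pKa, S) across
curves at different concentrations — that sharing is what identifies S,
because a *single* fixed-C curve is indistinguishable from an ideal curve
of shifted pKa up to the small dilution drift.  Accordingly, after every
fit an A = 0 profile comparison is run: if switching aggregation off and
refitting pKa alone costs less than 2% of the residual sum of squares, or
the S estimate sits at its bound, the result is flagged
`s_identifiable=False` (noisy single-curve data, data entirely below the
aggregation onset, or truly ideal compounds all land here).  Poor fits of
a shift table (RMSE > 0.1 pH, e.g. wrong polarity) are flagged via
`converged=False`.

Default initialization: pKa from the lowest-concentration observation,
log10 S from the concentration where the shift first exceeds 0.1 pH; both
overridable.  A per-curve pH electrode offset nuisance is available and
off by default.  Uncertainty is a case-resampling percentile bootstrap
(95%, default 200 resamples, seed mandatory): over points within curves
(multiplicity-weighted, equivalent to case resampling) for titration fits,
over concentrations for shift-table fits; degenerate resamples are redrawn
and logged.  Bootstrap refits start from the point estimate with a single
restart.

## Synthetic data

The generator emulates the three experimental designs with i.i.d. Gaussian
error: pH noise sd 0.01 on titration points (the electrode stability
criterion of the emulated protocol), absorbance noise sd 0.005 AU, and
pKa noise sd 0.01 on tabulated shift values.  The spectrophotometric
design uses the universal-buffer grid pH 4.5–10.5 in 0.5 steps and total
concentrations 0.025–2 mM; default extinction profiles are two Gaussian
bands (neutral 280 nm, charged 330 nm, ~10^4 L mol⁻¹ cm⁻¹) mimicking the
phenol → phenolate red shift, crossing at an isosbestic wavelength.  A
master seed derives an independent, reproducible stream per dataset, and
every artifact carries a truth record sufficient to rerun its fit.

What the generator does *not* emulate: instrument drift, electrode
hysteresis and junction potentials, CO₂ ingress, heteroscedastic or
correlated noise, co-solvent effects, and multi-site ionization.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to those systematic errors.

## Numerical choices and problem sizes

- Bisection depth 80 on (0+1e−9, pKw−1e−9); degenerate brackets raise.
- Apparent-pKa extraction: bounded golden-section minimization, xatol
  1e−7.
- Henderson–Hasselbalch limit holds to relative 1e−12 with A = 0; all
  speciation identities (mass balance, water product, mass action) hold to
  relative 1e−9 or better on solver outputs.
- Test-suite problem sizes: solver-versus-grid-search cross-checks use 100
  randomized systems at 1e−5 pH grid step; recovery studies use 2–3
  curves of 26 points; the bootstrap coverage smoke uses 50–100 resamples
  on one seeded dataset rather than a full replication study — the public
  API runs the full-size version unchanged.

## Known limitations

- The aggregation law is first-order in the dissolved neutral form and
  proportional to total concentration; cooperative effects (e.g. the
  proton give/take of bulk precipitation) are outside the model and show
  up as residual misfit at high supersaturation ratios.
- Shift-table fits treat tabulated observed pKa values as independent
  observations with equal weight.
- S is reported unbounded (flagged) rather than censored when the data
  carry no aggregation signal; downstream consumers should check
  `s_identifiable` before using the estimate.
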