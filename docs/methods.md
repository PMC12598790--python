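# Methods

`dnabind` implements the complete solution-phase workflow used to
characterize how a small drug molecule binds double-stranded DNA, plus the
voltammetric quantification method such a study validates. This note
records the models, the parameter choices, and the numerical decisions, and
states what the synthetic-data tests do and do not demonstrate.

## Binding models

**UV-vis, double-reciprocal (Benesi-Hildebrand) analysis.** A 1:1
complexation isotherm observed through the apparent extinction coefficient
`eps_a = A / (l * [DNA])` linearizes as

    x / (eps_a - eps_f) = x / (eps_b - eps_f) + 1 / (Kb * (eps_b - eps_f))

with `eps_f` taken from the zero-ligand point and x the titrant
concentration; `Kb = slope / intercept`. The classical presentation writes
x as [DNA]; because in this workflow the DNA is fixed (150 uM per
nucleotide) and the drug is varied (25-300 uM), the default regresses on
the drug axis (`mode="vary_ligand"`), with `vary_dna` retained for the
literal double-reciprocal reading; the two modes differ only in which
species is labelled as titrant, not in arithmetic. The standard error of
Kb comes from first-order propagation of the slope/intercept errors
including their covariance. A fit whose intercept is within 2 SE of zero
(a saturated titration) is flagged unreliable rather than reported.

The linearization assumes free ligand ~ total ligand. The generator
offers both that approximation (`free_ligand="total"`) and the exact 1:1
mass-action solution (the physical root of the binding quadratic). At the
study concentrations (Kb ~ 3e4 1/M, 150 uM DNA) the exact treatment
depletes the ligand severely and biases the double-reciprocal estimate low
by tens of percent; a dedicated test measures this bias instead of hiding
it. Recovery tests therefore generate with `"total"`, the model the
estimator itself assumes.

**Fluorescence quenching.** Stern-Volmer: `I0/I = 1 + Ksv*[Q]`, Ksv from
the slope with a freely fitted intercept (deviation from 1 beyond 0.1 is
warned about, not forced). Double-log: `log10((I0-I)/I) = log10 Kb +
n*log10 [Q]` with the zero-quencher point excluded; base-10 logs are used
on both sides so Kb is independent of the base convention. No inner-filter
correction is applied by default; a correction callable can be passed in.
Probe displacement compares Ksv for EtBr (intercalation probe) and Hoechst
33258 (minor-groove probe); a ratio of 5x in either direction names the
displaced probe, anything less is indeterminate.

**van't Hoff thermodynamics.** OLS of ln Kb on 1/T with R = 8.314
J/(mol K) and Kb treated as dimensionless against the implicit 1 M
standard state: `dH = -R*slope`, `dS = R*intercept`, `dG = dH - T*dS`.
With >= 4 temperatures a significant quadratic term in 1/T raises a
curvature warning (temperature-dependent enthalpy). Force classification
uses the conventional sign rules on the point estimates - (+,+)
hydrophobic, (-,-) van der Waals / hydrogen bonding, (-,+) electrostatic -
with an optional significance-aware mode requiring each sign to clear 2 SE.
Recomputing the worked example shows the tabulated dG values derive from
the rounded printed dH/dS (at 308.15 K: -26.46 kJ/mol) rather than from
-RT ln Kb; the two cooler temperatures then differ from the printed values
by 0.01 kJ/mol, a rounding artifact.

**Melting.** Four-parameter logistic
`A(T) = lower + (upper-lower)/(1+exp(-(T-Tm)/w))` fitted by
Levenberg-Marquardt, with a half-height linear-interpolation fallback
(plateaus = mean absorbance over the lowest/highest 15% of temperatures)
when the optimizer fails; the method used is recorded. Curves with
amplitude below 1e-6 of the absorbance scale raise a no-transition error;
so does a midpoint outside the measured range. The shift
`dTm = Tm(complex) - Tm(free)` is interpreted with tunable thresholds:
>= 10 C consistent with intercalation, <= 6 C with groove binding,
between them ambiguous. The 6 C default places the 5.4/5.6 C shifts of
groove-binding references on the groove side while the canonical "10-12 C"
intercalator stabilization sets the upper threshold. The EtBr reference
row is internally inconsistent in the source table (83.4 - 72.2 = 11.2,
printed as 11.6); `delta_tm` reports the subtraction.

**Viscometry and rheology.** Flow times reduce to the specific viscosity
`eta = (t - t0)/t0` (t0 = buffer flow time), presented as
`(eta/eta0)^(1/3)` against `r = [drug]/[DNA]` with eta0 from the
zero-ligand point; flow times below the buffer reference are flagged, not
dropped. The trend test is an OLS slope with a 95% t-interval: "flat" when
the interval covers zero or the predicted change over the observed r range
is below 0.05 cube-root units (an operationalization of "no significant
alteration"; tunable). Rheometer flow curves are fitted to the
Herschel-Bulkley model `tau = tau0 + K*gamma_dot**n` (the form implied by
the yield-stress / consistency / flow-index parameterization of the source
table, which never writes the equation) by bounded nonlinear least squares
with multi-start at n in {0.5, 1, 1.5}; the apparent viscosity
`tau(gamma*)/gamma*` requires a user-chosen shear rate because the source
does not state the one used for its viscosity column.

**Voltammetry.** Baseline estimation is an iterative moving-average lower
envelope: 50 fixed passes of "smooth, then take the pointwise minimum with
the signal", with odd-reflection padding so a straight ramp is reproduced
exactly at the edges. The pass count is fixed for determinism; the
correction is idempotent to well under 0.1%. Peak location takes the
maximum corrected current in a per-base search window (defaults 0.95-1.25 V
for dGuo, 1.25-1.50 V for dAdo, bracketing the +1.09/+1.36 V signals) with
parabolic refinement of the potential through the maximum and its
neighbours. A peak must rise above the sweep median by more than
3 sigma-scaled MADs (3 * 1.4826 * MAD) and above a numeric floor of 1e-9
of the pre-correction signal magnitude (carried in metadata), so pure
noise and floating-point ripple report "no peak". The binding regression
orients the printed relation as `y = log10(1/[drug])` on
`x = log10(S_complex/(S_free - S_complex))`, making log10 Kb the intercept;
the slope is theoretically 1 and a departure beyond 0.25 is warned about.

**Quantification.** Calibration is unweighted OLS of current (A) on
concentration (uM) with the n-2 residual SD; `LOD = 3*SD/|slope|`,
`LOQ = 10*SD/|slope|`, reported unrounded so their ratio is exactly 10/3.
The SD is the calibration residual SD (the standard regression-based
reading of those formulas); a blank-replicate SD can be substituted.
Note the printed pair (0.70, 2.31 uM) is not in a 3:10 ratio after 2-dp
rounding; the LOQ-implied LOD is 0.693 uM, which agrees at 1 dp.
Replicate statistics use the sample (n-1) SD throughout, which reproduces
the tabulated tablet SD 3.03 and recovery SD 18.17 (printed 18.16, a
truncation) exactly; recovery bias = mean recovery - 100. Predicted
concentrations invert the calibration line and are reported as-is (with a
warning if negative), never clipped. Externally studentized residuals
above 3 flag calibration outliers without removing them.

## Binding-mode inference

Six rules formalize the narrative synthesis of such studies, each casting
at most one vote: (R1) any method's Kb in [1e3, 1e5) votes groove, any
>= 1e6 votes intercalation (intercalation checked first); (R2) the dTm
interpretation; (R3) flat viscosity votes groove, increasing votes
intercalation; (R4) the displaced probe; (R5) hyperchromism without a
>= 10 nm red shift votes against intercalation (counted with the groove
votes); (R6) the thermodynamic force class is recorded but never votes,
because interaction forces describe chemistry, not site geometry. The
majority wins; ties or fewer than two votes are indeterminate. An
"electrostatic" mode is called only when the force class is electrostatic
and no structural evidence exists at all. All thresholds live in
`RuleThresholds`. The report serializes the evidence and the ordered rule
trace, so every call is reproducible from the JSON alone.

## Synthetic data: what it emulates, and what it does not

The generator produces each signal type from the stated model plus
i.i.d. Gaussian noise, with defaults equal to the published point
estimates so fixtures resemble the published figures: Kb = 3.22e4 1/M
(UV), Ksv = 1.17e2 / 1.63e3 1/M (EtBr/Hoechst), double-log Kb = 2.57e4 with
n = 1.17, Tm = 72.2 C free and 77.6 C complexed, DPV peaks at +1.09 and
+1.36 V with electrochemical Kb = 6.02e4 / 5.75e3 1/M, Herschel-Bulkley
(0.32 Pa, 5.95e-5 Pa s^n, 1.57) for the buffer, and calibration
I(A) = -5e-9 * C(uM) + 3e-7. An `INTERCALATOR_TRUTH` contrast fixture
(Kb = 1e7, dTm ~ 11 C, rising viscosity, EtBr displaced, hypochromic)
exercises every rule in the opposite direction.

Values the source does not state, chosen once as realistic and not
revisited: the bound-form extinction ceiling eps_b = 8600 M^-1 cm^-1
(~30% hyperchromism over the 6600 free-DNA coefficient), a 2.5 C logistic
transition width, melting plateaus 1.00/1.35 AU, Gaussian DPV peak sigma
0.03 V with heights 1.2/0.8 uA on a linear drift, a free-DNA specific
viscosity of 0.5 over a 100 s buffer flow time, and relative noise of
0.2% (UV), 0.5% (fluorescence), 0.3% (melting), 1% (DPV, rheology) and
0.2% (flow times). The calibration residual SD defaults to 1.155e-9 A,
the value implied by the published LOD/LOQ; the published R^2 = 0.9700
would require a ~4x larger scatter and is mutually inconsistent with
those limits, so the R^2-envelope test supplies its own scatter
explicitly. One seeded `numpy` generator is drawn per call and the seed
echoed into the output metadata; identical seeds give byte-identical
files.

The generator does not emulate full spectra (single-wavelength responses
only, so peak shifts are never available from these fixtures),
wavelength-dependent stray light or inner-filter effects, electrode
kinetics (DPV peaks are Gaussians on a polynomial drift, not
Butler-Volmer responses), multi-domain melting, or correlated/drifting
instrument noise. Passing recovery tests therefore demonstrate estimator
correctness under the stated models, not robustness to real-instrument
artifacts.

## Noise sensitivity of the linearized estimators

At 1% relative noise the estimators differ sharply in stability (median
absolute error over 200 seeds, concentration designs as above):
Stern-Volmer Ksv ~2%, electrochemical Kb ~0.6%, logistic Tm ~0.1%, and
Herschel-Bulkley tau0/n ~1%/0.7% are well behaved, but the
double-reciprocal Kb (~12%), the double-log Kb (~14%) and the
Herschel-Bulkley consistency K (~7%) are not: the first divides by small
(eps_a - eps_f) differences and extrapolates the intercept to zero
titrant, the second extrapolates the intercept ~4 decades from the data to
log[Q] = 0 so any slope error is amplified, and K trades off against n in
the power law. These are properties of the methods themselves, worth
knowing when quoting literature constants derived from them; the noiseless
recoveries are exact to well below 0.1%.

## Problem sizes and I/O

Default designs: 12-13 point titrations over the stated concentration
ranges, 81-point melting curves (20-100 C at 1 C), 161-point DPV sweeps
(0.8-1.6 V at 5 mV), 25-point flow curves (10-1000 1/s), 8-point
calibrations (2.5-20 uM). Stochastic summaries in tests and in
`scripts/acceptance.py` use 200-seed ensembles for recovery medians and
triplicate-averaged fits for reported constants, mirroring the
three-replicate bench protocol. CSVs use the canonical dialect (comma,
'.' decimal, `# key = value` metadata lines) and 12-significant-digit
formatting, making write-read-write byte-identical; all stage outputs are
pure functions of (inputs, seed).
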