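# dnabind

Solution-phase analysis of small-molecule/dsDNA interactions, for
medicinal chemists and analytical labs characterizing how a drug binds the
double helix and validating a DNA-biosensor assay for it.

Small molecules bind dsDNA by intercalation (inserting between base pairs)
or by lodging in a groove, and the two modes leave different fingerprints
across cheap solution techniques. `dnabind` implements the full evidence
chain as a tested library:

- **UV-vis titration** - Benesi-Hildebrand double-reciprocal analysis,
  `x/(ε_a − ε_f) = x/(ε_b − ε_f) + 1/(K_b(ε_b − ε_f))`, giving K_b from
  the slope/intercept ratio, plus hyper/hypochromism classification;
- **fluorescence displacement** - Stern-Volmer (`I₀/I = 1 + K_sv[Q]`) and
  double-log (`log((I₀−I)/I) = log K_b + n log[Q]`) analyses against EtBr
  (intercalation probe) and Hoechst 33258 (groove probe);
- **van't Hoff thermodynamics** - `ln K_b = −ΔH/RT + ΔS/R`, Gibbs
  energies, and the (ΔH, ΔS) sign-rule force classification;
- **thermal denaturation** - logistic T_m extraction and the ΔT_m
  groove/intercalation interpretation;
- **viscometry/rheology** - `(η/η₀)^{1/3}` vs `r = [drug]/[DNA]` trend
  testing and Herschel-Bulkley (`τ = τ₀ + K·γ̇ⁿ`) flow-curve fits;
- **voltammetry** - DPV baseline correction, dGuo/dAdo peak analysis, and
  the peak-suppression binding regression
  `log(1/[drug]) = log K_b + log(S/(S₀ − S))`;
- **method validation** - calibration, LOD/LOQ (3σ/10σ), repeatability,
  tablet assay and spike-recovery statistics;
- **mode inference** - a rule engine that aggregates the per-technique
  evidence into a minor-groove / intercalation call with a full rule trace;
- **synthetic data** - seeded generators for every signal type with known
  ground truth, so each estimator is verified by parameter recovery.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```sh
python examples/full_binding_mode_report.py
```

```
fixture set : paper
  kb_magnitude     -> vote: groove
  delta_tm         -> vote: groove
  viscosity_trend  -> vote: groove
  displacement     -> vote: groove
  spectral         -> vote: groove
  force_class      -> vote: None
mode call   : minor_groove
```

Five independent lines of evidence vote: the binding constant sits in the
1e3-1e5 M⁻¹ groove range (intercalators reach 1e6-1e7), the melting shift
is small, the viscosity series is flat (no helix lengthening), the
groove-selective probe is the one displaced, and the absorbance change is
hyperchromic without a red shift. The thermodynamic force class is
recorded but does not vote - interaction forces describe chemistry, not
geometry. `python examples/full_binding_mode_report.py intercalator`
shows every rule flipping on a classical-intercalator fixture.

The other scripts in `examples/` each run one capability end to end, e.g.:

```sh
$ python examples/thermodynamics_vant_hoff.py
dH = -6.44 kJ/mol   dS = +65.00 J/(mol K)
  dG(288.15 K) = -25.17 kJ/mol
  dG(298.15 K) = -25.82 kJ/mol
  dG(308.15 K) = -26.47 kJ/mol
force class : electrostatic
```

A negative enthalpy with positive entropy is the electrostatic signature,
and negative ΔG at every temperature means spontaneous association.

A thin CLI wraps the same functions for shell use
(`dnabind simulate | uvfit | fluor | thermo | melt | visc | volt | calib |
assay | recover | report`); run `dnabind --help`.

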