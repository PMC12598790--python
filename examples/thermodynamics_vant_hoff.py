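"""van't Hoff analysis of Kb(T): what force drives the binding?

Binding constants measured at three temperatures are regressed as ln Kb vs
1/T.  The slope gives the enthalpy (dH = -R*slope), the intercept the
entropy (dS = R*intercept); dG = dH - T*dS follows at each temperature, and
the signs of (dH, dS) classify the dominant interaction force.
"""

from dnabind import PAPER_TRUTH, vant_hoff_fit

result = vant_hoff_fit(PAPER_TRUTH.kb_by_temperature)

print(f"dH = {result.delta_h:+.2f} kJ/mol   dS = {result.delta_s:+.2f} J/(mol K)")
for t, dg in sorted(result.delta_g_per_temperature.items()):
    print(f"  dG({t:.2f} K) = {dg:+.2f} kJ/mol")
print(f"force class : {result.force_class.value}")
print()
print("Negative dH with positive dS is the classical electrostatic signature;")
print("negative dG at every temperature means the association is spontaneous.")
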