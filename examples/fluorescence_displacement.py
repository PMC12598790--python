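"""Probe-displacement assay: which DNA site does the drug occupy?

EtBr (intercalation probe) and Hoechst 33258 (minor-groove probe) fluoresce
strongly when bound to dsDNA.  A test drug that competes for one probe's
site quenches that probe's emission.  Stern-Volmer constants quantify the
quenching; a double-log fit gives the binding constant and stoichiometry.
"""

from dnabind import (
    PAPER_TRUTH,
    displacement_compare,
    double_log_fit,
    gen_quench_series,
    stern_volmer_fit,
)

etbr = stern_volmer_fit(gen_quench_series(PAPER_TRUTH, "etbr", seed=1))
hoechst = stern_volmer_fit(gen_quench_series(PAPER_TRUTH, "hoechst", seed=2))
call = displacement_compare(etbr, hoechst)
dl = double_log_fit(gen_quench_series(PAPER_TRUTH, use_double_log_model=True, seed=3))

print(f"Ksv (EtBr)    : {etbr.kb:.3g} 1/M")
print(f"Ksv (Hoechst) : {hoechst.kb:.3g} 1/M  (ratio {hoechst.kb / etbr.kb:.1f}x)")
print(f"displacement  : {call.value}")
print(f"double-log    : Kb = {dl.kb:.3g} 1/M, n = {dl.n_stoichiometry:.2f}")
print()
print("The groove probe is quenched ~14x more efficiently: the drug competes")
print("for the minor groove, not the intercalation site.")
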