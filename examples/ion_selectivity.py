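"""Classify a channel's ion selectivity from voltage-ramp ion substitution.

Simulates leak and ligand-evoked voltage ramps (-80 to +60 mV) in the
standard ND96 bath, a low-chloride (Na gluconate) bath and a sodium-free
(NMDG) bath, estimates the leak-subtracted reversal potential in each, and
classifies the channel from the pattern of reversal shifts.
"""

import chansyn as cs

experiment, truth = cs.gen_selectivity_experiment(
    "anion", erev_nd96=-25.0, noise_sd=2.0, seed=7
)

erevs = {cond: cs.estimate_reversal(lig, leak) for cond, (lig, leak) in experiment.items()}
for cond in ("ND96", "NaGluconate", "NMDG"):
    print(f"Erev in {cond:12s}: {erevs[cond]:+6.1f} mV "
          f"(planted {truth.params['erev_by_condition'][cond]:+.1f})")

d_low_cl = erevs["NaGluconate"] - erevs["ND96"]
d_na_free = erevs["NMDG"] - erevs["ND96"]
call = cs.classify_ion_selectivity(d_low_cl, d_na_free, threshold=10.0)
print(f"dErev low-Cl = {d_low_cl:+.1f} mV, dErev Na-free = {d_na_free:+.1f} mV")
print(f"selectivity call: {call}")
print(
    "# A reversal shift when chloride is replaced, but not when sodium is,\n"
    "# means the ligand-gated current is carried by anions (an inhibitory channel)."
)
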