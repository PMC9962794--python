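"""Predict synaptic polarity in a toy reversal-circuit connectome.

Uses the shipped channel catalog (curated cholinergic/GABA/glutamate channel
pharmacology) and an illustrative expression table for the classes of the
reversal/locomotion circuit. Each chemical edge gets the sign of the
postsynaptic class's net receptor expression for the released transmitter.
"""

import pandas as pd

import chansyn as cs

catalog = cs.example_catalog()

# Illustrative per-class expression of a few catalog channels (arbitrary
# thresholded-scRNAseq-like units). AVA expresses slightly more inhibitory
# than excitatory ACh channels but strongly excitatory glutamate receptors.
expression = cs.ExpressionMatrix(
    data=pd.DataFrame(
        {
            "acr-16": {"AVA": 30.0, "VA": 40.0, "DA": 35.0, "AVD": 0.0, "ASH": 0.0},
            "lgc-39": {"AVA": 25.0, "VA": 0.0, "DA": 0.0, "AVD": 0.0, "ASH": 0.0},
            "lgc-46": {"AVA": 14.0, "VA": 0.0, "DA": 0.0, "AVD": 12.0, "ASH": 0.0},
            "glr-1": {"AVA": 80.0, "VA": 0.0, "DA": 0.0, "AVD": 45.0, "ASH": 0.0},
            "nmr-1": {"AVA": 9.0, "VA": 0.0, "DA": 0.0, "AVD": 20.0, "ASH": 0.0},
            "glc-1": {"AVA": 10.0, "VA": 0.0, "DA": 0.0, "AVD": 0.0, "ASH": 0.0},
        }
    ),
    threshold_level=4,
)

connectome = cs.Connectome(
    chemical_edges=[
        cs.ChemicalEdge("AVA", "VA", 40),
        cs.ChemicalEdge("AVA", "DA", 30),
        cs.ChemicalEdge("AVD", "AVA", 12),
        cs.ChemicalEdge("ASH", "AVA", 9),
    ],
    gap_junctions=[cs.GapJunction("AVA", "VA", 8)],
    transmitters={
        "AVA": ("ACh",),
        "AVD": ("ACh",),
        "ASH": ("glutamate",),
        "VA": ("ACh",),
        "DA": ("ACh",),
    },
)

signed = cs.predict_edge_signs(connectome, expression, catalog)
print(signed.edge_frame().to_string(index=False))
for s in signed.summaries:
    if s.cls == "AVA":
        print(
            f"AVA {s.transmitter}: sum_exc={s.sum_exc:.0f} sum_inh={s.sum_inh:.0f} "
            f"net={s.net:+.0f} ratio={s.ratio:.1f} ({s.category})"
        )
print(cs.edge_sign_fractions(signed).round(1).to_string())
print(
    "# AVA receives inhibitory ACh input (slight inhibitory receptor excess)\n"
    "# but excitatory glutamate input, while its own cholinergic output onto\n"
    "# the VA/DA motor neurons is excitatory; the gap junction stays unsigned."
)
cs.export_signed_network(signed, "signed_circuit.graphml")
print("wrote signed_circuit.graphml")
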