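"""Infer ligands and ion selectivity for an orphan channel.

Combines two lines of evidence: the PAR (proline-alanine-arginine) motif in
the M1-2 intracellular loop, which marks anion selectivity in this channel
superfamily, and the ligands of electrophysiologically characterized channels
in the orphan's homology group.
"""

import chansyn as cs

catalog = cs.example_catalog()

# M1-2 loop segments (illustrative): one ends in a PAR-containing stretch
loops = {
    "orphan-A": "MVRLLLVFSLPARIF",  # PAR in the anchor window -> anion
    "orphan-B": "MVRLLLVFSLGEKIF",  # no PAR -> cation
}
for gene, loop in loops.items():
    print(f"{gene}: PAR scan of {loop!r} -> {cs.scan_par_motif(loop)}")

rec = cs.infer_orphan(
    "orphan-A", "LGC-57", catalog, par_call=cs.scan_par_motif(loops["orphan-A"])
)
print(f"inferred ligands     : {sorted(rec.ligands)}")
print(f"inferred selectivity : {rec.selectivity} ({rec.polarity})")
print(f"evidence             : {rec.evidence} -- {rec.basis}")
print(
    "# The orphan inherits the pooled ligands of its measured relatives\n"
    "# (choline/ACh for this group); the PAR call fixes the selectivity."
)
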