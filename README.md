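# chansyn

Ligand-gated ion channel (LGIC) pharmacology and connectome synaptic-polarity
prediction, built for *C. elegans*-style nervous systems where a single
transmitter — acetylcholine in particular — gates both excitatory cation
channels and inhibitory anion channels.

The package has two halves:

1. **TEVC quantification** — analysis of two-electrode voltage-clamp
   recordings from *Xenopus* oocytes: peak extraction from continuous traces,
   per-oocyte I/Imax normalization, three- or four-parameter Hill fits,

   R(d) = bottom + (top − bottom) / (1 + (EC50/d)^h),

   antagonist IC50 fits (decreasing Hill), leak-subtracted reversal-potential
   (E_rev) estimation from −80→+60 mV voltage ramps, ΔE_rev classification of
   ion selectivity under ionic substitution (low-Cl⁻ gluconate vs Na⁺-free
   NMDG baths), and second/first-pulse recovery ratios for repeated
   stimulation.

2. **Connectome polarity** — a channel catalog maps each receptor gene to its
   agonists and ion selectivity (anion → inhibitory, cation → excitatory);
   orphan channels are filled in from the PAR motif in the M1-2 loop and
   homology-group pooling. For each neural class and transmitter the signed
   net receptor expression is

   net = Σ expression(cation channels gated by T) − Σ expression(anion channels gated by T),

   and every chemical synapse takes the sign of its postsynaptic class's net
   for the transmitter its presynaptic class releases. Summary tables give
   the four-group receptor-complement fractions per transmitter and the
   predicted sign fractions per synapse; signed networks export to GraphML or
   SIF. A companion module ranks classes by cholinergic in/out synapse degree
   and correlates degree with receptor expression.

A synthetic-data module generates all inputs (connectomes, expression
matrices with planted receptor categories, dose-response series, voltage
ramps) with known ground truth, so the whole pipeline is testable offline.

## Worked example

`examples/predict_polarity.py` predicts edge signs in a toy reversal-circuit
connectome using the shipped channel catalog:

```
pre post transmitter  count       sign
AVA   VA         ACh     40 excitatory
AVA   DA         ACh     30 excitatory
AVD  AVA         ACh     12 inhibitory
ASH  AVA   glutamate      9 excitatory
AVA ACh: sum_exc=30 sum_inh=39 net=-9 ratio=1.3 (both)
AVA glutamate: sum_exc=89 sum_inh=10 net=+79 ratio=8.9 (both)
```

AVA expresses 1.3× as much inhibitory as excitatory ACh receptor, so its
incoming cholinergic synapse from AVD is predicted inhibitory, while its
glutamatergic input from ASH (8.9× excitatory dominance) and its cholinergic
output onto the VA/DA motor neurons are predicted excitatory. Gap junctions
are carried through unsigned. The other example scripts cover dose-response
fitting, ion-selectivity classification, orphan-channel inference and the
cholinergic degree–expression correlation; each prints the numbers it
computes and what they mean.

A thin CLI wraps the same functions, e.g.

```sh
chansyn simulate tevc --seed 3 --out-dir sim
chansyn tevc fit-ec50 --peaks sim/peaks.csv --out fits.csv
chansyn polarity predict --expression X.csv --catalog C.csv \
    --connectome E.csv --nt-map N.csv --out-dir out
```

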