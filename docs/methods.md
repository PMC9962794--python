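# Methods

This note documents the models, conventions and numerical choices behind
chansyn, and what the synthetic-data tests do and do not establish.

## Channel catalog and orphan inference

Each catalog record carries a gene, a subfamily label, its agonist set drawn
from a closed transmitter vocabulary (ACh, choline, GABA, glutamate,
tyramine, octopamine, dopamine, serotonin, histamine, betaine, glycine), an
ion selectivity (anion / cation / unknown) and an evidence tag. Polarity is a
pure function of selectivity: cation channels depolarize (excitatory), anion
channels typically hyperpolarize or shunt (inhibitory). Inferred records must
state their basis; records with unknown selectivity are excluded from all
polarity sums so that no sign is ever fabricated.

**PAR motif.** In this pentameric-channel superfamily a proline-alanine-
arginine triplet just N-terminal to the M2 pore helix marks anion
selectivity. The scanner takes a caller-supplied M1-2 intracellular loop
segment and looks for the literal triplet within an anchor window of the
final 8 residues of the segment, mirroring how the motif is aligned at the
loop's C-terminal end. We deliberately do not predict transmembrane topology;
locating the loop is the caller's responsibility (e.g. from a curated
coordinate table). Segments shorter than the window return `indeterminate`.

**Homology inference.** An orphan inherits the union of the ligands of the
measured members of its subfamily (union rather than intersection, since
absence of a ligand in one relative is weak evidence; an intersection mode is
available), and the majority selectivity of those members unless a PAR call
overrides it. A tied vote yields `unknown`. The donors are recorded in the
basis note.

## TEVC quantification

Sign convention: inward currents are negative; normalization uses current
magnitudes. Units: µM, mV, nA throughout (conductances µS, so g·V is nA).

**Normalization.** I/Imax uses the largest-magnitude current of the
individual oocyte, regardless of dose. Because Imax can occur at different
doses in different oocytes, the cross-oocyte mean of normalized responses
legitimately peaks below 1; the fitter's free `top` parameter absorbs this.

**Hill fits.** Fits minimize least squares on a log10(EC50)
parameterization with `scipy.optimize.least_squares`, multi-started across
the dose range (5 log-spaced EC50 starts × up to 3 slope starts) to avoid
local minima on plateau-poor data. The "three-parameter" agonist fit fixes
h = 1 with {bottom, top, EC50} free (a `fix_bottom` mode instead fixes
bottom = 0 with h free); the four-parameter fit frees all four. The
antagonist fit is the decreasing Hill with variable slope and floor fixed at
0. Bounds: EC50 ∈ [min dose/100, max dose×100], h ∈ [0.1, 10]; a fit pinned
at the EC50 bounds never bracketed a half-maximal dose and is reported
`converged=False` (flat block curves end up here, with IC50 outside the
tested range). Non-convergence is always a flag, never an exception.

**Reversal potentials.** The leak sweep (agonist absent) is interpolated
onto the ligand sweep's voltage grid and subtracted. The zero crossing of the
subtracted I–V is located by linear interpolation between the bracketing
samples; with multiple crossings the one nearest 0 mV is used (the
physiologically plausible reversal for these channels). The crossing is then
refined by an ordinary least-squares line over the samples within ±10 mV,
which plays the role of the low-pass filtering applied to raw recordings:
for noiseless linear data it reproduces the interpolated crossing exactly,
while under per-sample noise it reduces the error from roughly
noise/slope (≈2–3 mV at 2 nA noise and 1 µS) to a few tenths of a mV. A
subtracted current with no sign change over the sweep — including the null
current of an unexpressed channel — gives NaN (indeterminate).

**Ion-selectivity classification.** The two-bath substitution logic is a
fixed-threshold classifier (default 10 mV): an anion-selective channel
shifts E_rev when chloride is replaced by gluconate but not when sodium is
replaced by NMDG; a cation channel mirrors this; both-above or both-below
threshold is indeterminate. This replaces the ANOVA-style significance
testing a full statistical treatment would use; the threshold is a parameter.

**Repeated stimulation.** Recovery is the ratio of the second to the first
pulse peak per oocyte, aggregated as mean ± SEM per wash interval; oocytes
with a zero first pulse are excluded with a warning. No kinetic
(desensitization) model is fitted, deliberately — slow oocyte kinetics make
such inferences unreliable.

## Polarity prediction

For a class c and transmitter T, `sum_exc` / `sum_inh` add the expression of
every catalog cation / anion channel gated by T; `net = sum_exc − sum_inh`;
the fold-ratio max/min (∞ when one side is 0, printed "only") expresses
prediction strength. The four-group category (excitatory-only,
inhibitory-only, both, none) depends only on which sums are positive, so it
is invariant under any uniform positive rescaling of the matrix. Expression
values are used exactly as thresholded upstream; no re-normalization.

Per-edge signs assume every receptor of a class is present at all of its
synapses equally: each chemical edge takes the sign of the postsynaptic net
for the released transmitter. Cotransmitting presynaptic classes emit one
labelled edge per transmitter under the default `multi` policy; the `major`
policy keeps only the first-listed transmitter (the transmitter table is
ordered; no dominance rule is invented). Ties (net = 0), `none` categories,
unknown presynaptic transmitters and postsynaptic classes missing from the
expression matrix all yield `no_prediction`, so
excitatory + inhibitory + no_prediction always equals the number of edge
labels. Gap junctions are never signed. Edge-sign fractions weight by
aggregated synapse count by default ("% of synapses"), with a per-connection
mode.

Neuron-level connectomes are collapsed to classes either by an explicit
mapping table (recommended; unmapped endpoints are an error) or by a
heuristic that strips one trailing L/R, then one trailing D/V, and trailing
digits only if no letter was stripped (AVAL→AVA, RMED→RME, IL2DL→IL2,
VA12→VA). Synapse counts are summed within a class pair.

Known limitations: no heteromeric receptor composition, no synaptic
strength/conductance model, no extrasynaptic-vs-synaptic localization, no
dynamics — predictions are a receptor-complement prior, not a circuit
simulation.

## Cholinergic degree analysis

A class is ACh-producing if ACh appears anywhere in its transmitter list;
all of its synapses are counted as cholinergic even under cotransmission.
In-degree sums synapse counts (not partner counts) received from
ACh-producing classes; out-degree sums the synapses an ACh-producing class
makes. Degree-ranked heatmaps clip values at a display ceiling (default 500).
The degree–expression correlation removes zero-expression classes, then fits
ordinary least squares on untransformed values and reports Pearson r with a
t-based slope interval at the chosen level (default 68%, ≈ one standard
error, matching the usual regression-band convention). Fewer than three
surviving points, or a constant variable, is flagged `insufficient` rather
than raised. Correlations are descriptive; no significance testing is done.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Connectomes** — Bernoulli edges (density 0.15) between letter-named
  classes, geometric synapse counts (p = 0.3, heavy-tailed like real
  connectomes), 20% as many undirected electrical edges, transmitters drawn
  from a cholinergic-majority mix (ACh 0.45 / Glu 0.30 / GABA 0.25),
  cotransmission probability 0.1.
- **Expression** — planted four-group categories per (class, transmitter)
  using catalog genes gated by exactly that transmitter (so planting cannot
  leak across transmitters); `both` classes get a clear 2–4-fold dominant
  side so the planted net sign is unambiguous; values ~uniform(0.5,1.5)×100,
  like thresholded single-cell counts. Optional dropout zeroes entries; only
  the zero-dropout limit guarantees category recovery.
- **Dose-response** — fractional responses Hill(d)·(1+ε), ε ~ N(0, cv)
  (multiplicative, as pipette/expression variability scales with current),
  per-oocyte Imax log-normal around 200 nA, reported as inward currents. The
  recovery experiments use 11 doses per channel spanning EC50/30–EC50×30,
  reflecting the protocol of adjusting doses until both plateaus are reached.
- **Ramps** — I = g_leak(V − V_leak) [+ g_chan(V − E_rev)] + N(0, σ) on a
  1 mV grid over −80…+60 mV; substitution experiments plant Nernst-style
  offsets (+30 mV in low-Cl⁻ for anion channels, −40 mV in Na⁺-free for
  cation channels, 0 otherwise).
- **Recovery** — ratio(t) = 1 − d·e^(−t/τ), noisy pulse pairs.

All generators take a required seed (NumPy `default_rng`) and are
byte-deterministic under it. What passing these tests shows: the estimators
invert the stated generative models at realistic noise. What they do not
show: robustness to real-data pathologies (perfusion artifacts, oocyte
drift, dropout-heavy expression counts, annotation errors in connectomes).

## Validation conditions and measured recoveries

`scripts/acceptance.py` (and the mirrored tests) use: 200 simulated
dose-response series with EC50 log-uniform in [1, 1000] µM, h ∈ [1, 3], 5%
multiplicative noise (median EC50 and IC50 relative error, and a check that
the fitter's RSS never exceeds that of an exhaustive 200×71-point
(EC50, h) grid oracle); 100 ramp pairs at 2 nA noise (median |E_rev| error)
and 100 substitution experiments (classification accuracy); 50 random
connectomes of ≤20 classes with noiseless planted expression (edge-sign and
conservation checks); 20 random planted matrices (category recovery and
fraction sums); plus writer/reader round trips. These sizes keep the full
suite under a minute while leaving the medians stable across seeds.
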