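"""Synthetic inputs with known ground truth for every pipeline stage.

Generates connectome edge lists, expression matrices with planted receptor
categories, Hill-shaped dose-response series and ohmic + ligand-gated voltage
ramps, each paired with the ground truth that produced it. All generators are
deterministic under their seed.

The defaults emulate the real study conditions at desk scale: a nematode-like
class-level connectome (heavy-tailed synapse counts, a cholinergic-majority
transmitter mix, a minority of electrical edges), single-cell-RNAseq-like
thresholded expression values on a scale of hundreds, oocyte peak currents of
a few hundred nA with ~5% multiplicative variability, and ramp noise of a
couple of nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import TRANSMITTERS, ChannelCatalog
from .polarity import CATEGORIES, ChemicalEdge, Connectome, ExpressionMatrix, GapJunction
from .tevc import DoseResponseSeries, RampRecording, hill

__all__ = [
    "GroundTruth",
    "DEFAULT_TRANSMITTER_FREQUENCIES",
    "gen_connectome",
    "gen_expression",
    "gen_dose_response",
    "gen_inhibition_response",
    "gen_ramp",
    "gen_selectivity_experiment",
    "gen_recovery",
    "synthetic_catalog",
]

#: Roughly the cholinergic-majority transmitter mix of a nematode nervous system.
DEFAULT_TRANSMITTER_FREQUENCIES: dict[str, float] = {
    "ACh": 0.45,
    "glutamate": 0.30,
    "GABA": 0.25,
}


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated artifact."""

    seed: int
    categories: dict = field(default_factory=dict)  # (class, transmitter) -> category
    net_signs: dict = field(default_factory=dict)  # (class, transmitter) -> -1|0|+1
    params: dict = field(default_factory=dict)  # electrophysiology parameters


def synthetic_catalog(
    transmitters: Sequence[str] = ("ACh", "glutamate", "GABA")
) -> ChannelCatalog:
    """A minimal catalog with one dedicated anion and cation gene per transmitter.

    Genes are named ``syn-<transmitter>-<a|c>`` and gated by exactly one
    transmitter, so planted expression for one transmitter never leaks into
    another's sums.
    """
    from .catalog import ChannelRecord

    cat = ChannelCatalog()
    for t in transmitters:
        if t not in TRANSMITTERS:
            raise ValueError(f"unknown transmitter token {t!r}")
        for sel, tag in (("anion", "a"), ("cation", "c")):
            cat.add(
                ChannelRecord(
                    gene=f"syn-{t}-{tag}",
                    group="LGC-41",
                    ligands=frozenset({t}),
                    selectivity=sel,
                    evidence="measured",
                )
            )
    return cat


_SAFE_FINAL = "ABCEFGHIJKMNOPQSTUWXYZ"  # no L/R/D/V: stable under class collapsing


def _class_name(i: int) -> str:
    """Letter-only synthetic class names (NAA, NAB, ...).

    The final letter avoids the positional suffixes L/R/D/V so that names
    survive the neuron-to-class collapsing heuristic unchanged.
    """
    prefix = ""
    q = i // len(_SAFE_FINAL)
    while True:
        prefix = chr(65 + q % 26) + prefix
        q //= 26
        if q == 0:
            break
    return "N" + prefix + _SAFE_FINAL[i % len(_SAFE_FINAL)]


def gen_connectome(
    n_classes: int,
    edge_density: float = 0.15,
    synapse_count_p: float = 0.3,
    transmitter_frequencies: Optional[Mapping[str, float]] = None,
    gap_fraction: float = 0.2,
    cotransmission_prob: float = 0.1,
    seed: int = 0,
) -> tuple[Connectome, GroundTruth]:
    """Random class-level connectome with transmitter labels.

    Each ordered class pair receives a chemical edge with probability
    *edge_density*; synapse counts are geometric (parameter
    *synapse_count_p*, heavy-tailed like real connectomes). A further
    *gap_fraction* of the chemical edge count is drawn as undirected
    electrical edges. Every class gets >=1 transmitter sampled from
    *transmitter_frequencies* (must sum to 1); with probability
    *cotransmission_prob* a second, different transmitter is added.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    freqs = dict(transmitter_frequencies or DEFAULT_TRANSMITTER_FREQUENCIES)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("transmitter frequencies must sum to 1")
    if not 0 <= edge_density <= 1 or not 0 < synapse_count_p <= 1:
        raise ValueError("invalid distribution parameters")
    rng = np.random.default_rng(seed)
    classes = [_class_name(i) for i in range(n_classes)]
    names = list(freqs)
    probs = np.array([freqs[k] for k in names], dtype=float)

    transmitters: dict[str, tuple[str, ...]] = {}
    for cls in classes:
        first = names[rng.choice(len(names), p=probs)]
        released = [first]
        if rng.random() < cotransmission_prob and len(names) > 1:
            others = [t for t in names if t != first]
            released.append(others[rng.integers(len(others))])
        transmitters[cls] = tuple(released)

    edges: list[ChemicalEdge] = []
    for pre in classes:
        for post in classes:
            if pre == post:
                continue
            if rng.random() < edge_density:
                count = int(rng.geometric(synapse_count_p))
                edges.append(ChemicalEdge(pre, post, count))

    gaps: list[GapJunction] = []
    n_gaps = int(round(gap_fraction * len(edges)))
    seen: set[tuple[str, str]] = set()
    while len(gaps) < n_gaps:
        a, b = rng.choice(n_classes, size=2, replace=False)
        pair = tuple(sorted((classes[a], classes[b])))
        if pair in seen:
            continue
        seen.add(pair)
        gaps.append(GapJunction(pair[0], pair[1], int(rng.geometric(synapse_count_p))))

    conn = Connectome(chemical_edges=edges, gap_junctions=gaps, transmitters=transmitters)
    return conn, GroundTruth(seed=seed)


def gen_expression(
    classes: Sequence[str],
    catalog: ChannelCatalog,
    planted_categories: Mapping[str, Mapping[str, str]],
    expression_scale: float = 100.0,
    dropout_noise: float = 0.0,
    seed: int = 0,
    threshold_level: int = 4,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted four-group receptor categories.

    *planted_categories* maps class -> {transmitter -> category}. A ``both``
    class receives positive expression of at least one anion and one cation
    channel for the transmitter, with one side a clear (2-4 fold) dominant so
    the planted net sign is unambiguous; ``none`` classes stay at zero.
    Dropout noise zeroes entries with the stated probability after planting
    (at zero dropout the planted categories are recovered exactly).

    Planting only uses catalog genes whose ligand set is exactly the target
    transmitter; a missing polarity/transmitter combination is an error.
    """
    rng = np.random.default_rng(seed)
    transmitters = sorted({t for m in planted_categories.values() for t in m})
    pool: dict[tuple[str, str], list[str]] = {}
    for t in transmitters:
        for polarity in ("excitatory", "inhibitory"):
            genes = [
                r.gene
                for r in catalog.genes_for(t, polarity)
                if r.ligands == frozenset({t})
            ]
            if not genes:
                raise ValueError(
                    f"catalog lacks a single-ligand {polarity} channel for {t!r}"
                )
            pool[(t, polarity)] = genes

    all_genes = sorted({g for gs in pool.values() for g in gs})
    data = pd.DataFrame(0.0, index=list(classes), columns=all_genes)
    truth = GroundTruth(seed=seed)

    def plant(cls: str, genes: list[str], scale: float) -> float:
        gene = genes[rng.integers(len(genes))]
        value = float(rng.uniform(0.5, 1.5) * scale)
        data.loc[cls, gene] += value
        return value

    for cls, per_t in planted_categories.items():
        for t, category in per_t.items():
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
            truth.categories[(cls, t)] = category
            if category == "none":
                truth.net_signs[(cls, t)] = 0
            elif category == "excitatory_only":
                plant(cls, pool[(t, "excitatory")], expression_scale)
                truth.net_signs[(cls, t)] = +1
            elif category == "inhibitory_only":
                plant(cls, pool[(t, "inhibitory")], expression_scale)
                truth.net_signs[(cls, t)] = -1
            else:  # both, with a clear dominant side
                dominant = rng.integers(2)  # 0 -> excitatory dominates
                fold = rng.uniform(2.0, 4.0)
                exc_scale = expression_scale * (fold if dominant == 0 else 1.0)
                inh_scale = expression_scale * (fold if dominant == 1 else 1.0)
                exc = plant(cls, pool[(t, "excitatory")], exc_scale)
                inh = plant(cls, pool[(t, "inhibitory")], inh_scale)
                truth.net_signs[(cls, t)] = +1 if exc > inh else -1
    if dropout_noise > 0:
        mask = rng.random(data.shape) < dropout_noise
        data = data.mask(mask, 0.0)
    return ExpressionMatrix(data=data, threshold_level=threshold_level), truth


def gen_dose_response(
    ec50: float,
    h: float,
    doses: Sequence[float],
    n_oocytes: int = 5,
    top: float = 1.0,
    bottom: float = 0.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    agonist: str = "ACh",
    mean_imax_na: float = 200.0,
) -> tuple[list[DoseResponseSeries], GroundTruth]:
    """Noisy Hill-shaped dose-response series for *n_oocytes* oocytes.

    Fractional responses are Hill(d) * (1 + eps), eps ~ N(0, noise_cv); each
    oocyte's absolute current scale (its Imax) is drawn log-normally around
    *mean_imax_na* and peaks are reported as inward (negative) currents.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(doses, dtype=float)
    clean = hill(d, ec50, h, top, bottom)
    series = []
    for k in range(n_oocytes):
        scale = float(rng.lognormal(mean=np.log(mean_imax_na), sigma=0.3))
        resp = clean * (1.0 + rng.normal(0.0, noise_cv, size=d.shape)) if noise_cv > 0 else clean.copy()
        series.append(
            DoseResponseSeries(
                oocyte_id=f"oo{k:03d}",
                agonist=agonist,
                doses=d.copy(),
                peak_currents=-scale * resp,
            )
        )
    truth = GroundTruth(
        seed=seed,
        params={"ec50": ec50, "h": h, "top": top, "bottom": bottom, "noise_cv": noise_cv},
    )
    return series, truth


def gen_inhibition_response(
    ic50: float,
    h: float,
    doses: Sequence[float],
    n_oocytes: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
    antagonist: str = "mecamylamine",
) -> tuple[list[DoseResponseSeries], GroundTruth]:
    """Noisy decreasing block curves, normalized to the lowest antagonist dose."""
    rng = np.random.default_rng(seed)
    d = np.asarray(doses, dtype=float)
    clean = 1.0 / (1.0 + (d / ic50) ** h)
    clean = clean / clean[np.argmin(d)]  # normalize to the lowest dose
    series = []
    for k in range(n_oocytes):
        resp = clean * (1.0 + rng.normal(0.0, noise_cv, size=d.shape)) if noise_cv > 0 else clean.copy()
        series.append(
            DoseResponseSeries(
                oocyte_id=f"oo{k:03d}",
                agonist=antagonist,
                doses=d.copy(),
                peak_currents=-200.0 * resp,
                normalized=resp,
            )
        )
    truth = GroundTruth(seed=seed, params={"ic50": ic50, "h": h, "noise_cv": noise_cv})
    return series, truth


_V_GRID = np.linspace(-80.0, 60.0, 141)  # -80..+60 mV at 1 mV steps (20 mV/s)


def gen_ramp(
    erev: float,
    channel_conductance: float = 1.0,
    leak_conductance: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "ND96",
    leak_reversal: float = 0.0,
) -> tuple[RampRecording, RampRecording, GroundTruth]:
    """Paired (ligand, leak) voltage ramps with a planted reversal potential.

    Conductances in uS, voltages in mV, so currents come out in nA:
    leak = g_leak (V - V_leak_rev) + noise; the ligand sweep adds
    g_chan (V - erev). Returns (ligand ramp, leak ramp, truth).
    """
    if channel_conductance < 0 or leak_conductance < 0:
        raise ValueError("conductances must be >= 0")
    rng = np.random.default_rng(seed)
    v = _V_GRID.copy()
    leak_i = leak_conductance * (v - leak_reversal)
    chan_i = channel_conductance * (v - erev)
    noise = lambda: rng.normal(0.0, noise_sd, size=v.shape) if noise_sd > 0 else 0.0
    leak = RampRecording(v, leak_i + noise(), condition, ligand_present=False)
    ligand = RampRecording(v, leak_i + chan_i + noise(), condition, ligand_present=True)
    truth = GroundTruth(
        seed=seed,
        params={
            "erev": erev,
            "channel_conductance": channel_conductance,
            "leak_conductance": leak_conductance,
            "noise_sd": noise_sd,
        },
    )
    return ligand, leak, truth


#: Nernst-style reversal shifts (mV) planted per bath for each selectivity:
#: an anion channel follows the chloride gradient (large shift in low-chloride
#: gluconate, none in sodium-free NMDG); a cation channel mirrors the pattern.
SELECTIVITY_SHIFTS: dict[str, dict[str, float]] = {
    "anion": {"ND96": 0.0, "NaGluconate": +30.0, "NMDG": 0.0},
    "cation": {"ND96": 0.0, "NaGluconate": 0.0, "NMDG": -40.0},
}


def gen_selectivity_experiment(
    selectivity: str,
    erev_nd96: float = -25.0,
    channel_conductance: float = 1.0,
    leak_conductance: float = 1.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, tuple[RampRecording, RampRecording]], GroundTruth]:
    """Ion-substitution experiment: ramp pairs in ND96, NaGluconate and NMDG.

    The planted reversal in each bath is ``erev_nd96`` plus the Nernst-style
    offset for the stated selectivity (see :data:`SELECTIVITY_SHIFTS`).
    """
    if selectivity not in SELECTIVITY_SHIFTS:
        raise ValueError("selectivity must be 'anion' or 'cation'")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[RampRecording, RampRecording]] = {}
    planted = {}
    for condition, shift in SELECTIVITY_SHIFTS[selectivity].items():
        erev = erev_nd96 + shift
        planted[condition] = erev
        sub = int(rng.integers(0, 2**31 - 1))
        ligand, leak, _ = gen_ramp(
            erev,
            channel_conductance=channel_conductance,
            leak_conductance=leak_conductance,
            noise_sd=noise_sd,
            seed=sub,
            condition=condition,
        )
        out[condition] = (ligand, leak)
    truth = GroundTruth(
        seed=seed,
        params={"selectivity": selectivity, "erev_by_condition": planted},
    )
    return out, truth


def gen_recovery(
    tau_s: float,
    wash_intervals: Sequence[float] = (10.0, 30.0, 60.0),
    n_oocytes: int = 6,
    depression: float = 0.6,
    noise_cv: float = 0.05,
    seed: int = 0,
    peak_na: float = -150.0,
) -> tuple[dict[float, list[tuple[float, float]]], GroundTruth]:
    """Repeated-stimulation pulse pairs with exponential recovery.

    The second-pulse/first-pulse ratio recovers as 1 - depression *
    exp(-t / tau_s) with wash interval t, so longer washes give larger
    ratios. Returns {interval: [(peak1, peak2) per oocyte]}.
    """
    rng = np.random.default_rng(seed)
    out: dict[float, list[tuple[float, float]]] = {}
    for t in wash_intervals:
        ratio = 1.0 - depression * np.exp(-t / tau_s)
        pairs = []
        for _ in range(n_oocytes):
            p1 = peak_na * (1.0 + rng.normal(0.0, noise_cv))
            p2 = p1 * ratio * (1.0 + rng.normal(0.0, noise_cv))
            pairs.append((float(p1), float(p2)))
        out[float(t)] = pairs
    truth = GroundTruth(
        seed=seed,
        params={"tau_s": tau_s, "depression": depression, "noise_cv": noise_cv},
    )
    return out, truth
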