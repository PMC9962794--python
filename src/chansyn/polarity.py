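"""Connectome synaptic-polarity prediction from receptor expression.

Each neural class's response to a transmitter is predicted from its ionotropic
receptor complement: summed expression of cation (excitatory) channels gated
by that transmitter minus summed expression of anion (inhibitory) channels
gives a signed net; each incoming chemical synapse is then labelled with the
sign of the postsynaptic class's net for the transmitter the presynaptic class
releases. Receptors are assumed present equally at all synapses of a class;
gap junctions are carried through unsigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import TRANSMITTERS, ChannelCatalog

__all__ = [
    "ExpressionMatrix",
    "Connectome",
    "ChemicalEdge",
    "GapJunction",
    "PolaritySummary",
    "SignedEdge",
    "SignedNetwork",
    "classify_receptors",
    "net_polarity",
    "predict_edge_signs",
    "category_fractions",
    "edge_sign_fractions",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("excitatory_only", "inhibitory_only", "both", "none")
SIGNS = ("excitatory", "inhibitory", "no_prediction")

#: Sentinel for a polarity ratio with a zero denominator ("only" in reports).
ONLY = math.inf


@dataclass
class ExpressionMatrix:
    """Neural class x gene non-negative expression at a stated threshold level."""

    data: pd.DataFrame  # index: classes, columns: genes
    threshold_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate class identifiers in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.data.index.name = "class"
        self.data.columns.name = None

    @property
    def classes(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def row(self, cls: str) -> pd.Series:
        return self.data.loc[cls]


@dataclass(frozen=True)
class ChemicalEdge:
    pre: str
    post: str
    count: int  # aggregated synapse count, >= 1


@dataclass(frozen=True)
class GapJunction:
    a: str
    b: str
    count: int


@dataclass
class Connectome:
    """Directed chemical edges + undirected gap junctions + transmitter labels.

    ``transmitters`` maps class -> ordered tuple of released transmitters
    (more than one = cotransmission; the first entry is the "major" one).
    """

    chemical_edges: list[ChemicalEdge]
    gap_junctions: list[GapJunction]
    transmitters: dict[str, tuple[str, ...]]

    def classes(self) -> set[str]:
        out: set[str] = set(self.transmitters)
        for e in self.chemical_edges:
            out.update((e.pre, e.post))
        for g in self.gap_junctions:
            out.update((g.a, g.b))
        return out


@dataclass
class PolaritySummary:
    """Per-class signed receptor expression for one transmitter."""

    cls: str
    transmitter: str
    sum_exc: float
    sum_inh: float
    category: str

    @property
    def net(self) -> float:
        return self.sum_exc - self.sum_inh

    @property
    def ratio(self) -> float:
        """Fold magnitude of the dominant over the minor receptor type.

        Infinite (the ``ONLY`` sentinel) when one sum is zero; NaN when both
        are zero.
        """
        lo = min(self.sum_exc, self.sum_inh)
        hi = max(self.sum_exc, self.sum_inh)
        if hi == 0:
            return float("nan")
        if lo == 0:
            return ONLY
        return hi / lo


@dataclass(frozen=True)
class SignedEdge:
    pre: str
    post: str
    transmitter: str
    count: int
    sign: str  # excitatory | inhibitory | no_prediction


@dataclass
class SignedNetwork:
    """Connectome with per-edge polarity labels and per-class summaries."""

    edges: list[SignedEdge]
    gap_junctions: list[GapJunction]
    summaries: list[PolaritySummary] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": s.cls,
                    "transmitter": s.transmitter,
                    "sum_exc": s.sum_exc,
                    "sum_inh": s.sum_inh,
                    "net": s.net,
                    "ratio": s.ratio,
                    "category": s.category,
                }
                for s in self.summaries
            ]
        )

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pre": e.pre,
                    "post": e.post,
                    "transmitter": e.transmitter,
                    "count": e.count,
                    "sign": e.sign,
                }
                for e in self.edges
            ]
        )


def _split_sums(
    expr_row: Mapping[str, float], catalog: ChannelCatalog, transmitter: str
) -> tuple[float, float]:
    """(sum of cation-channel expression, sum of anion-channel expression).

    Genes absent from the catalog are ignored (counted once in the log);
    unknown-selectivity entries are excluded from the sums.
    """
    if transmitter not in TRANSMITTERS:
        raise ValueError(f"unknown transmitter token {transmitter!r}")
    sum_exc = 0.0
    sum_inh = 0.0
    n_unknown_gene = 0
    for gene, value in expr_row.items():
        if value <= 0:
            continue
        if gene not in catalog:
            n_unknown_gene += 1
            continue
        rec = catalog[gene]
        if transmitter not in rec.ligands:
            continue
        if rec.polarity == "excitatory":
            sum_exc += float(value)
        elif rec.polarity == "inhibitory":
            sum_inh += float(value)
        else:
            logger.warning("gene %s has unknown selectivity; skipped", gene)
    if n_unknown_gene:
        logger.debug("%d expressed genes absent from catalog ignored", n_unknown_gene)
    return sum_exc, sum_inh


def classify_receptors(
    expr_row: Mapping[str, float], catalog: ChannelCatalog, transmitter: str
) -> str:
    """Four-group receptor-complement category of one class for one transmitter.

    ``both`` if the class positively expresses at least one cation and one
    anion channel gated by the transmitter; ``excitatory_only`` /
    ``inhibitory_only`` if only one type; ``none`` otherwise.
    """
    sum_exc, sum_inh = _split_sums(expr_row, catalog, transmitter)
    if sum_exc > 0 and sum_inh > 0:
        return "both"
    if sum_exc > 0:
        return "excitatory_only"
    if sum_inh > 0:
        return "inhibitory_only"
    return "none"


def net_polarity(
    expr_row: Mapping[str, float],
    catalog: ChannelCatalog,
    transmitter: str,
    cls: str = "",
) -> PolaritySummary:
    """Summed signed expression of one class's receptors for one transmitter."""
    sum_exc, sum_inh = _split_sums(expr_row, catalog, transmitter)
    category = classify_receptors(expr_row, catalog, transmitter)
    return PolaritySummary(
        cls=cls, transmitter=transmitter, sum_exc=sum_exc, sum_inh=sum_inh,
        category=category,
    )


def predict_edge_signs(
    connectome: Connectome,
    expression: ExpressionMatrix,
    catalog: ChannelCatalog,
    policy: str = "multi",
) -> SignedNetwork:
    """Assign a polarity to every chemical edge of the connectome.

    For each edge, for each transmitter released by the presynaptic class
    (all of them under ``policy="multi"``; only the first-listed one under
    ``policy="major"``), the sign is excitatory if the postsynaptic class's
    net for that transmitter is > 0, inhibitory if < 0, and no_prediction on a
    tie, a ``none`` category, an unknown presynaptic transmitter set, or a
    postsynaptic class missing from the expression matrix. Gap junctions are
    copied through unsigned.
    """
    if policy not in ("multi", "major"):
        raise ValueError(f"unknown policy {policy!r}")
    known = set(expression.classes)
    # per-(class, transmitter) summaries, computed once
    cache: dict[tuple[str, str], PolaritySummary] = {}

    def summary(cls: str, transmitter: str) -> Optional[PolaritySummary]:
        if cls not in known:
            return None
        key = (cls, transmitter)
        if key not in cache:
            cache[key] = net_polarity(
                expression.row(cls), catalog, transmitter, cls=cls
            )
        return cache[key]

    edges: list[SignedEdge] = []
    for e in connectome.chemical_edges:
        released = connectome.transmitters.get(e.pre, ())
        if not released:
            edges.append(
                SignedEdge(e.pre, e.post, "unknown", e.count, "no_prediction")
            )
            continue
        considered = released if policy == "multi" else released[:1]
        for transmitter in considered:
            s = summary(e.post, transmitter)
            if s is None:
                logger.warning(
                    "postsynaptic class %s missing from expression; no prediction",
                    e.post,
                )
                sign = "no_prediction"
            elif s.category == "none" or s.net == 0:
                sign = "no_prediction"
            elif s.net > 0:
                sign = "excitatory"
            else:
                sign = "inhibitory"
            edges.append(SignedEdge(e.pre, e.post, transmitter, e.count, sign))
    summaries = sorted(cache.values(), key=lambda s: (s.cls, s.transmitter))
    return SignedNetwork(
        edges=edges,
        gap_junctions=list(connectome.gap_junctions),
        summaries=summaries,
    )


def category_fractions(
    expression: ExpressionMatrix,
    catalog: ChannelCatalog,
    transmitters: Sequence[str],
) -> pd.DataFrame:
    """Percentage of neural classes per four-group category, per transmitter.

    Rows are transmitters, columns the four categories; each row sums to 100.
    """
    if not expression.classes:
        raise ValueError("expression matrix has no classes")
    rows = {}
    n = len(expression.classes)
    for transmitter in transmitters:
        counts = dict.fromkeys(CATEGORIES, 0)
        for cls in expression.classes:
            counts[classify_receptors(expression.row(cls), catalog, transmitter)] += 1
        rows[transmitter] = {k: 100.0 * v / n for k, v in counts.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))


def edge_sign_fractions(
    signed: SignedNetwork, weight: str = "synapse_count"
) -> pd.DataFrame:
    """Percentage of synapses (or edges) per predicted sign, per transmitter.

    ``weight="synapse_count"`` (default) weights each edge by its aggregated
    synapse count; ``"edge"`` counts connections once. Rows sum to 100.
    """
    if weight not in ("synapse_count", "edge"):
        raise ValueError(f"unknown weight {weight!r}")
    if not signed.edges:
        raise ValueError("signed network has no chemical edges")
    totals: dict[str, dict[str, float]] = {}
    for e in signed.edges:
        w = e.count if weight == "synapse_count" else 1
        totals.setdefault(e.transmitter, dict.fromkeys(SIGNS, 0.0))[e.sign] += w
    rows = {
        t: {k: 100.0 * v / sum(d.values()) for k, v in d.items()}
        for t, d in totals.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SIGNS))
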