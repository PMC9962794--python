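"""Readers and writers for the package's file dialects.

Tabular formats are plain CSV/TSV (pandas); signed networks go to GraphML
(networkx) or SIF plus attribute CSVs. Units are normalized at ingestion:
concentrations to uM, voltages to mV, currents to nA.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .polarity import (
    ChemicalEdge,
    Connectome,
    ExpressionMatrix,
    GapJunction,
    PolaritySummary,
    SignedEdge,
    SignedNetwork,
)
from .tevc import DoseResponseSeries, RampRecording

__all__ = [
    "read_expression",
    "write_expression",
    "read_connectome",
    "write_connectome",
    "collapse_neuron_name",
    "read_peaks",
    "read_ramps",
    "export_signed_network",
    "read_signed_network",
    "RunConfig",
]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_expression(
    path: str | Path, threshold_level: Optional[int] = None
) -> ExpressionMatrix:
    """Read a class x gene expression table (CSV/TSV).

    Orientation is auto-detected from the header token of the first column:
    ``class`` means classes are rows, ``gene`` means genes are rows (the
    matrix is transposed). Negative values, duplicate identifiers and
    non-numeric cells are hard errors naming the offender.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    axis_token = (df.index.name or "").strip().lower()
    if axis_token == "gene":
        df = df.T
        df.index.name = "class"
    elif axis_token != "class":
        raise ValueError(
            "expression header must label the first column 'class' or 'gene', "
            f"got {df.index.name!r}"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"malformed numeric cell at row {bad[0]!r}, column {col!r}"
            )
        df[col] = coerced
    df = df.fillna(0.0).astype(float)
    return ExpressionMatrix(data=df, threshold_level=threshold_level)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "class"
    out.to_csv(path, sep=_sep_for(path))


_SIDE = re.compile(r"[LR]$")
_DORSOVENTRAL = re.compile(r"[DV]$")
_DIGITS = re.compile(r"\d+$")


def collapse_neuron_name(neuron: str) -> str:
    """Default neuron -> class heuristic: strip positional suffixes.

    One trailing L/R is stripped, then one trailing D/V; only if neither
    applied are trailing digits stripped (AVAL -> AVA, RMED -> RME,
    IL2DL -> IL2, VA12 -> VA). A provided mapping table always overrides this.
    """
    out, n_side = _SIDE.subn("", neuron)
    out2, n_dv = _DORSOVENTRAL.subn("", out)
    if n_side or n_dv:
        return out2
    return _DIGITS.sub("", neuron)


def read_connectome(
    edges_path: str | Path,
    nt_path: str | Path,
    class_map_path: Optional[str | Path] = None,
) -> Connectome:
    """Read connectome edge, transmitter and optional neuron->class map CSVs.

    Edge columns: ``pre,post,type{chemical|electrical},count``. Transmitter
    columns: ``class,transmitters`` (pipe-delimited, ordered, first = major).
    Neurons are collapsed to classes via the map when given (an edge endpoint
    missing from the map is an error listing the offenders) or via
    :func:`collapse_neuron_name` otherwise; counts are summed. Electrical rows
    become undirected gap junctions.
    """
    edges = pd.read_csv(edges_path, dtype={"pre": str, "post": str, "type": str})
    if edges.empty and not set(edges.columns) >= {"pre", "post", "type", "count"}:
        edges = pd.DataFrame(columns=["pre", "post", "type", "count"])

    if class_map_path is not None:
        cmap = pd.read_csv(class_map_path, dtype=str)
        mapping = dict(zip(cmap["neuron"], cmap["class"]))
        neurons = set(edges.get("pre", pd.Series(dtype=str))) | set(
            edges.get("post", pd.Series(dtype=str))
        )
        missing = sorted(n for n in neurons if n not in mapping)
        if missing:
            raise ValueError(f"edge references unmapped neuron(s): {missing}")
        to_class = mapping.__getitem__
    else:
        to_class = collapse_neuron_name

    chem: dict[tuple[str, str], int] = {}
    gaps: dict[tuple[str, str], int] = {}
    for _, row in edges.iterrows():
        pre, post = to_class(row["pre"]), to_class(row["post"])
        count = int(row["count"])
        kind = row["type"].strip().lower()
        if kind == "chemical":
            chem[(pre, post)] = chem.get((pre, post), 0) + count
        elif kind == "electrical":
            key = tuple(sorted((pre, post)))
            gaps[key] = gaps.get(key, 0) + count
        else:
            raise ValueError(f"unknown edge type {row['type']!r}")

    nts = pd.read_csv(nt_path, dtype=str)
    transmitters = {
        row["class"]: tuple(
            tok.strip() for tok in row["transmitters"].split("|") if tok.strip()
        )
        for _, row in nts.iterrows()
    }
    return Connectome(
        chemical_edges=[ChemicalEdge(p, q, c) for (p, q), c in sorted(chem.items())],
        gap_junctions=[GapJunction(a, b, c) for (a, b), c in sorted(gaps.items())],
        transmitters=transmitters,
    )


def write_connectome(
    connectome: Connectome, edges_path: str | Path, nt_path: str | Path
) -> None:
    rows = [
        {"pre": e.pre, "post": e.post, "type": "chemical", "count": e.count}
        for e in connectome.chemical_edges
    ] + [
        {"pre": g.a, "post": g.b, "type": "electrical", "count": g.count}
        for g in connectome.gap_junctions
    ]
    pd.DataFrame(rows, columns=["pre", "post", "type", "count"]).to_csv(
        edges_path, index=False
    )
    pd.DataFrame(
        [
            {"class": cls, "transmitters": "|".join(ts)}
            for cls, ts in sorted(connectome.transmitters.items())
        ]
    ).to_csv(nt_path, index=False)


def read_peaks(path: str | Path) -> list[DoseResponseSeries]:
    """Read a long-format peak table: ``oocyte_id,agonist,dose_uM,peak_nA``."""
    df = pd.read_csv(path, dtype={"oocyte_id": str, "agonist": str})
    out = []
    for (oocyte, agonist), grp in df.groupby(["oocyte_id", "agonist"], sort=True):
        grp = grp.sort_values("dose_uM")
        out.append(
            DoseResponseSeries(
                oocyte_id=oocyte,
                agonist=agonist,
                doses=grp["dose_uM"].to_numpy(float),
                peak_currents=grp["peak_nA"].to_numpy(float),
            )
        )
    return out


def read_ramps(path: str | Path) -> list[RampRecording]:
    """Read ramp sweeps: ``voltage_mV,current_nA,condition,ligand_present``."""
    df = pd.read_csv(path)
    out = []
    for (condition, ligand), grp in df.groupby(
        ["condition", "ligand_present"], sort=True
    ):
        grp = grp.sort_values("voltage_mV")
        out.append(
            RampRecording(
                voltages=grp["voltage_mV"].to_numpy(float),
                currents=grp["current_nA"].to_numpy(float),
                condition=condition,
                ligand_present=bool(ligand),
            )
        )
    return out


def export_signed_network(
    signed: SignedNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Write a signed network to GraphML (default) or SIF + attribute CSVs.

    GraphML edges carry the fixed attribute names ``sign``, ``transmitter``
    and ``count``; gap junctions get ``interaction="electrical"`` and no sign.
    The export round-trips losslessly through :func:`read_signed_network`.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.MultiDiGraph()
        for s in signed.summaries:
            if not g.has_node(s.cls):
                g.add_node(s.cls)
            g.nodes[s.cls][f"net_{s.transmitter}"] = float(s.net)
            g.nodes[s.cls][f"category_{s.transmitter}"] = s.category
        for e in signed.edges:
            g.add_edge(
                e.pre,
                e.post,
                sign=e.sign,
                transmitter=e.transmitter,
                count=int(e.count),
                interaction="chemical",
            )
        for gj in signed.gap_junctions:
            g.add_edge(
                gj.a, gj.b, count=int(gj.count), interaction="electrical"
            )
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in signed.edges:
                fh.write(f"{e.pre}\t{e.sign}:{e.transmitter}\t{e.post}\n")
            for gj in signed.gap_junctions:
                fh.write(f"{gj.a}\telectrical\t{gj.b}\n")
        attrs = pd.DataFrame(
            [
                {
                    "pre": e.pre,
                    "post": e.post,
                    "transmitter": e.transmitter,
                    "sign": e.sign,
                    "count": e.count,
                }
                for e in signed.edges
            ]
        )
        attrs.to_csv(path.with_suffix(".edges.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_signed_network(path: str | Path) -> SignedNetwork:
    """Read a GraphML file written by :func:`export_signed_network`."""
    g = nx.read_graphml(path, force_multigraph=True)
    edges: list[SignedEdge] = []
    gaps: list[GapJunction] = []
    for u, v, data in g.edges(data=True):
        if data.get("interaction") == "electrical":
            a, b = sorted((u, v))
            gaps.append(GapJunction(a, b, int(data["count"])))
        else:
            edges.append(
                SignedEdge(
                    pre=u,
                    post=v,
                    transmitter=data["transmitter"],
                    count=int(data["count"]),
                    sign=data["sign"],
                )
            )
    return SignedNetwork(edges=edges, gap_junctions=gaps, summaries=[])


@dataclass
class RunConfig:
    """Validated run configuration, serialized alongside outputs for provenance."""

    inputs: dict = field(default_factory=dict)
    threshold_level: Optional[int] = None
    policy: str = "multi"
    weight: str = "synapse_count"
    seed: Optional[int] = None
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
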