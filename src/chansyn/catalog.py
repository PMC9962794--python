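"""Ligand/ion-selectivity knowledge base for pentameric ligand-gated ion channels.

A :class:`ChannelCatalog` maps each channel gene to the transmitters that gate
it and to its ion selectivity (anion -> inhibitory, cation -> excitatory).
Measured entries come from heterologous-expression electrophysiology; orphan
channels can be filled in by homology-group inference (:func:`infer_orphan`)
optionally guided by the PAR-motif scan (:func:`scan_par_motif`), a
proline-alanine-arginine triplet in the M1-2 intracellular loop that marks
anion selectivity in this superfamily.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "TRANSMITTERS",
    "GROUPS",
    "ChannelRecord",
    "ChannelCatalog",
    "load_catalog",
    "write_catalog",
    "scan_par_motif",
    "infer_orphan",
    "example_catalog",
]

#: Closed transmitter vocabulary. betaine and glycine are accepted tokens but
#: play no polarity role unless a record actually lists them.
TRANSMITTERS = frozenset(
    {
        "ACh",
        "choline",
        "GABA",
        "glutamate",
        "tyramine",
        "octopamine",
        "dopamine",
        "serotonin",
        "histamine",
        "betaine",
        "glycine",
    }
)

#: Known subfamily labels.
GROUPS = frozenset(
    {"ACC", "LGC-57", "LGC-41", "LGC-45", "nAChR", "GABA", "GluCl", "GluR"}
)

_SELECTIVITIES = frozenset({"anion", "cation", "unknown"})
_EVIDENCE = frozenset({"measured", "inferred"})

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Width (residues) of the anchor window at the end of the M1-2 loop segment
#: inside which the PAR triplet is sought.
PAR_ANCHOR_WINDOW = 8


@dataclass(frozen=True)
class ChannelRecord:
    """One gene's ligands, ion selectivity and evidence provenance."""

    gene: str
    group: str
    ligands: frozenset[str]
    selectivity: str  # anion | cation | unknown
    evidence: str  # measured | inferred
    basis: str = ""  # non-empty for inferred records

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r} for {self.gene}")
        if self.selectivity not in _SELECTIVITIES:
            raise ValueError(
                f"unknown selectivity {self.selectivity!r} for {self.gene}"
            )
        if self.evidence not in _EVIDENCE:
            raise ValueError(f"unknown evidence {self.evidence!r} for {self.gene}")
        bad = set(self.ligands) - TRANSMITTERS
        if bad:
            raise ValueError(
                f"unknown transmitter token(s) {sorted(bad)} for {self.gene}"
            )
        if self.evidence == "inferred" and not self.basis:
            raise ValueError(
                f"inferred record {self.gene} must carry an inference basis note"
            )

    @property
    def polarity(self) -> Optional[str]:
        """excitatory iff cation, inhibitory iff anion, None if unknown."""
        if self.selectivity == "cation":
            return "excitatory"
        if self.selectivity == "anion":
            return "inhibitory"
        return None


@dataclass
class ChannelCatalog:
    """Collection of :class:`ChannelRecord` keyed by gene."""

    records: dict[str, ChannelRecord] = field(default_factory=dict)

    def add(self, record: ChannelRecord) -> None:
        if record.gene in self.records:
            raise ValueError(f"duplicate gene {record.gene!r}")
        self.records[record.gene] = record

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> ChannelRecord:
        return self.records[gene]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def genes_for(
        self, transmitter: str, polarity: Optional[str] = None
    ) -> list[ChannelRecord]:
        """Records gated by *transmitter*, optionally filtered by polarity."""
        if transmitter not in TRANSMITTERS:
            raise ValueError(f"unknown transmitter token {transmitter!r}")
        out = [r for r in self if transmitter in r.ligands]
        if polarity is not None:
            out = [r for r in out if r.polarity == polarity]
        return out

    def measured_in_group(self, group: str) -> list[ChannelRecord]:
        return [r for r in self if r.group == group and r.evidence == "measured"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "group": r.group,
                "ligands": "|".join(sorted(r.ligands)),
                "selectivity": r.selectivity,
                "evidence": r.evidence,
                "basis": r.basis,
            }
            for r in self
        ]
        return pd.DataFrame(
            rows, columns=["gene", "group", "ligands", "selectivity", "evidence", "basis"]
        )


def load_catalog(path: str | Path) -> ChannelCatalog:
    """Read a channel catalog CSV.

    Expected columns: ``gene,group,ligands,selectivity,evidence[,basis]`` with
    the ligand list pipe-delimited. Duplicate genes and unknown transmitter or
    selectivity tokens are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"gene", "group", "ligands", "selectivity", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing required column(s): {sorted(missing)}")
    catalog = ChannelCatalog()
    for _, row in df.iterrows():
        ligands = frozenset(
            tok.strip() for tok in row["ligands"].split("|") if tok.strip()
        )
        rec = ChannelRecord(
            gene=row["gene"].strip(),
            group=row["group"].strip(),
            ligands=ligands,
            selectivity=row["selectivity"].strip(),
            evidence=row["evidence"].strip(),
            basis=row.get("basis", "").strip() if "basis" in df.columns else "",
        )
        catalog.add(rec)
    return catalog


def write_catalog(catalog: ChannelCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)


def scan_par_motif(loop_sequence: str, window: int = PAR_ANCHOR_WINDOW) -> str:
    """Predict ion selectivity from the M1-2 intracellular loop segment.

    Returns ``"anion"`` iff the literal triplet ``PAR`` occurs within the
    anchor window (the final *window* residues of the segment), else
    ``"cation"``. Segments shorter than the window give ``"indeterminate"``.
    The caller supplies the loop segment; no topology prediction is attempted.
    """
    seq = loop_sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid character(s) in loop sequence: {sorted(bad)}")
    if len(seq) < window:
        return "indeterminate"
    return "anion" if "PAR" in seq[-window:] else "cation"


def infer_orphan(
    gene: str,
    group: str,
    catalog: ChannelCatalog,
    par_call: Optional[str] = None,
    ligand_mode: str = "union",
) -> ChannelRecord:
    """Infer an orphan channel's ligands and selectivity from its homology group.

    Ligands are pooled (union by default, intersection optionally) over the
    measured members of *group*. Selectivity is *par_call* when supplied,
    otherwise the majority selectivity of the measured members; a tie yields
    ``unknown`` so that no sign is fabricated. The returned record carries
    ``evidence="inferred"`` with a basis note naming the donor genes.
    """
    donors = catalog.measured_in_group(group)
    if not donors:
        raise ValueError(f"no homology basis: group {group!r} has no measured members")
    if ligand_mode == "union":
        ligands: frozenset[str] = frozenset().union(*(d.ligands for d in donors))
    elif ligand_mode == "intersection":
        ligands = frozenset.intersection(*(d.ligands for d in donors))
    else:
        raise ValueError(f"unknown ligand_mode {ligand_mode!r}")

    if par_call is not None:
        if par_call not in {"anion", "cation"}:
            raise ValueError(f"par_call must be anion or cation, got {par_call!r}")
        selectivity = par_call
    else:
        votes = Counter(d.selectivity for d in donors if d.selectivity != "unknown")
        if not votes:
            selectivity = "unknown"
        else:
            top_two = votes.most_common(2)
            if len(top_two) == 2 and top_two[0][1] == top_two[1][1]:
                selectivity = "unknown"  # tie: never fabricate a sign
            else:
                selectivity = top_two[0][0]
    basis = "homology to measured group members: " + ", ".join(
        sorted(d.gene for d in donors)
    )
    if par_call is not None:
        basis += f"; PAR-motif call: {par_call}"
    return ChannelRecord(
        gene=gene,
        group=group,
        ligands=ligands,
        selectivity=selectivity,
        evidence="inferred",
        basis=basis,
    )


def example_catalog() -> ChannelCatalog:
    """The small curated catalog shipped with the package (see data/)."""
    from importlib.resources import files

    return load_catalog(files("chansyn.data").joinpath("example_catalog.csv"))
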