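"""Cholinergic synapse-degree analysis.

Per-class counts of incoming/outgoing cholinergic synapses, degree-ranked
expression heatmaps (with a display cap), and the correlation between a gene's
expression level and a class's cholinergic degree. A class counts as
ACh-producing if ACh appears anywhere in its transmitter list: every synapse
made by such a class is assumed to release ACh, even under cotransmission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .polarity import Connectome, ExpressionMatrix

__all__ = [
    "cholinergic_degrees",
    "degree_ranked_heatmap",
    "CorrelationResult",
    "correlate_degree_expression",
]


def cholinergic_degrees(connectome: Connectome) -> pd.DataFrame:
    """Per-class cholinergic in/out synapse degree.

    ``in_degree``: total synapses received from ACh-producing classes.
    ``out_degree``: total synapses made by the class if it is ACh-producing,
    else 0. Indexed by class, sorted alphabetically.
    """
    classes = sorted(connectome.classes())
    in_deg = dict.fromkeys(classes, 0)
    out_deg = dict.fromkeys(classes, 0)
    for e in connectome.chemical_edges:
        if "ACh" in connectome.transmitters.get(e.pre, ()):
            in_deg[e.post] += e.count
            out_deg[e.pre] += e.count
    return pd.DataFrame(
        {"in_degree": pd.Series(in_deg), "out_degree": pd.Series(out_deg)}
    ).rename_axis("class")


def degree_ranked_heatmap(
    expression: ExpressionMatrix,
    degrees: pd.DataFrame,
    direction: str = "in",
    cap: float = 500.0,
) -> pd.DataFrame:
    """Expression matrix re-ordered by cholinergic degree, clipped at *cap*.

    Rows (classes) are sorted by in- or out-degree descending; values above
    the display ceiling (default 500) are clipped to it. Returns the matrix
    ready for heatmap plotting; clipping is idempotent.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    col = f"{direction}_degree"
    common = [c for c in expression.classes if c in degrees.index]
    order = (
        degrees.loc[common, col]
        .sort_values(ascending=False, kind="stable")
        .index
    )
    mat = expression.data.loc[order].rename_axis("class")
    return mat.clip(upper=cap) if math.isfinite(cap) else mat.copy()


@dataclass
class CorrelationResult:
    """OLS line + Pearson correlation of expression vs synapse degree."""

    slope: float
    intercept: float
    pearson_r: float
    slope_ci: tuple[float, float]  # at ci_level, from the SE of the slope
    ci_level: float
    n: int
    sufficient: bool  # False when <3 positive-expression classes remain

    @property
    def ok(self) -> bool:
        return self.sufficient and not math.isnan(self.pearson_r)


def correlate_degree_expression(
    gene_expression: pd.Series,
    degrees: pd.DataFrame,
    direction: str = "in",
    ci_level: float = 0.68,
) -> CorrelationResult:
    """Correlate one gene's expression with cholinergic degree across classes.

    Classes with zero expression of the gene are removed before fitting; the
    remaining points get an ordinary least-squares line and a Pearson r, with
    a confidence interval on the slope at *ci_level* (default 68%, i.e. about
    one standard error of the estimate). Fewer than 3 surviving points, or a
    degenerate (constant) variable, is flagged rather than raised.
    """
    col = f"{direction}_degree"
    common = gene_expression.index.intersection(degrees.index)
    x = degrees.loc[common, col].astype(float)
    y = gene_expression.loc[common].astype(float)
    mask = y > 0
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3 or x.nunique() < 2 or y.nunique() < 2:
        return CorrelationResult(
            slope=float("nan"), intercept=float("nan"), pearson_r=float("nan"),
            slope_ci=(float("nan"), float("nan")), ci_level=ci_level, n=n,
            sufficient=False,
        )
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 2)
    half = tcrit * fit.stderr
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        slope_ci=(float(fit.slope - half), float(fit.slope + half)),
        ci_level=ci_level,
        n=n,
        sufficient=True,
    )
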