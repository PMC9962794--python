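"""Two-electrode voltage-clamp (TEVC) quantification.

Implements the standard oocyte dose-response workflow: peak extraction from
continuous current traces, per-oocyte I/Imax normalization, three- or
four-parameter Hill fits for agonist EC50 and antagonist IC50, leak-subtracted
reversal-potential (Erev) estimation from voltage ramps, threshold
classification of ion selectivity from Erev shifts under ionic substitution,
and recovery ratios for repeated agonist stimulation.

Sign convention: inward currents are negative; normalization uses magnitudes.
Units throughout: concentrations in uM, voltages in mV, currents in nA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponseSeries",
    "HillFit",
    "InhibitionFit",
    "RampRecording",
    "ReversalShift",
    "hill",
    "extract_peak",
    "normalize_by_imax",
    "fit_dose_response",
    "fit_antagonist",
    "estimate_reversal",
    "delta_erev",
    "classify_ion_selectivity",
    "repeat_stim_ratio",
]

RAMP_CONDITIONS = frozenset({"ND96", "NMDG", "NaGluconate"})


@dataclass
class DoseResponseSeries:
    """Peak currents of one oocyte across an agonist dose series."""

    oocyte_id: str
    agonist: str
    doses: np.ndarray  # uM, strictly positive
    peak_currents: np.ndarray  # nA, signed
    normalized: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.peak_currents = np.asarray(self.peak_currents, dtype=float)
        if self.doses.shape != self.peak_currents.shape:
            raise ValueError("doses and peak_currents must be aligned")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)


@dataclass
class HillFit:
    """Agonist Hill-equation fit result (EC50 in uM)."""

    ec50: float
    hill_slope: float
    top: float
    bottom: float
    n_params: int
    rss: float
    converged: bool


@dataclass
class InhibitionFit:
    """Antagonist (decreasing) Hill fit result (IC50 in uM)."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    converged: bool


@dataclass
class RampRecording:
    """One voltage-ramp sweep (-80 to +60 mV protocol) in a named bath."""

    voltages: np.ndarray  # mV, strictly increasing
    currents: np.ndarray  # nA
    condition: str  # ND96 | NMDG | NaGluconate
    ligand_present: bool

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must be aligned")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.condition not in RAMP_CONDITIONS:
            raise ValueError(f"unknown ramp condition {self.condition!r}")


@dataclass
class ReversalShift:
    """Reversal-potential shift of a substituted bath relative to ND96."""

    erev_ref: float  # mV in ND96
    erev_test: float  # mV in NMDG or NaGluconate
    condition: str

    @property
    def delta(self) -> float:
        return self.erev_test - self.erev_ref


def hill(
    dose: np.ndarray, ec50: float, hill_slope: float, top: float, bottom: float
) -> np.ndarray:
    """R(d) = bottom + (top - bottom) / (1 + (ec50/d)^h)."""
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / d) ** hill_slope)


def extract_peak(
    time: Sequence[float],
    current: Sequence[float],
    window: tuple[float, float],
    baseline_window: Optional[tuple[float, float]] = None,
) -> float:
    """Baseline-subtracted peak current within an application window.

    The baseline is the median current over *baseline_window* (default: the
    whole trace before the window). The peak is the largest-magnitude
    baseline-subtracted sample inside the window, sign preserved.
    """
    t = np.asarray(time, dtype=float)
    i = np.asarray(current, dtype=float)
    t0, t1 = window
    in_win = (t >= t0) & (t <= t1)
    if not np.any(in_win):
        raise ValueError("empty peak-search window")
    if baseline_window is None:
        pre = t < t0
    else:
        b0, b1 = baseline_window
        pre = (t >= b0) & (t <= b1)
    baseline = float(np.median(i[pre])) if np.any(pre) else 0.0
    seg = i[in_win] - baseline
    return float(seg[np.argmax(np.abs(seg))])


def normalize_by_imax(series: DoseResponseSeries) -> DoseResponseSeries:
    """Fill ``normalized`` with |I| / Imax for the oocyte.

    Imax is the largest-magnitude current of the individual oocyte, regardless
    of the dose at which it occurred; exactly one entry equals 1. Idempotent.
    """
    mags = np.abs(series.peak_currents)
    imax = mags.max() if mags.size else 0.0
    if imax == 0.0:
        raise ValueError(f"no response: all peaks zero for oocyte {series.oocyte_id}")
    return DoseResponseSeries(
        oocyte_id=series.oocyte_id,
        agonist=series.agonist,
        doses=series.doses.copy(),
        peak_currents=series.peak_currents.copy(),
        normalized=mags / imax,
    )


_H_BOUNDS = (0.1, 10.0)


def _hill_least_squares(
    doses: np.ndarray,
    response: np.ndarray,
    free_h: bool,
    free_bottom: bool,
    increasing: bool,
) -> tuple[dict, float, bool]:
    """Shared least-squares core for agonist and antagonist fits.

    Parametrized on log10(c50) with multi-start over the dose range to dodge
    local minima on plateau-poor data. Returns (params, rss, converged).
    """
    log_d = np.log10(doses)
    lo, hi = np.log10(doses.min() / 100.0), np.log10(doses.max() * 100.0)
    sign = 1.0 if increasing else -1.0

    def model(theta: np.ndarray) -> np.ndarray:
        log_c50, h, top, bottom = theta
        return bottom + (top - bottom) / (1.0 + 10 ** (sign * h * (log_c50 - log_d)))

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - response

    r_lo, r_hi = float(response.min()), float(response.max())
    span = max(r_hi - r_lo, 1e-6)
    bounds_lo = [lo, _H_BOUNDS[0] if free_h else 1.0 - 1e-12, r_lo - span, 0.0 if not free_bottom else r_lo - span]
    bounds_hi = [hi, _H_BOUNDS[1] if free_h else 1.0 + 1e-12, r_hi + span, 0.0 + 1e-12 if not free_bottom else r_hi + span]

    best = None
    starts = np.linspace(lo + 1.0, hi - 1.0, 5)
    h0s = [1.0] if not free_h else [0.5, 1.0, 2.0]
    for s in starts:
        for h0 in h0s:
            theta0 = np.array(
                [s, h0, r_hi, 0.0 if not free_bottom else r_lo], dtype=float
            )
            theta0 = np.clip(theta0, bounds_lo, bounds_hi)
            try:
                sol = optimize.least_squares(
                    resid, theta0, bounds=(bounds_lo, bounds_hi), method="trf"
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[1]:
                best = (sol, rss)
    if best is None:
        # optimizer never ran to completion; report flat curve honestly
        mean = float(np.mean(response))
        params = {
            "c50": float(np.sqrt(doses.min() * doses.max())),
            "h": 1.0,
            "top": mean,
            "bottom": mean,
        }
        return params, float(np.sum((response - mean) ** 2)), False
    sol, rss = best
    log_c50, h, top, bottom = sol.x
    # fits pinned at the c50 bounds have not located a half-maximal dose
    at_bound = log_c50 <= lo + 1e-9 or log_c50 >= hi - 1e-9
    params = {"c50": float(10**log_c50), "h": float(h), "top": float(top), "bottom": float(bottom)}
    return params, rss, bool(sol.success) and not at_bound


def fit_dose_response(
    doses: Sequence[float],
    normalized: Sequence[float],
    n_params: int = 4,
    three_param_mode: str = "fix_hill",
) -> HillFit:
    """Least-squares Hill fit of an agonist dose-response curve.

    ``n_params=4`` frees {bottom, top, ec50, h}. ``n_params=3`` fixes one
    parameter: the Hill slope at 1 (``three_param_mode="fix_hill"``, default)
    or the floor at 0 (``"fix_bottom"``). EC50 is constrained to
    [min dose / 100, max dose * 100] and h to [0.1, 10] to keep plateau-less
    data from diverging. Non-convergence is reported via ``converged``, never
    raised.
    """
    doses = np.asarray(doses, dtype=float)
    response = np.asarray(normalized, dtype=float)
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    if np.unique(doses).size < n_params:
        raise ValueError(f"need at least {n_params} distinct doses")
    free_h = n_params == 4 or three_param_mode == "fix_bottom"
    free_bottom = n_params == 4 or three_param_mode == "fix_hill"
    params, rss, converged = _hill_least_squares(
        doses, response, free_h=free_h, free_bottom=free_bottom, increasing=True
    )
    return HillFit(
        ec50=params["c50"],
        hill_slope=params["h"] if free_h else 1.0,
        top=params["top"],
        bottom=params["bottom"] if free_bottom else 0.0,
        n_params=n_params,
        rss=rss,
        converged=converged,
    )


def fit_antagonist(
    antagonist_doses: Sequence[float],
    normalized: Sequence[float],
) -> InhibitionFit:
    """Three-parameter decreasing Hill fit for antagonist block.

    Responses are normalized to the lowest antagonist dose (agonist held at
    its EC50). The slope stays free ("variable slope") and the floor is fixed
    at 0; IC50 is the dose of half-maximal block. Flat or non-monotonic data
    still fit; quality is reported via ``converged``.
    """
    doses = np.asarray(antagonist_doses, dtype=float)
    response = np.asarray(normalized, dtype=float)
    if np.unique(doses).size < 3:
        raise ValueError("need at least 3 distinct antagonist doses")
    params, rss, converged = _hill_least_squares(
        doses, response, free_h=True, free_bottom=False, increasing=False
    )
    return InhibitionFit(
        ic50=params["c50"],
        hill_slope=params["h"],
        top=params["top"],
        bottom=0.0,
        rss=rss,
        converged=converged,
    )


def estimate_reversal(
    ramp_ligand: RampRecording,
    ramp_leak: RampRecording,
    refine_window_mv: float = 10.0,
) -> float:
    """Leak-subtracted reversal potential (mV) from a ramp pair.

    The leak sweep (no ligand) is subtracted pointwise from the ligand sweep
    (resampled onto the ligand voltage grid if needed); Erev is the
    zero-crossing of the subtracted I-V, located by linear interpolation
    between the bracketing samples and then refined by an ordinary
    least-squares line over the samples within ``refine_window_mv`` of the
    coarse crossing, which suppresses per-sample recording noise (for clean
    linear data the two coincide exactly). With multiple crossings the one
    nearest 0 mV is taken. Returns NaN when the subtracted current never
    changes sign over the sweep (indeterminate).
    """
    if ramp_ligand.condition != ramp_leak.condition:
        raise ValueError("ramp pair must share a bath condition")
    if not ramp_ligand.ligand_present or ramp_leak.ligand_present:
        raise ValueError("expected (ligand, leak) ramp pair in that order")
    v = ramp_ligand.voltages
    leak_i = ramp_leak.currents
    if not np.array_equal(v, ramp_leak.voltages):
        leak_i = np.interp(v, ramp_leak.voltages, ramp_leak.currents)
    i = ramp_ligand.currents - leak_i
    if np.all(i == 0):
        return float("nan")  # null ligand-gated current: no reversal to find
    crossings = []
    for k in np.nonzero(np.diff(np.sign(i)) != 0)[0]:
        i0, i1 = i[k], i[k + 1]
        if i0 == i1:
            continue
        crossings.append(v[k] - i0 * (v[k + 1] - v[k]) / (i1 - i0))
    crossings.extend(v[i == 0.0].tolist())
    if not crossings:
        return float("nan")
    coarse = float(min(crossings, key=lambda x: abs(x)))
    if refine_window_mv > 0:
        near = np.abs(v - coarse) <= refine_window_mv
        if near.sum() >= 5 and np.ptp(v[near]) > 0:
            slope, intercept = np.polyfit(v[near], i[near], 1)
            if slope != 0:
                refined = -intercept / slope
                lo, hi = v[near].min(), v[near].max()
                if lo <= refined <= hi:
                    return float(refined)
    return coarse


def delta_erev(erev_test: float, erev_ref: float, condition: str) -> ReversalShift:
    """Shift of the test-bath Erev relative to the ND96 reference."""
    return ReversalShift(erev_ref=erev_ref, erev_test=erev_test, condition=condition)


def classify_ion_selectivity(
    shift_low_cl: float, shift_na_free: float, threshold: float = 10.0
) -> str:
    """Classify selectivity from Erev shifts under ionic substitution.

    An anion-selective channel shifts its reversal when chloride is replaced
    (Na gluconate) but not when sodium is (NMDG); a cation-selective channel
    shows the mirrored pattern. Shifts are compared in magnitude against
    *threshold* (mV, default 10); both-above or both-below is indeterminate,
    as is any NaN input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if np.isnan(shift_low_cl) or np.isnan(shift_na_free):
        return "indeterminate"
    cl_moves = abs(shift_low_cl) >= threshold
    na_moves = abs(shift_na_free) >= threshold
    if cl_moves and not na_moves:
        return "anion"
    if na_moves and not cl_moves:
        return "cation"
    return "indeterminate"


def repeat_stim_ratio(
    pulse_pairs: Iterable[tuple[float, float]],
) -> tuple[float, float, int]:
    """Recovery ratio peak2/peak1 aggregated across oocytes at one wash interval.

    Each element of *pulse_pairs* is (first peak, second peak) for one oocyte.
    Oocytes with a zero first-pulse peak are excluded with a warning. Returns
    (mean ratio, SEM, n).
    """
    ratios = []
    for first, second in pulse_pairs:
        if first == 0:
            warnings.warn("oocyte excluded: zero first-pulse peak", stacklevel=2)
            continue
        ratios.append(second / first)
    arr = np.asarray(ratios, dtype=float)
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n
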