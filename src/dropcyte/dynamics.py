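"""Secretion dynamics: active-window extraction, pair-wise temporal pattern
classification, and population-level dynamic summaries.

The assay samples every 30 min, so onset and offset snap to frame boundaries —
sub-frame timing is unknowable. An interval counts as actively secreting when
its concentration increment exceeds ``k * sigma_c``, where ``sigma_c`` is the
blank relocation noise propagated through the local slope of the calibration
curve. Two cytokines in one cell are then classified by window overlap:
disjoint -> sequential, overlap of at least ``rho`` of the shorter window ->
simultaneous, anything between -> semi-sequential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import TimeGrid
from .quantify import CalibrationCurve, ConcentrationTrace, RateEstimate

#: Default active-interval threshold: one-sided 95% normal bound on the
#: difference of two noisy frames.
DEFAULT_K = 1.645 * math.sqrt(2.0)
#: Default overlap fraction of the shorter window above which a pair counts as
#: simultaneous rather than semi-sequential.
DEFAULT_RHO = 0.75
#: Populations with fewer secreting cells than this are suppressed in reports.
MIN_POPULATION = 10

PATTERN_SIMULTANEOUS = "simultaneous"
PATTERN_SEQUENTIAL = "sequential"
PATTERN_SEMI = "semi_sequential"
PATTERN_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ActiveWindow:
    """Frame-aligned interval [onset, offset] of detectable secretion, minutes."""

    cytokine: str
    onset_min: float
    offset_min: float

    def __post_init__(self) -> None:
        if self.onset_min > self.offset_min:
            raise ValueError("onset must be <= offset")

    @property
    def duration_min(self) -> float:
        return self.offset_min - self.onset_min


@dataclass(frozen=True)
class PatternCall:
    """Temporal relationship of one cytokine pair in one co-secreting droplet."""

    droplet_id: str
    cytokine_a: str
    cytokine_b: str
    label: str
    window_a: ActiveWindow | None
    window_b: ActiveWindow | None


def active_windows(
    conc_trace: ConcentrationTrace,
    sigma_blk: float,
    curve: CalibrationCurve,
    grid: TimeGrid,
    k: float = DEFAULT_K,
) -> ActiveWindow | None:
    """Span from the first to the last interval with a significant increment.

    ``sigma_blk`` is the blank-model sd (t0-referenced relocation deltas, a.u.);
    it is converted to concentration units through the calibration slope at the
    local concentration. Returns None when no interval is active.
    """
    conc = np.asarray(conc_trace.concentration, dtype=float)
    inc = np.diff(conc)
    mid = 0.5 * (conc[:-1] + conc[1:])
    sigma_c = sigma_blk * np.asarray(curve.dconc_drelocation(mid), dtype=float)
    active = inc > k * sigma_c
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return None
    t = grid.minutes
    return ActiveWindow(
        cytokine=conc_trace.cytokine,
        onset_min=float(t[idx[0]]),
        offset_min=float(t[idx[-1] + 1]),
    )


def classify_pair(
    window_a: ActiveWindow | None,
    window_b: ActiveWindow | None,
    droplet_id: str = "",
    rho: float = DEFAULT_RHO,
) -> PatternCall:
    """Classify one cytokine pair from its two active windows.

    sequential: zero window intersection; simultaneous: intersection covers at
    least ``rho`` of the shorter window; semi_sequential otherwise;
    indeterminate when either window is missing. Symmetric in the pair.
    """
    name_a = window_a.cytokine if window_a else ""
    name_b = window_b.cytokine if window_b else ""
    if window_a is None or window_b is None:
        label = PATTERN_INDETERMINATE
    else:
        inter = min(window_a.offset_min, window_b.offset_min) - max(
            window_a.onset_min, window_b.onset_min
        )
        inter = max(0.0, inter)
        shorter = min(window_a.duration_min, window_b.duration_min)
        if inter == 0.0:
            label = PATTERN_SEQUENTIAL
        elif inter >= rho * shorter:
            label = PATTERN_SIMULTANEOUS
        else:
            label = PATTERN_SEMI
    return PatternCall(
        droplet_id=droplet_id,
        cytokine_a=name_a,
        cytokine_b=name_b,
        label=label,
        window_a=window_a,
        window_b=window_b,
    )


def classify_droplet(
    windows: Mapping[str, ActiveWindow | None],
    droplet_id: str,
    rho: float = DEFAULT_RHO,
) -> list[PatternCall]:
    """Pair-wise pattern calls for a droplet positive for >= 2 cytokines.

    Triple-positive droplets yield three pair calls; no 3-way label exists.
    """
    calls = []
    for cyt_a, cyt_b in combinations(sorted(windows), 2):
        win_a, win_b = windows[cyt_a], windows[cyt_b]
        call = classify_pair(win_a, win_b, droplet_id=droplet_id, rho=rho)
        # keep cytokine names even when a window is missing
        calls.append(
            PatternCall(
                droplet_id=droplet_id,
                cytokine_a=cyt_a,
                cytokine_b=cyt_b,
                label=call.label,
                window_a=win_a,
                window_b=win_b,
            )
        )
    return calls


@dataclass
class DynamicsSummary:
    """Population-level dynamic profile for one (bin, condition) population.

    Populations below :data:`MIN_POPULATION` secreting cells are suppressed:
    the flag is set and no depicted values are carried.
    """

    population: str
    n_cells: int
    suppressed: bool
    mean_concentration: np.ndarray | None  # nM per frame
    frac_over_100: float | None
    frac_over_1000: float | None


def summarize_population(
    conc_traces: Sequence[ConcentrationTrace],
    rates: Sequence[RateEstimate],
    population: str = "",
    min_cells: int = MIN_POPULATION,
) -> DynamicsSummary:
    """Average in-droplet concentration trajectory and high-secretor fractions.

    High-secretor fractions count cells with average rates above 100 and 1000
    molecules/s among cells with an available rate.
    """
    n = len(conc_traces)
    if n < min_cells:
        return DynamicsSummary(
            population=population,
            n_cells=n,
            suppressed=True,
            mean_concentration=None,
            frac_over_100=None,
            frac_over_1000=None,
        )
    stack = np.vstack([np.asarray(ct.concentration, dtype=float) for ct in conc_traces])
    avg_rates = np.array(
        [r.avg_rate for r in rates if r.available and r.avg_rate is not None]
    )
    frac_100 = float(np.mean(avg_rates > 100.0)) if avg_rates.size else None
    frac_1000 = float(np.mean(avg_rates > 1000.0)) if avg_rates.size else None
    return DynamicsSummary(
        population=population,
        n_cells=n,
        suppressed=False,
        mean_concentration=stack.mean(axis=0),
        frac_over_100=frac_100,
        frac_over_1000=frac_1000,
    )
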