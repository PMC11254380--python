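"""Four-criterion identification of cytokine-secreting cells plus measurement QC.

A droplet is called a secretor for a cytokine when all four hold:

1. ``c_cell``   — positive cell stain (CellTrace/DAPI flag);
2. ``c_exceed`` — some later frame's relocation exceeds the droplet's own
   first-frame relocation plus ``threshold_multiplier * sigma_blk``;
3. ``c_range``  — max - min relocation over the series is greater than
   ``threshold_multiplier * sigma_blk``;
4. ``c_slope``  — the OLS slope of relocation against time is strictly > 0.

``sigma_blk`` is estimated per channel from cell-free droplets of the same
measurement as the sample sd of t0-referenced deltas, matching the form of the
exceed criterion it feeds. All comparisons are strict, mirroring the wording
"exceeding" / "greater than". Polyfunctional cells are droplets positive for
more than one cytokine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import AssayConstants, BlankModel, DropletTrace, Panel, TimeGrid
from .errors import EstimationError

#: Below this many positives per cytokine the study protocol calls for manual
#: inspection of the droplets.
MANUAL_INSPECTION_FLOOR = 50
#: Below this many validated droplets a population is excluded from analysis.
EXCLUSION_FLOOR = 10


@dataclass(frozen=True)
class SecretionCall:
    """Per droplet-cytokine decision with per-criterion flags."""

    droplet_id: str
    cytokine: str
    c_cell: bool
    c_exceed: bool
    c_range: bool
    c_slope: bool

    @property
    def is_secretor(self) -> bool:
        return self.c_cell and self.c_exceed and self.c_range and self.c_slope


@dataclass(frozen=True)
class QCReport:
    """Measurement-level QC flags derived from positive-call counts.

    Flags are recorded per cytokine; they never mutate the calls themselves
    (actual manual inspection is an upstream, human step).
    """

    measurement_id: str
    n_positive: Mapping[str, int]
    manual_inspection_flag: Mapping[str, bool]
    excluded_flag: Mapping[str, bool]

    @property
    def any_manual_inspection(self) -> bool:
        return any(self.manual_inspection_flag.values())

    @property
    def any_excluded(self) -> bool:
        return any(self.excluded_flag.values())


def estimate_blank_sigma(
    traces: Iterable[DropletTrace],
    channel: str,
    floor: int = 30,
) -> tuple[float, int]:
    """Estimate sigma_blk for one channel from cell-free droplets.

    Pools the deltas R(t) - R(t0) over all t > 0 across blank droplets and
    returns their sample standard deviation together with the number of blanks
    used. Raises :class:`EstimationError` when no blanks exist; warns (and
    proceeds) below the configurable ``floor``.
    """
    deltas: list[np.ndarray] = []
    n_blanks = 0
    for trace in traces:
        if trace.has_cell:
            continue
        series = trace.series(channel)
        deltas.append(series[1:] - series[0])
        n_blanks += 1
    if n_blanks == 0:
        raise EstimationError(f"no cell-free droplets to estimate sigma_blk[{channel}]")
    if n_blanks < floor:
        warnings.warn(
            f"only {n_blanks} blank droplets for channel {channel} "
            f"(floor {floor}); sigma_blk estimate may be unstable",
            stacklevel=2,
        )
    pooled = np.concatenate(deltas)
    sigma = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return sigma, n_blanks


def estimate_blanks(
    traces: Sequence[DropletTrace],
    panel: Panel,
    floor: int = 30,
) -> BlankModel:
    """BlankModel over all panel channels."""
    sigma: dict[str, float] = {}
    n: dict[str, int] = {}
    for ch in panel.channels:
        sigma[ch], n[ch] = estimate_blank_sigma(traces, ch, floor=floor)
    return BlankModel(sigma_blk=sigma, n_blanks=n)


def criterion_exceed(
    series: np.ndarray, sigma_blk: float, multiplier: float
) -> bool:
    """True iff some frame after t0 exceeds R(t0) + multiplier * sigma_blk."""
    series = np.asarray(series, dtype=float)
    threshold = series[0] + multiplier * sigma_blk
    return bool(np.any(series[1:] > threshold))


def criterion_range(
    series: np.ndarray, sigma_blk: float, multiplier: float
) -> bool:
    """True iff max - min relocation is strictly greater than multiplier * sigma_blk."""
    series = np.asarray(series, dtype=float)
    return bool(series.max() - series.min() > multiplier * sigma_blk)


def criterion_slope(series: np.ndarray, times_min: np.ndarray) -> bool:
    """True iff the ordinary-least-squares slope of R against time is strictly > 0.

    The OLS slope sign equals the sign of cov(t, R); since the centered times
    sum to zero, sum((t - mean(t)) * R) is that covariance without centering R,
    which keeps exactly symmetric series at exactly zero.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(times_min, dtype=float)
    cov = float(np.sum((t - t.mean()) * series))
    return cov > 0.0


def call_droplet(
    trace: DropletTrace,
    blanks: BlankModel,
    panel: Panel,
    constants: AssayConstants,
    grid: TimeGrid,
) -> list[SecretionCall]:
    """All per-cytokine calls for one droplet."""
    calls = []
    for ch, cytokine in panel.channel_map.items():
        if ch not in blanks.sigma_blk:
            raise EstimationError(f"no blank sigma for channel {ch}")
        series = trace.series(ch)
        sigma = blanks.sigma_blk[ch]
        calls.append(
            SecretionCall(
                droplet_id=trace.droplet_id,
                cytokine=cytokine,
                c_cell=bool(trace.has_cell),
                c_exceed=criterion_exceed(series, sigma, constants.threshold_multiplier),
                c_range=criterion_range(series, sigma, constants.threshold_multiplier),
                c_slope=criterion_slope(series, grid.minutes),
            )
        )
    return calls


def call_secretors(
    traces: Sequence[DropletTrace],
    blanks: BlankModel,
    panel: Panel,
    constants: AssayConstants,
    grid: TimeGrid,
) -> list[SecretionCall]:
    """One call per (cell-containing droplet, panel cytokine).

    Cell-free droplets produce no calls: they fail the stain criterion by
    definition and only contribute to the blank model.
    """
    calls: list[SecretionCall] = []
    for trace in traces:
        if not trace.has_cell:
            continue
        calls.extend(call_droplet(trace, blanks, panel, constants, grid))
    return calls


def positive_sets(calls: Iterable[SecretionCall]) -> dict[str, frozenset[str]]:
    """Map droplet_id -> set of cytokines called positive (secreting droplets only)."""
    out: dict[str, set[str]] = {}
    for call in calls:
        if call.is_secretor:
            out.setdefault(call.droplet_id, set()).add(call.cytokine)
    return {k: frozenset(v) for k, v in out.items()}


def qc_measurement(
    calls: Sequence[SecretionCall],
    measurement_id: str,
    panel: Panel,
) -> QCReport:
    """Flag cytokines with few positives for manual inspection / exclusion."""
    n_pos = {cyt: 0 for cyt in panel.cytokines}
    for call in calls:
        if call.is_secretor:
            n_pos[call.cytokine] += 1
    manual = {cyt: n < MANUAL_INSPECTION_FLOOR for cyt, n in n_pos.items()}
    excluded = {cyt: n < EXCLUSION_FLOOR for cyt, n in n_pos.items()}
    return QCReport(
        measurement_id=measurement_id,
        n_positive=n_pos,
        manual_inspection_flag=manual,
        excluded_flag=excluded,
    )
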