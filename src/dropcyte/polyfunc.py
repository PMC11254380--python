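"""Polyfunctionality binning: cytokine-combination bins, multiplicity rollups,
cross-condition aggregation and comparison.

Every secreting cell contributes to exactly one combination bin — the full set
of cytokines it was called positive for — so bins are mutually exclusive and
their counts sum to the cytokine-secreting-cell (CSC) total. Percentages come
in two denominators: %Bin of all assayed cells (sum of cells in bin over cells
per measurement) and the CSC-normalized form (% of all secreting cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import SecretionCall, positive_sets
from .core import Panel
from .errors import ConfigurationError, PairingError

BinKey = frozenset  # frozenset of cytokine names, size 1-3


@dataclass(frozen=True)
class BinStats:
    count: int
    pct_total: float
    pct_csc: float | None  # None when there are no CSCs


@dataclass
class BinSummary:
    """Counts and percentages per combination bin and per multiplicity."""

    measurement_id: str
    n_total_cells: int
    n_csc: int
    bins: dict[BinKey, BinStats]
    multiplicity: dict[int, BinStats]

    def multiplicity_pct(self, n: int, normalized: bool = False) -> float:
        stats = self.multiplicity.get(n)
        if stats is None:
            return 0.0
        if normalized:
            return stats.pct_csc if stats.pct_csc is not None else 0.0
        return stats.pct_total

    def two_or_more_pct(self, normalized: bool = False) -> float:
        """The 'two or more cytokines' grouping: bi + tri."""
        return self.multiplicity_pct(2, normalized) + self.multiplicity_pct(3, normalized)


def bin_cells(
    calls: Sequence[SecretionCall],
    panel: Panel,
    n_total_cells: int,
    measurement_id: str = "",
) -> BinSummary:
    """Assign each secreting cell to its exact cytokine-combination bin.

    ``n_total_cells`` is the denominator of %Bin — all assayed cell-containing
    droplets of the measurement, whether secreting or not.
    """
    panel_cytokines = set(panel.cytokines)
    for call in calls:
        if call.cytokine not in panel_cytokines:
            raise ConfigurationError(
                f"call for {call.cytokine!r} outside panel {panel.panel_id}"
            )
    combos = positive_sets(calls)
    if n_total_cells < len(combos):
        raise ConfigurationError("n_total_cells smaller than the number of called cells")
    n_csc = len(combos)

    counts: dict[BinKey, int] = {}
    for combo in combos.values():
        counts[combo] = counts.get(combo, 0) + 1

    def stats(count: int) -> BinStats:
        pct_total = 100.0 * count / n_total_cells if n_total_cells else 0.0
        pct_csc = 100.0 * count / n_csc if n_csc else None
        return BinStats(count=count, pct_total=pct_total, pct_csc=pct_csc)

    bins = {key: stats(c) for key, c in counts.items()}
    mult_counts: dict[int, int] = {}
    for key, c in counts.items():
        mult_counts[len(key)] = mult_counts.get(len(key), 0) + c
    multiplicity = {n: stats(c) for n, c in sorted(mult_counts.items())}
    return BinSummary(
        measurement_id=measurement_id,
        n_total_cells=n_total_cells,
        n_csc=n_csc,
        bins=bins,
        multiplicity=multiplicity,
    )


@dataclass(frozen=True)
class AggregateStat:
    mean: float
    sem: float | None  # None for a single measurement
    n: int
    values: tuple[float, ...]


def mean_sem(values: Sequence[float]) -> AggregateStat:
    arr = np.asarray(values, dtype=float)
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return AggregateStat(mean=float(arr.mean()), sem=sem, n=arr.size, values=tuple(arr))


def aggregate_measurements(
    summaries: Mapping[object, Mapping[str, BinSummary]],
    normalized: bool = False,
) -> dict[object, dict[int, AggregateStat]]:
    """Per-multiplicity mean +/- SEM at each condition (e.g. stimulation duration).

    ``summaries`` maps condition -> {measurement key -> BinSummary}; every
    condition must hold the same measurement keys so downstream paired tests
    stay paired (values are emitted in sorted-key order). ``normalized``
    switches the metric from %-of-all-cells to %-of-CSCs.
    """
    key_sets = {cond: frozenset(group) for cond, group in summaries.items()}
    reference = None
    for cond, keys in key_sets.items():
        if reference is None:
            reference = keys
        elif keys != reference:
            raise PairingError(
                f"condition {cond!r} has measurement keys {sorted(keys)} "
                f"!= {sorted(reference)}"
            )
    out: dict[object, dict[int, AggregateStat]] = {}
    for cond, group in summaries.items():
        per_mult: dict[int, AggregateStat] = {}
        for mult in (1, 2, 3):
            values = [
                group[k].multiplicity_pct(mult, normalized) for k in sorted(group)
            ]
            per_mult[mult] = mean_sem(values)
        out[cond] = per_mult
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Delta (B - A, percentage points) and fold change (B / A) for one bin."""

    key: object  # BinKey or multiplicity int or "2+"
    value_a: float
    value_b: float

    @property
    def delta(self) -> float:
        return self.value_b - self.value_a

    @property
    def fold_change(self) -> float | None:
        if self.value_a <= 0:
            return None
        return self.value_b / self.value_a


def compare_conditions(
    summary_a: BinSummary,
    summary_b: BinSummary,
    normalized: bool = False,
) -> list[ComparisonResult]:
    """Per-bin and per-multiplicity comparisons between two conditions."""

    def pct(summary: BinSummary, key: BinKey) -> float:
        stats = summary.bins.get(key)
        if stats is None:
            return 0.0
        if normalized:
            return stats.pct_csc if stats.pct_csc is not None else 0.0
        return stats.pct_total

    results: list[ComparisonResult] = []
    for key in sorted(
        set(summary_a.bins) | set(summary_b.bins), key=lambda k: (len(k), sorted(k))
    ):
        results.append(ComparisonResult(key, pct(summary_a, key), pct(summary_b, key)))
    for mult in (1, 2, 3):
        results.append(
            ComparisonResult(
                mult,
                summary_a.multiplicity_pct(mult, normalized),
                summary_b.multiplicity_pct(mult, normalized),
            )
        )
    results.append(
        ComparisonResult(
            "2+",
            summary_a.two_or_more_pct(normalized),
            summary_b.two_or_more_pct(normalized),
        )
    )
    return results
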