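"""Shared constants, time grid, panels, and the domain types used across pipeline stages.

The unit of analysis is a droplet: a ~65-pL water-in-oil emulsion containing
zero or more cells, imaged on a fixed time grid (every 30 min over 4 hr by
default) on three fluorescence channels. Each channel reports "relocation" —
fluorescence accumulating on the magnetized nanoparticle aggregate (beadline)
as secreted cytokine is captured — in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

#: Avogadro's number, molecules per mole (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Default calling threshold multiplier: a one-sided 95% normal bound (1.645)
#: on a difference of two frames, i.e. 1.645 * 2 = 3.29.
DEFAULT_THRESHOLD_MULTIPLIER = 1.645 * 2

#: Stimulants used in the assay; `media` is the unstimulated control.
STIMULANTS = frozenset(
    {"LPS", "zymosan", "PMA_ionomycin", "antiCD3_antiCD28", "PHA", "media"}
)

#: Stimulation durations (hours) at which measurements were taken.
STIM_DURATIONS_HR = frozenset({1, 6, 16, 24})


@dataclass(frozen=True)
class AssayConstants:
    """Physical and protocol constants of the droplet assay.

    Parameters
    ----------
    droplet_volume_pl : droplet volume in picolitres.
    avogadro : molecules per mole.
    threshold_multiplier : multiplier on sigma_blk in the calling criteria.
    frame_interval_min : imaging interval in minutes.
    duration_min : total measurement duration in minutes.
    """

    droplet_volume_pl: float = 65.0
    avogadro: float = AVOGADRO
    threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER
    frame_interval_min: float = 30.0
    duration_min: float = 240.0

    def __post_init__(self) -> None:
        for name in (
            "droplet_volume_pl",
            "avogadro",
            "threshold_multiplier",
            "frame_interval_min",
            "duration_min",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    @property
    def droplet_volume_l(self) -> float:
        return self.droplet_volume_pl * 1e-12

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_min * 60.0


@dataclass(frozen=True)
class TimeGrid:
    """Ordered imaging timepoints in minutes, starting at the encapsulation frame t0=0."""

    timepoints: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2:
            raise ConfigurationError("time grid needs at least two frames")
        if t[0] != 0.0:
            raise ConfigurationError("time grid must start at 0")
        d = np.diff(t)
        if not np.all(d > 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if not np.allclose(d, d[0]):
            raise ConfigurationError("time grid must be uniformly spaced")

    @property
    def minutes(self) -> np.ndarray:
        return np.asarray(self.timepoints, dtype=float)

    @property
    def seconds(self) -> np.ndarray:
        return self.minutes * 60.0

    @property
    def n_frames(self) -> int:
        return len(self.timepoints)

    @property
    def frame_interval_min(self) -> float:
        return self.timepoints[1] - self.timepoints[0]


def make_time_grid(frame_interval_min: float, duration_min: float) -> TimeGrid:
    """Build the uniform grid 0, dt, ..., duration (inclusive).

    Raises :class:`ConfigurationError` when the interval does not divide the
    duration, so a 30-min interval over 4 hr gives 9 frames including t0.
    """
    if frame_interval_min <= 0 or duration_min <= 0:
        raise ConfigurationError("interval and duration must be positive")
    n_intervals = duration_min / frame_interval_min
    if abs(n_intervals - round(n_intervals)) > 1e-9:
        raise ConfigurationError(
            f"frame interval {frame_interval_min} min does not divide "
            f"duration {duration_min} min"
        )
    n = int(round(n_intervals))
    return TimeGrid(tuple(float(i) * frame_interval_min for i in range(n + 1)))


DEFAULT_GRID = make_time_grid(30.0, 240.0)


@dataclass(frozen=True)
class Panel:
    """A multiplexed panel: mapping of fluorescence channel label -> cytokine name."""

    panel_id: str
    channel_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.channel_map) != 3:
            raise ConfigurationError("a panel has exactly 3 channels")
        names = list(self.channel_map.values())
        if len(set(names)) != len(names):
            raise ConfigurationError("cytokine names must be unique within a panel")
        object.__setattr__(self, "channel_map", dict(self.channel_map))

    @property
    def channels(self) -> list[str]:
        return list(self.channel_map)

    @property
    def cytokines(self) -> list[str]:
        return list(self.channel_map.values())

    def channel_for(self, cytokine: str) -> str:
        for ch, cyt in self.channel_map.items():
            if cyt == cytokine:
                return ch
        raise KeyError(cytokine)


# Channel labels are opaque strings; the fluorophores actually used on each
# channel are documentation only and irrelevant to the analysis.
BUILTIN_PANELS: dict[str, Panel] = {
    "panel1": Panel("panel1", {"ch1": "IL-6", "ch2": "TNF-a", "ch3": "IFN-g"}),
    "panel2": Panel("panel2", {"ch1": "IL-2", "ch2": "IL-8", "ch3": "MIP-1a"}),
    "panel1b": Panel("panel1b", {"ch1": "IL-6", "ch2": "TNF-a", "ch3": "IL-1b"}),
}


@dataclass(frozen=True)
class MeasurementMeta:
    """Metadata of one measurement (one chip run)."""

    stimulant: str
    stim_duration_hr: int
    panel_id: str
    donor_id: str | None = None

    def __post_init__(self) -> None:
        if self.stimulant not in STIMULANTS:
            raise ConfigurationError(
                f"unknown stimulant {self.stimulant!r}; known: {sorted(STIMULANTS)}"
            )
        if self.stim_duration_hr not in STIM_DURATIONS_HR:
            raise ConfigurationError(
                f"stim_duration_hr must be one of {sorted(STIM_DURATIONS_HR)}"
            )

    @property
    def measurement_id(self) -> str:
        donor = self.donor_id or "na"
        return f"{self.stimulant}_{self.stim_duration_hr}h_{self.panel_id}_{donor}"


@dataclass
class DropletTrace:
    """One droplet's multichannel relocation time series plus its cell-stain flag.

    ``relocation`` maps channel label -> array of arbitrary-unit values, one per
    grid frame. ``has_cell`` is the CellTrace (DAPI channel) positivity.
    The droplet's own first-frame relocation serves as its baseline
    (mu_relocation_t0) in the calling criteria.
    """

    droplet_id: str
    measurement_id: str
    has_cell: bool
    relocation: dict[str, np.ndarray]

    def validate(self, grid: TimeGrid) -> None:
        for ch, series in self.relocation.items():
            series = np.asarray(series, dtype=float)
            if series.shape != (grid.n_frames,):
                raise ConfigurationError(
                    f"droplet {self.droplet_id}: channel {ch} has {series.size} "
                    f"frames, grid has {grid.n_frames}"
                )
            if not np.all(np.isfinite(series)):
                raise ConfigurationError(
                    f"droplet {self.droplet_id}: non-finite relocation on {ch}"
                )

    def series(self, channel: str) -> np.ndarray:
        return np.asarray(self.relocation[channel], dtype=float)


@dataclass(frozen=True)
class BlankModel:
    """Per-channel relocation noise estimated from cell-free (blank) droplets.

    ``sigma_blk`` is the sd of t0-referenced relocation deltas, the scale the
    calling thresholds multiply.
    """

    sigma_blk: Mapping[str, float]
    n_blanks: Mapping[str, int]

    def __post_init__(self) -> None:
        for ch, s in self.sigma_blk.items():
            if s < 0:
                raise ConfigurationError(f"sigma_blk[{ch}] must be >= 0")
        for ch, n in self.n_blanks.items():
            if n < 1:
                raise ConfigurationError(f"n_blanks[{ch}] must be >= 1")
        object.__setattr__(self, "sigma_blk", dict(self.sigma_blk))
        object.__setattr__(self, "n_blanks", dict(self.n_blanks))
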