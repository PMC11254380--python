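"""Forward simulator for droplet secretion assays with known ground truth.

Emulates the physical measurement: Poisson encapsulation of cells into 65-pL
droplets, per-cell cytokine secretion programs (lognormal rates, onset/offset
windows, configurable simultaneous / sequential / semi-sequential co-secretion
patterns), accumulation of secreted molecules into in-droplet concentration,
the inverse calibration map back to fluorescence relocation, and additive
Gaussian frame noise. Cell-free droplets emit baseline plus noise only.

No degradation, diffusion limits, or immunoassay binding kinetics are
modelled: the downstream analysis quantifies accumulated concentration only.
Multi-cell droplets are simulated faithfully (secretion sums over cells); the
caller cannot distinguish occupancy and treats them as one cell — a deliberate
realism stressor recorded in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AssayConstants,
    BUILTIN_PANELS,
    DropletTrace,
    MeasurementMeta,
    Panel,
    TimeGrid,
    make_time_grid,
)
from .errors import ConfigurationError
from .quantify import CalibrationCurve, linear_curve

PATTERN_LABELS = ("simultaneous", "sequential", "semi_sequential")


@dataclass(frozen=True)
class SecretionProgram:
    """One cell's secretion of one cytokine: constant rate inside [onset, offset]."""

    cytokine: str
    rate: float  # molecules/second
    onset_min: float
    offset_min: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("secretion rate must be >= 0")
        if not 0 <= self.onset_min <= self.offset_min:
            raise ConfigurationError("need 0 <= onset <= offset")

    def active_seconds(self, t_min: float) -> float:
        """Seconds of active secretion within [0, t]."""
        return max(0.0, (min(t_min, self.offset_min) - self.onset_min)) * 60.0


@dataclass
class SimConfig:
    """Study conditions of a simulated measurement.

    Defaults reflect the assay's operating point: loading of 0.3 cells/droplet
    (within the 0.2-0.4 protocol range), co-secretion pattern mix of roughly
    40/40/20% simultaneous/sequential/semi-sequential, and lognormal secretion
    rates whose support spans ~1-1000 molecules/s (median ~30 molecules/s).
    ``secretor_fraction`` / ``sigma_blk`` / ``rate_lognormal`` accept either a
    scalar applied to every cytokine/channel or a per-name mapping.
    """

    n_droplets: int
    seed: int
    cell_loading: float = 0.3
    secretor_fraction: float | Mapping[str, float] = 0.08
    rate_lognormal: tuple[float, float] | Mapping[str, tuple[float, float]] = (
        math.log(30.0),
        1.5,
    )
    pattern_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    sigma_blk: float | Mapping[str, float] = 5.0
    baseline_mean: float = 100.0
    baseline_sd: float = 10.0
    calibration: Mapping[str, CalibrationCurve] | None = None
    window_mode: str = "uniform"  # "uniform" onset over the run, or "full" windows

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ConfigurationError("n_droplets must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not 0 < self.cell_loading <= 2.0:
            raise ConfigurationError("cell_loading out of plausible range (0, 2]")
        if abs(sum(self.pattern_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("pattern_fractions must sum to 1")
        if self.window_mode not in ("uniform", "full"):
            raise ConfigurationError("window_mode must be 'uniform' or 'full'")

    def fraction_for(self, cytokine: str) -> float:
        if isinstance(self.secretor_fraction, Mapping):
            return self.secretor_fraction[cytokine]
        return self.secretor_fraction

    def lognormal_for(self, cytokine: str) -> tuple[float, float]:
        if isinstance(self.rate_lognormal, Mapping):
            return self.rate_lognormal[cytokine]
        return self.rate_lognormal

    def sigma_for(self, channel: str) -> float:
        if isinstance(self.sigma_blk, Mapping):
            return self.sigma_blk[channel]
        return self.sigma_blk


def default_calibration(
    panel: Panel, gain_nm_per_au: float = 0.05, c_max: float = 500.0
) -> dict[str, CalibrationCurve]:
    """Toy linear curves for simulation and tests: 0.05 nM/a.u., c_max 500 nM."""
    return {cyt: linear_curve(cyt, gain_nm_per_au, c_max) for cyt in panel.cytokines}


@dataclass
class DropletTruth:
    droplet_id: str
    n_cells: int
    # (cell_index, program) so multi-cell droplets stay attributable
    programs: list[tuple[int, SecretionProgram]] = field(default_factory=list)
    # frozenset({cytA, cytB}) -> pattern label, for co-secreting cells
    patterns: dict[frozenset[str], str] = field(default_factory=dict)

    def secreted_cytokines(self) -> frozenset[str]:
        return frozenset(p.cytokine for _, p in self.programs if p.rate > 0)

    def total_rate(self, cytokine: str) -> float:
        """Droplet-level constant-equivalent rate: sum over cells, full-window only."""
        return sum(p.rate for _, p in self.programs if p.cytokine == cytokine)


@dataclass
class GroundTruth:
    """Who secretes what, at which rate, with which temporal pattern."""

    droplets: dict[str, DropletTruth]

    def secretor_ids(self, cytokine: str) -> frozenset[str]:
        return frozenset(
            d.droplet_id
            for d in self.droplets.values()
            if cytokine in d.secreted_cytokines()
        )


def _mono_window(rng: np.random.Generator, grid: TimeGrid, mode: str) -> tuple[float, float]:
    dt = grid.frame_interval_min
    nint = grid.n_frames - 1
    if mode == "full":
        return 0.0, nint * dt
    onset = int(rng.integers(0, nint // 2 + 1))
    offset = int(rng.integers(onset + 2, nint + 1))
    return onset * dt, offset * dt


def assign_pattern(
    pattern_fractions: Sequence[float],
    rng: np.random.Generator,
    grid: TimeGrid,
) -> tuple[str, tuple[float, float], tuple[float, float]]:
    """Draw a co-secretion pattern label and frame-aligned windows for a cytokine pair.

    * simultaneous: identical windows;
    * sequential: disjoint windows separated by one frame (zero intersection);
    * semi_sequential: overlapping by one frame, well under 75% of the shorter
      window so the overlap never qualifies as simultaneous.
    """
    if abs(sum(pattern_fractions) - 1.0) > 1e-9:
        raise ConfigurationError("pattern fractions must sum to 1")
    dt = grid.frame_interval_min
    nint = grid.n_frames - 1
    duration = nint * dt
    label = PATTERN_LABELS[rng.choice(3, p=np.asarray(pattern_fractions, dtype=float))]
    if label == "simultaneous":
        onset = int(rng.integers(0, max(1, nint - 3)))
        offset = int(rng.integers(onset + 3, nint + 1))
        win = (onset * dt, offset * dt)
        return label, win, win
    if label == "sequential":
        b = int(rng.integers(max(2, nint // 3), nint // 2 + 1))
        onset_a = int(rng.integers(0, 2))
        win_a = (onset_a * dt, b * dt)
        win_b = ((b + 1) * dt, duration)
    else:  # semi_sequential: one-frame overlap
        m = int(rng.integers(max(2, nint // 3), max(3, nint - 2)))
        win_a = (0.0, m * dt)
        win_b = ((m - 1) * dt, duration)
    if rng.random() < 0.5:  # which cytokine leads is arbitrary
        win_a, win_b = win_b, win_a
    return label, win_a, win_b


def _concentration_nm(
    programs: Sequence[SecretionProgram],
    grid: TimeGrid,
    constants: AssayConstants,
) -> np.ndarray:
    per_nm = constants.droplet_volume_l * constants.avogadro * 1e-9  # molecules per nM
    conc = np.zeros(grid.n_frames)
    for prog in programs:
        if prog.rate <= 0:
            continue
        conc += prog.rate * np.array(
            [prog.active_seconds(t) for t in grid.minutes]
        ) / per_nm
    return conc


def simulate_droplet(
    droplet_id: str,
    measurement_id: str,
    rng: np.random.Generator,
    config: SimConfig,
    panel: Panel,
    calibration: Mapping[str, CalibrationCurve],
    constants: AssayConstants,
    grid: TimeGrid,
) -> tuple[DropletTrace, DropletTruth]:
    n_cells = int(rng.poisson(config.cell_loading))
    truth = DropletTruth(droplet_id=droplet_id, n_cells=n_cells)
    for cell in range(n_cells):
        secreted = [
            cyt for cyt in panel.cytokines if rng.random() < config.fraction_for(cyt)
        ]
        windows: dict[str, tuple[float, float]] = {}
        if len(secreted) >= 2:
            order = list(rng.permutation(len(secreted)))
            pair = (secreted[order[0]], secreted[order[1]])
            label, win_a, win_b = assign_pattern(config.pattern_fractions, rng, grid)
            windows[pair[0]], windows[pair[1]] = win_a, win_b
            truth.patterns[frozenset(pair)] = label
            for cyt in secreted:
                if cyt not in windows:
                    windows[cyt] = _mono_window(rng, grid, config.window_mode)
        elif len(secreted) == 1:
            windows[secreted[0]] = _mono_window(rng, grid, config.window_mode)
        for cyt in secreted:
            mu, sig = config.lognormal_for(cyt)
            rate = float(rng.lognormal(mu, sig))
            onset, offset = windows[cyt]
            truth.programs.append(
                (cell, SecretionProgram(cyt, rate, onset, offset))
            )
    relocation: dict[str, np.ndarray] = {}
    for ch in panel.channels:
        cyt = panel.channel_map[ch]
        curve = calibration[cyt]
        progs = [p for _, p in truth.programs if p.cytokine == cyt]
        conc = np.minimum(_concentration_nm(progs, grid, constants), curve.c_max)
        baseline = config.baseline_mean + (
            rng.normal(0.0, config.baseline_sd) if config.baseline_sd > 0 else 0.0
        )
        noise_sd = config.sigma_for(ch)
        noise = rng.normal(0.0, noise_sd, grid.n_frames) if noise_sd > 0 else 0.0
        relocation[ch] = baseline + np.asarray(curve.relocation(conc)) + noise
    trace = DropletTrace(
        droplet_id=droplet_id,
        measurement_id=measurement_id,
        has_cell=n_cells >= 1,
        relocation=relocation,
    )
    return trace, truth


def simulate_measurement(
    config: SimConfig,
    meta: MeasurementMeta,
    constants: AssayConstants | None = None,
    grid: TimeGrid | None = None,
    panel: Panel | None = None,
) -> tuple[list[DropletTrace], GroundTruth]:
    """Simulate one measurement: a list of droplet traces plus ground truth.

    Deterministic: identical (config, meta) yield bit-identical output. Each
    droplet consumes an independent substream spawned from the root seed, so
    droplet order never changes results.
    """
    constants = constants or AssayConstants()
    grid = grid or make_time_grid(constants.frame_interval_min, constants.duration_min)
    panel = panel or BUILTIN_PANELS[meta.panel_id]
    calibration = config.calibration or default_calibration(panel)
    missing = [c for c in panel.cytokines if c not in calibration]
    if missing:
        raise ConfigurationError(f"missing calibration for: {', '.join(missing)}")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_droplets)
    traces: list[DropletTrace] = []
    truths: dict[str, DropletTruth] = {}
    width = len(str(config.n_droplets - 1))
    for i, stream in enumerate(streams):
        droplet_id = f"d{i:0{width}d}"
        trace, truth = simulate_droplet(
            droplet_id,
            meta.measurement_id,
            np.random.default_rng(stream),
            config,
            panel,
            calibration,
            constants,
            grid,
        )
        traces.append(trace)
        truths[droplet_id] = truth
    return traces, GroundTruth(droplets=truths)
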