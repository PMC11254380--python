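"""Readers/writers for on-disk artifacts and the YAML configuration layer.

Trace tables are long (tidy) CSV — one row per (droplet, frame, channel) —
robust to panels with different channel counts. Summaries are JSON with
sorted keys and a provenance block (config hash, seed, thresholds) so a run
can be reproduced from its outputs. All writers are deterministic: stable row
ordering, fixed float formatting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import SecretionCall
from .core import (
    AssayConstants,
    BUILTIN_PANELS,
    DropletTrace,
    Panel,
    TimeGrid,
    make_time_grid,
)
from .dynamics import DEFAULT_K, DEFAULT_RHO, PatternCall
from .errors import ConfigurationError, IntegrityError, SchemaError
from .polyfunc import BinSummary
from .quantify import CalibrationCurve, RateEstimate
from .simulate import GroundTruth, SimConfig
from .stats import StatResult

TRACE_COLUMNS = [
    "measurement_id",
    "droplet_id",
    "time_min",
    "channel",
    "relocation",
    "has_cell",
]


# ---------------------------------------------------------------------------
# traces

def write_traces(traces: Sequence[DropletTrace], path, grid: TimeGrid) -> None:
    rows = []
    for trace in traces:
        for ch in sorted(trace.relocation):
            series = trace.series(ch)
            for t, r in zip(grid.minutes, series):
                rows.append(
                    (
                        trace.measurement_id,
                        trace.droplet_id,
                        float(t),
                        ch,
                        float(r),
                        bool(trace.has_cell),
                    )
                )
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df = df.sort_values(["droplet_id", "channel", "time_min"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")


def read_traces(path, panel: Panel, grid: TimeGrid) -> list[DropletTrace]:
    """Read a long-format trace CSV into complete droplet traces.

    Droplets with missing or extra frames are rejected with the droplet id in
    the message; channels not in the panel raise a schema error.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"trace file missing columns: {', '.join(missing_cols)}")
    unknown = sorted(set(df["channel"].unique()) - set(panel.channels))
    if unknown:
        raise SchemaError(
            f"unknown channels {unknown} for panel {panel.panel_id}"
        )
    expected_times = grid.minutes
    traces: list[DropletTrace] = []
    for droplet_id, group in df.groupby("droplet_id", sort=True):
        has_cell_vals = group["has_cell"].unique()
        if len(has_cell_vals) != 1:
            raise IntegrityError(f"droplet {droplet_id}: inconsistent has_cell flag")
        relocation: dict[str, np.ndarray] = {}
        for ch in panel.channels:
            block = group[group["channel"] == ch].sort_values("time_min")
            times = block["time_min"].to_numpy(dtype=float)
            if times.shape != expected_times.shape or not np.allclose(
                times, expected_times
            ):
                raise IntegrityError(
                    f"droplet {droplet_id}: channel {ch} frames {times.tolist()} "
                    f"do not match the time grid"
                )
            relocation[ch] = block["relocation"].to_numpy(dtype=float)
        measurement_id = str(group["measurement_id"].iloc[0])
        traces.append(
            DropletTrace(
                droplet_id=str(droplet_id),
                measurement_id=measurement_id,
                has_cell=bool(has_cell_vals[0]),
                relocation=relocation,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# ground truth

def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = []
    for droplet_id in sorted(truth.droplets):
        d = truth.droplets[droplet_id]
        for cell_index, prog in d.programs:
            pattern = ""
            for pair, label in d.patterns.items():
                if prog.cytokine in pair:
                    pattern = label
                    break
            rows.append(
                (
                    droplet_id,
                    d.n_cells,
                    cell_index,
                    prog.cytokine,
                    prog.rate,
                    prog.onset_min,
                    prog.offset_min,
                    pattern,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "droplet_id",
            "n_cells",
            "cell_index",
            "cytokine",
            "rate",
            "onset_min",
            "offset_min",
            "pattern",
        ],
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# calls / rates / patterns

def write_calls(
    calls: Sequence[SecretionCall],
    path,
    rates: Mapping[tuple[str, str], RateEstimate] | None = None,
) -> None:
    """Calls CSV; when rate estimates are supplied they are joined in."""
    rows = []
    for call in sorted(calls, key=lambda c: (c.droplet_id, c.cytokine)):
        rate = (rates or {}).get((call.droplet_id, call.cytokine))
        rows.append(
            {
                "droplet_id": call.droplet_id,
                "cytokine": call.cytokine,
                "is_secretor": call.is_secretor,
                "c_cell": call.c_cell,
                "c_exceed": call.c_exceed,
                "c_range": call.c_range,
                "c_slope": call.c_slope,
                "avg_rate": "" if rate is None or rate.avg_rate is None else rate.avg_rate,
                "endpoint_conc": "" if rate is None else rate.endpoint_concentration,
                "censored": "" if rate is None else rate.censored,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "droplet_id",
            "cytokine",
            "is_secretor",
            "c_cell",
            "c_exceed",
            "c_range",
            "c_slope",
            "avg_rate",
            "endpoint_conc",
            "censored",
        ],
    ).to_csv(path, index=False, float_format="%.10g")


def read_calls(path) -> list[SecretionCall]:
    df = pd.read_csv(path)
    needed = ["droplet_id", "cytokine", "c_cell", "c_exceed", "c_range", "c_slope"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"calls file missing columns: {', '.join(missing)}")
    return [
        SecretionCall(
            droplet_id=str(row.droplet_id),
            cytokine=str(row.cytokine),
            c_cell=bool(row.c_cell),
            c_exceed=bool(row.c_exceed),
            c_range=bool(row.c_range),
            c_slope=bool(row.c_slope),
        )
        for row in df.itertuples()
    ]


def write_patterns(patterns: Sequence[PatternCall], path) -> None:
    rows = []
    for p in sorted(patterns, key=lambda p: (p.droplet_id, p.cytokine_a, p.cytokine_b)):
        rows.append(
            {
                "droplet_id": p.droplet_id,
                "cytokine_a": p.cytokine_a,
                "cytokine_b": p.cytokine_b,
                "label": p.label,
                "onset_a": "" if p.window_a is None else p.window_a.onset_min,
                "offset_a": "" if p.window_a is None else p.window_a.offset_min,
                "onset_b": "" if p.window_b is None else p.window_b.onset_min,
                "offset_b": "" if p.window_b is None else p.window_b.offset_min,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "droplet_id",
            "cytokine_a",
            "cytokine_b",
            "label",
            "onset_a",
            "offset_a",
            "onset_b",
            "offset_b",
        ],
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# provenance and JSON summaries

def config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def provenance_block(
    config: Mapping[str, Any],
    seed: int | None,
    constants: AssayConstants | None = None,
) -> dict[str, Any]:
    constants = constants or AssayConstants()
    return {
        "tool": "dropcyte",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "threshold_multiplier": constants.threshold_multiplier,
        "droplet_volume_pl": constants.droplet_volume_pl,
        "multiple_testing_correction": "none",
    }


def _bin_key_str(key: frozenset) -> str:
    return "+".join(sorted(key))


def bin_summary_dict(summary: BinSummary) -> dict[str, Any]:
    return {
        "measurement_id": summary.measurement_id,
        "n_total_cells": summary.n_total_cells,
        "n_csc": summary.n_csc,
        "bins": {
            _bin_key_str(key): {
                "count": s.count,
                "pct_total": s.pct_total,
                "pct_csc": s.pct_csc,
            }
            for key, s in summary.bins.items()
        },
        "multiplicity": {
            str(n): {
                "count": s.count,
                "pct_total": s.pct_total,
                "pct_csc": s.pct_csc,
            }
            for n, s in summary.multiplicity.items()
        },
    }


def _write_json(obj: Mapping[str, Any], path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n",
        encoding="utf-8",
    )


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_bins(
    summaries: Sequence[BinSummary],
    path,
    provenance: Mapping[str, Any],
) -> None:
    _write_json(
        {
            "provenance": dict(provenance),
            "measurements": {
                s.measurement_id or f"measurement_{i}": bin_summary_dict(s)
                for i, s in enumerate(summaries)
            },
        },
        path,
    )


def write_stats(
    results: Mapping[str, StatResult],
    path,
    provenance: Mapping[str, Any],
) -> None:
    _write_json(
        {
            "provenance": dict(provenance),
            "tests": {
                name: {
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n": list(r.n),
                    "stars": r.stars,
                    "correction": r.correction,
                }
                for name, r in results.items()
            },
        },
        path,
    )


def read_json(path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# configuration layer

@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    constants: AssayConstants
    panel: Panel
    sim: SimConfig
    blank_floor: int = 30
    dynamics_k: float = DEFAULT_K
    dynamics_rho: float = DEFAULT_RHO

    @property
    def grid(self) -> TimeGrid:
        return make_time_grid(
            self.constants.frame_interval_min, self.constants.duration_min
        )

    def to_dict(self) -> dict[str, Any]:
        sim = asdict(self.sim)
        sim["calibration"] = {
            cyt: {
                "form": c.form,
                "parameters": dict(c.parameters),
                "c_max": c.c_max,
            }
            for cyt, c in (self.sim.calibration or {}).items()
        }
        return {
            "constants": asdict(self.constants),
            "panel": {
                "panel_id": self.panel.panel_id,
                "channel_map": dict(self.panel.channel_map),
            },
            "simulation": sim,
            "calling": {"blank_floor": int(self.blank_floor)},
            "dynamics": {"k": float(self.dynamics_k), "rho": float(self.dynamics_rho)},
        }


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        constants = AssayConstants(**raw.get("constants", {}))
        panel_raw = raw.get("panel", "panel1")
        if isinstance(panel_raw, str):
            panel = BUILTIN_PANELS[panel_raw]
        else:
            panel = Panel(panel_raw["panel_id"], panel_raw["channel_map"])
        sim_raw = dict(raw.get("simulation", {}))
        calib_raw = sim_raw.pop("calibration", None)
        calibration = None
        if calib_raw:
            calibration = {
                cyt: CalibrationCurve(
                    cytokine=cyt,
                    form=c["form"],
                    parameters=c["parameters"],
                    c_max=c["c_max"],
                )
                for cyt, c in calib_raw.items()
            }
        if "pattern_fractions" in sim_raw:
            sim_raw["pattern_fractions"] = tuple(sim_raw["pattern_fractions"])
        if "rate_lognormal" in sim_raw and isinstance(sim_raw["rate_lognormal"], list):
            sim_raw["rate_lognormal"] = tuple(sim_raw["rate_lognormal"])
        sim = SimConfig(calibration=calibration, **sim_raw)
        calling_raw = raw.get("calling", {})
        dyn_raw = raw.get("dynamics", {})
        return RunConfig(
            constants=constants,
            panel=panel,
            sim=sim,
            blank_floor=int(calling_raw.get("blank_floor", 30)),
            dynamics_k=float(dyn_raw.get("k", DEFAULT_K)),
            dynamics_rho=float(dyn_raw.get("rho", DEFAULT_RHO)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid config file {path}: {exc}") from exc
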