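"""Relocation-to-concentration calibration and per-cell secretion-rate estimation.

Relocation (arbitrary units, baseline-subtracted against the droplet's own
first frame) is mapped to in-droplet cytokine concentration (nM) through a
strictly monotone calibration curve with a finite maximum detectable
concentration ``c_max``. Frame-to-frame concentration increments are converted
to molecules/second through the droplet volume and Avogadro's number and
averaged; once ``c_max`` is reached the trace is censored and the average runs
only up to the censoring frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import AssayConstants, TimeGrid
from .errors import ConfigurationError

CURVE_FORMS = ("linear", "four_parameter_logistic")


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map between baseline-subtracted relocation and concentration.

    Two forms are supported:

    * ``linear``: concentration = gain_nm_per_au * delta_relocation.
    * ``four_parameter_logistic``: a baseline-subtracted Hill response
      delta_R(C) = r_max * C^hill / (C^hill + ec50_nm^hill), inverted
      analytically. Strictly increasing for r_max, ec50_nm, hill > 0.

    ``c_max`` (nM) is the maximum detectable concentration; concentrations are
    clamped there and the frame index of first saturation is recorded as the
    censoring point downstream.
    """

    cytokine: str
    form: str
    parameters: Mapping[str, float]
    c_max: float

    def __post_init__(self) -> None:
        if self.form not in CURVE_FORMS:
            raise ConfigurationError(f"unknown calibration form {self.form!r}")
        if not (math.isfinite(self.c_max) and self.c_max > 0):
            raise ConfigurationError("c_max must be finite and > 0")
        p = dict(self.parameters)
        if self.form == "linear":
            if p.get("gain_nm_per_au", 0) <= 0:
                raise ConfigurationError("linear curve needs gain_nm_per_au > 0")
        else:
            for key in ("r_max", "ec50_nm", "hill"):
                if p.get(key, 0) <= 0:
                    raise ConfigurationError(
                        f"four_parameter_logistic curve needs {key} > 0"
                    )
            # c_max must stay strictly below the response asymptote to be invertible
            if not self.relocation(self.c_max) < p["r_max"]:
                raise ConfigurationError("c_max beyond the invertible range")
        object.__setattr__(self, "parameters", p)

    # relocation excess -> concentration (nM)
    def concentration(self, delta_relocation: np.ndarray | float) -> np.ndarray | float:
        dr = np.asarray(delta_relocation, dtype=float)
        if self.form == "linear":
            c = self.parameters["gain_nm_per_au"] * dr
        else:
            rmax = self.parameters["r_max"]
            ec50 = self.parameters["ec50_nm"]
            hill = self.parameters["hill"]
            dr = np.clip(dr, 0.0, None)
            # invert dr = rmax * C^h / (C^h + ec50^h); saturate at c_max beyond range
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dr < rmax, dr / np.maximum(rmax - dr, 1e-300), np.inf)
                c = ec50 * np.power(ratio, 1.0 / hill)
            c = np.where(dr >= rmax, np.inf, c)
        return c if np.ndim(delta_relocation) else float(c)

    # concentration (nM) -> relocation excess (inverse map)
    def relocation(self, concentration: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=float)
        if self.form == "linear":
            r = c / self.parameters["gain_nm_per_au"]
        else:
            rmax = self.parameters["r_max"]
            ec50 = self.parameters["ec50_nm"]
            hill = self.parameters["hill"]
            ch = np.power(np.clip(c, 0.0, None), hill)
            r = rmax * ch / (ch + ec50**hill)
        return r if np.ndim(concentration) else float(r)

    def dconc_drelocation(self, concentration: np.ndarray | float) -> np.ndarray | float:
        """Local slope dC/dR (nM per a.u.) at a given concentration.

        Used to propagate relocation noise into concentration units.
        """
        c = np.asarray(concentration, dtype=float)
        if self.form == "linear":
            d = np.full_like(c, self.parameters["gain_nm_per_au"])
        else:
            rmax = self.parameters["r_max"]
            ec50 = self.parameters["ec50_nm"]
            hill = self.parameters["hill"]
            c = np.clip(c, 1e-12, None)
            ch = np.power(c, hill)
            denom = ch + ec50**hill
            drdc = rmax * hill * (ec50**hill) * np.power(c, hill - 1.0) / denom**2
            d = 1.0 / drdc
        return d if np.ndim(concentration) else float(d)


def linear_curve(cytokine: str, gain_nm_per_au: float, c_max: float) -> CalibrationCurve:
    return CalibrationCurve(
        cytokine, "linear", {"gain_nm_per_au": gain_nm_per_au}, c_max
    )


@dataclass
class ConcentrationTrace:
    """Per-frame in-droplet concentration (nM) for one droplet-cytokine.

    ``censored_from`` is the index of the first frame at ``c_max`` (saturation),
    or None if the maximum detectable concentration was never reached.
    """

    droplet_id: str
    cytokine: str
    concentration: np.ndarray
    c_max: float
    censored_from: int | None = None

    @property
    def censored(self) -> bool:
        return self.censored_from is not None

    @property
    def endpoint(self) -> float:
        return float(self.concentration[-1])


@dataclass
class RateEstimate:
    """Average secretion rate (molecules/s) of one droplet-cytokine.

    ``interval_rates`` holds one rate per frame-to-frame interval (negative
    values from noise retained); ``avg_rate`` averages the intervals strictly
    before the censoring frame (all intervals when uncensored) and is floored
    at 0 since secretion is non-negative. ``available`` is False when the trace
    saturated too early (< 2 frames before the censor) for a rate to exist.
    """

    droplet_id: str
    cytokine: str
    interval_rates: np.ndarray
    avg_rate: float | None
    endpoint_concentration: float
    censored: bool
    available: bool = True


def apply_calibration(
    trace,
    channel: str,
    curve: CalibrationCurve,
    cytokine: str | None = None,
    baseline: float | None = None,
) -> ConcentrationTrace:
    """Convert one channel of a droplet trace into a concentration trace.

    The baseline defaults to the droplet's own first-frame relocation. The
    result is clamped to [0, c_max]; once a frame reaches c_max, that and all
    later frames are set to c_max and the first such frame index recorded as
    ``censored_from``.
    """
    series = trace.series(channel)
    if baseline is None:
        baseline = float(series[0])
    raw = np.asarray(curve.concentration(series - baseline), dtype=float)
    raw = np.clip(raw, 0.0, None)
    hit = np.nonzero(raw >= curve.c_max)[0]
    censored_from: int | None = None
    conc = np.minimum(raw, curve.c_max)
    if hit.size:
        censored_from = int(hit[0])
        conc[censored_from:] = curve.c_max
    return ConcentrationTrace(
        droplet_id=trace.droplet_id,
        cytokine=cytokine or curve.cytokine,
        concentration=conc,
        c_max=curve.c_max,
        censored_from=censored_from,
    )


def molecules_per_second(
    delta_conc_nm: float | np.ndarray,
    delta_t_s: float,
    volume_pl: float,
    avogadro: float = 6.02214076e23,
) -> float | np.ndarray:
    """Convert a concentration change (nM) over an interval into molecules/second.

    rate = dC[nM] * 1e-9 [mol/L per nM] * V[pL] * 1e-12 [L/pL] * N_A / dt[s]
    """
    if delta_t_s <= 0:
        raise ValueError("delta_t_s must be > 0")
    scale = 1e-9 * volume_pl * 1e-12 * avogadro / delta_t_s
    out = np.asarray(delta_conc_nm, dtype=float) * scale
    return out if np.ndim(delta_conc_nm) else float(out)


def average_rate(
    conc_trace: ConcentrationTrace,
    constants: AssayConstants,
    grid: TimeGrid,
) -> RateEstimate:
    """Average per-interval secretion rates, censoring at saturation.

    Interval i spans frames i -> i+1. When the trace saturates at frame c, the
    average covers intervals 0..c-1 (the last one ends at the censoring frame);
    a censor at frame 0 or 1 leaves fewer than two informative frames and the
    rate is marked unavailable.
    """
    conc = np.asarray(conc_trace.concentration, dtype=float)
    dt = grid.frame_interval_min * 60.0
    rates = molecules_per_second(np.diff(conc), dt, constants.droplet_volume_pl,
                                 constants.avogadro)
    c = conc_trace.censored_from
    if c is not None and c < 2:
        return RateEstimate(
            droplet_id=conc_trace.droplet_id,
            cytokine=conc_trace.cytokine,
            interval_rates=rates,
            avg_rate=None,
            endpoint_concentration=conc_trace.endpoint,
            censored=True,
            available=False,
        )
    used = rates if c is None else rates[:c]
    avg = max(0.0, float(np.mean(used)))
    return RateEstimate(
        droplet_id=conc_trace.droplet_id,
        cytokine=conc_trace.cytokine,
        interval_rates=rates,
        avg_rate=avg,
        endpoint_concentration=conc_trace.endpoint,
        censored=c is not None,
        available=True,
    )


def quantify_secretors(
    traces,
    calls,
    panel,
    calibration: Mapping[str, CalibrationCurve],
    constants: AssayConstants,
    grid: TimeGrid,
) -> tuple[list[ConcentrationTrace], list[RateEstimate]]:
    """Concentration traces and rate estimates for every positive call."""
    by_id = {t.droplet_id: t for t in traces}
    conc_traces: list[ConcentrationTrace] = []
    rates: list[RateEstimate] = []
    for call in calls:
        if not call.is_secretor:
            continue
        if call.cytokine not in calibration:
            raise ConfigurationError(f"no calibration curve for {call.cytokine}")
        trace = by_id[call.droplet_id]
        ct = apply_calibration(
            trace, panel.channel_for(call.cytokine), calibration[call.cytokine],
            cytokine=call.cytokine,
        )
        conc_traces.append(ct)
        rates.append(average_rate(ct, constants, grid))
    return conc_traces, rates
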