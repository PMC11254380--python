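import math

import numpy as np
import pytest

from dropcyte import (
    AssayConstants,
    BlankModel,
    SimConfig,
    call_secretors,
    estimate_blank_sigma,
    estimate_blanks,
    qc_measurement,
    simulate_measurement,
)
from dropcyte.calling import (
    SecretionCall,
    criterion_exceed,
    criterion_range,
    criterion_slope,
    positive_sets,
)
from dropcyte.errors import EstimationError

from conftest import make_trace


def blank_traces(rng, n, sigma, n_frames=9, channels=("ch1", "ch2", "ch3")):
    return [
        make_trace(
            f"b{i}",
            {ch: 100.0 + rng.normal(0, sigma, n_frames) for ch in channels},
            has_cell=False,
        )
        for i in range(n)
    ]


class TestBlankSigma:
    def test_constant_blanks_give_zero(self):
        traces = [
            make_trace(f"b{i}", {"ch1": np.full(9, 50.0)}, has_cell=False)
            for i in range(40)
        ]
        sigma, n = estimate_blank_sigma(traces, "ch1")
        assert sigma == 0.0
        assert n == 40

    def test_iid_gaussian_noise_recovers_delta_sd(self):
        """Frame noise sd 5 makes t0-referenced deltas sd 5*sqrt(2) ~ 7.07."""
        rng = np.random.default_rng(5)
        traces = blank_traces(rng, 1000, 5.0, channels=("ch1",))
        sigma, _ = estimate_blank_sigma(traces, "ch1")
        assert sigma == pytest.approx(5.0 * math.sqrt(2.0), rel=0.05)

    def test_no_blanks_is_an_error(self):
        traces = [make_trace("d0", {"ch1": np.zeros(9)}, has_cell=True)]
        with pytest.raises(EstimationError):
            estimate_blank_sigma(traces, "ch1")

    def test_below_floor_warns_but_proceeds(self):
        rng = np.random.default_rng(6)
        traces = blank_traces(rng, 5, 2.0, channels=("ch1",))
        with pytest.warns(UserWarning, match="floor"):
            sigma, n = estimate_blank_sigma(traces, "ch1", floor=30)
        assert n == 5
        assert sigma > 0


class TestCriteria:
    def test_exceed_flat_series_false(self):
        assert not criterion_exceed(np.full(9, 100.0), 2.0, 3.29)

    def test_exceed_arithmetic_threshold(self):
        # threshold = 100 + 3.29 * 2 = 106.58
        series = np.array([100.0, 101, 102, 103, 104, 105, 106, 106.5, 107])
        assert criterion_exceed(series, 2.0, 3.29)
        series[-1] = 106.58  # exactly at threshold: strict comparison fails
        assert not criterion_exceed(series, 2.0, 3.29)

    def test_exceed_degenerate_zero_sigma(self):
        series = np.array([100.0] * 8 + [100.0001])
        assert criterion_exceed(series, 0.0, 3.29)

    def test_range_constant_false(self):
        assert not criterion_range(np.full(9, 100.0), 1.0, 3.29)

    def test_range_arithmetic(self):
        series = np.linspace(100.0, 180.0, 9)  # range 80 > 3.29 * 2 = 6.58
        assert criterion_range(series, 2.0, 3.29)

    def test_range_boundary_is_strict(self):
        series = np.array([100.0] * 8 + [106.58])
        assert not criterion_range(series, 2.0, 3.29)

    def test_slope_increasing_true_decreasing_false(self):
        t = np.arange(9) * 30.0
        assert criterion_slope(np.linspace(0, 10, 9), t)
        assert not criterion_slope(np.linspace(10, 0, 9), t)

    def test_slope_symmetric_rise_fall_is_zero_hence_false(self):
        t = np.arange(9) * 30.0
        series = np.array([0.0, 1, 2, 3, 4, 3, 2, 1, 0])
        assert not criterion_slope(series, t)


class TestCallSecretors:
    def test_zero_cells_zero_calls(self, panel1, constants, grid):
        rng = np.random.default_rng(7)
        traces = blank_traces(rng, 60, 3.0)
        blanks = estimate_blanks(traces, panel1)
        assert call_secretors(traces, blanks, panel1, constants, grid) == []

    def test_high_snr_secretors_called_for_their_programmed_cytokines(
        self, meta, panel1, constants, grid
    ):
        config = SimConfig(
            n_droplets=500,
            seed=21,
            secretor_fraction=0.3,
            sigma_blk=1e-3,
            baseline_sd=0.0,
            rate_lognormal=(math.log(50.0), 0.5),
        )
        traces, truth = simulate_measurement(config, meta)
        blanks = estimate_blanks(traces, panel1)
        calls = call_secretors(traces, blanks, panel1, constants, grid)
        called = positive_sets(calls)
        missed = 0
        total = 0
        for droplet_id, d in truth.droplets.items():
            true_set = d.secreted_cytokines()
            if not true_set:
                continue
            total += len(true_set)
            missed += len(true_set - called.get(droplet_id, frozenset()))
        assert total > 100
        assert missed == 0  # every programmed cytokine detected at high SNR

    def test_monotone_in_threshold_multiplier(self, meta, panel1, grid):
        config = SimConfig(n_droplets=400, seed=22)
        traces, _ = simulate_measurement(config, meta)
        blanks = estimate_blanks(traces, panel1)
        n_positive = []
        for mult in (1.0, 2.0, 3.29, 5.0, 8.0):
            constants = AssayConstants(threshold_multiplier=mult)
            calls = call_secretors(traces, blanks, panel1, constants, grid)
            n_positive.append(sum(c.is_secretor for c in calls))
        assert n_positive == sorted(n_positive, reverse=True)

    def test_invariant_to_droplet_ordering(self, small_dataset, panel1, constants, grid):
        _, traces, _ = small_dataset
        blanks = estimate_blanks(traces, panel1)
        calls = call_secretors(traces, blanks, panel1, constants, grid)
        shuffled = list(traces)
        np.random.default_rng(0).shuffle(shuffled)
        calls_shuffled = call_secretors(shuffled, blanks, panel1, constants, grid)
        assert sorted(calls, key=lambda c: (c.droplet_id, c.cytokine)) == sorted(
            calls_shuffled, key=lambda c: (c.droplet_id, c.cytokine)
        )

    def test_agrees_with_naive_per_droplet_oracle(
        self, small_dataset, panel1, constants, grid
    ):
        """The vectorizable implementation must agree exactly with a naive,
        pure-Python restatement of the four criteria."""
        _, traces, _ = small_dataset
        blanks = estimate_blanks(traces, panel1)
        calls = {
            (c.droplet_id, c.cytokine): c.is_secretor
            for c in call_secretors(traces, blanks, panel1, constants, grid)
        }
        t_min = list(grid.minutes)
        t_mean = sum(t_min) / len(t_min)
        for trace in traces:
            if not trace.has_cell:
                continue
            for ch, cyt in panel1.channel_map.items():
                r = list(trace.series(ch))
                thr = constants.threshold_multiplier * blanks.sigma_blk[ch]
                c_exceed = any(v > r[0] + thr for v in r[1:])
                c_range = (max(r) - min(r)) > thr
                r_mean = sum(r) / len(r)
                slope_num = sum((t - t_mean) * (v - r_mean) for t, v in zip(t_min, r))
                expected = c_exceed and c_range and (slope_num > 0)
                assert calls[(trace.droplet_id, cyt)] == expected


class TestQC:
    @staticmethod
    def _calls(n_positive, cytokine="IL-6"):
        calls = [
            SecretionCall(f"d{i}", cytokine, True, True, True, True)
            for i in range(n_positive)
        ]
        return calls

    def test_thirty_positives_flags_manual_inspection(self, panel1):
        qc = qc_measurement(self._calls(30), "m0", panel1)
        assert qc.manual_inspection_flag["IL-6"]
        assert not qc.excluded_flag["IL-6"]

    def test_eight_positives_flags_exclusion(self, panel1):
        qc = qc_measurement(self._calls(8), "m0", panel1)
        assert qc.excluded_flag["IL-6"]
        assert qc.manual_inspection_flag["IL-6"]

    def test_hundred_positives_no_flags(self, panel1):
        qc = qc_measurement(self._calls(100), "m0", panel1)
        assert not qc.manual_inspection_flag["IL-6"]
        assert not qc.excluded_flag["IL-6"]

    def test_boundaries_are_strict_fewer_than(self, panel1):
        assert not qc_measurement(self._calls(50), "m0", panel1).manual_inspection_flag["IL-6"]
        assert qc_measurement(self._calls(49), "m0", panel1).manual_inspection_flag["IL-6"]
        assert not qc_measurement(self._calls(10), "m0", panel1).excluded_flag["IL-6"]
        assert qc_measurement(self._calls(9), "m0", panel1).excluded_flag["IL-6"]
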