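import math

import numpy as np
import pytest
from scipy import stats as sps

from dropcyte import (
    AssayConstants,
    BUILTIN_PANELS,
    SimConfig,
    apply_calibration,
    assign_pattern,
    default_calibration,
    make_time_grid,
    simulate_measurement,
)
from dropcyte.errors import ConfigurationError
from dropcyte.simulate import SecretionProgram


@pytest.fixture(scope="module")
def grid():
    return make_time_grid(30, 240)


class TestOccupancy:
    def test_cell_fraction_matches_poisson_closed_form(self, meta):
        lam = 0.3
        n = 10_000
        config = SimConfig(n_droplets=n, seed=101, cell_loading=lam,
                           secretor_fraction=0.0)
        traces, truth = simulate_measurement(config, meta)
        frac = sum(t.has_cell for t in traces) / n
        expected = 1.0 - math.exp(-lam)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * se

    @pytest.mark.parametrize("lam", [0.1, 0.2, 0.4])
    def test_occupancy_distribution_not_rejected_by_chi2(self, lam, meta):
        n = 20_000
        config = SimConfig(n_droplets=n, seed=202, cell_loading=lam,
                           secretor_fraction=0.0)
        _, truth = simulate_measurement(config, meta)
        counts = np.bincount(
            [min(d.n_cells, 3) for d in truth.droplets.values()], minlength=4
        )
        probs = np.array([sps.poisson.pmf(k, lam) for k in range(3)])
        probs = np.append(probs, 1.0 - probs.sum())
        res = sps.chisquare(counts, n * probs)
        assert res.pvalue > 0.01


@pytest.fixture(scope="module")
def noise_free(meta):
    config = SimConfig(
        n_droplets=60,
        seed=7,
        cell_loading=0.5,
        secretor_fraction={"IL-6": 1.0, "TNF-a": 0.0, "IFN-g": 0.0},
        rate_lognormal=(math.log(100.0), 0.0),
        sigma_blk=0.0,
        baseline_sd=0.0,
        window_mode="full",
    )
    return config, *simulate_measurement(config, meta)


class TestNoiseFreeAccumulation:
    def test_endpoint_concentration_matches_closed_form(self, noise_free, grid):
        config, traces, truth = noise_free
        constants = AssayConstants()
        # 100 molecules/s for 240 min into 65 pL
        expected = 100.0 * 240 * 60 / (constants.droplet_volume_l *
                                       constants.avogadro * 1e-9)
        assert expected == pytest.approx(36.79, abs=0.2)
        curve = default_calibration(BUILTIN_PANELS["panel1"])["IL-6"]
        checked = 0
        for t in traces:
            if truth.droplets[t.droplet_id].n_cells != 1:
                continue
            conc = apply_calibration(t, "ch1", curve)
            assert conc.concentration[-1] == pytest.approx(expected, rel=1e-9)
            checked += 1
        assert checked > 5

    def test_relocation_equals_inverse_calibration_exactly(self, noise_free, grid):
        """With zero noise the emitted relocation is the analytic concentration
        pushed through the inverse calibration map, to the last bit."""
        config, traces, truth = noise_free
        constants = AssayConstants()
        curve = default_calibration(BUILTIN_PANELS["panel1"])["IL-6"]
        per_nm = constants.droplet_volume_l * constants.avogadro * 1e-9
        for t in traces[:20]:
            d = truth.droplets[t.droplet_id]
            conc = np.zeros(grid.n_frames)
            for _, prog in d.programs:
                conc += prog.rate * np.array(
                    [prog.active_seconds(tm) for tm in grid.minutes]
                ) / per_nm
            conc = np.minimum(conc, curve.c_max)
            expected = config.baseline_mean + np.asarray(curve.relocation(conc))
            np.testing.assert_array_equal(t.series("ch1"), expected)

    def test_concentration_nondecreasing(self, noise_free):
        config, traces, truth = noise_free
        curve = default_calibration(BUILTIN_PANELS["panel1"])["IL-6"]
        for t in traces:
            conc = apply_calibration(t, "ch1", curve)
            assert np.all(np.diff(conc.concentration) >= -1e-12)


class TestDeterminism:
    def test_same_seed_gives_bit_identical_traces(self, meta):
        config = SimConfig(n_droplets=150, seed=42)
        a, truth_a = simulate_measurement(config, meta)
        b, truth_b = simulate_measurement(config, meta)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            assert ta.droplet_id == tb.droplet_id
            assert ta.has_cell == tb.has_cell
            for ch in ta.relocation:
                np.testing.assert_array_equal(ta.series(ch), tb.series(ch))
        assert truth_a.droplets.keys() == truth_b.droplets.keys()

    def test_different_seed_differs(self, meta):
        a, _ = simulate_measurement(SimConfig(n_droplets=50, seed=1), meta)
        b, _ = simulate_measurement(SimConfig(n_droplets=50, seed=2), meta)
        assert any(
            not np.array_equal(ta.series("ch1"), tb.series("ch1"))
            for ta, tb in zip(a, b)
        )


class TestAssignPattern:
    def test_degenerate_mixture_all_simultaneous(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(50):
            label, win_a, win_b = assign_pattern((1.0, 0.0, 0.0), rng, grid)
            assert label == "simultaneous"
            assert win_a == win_b

    def test_sequential_windows_are_disjoint(self, grid):
        rng = np.random.default_rng(1)
        seen = 0
        for _ in range(300):
            label, (on_a, off_a), (on_b, off_b) = assign_pattern(
                (0.0, 1.0, 0.0), rng, grid
            )
            assert label == "sequential"
            inter = min(off_a, off_b) - max(on_a, on_b)
            assert inter <= 0.0
            seen += 1
        assert seen == 300

    def test_semi_sequential_overlap_below_three_quarters(self, grid):
        rng = np.random.default_rng(2)
        for _ in range(300):
            label, (on_a, off_a), (on_b, off_b) = assign_pattern(
                (0.0, 0.0, 1.0), rng, grid
            )
            assert label == "semi_sequential"
            inter = min(off_a, off_b) - max(on_a, on_b)
            shorter = min(off_a - on_a, off_b - on_b)
            assert 0.0 < inter < 0.75 * shorter

    def test_label_proportions_within_multinomial_ci(self, grid):
        rng = np.random.default_rng(3)
        fractions = (0.4, 0.4, 0.2)
        n = 1000
        counts = {"simultaneous": 0, "sequential": 0, "semi_sequential": 0}
        for _ in range(n):
            label, *_ = assign_pattern(fractions, rng, grid)
            counts[label] += 1
        for frac, label in zip(fractions, counts):
            se = math.sqrt(frac * (1 - frac) / n)
            assert abs(counts[label] / n - frac) < 3 * se

    def test_fractions_must_sum_to_one(self, grid):
        with pytest.raises(ConfigurationError):
            assign_pattern((0.5, 0.2, 0.2), np.random.default_rng(0), grid)


class TestConfigValidation:
    def test_seed_is_mandatory(self):
        with pytest.raises((ConfigurationError, TypeError)):
            SimConfig(n_droplets=10, seed=None)

    def test_pattern_fractions_validated(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_droplets=10, seed=1, pattern_fractions=(0.5, 0.5, 0.5))

    def test_missing_calibration_rejected(self, meta):
        from dropcyte import linear_curve

        config = SimConfig(
            n_droplets=10, seed=1,
            calibration={"IL-6": linear_curve("IL-6", 0.05, 500.0)},
        )
        with pytest.raises(ConfigurationError, match="missing calibration"):
            simulate_measurement(config, meta)

    def test_program_invariants(self):
        with pytest.raises(ConfigurationError):
            SecretionProgram("IL-6", -1.0, 0.0, 240.0)
        with pytest.raises(ConfigurationError):
            SecretionProgram("IL-6", 1.0, 100.0, 50.0)
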