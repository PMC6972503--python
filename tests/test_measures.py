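"""Analysis statistics against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibnet.fixtures import FixtureSpec, make_raster
from inhibnet.measures import (
    MeasureWindow,
    bistability_measure,
    classify_synchrony,
    delta_synchrony,
    mean_firing_frequency,
    synchrony_details,
    synchrony_measure,
    transition_slope,
)
from inhibnet.raster import SpikeRaster


def brute_force_synchrony(trains, window, kernel_sd=2.0, grid_step=0.5):
    """Direct evaluation of the variance-ratio measure from Gaussian sums.

    Independent of the package implementation: plain per-neuron loops over
    untruncated Gaussian kernels on the analysis grid.
    """
    n_grid = int(round((window.t_end - window.t_start) / grid_step)) + 1
    grid = window.t_start + grid_step * np.arange(n_grid)
    traces = []
    for train in trains:
        v = np.zeros(n_grid)
        for t in train:
            v += np.exp(-0.5 * ((grid - t) / kernel_sd) ** 2)
        traces.append(v)
    traces = np.array(traces)
    var_i = traces.var(axis=1)
    active = var_i > 0
    if not active.any():
        return float("nan")
    return traces.mean(axis=0).var() / var_i[active].mean()


class TestSynchronyMeasure:
    def test_identical_trains_score_one(self, window500):
        """N copies of one train: population trace equals each trace, S = 1."""
        train = np.arange(520.0, 1000.0, 33.0)
        r = SpikeRaster.from_trains([train.copy() for _ in range(40)])
        assert synchrony_measure(r, window500) == pytest.approx(1.0, abs=1e-9)

    def test_single_neuron_scores_one(self, window500):
        r = SpikeRaster.from_trains([np.array([600.0, 700.0, 800.0])])
        assert synchrony_measure(r, window500) == pytest.approx(1.0, abs=1e-12)

    def test_poisson_population_scores_low(self, window500):
        r = make_raster(FixtureSpec(kind="poisson", N=500, window=window500,
                                    rate=30.0, seed=17))
        assert synchrony_measure(r, window500) < 0.25

    def test_antiphase_clusters_match_brute_force_oracle(self, window500):
        r = make_raster(FixtureSpec(kind="clustered", N=30, window=window500,
                                    rate=25.0, n_clusters=2))
        oracle = brute_force_synchrony(r.spike_trains(), window500)
        # the implementation truncates kernels at +-5 SD; the oracle does not
        assert synchrony_measure(r, window500) == pytest.approx(oracle, abs=1e-5)

    def test_random_rasters_match_brute_force_oracle(self, window500, rng):
        for seed in range(3):
            r = make_raster(FixtureSpec(kind="jittered", N=15, window=window500,
                                        rate=20.0, jitter_sd=6.0, seed=seed))
            oracle = brute_force_synchrony(r.spike_trains(), window500)
            assert synchrony_measure(r, window500) == pytest.approx(oracle, abs=1e-6)

    def test_silent_window_is_undefined_not_zero(self, window500):
        r = SpikeRaster(np.empty(0, np.int64), np.empty(0), 10)
        assert np.isnan(synchrony_measure(r, window500))

    def test_silent_neurons_excluded_and_counted(self, window500):
        """Silent cells dilute the population mean but not the denominator.

        Two identical active trains plus one silent cell: the population
        average is 2/3 of the active trace, so S = (2/3)^2; the silent
        cell is excluded from the per-cell variance mean and tallied.
        """
        train = np.arange(520.0, 1000.0, 40.0)
        trains = [train.copy(), train.copy(), np.empty(0)]
        r = SpikeRaster.from_trains(trains)
        det = synchrony_details(r, window500)
        assert det.n_excluded_silent == 1
        assert det.n_active == 2
        assert det.S == pytest.approx(4.0 / 9.0, abs=1e-9)

    def test_invariant_under_relabeling(self, window500, rng):
        r = make_raster(FixtureSpec(kind="poisson", N=25, window=window500,
                                    rate=30.0, seed=2))
        perm = rng.permutation(25)
        assert synchrony_measure(r.relabeled(perm), window500) == \
            pytest.approx(synchrony_measure(r, window500), abs=1e-12)

    def test_invariant_under_interior_time_shift(self):
        """Shifting all spikes rigidly (away from window edges) preserves S."""
        window = MeasureWindow(0.0, 500.0)
        base = make_raster(FixtureSpec(kind="jittered", N=20, rate=20.0,
                                       jitter_sd=2.0, seed=3,
                                       window=MeasureWindow(100.0, 400.0)))
        shifted = SpikeRaster(base.neuron_ids, base.times + 40.0, base.n_neurons)
        s0 = synchrony_measure(base, window)
        s1 = synchrony_measure(shifted, MeasureWindow(40.0, 540.0))
        assert s1 == pytest.approx(s0, abs=1e-6)

    def test_discretization_robustness(self, window500):
        """S at the default grid step and a 5x finer one differ by < 0.02."""
        for kind, kwargs in [("clustered", dict(n_clusters=3)),
                             ("jittered", dict(jitter_sd=4.0)),
                             ("poisson", dict())]:
            r = make_raster(FixtureSpec(kind=kind, N=40, window=window500,
                                        rate=25.0, seed=8, **kwargs))
            s_coarse = synchrony_measure(r, window500, grid_step=0.5)
            s_fine = synchrony_measure(r, window500, grid_step=0.1)
            assert abs(s_coarse - s_fine) < 0.02


class TestDeltaSynchrony:
    def test_identical_dynamics_gives_zero_diff(self):
        # period divides the window offset (1000 ms) exactly, and the train
        # covers both windows' kernel reach, so the two windows see
        # translated copies of the same activity
        train = np.arange(0.0, 2020.0, 40.0)
        r = SpikeRaster.from_trains([train + i * 0.5 for i in range(10)])
        ds = delta_synchrony(r)
        assert ds.diff == pytest.approx(0.0, abs=1e-9)

    def test_silent_pre_window_flags_undefined(self):
        # spikes only after the perturbation
        train = np.arange(1600.0, 2000.0, 30.0)
        r = SpikeRaster.from_trains([train.copy() for _ in range(5)])
        ds = delta_synchrony(r)
        assert np.isnan(ds.S_before)
        assert np.isnan(ds.diff)


class TestBistabilityMeasure:
    def test_all_below_threshold_scores_zero(self):
        assert bistability_measure(np.array([0.1, 0.3, -0.2])) == 0.0

    def test_three_step_rule(self):
        assert bistability_measure(np.array([0.5, 0.2, 0.31])) == pytest.approx(0.81)

    def test_matches_filter_then_sum_oracle(self, rng):
        m = rng.uniform(-0.5, 1.0, size=(6, 8))
        expected = sum(x for x in m.ravel() if x > 0.3)
        assert bistability_measure(m) == pytest.approx(expected)

    def test_nan_entries_skipped_and_tallied(self):
        m = np.array([[0.5, np.nan], [0.8, 0.1]])
        score, excluded = bistability_measure(m, return_excluded=True)
        assert score == pytest.approx(1.3)
        assert excluded == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.one_of(st.floats(-1.0, 1.5), st.just(float("nan"))),
                    min_size=1, max_size=40))
    def test_property_equals_filter_then_sum(self, entries):
        m = np.array(entries)
        expected = sum(x for x in entries if not np.isnan(x) and x > 0.3)
        score, excluded = bistability_measure(m, return_excluded=True)
        assert score == pytest.approx(expected)
        assert excluded == sum(1 for x in entries if np.isnan(x))
        assert score >= 0.0

    def test_nonnegative_and_monotone(self, rng):
        m = rng.uniform(-1, 1, size=20)
        base = bistability_measure(m)
        assert base >= 0.0
        bumped = m.copy()
        bumped[3] += 0.5
        assert bistability_measure(bumped) >= base


class TestMeanFiringFrequency:
    def test_empty_raster_is_zero(self, window500):
        r = SpikeRaster(np.empty(0, np.int64), np.empty(0), 500)
        assert mean_firing_frequency(r, window500) == 0.0

    def test_arithmetic(self, window500):
        # 500 cells x 10 spikes over 500 ms -> 20 Hz
        trains = [np.linspace(510.0, 990.0, 10) for _ in range(500)]
        r = SpikeRaster.from_trains(trains)
        assert mean_firing_frequency(r, window500) == pytest.approx(20.0)

    def test_equals_per_neuron_rate_average(self, window500):
        r = make_raster(FixtureSpec(kind="poisson", N=40, window=window500,
                                    rate=22.0, seed=6))
        per_neuron = [1000.0 * len(t) / window500.length for t in r.spike_trains()]
        assert mean_firing_frequency(r, window500) == pytest.approx(np.mean(per_neuron))

    def test_additive_over_disjoint_windows(self):
        r = make_raster(FixtureSpec(kind="poisson", N=30, rate=35.0, seed=4,
                                    window=MeasureWindow(0.0, 1000.0)))
        w1, w2 = MeasureWindow(0.0, 400.0), MeasureWindow(400.0, 1000.0)
        whole = mean_firing_frequency(r, MeasureWindow(0.0, 1000.0))
        combined = (mean_firing_frequency(r, w1) * w1.length
                    + mean_firing_frequency(r, w2) * w2.length) / 1000.0
        assert whole == pytest.approx(combined)


class TestClassification:
    @pytest.mark.parametrize("S,label", [(0.1, "asynchronous"),
                                         (0.8, "synchronous"),
                                         (0.25, "asynchronous")])
    def test_cutoff_with_strict_boundary(self, S, label):
        assert classify_synchrony(S) == label

    def test_undefined_rejected(self):
        with pytest.raises(ValueError):
            classify_synchrony(float("nan"))


class TestTransitionSlope:
    def test_step_column_arithmetic(self):
        pairs = [(100.0, 0.0), (125.0, 0.8)]
        assert transition_slope(pairs, 0.8) == pytest.approx(0.032)

    def test_never_exceeding_half_max_is_undefined(self):
        pairs = [(100.0, 0.1), (125.0, 0.2), (150.0, 0.3)]
        assert np.isnan(transition_slope(pairs, 0.8))

    def test_first_point_above_half_max_is_undefined(self):
        pairs = [(100.0, 0.7), (125.0, 0.8)]
        assert np.isnan(transition_slope(pairs, 0.8))

    def test_sigmoid_matches_exhaustive_scan(self):
        I = np.arange(100.0, 300.0, 5.0)
        S = 0.9 / (1.0 + np.exp(-(I - 200.0) / 12.0))
        panel_max = S.max()
        # brute-force scan of the rule
        k = next(i for i, s in enumerate(S) if s > panel_max / 2)
        expected = (S[k] - S[k - 1]) / (I[k] - I[k - 1])
        assert transition_slope(list(zip(I, S)), panel_max) == pytest.approx(expected)

    def test_unsorted_currents_rejected(self):
        with pytest.raises(ValueError):
            transition_slope([(125.0, 0.1), (100.0, 0.9)], 0.9)
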