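import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugof import (
    DegenerateDistributionError,
    InsufficientDataError,
    OnsetSequence,
    UgofDistribution,
    make_grid,
    mean_ugof_grid,
    model_ugof_distribution,
    sensitivity_scan,
    ugof_elements,
    zscore,
)


def brute_force_ugof(onsets, frequency, anchor):
    """Oracle: 2f * min_k |t - anchor - k/f| over an exhaustive k range."""
    period = 1.0 / frequency
    out = []
    for t in onsets:
        kmax = int(abs(t - anchor) / period) + 2
        beats = anchor + np.arange(-kmax, kmax + 1) * period
        out.append(2.0 * frequency * np.min(np.abs(t - beats)))
    return np.array(out)


def seq_of(times):
    return OnsetSequence.from_times(times, id="t")


class TestUgofElements:
    def test_perfect_fit(self):
        res = ugof_elements(seq_of([0, 0.1, 0.2, 0.3]), 10.0)
        np.testing.assert_array_equal(res.element_ugof, 0.0)
        assert res.mean_ugof == 0.0

    def test_halfway_element_scores_exactly_one(self):
        res = ugof_elements(seq_of([0, 0.15, 0.2]), 10.0)
        np.testing.assert_allclose(res.element_ugof, [0.0, 1.0, 0.0])
        assert res.mean_ugof == pytest.approx(1 / 3)

    def test_fractional_deviation(self):
        res = ugof_elements(seq_of([0, 0.12, 0.2]), 10.0)
        np.testing.assert_allclose(res.element_ugof, [0.0, 0.4, 0.0],
                                   atol=1e-12)
        assert res.mean_ugof == pytest.approx(0.4 / 3)

    def test_silent_beats_incur_no_penalty(self):
        """Elements at 0 and 0.35 s of a 10 Hz beat: the skipped beats at
        0.1 and 0.2 s do not contribute, only realized elements score."""
        res = ugof_elements(seq_of([0, 0.35, 0.7]), 10.0)
        np.testing.assert_allclose(res.element_ugof, [0.0, 1.0, 0.0],
                                   atol=1e-12)

    def test_anchor_element_always_zero(self, jittered_train):
        res = ugof_elements(jittered_train, 7.31)
        assert res.element_ugof[0] == 0.0
        assert res.anchor == jittered_train.onsets[0]

    def test_invalid_frequency(self, perfect_train):
        with pytest.raises(ValueError):
            ugof_elements(perfect_train, -1.0)

    def test_phase_optimization_never_worse(self, jittered_train):
        fixed = ugof_elements(jittered_train, 10.0)
        opt = ugof_elements(jittered_train, 10.0, optimize_phase=True)
        assert opt.mean_ugof <= fixed.mean_ugof + 1e-12

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(0.0, 50.0), min_size=1, max_size=20,
                 unique=True).map(sorted)
            .filter(lambda xs: len(xs) < 2 or min(np.diff(xs)) > 1e-6),
        st.floats(0.1, 100.0),
    )
    def test_matches_brute_force_oracle(self, times, frequency):
        res = ugof_elements(seq_of(times), frequency)
        oracle = brute_force_ugof(np.array(times), frequency, times[0])
        np.testing.assert_allclose(res.element_ugof, oracle, atol=1e-9)
        assert np.all(res.element_ugof >= 0)
        assert np.all(res.element_ugof <= 1)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, a):
        """Dilating time by a and dividing frequency by a leaves every
        element's ugof unchanged."""
        times = np.array([0.0, 0.07, 0.21, 0.33, 0.5])
        r0 = ugof_elements(seq_of(times), 9.0)
        r1 = ugof_elements(seq_of(a * times), 9.0 / a)
        np.testing.assert_allclose(r1.element_ugof, r0.element_ugof,
                                   atol=1e-9)


class TestModelDistribution:
    def test_default_grid_has_9991_frequencies(self):
        assert make_grid().size == 9991

    def test_value_count_scales_with_sequences(self, rng):
        seqs = [seq_of(np.sort(rng.uniform(0, 2, 5))) for _ in range(3)]
        dist = model_ugof_distribution(seqs, grid=(0.5, 2.0, 0.1))
        assert dist.n_frequencies == 16
        assert dist.n_values == 48
        assert 0 < dist.mean < 1
        assert dist.sd > 0

    def test_minimum_at_true_frequency_for_perfect_train(self,
                                                         perfect_train):
        freqs = make_grid((0.1, 20.0, 0.01))
        vals = mean_ugof_grid(perfect_train, freqs)
        assert vals.min() == pytest.approx(0.0, abs=1e-9)
        at_true = vals[np.isclose(freqs, 10.0)]
        assert at_true == pytest.approx(0.0, abs=1e-9)

    def test_empty_dataset_errors(self):
        with pytest.raises(InsufficientDataError):
            model_ugof_distribution([])

    def test_per_element_pooling_counts_elements(self, rng):
        seqs = [seq_of(np.sort(rng.uniform(0, 2, n))) for n in (4, 6)]
        dist = model_ugof_distribution(seqs, grid=(1.0, 2.0, 0.5),
                                       per_element=True)
        assert dist.n_values == 3 * (4 + 6)

    def test_json_round_trip(self, tmp_path, rng):
        seqs = [seq_of(np.sort(rng.uniform(0, 2, 5)))]
        dist = model_ugof_distribution(seqs, grid=(0.5, 2.0, 0.1))
        path = tmp_path / "dist.json"
        dist.to_json(path)
        back = UgofDistribution.from_json(path)
        assert back == dist


class TestZscore:
    dist = UgofDistribution(grid=(0.1, 100.0, 0.01), n_frequencies=9991,
                            n_sequences=1, n_values=9991, mean=0.5, sd=0.1)

    def test_at_mean(self):
        sig = zscore(0.5, self.dist)
        assert sig.z == 0.0
        assert sig.p == pytest.approx(0.5)
        assert not sig.significant

    def test_standard_normal_quantile(self):
        sig = zscore(0.5 - 1.6449 * 0.1, self.dist)
        assert sig.z == pytest.approx(-1.6449)
        assert sig.p == pytest.approx(0.05, abs=1e-4)
        assert sig.significant

    def test_positive_z_never_significant(self):
        sig = zscore(0.9, self.dist, alpha=0.9999)
        assert sig.z > 0
        assert not sig.significant

    def test_degenerate_distribution(self):
        bad = UgofDistribution(grid=(0.1, 1.0, 0.1), n_frequencies=10,
                               n_sequences=1, n_values=10, mean=0.5, sd=0.0)
        with pytest.raises(DegenerateDistributionError):
            zscore(0.4, bad)


class TestSensitivityScan:
    def test_perfect_train_minimum_at_true_beat(self, perfect_train):
        scan = sensitivity_scan(perfect_train, 10.0)
        assert scan.min_frequency == pytest.approx(10.0)
        assert scan.min_value == pytest.approx(0.0, abs=1e-9)
        assert not scan.improved

    def test_band_crossing_zero_rejected(self, perfect_train):
        with pytest.raises(ValueError, match="crosses 0"):
            sensitivity_scan(perfect_train, 0.5, half_width=1.0)

    def test_offset_center_improves_toward_truth(self, jittered_train):
        scan = sensitivity_scan(jittered_train, 10.5)
        assert scan.improved
        assert scan.min_value < scan.center_value
        assert scan.min_frequency == pytest.approx(10.0, abs=0.1)

    def test_grid_sorted_and_bounded(self, perfect_train):
        scan = sensitivity_scan(perfect_train, 10.0, half_width=0.5,
                                step=0.05)
        assert (np.diff(scan.frequencies) > 0).all()
        assert scan.frequencies[0] == pytest.approx(9.5)
        assert scan.frequencies[-1] == pytest.approx(10.5)
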