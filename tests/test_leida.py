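"""Signal stages, eigenvectors and clustering of the LEiDA pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from braindyn.leida import (
    BrainStateSet,
    assign_to_centroids,
    bandpass_filter,
    cluster_states,
    eigenvector_series,
    hilbert_phase,
    leading_eigenvector,
    network_correlation,
    occurrence_probabilities,
    phase_coherence_matrix,
    _leading_eigenvectors_rank2,
)


TR = 2.0
T = 200
TIME = np.arange(T) * TR


class TestBandpass:
    def test_passband_sinusoid_amplitude_preserved(self):
        x = np.sin(2 * np.pi * 0.04 * TIME)[None, :]
        y = bandpass_filter(x, TR)
        # compare amplitudes away from the filter edges
        assert np.abs(y[0, 40:-40]).max() == pytest.approx(1.0, rel=0.05)

    def test_constant_series_zeroed(self):
        y = bandpass_filter(np.full((3, T), 7.5), TR)
        assert np.abs(y).max() < 1e-8

    def test_stopband_sinusoid_attenuated(self):
        x = np.sin(2 * np.pi * 0.2 * TIME)[None, :]
        y = bandpass_filter(x, TR)
        assert np.abs(y[0, 40:-40]).max() < 0.2

    def test_output_mean_small_relative_to_amplitude(self, rng):
        # edge transients leave a small residual mean on finite noisy series
        y = bandpass_filter(rng.standard_normal((4, T)) + 5.0, TR)
        assert np.all(np.abs(y.mean(axis=1)) < 0.15 * y.std(axis=1))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((2, T)), TR, 0.01, 0.3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((2, 10)), TR)


class TestHilbertPhase:
    def test_phase_advances_at_signal_frequency(self):
        f = 0.04
        theta = hilbert_phase(np.cos(2 * np.pi * f * TIME)[None, :])
        dphi = np.diff(np.unwrap(theta[0]))[20:-20] / TR
        assert np.allclose(dphi, 2 * np.pi * f, rtol=0.02)

    def test_quadrature_offset(self):
        f = 0.04
        theta = hilbert_phase(
            np.vstack([np.cos(2 * np.pi * f * TIME), np.sin(2 * np.pi * f * TIME)])
        )
        diff = np.angle(np.exp(1j * (theta[0] - theta[1])))[20:-20]
        assert np.allclose(diff, np.pi / 2, atol=0.05)

    def test_sign_flip_shifts_phase_by_pi(self):
        f = 0.04
        theta = hilbert_phase(
            np.vstack([np.cos(2 * np.pi * f * TIME), -np.cos(2 * np.pi * f * TIME)])
        )
        diff = np.abs(np.angle(np.exp(1j * (theta[0] - theta[1]))))[20:-20]
        assert np.allclose(diff, np.pi, atol=0.05)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros((2, T)))

    def test_range_convention(self, rng):
        theta = hilbert_phase(rng.standard_normal((3, T)))
        assert np.all(theta > -np.pi) and np.all(theta <= np.pi)


class TestPhaseCoherence:
    def test_canonical_relationships(self):
        theta = np.array([0.3, 0.3, 0.3 + np.pi, 0.3 + np.pi / 2])
        m = phase_coherence_matrix(theta)
        assert m[0, 1] == pytest.approx(1.0)          # in-phase
        assert m[0, 2] == pytest.approx(-1.0)         # anti-phase
        assert m[0, 3] == pytest.approx(0.0, abs=1e-12)  # orthogonal

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_bruteforce_and_is_symmetric(self, seed):
        theta = np.random.default_rng(seed).uniform(-np.pi, np.pi, 8)
        m = phase_coherence_matrix(theta)
        brute = np.array([[np.cos(a - b) for b in theta] for a in theta])
        assert np.allclose(m, brute)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v = leading_eigenvector(np.ones((5, 5)))
        assert np.allclose(np.abs(v), 1 / np.sqrt(5))
        assert np.all(v < 0)  # sign convention

    def test_2x2_closed_form(self):
        v = leading_eigenvector(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert np.allclose(np.abs(v), 1 / np.sqrt(2), atol=1e-12)
        assert v[0] * v[1] > 0  # same sign pair

    def test_against_power_iteration(self, rng):
        m = rng.standard_normal((6, 6))
        m = m + m.T
        v = leading_eigenvector(m)
        w = rng.standard_normal(6)
        for _ in range(5000):
            w = m @ w + 10 * w  # shift to make the top eigenvalue dominant
            w /= np.linalg.norm(w)
        assert abs(abs(v @ w) - 1) < 1e-8

    def test_rank2_fast_path_matches_dense(self, rng):
        theta = rng.uniform(-np.pi, np.pi, (12, 9))
        fast = _leading_eigenvectors_rank2(theta)
        for t in range(theta.shape[1]):
            dense = leading_eigenvector(phase_coherence_matrix(theta[:, t]))
            assert np.allclose(fast[t], dense, atol=1e-8)


class TestEigenvectorSeries:
    def test_row_count_and_norms(self, small_cohort):
        es = eigenvector_series(small_cohort["cohort"])
        n_sub = len(small_cohort["cohort"])
        assert es.vectors.shape == (n_sub * 150, 20)
        assert np.allclose(np.linalg.norm(es.vectors, axis=1), 1.0, atol=1e-9)

    def test_block_structure_under_subject_permutation(self, small_cohort):
        cohort = small_cohort["cohort"]
        es = eigenvector_series(cohort)
        perm = [3, 0, 1, 2, 4, 5, 6, 7]
        es_perm = eigenvector_series(cohort.subset(perm))
        blocks = [es.vectors[s * 150:(s + 1) * 150] for s in range(8)]
        for new_pos, old_pos in enumerate(perm):
            assert np.allclose(
                es_perm.vectors[new_pos * 150:(new_pos + 1) * 150], blocks[old_pos]
            )

    def test_region_mismatch_rejected(self, rng):
        from braindyn.cohort import RegionalTimeSeriesSet

        series = [rng.standard_normal((6, 60)), rng.standard_normal((5, 60))]
        with pytest.raises(ValueError):
            eigenvector_series(RegionalTimeSeriesSet(series, 2.0))

    def test_full_synchrony_gives_uniform_vectors(self):
        from braindyn.cohort import RegionalTimeSeriesSet

        base = np.sin(2 * np.pi * 0.04 * TIME)
        cohort = RegionalTimeSeriesSet([np.tile(base, (6, 1))], 2.0)
        es = eigenvector_series(cohort)
        assert np.allclose(np.abs(es.vectors), 1 / np.sqrt(6), atol=1e-6)
        states = cluster_states(es, k=1, n_replicates=2, seed=0)
        assert states.inertia < 1e-6


class TestClusterStates:
    def test_planted_partition_recovery(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.array([[5.0, 0, 0, 0], [0, 5.0, 0, 0], [0, 0, 5.0, 0]])
        labels_true = np.repeat([0, 1, 2], 40)
        x = centers[labels_true] + 0.1 * rng.standard_normal((120, 4))
        states = cluster_states(x, k=3, n_replicates=10, seed=0)
        assert adjusted_rand_score(labels_true, states.assignment) == 1.0

    def test_k1_centroid_is_median(self, rng):
        x = rng.standard_normal((30, 5))
        states = cluster_states(x, k=1, n_replicates=3, seed=0)
        assert np.allclose(states.centroids[0], np.median(x, axis=0))

    def test_k_equals_distinct_rows_zero_inertia(self):
        x = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        states = cluster_states(x, k=4, n_replicates=5, seed=0)
        assert states.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_per_seed(self, rng):
        x = rng.standard_normal((60, 4))
        a = cluster_states(x, k=3, n_replicates=5, seed=9)
        b = cluster_states(x, k=3, n_replicates=5, seed=9)
        assert np.array_equal(a.assignment, b.assignment)
        assert np.allclose(a.centroids, b.centroids)

    def test_states_ordered_by_occupancy(self, rng):
        x = np.vstack([
            np.zeros((50, 3)) + [5, 0, 0],
            np.zeros((30, 3)) + [0, 5, 0],
            np.zeros((20, 3)) + [0, 0, 5],
        ]) + 0.05 * rng.standard_normal((100, 3))
        states = cluster_states(x, k=3, n_replicates=5, seed=1)
        counts = np.bincount(states.assignment - 1, minlength=3)
        assert np.all(np.diff(counts) <= 0)


class TestAssignment:
    def test_centroid_maps_to_own_label(self, rng):
        centroids = rng.standard_normal((4, 6))
        states = BrainStateSet(centroids, 4, np.arange(4) + 1, 0.0)
        assert np.array_equal(assign_to_centroids(centroids, states), [1, 2, 3, 4])

    def test_tie_goes_to_lowest_label(self):
        centroids = np.array([[0.0, 0.0], [2.0, 0.0]])
        states = BrainStateSet(centroids, 2, np.array([1, 2]), 0.0)
        assert assign_to_centroids(np.array([[1.0, 0.0]]), states)[0] == 1

    def test_matches_bruteforce(self, rng):
        centroids = rng.standard_normal((5, 7))
        states = BrainStateSet(centroids, 5, np.arange(5) + 1, 0.0)
        rows = rng.standard_normal((40, 7))
        labels = assign_to_centroids(rows, states)
        brute = cdist(rows, centroids, "cityblock").argmin(axis=1) + 1
        assert np.array_equal(labels, brute)


class TestOccurrenceProbabilities:
    @pytest.mark.parametrize("seq,k,expected", [
        ([1, 1, 1, 1], 3, (1, 0, 0)),
        ([1, 2, 3, 1], 3, (0.5, 0.25, 0.25)),
    ])
    def test_known_sequences(self, seq, k, expected):
        pms = occurrence_probabilities(seq, k)
        assert np.allclose(pms.probabilities, expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_concatenation_is_weighted_mean(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(1, 4, size=r.integers(1, 30))
        b = r.integers(1, 4, size=r.integers(1, 30))
        pa = occurrence_probabilities(a, 3).probabilities
        pb = occurrence_probabilities(b, 3).probabilities
        pc = occurrence_probabilities(np.concatenate([a, b]), 3).probabilities
        wa, wb = len(a) / (len(a) + len(b)), len(b) / (len(a) + len(b))
        assert np.allclose(pc, wa * pa + wb * pb)
        assert pc.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            occurrence_probabilities([], 3)


class TestNetworkCorrelation:
    def test_indicator_itself_gives_r_one(self, region_table_20):
        indicator = (region_table_20["network"] == "VIS").to_numpy(float)
        r, lo, hi, p = network_correlation(indicator, region_table_20, "VIS")
        assert r == pytest.approx(1.0)

    def test_matches_textbook_oracle(self, region_table_20, rng):
        from scipy.stats import pearsonr, norm

        centroid = rng.standard_normal(20)
        r, lo, hi, p = network_correlation(centroid, region_table_20, "DMN")
        rect = np.maximum(centroid, 0)
        ind = (region_table_20["network"] == "DMN").to_numpy(float)
        r0, p0 = pearsonr(rect, ind)
        z = np.arctanh(r0)
        half = norm.ppf(0.975) / np.sqrt(20 - 3)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-12)

    def test_all_nonpositive_centroid_rejected(self, region_table_20):
        with pytest.raises(ValueError):
            network_correlation(-np.ones(20), region_table_20, "VIS")
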