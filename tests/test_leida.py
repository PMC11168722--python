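"""Model-free stage: filtering, phases, coherence, eigenvectors, clustering, PMS."""

import numpy as np
import pytest

from pmspace.leida import (
    PMS,
    BoldTimeSeries,
    EigenvectorPool,
    _apply_sign_convention,
    bandpass_filter,
    cluster_eigenvectors,
    compute_pms,
    instantaneous_phase,
    leading_eigenvector,
    leading_eigenvectors_from_phases,
    phase_coherence,
    pool_eigenvectors,
    select_k,
)

TR = 2.0
T = 350
TIME = np.arange(T) * TR


def _ts(rows, tr=TR, **kw):
    return BoldTimeSeries(np.asarray(rows, float), tr, **kw)


class TestBandpassFilter:
    def test_passband_sinusoid_amplitude_preserved(self):
        """A 0.055 Hz sinusoid inside the band keeps its amplitude within 5%."""
        sig = np.cos(2 * np.pi * 0.055 * TIME)
        out = bandpass_filter(_ts([sig, sig])).data[0]
        interior = slice(30, -30)
        in_amp = np.sqrt(2) * np.std(sig[interior])
        out_amp = np.sqrt(2) * np.std(out[interior])
        assert abs(out_amp - in_amp) / in_amp < 0.05

    def test_stopband_sinusoid_suppressed(self):
        """A 0.2 Hz sinusoid far above the band is attenuated below 10% RMS."""
        sig = np.cos(2 * np.pi * 0.2 * TIME)
        out = bandpass_filter(_ts([sig, sig])).data[0]
        assert np.std(out) < 0.1 * np.std(sig)

    def test_constant_signal_maps_to_zero(self):
        out = bandpass_filter(_ts([np.full(T, 3.7), np.full(T, -1.0)])).data
        assert np.all(np.abs(out) < 1e-8)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(_ts(np.ones((2, T))), low_hz=0.04, high_hz=0.3)


class TestInstantaneousPhase:
    def test_cosine_phase_advances_at_signal_frequency(self):
        """Unwrapped phase of cos(2 pi f t) advances ~2 pi f tr per TR."""
        f = 0.05
        sig = np.cos(2 * np.pi * f * TIME)
        theta = instantaneous_phase(_ts([sig, sig])).theta[0]
        steps = np.diff(np.unwrap(theta))[20:-20]
        assert np.allclose(steps, 2 * np.pi * f * TR, rtol=0.02)

    def test_identical_rows_get_identical_phases(self):
        sig = np.cos(2 * np.pi * 0.05 * TIME) + 0.1 * np.sin(2 * np.pi * 0.06 * TIME)
        theta = instantaneous_phase(_ts([sig, sig])).theta
        assert np.array_equal(theta[0], theta[1])

    def test_sin_lags_cos_by_quarter_cycle(self):
        f = 0.05
        c = np.cos(2 * np.pi * f * TIME)
        s = np.sin(2 * np.pi * f * TIME)
        theta = instantaneous_phase(_ts([c, s])).theta
        gap = np.angle(np.exp(1j * (theta[0] - theta[1])))[30:-30]
        assert np.allclose(np.abs(gap), np.pi / 2, atol=0.05)

    def test_all_zero_row_flagged_and_zeroed(self):
        sig = np.cos(2 * np.pi * 0.05 * TIME)
        with pytest.warns(RuntimeWarning, match="all-zero"):
            theta = instantaneous_phase(_ts([sig, np.zeros(T)])).theta
        assert np.all(theta[1] == 0.0)

    def test_phases_in_half_open_interval(self, rng):
        data = rng.standard_normal((5, T))
        theta = instantaneous_phase(bandpass_filter(_ts(data))).theta
        assert np.all(theta > -np.pi) and np.all(theta <= np.pi)


class TestPhaseCoherence:
    def test_aligned_phases_give_unit_coherence(self):
        m = phase_coherence(np.array([0.3, 0.3, 1.2])).values
        assert m[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_phases_give_zero_coherence(self):
        m = phase_coherence(np.array([0.1, 0.1 + np.pi / 2])).values
        assert m[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_antiphase_gives_minus_one(self):
        m = phase_coherence(np.array([0.0, np.pi])).values
        assert m[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        m = phase_coherence(rng.uniform(-np.pi, np.pi, 17)).values
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 1.0)
        assert np.all((m >= -1.0) & (m <= 1.0))


class TestLeadingEigenvector:
    def test_rank_one_matrix_recovers_generator(self, rng):
        u = rng.standard_normal(6)
        u /= np.linalg.norm(u)
        v = leading_eigenvector(np.outer(u, u)).v
        assert np.allclose(np.abs(v), np.abs(u), atol=1e-10)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_equal_phases_give_uniform_negative_vector(self):
        m = phase_coherence(np.full(8, 0.7))
        v = leading_eigenvector(m).v
        assert np.allclose(v, -1 / np.sqrt(8), atol=1e-10)

    def test_degenerate_top_eigenvalue_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            leading_eigenvector(np.eye(4))

    def test_matches_dense_eigensolver(self, rng):
        """Sign-normalized top eigenvector agrees with an independent dense solve."""
        for _ in range(5):
            a = rng.standard_normal((5, 5))
            m = a + a.T
            v = leading_eigenvector(m).v
            w, vecs = np.linalg.eigh(m)
            ref = _apply_sign_convention(vecs[:, -1])
            assert np.allclose(v, ref, atol=1e-10)

    def test_sign_convention_majority_nonpositive_and_idempotent(self, rng):
        for _ in range(20):
            v = rng.standard_normal(9)
            v /= np.linalg.norm(v)
            out = _apply_sign_convention(v)
            n_nonpos = np.sum(out <= 0)
            if n_nonpos * 2 == out.size:  # tie: largest-magnitude entry negative
                assert out[np.argmax(np.abs(out))] <= 0
            else:
                assert n_nonpos * 2 > out.size
            assert np.array_equal(_apply_sign_convention(out), out)

    def test_rank2_fast_path_equals_per_tr_solve(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(12, 9))
        fast = leading_eigenvectors_from_phases(theta)
        for t in range(9):
            dense = leading_eigenvector(phase_coherence(theta[:, t])).v
            assert np.allclose(fast[t], dense, atol=1e-8)


def _two_cloud_pool(rng, n_per=40, n_dim=8):
    c1 = np.zeros(n_dim)
    c1[:4] = -0.5
    c2 = np.zeros(n_dim)
    c2[4:] = -0.5
    vecs = np.vstack(
        [c1 + 0.01 * rng.standard_normal((n_per, n_dim)),
         c2 + 0.01 * rng.standard_normal((n_per, n_dim))]
    )
    truth = np.repeat([0, 1], n_per)
    pool = EigenvectorPool(
        vectors=vecs,
        subjects=np.repeat("s0", 2 * n_per),
        conditions=np.array(["a"] * n_per + ["b"] * n_per),
        ts=np.arange(2 * n_per),
    )
    return pool, truth


class TestClustering:
    def test_separable_clouds_recovered_exactly(self, rng):
        pool, truth = _two_cloud_pool(rng)
        model = cluster_eigenvectors(pool, k=2, seed=0, n_replicates=5)
        labels = model.assignments["cluster"].to_numpy()
        agreement = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agreement == 1.0

    def test_same_seed_reproduces_assignments(self, rng):
        pool, _ = _two_cloud_pool(rng)
        m1 = cluster_eigenvectors(pool, k=2, seed=7, n_replicates=5)
        m2 = cluster_eigenvectors(pool, k=2, seed=7, n_replicates=5)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert m1.assignments.equals(m2.assignments)

    def test_k_below_two_rejected(self, rng):
        pool, _ = _two_cloud_pool(rng)
        with pytest.raises(ValueError, match="k must be >= 2"):
            cluster_eigenvectors(pool, k=1)

    def test_centroids_ordered_by_descending_occupancy(self, cluster_k3):
        counts = np.bincount(
            cluster_k3.assignments["cluster"].to_numpy(), minlength=cluster_k3.k
        )
        assert np.all(np.diff(counts) <= 0)


class TestPMS:
    def test_single_cluster_occupancy_is_one_hot(self, rng):
        pool, _ = _two_cloud_pool(rng)
        model = cluster_eigenvectors(pool, k=2, seed=0, n_replicates=5)
        pms = compute_pms(model, "a")
        assert pms.probabilities.max() == 1.0 and pms.probabilities.min() == 0.0

    def test_occupancy_fractions_are_exact_ratios(self):
        import pandas as pd
        from pmspace.leida import ClusterModel

        assignments = pd.DataFrame(
            {
                "subject": ["s"] * 14,
                "condition": ["x"] * 14,
                "t": range(14),
                "cluster": [0] * 7 + [1] * 4 + [2] * 3,
            }
        )
        model = ClusterModel(k=3, centroids=np.zeros((3, 2)), assignments=assignments)
        pms = compute_pms(model, "x")
        assert np.allclose(pms.probabilities, [0.5, 4 / 14, 3 / 14])
        assert pms.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_absent_condition_rejected(self, cluster_k3):
        with pytest.raises(ValueError, match="absent"):
            compute_pms(cluster_k3, "no-such-condition")

    def test_weighted_condition_pms_reproduces_pooled_occupancy(
        self, cluster_k3, pms_by_condition
    ):
        """Observation-weighted mixture of condition PMS equals pooled occupancy."""
        total = sum(p.n_observations for p in pms_by_condition.values())
        mixed = sum(
            p.probabilities * (p.n_observations / total)
            for p in pms_by_condition.values()
        )
        pooled = np.bincount(
            cluster_k3.assignments["cluster"].to_numpy(), minlength=cluster_k3.k
        )
        assert np.allclose(mixed, pooled / pooled.sum(), atol=1e-12)


class TestSelectK:
    @staticmethod
    def _pvals(k, n_sig):
        p = np.full(k, 0.9)
        p[:n_sig] = 0.01
        return p

    def test_argmax_of_significant_fraction(self):
        results = {2: self._pvals(2, 1), 3: self._pvals(3, 1), 5: self._pvals(5, 3)}
        assert select_k(results) == 5

    def test_tie_goes_to_smallest_k(self):
        results = {2: self._pvals(2, 1), 4: self._pvals(4, 2)}
        assert select_k(results) == 2

    def test_all_nonsignificant_warns_and_returns_min_k(self):
        results = {2: self._pvals(2, 0), 3: self._pvals(3, 0)}
        with pytest.warns(RuntimeWarning, match="no significant"):
            assert select_k(results) == 2

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_k({})


class TestPoolBookkeeping:
    def test_pms_requires_normalized_nonnegative_vector(self):
        with pytest.raises(ValueError):
            PMS(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            PMS(np.array([-0.1, 1.1]))

    def test_edge_trim_drops_both_ends(self, rng):
        data = rng.standard_normal((4, 60))
        ps = instantaneous_phase(bandpass_filter(_ts(data)))
        full = pool_eigenvectors([ps], edge_trim=0)
        trimmed = pool_eigenvectors([ps], edge_trim=5)
        assert len(full) == 60 and len(trimmed) == 50
        assert trimmed.ts.min() == 5 and trimmed.ts.max() == 54
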