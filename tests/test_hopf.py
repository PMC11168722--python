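"""Stuart-Landau simulation, KL objective, phase FC, EC updates, coupling fit."""

import numpy as np
import pytest

from pmspace.hopf import (
    GrandAveragePhaseFC,
    HopfModel,
    IntegrationDivergedError,
    assign_to_centroids,
    estimate_node_frequencies,
    grand_average_phase_fc,
    kl_distance,
    simulate_hopf,
    simulate_hopf_ensemble,
    simulated_pms,
    update_effective_connectivity,
)
from pmspace.leida import BoldTimeSeries, PMS, bandpass_filter, phase_coherence


def _uncoupled(n=3, a=0.09, f=0.05, beta=0.0, dt=0.1):
    return HopfModel(
        a=np.full(n, a),
        omega=np.full(n, 2 * np.pi * f),
        G=0.0,
        C=np.zeros((n, n)),
        beta=beta,
        dt=dt,
    )


def _limit_cycle_radius(model, seed=1):
    """Stationary oscillation radius from x = r cos(wt): r = sqrt(2) * RMS(x)."""
    ts = simulate_hopf(model, 200, seed=seed, transient_s=600.0)
    return np.sqrt(2.0) * np.std(ts.data, axis=1)


class TestSimulator:
    def test_supercritical_radius_is_sqrt_a(self):
        """Noise-free uncoupled oscillator settles on the radius-sqrt(a) limit cycle."""
        radius = _limit_cycle_radius(_uncoupled(a=0.09))
        assert np.allclose(radius, 0.3, rtol=0.01)

    def test_subcritical_amplitude_decays_to_zero(self):
        model = _uncoupled(a=-0.02)
        x, _ = simulate_hopf_ensemble(model, 300, 1, seed=2, transient_s=0.0)
        env = np.abs(x[0, 0])
        assert env[-1] < 1e-3
        peaks = np.maximum.accumulate(env[::-1])[::-1]  # running forward max envelope
        assert np.all(np.diff(peaks) <= 1e-12)

    def test_oscillation_at_programmed_frequency(self):
        f = 0.05
        ts = simulate_hopf(_uncoupled(a=0.09, f=f), 512, seed=3, transient_s=600.0)
        from scipy.signal import periodogram

        freqs, pxx = periodogram(ts.data[0], fs=1.0 / ts.tr)
        peak = freqs[np.argmax(pxx)]
        assert abs(peak - f) <= freqs[1] - freqs[0]

    def test_step_halving_leaves_radius_unchanged_within_1pct(self):
        r_coarse = _limit_cycle_radius(_uncoupled(a=0.09, dt=0.1))
        r_fine = _limit_cycle_radius(_uncoupled(a=0.09, dt=0.05))
        assert np.allclose(r_coarse, r_fine, rtol=0.01)

    def test_deterministic_for_fixed_seed(self):
        model = _uncoupled(a=-0.02, beta=0.01)
        t1 = simulate_hopf(model, 50, seed=7, transient_s=10.0)
        t2 = simulate_hopf(model, 50, seed=7, transient_s=10.0)
        assert np.array_equal(t1.data, t2.data)

    def test_divergence_raises_and_names_coupling(self):
        n = 3
        model = HopfModel(
            a=np.full(n, 1e4),  # far beyond the stable regime at dt=0.1
            omega=np.full(n, 2 * np.pi * 0.05),
            G=5.0,
            C=np.ones((n, n)) - np.eye(n),
            beta=0.0,
        )
        with pytest.raises(IntegrationDivergedError, match="G=5"):
            simulate_hopf(model, 10, seed=0, transient_s=0.0)

    def test_ensemble_per_replicate_parameters(self):
        """Per-replicate a-columns reproduce separately integrated dynamics."""
        model = _uncoupled(n=2, a=0.09, beta=0.0)
        a_cols = np.column_stack([np.full(2, 0.09), np.full(2, 0.04)])
        x, div = simulate_hopf_ensemble(
            model, 100, 2, seed=5, transient_s=600.0, a=a_cols
        )
        assert not div.any()
        assert np.sqrt(2) * np.std(x[0, 0]) == pytest.approx(0.3, rel=0.02)
        assert np.sqrt(2) * np.std(x[1, 0]) == pytest.approx(0.2, rel=0.02)


class TestNodeFrequencies:
    def test_recovers_programmed_frequency_within_one_bin(self):
        t = np.arange(350) * 2.0
        sig = np.cos(2 * np.pi * 0.05 * t)
        ts = BoldTimeSeries(np.vstack([sig, sig]), 2.0)
        omega = estimate_node_frequencies([bandpass_filter(ts)])
        df = 1.0 / (350 * 2.0)
        assert np.all(np.abs(omega / (2 * np.pi) - 0.05) <= df)

    def test_identical_nodes_get_identical_frequencies(self, rng):
        data = rng.standard_normal(350)
        ts = bandpass_filter(BoldTimeSeries(np.vstack([data] * 3), 2.0))
        omega = estimate_node_frequencies([ts])
        assert np.all(omega == omega[0])

    def test_estimates_clamped_to_band(self, rng):
        ts = bandpass_filter(BoldTimeSeries(rng.standard_normal((4, 350)), 2.0))
        f = estimate_node_frequencies([ts]) / (2 * np.pi)
        assert np.all((f >= 0.04) & (f <= 0.07))


class TestKLDistance:
    def test_zero_iff_equal(self):
        p = PMS(np.array([0.5, 0.3, 0.2]), n_observations=1000)
        assert kl_distance(p, p) == 0.0

    def test_matches_direct_evaluation(self):
        """Hand-evaluated symmetrized KL for (0.5,0.5) vs (0.9,0.1)."""
        p = np.array([0.5, 0.5])
        q = np.array([0.9, 0.1])
        expected = 0.5 * (
            np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))
        )  # independent direct evaluation
        assert kl_distance(p, q) == pytest.approx(expected, abs=1e-12)

    def test_premetric_on_random_simplex_pairs(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            d_pq = kl_distance(p, q)
            d_qp = kl_distance(q, p)
            assert d_pq >= 0.0
            assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert kl_distance(p, p) == 0.0

    def test_zero_probabilities_stay_finite(self):
        p = PMS(np.array([1.0, 0.0]), n_observations=700)
        q = PMS(np.array([0.5, 0.5]), n_observations=700)
        d = kl_distance(p, q)
        assert np.isfinite(d) and d > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_distance(np.array([1.0]), np.array([0.5, 0.5]))


class TestGrandAverageFC:
    def test_constant_phase_offsets_give_cosine_entries(self):
        t = np.arange(200)
        theta = np.vstack([0.01 * t, 0.01 * t + 1.1])
        fc = grand_average_phase_fc(theta).values
        assert fc[0, 1] == pytest.approx(np.cos(1.1), abs=1e-12)

    def test_independent_phases_average_to_zero(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(4, 10_000))
        fc = grand_average_phase_fc(theta).values
        off = fc[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_equals_mean_of_per_tr_coherence(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(5, 40))
        fc = grand_average_phase_fc(theta).values
        stacked = np.mean(
            [phase_coherence(theta[:, t]).values for t in range(40)], axis=0
        )
        assert np.allclose(fc, stacked, atol=1e-12)


class TestEffectiveConnectivityUpdate:
    def test_zero_gradient_leaves_c_unchanged(self, rng):
        c = np.abs(rng.uniform(0, 0.1, (4, 4)))
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 0.0)
        fc = rng.uniform(-1, 1, (4, 4))
        fc = 0.5 * (fc + fc.T)
        out = update_effective_connectivity(c, fc, fc)
        assert np.allclose(out, c, atol=1e-15)

    def test_single_pair_discrepancy_moves_by_epsilon_times_gap(self):
        c = np.zeros((3, 3))
        fe = np.eye(3)
        fs = np.eye(3).astype(float)
        fe[0, 1] = fe[1, 0] = 0.1
        fs[0, 1] = fs[1, 0] = 0.0
        out = update_effective_connectivity(c, fe, fs, epsilon=0.01)
        assert out[0, 1] == pytest.approx(0.001, abs=1e-15)
        assert out[2, 1] == 0.0

    def test_clamped_to_valid_weight_range(self, rng):
        c = np.full((3, 3), 0.199)
        np.fill_diagonal(c, 0.0)
        fe = np.ones((3, 3))
        fs = -np.ones((3, 3))
        out = update_effective_connectivity(c, fe, fs, epsilon=0.5)
        assert out.max() <= 0.2 and out.min() >= 0.0
        assert np.all(np.diag(out) == 0.0)


class TestSimulatedPMS:
    def test_eigenvectors_on_centroids_give_point_mass(self, rng):
        cents = rng.standard_normal((3, 6))
        vecs = np.tile(cents[1], (20, 1))
        labels = assign_to_centroids(vecs, cents)
        assert np.all(labels == 1)

    def test_assignment_matches_brute_force(self, rng):
        cents = rng.standard_normal((4, 10))
        vecs = rng.standard_normal((100, 10))
        fast = assign_to_centroids(vecs, cents)
        brute = np.array(
            [np.argmin([np.linalg.norm(v - c) for c in cents]) for v in vecs]
        )
        assert np.array_equal(fast, brute)

    def test_probabilities_sum_to_one_and_parcels_checked(self, rng):
        model = _uncoupled(n=4, a=-0.02, beta=0.01)
        sim = simulate_hopf(model, 120, seed=11, transient_s=60.0)
        cents = rng.standard_normal((3, 4))
        pms = simulated_pms(sim, cents)
        assert pms.kind == "simulated"
        assert pms.probabilities.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="parcel mismatch"):
            simulated_pms(sim, rng.standard_normal((3, 5)))
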