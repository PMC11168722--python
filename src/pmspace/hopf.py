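"""Coupled Stuart-Landau (Hopf) whole-brain model: simulation, fitting, optimization.

Each parcel n is a Stuart-Landau oscillator at the normal form of a
supercritical Hopf bifurcation,

    dx_n/dt = (a_n - x_n^2 - y_n^2) x_n - w_n y_n + G sum_p C_np (x_p - x_n) + b eta_n
    dy_n/dt = (a_n - x_n^2 - y_n^2) y_n + w_n x_n + G sum_p C_np (y_p - y_n) + b eta_n

with bifurcation parameter a_n (noisy decay for a < 0, a limit cycle of radius
sqrt(a) for a > 0), intrinsic angular frequency w_n, global coupling G scaling
the connectome C, and additive Gaussian noise of standard deviation b (beta).

The model-based stage fits G by sweeping a grid, simulating the model, pushing
the simulated signal through the same LEiDA chain as the empirical data, and
minimizing the symmetrized Kullback-Leibler distance between simulated and
empirical substate occupancy distributions; the connectome is promoted to
effective connectivity by gradient descent on the grand-average phase-coherence
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .leida import (
    PMS,
    BoldTimeSeries,
    ClusterModel,
    PhaseSeries,
    bandpass_filter,
    instantaneous_phase,
    leading_eigenvectors_from_phases,
)

__all__ = [
    "HopfModel",
    "GrandAveragePhaseFC",
    "FitResult",
    "IntegrationDivergedError",
    "FittingFailedError",
    "estimate_node_frequencies",
    "simulate_hopf",
    "simulate_hopf_ensemble",
    "assign_to_centroids",
    "simulated_pms",
    "simulated_pms_from_runs",
    "kl_distance",
    "grand_average_phase_fc",
    "update_effective_connectivity",
    "optimize_model",
    "fit_global_coupling",
]

DIVERGENCE_LIMIT = 1e6


class IntegrationDivergedError(RuntimeError):
    """Raised when the Euler-Maruyama state exceeds the divergence limit."""


class FittingFailedError(RuntimeError):
    """Raised when every value on the coupling grid diverges."""


@dataclass
class HopfModel:
    """Parameters of the coupled Hopf whole-brain model.

    a : per-node bifurcation parameters (default -0.02 everywhere, just below
        the bifurcation, where noise-driven fluctuations are structured).
    omega : per-node angular frequencies in rad/s (f = omega / 2 pi in Hz).
    G : global coupling weight.
    C : coupling matrix (structural or effective connectivity), symmetric,
        nonnegative, zero diagonal, max entry 0.2 by convention.
    beta : additive Gaussian noise standard deviation (default 0.01).
    dt : Euler-Maruyama step in seconds; tr : output sampling interval.
    """

    a: np.ndarray
    omega: np.ndarray
    G: float
    C: np.ndarray
    beta: float = 0.01
    dt: float = 0.1
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.a.size
        if self.omega.size != n or self.C.shape != (n, n):
            raise ValueError("a, omega and C must agree on the number of nodes")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0 or self.dt > self.tr:
            raise ValueError("require 0 < dt <= tr")

    @property
    def n_nodes(self) -> int:
        return self.a.size


@dataclass
class GrandAveragePhaseFC:
    """Time-averaged phase-coherence matrix <cos(phi_j - phi_i)>_t."""

    values: np.ndarray


@dataclass
class FitResult:
    """Outcome of the global-coupling sweep."""

    g_grid: np.ndarray
    kl_by_g: np.ndarray
    g_best: float
    kl_best: float
    n_reps: int
    ec_final: np.ndarray | None = None
    pms_by_g: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# frequencies


def estimate_node_frequencies(
    filtered_bold: Sequence[BoldTimeSeries],
    band: tuple[float, float] = (0.04, 0.07),
) -> np.ndarray:
    """Intrinsic angular frequencies from band-passed BOLD.

    Per node, the peak of the subject-averaged periodogram restricted to the
    band, clamped to the band; returned as omega = 2 pi f in rad/s. A flat
    in-band spectrum falls back to the band midpoint with a warning.
    """
    if not filtered_bold:
        raise ValueError("need at least one time series")
    fs = 1.0 / filtered_bold[0].tr
    psd_sum = None
    for ts in filtered_bold:
        f, pxx = periodogram(ts.data, fs=fs, axis=1)
        psd_sum = pxx if psd_sum is None else psd_sum + pxx
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError("periodogram has no bins inside the band; series too short")
    band_psd = psd_sum[:, in_band]
    band_f = f[in_band]
    peak_f = band_f[np.argmax(band_psd, axis=1)]
    flat = np.ptp(band_psd, axis=1) <= 1e-300
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} node(s) with flat spectrum; using band midpoint",
            RuntimeWarning,
        )
        peak_f = np.where(flat, 0.5 * (band[0] + band[1]), peak_f)
    return 2.0 * np.pi * np.clip(peak_f, band[0], band[1])


# ---------------------------------------------------------------------------
# simulation


def _as_columns(arr: np.ndarray, n: int, n_reps: int, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        if arr.size != n:
            raise ValueError(f"{name} must have length {n}")
        return np.broadcast_to(arr[:, None], (n, n_reps)).copy()
    if arr.shape != (n, n_reps):
        raise ValueError(f"{name} must have shape ({n},) or ({n}, {n_reps})")
    return arr.copy()


def simulate_hopf_ensemble(
    model: HopfModel,
    n_timepoints: int,
    n_reps: int,
    seed: int,
    transient_s: float = 300.0,
    a: np.ndarray | None = None,
    g: np.ndarray | float | None = None,
    omega: np.ndarray | None = None,
    raise_on_divergence: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``n_reps`` independent realizations in one vectorized pass.

    Euler-Maruyama at step ``model.dt`` with diffusion ``beta * sqrt(dt)`` per
    node per component; the first ``transient_s`` seconds are discarded and the
    x-component is sampled every ``model.tr``. ``a``/``g``/``omega`` may vary
    per replicate (shape (n, n_reps) for a and omega, length n_reps for g),
    which lets one call sweep bifurcation or coupling values.

    Returns ``(x, diverged)`` with ``x`` of shape (n_reps, n_nodes,
    n_timepoints) and ``diverged`` a boolean mask per replicate. Diverged
    replicates are NaN-filled; if ``raise_on_divergence`` the first divergence
    raises :class:`IntegrationDivergedError` naming the coupling at fault.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    n = model.n_nodes
    dt = model.dt
    steps_per_tr = int(round(model.tr / dt))
    if abs(steps_per_tr * dt - model.tr) > 1e-9:
        raise ValueError("tr must be an integer multiple of dt")
    n_transient = int(round(transient_s / dt))
    a_cols = _as_columns(model.a if a is None else a, n, n_reps, "a")
    w_cols = _as_columns(model.omega if omega is None else omega, n, n_reps, "omega")
    if g is None:
        g_cols = np.full(n_reps, float(model.G))
    else:
        g_cols = np.broadcast_to(np.asarray(g, dtype=float), (n_reps,)).copy()
    C = model.C
    row_sum = C.sum(axis=1)  # sum_p C_np, for the (x_p - x_n) diffusive form

    rng = np.random.default_rng(seed)
    x = 0.1 * rng.standard_normal((n, n_reps))
    y = 0.1 * rng.standard_normal((n, n_reps))
    sqdt = np.sqrt(dt)
    out = np.empty((n_reps, n, n_timepoints))
    diverged = np.zeros(n_reps, dtype=bool)
    # splitting scheme: Euler-Maruyama for the radial, coupling and noise
    # terms, then the rotation by omega*dt applied exactly — a plain Euler
    # rotation inflates the limit-cycle radius by O(dt * omega^2)
    cos_wdt = np.cos(w_cols * dt)
    sin_wdt = np.sin(w_cols * dt)

    n_total = n_transient + n_timepoints * steps_per_tr
    sample_idx = 0
    for step in range(1, n_total + 1):
        r2 = x * x + y * y
        coupling_x = g_cols[None, :] * (C @ x - row_sum[:, None] * x)
        coupling_y = g_cols[None, :] * (C @ y - row_sum[:, None] * y)
        growth = a_cols - r2
        x1 = x + dt * (growth * x + coupling_x) + model.beta * sqdt * rng.standard_normal((n, n_reps))
        y1 = y + dt * (growth * y + coupling_y) + model.beta * sqdt * rng.standard_normal((n, n_reps))
        x = cos_wdt * x1 - sin_wdt * y1
        y = sin_wdt * x1 + cos_wdt * y1
        if step > n_transient and (step - n_transient) % steps_per_tr == 0:
            bad = ~np.isfinite(x).all(axis=0) | (np.abs(x).max(axis=0) > DIVERGENCE_LIMIT)
            if np.any(bad & ~diverged):
                if raise_on_divergence:
                    j = int(np.flatnonzero(bad & ~diverged)[0])
                    raise IntegrationDivergedError(
                        f"integration diverged at G={g_cols[j]:g} (replicate {j})"
                    )
                x[:, bad] = 0.0
                y[:, bad] = 0.0
                diverged |= bad
            out[:, :, sample_idx] = x.T
            sample_idx += 1
    out[diverged] = np.nan
    return out, diverged


def simulate_hopf(
    model: HopfModel,
    n_timepoints: int,
    seed: int,
    transient_s: float = 300.0,
    subject_id: str = "sim",
    condition: str = "simulated",
) -> BoldTimeSeries:
    """Single realization of the model; returns the x-component per node."""
    x, _ = simulate_hopf_ensemble(
        model, n_timepoints, 1, seed, transient_s, raise_on_divergence=True
    )
    return BoldTimeSeries(x[0], model.tr, subject_id, condition)


# ---------------------------------------------------------------------------
# simulated PMS and the fitting objective


def assign_to_centroids(vectors: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) label for each row of ``vectors``."""
    d2 = (
        np.sum(vectors**2, axis=1)[:, None]
        - 2.0 * vectors @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def _eigenvectors_of_sim(sim: BoldTimeSeries, band: tuple[float, float]) -> np.ndarray:
    filtered = bandpass_filter(sim, band[0], band[1])
    phases = instantaneous_phase(filtered)
    return leading_eigenvectors_from_phases(phases.theta)


def simulated_pms(
    sim: BoldTimeSeries,
    centroids: ClusterModel | np.ndarray,
    band: tuple[float, float] = (0.04, 0.07),
) -> PMS:
    """PMS of a simulated run against the empirical substate centroids.

    Runs the same LEiDA chain as the empirical stage (filter, Hilbert phase,
    phase coherence, sign-normalized leading eigenvector) on the simulated
    signal and assigns each eigenvector to its nearest empirical centroid.
    """
    return simulated_pms_from_runs([sim], centroids, band)


def simulated_pms_from_runs(
    sims: Sequence[BoldTimeSeries],
    centroids: ClusterModel | np.ndarray,
    band: tuple[float, float] = (0.04, 0.07),
) -> PMS:
    """Pool eigenvector assignments of several runs into one simulated PMS."""
    cents = centroids.centroids if isinstance(centroids, ClusterModel) else np.asarray(centroids)
    k = cents.shape[0]
    counts = np.zeros(k)
    n_obs = 0
    for sim in sims:
        if sim.n_parcels != cents.shape[1]:
            raise ValueError(
                f"parcel mismatch: simulation has {sim.n_parcels}, centroids {cents.shape[1]}"
            )
        labels = assign_to_centroids(_eigenvectors_of_sim(sim, band), cents)
        counts += np.bincount(labels, minlength=k)
        n_obs += labels.size
    return PMS(counts / counts.sum(), condition="simulated",
               n_observations=n_obs, kind="simulated")


def kl_distance(
    p_emp: PMS | np.ndarray, p_sim: PMS | np.ndarray, n_obs_floor: int = 1000
) -> float:
    """Symmetrized Kullback-Leibler distance between two substate distributions.

    0.5 * [ sum_i P ln(P/Q) + sum_i Q ln(Q/P) ]. Zero probabilities are floored
    at 1/(10 * n_observations) of the respective distribution (then both are
    renormalized) so the distance stays finite while preserving ordering.
    Nonnegative, symmetric, and zero iff the distributions are equal.
    """

    def _vec_and_nobs(p, default):
        if isinstance(p, PMS):
            return np.asarray(p.probabilities, float), p.n_observations
        return np.asarray(p, float), default

    p, n_p = _vec_and_nobs(p_emp, n_obs_floor)
    q, n_q = _vec_and_nobs(p_sim, n_obs_floor)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    p = np.maximum(p, 1.0 / (10.0 * n_p))
    q = np.maximum(q, 1.0 / (10.0 * n_q))
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


# ---------------------------------------------------------------------------
# effective connectivity


def grand_average_phase_fc(phases: PhaseSeries | np.ndarray) -> GrandAveragePhaseFC:
    """Time-average of cos(phi_j(t) - phi_i(t)); symmetric with unit diagonal."""
    theta = phases.theta if isinstance(phases, PhaseSeries) else np.asarray(phases, float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("phases must be finite")
    c, s = np.cos(theta), np.sin(theta)
    t = theta.shape[1]
    m = (c @ c.T + s @ s.T) / t
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return GrandAveragePhaseFC(m)


def update_effective_connectivity(
    C: np.ndarray,
    fc_emp: GrandAveragePhaseFC | np.ndarray,
    fc_sim: GrandAveragePhaseFC | np.ndarray,
    epsilon: float = 0.01,
    c_max: float = 0.2,
) -> np.ndarray:
    """One gradient-descent step on the coupling matrix.

    C_ij <- C_ij + epsilon * (FC_emp_ij - FC_sim_ij) on off-diagonal entries,
    re-symmetrized, clamped to [0, c_max], diagonal forced to zero.
    """
    fe = fc_emp.values if isinstance(fc_emp, GrandAveragePhaseFC) else np.asarray(fc_emp)
    fs = fc_sim.values if isinstance(fc_sim, GrandAveragePhaseFC) else np.asarray(fc_sim)
    if C.shape != fe.shape or fe.shape != fs.shape:
        raise ValueError("shape mismatch between C and the FC matrices")
    out = C + epsilon * (fe - fs)
    out = 0.5 * (out + out.T)
    out = np.clip(out, 0.0, c_max)
    np.fill_diagonal(out, 0.0)
    return out


def _mean_abs_offdiag(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.mean(np.abs(a - b)[mask]))


# ---------------------------------------------------------------------------
# global-coupling fit


def optimize_model(
    p_emp: PMS,
    centroids: ClusterModel | np.ndarray,
    omega: np.ndarray,
    sc: np.ndarray,
    fc_emp: GrandAveragePhaseFC | np.ndarray | None = None,
    g_grid: np.ndarray | None = None,
    n_reps: int = 200,
    seed: int = 0,
    ec_tolerance: float = 0.001,
    max_ec_iters: int = 300,
    a_baseline: float = -0.02,
    beta: float = 0.01,
    dt: float = 0.1,
    tr: float = 2.0,
    n_timepoints: int = 350,
    transient_s: float = 300.0,
    band: tuple[float, float] = (0.04, 0.07),
) -> FitResult:
    """Fit the global coupling G (and effective connectivity) to an empirical PMS.

    For each G on the grid the coupling matrix starts at the structural
    connectome and is updated by gradient descent on the grand-average phase
    FC until the mean absolute off-diagonal difference drops below
    ``ec_tolerance`` or ``max_ec_iters`` is reached (set ``max_ec_iters=0`` to
    fit on the raw connectome). The simulated PMS is then estimated from
    ``n_reps`` pooled independent runs and scored by the symmetrized KL
    distance to the empirical PMS; the best G minimizes that distance.
    """
    if g_grid is None:
        g_grid = np.round(np.arange(0.0, 0.3 + 1e-9, 0.01), 10)
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size == 0:
        raise ValueError("g_grid must be nonempty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if fc_emp is None and max_ec_iters > 0:
        raise ValueError("fc_emp is required when max_ec_iters > 0")
    fe = fc_emp.values if isinstance(fc_emp, GrandAveragePhaseFC) else fc_emp
    n = omega.size
    a_vec = np.full(n, a_baseline)
    kl_by_g = np.full(g_grid.size, np.inf)
    pms_by_g: list[PMS | None] = [None] * g_grid.size
    ec_by_g: list[np.ndarray] = [None] * g_grid.size
    cents = centroids.centroids if isinstance(centroids, ClusterModel) else np.asarray(centroids)

    for gi, g in enumerate(g_grid):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(gi,))
        ec_seeds = child.generate_state(max(max_ec_iters, 1) + 1)
        C = sc.copy()
        model = HopfModel(a_vec, omega, float(g), C, beta=beta, dt=dt, tr=tr)
        try:
            # EC gradient-descent loop
            prev_diff = np.inf
            n_increases = 0
            for it in range(max_ec_iters):
                sim = simulate_hopf(
                    model, n_timepoints, int(ec_seeds[it] % (2**31)), transient_s
                )
                theta = instantaneous_phase(bandpass_filter(sim, band[0], band[1])).theta
                fc_sim = grand_average_phase_fc(theta).values
                diff = _mean_abs_offdiag(fe, fc_sim)
                if diff < ec_tolerance:
                    break
                if diff > prev_diff:
                    n_increases += 1
                    if n_increases >= 3:
                        warnings.warn(
                            f"EC loop not descending at G={g:g} "
                            f"(3 consecutive increases)", RuntimeWarning
                        )
                        n_increases = 0
                else:
                    n_increases = 0
                prev_diff = diff
                model.C = update_effective_connectivity(model.C, fe, fc_sim)
            # pooled simulated PMS from n_reps independent replicates
            x, diverged = simulate_hopf_ensemble(
                model, n_timepoints, n_reps,
                int(ec_seeds[-1] % (2**31)), transient_s,
                raise_on_divergence=False,
            )
            if diverged.all():
                raise IntegrationDivergedError(f"all replicates diverged at G={g:g}")
            sims = [
                BoldTimeSeries(x[r], tr, subject_id=f"rep{r}", condition="simulated")
                for r in range(n_reps)
                if not diverged[r]
            ]
            p_sim = simulated_pms_from_runs(sims, cents, band)
            kl_by_g[gi] = kl_distance(p_emp, p_sim)
            pms_by_g[gi] = p_sim
            ec_by_g[gi] = model.C
        except IntegrationDivergedError:
            warnings.warn(f"simulation diverged at G={g:g}; KL set to inf", RuntimeWarning)
            continue
    if not np.any(np.isfinite(kl_by_g)):
        raise FittingFailedError("every value of G on the grid diverged")
    best = int(np.argmin(kl_by_g))
    return FitResult(
        g_grid=g_grid,
        kl_by_g=kl_by_g,
        g_best=float(g_grid[best]),
        kl_best=float(kl_by_g[best]),
        n_reps=n_reps,
        ec_final=ec_by_g[best],
        pms_by_g=pms_by_g,
    )


def fit_global_coupling(
    p_emp: PMS,
    centroids: ClusterModel | np.ndarray,
    omega: np.ndarray,
    sc: np.ndarray,
    g_grid: np.ndarray | None = None,
    n_reps: int = 20,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Global-coupling sweep on the raw connectome (no EC optimization)."""
    return optimize_model(
        p_emp, centroids, omega, sc, fc_emp=None,
        g_grid=g_grid, n_reps=n_reps, seed=seed, max_ec_iters=0, **kwargs
    )
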