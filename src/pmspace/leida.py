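"""Leading-eigenvector dynamics analysis (LEiDA) of multivariate BOLD signals.

The model-free stage of the pipeline: band-pass filter parcellated BOLD time
series into the slow oscillatory band, extract instantaneous Hilbert phases,
build per-TR phase-coherence matrices ``dFC(t)[n, p] = cos(theta_n - theta_p)``,
reduce each matrix to its leading eigenvector, cluster the pooled eigenvectors
into a repertoire of metastable substates with K-means, and summarize each
condition by its probabilistic metastable substate (PMS) space — the occupancy
distribution over substates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.signal import butter, filtfilt, hilbert
from sklearn.cluster import KMeans

__all__ = [
    "BoldTimeSeries",
    "PhaseSeries",
    "PhaseCoherenceMatrix",
    "LeadingEigenvector",
    "EigenvectorPool",
    "ClusterModel",
    "PMS",
    "bandpass_filter",
    "instantaneous_phase",
    "phase_coherence",
    "leading_eigenvector",
    "leading_eigenvectors_from_phases",
    "pool_eigenvectors",
    "cluster_eigenvectors",
    "compute_pms",
    "select_k",
]


@dataclass
class BoldTimeSeries:
    """A parcels x time matrix of BOLD-like signal with its sampling interval.

    Parameters
    ----------
    data : ndarray, shape (n_parcels, n_timepoints)
        Signal values, arbitrary units.
    tr : float
        Sampling interval (repetition time) in seconds.
    subject_id, condition : str
        Identifiers carried through the pipeline.
    """

    data: np.ndarray
    tr: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be a 2-D (parcels x time) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 parcels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians in (-pi, pi]) per parcel per TR."""

    theta: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class PhaseCoherenceMatrix:
    """Per-TR phase coherence dFC(t): symmetric, unit diagonal, entries in [-1, 1]."""

    values: np.ndarray
    t: int = 0


@dataclass
class LeadingEigenvector:
    """Unit leading eigenvector of a phase-coherence matrix, sign-normalized."""

    v: np.ndarray
    t: int = 0
    subject_id: str = ""
    condition: str = ""


@dataclass
class EigenvectorPool:
    """Leading eigenvectors pooled across subjects and conditions.

    ``vectors`` is (n_observations, n_parcels); ``subjects``, ``conditions``
    and ``ts`` are parallel label arrays.
    """

    vectors: np.ndarray
    subjects: np.ndarray
    conditions: np.ndarray
    ts: np.ndarray

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ClusterModel:
    """K-means substate repertoire: centroids plus per-TR assignments.

    Centroids are ordered by descending pooled occupancy (ties broken by the
    index of first occurrence), and ``assignments`` is a DataFrame with
    columns subject, condition, t, cluster.
    """

    k: int
    centroids: np.ndarray
    assignments: pd.DataFrame
    seed: int = 0
    inertia: float = float("nan")

    def conditions(self) -> list:
        return list(pd.unique(self.assignments["condition"]))


@dataclass
class PMS:
    """Probabilistic metastable substate space: occupancy distribution over substates."""

    probabilities: np.ndarray
    condition: str = ""
    n_observations: int = 1
    kind: str = "empirical"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if self.n_observations < 1:
            raise ValueError("n_observations must be >= 1")
        self.probabilities = p

    @property
    def k(self) -> int:
        return len(self.probabilities)


# ---------------------------------------------------------------------------
# signal stage


def bandpass_filter(
    ts: BoldTimeSeries, low_hz: float = 0.04, high_hz: float = 0.07, order: int = 2
) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass of each parcel's demeaned signal.

    The default band 0.04-0.07 Hz isolates the slow oscillations the phase
    analysis is built on. A second-order Butterworth applied forward-backward
    (``filtfilt``) gives zero phase distortion so Hilbert phases are not biased.
    """
    nyquist = 0.5 / ts.tr
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, Nyquist={nyquist}) Hz"
        )
    b, a = butter(order, [low_hz / nyquist, high_hz / nyquist], btype="band")
    demeaned = ts.data - ts.data.mean(axis=1, keepdims=True)
    filtered = filtfilt(b, a, demeaned, axis=1)
    return BoldTimeSeries(filtered, ts.tr, ts.subject_id, ts.condition)


def _wrap_phase(theta: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi]."""
    theta = np.where(theta <= -np.pi, theta + 2 * np.pi, theta)
    return np.where(theta > np.pi, theta - 2 * np.pi, theta)


def instantaneous_phase(ts: BoldTimeSeries) -> PhaseSeries:
    """Phase of the analytic (Hilbert) signal per parcel per TR.

    Input is expected to be band-passed already. All-zero parcels have no
    defined phase; they are set to 0 with a warning.
    """
    data = ts.data
    zero_rows = np.all(data == 0.0, axis=1)
    theta = np.angle(hilbert(data, axis=1))
    if np.any(zero_rows):
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero parcel(s): phase undefined, set to 0",
            RuntimeWarning,
        )
        theta[zero_rows] = 0.0
    return PhaseSeries(_wrap_phase(theta), ts.subject_id, ts.condition)


def phase_coherence(theta_t: np.ndarray, t: int = 0) -> PhaseCoherenceMatrix:
    """Phase-coherence matrix at one TR: entry (n, p) = cos(theta_n - theta_p).

    Aligned parcels give 1, orthogonal (90 degree offset) give 0, anti-phase
    gives -1. The matrix is symmetric with unit diagonal by construction.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if theta_t.ndim != 1:
        raise ValueError("expected a 1-D phase vector for a single TR")
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("phases must be finite")
    m = np.cos(theta_t[:, None] - theta_t[None, :])
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return PhaseCoherenceMatrix(m, t=t)


# ---------------------------------------------------------------------------
# eigenvector stage


def _apply_sign_convention(v: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so that strictly more than half its entries are <= 0.

    If neither orientation has a strict majority of nonpositive entries (a
    tie), the orientation making the largest-magnitude entry negative is used.
    The convention is idempotent.
    """
    n = v.size
    keep_ok = 2 * int(np.sum(v <= 0.0)) > n
    flip_ok = 2 * int(np.sum(v >= 0.0)) > n
    if keep_ok and not flip_ok:
        return v
    if flip_ok and not keep_ok:
        return -v
    # tie (zeros can make both or neither orientation a strict majority):
    # force the largest-magnitude entry negative
    i = int(np.argmax(np.abs(v)))
    return v if v[i] <= 0 else -v


def leading_eigenvector(
    m: PhaseCoherenceMatrix | np.ndarray,
    t: int = 0,
    subject_id: str = "",
    condition: str = "",
    degeneracy_tol: float = 1e-10,
) -> LeadingEigenvector:
    """Unit eigenvector of the algebraically largest eigenvalue, sign-normalized.

    Uses a dense symmetric eigensolver. If the top eigenvalue is degenerate
    within ``degeneracy_tol`` the returned basis vector is still deterministic
    (LAPACK ordering) but a warning is emitted.
    """
    values = m.values if isinstance(m, PhaseCoherenceMatrix) else np.asarray(m, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("expected a symmetric matrix")
    n = values.shape[0]
    w, vecs = eigh(values, subset_by_index=[n - 2, n - 1])
    if w[1] - w[0] < degeneracy_tol:
        warnings.warn(
            "leading eigenvalue is degenerate; picking a deterministic basis vector",
            RuntimeWarning,
        )
    v = vecs[:, -1]
    v = v / np.linalg.norm(v)
    return LeadingEigenvector(_apply_sign_convention(v), t, subject_id, condition)


def leading_eigenvectors_from_phases(theta: np.ndarray) -> np.ndarray:
    """Leading eigenvectors of all per-TR phase-coherence matrices of a phase series.

    Exploits the exact rank-2 structure dFC(t) = c c^T + s s^T with
    c = cos(theta_t), s = sin(theta_t): the leading eigenvector lies in
    span{c, s} and its coefficients solve a 2x2 symmetric eigenproblem in the
    (c, s) coefficient basis. Returns an array of shape (T, N), each row a
    unit vector under the package's sign convention. Equivalent to calling
    :func:`leading_eigenvector` per TR, but O(N) per TR instead of O(N^3).
    """
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta)  # (N, T)
    s = np.sin(theta)
    a = np.sum(c * c, axis=0)  # (T,)
    b = np.sum(c * s, axis=0)
    d = np.sum(s * s, axis=0)
    lam = 0.5 * ((a + d) + np.sqrt((a - d) ** 2 + 4.0 * b * b))
    # eigenvector of [[a, b], [b, d]] for eigenvalue lam; pick the numerically
    # safer of the two equivalent forms per TR
    alpha1, beta1 = lam - d, b
    alpha2, beta2 = b, lam - a
    use1 = np.abs(lam - d) >= np.abs(lam - a)
    alpha = np.where(use1, alpha1, alpha2)
    beta = np.where(use1, beta1, beta2)
    norm_ab = np.hypot(alpha, beta)
    degenerate = norm_ab < 1e-12
    alpha = np.where(degenerate, 1.0, alpha)
    beta = np.where(degenerate, 0.0, beta)
    v = c * alpha[None, :] + s * beta[None, :]  # (N, T)
    v = v / np.linalg.norm(v, axis=0, keepdims=True)
    out = v.T.copy()
    for i in range(out.shape[0]):
        out[i] = _apply_sign_convention(out[i])
    return out


def pool_eigenvectors(
    phase_series: Sequence[PhaseSeries], edge_trim: int = 0
) -> EigenvectorPool:
    """Compute and pool leading eigenvectors across subjects and conditions.

    ``edge_trim`` drops that many TRs at each end of every series before
    pooling (Hilbert edge distortion); the default 0 keeps every TR so the
    pooled count equals subjects x TRs x conditions exactly.
    """
    vecs, subs, conds, ts = [], [], [], []
    for ps in phase_series:
        v = leading_eigenvectors_from_phases(ps.theta)
        t_idx = np.arange(v.shape[0])
        if edge_trim > 0:
            v = v[edge_trim:-edge_trim]
            t_idx = t_idx[edge_trim:-edge_trim]
        vecs.append(v)
        subs.append(np.repeat(ps.subject_id, v.shape[0]))
        conds.append(np.repeat(ps.condition, v.shape[0]))
        ts.append(t_idx)
    return EigenvectorPool(
        np.concatenate(vecs, axis=0),
        np.concatenate(subs),
        np.concatenate(conds),
        np.concatenate(ts),
    )


# ---------------------------------------------------------------------------
# clustering stage


def cluster_eigenvectors(
    pool: EigenvectorPool, k: int, seed: int = 0, n_replicates: int = 50
) -> ClusterModel:
    """K-means substate repertoire from pooled leading eigenvectors.

    Euclidean K-means with k-means++ initialization and ``n_replicates``
    restarts; the best-inertia solution is kept. Centroids are reordered by
    descending pooled occupancy so substate 0 is always the most visited.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = np.unique(pool.vectors, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct vectors ({n_distinct})")
    if len(pool) < 10 * k:
        raise ValueError(f"need at least 10*k={10 * k} vectors, got {len(pool)}")
    km = KMeans(n_clusters=k, n_init=n_replicates, random_state=seed)
    raw_labels = km.fit_predict(pool.vectors)
    counts = np.bincount(raw_labels, minlength=k)
    # descending occupancy; ties by first occurrence in the pooled stream
    first_seen = np.full(k, len(raw_labels))
    for idx, lab in enumerate(raw_labels):
        if first_seen[lab] == len(raw_labels):
            first_seen[lab] = idx
    order = sorted(range(k), key=lambda j: (-counts[j], first_seen[j]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    assignments = pd.DataFrame(
        {
            "subject": pool.subjects,
            "condition": pool.conditions,
            "t": pool.ts,
            "cluster": remap[raw_labels],
        }
    )
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_[order],
        assignments=assignments,
        seed=seed,
        inertia=float(km.inertia_),
    )


def compute_pms(model: ClusterModel, condition: str) -> PMS:
    """Occupancy distribution over substates for one condition."""
    sel = model.assignments[model.assignments["condition"] == condition]
    if sel.empty:
        raise ValueError(f"condition {condition!r} absent from assignments")
    counts = np.bincount(sel["cluster"].to_numpy(), minlength=model.k)
    return PMS(counts / counts.sum(), condition=condition, n_observations=len(sel))


def select_k(
    pvalues_by_k: Mapping[int, np.ndarray], alpha: float = 0.05
) -> int:
    """Choose the number of substates from per-k FDR-corrected p-values.

    Scores each k by the fraction of substates whose corrected p-value falls
    below ``alpha`` and returns the smallest k attaining the maximal score.
    If no substate is significant at any k, the smallest k is returned with a
    warning.
    """
    if not pvalues_by_k:
        raise ValueError("empty results")
    scores = {
        k: float(np.sum(np.asarray(p) < alpha)) / k for k, p in pvalues_by_k.items()
    }
    best = max(scores.values())
    if best == 0.0:
        warnings.warn("no significant substate at any k; returning the smallest k",
                      RuntimeWarning)
    return min(k for k, s in scores.items() if s == best)
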