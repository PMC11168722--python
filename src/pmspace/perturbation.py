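"""In-silico unilateral perturbation of a fitted Hopf whole-brain model.

One node at a time, the local bifurcation parameter is shifted away from its
working point (-0.02) — positively toward self-sustained oscillation
(synchronization protocol, up to 0.18) or negatively toward a noise-dominated
fixed point (noise protocol, down to -0.22) — while all other nodes stay
fixed. Each perturbed model is simulated, its PMS computed against the
empirical substate centroids, and scored by the symmetrized KL distance to a
target condition's empirical PMS. Low KL marks nodes and intensities that
force a transition toward the target state.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hopf import (
    HopfModel,
    assign_to_centroids,
    kl_distance,
    simulate_hopf_ensemble,
    _eigenvectors_of_sim,
)
from .leida import PMS, BoldTimeSeries, ClusterModel

__all__ = [
    "Protocol",
    "synchronization_protocol",
    "noise_protocol",
    "PerturbationGrid",
    "TransitionResult",
    "NoTransitionError",
    "perturb_node",
    "run_protocol",
    "optimal_transition",
    "summarize_top_nodes",
]

BASELINE_A = -0.02


class NoTransitionError(RuntimeError):
    """Raised when every grid cell diverged and no transition can be ranked."""


@dataclass
class Protocol:
    """An ordered sweep of bifurcation values, starting at the working point."""

    name: str
    a_values: np.ndarray

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        if abs(self.a_values[0] - BASELINE_A) > 1e-12:
            raise ValueError("the first value must be the unperturbed baseline")

    @property
    def n_intensities(self) -> int:
        return self.a_values.size


def synchronization_protocol() -> Protocol:
    """a shifted from -0.02 up to 0.18 in steps of 0.01 (21 values, ascending)."""
    return Protocol("synchronization", np.round(np.linspace(-0.02, 0.18, 21), 10))


def noise_protocol() -> Protocol:
    """a shifted from -0.02 down to -0.22 in steps of 0.01 (21 values, descending)."""
    return Protocol("noise", np.round(np.linspace(-0.02, -0.22, 21), 10))


@dataclass
class PerturbationGrid:
    """KL distance to the target PMS for every (node, intensity) cell."""

    kl: np.ndarray
    protocol: Protocol
    nodes: np.ndarray
    n_reps: int
    source_state: str = ""
    target_state: str = ""
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, node in enumerate(self.nodes):
            for j, a in enumerate(self.protocol.a_values):
                rows.append(
                    {"node": int(node), "a_value": float(a), "kl": float(self.kl[i, j])}
                )
        return pd.DataFrame(rows)


@dataclass
class TransitionResult:
    """Optimal perturbation and full per-node ranking for one protocol sweep."""

    best_node: int
    best_a: float
    best_kl: float
    ranking: np.ndarray
    baseline_kl: float
    protocol_name: str = ""
    node_min_kl: np.ndarray | None = None
    node_best_a: np.ndarray | None = None


def perturb_node(model: HopfModel, node: int, a_value: float) -> HopfModel:
    """Copy of the model with one node's bifurcation parameter replaced."""
    if not (0 <= node < model.n_nodes):
        raise ValueError(f"node {node} out of range [0, {model.n_nodes})")
    out = copy.deepcopy(model)
    out.a = out.a.copy()
    out.a[node] = a_value
    return out


def run_protocol(
    model: HopfModel,
    protocol: Protocol,
    target_pms: PMS,
    centroids: ClusterModel | np.ndarray,
    n_reps: int = 3,
    seed: int = 0,
    nodes: np.ndarray | None = None,
    n_timepoints: int = 350,
    transient_s: float = 300.0,
    band: tuple[float, float] = (0.04, 0.07),
    source_state: str = "",
    target_state: str = "",
) -> PerturbationGrid:
    """Sweep every node and intensity of a protocol; KL to the target per cell.

    For each node all intensities x repetitions are integrated in one
    vectorized ensemble call (the bifurcation vector varies per replicate);
    the repetitions' eigenvector assignments are pooled into one perturbed PMS
    per cell. Diverged cells are recorded as KL = +inf and the sweep
    continues. Deterministic for a fixed seed.
    """
    cents = centroids.centroids if isinstance(centroids, ClusterModel) else np.asarray(centroids)
    if cents.shape[0] != target_pms.k:
        raise ValueError("target PMS and centroids disagree on the number of substates")
    if cents.shape[1] != model.n_nodes:
        raise ValueError("centroids do not match the model's parcel count")
    if nodes is None:
        nodes = np.arange(model.n_nodes)
    nodes = np.asarray(nodes, dtype=int)
    n_int = protocol.n_intensities
    kl = np.full((nodes.size, n_int), np.inf)
    root = np.random.SeedSequence(seed)
    for i, node in enumerate(nodes):
        # replicate layout: intensity-major, repetitions within intensity
        a_cols = np.tile(model.a[:, None], (1, n_int * n_reps))
        for j, a_val in enumerate(protocol.a_values):
            a_cols[node, j * n_reps : (j + 1) * n_reps] = a_val
        node_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(int(node),)).generate_state(1)[0]
            % (2**31)
        )
        x, diverged = simulate_hopf_ensemble(
            model,
            n_timepoints,
            n_int * n_reps,
            node_seed,
            transient_s,
            a=a_cols,
            raise_on_divergence=False,
        )
        for j in range(n_int):
            cols = range(j * n_reps, (j + 1) * n_reps)
            good = [c for c in cols if not diverged[c]]
            if not good:
                continue  # KL stays +inf for this cell
            counts = np.zeros(cents.shape[0])
            n_obs = 0
            for c in good:
                sim = BoldTimeSeries(x[c], model.tr, subject_id=f"node{node}",
                                     condition="perturbed")
                labels = assign_to_centroids(_eigenvectors_of_sim(sim, band), cents)
                counts += np.bincount(labels, minlength=cents.shape[0])
                n_obs += labels.size
            p_pert = PMS(counts / counts.sum(), condition="perturbed",
                         n_observations=n_obs, kind="perturbed")
            kl[i, j] = kl_distance(p_pert, target_pms)
    if np.isinf(kl).any():
        warnings.warn(
            f"{int(np.isinf(kl).sum())} diverged cell(s) recorded as KL=+inf",
            RuntimeWarning,
        )
    return PerturbationGrid(
        kl=kl,
        protocol=protocol,
        nodes=nodes,
        n_reps=n_reps,
        source_state=source_state,
        target_state=target_state,
        seed=seed,
    )


def optimal_transition(grid: PerturbationGrid) -> TransitionResult:
    """Global argmin over the grid plus a per-node ranking by minimum KL.

    Ties go to the lower node index, then to the intensity closest to the
    unperturbed baseline. The baseline KL is the mean of the first grid
    column (every node's first intensity is the unperturbed model).
    """
    kl = grid.kl
    if kl.size == 0:
        raise ValueError("empty grid")
    if not np.isfinite(kl).any():
        raise NoTransitionError("every grid cell diverged")
    a_vals = grid.protocol.a_values
    dist_to_baseline = np.abs(a_vals - BASELINE_A)
    node_min = kl.min(axis=1)
    node_best_j = np.empty(kl.shape[0], dtype=int)
    for i in range(kl.shape[0]):
        js = np.flatnonzero(kl[i] == node_min[i])
        node_best_j[i] = js[np.argmin(dist_to_baseline[js])]
    order = np.argsort(node_min, kind="stable")  # stable sort: lower index wins ties
    best_i = int(order[0])
    baseline_col = kl[:, 0]
    baseline_kl = float(np.mean(baseline_col[np.isfinite(baseline_col)]))
    return TransitionResult(
        best_node=int(grid.nodes[best_i]),
        best_a=float(a_vals[node_best_j[best_i]]),
        best_kl=float(node_min[best_i]),
        ranking=grid.nodes[order],
        baseline_kl=baseline_kl,
        protocol_name=grid.protocol.name,
        node_min_kl=node_min,
        node_best_a=a_vals[node_best_j],
    )


def summarize_top_nodes(
    result: TransitionResult,
    grid: PerturbationGrid,
    labels: pd.DataFrame,
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Annotate the best ``top_n`` nodes with names and networks.

    Returns the table (node, name, network, min KL, optimal a, rank) and the
    frequency of each network among those nodes.
    """
    n_nodes = grid.nodes.size
    if top_n > n_nodes:
        warnings.warn(
            f"top_n={top_n} exceeds the {n_nodes} swept nodes; truncating",
            RuntimeWarning,
        )
        top_n = n_nodes
    by_node = {int(n): i for i, n in enumerate(grid.nodes)}
    lab = labels.set_index("index")
    rows = []
    for rank, node in enumerate(result.ranking[:top_n]):
        i = by_node[int(node)]
        rows.append(
            {
                "rank": rank + 1,
                "node": int(node),
                "name": lab.loc[int(node), "name"],
                "network": lab.loc[int(node), "network"],
                "min_kl": float(result.node_min_kl[i]),
                "optimal_a": float(result.node_best_a[i]),
            }
        )
    table = pd.DataFrame(rows)
    counts = table["network"].value_counts()
    return table, counts
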