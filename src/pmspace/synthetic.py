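"""Synthetic connectomes, parcel tables and two-condition BOLD ensembles.

Ground-truth data for every downstream stage: a block-modular connectome
standing in for a tractography-derived structural matrix, a parcel label table
mimicking a 100-cortical + 16-subcortical parcellation, and BOLD ensembles
generated by the coupled Hopf model itself, so the generating global coupling
and bifurcation parameters are known exactly and parameter-recovery tests are
well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hopf import HopfModel, simulate_hopf
from .leida import BoldTimeSeries

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "recovery_scenario",
    "null_scenario",
    "make_structural_connectivity",
    "symmetrize_and_normalize_sc",
    "make_parcel_labels",
    "make_two_condition_dataset",
    "subject_frequencies",
]

#: canonical cortical resting-state network names (seven-network scheme)
CORTICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "Salience",
    "Limbic",
    "Control",
    "Default",
)

#: subcortical structure names, one set per hemisphere (16 total)
SUBCORTICAL_STRUCTURES = (
    "Hippocampus",
    "Amygdala",
    "ThalamusAnterior",
    "ThalamusPosterior",
    "NucleusAccumbens",
    "GlobusPallidus",
    "Putamen",
    "Caudate",
)


@dataclass
class SyntheticScenario:
    """Study conditions for a synthetic two-condition experiment.

    Defaults emulate the target study dimensions: 116 parcels, 20 subjects,
    two conditions of 350 TRs at TR = 2 s, oscillations in 0.04-0.07 Hz.
    The condition contrast is induced by global coupling: a rest-like
    condition at G = 0.04 and a meditation-like condition at G = 0.09
    (both inside the fitted sweep range 0-0.3).
    """

    n_parcels: int = 116
    n_subjects: int = 20
    n_timepoints: int = 350
    tr: float = 2.0
    sc_seed: int = 11
    sim_seed: int = 23
    g_true_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"rest": 0.04, "meditation": 0.09}
    )
    a_offsets_by_condition: Mapping[str, np.ndarray | float] = field(
        default_factory=dict
    )
    a_baseline: float = -0.02
    beta: float = 0.01
    dt: float = 0.1
    transient_s: float = 300.0
    freq_range: tuple[float, float] = (0.04, 0.07)

    def __post_init__(self) -> None:
        if self.n_parcels < 2:
            raise ValueError("n_parcels must be >= 2")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(self.g_true_by_condition)


def default_scenario(**overrides) -> SyntheticScenario:
    """The packaged two-condition scenario (rest-like vs meditation-like)."""
    return SyntheticScenario(**overrides)


def recovery_scenario(g_true: float = 0.05, **overrides) -> SyntheticScenario:
    """Single-condition scenario generated at a known coupling, for parameter recovery."""
    overrides.setdefault("g_true_by_condition", {"rest": g_true})
    return SyntheticScenario(**overrides)


def null_scenario(g: float = 0.04, **overrides) -> SyntheticScenario:
    """Both conditions generated with identical parameters (calibration runs)."""
    overrides.setdefault("g_true_by_condition", {"rest": g, "meditation": g})
    return SyntheticScenario(**overrides)


def make_structural_connectivity(
    n_parcels: int,
    seed: int = 0,
    n_modules: int = 4,
    intra_weight: float = 0.1,
    inter_weight: float = 0.02,
    core_fraction: float = 0.2,
    core_weight: float = 1.0,
    jitter_sigma: float = 0.5,
    target_max: float = 0.2,
) -> np.ndarray:
    """Block-modular random connectome with a rich-club core and heavy-tailed weights.

    Parcels are split into ``n_modules`` contiguous blocks; within-block edges
    get ``intra_weight`` and between-block edges ``inter_weight``. A fraction
    ``core_fraction`` of parcels, spread evenly across blocks, forms a densely
    interconnected rich-club core whose mutual edges get ``core_weight`` —
    mirroring the hub core of tractography connectomes. Every edge is
    multiplied by lognormal jitter (sigma ``jitter_sigma``; 0 disables it,
    resembling the heavy tail of streamline counts). The result is
    symmetrized, zero-diagonal, and rescaled so its maximum entry equals
    ``target_max``. Deterministic for a fixed seed.

    The hub core concentrates the network's spectral radius in few nodes, so
    the coupled model synchronizes through the core as G grows while most
    parcels keep a low coupling load — their noise-driven oscillations stay
    narrow-band, inside the analysis band.
    """
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if intra_weight < 0 or inter_weight < 0 or core_weight < 0:
        raise ValueError("weights must be nonnegative")
    if intra_weight < inter_weight:
        raise ValueError("intra_weight must be >= inter_weight")
    if not (0.0 <= core_fraction <= 1.0):
        raise ValueError("core_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    module = (np.arange(n_parcels) * n_modules) // n_parcels
    same = module[:, None] == module[None, :]
    base = np.where(same, intra_weight, inter_weight).astype(float)
    n_core = int(round(core_fraction * n_parcels))
    if n_core >= 2:
        core_idx = np.linspace(0, n_parcels - 1, n_core).astype(int)
        is_core = np.zeros(n_parcels, dtype=bool)
        is_core[core_idx] = True
        base[np.outer(is_core, is_core)] = core_weight
    if jitter_sigma > 0:
        jitter = rng.lognormal(mean=0.0, sigma=jitter_sigma, size=(n_parcels, n_parcels))
        base = base * jitter
    np.fill_diagonal(base, 0.0)
    return symmetrize_and_normalize_sc(base, target_max=target_max)


def symmetrize_and_normalize_sc(
    sc_raw: np.ndarray, target_max: float = 0.2
) -> np.ndarray:
    """Average a connectivity matrix with its transpose and rescale its maximum.

    Tractography counts are not direction-resolved, so the matrix is
    symmetrized as (M + M^T)/2; the off-diagonal maximum is then rescaled to
    ``target_max`` (0.2 by convention, the scale at which the coupled model is
    fitted). A zero matrix passes through unchanged.
    """
    m = np.asarray(sc_raw, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("entries must be finite")
    if np.any(m < 0):
        raise ValueError("entries must be nonnegative")
    out = 0.5 * (m + m.T)
    np.fill_diagonal(out, 0.0)
    peak = out.max()
    if peak > 0:
        out = out * (target_max / peak)
    return out


def make_parcel_labels(n_cortical: int = 100, n_subcortical: int = 16) -> pd.DataFrame:
    """Parcel label table: index, name, hemisphere, network.

    Cortical parcels are split evenly between hemispheres and assigned
    round-robin to the seven canonical resting-state networks; subcortical
    parcels cycle through a fixed set of structures per hemisphere.
    """
    if n_cortical < 0 or n_subcortical < 0:
        raise ValueError("counts must be >= 0")
    rows = []
    idx = 0
    per_hemi = [n_cortical - n_cortical // 2, n_cortical // 2]
    for hemi, count in zip(("LH", "RH"), per_hemi):
        seg_counter: dict[str, int] = {}
        for i in range(count):
            net = CORTICAL_NETWORKS[(i * len(CORTICAL_NETWORKS)) // count]
            seg_counter[net] = seg_counter.get(net, 0) + 1
            rows.append(
                {
                    "index": idx,
                    "name": f"{hemi}-{net}-{seg_counter[net]}",
                    "hemisphere": hemi,
                    "network": net,
                }
            )
            idx += 1
    for j in range(n_subcortical):
        hemi = "LH" if j < (n_subcortical + 1) // 2 else "RH"
        struct = SUBCORTICAL_STRUCTURES[j % len(SUBCORTICAL_STRUCTURES)]
        rows.append(
            {
                "index": idx,
                "name": f"{hemi}-{struct}",
                "hemisphere": hemi,
                "network": "Subcortical",
            }
        )
        idx += 1
    return pd.DataFrame(rows, columns=["index", "name", "hemisphere", "network"])


def subject_seed(sim_seed: int, condition_index: int, subject_index: int) -> int:
    """Deterministic, independent per-subject noise streams."""
    return sim_seed + 1000 * condition_index + subject_index


def subject_frequencies(scenario: SyntheticScenario) -> dict[int, np.ndarray]:
    """Ground-truth node angular frequencies per subject (shared across conditions)."""
    rng = np.random.default_rng(scenario.sim_seed)
    lo, hi = scenario.freq_range
    return {
        s: 2.0 * np.pi * rng.uniform(lo, hi, size=scenario.n_parcels)
        for s in range(scenario.n_subjects)
    }


def make_two_condition_dataset(
    scenario: SyntheticScenario, sc: np.ndarray
) -> dict[tuple[str, str], BoldTimeSeries]:
    """BOLD ensemble keyed by (subject_id, condition), generated by the Hopf model.

    Each subject gets node frequencies drawn uniformly in ``freq_range``
    (shared across conditions, as intrinsic frequencies are a subject trait);
    each (subject, condition) run uses the condition's global coupling and
    bifurcation offsets with a deterministic per-subject seed.
    """
    sc = np.asarray(sc, dtype=float)
    if sc.shape != (scenario.n_parcels, scenario.n_parcels):
        raise ValueError("sc shape does not match scenario.n_parcels")
    omega_by_subject = subject_frequencies(scenario)
    out: dict[tuple[str, str], BoldTimeSeries] = {}
    for ci, cond in enumerate(scenario.conditions):
        g = scenario.g_true_by_condition[cond]
        offset = np.asarray(
            scenario.a_offsets_by_condition.get(cond, 0.0), dtype=float
        )
        a = scenario.a_baseline + np.broadcast_to(offset, (scenario.n_parcels,))
        for s in range(scenario.n_subjects):
            sid = f"sub{s:02d}"
            model = HopfModel(
                a=a,
                omega=omega_by_subject[s],
                G=g,
                C=sc,
                beta=scenario.beta,
                dt=scenario.dt,
                tr=scenario.tr,
            )
            out[(sid, cond)] = simulate_hopf(
                model,
                scenario.n_timepoints,
                seed=subject_seed(scenario.sim_seed, ci, s),
                transient_s=scenario.transient_s,
                subject_id=sid,
                condition=cond,
            )
    return out
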