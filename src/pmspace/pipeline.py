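"""End-to-end orchestration of the model-free and model-based stages.

Ties the generator, LEiDA, statistics, Hopf fitting and perturbation modules
into reproducible runs: every stage takes a :class:`RunConfig`, logs its
parameters, and writes its artifacts plus a JSON manifest recording seeds and
a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .hopf import (
    FitResult,
    HopfModel,
    estimate_node_frequencies,
    grand_average_phase_fc,
    optimize_model,
)
from .leida import (
    PMS,
    BoldTimeSeries,
    ClusterModel,
    bandpass_filter,
    cluster_eigenvectors,
    compute_pms,
    instantaneous_phase,
    pool_eigenvectors,
    select_k,
)
from .perturbation import (
    PerturbationGrid,
    TransitionResult,
    noise_protocol,
    optimal_transition,
    run_protocol,
    summarize_top_nodes,
    synchronization_protocol,
)
from .stats import SubstateTestResult, condition_contrast

logger = logging.getLogger("pmspace")

__all__ = ["RunConfig", "ModelFreeResult", "run_model_free", "run_model_based",
           "run_perturbation"]


@dataclass
class RunConfig:
    """All tunables of the pipeline, with study defaults.

    The ``paper`` preset keeps the study-scale settings (k from 2 to 8,
    coupling grid 0-0.3, 200 fitting repetitions, all nodes perturbed); the
    ``desk`` preset reduces repetition counts and grid sizes for a single
    workstation run without changing any formula.
    """

    # band and clustering
    band: tuple[float, float] = (0.04, 0.07)
    k_min: int = 2
    k_max: int = 8
    kmeans_replicates: int = 50
    leida_seed: int = 0
    edge_trim: int = 0
    # model
    a_baseline: float = -0.02
    beta: float = 0.01
    dt: float = 0.1
    tr: float = 2.0
    g_grid_max: float = 0.3
    g_grid_step: float = 0.01
    fit_n_reps: int = 200
    ec_tolerance: float = 0.001
    ec_epsilon: float = 0.01
    max_ec_iters: int = 300
    fit_seed: int = 0
    n_timepoints_sim: int = 350
    transient_s: float = 300.0
    # perturbation
    perturb_n_reps: int = 3
    perturb_seed: int = 0
    perturb_nodes: Sequence[int] | None = None
    protocols: tuple[str, ...] = ("synchronization", "noise")
    # stats
    n_perm: int = 1000
    alpha: float = 0.05
    stats_seed: int = 0
    paired: bool = False
    scale: str = "paper"

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Reduced-scale preset: smaller grids and repetition counts only."""
        defaults = dict(
            k_min=2,
            k_max=4,
            kmeans_replicates=10,
            g_grid_max=0.15,
            fit_n_reps=20,
            max_ec_iters=3,
            n_perm=500,
            scale="desk",
        )
        defaults.update(overrides)
        return cls(**defaults)

    def g_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.g_grid_max + 1e-9, self.g_grid_step), 10)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, (tuple, list)) else v)
             for k, v in asdict(self).items() if v is not None},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModelFreeResult:
    """Everything the model-free stage produces across the k range."""

    models_by_k: dict[int, ClusterModel]
    pms_by_k: dict[int, dict[str, PMS]]
    tests_by_k: dict[int, SubstateTestResult]
    chosen_k: int
    n_eigenvectors_pooled: int
    phases_by_key: dict = field(default_factory=dict)


def run_model_free(
    dataset: Mapping[tuple[str, str], BoldTimeSeries],
    config: RunConfig,
    outdir: str | Path | None = None,
) -> ModelFreeResult:
    """Filter, phase, eigenvector, cluster (k range), PMS, contrast, select k."""
    conditions = sorted({cond for _, cond in dataset})
    if len(conditions) < 2:
        raise ValueError(
            "the model-free contrast needs at least 2 conditions; "
            f"got {conditions!r}"
        )
    logger.info("model-free stage: %d series, conditions %s", len(dataset), conditions)
    phase_series = []
    phases_by_key = {}
    for (subject, cond), ts in sorted(dataset.items()):
        ps = instantaneous_phase(bandpass_filter(ts, *config.band))
        phase_series.append(ps)
        phases_by_key[(subject, cond)] = ps
    pool = pool_eigenvectors(phase_series, edge_trim=config.edge_trim)
    logger.info("pooled %d leading eigenvectors", len(pool))

    models_by_k: dict[int, ClusterModel] = {}
    pms_by_k: dict[int, dict[str, PMS]] = {}
    tests_by_k: dict[int, SubstateTestResult] = {}
    for k in range(config.k_min, config.k_max + 1):
        model = cluster_eigenvectors(
            pool, k, seed=config.leida_seed, n_replicates=config.kmeans_replicates
        )
        models_by_k[k] = model
        pms_by_k[k] = {c: compute_pms(model, c) for c in conditions}
        tests_by_k[k] = condition_contrast(
            model,
            conditions[0],
            conditions[1],
            n_perm=config.n_perm,
            seed=config.stats_seed,
            alpha=config.alpha,
            paired=config.paired,
        )
    chosen = select_k(
        {k: t.p_fdr for k, t in tests_by_k.items()}, alpha=config.alpha
    )
    logger.info("selected k = %d", chosen)
    result = ModelFreeResult(
        models_by_k, pms_by_k, tests_by_k, chosen, len(pool), phases_by_key
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, model in models_by_k.items():
            pio.write_centroids(outdir / f"centroids_k{k}.csv", model)
            pio.write_assignments(outdir / f"assignments_k{k}.csv", model)
            pio.write_pms(outdir / f"pms_k{k}.csv", pms_by_k[k].values())
            tests_by_k[k].to_frame().to_csv(outdir / f"stats_k{k}.csv", index=False)
        pio.write_manifest(
            outdir / "model_free_manifest.json",
            {
                "config_hash": config.config_hash(),
                "seeds": {"leida": config.leida_seed, "stats": config.stats_seed},
                "n_eigenvectors_pooled": len(pool),
                "n_series": len(dataset),
                "conditions": conditions,
                "chosen_k": chosen,
            },
        )
    return result


def run_model_based(
    dataset: Mapping[tuple[str, str], BoldTimeSeries],
    model_free: ModelFreeResult,
    sc: np.ndarray,
    config: RunConfig,
    outdir: str | Path | None = None,
    k: int | None = None,
) -> dict[str, FitResult]:
    """Per condition: node frequencies, coupling sweep with EC optimization."""
    k = model_free.chosen_k if k is None else k
    centroids = model_free.models_by_k[k]
    conditions = sorted({cond for _, cond in dataset})
    fits: dict[str, FitResult] = {}
    for cond in conditions:
        series = [ts for (s, c), ts in sorted(dataset.items()) if c == cond]
        filtered = [bandpass_filter(ts, *config.band) for ts in series]
        omega = estimate_node_frequencies(filtered, band=config.band)
        fc_stack = [
            grand_average_phase_fc(instantaneous_phase(f).theta).values
            for f in filtered
        ]
        fc_emp = np.mean(fc_stack, axis=0)
        p_emp = model_free.pms_by_k[k][cond]
        logger.info("fitting condition %r (k=%d)", cond, k)
        fits[cond] = optimize_model(
            p_emp,
            centroids,
            omega,
            sc,
            fc_emp=fc_emp,
            g_grid=config.g_grid(),
            n_reps=config.fit_n_reps,
            seed=config.fit_seed,
            ec_tolerance=config.ec_tolerance,
            max_ec_iters=config.max_ec_iters,
            a_baseline=config.a_baseline,
            beta=config.beta,
            dt=config.dt,
            tr=config.tr,
            n_timepoints=config.n_timepoints_sim,
            transient_s=config.transient_s,
            band=config.band,
        )
        logger.info(
            "condition %r: G_best=%.3f KL_best=%.4f", cond,
            fits[cond].g_best, fits[cond].kl_best,
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, fit in fits.items():
            pd.DataFrame({"G": fit.g_grid, "KL": fit.kl_by_g}).to_csv(
                outdir / f"fit_{cond}.csv", index=False
            )
            if fit.ec_final is not None:
                pio.write_matrix_tsv(outdir / f"ec_{cond}.tsv", fit.ec_final)
        pio.write_manifest(
            outdir / "model_based_manifest.json",
            {
                "config_hash": config.config_hash(),
                "seeds": {"fit": config.fit_seed},
                "k": k,
                "g_best": {c: f.g_best for c, f in fits.items()},
                "kl_best": {c: f.kl_best for c, f in fits.items()},
            },
        )
    return fits


def run_perturbation(
    fitted_source: HopfModel,
    target_pms: PMS,
    centroids: ClusterModel | np.ndarray,
    config: RunConfig,
    labels: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    source_state: str = "source",
    target_state: str = "target",
) -> dict[str, tuple[PerturbationGrid, TransitionResult]]:
    """Sweep the configured protocols on a fitted source model."""
    available = {
        "synchronization": synchronization_protocol,
        "noise": noise_protocol,
    }
    results: dict[str, tuple[PerturbationGrid, TransitionResult]] = {}
    for name in config.protocols:
        protocol = available[name]()
        logger.info("perturbation protocol %r (%s -> %s)", name, source_state, target_state)
        grid = run_protocol(
            fitted_source,
            protocol,
            target_pms,
            centroids,
            n_reps=config.perturb_n_reps,
            seed=config.perturb_seed,
            nodes=None if config.perturb_nodes is None else np.asarray(config.perturb_nodes),
            n_timepoints=config.n_timepoints_sim,
            transient_s=config.transient_s,
            band=config.band,
            source_state=source_state,
            target_state=target_state,
        )
        transition = optimal_transition(grid)
        results[name] = (grid, transition)
        logger.info(
            "protocol %r: best node %d at a=%.2f (KL %.4f, baseline %.4f)",
            name, transition.best_node, transition.best_a,
            transition.best_kl, transition.baseline_kl,
        )
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            grid.to_frame().to_csv(
                outdir / f"grid_{source_state}_to_{target_state}_{name}.csv", index=False
            )
            pio.write_manifest(
                outdir / f"transition_{source_state}_to_{target_state}_{name}.json",
                {
                    "best_node": transition.best_node,
                    "best_a": transition.best_a,
                    "best_kl": transition.best_kl,
                    "baseline_kl": transition.baseline_kl,
                    "ranking": transition.ranking,
                    "seed": config.perturb_seed,
                },
            )
            if labels is not None:
                table, _ = summarize_top_nodes(transition, grid, labels)
                table.to_csv(
                    outdir / f"top_nodes_{source_state}_to_{target_state}_{name}.csv",
                    index=False,
                )
    return results
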