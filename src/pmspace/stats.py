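"""Condition contrasts on substate probabilities.

Group differences in substate occupancy are assessed with permutation tests
built on Wilcoxon statistics — the rank-sum statistic with random group
relabelings for independent groups, or the signed-rank statistic with random
sign flips for paired designs — followed by Benjamini-Hochberg FDR correction
across substates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .leida import PMS, ClusterModel

__all__ = [
    "SubstateTestResult",
    "subject_level_pms",
    "permutation_wilcoxon",
    "fdr_correct",
    "condition_contrast",
]


@dataclass
class SubstateTestResult:
    """Per-substate permutation test outcome with FDR mask."""

    k: int
    statistic: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    p_fdr_mask: np.ndarray
    n_permutations: int
    seed: int
    alpha: float = 0.05
    paired: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substate": np.arange(self.k),
                "statistic": self.statistic,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_fdr,
                "significant_fdr": self.p_fdr_mask,
            }
        )


def subject_level_pms(model: ClusterModel, condition: str) -> dict[str, PMS]:
    """One substate-occupancy vector per subject for a condition.

    The TR-count-weighted average of the subject vectors reproduces the
    pooled condition PMS exactly.
    """
    sel = model.assignments[model.assignments["condition"] == condition]
    if sel.empty:
        raise ValueError(f"condition {condition!r} absent from assignments")
    out: dict[str, PMS] = {}
    for subject, grp in sel.groupby("subject", sort=True):
        counts = np.bincount(grp["cluster"].to_numpy(), minlength=model.k)
        if counts.sum() == 0:
            raise ValueError(f"subject {subject!r} has no TRs in {condition!r}")
        out[str(subject)] = PMS(
            counts / counts.sum(), condition=condition, n_observations=len(grp)
        )
    return out


def _ranksum_statistics(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rank-sum of group a per column, centered at its null expectation."""
    na = a.shape[0]
    pooled = np.vstack([a, b])
    ranks = np.apply_along_axis(rankdata, 0, pooled)
    w = ranks[:na].sum(axis=0)
    expected = na * (pooled.shape[0] + 1) / 2.0
    return w - expected


def _signrank_statistics(d: np.ndarray) -> np.ndarray:
    """Signed-rank statistic per column, centered at its null expectation."""
    n = d.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, np.abs(d))
    w_pos = np.where(d > 0, ranks, 0.0).sum(axis=0)
    return w_pos - n * (n + 1) / 4.0


def permutation_wilcoxon(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    paired: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation test with a Wilcoxon statistic, per substate.

    ``group_a`` and ``group_b`` are (subjects x substates) probability arrays.
    Unpaired: the rank-sum statistic of group a under ``n_perm`` random group
    relabelings. Paired (equal subject counts, matched rows): the signed-rank
    statistic under random sign flips of the per-subject differences.

    Returns ``(statistic, p_raw)`` where p uses the add-one estimator
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``, so p is never 0 and
    is invariant under swapping the two groups.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have the same number of substates")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value resolution", RuntimeWarning)
    rng = np.random.default_rng(seed)
    k = a.shape[1]
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        obs = _signrank_statistics(d)
        null = np.empty((n_perm, k))
        for i in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=(d.shape[0], 1))
            null[i] = _signrank_statistics(d * flips)
    else:
        obs = _ranksum_statistics(a, b)
        pooled = np.vstack([a, b])
        na = a.shape[0]
        null = np.empty((n_perm, k))
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            null[i] = _ranksum_statistics(pooled[perm[:na]], pooled[perm[na:]])
    zero_var = np.ptp(np.vstack([a, b]), axis=0) == 0
    p = (1.0 + np.sum(np.abs(null) >= np.abs(obs)[None, :] - 1e-12, axis=0)) / (
        1.0 + n_perm
    )
    p[zero_var] = 1.0
    return obs, p


def fdr_correct(
    p_raw: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction: (reject mask, adjusted p)."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def condition_contrast(
    model: ClusterModel,
    condition_a: str,
    condition_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    paired: bool = False,
) -> SubstateTestResult:
    """Full contrast: subject-level PMS per condition, permutation test, FDR."""
    pa = subject_level_pms(model, condition_a)
    pb = subject_level_pms(model, condition_b)
    a = np.vstack([p.probabilities for p in pa.values()])
    b = np.vstack([p.probabilities for p in pb.values()])
    stat, p_raw = permutation_wilcoxon(a, b, n_perm=n_perm, seed=seed, paired=paired)
    mask, p_adj = fdr_correct(p_raw, alpha=alpha)
    return SubstateTestResult(
        k=model.k,
        statistic=stat,
        p_raw=p_raw,
        p_fdr=p_adj,
        p_fdr_mask=mask,
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
        paired=paired,
    )
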