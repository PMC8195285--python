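"""Nonparametric resampling differential expression (SAM-seq style).

The test is a two-class unpaired standardized Wilcoxon rank-sum computed
on Poisson-downsampled count stacks and averaged over resamples, with a
permutation-based false-discovery estimate:

1. :func:`depth_standardize` draws, per resample, Poisson counts with
   mean ``count * min_library / library`` so every sample is compared at
   the shallowest depth;
2. per gene, the standardized rank-sum statistic (average ranks and the
   tie-corrected null variance) is averaged over resamples;
3. :func:`estimate_fdr` converts |statistic| thresholds into q-values as
   the median, over complete group-label permutations, of the permuted
   exceedance count divided by the observed exceedance count.

Genes are called up/down with strict thresholds on q and on the
pseudo-counted CPM fold change (numerator group / denominator group).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import GeneCountMatrix
from .errors import (
    InsufficientPermutationsError,
    InvalidArgumentError,
)

__all__ = [
    "depth_standardize",
    "rank_statistic",
    "resampled_statistics",
    "estimate_fdr",
    "fold_change",
    "classify_de",
    "sam_de",
    "shared_regulation",
]


def depth_standardize(
    matrix: GeneCountMatrix, n_resamples: int = 20, seed: int = 0
) -> np.ndarray:
    """Poisson downsampling of every sample to the minimum library size.

    Returns an integer stack of shape (n_resamples, n_genes, n_samples);
    resample r, gene g, sample s is Poisson with mean
    ``count[g, s] * min(lib) / lib[s]``.
    """
    counts = matrix.counts.values.astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise InvalidArgumentError("all library sizes must be positive")
    scaled = counts * (lib.min() / lib)[None, :]
    rng = np.random.default_rng(seed)
    return rng.poisson(scaled[None, :, :].repeat(n_resamples, axis=0))


def _tie_term(values: np.ndarray) -> np.ndarray:
    """sum over tied groups of (t^3 - t), vectorized over leading axes.

    Uses the identity sum_groups t^3 = sum_i c_i^2 where c_i is the
    multiplicity of observation i's value within its row.
    """
    n = values.shape[-1]
    c = (values[..., :, None] == values[..., None, :]).sum(axis=-1)
    return (c * c).sum(axis=-1).astype(float) - n


def _standardize(tie: np.ndarray, n_a: int, n: int):
    """Null mean and SD of the group-A rank sum with tie correction."""
    n_b = n - n_a
    e_w = n_a * (n + 1) / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    return e_w, sd


def rank_statistic(values_group_a, values_group_b) -> float:
    """Standardized two-sample Wilcoxon rank-sum statistic.

    Returns (W - E[W]) / SD[W] with average ranks for ties, where W is
    the rank sum of group A; positive when A is stochastically larger.
    A group of fewer than 2 values is rejected.
    """
    a = np.asarray(values_group_a, dtype=float)
    b = np.asarray(values_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = ranks[: a.size].sum()
    e_w, sd = _standardize(_tie_term(pooled[None, :])[0], a.size, pooled.size)
    if sd == 0:
        return 0.0
    return float((w - e_w) / sd)


def _rank_stack(stack: np.ndarray):
    """Per-resample ranks, null mean/SD of the rank sum for a group of n_a."""
    ranks = rankdata(stack, axis=-1)
    tie = np.stack([_tie_term(stack[r]) for r in range(stack.shape[0])])
    return ranks, tie


def _stats_for_masks(ranks, tie, masks: np.ndarray) -> np.ndarray:
    """Mean-over-resamples standardized statistics for each 0/1 mask row.

    ranks: (R, G, S); masks: (M, S) with identical row sums. Returns (M, G).
    """
    n_r, n_g, n = ranks.shape
    n_a = int(masks[0].sum())
    e_w, sd = _standardize(tie, n_a, n)  # sd shape (R, G)
    out = np.zeros((masks.shape[0], n_g))
    m_t = masks.T.astype(float)  # (S, M)
    for r in range(n_r):
        w = ranks[r] @ m_t  # (G, M)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (w - e_w) / sd[r][:, None]
        out += np.where(sd[r][:, None] > 0, z, 0.0).T
    return out / n_r


def resampled_statistics(
    matrix: GeneCountMatrix,
    group_mask: np.ndarray,
    n_resamples: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Per-gene resampling-averaged standardized Wilcoxon statistics."""
    stack = depth_standardize(matrix, n_resamples=n_resamples, seed=seed)
    ranks, tie = _rank_stack(stack)
    stats = _stats_for_masks(ranks, tie, np.asarray(group_mask, dtype=int)[None, :])[0]
    return pd.Series(stats, index=matrix.genes, name="statistic")


def _permutation_masks(n: int, n_a: int, n_permutations: int, rng) -> np.ndarray:
    """Distinct complete group-label reshufflings as 0/1 masks."""
    total = math.comb(n, n_a)
    if total < 20:
        raise InsufficientPermutationsError(
            f"only {total} distinct group assignments exist; >= 20 required"
        )
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=int)
        for i, idx in enumerate(combinations(range(n), n_a)):
            masks[i, list(idx)] = 1
        return masks
    masks = np.zeros((n_permutations, n), dtype=int)
    for i in range(n_permutations):
        masks[i, rng.choice(n, size=n_a, replace=False)] = 1
    return masks


def estimate_fdr(
    observed_stats: np.ndarray, permuted_stats: np.ndarray
) -> np.ndarray:
    """q-values from observed and permuted statistic magnitudes.

    For each observed |t|: FDR(t) = median over permutations of
    #{permuted |stat| >= t} divided by #{observed |stat| >= t}, clipped to
    [0, 1] and made monotone non-increasing in t. Each gene's q-value is
    the FDR at its own |statistic|.
    """
    obs = np.abs(np.asarray(observed_stats, dtype=float))
    perm = np.abs(np.asarray(permuted_stats, dtype=float))
    order = np.argsort(obs)
    obs_sorted = obs[order]
    n_genes = obs.size

    # observed exceedance counts at each gene's own threshold
    obs_count = n_genes - np.searchsorted(obs_sorted, obs, side="left")

    perm_counts = np.empty((perm.shape[0], n_genes))
    for p in range(perm.shape[0]):
        row = np.sort(perm[p])
        perm_counts[p] = row.size - np.searchsorted(row, obs, side="left")
    med = np.median(perm_counts, axis=0)

    q = np.clip(med / np.maximum(obs_count, 1), 0.0, 1.0)
    # step-up: each gene may inherit a smaller FDR from a *less* significant
    # threshold, which also enforces q monotone non-increasing in |t|
    q_sorted = np.minimum.accumulate(q[order])
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


def fold_change(
    matrix: GeneCountMatrix,
    group_mask: np.ndarray,
    pseudo: float = 1.0,
) -> pd.Series:
    """Pseudo-counted CPM fold change, mask group (numerator) over the rest."""
    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    cpm = matrix.cpm()
    num = cpm.loc[:, mask].mean(axis=1) + pseudo
    den = cpm.loc[:, ~mask].mean(axis=1) + pseudo
    return (num / den).rename("fold_change")


def classify_de(
    results: pd.DataFrame,
    q_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.Series:
    """Direction calls with strict thresholds: up iff q < q_max and
    FC > fc_up; down iff q < q_max and FC < fc_down; otherwise none."""
    q = results["q_value"]
    fc = results["fold_change"]
    direction = pd.Series("none", index=results.index, name="direction")
    direction[(q < q_max) & (fc > fc_up)] = "up"
    direction[(q < q_max) & (fc < fc_down)] = "down"
    return direction


def sam_de(
    matrix: GeneCountMatrix,
    numerator: str = "HFD",
    denominator: str = "RFD",
    group_col: str = "group",
    n_resamples: int = 20,
    n_permutations: int = 200,
    q_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-class differential-expression analysis on one matrix.

    Returns a DataFrame indexed by gene with columns ``statistic``
    (positive = higher in the numerator group), ``fold_change``
    (numerator/denominator, pseudo-counted CPM), ``q_value`` and
    ``direction``.
    """
    groups = matrix.design[group_col].astype(str)
    if not set(groups) >= {numerator, denominator}:
        raise InvalidArgumentError(
            f"design column {group_col!r} must contain {numerator!r} and {denominator!r}"
        )
    keep = groups.isin([numerator, denominator])
    sub = matrix.subset_samples(matrix.samples[keep.values])
    mask = (sub.design[group_col].astype(str) == numerator).to_numpy().astype(int)
    if mask.sum() < 2 or (1 - mask).sum() < 2:
        raise InvalidArgumentError("each group needs at least 2 samples")

    rng = np.random.default_rng(seed)
    stack = depth_standardize(sub, n_resamples=n_resamples, seed=seed)
    ranks, tie = _rank_stack(stack)
    observed = _stats_for_masks(ranks, tie, mask[None, :])[0]
    masks = _permutation_masks(sub.n_samples, int(mask.sum()), n_permutations, rng)
    permuted = _stats_for_masks(ranks, tie, masks)
    q = estimate_fdr(observed, permuted)

    results = pd.DataFrame(
        {
            "statistic": observed,
            "fold_change": fold_change(sub, mask).values,
            "q_value": q,
        },
        index=sub.genes,
    )
    results["direction"] = classify_de(results, q_max=q_max, fc_up=fc_up, fc_down=fc_down)
    return results


def shared_regulation(de_t1: pd.DataFrame, de_t2: pd.DataFrame) -> pd.DataFrame:
    """Genes significantly regulated at both time points, with concordance.

    Returns a DataFrame indexed by the shared genes (non-``none`` direction
    in both inputs) with both directions and a ``concordant`` flag (same
    direction at both time points).
    """
    common = de_t1.index.intersection(de_t2.index)
    d1 = de_t1.loc[common, "direction"]
    d2 = de_t2.loc[common, "direction"]
    shared = common[(d1 != "none") & (d2 != "none")]
    return pd.DataFrame(
        {
            "direction_t1": d1.loc[shared],
            "direction_t2": d2.loc[shared],
            "concordant": (d1.loc[shared] == d2.loc[shared]),
        },
        index=shared,
    )
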