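"""Summaries of the single-cell reference used for in-silico purification.

Three quantities drive the decontamination procedure downstream:

* per-type mean expression profiles (the deconvolution signature),
* per-type expression *prevalence* — the fraction of cells of a type with
  at least a floor number of reads (3 by default) of a gene — which
  classifies genes as target-only / shared / non-target,
* the mode and the one-sided 95% cutoffs of the pooled log10 read-count
  distribution, whose lower cutoff guards the target-read-fraction
  estimate against weakly measured genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "SignatureReference",
    "CountDistributionSummary",
    "summarize_reference",
    "estimate_mode_and_cutoffs",
    "classify_genes",
]


@dataclass
class SignatureReference:
    """Per-cell-type expression summaries of a single-cell reference.

    Attributes
    ----------
    mean_profile : DataFrame, genes x cell types
        Arithmetic mean reads per cell.
    prevalence : DataFrame, genes x cell types
        Fraction of cells of the type with >= ``prevalence_min_reads``
        reads of the gene; values in [0, 1].
    marker_sets : dict of cell type -> list of genes
        Genes prevalent (>= threshold) in exactly one type.
    target_type : str
    """

    mean_profile: pd.DataFrame
    prevalence: pd.DataFrame
    marker_sets: dict
    target_type: str

    def __post_init__(self):
        if self.target_type not in self.mean_profile.columns:
            raise InvalidArgumentError(
                f"target type {self.target_type!r} absent from reference types"
            )
        p = self.prevalence.values
        if (p < 0).any() or (p > 1).any():
            raise InvalidArgumentError("prevalence values must lie in [0, 1]")

    @property
    def cell_types(self) -> list:
        return list(self.mean_profile.columns)

    @property
    def non_target_types(self) -> list:
        return [t for t in self.cell_types if t != self.target_type]

    def relative_profile(self) -> pd.DataFrame:
        """Mean profiles normalized to sum to one per type (relative abundance)."""
        return self.mean_profile / self.mean_profile.sum(axis=0)

    def non_target_markers(self) -> list:
        out = []
        for t in self.non_target_types:
            out.extend(self.marker_sets.get(t, []))
        return sorted(set(out))


@dataclass
class CountDistributionSummary:
    """Mode and one-sided mass cutoffs of a log10 read-count distribution."""

    mode_log10: float
    lower_cutoff: float
    upper_cutoff: float

    def __post_init__(self):
        if not (self.lower_cutoff <= self.mode_log10 <= self.upper_cutoff):
            raise InvalidArgumentError(
                "cutoffs must bracket the mode: "
                f"{self.lower_cutoff} <= {self.mode_log10} <= {self.upper_cutoff}"
            )


def summarize_reference(
    raw: ad.AnnData,
    target_type: str | None = None,
    prevalence_min_reads: int = 3,
    marker_prevalence: float = 0.2,
) -> SignatureReference:
    """Summarize a labelled single-cell reference into a signature.

    ``raw`` must carry ``obs["cell_type"]``; the target type defaults to
    ``raw.uns["target_type"]``. Marker sets are the genes whose prevalence
    reaches ``marker_prevalence`` in exactly one cell type.
    """
    if "cell_type" not in raw.obs:
        raise InvalidArgumentError('reference is missing obs["cell_type"]')
    if target_type is None:
        target_type = raw.uns.get("target_type")
        if target_type is None:
            raise InvalidArgumentError("target_type not given and not recorded in uns")
    labels = raw.obs["cell_type"].astype(str)
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise InvalidArgumentError("reference must contain >= 2 cell types")

    X = raw.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    means = {}
    prev = {}
    for t in types:
        mask = (labels == t).to_numpy()
        if mask.sum() == 0:
            raise InvalidArgumentError(f"cell type {t!r} has no cells")
        sub = X[mask]
        means[t] = sub.mean(axis=0)
        prev[t] = (sub >= prevalence_min_reads).mean(axis=0)

    mean_profile = pd.DataFrame(means, index=raw.var_names.copy())
    prevalence = pd.DataFrame(prev, index=raw.var_names.copy())
    mean_profile.index.name = prevalence.index.name = "gene"

    prevalent = prevalence.values >= marker_prevalence
    exclusive = prevalent.sum(axis=1) == 1
    marker_sets = {}
    for j, t in enumerate(types):
        marker_sets[t] = prevalence.index[prevalent[:, j] & exclusive].tolist()

    return SignatureReference(mean_profile, prevalence, marker_sets, target_type)


def estimate_mode_and_cutoffs(
    log10_counts, mass: float = 0.95, grid_size: int = 512
) -> CountDistributionSummary:
    """Mode and one-sided cutoffs containing ``mass`` of the sub-/supra-mode reads.

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth)
    evaluated on a ``grid_size``-point grid spanning the sample. The lower
    cutoff L is the largest observed value such that at least ``mass`` of
    the observations at or below the mode are >= L; the upper cutoff is
    symmetric above the mode. With ``mass=1`` the cutoffs are the sample
    extrema.
    """
    x = np.asarray(log10_counts, dtype=float).ravel()
    if x.size < 100:
        raise InsufficientDataError(
            f"need >= 100 observations to estimate the mode, got {x.size}"
        )
    if not (0 < mass <= 1):
        raise InvalidArgumentError("mass must lie in (0, 1]")
    if np.ptp(x) == 0:  # degenerate: all observations identical
        v = float(x[0])
        return CountDistributionSummary(v, v, v)

    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    mode = float(grid[np.argmax(kde(grid))])

    below = np.sort(x[x <= mode])
    above = np.sort(x[x >= mode])
    lower = _one_sided_cutoff(below, mass, side="lower") if below.size else mode
    upper = _one_sided_cutoff(above, mass, side="upper") if above.size else mode
    return CountDistributionSummary(mode, min(lower, mode), max(upper, mode))


def _one_sided_cutoff(sorted_vals: np.ndarray, mass: float, side: str) -> float:
    """Counting quantile: the cutoff retaining >= mass of the one-sided sample."""
    n = sorted_vals.size
    k = int(np.floor(n * (1.0 - mass)))  # observations allowed outside the cutoff
    k = min(k, n - 1)
    if side == "lower":
        return float(sorted_vals[k])
    return float(sorted_vals[n - 1 - k])


def pooled_log10_counts(
    raw: ad.AnnData, cell_type: str, nonzero_only: bool = True
) -> np.ndarray:
    """Pooled log10(count + 1) values of one cell type's gene-cell counts.

    Zeros are dropout-dominated and would pin the distribution's mode at
    0, so by default only positive counts enter the pooled distribution.
    """
    labels = raw.obs["cell_type"].astype(str)
    X = raw.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    sub = X[(labels == cell_type).to_numpy()].ravel()
    if nonzero_only:
        sub = sub[sub > 0]
    return np.log10(sub + 1.0)


def classify_genes(
    ref: SignatureReference, prevalence_threshold: float = 0.2
) -> pd.Series:
    """Label every gene as ``target-only``, ``shared`` or ``non-target``.

    ``non-target``: prevalent (>= threshold) in at least one non-target
    type and *not* prevalent (< threshold) in the target type — these are
    pure contamination and are removed downstream. ``target-only``:
    prevalent in the target type alone. Everything else — including genes
    below threshold everywhere, which are conservatively kept subject to
    decontamination — is ``shared``.
    """
    prev = ref.prevalence
    in_target = prev[ref.target_type] >= prevalence_threshold
    in_non_target = (prev[ref.non_target_types] >= prevalence_threshold).any(axis=1)

    labels = pd.Series("shared", index=prev.index, name="label")
    labels[in_non_target & ~in_target] = "non-target"
    labels[in_target & ~in_non_target] = "target-only"
    return labels
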