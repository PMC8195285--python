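"""In-silico purification of FACS-enriched bulk profiles.

A sorted rare population (here: intestinal tuft cells) still carries reads
from co-sorted epithelial contaminants. Purification proceeds in three
steps, all guided by the single-cell signature:

1. estimate per-sample cell-type proportions by non-negative least
   squares of the bulk CPM profile on the type signatures over the
   marker-gene union (:func:`estimate_proportions`);
2. estimate the fraction of each sample's reads that originate from the
   target type, restricted to genes measured above the reference
   distribution's lower read-count cutoff
   (:func:`estimate_target_read_fraction`);
3. down-weight every *shared* gene's counts by the target's expected
   share of its reads, scaled by the sample's relative target-read
   fraction, and remove genes the target type does not express
   (:func:`decontaminate`).

Corrected counts never exceed the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data import GeneCountMatrix, cpm
from .errors import (
    InsufficientDataError,
    InsufficientMarkersError,
    InvalidArgumentError,
)
from .reference import CountDistributionSummary, SignatureReference

__all__ = [
    "ProportionEstimate",
    "DecontaminationResult",
    "estimate_proportions",
    "estimate_target_read_fraction",
    "decontaminate",
]


@dataclass
class ProportionEstimate:
    """Per-sample cell-type fractions (rows sum to one) and NNLS residuals."""

    proportions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series   # per sample

    def __post_init__(self):
        p = self.proportions.values
        if (p < -1e-12).any():
            raise InvalidArgumentError("proportions must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidArgumentError("proportions must sum to 1 per sample")

    def target_fraction(self, target_type: str) -> pd.Series:
        return self.proportions[target_type]


@dataclass
class DecontaminationResult:
    """Outcome of read-level decontamination."""

    corrected_counts: pd.DataFrame          # genes x samples, non-negative reals
    per_gene_weight: pd.DataFrame           # shared genes x samples, in [0, 1]
    target_read_fraction: pd.Series         # per sample, in [0, 1]
    removed_genes: list

    def to_matrix(self, design: pd.DataFrame) -> GeneCountMatrix:
        return GeneCountMatrix(self.corrected_counts.copy(), design.copy())


def _signature_cpm(ref: SignatureReference) -> pd.DataFrame:
    """Type signatures on a common depth scale (CPM of the mean profile)."""
    prof = ref.mean_profile
    return prof / prof.sum(axis=0) * 1e6


def estimate_proportions(
    bulk: GeneCountMatrix,
    ref: SignatureReference,
    min_markers: int = 5,
) -> ProportionEstimate:
    """Marker-based constrained least-squares deconvolution.

    Solves, per sample, non-negative least squares of the bulk CPM vector
    on the CPM-scaled type signatures restricted to the union of marker
    genes, then renormalizes the coefficients to the simplex. Deterministic.
    """
    marker_union: list = []
    for t in ref.cell_types:
        present = [g for g in ref.marker_sets.get(t, []) if g in bulk.genes]
        if len(present) < min_markers:
            raise InsufficientMarkersError(t, len(present), min_markers)
        marker_union.extend(present)
    marker_union = sorted(set(marker_union))

    sig = _signature_cpm(ref).loc[marker_union, ref.cell_types]
    bulk_cpm = bulk.cpm().loc[marker_union]

    A = sig.values
    rows = {}
    resid = {}
    for s in bulk.samples:
        coef, rnorm = nnls(A, bulk_cpm[s].values)
        total = coef.sum()
        if total <= 0:
            raise InsufficientDataError(
                f"deconvolution produced an all-zero solution for sample {s!r}"
            )
        rows[s] = coef / total
        resid[s] = rnorm
    props = pd.DataFrame.from_dict(rows, orient="index", columns=ref.cell_types)
    props = props.loc[list(bulk.samples)]
    return ProportionEstimate(props, pd.Series(resid).loc[list(bulk.samples)])


def _target_share(
    ref: SignatureReference, proportions: pd.Series, genes: pd.Index
) -> pd.Series:
    """Expected fraction of a gene's bulk reads that come from the target type.

    share_g = p_t * f_{t,g} / sum_c p_c * f_{c,g} on depth-normalized
    profiles f; 0 where the denominator vanishes (gene unattributable).
    """
    rel = ref.relative_profile().reindex(genes).fillna(0.0)
    p = proportions[ref.cell_types].values
    denom = rel.values @ p
    numer = p[ref.cell_types.index(ref.target_type)] * rel[ref.target_type].values
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, numer / denom, 0.0)
    return pd.Series(share, index=genes, name="target_share")


def estimate_target_read_fraction(
    bulk_sample: pd.Series,
    proportions: pd.Series,
    ref: SignatureReference,
    summary: CountDistributionSummary,
) -> float:
    """Fraction of a sample's reads attributable to the target cell type.

    Restricted to genes with log10(count + 1) >= the reference
    distribution's lower cutoff — genes below it are too weakly measured
    to apportion reads confidently.
    """
    counts = bulk_sample.astype(float)
    passing = counts.index[np.log10(counts.values + 1.0) >= summary.lower_cutoff]
    if len(passing) == 0:
        raise InsufficientDataError(
            "no gene passes the lower read-count cutoff "
            f"({summary.lower_cutoff:.3f} log10 reads)"
        )
    share = _target_share(ref, proportions, passing)
    sub = counts.loc[passing]
    total = float(sub.sum())
    if total <= 0:
        raise InsufficientDataError("passing genes carry zero reads")
    return float((sub * share).sum() / total)


def decontaminate(
    bulk: GeneCountMatrix,
    proportions: ProportionEstimate,
    ref: SignatureReference,
    labels: pd.Series,
    summary: CountDistributionSummary,
) -> DecontaminationResult:
    """Remove contaminating read contributions from the bulk matrix.

    Shared genes are scaled by ``share * f_s / f_mean`` (clamped so that
    corrected <= raw), where ``share`` is the target type's expected read
    share of the gene under the sample's estimated proportions, ``f_s``
    the sample's target-read fraction and ``f_mean`` the cohort mean —
    samples of poorer purity receive a stronger correction. Target-only
    genes pass through unchanged. Genes labelled non-target, together with
    the non-target marker genes, are removed outright.
    """
    missing = bulk.genes.difference(labels.index)
    if len(missing):
        raise InvalidArgumentError(
            f"labels missing for {len(missing)} genes (e.g. {list(missing[:3])})"
        )
    missing_samples = bulk.samples.difference(proportions.proportions.index)
    if len(missing_samples):
        raise InvalidArgumentError(
            f"proportions missing for samples {list(missing_samples)}"
        )

    labels = labels.loc[bulk.genes]
    non_target_label = set(labels.index[labels == "non-target"])
    removed = sorted(
        (non_target_label | set(ref.non_target_markers())) & set(bulk.genes)
    )
    kept = bulk.genes.difference(removed, sort=False)
    shared = [g for g in kept if labels[g] == "shared"]

    f = pd.Series(
        {
            s: estimate_target_read_fraction(
                bulk.counts[s], proportions.proportions.loc[s], ref, summary
            )
            for s in bulk.samples
        },
        name="target_read_fraction",
    )
    f_mean = float(f.mean())

    corrected = bulk.counts.loc[kept].astype(float).copy()
    weights = pd.DataFrame(1.0, index=pd.Index(shared, name="gene"), columns=bulk.samples)
    for s in bulk.samples:
        share = _target_share(ref, proportions.proportions.loc[s], pd.Index(shared))
        w = np.clip(share.values * (f[s] / f_mean), 0.0, 1.0)
        weights[s] = w
        corrected.loc[shared, s] = bulk.counts.loc[shared, s].astype(float) * w

    return DecontaminationResult(
        corrected_counts=corrected,
        per_gene_weight=weights,
        target_read_fraction=f,
        removed_genes=removed,
    )
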