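"""Spearman correlation screens, threshold regimes, network export, and
qPCR relative expression.

Two significance regimes are applied to the same correlation matrices:

* the *screen* regime (heatmap-style): p < 0.05 and BH q < 0.1;
* the *network* regime (integration network): |SCC| > 0.7 and q < 0.05,
  strict inequalities.

q-values are Benjamini-Hochberg over all pairs tested in the analysis
batch. Networks are exported as simple interaction format (SIF) plus an
edge-attribute table loadable by graph viewers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

__all__ = [
    "QPCRMeasurement",
    "relative_expression",
    "bh_qvalues",
    "spearman_matrix",
    "build_network",
    "correlation_screen",
    "write_sif",
]


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a vector of p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]

log = logging.getLogger(__name__)


@dataclass
class QPCRMeasurement:
    """Relative expression from qPCR threshold cycles (delta-Ct method)."""

    ct_target: float
    ct_reference: float
    delta_ct: float
    relative_expression: float


def relative_expression(ct_target: float, ct_reference: float) -> QPCRMeasurement:
    """delta-Ct relative expression: 2**(-(Ct_target - Ct_reference)).

    One PCR cycle doubles the product, so a transcript crossing threshold
    one cycle later than the reference is half as abundant.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise InvalidArgumentError("Ct values must be finite")
    delta = float(ct_target) - float(ct_reference)
    return QPCRMeasurement(float(ct_target), float(ct_reference), delta, 2.0 ** (-delta))


def spearman_matrix(
    variables: pd.DataFrame, min_n: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations with pairwise-complete observations.

    Returns (scc, p, q) DataFrames (symmetric, unit/NaN diagonal). Ties get
    average ranks; two-sided p-values use the t-distribution
    approximation; q-values are BH over every pair actually tested in this
    batch. Pairs with fewer than ``min_n`` complete observations, or a
    zero-variance variable on the complete subset, are reported missing
    (NaN) and logged.
    """
    cols = list(variables.columns)
    k = len(cols)
    scc = pd.DataFrame(np.nan, index=cols, columns=cols)
    pmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    np.fill_diagonal(scc.values, 1.0)

    tested = []
    pvals = []
    for a, b in combinations(cols, 2):
        sub = variables[[a, b]].dropna()
        if len(sub) < min_n:
            log.info("pair (%s, %s): only %d complete observations", a, b, len(sub))
            continue
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            log.info("pair (%s, %s): zero variance on complete subset", a, b)
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        scc.loc[a, b] = scc.loc[b, a] = rho
        pmat.loc[a, b] = pmat.loc[b, a] = p
        tested.append((a, b))
        pvals.append(p)

    qmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    if tested:
        qvals = bh_qvalues(pvals)
        for (a, b), q in zip(tested, qvals):
            qmat.loc[a, b] = qmat.loc[b, a] = q
    return scc, pmat, qmat


def build_network(
    scc: pd.DataFrame,
    p: pd.DataFrame,
    q: pd.DataFrame,
    scc_min: float = 0.7,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Edges of the integration network: |SCC| > scc_min and q < q_max.

    Both inequalities are strict; each undirected pair appears once.
    Returns a DataFrame with columns node_a, node_b, scc, p_value,
    q_value, sign.
    """
    _check_aligned(scc, p, q)
    rows = []
    for a, b in combinations(scc.columns, 2):
        r, pv, qv = scc.loc[a, b], p.loc[a, b], q.loc[a, b]
        if np.isnan(r) or np.isnan(qv):
            continue
        if abs(r) > scc_min and qv < q_max:
            rows.append(
                {"node_a": a, "node_b": b, "scc": r, "p_value": pv, "q_value": qv,
                 "sign": "positive" if r > 0 else "negative"}
            )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "scc", "p_value", "q_value", "sign"])


def correlation_screen(
    scc: pd.DataFrame,
    p: pd.DataFrame,
    q: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Heatmap-style screen: flag pairs with p < p_max and q < q_max.

    Returns a long-format table of every tested pair with a ``flagged``
    column and significance stars by p-value decade (* p<0.05, ** p<0.01,
    ... up to ****** p<1e-6).
    """
    _check_aligned(scc, p, q)
    rows = []
    for a, b in combinations(scc.columns, 2):
        r, pv, qv = scc.loc[a, b], p.loc[a, b], q.loc[a, b]
        if np.isnan(r) or np.isnan(pv):
            continue
        rows.append(
            {"node_a": a, "node_b": b, "scc": r, "p_value": pv, "q_value": qv,
             "flagged": bool(pv < p_max and qv < q_max), "stars": _stars(pv)}
        )
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "scc", "p_value", "q_value", "flagged", "stars"]
    )


def _stars(p: float) -> str:
    """Significance stars by p-value decade: 0.05, 0.01, 0.001, ... 1e-6."""
    thresholds = [0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6]
    n = sum(p < t for t in thresholds)
    return "*" * n


def _check_aligned(*mats: pd.DataFrame) -> None:
    first = mats[0]
    for m in mats[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise InvalidArgumentError("correlation matrices are not aligned")


def write_sif(edges: pd.DataFrame, sif_path, attributes_path=None) -> None:
    """Write the network as SIF (node_a<TAB>sign<TAB>node_b) and optionally
    an edge-attribute TSV for graph viewers."""
    lines = [
        f"{r.node_a}\t{r.sign}\t{r.node_b}" for r in edges.itertuples(index=False)
    ]
    Path(sif_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if attributes_path is not None:
        edges.to_csv(attributes_path, sep="\t", index=False)
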