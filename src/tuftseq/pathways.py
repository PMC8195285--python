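"""Gene-set scoring and orphan-gene classification.

Gene sets (e.g. Reactome pathways) are read from GMT files and scored by
the mean of their member genes' standardized DE statistics against a null
of size-matched random gene sets; q-values are Benjamini-Hochberg across
all scored sets. Differentially expressed genes belonging to no loaded set
are "orphans" and are flagged by membership of the two broad GO branches
metabolic process (GO:0008152) and immune system process (GO:0002376).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import GMTParseError, InvalidArgumentError

__all__ = [
    "GO_METABOLIC_PROCESS",
    "GO_IMMUNE_SYSTEM_PROCESS",
    "load_gene_sets",
    "load_go_map",
    "score_gene_sets",
    "classify_orphans",
]

log = logging.getLogger(__name__)

GO_METABOLIC_PROCESS = "GO:0008152"
GO_IMMUNE_SYSTEM_PROCESS = "GO:0002376"


def load_gene_sets(path) -> dict:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are stored once (first occurrence);
    a line without any gene raises :class:`GMTParseError` with its line
    number, as does a repeated set name.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    lineno, "expected name, description and at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise GMTParseError(lineno, f"duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise GMTParseError(lineno, f"set {name!r} has no genes")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gene_sets(sets: dict, path, description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_go_map(path) -> dict:
    """Read a two-column TSV (gene, GO term) into gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def score_gene_sets(
    gene_stats: pd.Series,
    gene_sets: dict,
    n_permutations: int = 1000,
    min_size: int = 3,
    q_max: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each gene set by its mean member statistic against a
    size-matched random-set null.

    For every set with at least ``min_size`` measured members, the set
    statistic is the arithmetic mean of the members' standardized DE
    statistics; the two-sided permutation p-value compares its magnitude
    with ``n_permutations`` random sets of the same size drawn from the
    measured gene universe (add-one rank estimate). q-values are BH over
    all scored sets; undersized sets are skipped with a logged reason.

    Returns a DataFrame indexed by set id with columns
    ``n_genes_measured``, ``set_statistic``, ``p_value``, ``q_value``,
    ``direction``.
    """
    if gene_stats.index.has_duplicates:
        raise InvalidArgumentError("gene_stats index must be unique")
    rng = np.random.default_rng(seed)
    stats = gene_stats.astype(float)
    universe = stats.values
    index = pd.Index(stats.index)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in gene_sets.items():
        members = index.intersection(genes)
        k = len(members)
        if k < min_size:
            log.info("skipping gene set %s: %d measured members < %d", name, k, min_size)
            continue
        observed = float(stats.loc[members].mean())
        if k not in null_cache:
            draws = rng.choice(universe.size, size=(n_permutations, k))
            null_cache[k] = universe[draws].mean(axis=1)
        null = null_cache[k]
        p = (1 + np.sum(np.abs(null) >= abs(observed))) / (n_permutations + 1)
        rows.append(
            {"set_id": name, "n_genes_measured": k, "set_statistic": observed,
             "p_value": float(p)}
        )
    result = pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["n_genes_measured", "set_statistic", "p_value", "q_value", "direction"]
    )
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        direction = pd.Series("none", index=result.index)
        sig = result["q_value"] < q_max
        direction[sig & (result["set_statistic"] > 0)] = "up"
        direction[sig & (result["set_statistic"] < 0)] = "down"
        result["direction"] = direction
    return result


def classify_orphans(
    de_genes, gene_sets: dict, go_map: dict
) -> pd.DataFrame:
    """Flag DE genes outside every loaded gene set and annotate them.

    ``is_orphan`` is true when the gene belongs to no loaded set;
    ``metabolism_flag``/``immune_flag`` record membership of
    GO:0008152 / GO:0002376 (genes absent from the GO map are treated as
    unannotated). The flags are reported for orphans only (False
    otherwise).
    """
    in_any_set = set()
    for genes in gene_sets.values():
        in_any_set.update(genes)
    rows = []
    for gene in de_genes:
        orphan = gene not in in_any_set
        terms = go_map.get(gene, set())
        rows.append(
            {
                "gene": gene,
                "is_orphan": orphan,
                "metabolism_flag": orphan and GO_METABOLIC_PROCESS in terms,
                "immune_flag": orphan and GO_IMMUNE_SYSTEM_PROCESS in terms,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
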