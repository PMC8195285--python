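"""Synthetic data with recorded ground truth.

Emulates the three inputs of the analysis:

* a single-cell reference (cells x genes, labelled by cell type) in which
  each type carries a disjoint block of marker genes and the remaining
  genes are shared across two or more types;
* FACS-enriched bulk samples of a rare "target" type (tuft cells) that are
  negative-binomial mixtures of the target profile plus epithelial
  contaminants at known per-sample proportions, with differential
  expression between two diet groups planted multiplicatively on the
  target profile only;
* a per-animal phenotype table (body composition, immune-cell proportions,
  cytokines) in which selected phenotypes are monotone transforms of a
  chosen transcript's expression.

Every generator is a pure function of its seed; the ground truth needed to
score downstream stages is returned alongside the data in
:class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .data import GeneCountMatrix
from .errors import InvalidArgumentError

__all__ = [
    "SyntheticTruth",
    "generate_reference",
    "make_design",
    "generate_bulk_mixtures",
    "generate_phenotypes",
    "PHENOTYPE_PANEL",
]

#: Phenotype panel emulating the measured animal variables: body composition
#: (MRI), tissue masses, intestinal immune-cell proportions (flow cytometry),
#: tissue cytokines (immunoassay), glucose homeostasis and tuft-cell counts.
PHENOTYPE_PANEL = (
    "body_mass_g",
    "fat_to_lean_ratio",
    "ewat_mass_g",
    "liver_mass_g",
    "ilc2_pct_cd45",
    "eosinophil_pct_cd45",
    "m1_macrophage_pct_cd45",
    "m2_macrophage_pct_cd45",
    "il25_pg_per_ml",
    "tnfa_pg_per_ml",
    "fasting_glucose_mm",
    "tuft_cells_per_mm2",
)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    Attributes
    ----------
    cell_type_proportions : DataFrame, samples x cell types
        Mixing proportions of each bulk sample; rows sum to one.
    true_target_expression : DataFrame, genes x samples
        Expected counts contributed by the target cell type in each sample.
    de_genes : list of dict
        Planted effects: ``{"gene", "log2_effect", "direction", "time"}``.
    phenotype_links : list of dict
        Planted phenotype-transcript links:
        ``{"phenotype", "gene", "sign", "noise_sd"}``.
    seed : int
    """

    cell_type_proportions: pd.DataFrame
    true_target_expression: pd.DataFrame
    de_genes: list = field(default_factory=list)
    phenotype_links: list = field(default_factory=list)
    seed: int = 0

    def de_gene_names(self, time: str | None = None) -> list:
        return sorted(
            {d["gene"] for d in self.de_genes if time is None or d["time"] == time}
        )

    def to_json(self, path) -> None:
        obj = {
            "seed": int(self.seed),
            "cell_type_proportions": {
                s: {t: float(v) for t, v in row.items()}
                for s, row in self.cell_type_proportions.iterrows()
            },
            "de_genes": self.de_genes,
            "phenotype_links": self.phenotype_links,
            "true_target_expression": {
                "genes": self.true_target_expression.index.tolist(),
                "samples": self.true_target_expression.columns.tolist(),
                "values": self.true_target_expression.values.round(4).tolist(),
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        props = pd.DataFrame(obj["cell_type_proportions"]).T
        tte = obj["true_target_expression"]
        expr = pd.DataFrame(
            tte["values"], index=pd.Index(tte["genes"], name="gene"),
            columns=tte["samples"],
        )
        return cls(props, expr, obj["de_genes"], obj["phenotype_links"], obj["seed"])


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial sampling, mean/dispersion parameterization.

    var = mu + dispersion * mu^2; dispersion == 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = np.where(mean > 0, rng.gamma(shape, np.maximum(mean, 1e-300) * dispersion), 0.0)
    return rng.poisson(lam)


def generate_reference(
    n_cell_types: int = 8,
    n_genes: int = 2000,
    cells_per_type: int = 50,
    marker_fraction: float = 0.05,
    seed: int = 0,
    target_type: str = "tuft",
    dispersion: float = 0.3,
) -> ad.AnnData:
    """Generate a single-cell style reference with disjoint marker blocks.

    Cell types are named ``tuft`` (the target) plus generic epithelial
    contaminants. Each type receives a disjoint block of
    ``round(n_genes * marker_fraction)`` marker genes expressed at high
    mean in that type and at 1/50 of that mean elsewhere; every remaining
    gene is expressed in a random subset of >= 2 types. Per-cell counts are
    negative binomial around the type means.

    Returns an :class:`anndata.AnnData` (cells x genes) with
    ``obs["cell_type"]``, ``uns["target_type"]``, ``uns["cell_types"]``,
    ``uns["marker_sets"]`` (the true marker blocks) and the true per-type
    mean profile in ``varm["true_mean"]`` (genes x types, type order as in
    ``uns["cell_types"]``).
    """
    if n_cell_types < 2 or cells_per_type <= 0 or n_genes <= 0:
        raise InvalidArgumentError("n_cell_types >= 2 and positive sizes required")
    if n_genes < 50:
        raise InvalidArgumentError("n_genes must be >= 50")
    if not (0 < marker_fraction < 0.5):
        raise InvalidArgumentError("marker_fraction must lie in (0, 0.5)")
    n_markers = max(1, int(round(n_genes * marker_fraction)))
    if n_cell_types * n_markers >= n_genes:
        raise InvalidArgumentError(
            "marker blocks exhaust the gene universe; lower marker_fraction"
        )

    rng = np.random.default_rng(seed)
    contaminant_names = [
        "enterocyte", "goblet", "paneth", "enteroendocrine", "stem",
        "transit_amplifying", "m_cell", "early_progenitor", "late_progenitor",
    ]
    types = [target_type] + [
        contaminant_names[i] if i < len(contaminant_names) else f"type_{i}"
        for i in range(n_cell_types - 1)
    ]
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]

    means = np.zeros((n_genes, n_cell_types))
    marker_sets: dict[str, list] = {}
    pos = 0
    for j, t in enumerate(types):
        block = slice(pos, pos + n_markers)
        high = rng.uniform(10.0, 50.0, size=n_markers)
        means[block, :] = high[:, None] / 50.0   # faint background elsewhere
        means[block, j] = high
        marker_sets[t] = [genes[i] for i in range(pos, pos + n_markers)]
        pos += n_markers

    # Shared genes: expressed in a random subset of >=2 types around a
    # lognormal base abundance, with mild type-to-type variation.
    n_shared = n_genes - pos
    base = np.exp(rng.normal(1.0, 1.2, size=n_shared))
    for k in range(n_shared):
        n_expr = rng.integers(2, n_cell_types + 1)
        which = rng.choice(n_cell_types, size=n_expr, replace=False)
        means[pos + k, which] = base[k] * rng.uniform(0.5, 2.0, size=n_expr)

    counts = np.zeros((n_cell_types * cells_per_type, n_genes), dtype=np.int64)
    labels = []
    for j, t in enumerate(types):
        rows = slice(j * cells_per_type, (j + 1) * cells_per_type)
        counts[rows] = _nb_draws(
            rng, np.broadcast_to(means[:, j], (cells_per_type, n_genes)), dispersion
        )
        labels.extend([t] * cells_per_type)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels)},
            index=[f"cell_{i:05d}" for i in range(counts.shape[0])],
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.varm["true_mean"] = means
    adata.uns["target_type"] = target_type
    adata.uns["cell_types"] = list(types)
    adata.uns["marker_sets"] = {t: list(v) for t, v in marker_sets.items()}
    return adata


def make_design(
    groups=("RFD", "HFD"), times=("9w", "22w"), replicates: int = 6
) -> pd.DataFrame:
    """Two-diet, two-time-point sample design table."""
    rows = []
    for t in times:
        for g in groups:
            for r in range(1, replicates + 1):
                rows.append({"sample": f"{g}_{t}_r{r}", "group": g, "time": t})
    return pd.DataFrame(rows).set_index("sample")


def generate_bulk_mixtures(
    reference: ad.AnnData,
    design: pd.DataFrame | None = None,
    target_purity_range: tuple = (0.6, 0.9),
    n_de: int = 60,
    effect_log2: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    library_size_range: tuple = (5e5, 1e6),
    de_shared_fraction: float = 0.5,
    de_group: str = "HFD",
) -> tuple[GeneCountMatrix, SyntheticTruth]:
    """Simulate FACS-enriched bulk samples as mixtures of reference profiles.

    Each sample's expected counts are ``library_size * sum_c p_c * f_c``
    where ``f_c`` is the type-c mean profile normalized to sum to one and
    ``p_c`` are the mixing (read) proportions: the target proportion is
    drawn uniformly from ``target_purity_range`` and the remainder is
    spread over the contaminant types uniformly on the simplex. Library
    sizes are log-uniform over ``library_size_range``.

    Differential expression is planted multiplicatively (factor
    ``2**effect_log2``, random sign) on the target profile only, for the
    ``de_group`` samples; a fraction ``de_shared_fraction`` of the planted
    genes is active at both time points and the rest at a single one.
    """
    if design is None:
        design = make_design()
    if not (0 < target_purity_range[0] <= target_purity_range[1] <= 1):
        raise InvalidArgumentError("target_purity_range must lie within (0, 1]")
    for (g, t), sub in design.groupby(["group", "time"], observed=True):
        if len(sub) < 2:
            raise InvalidArgumentError(f"need >= 2 samples per group; {g}/{t} has {len(sub)}")

    genes = reference.var_names
    types = list(reference.uns["cell_types"])
    target = reference.uns["target_type"]
    means = np.asarray(reference.varm["true_mean"], dtype=float)
    if n_de > len(genes):
        raise InvalidArgumentError("n_de exceeds the number of genes")

    rng = np.random.default_rng(seed)
    profiles = means / means.sum(axis=0, keepdims=True)  # relative abundance per type
    t_idx = types.index(target)
    times = list(pd.unique(design["time"]))

    # Plant effects among genes robustly expressed by the target type:
    # diet effects on the target cell's transcriptome only make sense for
    # genes the target reliably expresses (>= ~5 mean reads per cell keeps
    # the per-cell detection prevalence well above the 3-read/20% floor).
    expressed = np.flatnonzero(means[:, t_idx] >= 5.0)
    if n_de > len(expressed):
        raise InvalidArgumentError("n_de exceeds the number of target-expressed genes")
    chosen = rng.choice(expressed, size=n_de, replace=False)
    de_genes = []
    if n_de:
        n_shared = int(round(n_de * de_shared_fraction)) if len(times) > 1 else n_de
        for k, gi in enumerate(chosen):
            sign = 1 if rng.random() < 0.5 else -1
            active = times if k < n_shared else [times[k % len(times)]]
            for tp in active:
                de_genes.append(
                    {
                        "gene": genes[gi],
                        "log2_effect": float(sign * effect_log2),
                        "direction": "up" if sign > 0 else "down",
                        "time": tp,
                    }
                )

    effect_by_time = {
        tp: np.ones(len(genes)) for tp in times
    }
    for d in de_genes:
        gi = genes.get_loc(d["gene"])
        effect_by_time[d["time"]][gi] = 2.0 ** d["log2_effect"]

    lo, hi = np.log(library_size_range[0]), np.log(library_size_range[1])
    n_types = len(types)
    props = np.zeros((len(design), n_types))
    counts = np.zeros((len(genes), len(design)), dtype=np.int64)
    true_target = np.zeros((len(genes), len(design)))

    for s, (sample, row) in enumerate(design.iterrows()):
        p_t = rng.uniform(*target_purity_range)
        contam = rng.dirichlet(np.ones(n_types - 1)) * (1.0 - p_t)
        p = np.insert(contam, t_idx, p_t)
        props[s] = p

        target_prof = profiles[:, t_idx].copy()
        if row["group"] == de_group:
            target_prof = target_prof * effect_by_time[row["time"]]
            target_prof = target_prof / target_prof.sum()

        mix = np.zeros(len(genes))
        for j in range(n_types):
            prof = target_prof if j == t_idx else profiles[:, j]
            mix += p[j] * prof
        lib = float(np.exp(rng.uniform(lo, hi)))
        counts[:, s] = _nb_draws(rng, lib * mix, dispersion)
        true_target[:, s] = lib * p_t * target_prof

    prop_df = pd.DataFrame(props, index=design.index, columns=types)
    matrix = GeneCountMatrix(
        pd.DataFrame(counts, index=genes.copy(), columns=design.index), design.copy()
    )
    truth = SyntheticTruth(
        cell_type_proportions=prop_df,
        true_target_expression=pd.DataFrame(
            true_target, index=genes.copy(), columns=design.index
        ),
        de_genes=de_genes,
        seed=seed,
    )
    return matrix, truth


def generate_phenotypes(
    truth: SyntheticTruth,
    matrix: GeneCountMatrix,
    n_links: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    phenotypes=PHENOTYPE_PANEL,
) -> pd.DataFrame:
    """Phenotype table with planted monotone transcript links.

    The first ``n_links`` phenotypes are monotone transforms of the
    per-sample rank of a chosen transcript's CPM (planted genes are taken
    from the recorded differential-expression set first), plus Gaussian
    noise of standard deviation ``noise_sd`` on the normalized rank scale
    (the signal spans one unit, so ``noise_sd`` is unit-free). Remaining
    phenotypes are independent of every transcript. ``truth`` is updated
    in place with the planted links.
    """
    phenotypes = list(phenotypes)
    if n_links > len(phenotypes):
        raise InvalidArgumentError("n_links exceeds the phenotype panel size")
    rng = np.random.default_rng(seed)
    cpm = matrix.cpm()
    n = matrix.n_samples

    candidates = [g for g in truth.de_gene_names() if g in matrix.genes]
    extra = [g for g in matrix.genes if g not in set(candidates)]
    rng.shuffle(extra)
    pool = candidates + extra
    if n_links > len(pool):
        raise InvalidArgumentError("not enough genes to link")

    table = pd.DataFrame(index=matrix.samples, columns=phenotypes, dtype=float)
    table.index.name = "sample"
    for i, ph in enumerate(phenotypes):
        base, scale = _PHENOTYPE_SCALE.get(ph, (10.0, 5.0))
        if i < n_links:
            gene = pool[i]
            sign = 1 if rng.random() < 0.5 else -1
            ranks = cpm.loc[gene].rank(method="average").to_numpy()
            values = base + scale * (sign * ranks / n + rng.normal(0, noise_sd, n))
            truth.phenotype_links.append(
                {"phenotype": ph, "gene": gene, "sign": sign, "noise_sd": float(noise_sd)}
            )
        else:
            values = base + rng.normal(0, scale / 4.0, n)
        table[ph] = values
    return table


# plausible (baseline, dynamic range) per phenotype, in the unit of its name
_PHENOTYPE_SCALE = {
    "body_mass_g": (28.0, 18.0),
    "fat_to_lean_ratio": (0.15, 0.55),
    "ewat_mass_g": (0.5, 2.2),
    "liver_mass_g": (1.0, 1.4),
    "ilc2_pct_cd45": (1.0, 2.5),
    "eosinophil_pct_cd45": (2.0, 4.0),
    "m1_macrophage_pct_cd45": (1.5, 3.0),
    "m2_macrophage_pct_cd45": (3.0, 5.0),
    "il25_pg_per_ml": (20.0, 60.0),
    "tnfa_pg_per_ml": (8.0, 25.0),
    "fasting_glucose_mm": (7.0, 6.0),
    "tuft_cells_per_mm2": (4.0, 9.0),
}
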