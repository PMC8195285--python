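"""End-to-end orchestration: configuration, fixture simulation, full runs.

The pipeline composes the stages in the analysis order: reference
summarization -> gene-matrix cleanup -> deconvolution and decontamination
-> per-time-point differential expression -> gene-set/orphan annotation ->
phenotype correlation networks. A run is fully determined by its
configuration and seed; every stage writes plain-text tables plus a JSON
manifest sufficient to re-run the identical analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import GeneCountMatrix, read_counts_tsv, write_counts_tsv, write_json
from .de import sam_de, shared_regulation
from .errors import InvalidArgumentError
from .filtering import apply_filters
from .network import build_network, correlation_screen, spearman_matrix, write_sif
from .pathways import (
    GO_IMMUNE_SYSTEM_PROCESS,
    GO_METABOLIC_PROCESS,
    classify_orphans,
    load_gene_sets,
    load_go_map,
    score_gene_sets,
    write_gene_sets,
)
from .purify import decontaminate, estimate_proportions
from .reference import (
    classify_genes,
    estimate_mode_and_cutoffs,
    pooled_log10_counts,
    summarize_reference,
)
from .synthetic import (
    generate_bulk_mixtures,
    generate_phenotypes,
    generate_reference,
    make_design,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_command"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and toggles of a pipeline run.

    Threshold defaults are the analysis' stated values: prevalence floor of
    3 reads at 20% of cells, 95% read-count mass cutoffs, the >5-reads-in-
    >=6-samples expression filter, 20 Poisson resamples and 200 label
    permutations for DE with q < 0.05 and fold change > 2 or < 0.5, BH
    q < 0.05 for gene sets, and the two correlation regimes (p < 0.05 with
    q < 0.1 for screens; |SCC| > 0.7 with q < 0.05 for the network).
    """

    # input paths
    counts: str = ""
    sample_metadata: str = ""
    reference_counts: str = ""
    reference_cell_types: str = ""
    gene_sets: str = ""
    go_map: str = ""
    phenotypes: str = ""
    output_dir: str = "tuftseq_run"

    # design
    target_type: str = "tuft"
    group_col: str = "group"
    time_col: str = "time"
    numerator: str = "HFD"
    denominator: str = "RFD"

    # stage parameters (analysis defaults)
    prevalence_min_reads: int = 3
    prevalence_threshold: float = 0.2
    cutoff_mass: float = 0.95
    min_markers: int = 5
    min_reads_exclusive: int = 5
    min_samples: int = 6
    n_resamples: int = 20
    n_permutations: int = 200
    de_q_max: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    pathway_permutations: int = 1000
    pathway_min_size: int = 3
    pathway_q_max: float = 0.05
    network_scc_min: float = 0.7
    network_q_max: float = 0.05
    screen_p_max: float = 0.05
    screen_q_max: float = 0.1
    spearman_min_n: int = 5
    n_network_genes: int = 20

    # toggles
    skip_decontamination: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def validate_paths(self) -> None:
        """Fail before any computation if a referenced input is missing."""
        for name in ("counts", "sample_metadata", "reference_counts",
                     "reference_cell_types", "gene_sets", "go_map", "phenotypes"):
            p = getattr(self, name)
            if not p:
                raise InvalidArgumentError(f"config path {name!r} is not set")
            if not Path(p).exists():
                raise InvalidArgumentError(f"config path {name!r} does not exist: {p}")


def _load_reference(config: PipelineConfig) -> ad.AnnData:
    counts = pd.read_csv(config.reference_counts, sep="\t", index_col=0)
    labels = pd.read_csv(config.reference_cell_types, sep="\t", index_col=0)
    adata = ad.AnnData(
        X=counts.T.values,
        obs=pd.DataFrame(
            {"cell_type": labels.loc[counts.columns, "cell_type"].astype("category")},
            index=counts.columns,
        ),
        var=pd.DataFrame(index=counts.index.rename("gene")),
    )
    adata.uns["target_type"] = config.target_type
    return adata


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tuftseq_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str, **kwargs):
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        manifest["outputs"].append(name)
        return path

    # --- reference summarization -------------------------------------------------
    raw_ref = _load_reference(config)
    ref = summarize_reference(
        raw_ref,
        target_type=config.target_type,
        prevalence_min_reads=config.prevalence_min_reads,
        marker_prevalence=config.prevalence_threshold,
    )
    pooled = pooled_log10_counts(raw_ref, config.target_type)
    summary = estimate_mode_and_cutoffs(pooled, mass=config.cutoff_mass)
    labels = classify_genes(ref, prevalence_threshold=config.prevalence_threshold)

    _write(ref.mean_profile, "signature_mean_profile.tsv")
    _write(ref.prevalence, "signature_prevalence.tsv")
    _write(labels.to_frame(), "gene_labels.tsv")
    write_json(dataclasses.asdict(summary), out / "count_distribution.json")
    manifest["outputs"].append("count_distribution.json")
    manifest["stages"]["reference"] = {
        "n_types": len(ref.cell_types),
        "mode_log10": summary.mode_log10,
        "lower_cutoff": summary.lower_cutoff,
        "upper_cutoff": summary.upper_cutoff,
    }

    # --- gene-matrix cleanup ------------------------------------------------------
    bulk = read_counts_tsv(config.counts, config.sample_metadata)
    filtered, report = apply_filters(
        bulk, config.min_reads_exclusive, config.min_samples
    )
    log.info(report.summary_line())
    write_json(report.as_dict(), out / "filter_report.json")
    manifest["outputs"].append("filter_report.json")
    manifest["stages"]["filtering"] = report.as_dict()

    # --- purification -------------------------------------------------------------
    labels_f = labels.reindex(filtered.genes).fillna("shared")
    proportions = estimate_proportions(filtered, ref, min_markers=config.min_markers)
    _write(proportions.proportions, "cell_type_proportions.tsv")
    if config.skip_decontamination:
        analysis_matrix = filtered
        manifest["stages"]["purification"] = {"skipped": True}
    else:
        decon = decontaminate(filtered, proportions, ref, labels_f, summary)
        analysis_matrix = decon.to_matrix(filtered.design)
        _write(decon.corrected_counts, "corrected_counts.tsv")
        _write(decon.per_gene_weight, "decontamination_weights.tsv")
        pd.Series(decon.removed_genes, name="gene").to_frame().to_csv(
            out / "removed_genes.tsv", sep="\t", index=False
        )
        manifest["outputs"].append("removed_genes.tsv")
        write_json(
            {
                "target_read_fraction": decon.target_read_fraction.to_dict(),
                "residual_norm": proportions.residual_norm.to_dict(),
                "n_removed_genes": len(decon.removed_genes),
            },
            out / "decontamination_report.json",
        )
        manifest["outputs"].append("decontamination_report.json")
        manifest["stages"]["purification"] = {
            "n_removed_genes": len(decon.removed_genes),
            "mean_target_read_fraction": float(decon.target_read_fraction.mean()),
        }

    # --- differential expression per time point ----------------------------------
    times = list(pd.unique(analysis_matrix.design[config.time_col]))
    de_tables: dict = {}
    for i, tp in enumerate(times):
        sub = analysis_matrix.subset_samples(
            analysis_matrix.samples[
                (analysis_matrix.design[config.time_col] == tp).to_numpy()
            ]
        )
        de = sam_de(
            sub,
            numerator=config.numerator,
            denominator=config.denominator,
            group_col=config.group_col,
            n_resamples=config.n_resamples,
            n_permutations=config.n_permutations,
            q_max=config.de_q_max,
            fc_up=config.fc_up,
            fc_down=config.fc_down,
            seed=config.seed + 1000 + i,
        )
        de_tables[tp] = de
        _write(de, f"de_{tp}.tsv")
        manifest["stages"][f"de_{tp}"] = {
            "n_up": int((de["direction"] == "up").sum()),
            "n_down": int((de["direction"] == "down").sum()),
        }
    if len(times) >= 2:
        shared = shared_regulation(de_tables[times[0]], de_tables[times[1]])
        _write(shared, "shared_regulation.tsv")
        manifest["stages"]["shared_regulation"] = {
            "n_shared": int(len(shared)),
            "n_concordant": int(shared["concordant"].sum()) if len(shared) else 0,
        }

    # --- pathways and orphans -----------------------------------------------------
    gene_sets = load_gene_sets(config.gene_sets)
    go_map = load_go_map(config.go_map)
    for i, tp in enumerate(times):
        scored = score_gene_sets(
            de_tables[tp]["statistic"],
            gene_sets,
            n_permutations=config.pathway_permutations,
            min_size=config.pathway_min_size,
            q_max=config.pathway_q_max,
            seed=config.seed + 2000 + i,
        )
        _write(scored, f"pathways_{tp}.tsv")
        manifest["stages"][f"pathways_{tp}"] = {
            "n_scored": int(len(scored)),
            "n_significant": int((scored["direction"] != "none").sum())
            if len(scored)
            else 0,
        }
    de_called = sorted(
        set().union(
            *[t.index[t["direction"] != "none"].tolist() for t in de_tables.values()]
        )
    )
    orphans = classify_orphans(de_called, gene_sets, go_map)
    _write(orphans, "orphan_genes.tsv")
    manifest["stages"]["orphans"] = {
        "n_de_genes": len(de_called),
        "n_orphans": int(orphans["is_orphan"].sum()) if len(orphans) else 0,
    }

    # --- correlation networks per time point --------------------------------------
    phenotypes = pd.read_csv(config.phenotypes, sep="\t", index_col=0)
    cpm_all = analysis_matrix.cpm()
    for tp in times:
        tp_samples = analysis_matrix.samples[
            (analysis_matrix.design[config.time_col] == tp).to_numpy()
        ]
        de = de_tables[tp]
        focus = de.reindex(de["statistic"].abs().sort_values(ascending=False).index)
        genes = focus.index[focus["direction"] != "none"][: config.n_network_genes]
        if len(genes) == 0:
            genes = focus.index[: config.n_network_genes]
        variables = pd.concat(
            [cpm_all.loc[genes, tp_samples].T, phenotypes.loc[tp_samples]], axis=1
        )
        scc, p, q = spearman_matrix(variables, min_n=config.spearman_min_n)
        edges = build_network(
            scc, p, q, scc_min=config.network_scc_min, q_max=config.network_q_max
        )
        screen = correlation_screen(
            scc, p, q, p_max=config.screen_p_max, q_max=config.screen_q_max
        )
        _write(edges, f"network_edges_{tp}.tsv", index=False)
        _write(screen, f"correlation_screen_{tp}.tsv", index=False)
        write_sif(edges, out / f"network_{tp}.sif", out / f"network_{tp}_attributes.tsv")
        manifest["outputs"].extend([f"network_{tp}.sif", f"network_{tp}_attributes.tsv"])
        manifest["stages"][f"network_{tp}"] = {
            "n_edges": int(len(edges)),
            "n_flagged": int(screen["flagged"].sum()) if len(screen) else 0,
        }

    write_json(manifest, out / "manifest.json")
    return manifest


def simulate_command(
    output_dir,
    n_cell_types: int = 8,
    n_genes: int = 2000,
    cells_per_type: int = 50,
    marker_fraction: float = 0.05,
    replicates: int = 6,
    target_purity_range: tuple = (0.6, 0.9),
    n_de: int = 60,
    effect_log2: float = 2.0,
    dispersion: float = 0.1,
    n_links: int = 6,
    noise_sd: float = 0.05,
    n_gene_sets: int = 25,
    seed: int = 0,
    force: bool = False,
) -> PipelineConfig:
    """Write a complete synthetic input bundle ready for :func:`run_pipeline`.

    Produces reference counts and cell labels, bulk counts and sample
    metadata, phenotypes, a toy GMT of random gene sets, a toy GO map,
    the ground-truth JSON and a ready-to-run config YAML. Refuses to write
    into a non-empty directory unless ``force``.
    """
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise InvalidArgumentError(
            f"output directory {out} exists and is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    reference = generate_reference(
        n_cell_types=n_cell_types,
        n_genes=n_genes,
        cells_per_type=cells_per_type,
        marker_fraction=marker_fraction,
        seed=seed,
    )
    design = make_design(replicates=replicates)
    matrix, truth = generate_bulk_mixtures(
        reference,
        design,
        target_purity_range=target_purity_range,
        n_de=n_de,
        effect_log2=effect_log2,
        dispersion=dispersion,
        seed=seed + 1,
    )
    phenotypes = generate_phenotypes(
        truth, matrix, n_links=n_links, noise_sd=noise_sd, seed=seed + 2
    )

    # reference as genes x cells TSV plus a cell-type table
    ref_counts = pd.DataFrame(
        np.asarray(reference.X).T, index=reference.var_names.rename("gene"),
        columns=reference.obs_names,
    )
    ref_counts.to_csv(out / "reference_counts.tsv", sep="\t")
    labels = reference.obs[["cell_type"]].copy()
    labels.index.name = "cell"
    labels.to_csv(out / "reference_cell_types.tsv", sep="\t")

    write_counts_tsv(matrix, out / "counts.tsv", out / "sample_metadata.tsv")
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    truth.to_json(out / "truth.json")

    # toy gene sets over the simulated universe; coverage is deliberately
    # partial so that orphan genes exist, and the first few sets are
    # enriched in planted DE genes so set-level signal is recoverable
    genes = list(matrix.genes)
    # coherent pools: a set of co-upregulated (or co-downregulated) genes
    # carries a nonzero mean statistic, unlike a mixed-direction draw
    up_pool = sorted({d["gene"] for d in truth.de_genes if d["direction"] == "up"})
    down_pool = sorted({d["gene"] for d in truth.de_genes if d["direction"] == "down"})
    sets = {}
    for i in range(n_gene_sets):
        size = int(rng.integers(5, 41))
        de_pool = up_pool if i % 2 == 0 else down_pool
        if i < 3 and len(de_pool) >= 8:
            core = rng.choice(de_pool, size=8, replace=False).tolist()
            rest = rng.choice(genes, size=max(size - 8, 2), replace=False).tolist()
            members = list(dict.fromkeys(core + rest))
        else:
            members = rng.choice(genes, size=size, replace=False).tolist()
        sets[f"PATHWAY_{i + 1:03d}"] = members
    write_gene_sets(sets, out / "gene_sets.gmt")

    # toy GO map: the two broad branches assigned at plausible coverage
    lines = []
    for g in genes:
        if rng.random() < 0.35:
            lines.append(f"{g}\t{GO_METABOLIC_PROCESS}")
        if rng.random() < 0.20:
            lines.append(f"{g}\t{GO_IMMUNE_SYSTEM_PROCESS}")
    (out / "go_map.tsv").write_text("\n".join(lines) + "\n")

    config = PipelineConfig(
        counts=str(out / "counts.tsv"),
        sample_metadata=str(out / "sample_metadata.tsv"),
        reference_counts=str(out / "reference_counts.tsv"),
        reference_cell_types=str(out / "reference_cell_types.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        go_map=str(out / "go_map.tsv"),
        phenotypes=str(out / "phenotypes.tsv"),
        output_dir=str(out / "results"),
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
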