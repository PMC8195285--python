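"""Generator contracts: determinism, marker structure, mixture arithmetic,
planted effects and phenotype links."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tuftseq.errors import InvalidArgumentError
from tuftseq.synthetic import (
    generate_bulk_mixtures,
    generate_phenotypes,
    generate_reference,
    make_design,
)


class TestGenerateReference:
    def test_marker_blocks_are_disjoint_and_sized(self):
        ref = generate_reference(2, 100, 50, 0.1, seed=1)
        markers = ref.uns["marker_sets"]
        assert ref.n_obs == 100
        assert all(len(v) == 10 for v in markers.values())
        sets = [set(v) for v in markers.values()]
        assert not (sets[0] & sets[1])

    def test_same_seed_is_bit_identical(self):
        a = generate_reference(3, 200, 20, 0.1, seed=7)
        b = generate_reference(3, 200, 20, 0.1, seed=7)
        assert np.array_equal(a.X, b.X)
        assert list(a.obs["cell_type"]) == list(b.obs["cell_type"])

    def test_marker_mean_dominates_other_types(self, small_reference):
        ref = small_reference
        X = np.asarray(ref.X)
        labels = ref.obs["cell_type"].astype(str).to_numpy()
        for t, markers in ref.uns["marker_sets"].items():
            own = X[labels == t][:, [ref.var_names.get_loc(g) for g in markers]].mean()
            other = X[labels != t][:, [ref.var_names.get_loc(g) for g in markers]].mean()
            assert own >= 10 * max(other, 1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cell_types=1),
            dict(n_genes=40),
            dict(cells_per_type=0),
            dict(marker_fraction=0.6),
            dict(marker_fraction=0.0),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        args = dict(n_cell_types=3, n_genes=200, cells_per_type=10, marker_fraction=0.1)
        args.update(kwargs)
        with pytest.raises(InvalidArgumentError):
            generate_reference(**args, seed=0)


class TestGenerateBulkMixtures:
    def test_pure_low_noise_sample_matches_target_profile(self, small_reference):
        design = make_design(times=("9w",), replicates=3)
        m, truth = generate_bulk_mixtures(
            small_reference,
            design,
            target_purity_range=(1.0, 1.0),
            n_de=0,
            dispersion=0.0,
            library_size_range=(5e6, 5e6),
            seed=2,
        )
        means = np.asarray(small_reference.varm["true_mean"])
        t_idx = small_reference.uns["cell_types"].index("tuft")
        profile = means[:, t_idx] / means[:, t_idx].sum()
        observed = m.counts.mean(axis=1).to_numpy()
        np.testing.assert_allclose(observed / observed.sum(), profile, atol=2e-4)
        assert truth.de_genes == []

    def test_planted_two_fold_change_recovered(self, small_reference):
        design = make_design(times=("9w",), replicates=12)
        m, truth = generate_bulk_mixtures(
            small_reference,
            design,
            target_purity_range=(1.0, 1.0),
            n_de=1,
            effect_log2=1.0,
            dispersion=0.1,
            library_size_range=(1e6, 1e6),
            seed=3,
        )
        (record,) = [d for d in truth.de_genes]
        hfd = m.design["group"] == "HFD"
        gene = m.counts.loc[record["gene"]]
        ratio = gene[hfd.values].mean() / gene[(~hfd).values].mean()
        expected = 2.0 ** record["log2_effect"]
        assert abs(ratio - expected) / expected < 0.10

    def test_mixture_conserves_library_size(self, small_reference):
        design = make_design(times=("9w",), replicates=12)
        m, truth = generate_bulk_mixtures(
            small_reference,
            design,
            target_purity_range=(0.7, 0.7),
            n_de=0,
            dispersion=0.05,
            seed=4,
        )
        # library size is recoverable from the recorded target expression
        p_t = truth.cell_type_proportions["tuft"]
        lib = truth.true_target_expression.sum(axis=0) / p_t
        total = m.counts.sum(axis=0)
        dev = np.abs(total / lib - 1.0)
        # per-sample totals fluctuate with the NB noise of the largest genes
        assert dev.mean() < 0.03
        assert dev.max() < 0.10

    def test_proportions_sum_to_one_and_seed_determinism(self, small_reference):
        design = make_design(times=("9w",), replicates=3)
        m1, t1 = generate_bulk_mixtures(small_reference, design, seed=5)
        m2, t2 = generate_bulk_mixtures(small_reference, design, seed=5)
        np.testing.assert_allclose(
            t1.cell_type_proportions.sum(axis=1), 1.0, atol=1e-9
        )
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        assert t1.de_genes == t2.de_genes

    def test_planted_genes_exist_in_universe(self, small_mixture):
        m, truth = small_mixture
        assert set(truth.de_gene_names()) <= set(m.genes)

    def test_too_many_de_genes_rejected(self, small_reference):
        design = make_design(times=("9w",), replicates=3)
        with pytest.raises(InvalidArgumentError):
            generate_bulk_mixtures(small_reference, design, n_de=10_000, seed=0)

    def test_attenuation_at_half_purity_matches_closed_form(self, small_reference):
        """With 50% contamination the realized fold change of a planted gene
        attenuates toward (p*w*f + (1-p)*c) / (p*f + (1-p)*c)."""
        design = make_design(times=("9w",), replicates=12)
        m, truth = generate_bulk_mixtures(
            small_reference,
            design,
            target_purity_range=(0.5, 0.5),
            n_de=1,
            effect_log2=2.0,
            dispersion=0.05,
            library_size_range=(1e6, 1e6),
            seed=6,
        )
        (record,) = truth.de_genes
        gi = m.genes.get_loc(record["gene"])
        means = np.asarray(small_reference.varm["true_mean"])
        profiles = means / means.sum(axis=0)
        types = small_reference.uns["cell_types"]
        t_idx = types.index("tuft")
        w = 2.0 ** record["log2_effect"]
        f = profiles[gi, t_idx]
        hfd = (m.design["group"] == "HFD").to_numpy()
        # per-sample expected contaminant abundance from recorded proportions
        props = truth.cell_type_proportions
        c = np.array(
            [
                sum(
                    props.iloc[s, j] * profiles[gi, j]
                    for j in range(len(types))
                    if j != t_idx
                )
                for s in range(len(props))
            ]
        )
        # planted-profile renormalization factor is ~1 for a single gene
        expected = (0.5 * w * f + c[hfd].mean()) / (0.5 * f + c[~hfd].mean())
        gene = m.counts.iloc[gi]
        ratio = gene[hfd].mean() / gene[~hfd].mean()
        assert abs(ratio - expected) / expected < 0.15
        assert ratio < w  # attenuated relative to the pure-sample effect


class TestGeneratePhenotypes:
    def test_noiseless_link_gives_perfect_rank_correlation(self, small_mixture):
        m, truth = small_mixture
        truth.phenotype_links = []
        table = generate_phenotypes(truth, m, n_links=4, noise_sd=0.0, seed=9)
        cpm = m.cpm()
        for link in truth.phenotype_links:
            rho, _ = spearmanr(table[link["phenotype"]], cpm.loc[link["gene"]])
            assert rho == pytest.approx(link["sign"] * 1.0)

    def test_unlinked_phenotypes_stay_below_network_threshold(self, small_mixture):
        m, truth = small_mixture
        cpm = m.cpm()
        gene = cpm.iloc[0]
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            t = SimpleTruth()
            table = generate_phenotypes(t, m, n_links=0, noise_sd=0.0, seed=seed)
            rho, _ = spearmanr(table["body_mass_g"], gene)
            hits += abs(rho) >= 0.7
        assert hits / n_seeds <= 0.05

    def test_seed_determinism(self, small_mixture):
        m, truth = small_mixture
        a = generate_phenotypes(SimpleTruth(), m, n_links=2, noise_sd=0.1, seed=3)
        b = generate_phenotypes(SimpleTruth(), m, n_links=2, noise_sd=0.1, seed=3)
        pd.testing.assert_frame_equal(a, b)


class SimpleTruth:
    """Minimal truth stand-in for phenotype generation tests."""

    def __init__(self):
        self.phenotype_links = []

    def de_gene_names(self, time=None):
        return []
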