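"""Deconvolution and decontamination: exact arithmetic on constructed
signatures and recovery on simulated mixtures."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from tuftseq.errors import (
    InsufficientDataError,
    InsufficientMarkersError,
    InvalidArgumentError,
)
from tuftseq.purify import (
    decontaminate,
    estimate_proportions,
    estimate_target_read_fraction,
)
from tuftseq.reference import (
    CountDistributionSummary,
    classify_genes,
    estimate_mode_and_cutoffs,
    pooled_log10_counts,
    summarize_reference,
)
from tuftseq.synthetic import generate_bulk_mixtures, generate_reference, make_design

LOW_SUMMARY = CountDistributionSummary(1.0, 0.0, 2.0)  # lower cutoff admits all


def _mixture_matrix(signature, weights_by_sample, scale=1000.0):
    """Bulk counts as exact mixtures of the signature's relative profiles."""
    rel = signature.relative_profile()
    cols = {}
    for sample, w in weights_by_sample.items():
        cols[sample] = scale * sum(
            w[t] * rel[t].to_numpy() for t in signature.cell_types
        )
    counts = pd.DataFrame(cols, index=rel.index)
    return make_matrix(counts.values, rel.index, list(weights_by_sample))


class TestEstimateProportions:
    def test_pure_target_sample(self, two_type_signature):
        m = _mixture_matrix(two_type_signature, {"s1": {"tuft": 1.0, "enterocyte": 0.0}})
        est = estimate_proportions(m, two_type_signature)
        assert est.proportions.loc["s1", "tuft"] == pytest.approx(1.0, abs=1e-9)
        assert est.proportions.loc["s1", "enterocyte"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_sixty_forty_mixture(self, two_type_signature):
        m = _mixture_matrix(two_type_signature, {"s1": {"tuft": 0.6, "enterocyte": 0.4}})
        est = estimate_proportions(m, two_type_signature)
        assert est.proportions.loc["s1", "tuft"] == pytest.approx(0.6, abs=1e-6)
        assert est.proportions.loc["s1", "enterocyte"] == pytest.approx(0.4, abs=1e-6)

    def test_rows_on_simplex_and_deterministic(self, small_mixture, small_reference):
        m, _ = small_mixture
        ref = summarize_reference(small_reference)
        a = estimate_proportions(m, ref)
        b = estimate_proportions(m, ref)
        np.testing.assert_allclose(a.proportions.sum(axis=1), 1.0, atol=1e-9)
        assert (a.proportions.values >= 0).all()
        pd.testing.assert_frame_equal(a.proportions, b.proportions)

    def test_missing_markers_error_names_the_type(self, two_type_signature):
        # bulk matrix without any enterocyte markers
        genes = two_type_signature.marker_sets["tuft"]
        m = make_matrix(np.ones((len(genes), 2)), genes, ["s1", "s2"])
        with pytest.raises(InsufficientMarkersError, match="enterocyte"):
            estimate_proportions(m, two_type_signature)


class TestTargetReadFraction:
    def test_pure_target_gives_one(self, two_type_signature):
        # reads fall on genes the target expresses, as in a truly pure sample
        expressed = two_type_signature.mean_profile["tuft"] > 0
        counts = pd.Series(0.0, index=two_type_signature.mean_profile.index)
        counts[expressed] = 100.0
        p = pd.Series({"tuft": 1.0, "enterocyte": 0.0})
        f = estimate_target_read_fraction(counts, p, two_type_signature, LOW_SUMMARY)
        assert f == pytest.approx(1.0)

    def test_two_equal_genes_with_opposite_shares(self, two_type_signature):
        # sh1 is tuft-exclusive (share 1), sh3 enterocyte-exclusive (share 0)
        counts = pd.Series(0.0, index=two_type_signature.mean_profile.index)
        counts[["sh1", "sh3"]] = 500.0
        p = pd.Series({"tuft": 0.5, "enterocyte": 0.5})
        f = estimate_target_read_fraction(counts, p, two_type_signature, LOW_SUMMARY)
        assert f == pytest.approx(0.5)

    def test_monotone_in_target_proportion(self, two_type_signature):
        counts = pd.Series(50.0, index=two_type_signature.mean_profile.index)
        fractions = [
            estimate_target_read_fraction(
                counts,
                pd.Series({"tuft": pt, "enterocyte": 1 - pt}),
                two_type_signature,
                LOW_SUMMARY,
            )
            for pt in np.linspace(0.1, 1.0, 10)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_no_passing_gene_raises(self, two_type_signature):
        counts = pd.Series(0.0, index=two_type_signature.mean_profile.index)
        p = pd.Series({"tuft": 0.5, "enterocyte": 0.5})
        strict = CountDistributionSummary(5.0, 4.0, 6.0)
        with pytest.raises(InsufficientDataError):
            estimate_target_read_fraction(counts, p, two_type_signature, strict)


class TestDecontaminate:
    @staticmethod
    def _setup(two_type_signature, weights):
        m = _mixture_matrix(two_type_signature, weights)
        est = estimate_proportions(m, two_type_signature)
        labels = classify_genes(two_type_signature)
        return m, est, labels

    def test_equal_profiles_at_half_purity_halve_counts(self, two_type_signature):
        # gene sh0 has identical mean in both types; single sample so f_s = f_mean
        m, est, labels = self._setup(
            two_type_signature, {"s1": {"tuft": 0.5, "enterocyte": 0.5}}
        )
        res = decontaminate(m, est, two_type_signature, labels, LOW_SUMMARY)
        raw = m.counts.loc["sh0", "s1"]
        assert res.corrected_counts.loc["sh0", "s1"] == pytest.approx(0.5 * raw, rel=1e-6)

    def test_target_exclusive_gene_unchanged(self, two_type_signature):
        m, est, labels = self._setup(
            two_type_signature, {"s1": {"tuft": 0.5, "enterocyte": 0.5}}
        )
        res = decontaminate(m, est, two_type_signature, labels, LOW_SUMMARY)
        assert res.corrected_counts.loc["sh1", "s1"] == pytest.approx(
            m.counts.loc["sh1", "s1"]
        )

    def test_removed_set_is_nontarget_labels_plus_nontarget_markers(
        self, two_type_signature
    ):
        m, est, labels = self._setup(
            two_type_signature, {"s1": {"tuft": 0.5, "enterocyte": 0.5}}
        )
        res = decontaminate(m, est, two_type_signature, labels, LOW_SUMMARY)
        expected = set(labels.index[labels == "non-target"]) | set(
            two_type_signature.non_target_markers()
        )
        assert set(res.removed_genes) == expected & set(m.genes)
        assert not set(res.removed_genes) & set(res.corrected_counts.index)

    def test_contraction_and_weight_bounds(self, small_mixture, small_reference):
        m, _ = small_mixture
        ref = summarize_reference(small_reference)
        summary = estimate_mode_and_cutoffs(pooled_log10_counts(small_reference, "tuft"))
        labels = classify_genes(ref)
        est = estimate_proportions(m, ref)
        res = decontaminate(m, est, ref, labels, summary)
        raw = m.counts.loc[res.corrected_counts.index]
        assert (res.corrected_counts.values <= raw.values + 1e-9).all()
        assert ((res.per_gene_weight.values >= 0) & (res.per_gene_weight.values <= 1)).all()
        assert ((res.target_read_fraction >= 0) & (res.target_read_fraction <= 1)).all()

    def test_purity_limit_recovers_raw_counts(self, small_reference):
        design = make_design(times=("9w",), replicates=3)
        m, _ = generate_bulk_mixtures(
            small_reference, design, target_purity_range=(1.0, 1.0),
            n_de=0, dispersion=0.05, seed=8,
        )
        ref = summarize_reference(small_reference)
        labels = classify_genes(ref)
        est = estimate_proportions(m, ref)
        res = decontaminate(m, est, ref, labels, LOW_SUMMARY)
        raw = m.counts.loc[res.corrected_counts.index].astype(float)
        # estimated purity is ~1 (up to deconvolution noise), so shares are
        # ~1 and f_s/f_mean ~ 1
        np.testing.assert_allclose(res.corrected_counts.values, raw.values, rtol=0.05)
        rel = np.abs(res.corrected_counts.values - raw.values) / np.maximum(raw.values, 1)
        assert np.median(rel) < 1e-6

    def test_incomplete_labels_rejected(self, two_type_signature):
        m, est, labels = self._setup(
            two_type_signature, {"s1": {"tuft": 0.5, "enterocyte": 0.5}}
        )
        with pytest.raises(InvalidArgumentError):
            decontaminate(m, est, two_type_signature, labels.iloc[:3], LOW_SUMMARY)
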