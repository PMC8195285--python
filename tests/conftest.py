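import numpy as np
import pandas as pd
import pytest

from tuftseq.data import GeneCountMatrix
from tuftseq.reference import SignatureReference
from tuftseq.synthetic import generate_bulk_mixtures, generate_reference, make_design


@pytest.fixture(scope="session")
def small_reference():
    """3-type, 200-gene reference, 30 cells/type: fast but structured."""
    return generate_reference(
        n_cell_types=3, n_genes=200, cells_per_type=30, marker_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_mixture(small_reference):
    design = make_design(times=("9w",), replicates=6)
    return generate_bulk_mixtures(
        small_reference,
        design,
        target_purity_range=(0.6, 0.9),
        n_de=10,
        effect_log2=2.0,
        dispersion=0.1,
        seed=11,
    )


@pytest.fixture
def two_type_signature():
    """Hand-built two-type signature for exact deconvolution arithmetic.

    10 marker genes per type plus 4 shared genes; mean profiles chosen so
    the expected values in tests are simple closed forms.
    """
    genes = [f"tm{i}" for i in range(10)] + [f"cm{i}" for i in range(10)] + [
        "sh0", "sh1", "sh2", "sh3"
    ]
    mean = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=["tuft", "enterocyte"])
    mean.loc[[f"tm{i}" for i in range(10)], "tuft"] = 20.0
    mean.loc[[f"cm{i}" for i in range(10)], "enterocyte"] = 20.0
    # equal per-type totals (225) keep relative and absolute profiles
    # proportional, so share arithmetic has simple closed forms
    mean.loc[["sh0", "sh1", "sh2", "sh3"], "tuft"] = [10.0, 10.0, 5.0, 0.0]
    mean.loc[["sh0", "sh1", "sh2", "sh3"], "enterocyte"] = [10.0, 0.0, 5.0, 10.0]
    prevalence = (mean > 0).astype(float).clip(upper=0.9)
    prevalence[mean > 0] = 0.9
    markers = {
        "tuft": [f"tm{i}" for i in range(10)],
        "enterocyte": [f"cm{i}" for i in range(10)],
    }
    return SignatureReference(mean, prevalence, markers, "tuft")


def make_matrix(counts: np.ndarray, genes, samples, groups=None, times=None):
    design = pd.DataFrame(index=pd.Index(samples, name="sample"))
    if groups is not None:
        design["group"] = groups
    if times is not None:
        design["time"] = times
    return GeneCountMatrix(
        pd.DataFrame(np.asarray(counts), index=pd.Index(genes, name="gene"), columns=samples),
        design,
    )
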