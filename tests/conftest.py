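import numpy as np
import pandas as pd
import pytest

from surfaceomics import (
    Catalogue,
    ExpressionDataset,
    GeneAnnotation,
    SampleMeta,
    SimulationConfig,
    fixture_reference_tables,
)


@pytest.fixture(scope="session")
def reference_tables():
    return fixture_reference_tables()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation: fast enough for per-test use."""
    return SimulationConfig(seed=7, n_genes=400, n_surfaceome=80)


@pytest.fixture
def tiny_catalogue():
    return Catalogue(
        [
            GeneAnnotation("BSG", True, "Receptors", "IG", True, False, True),
            GeneAnnotation("SLC16A1", True, "Transporters", "SLC", False, False, True),
            GeneAnnotation("FGFR1", True, "Receptors", "RTK", True, True, True),
            GeneAnnotation("MRC1", True, "Receptors", "SCAR", False, False, False),
            GeneAnnotation(
                "ORPHAN", True, None, None, False, False, True
            ),
            GeneAnnotation("ACTB", False),
            GeneAnnotation("GAPDH", False),
        ]
    )


@pytest.fixture
def eight_gene_dataset():
    """8 genes x 2 samples, expression chosen so tiers are hand-enumerable.

    Per sample the 8 genes are a permutation of 1..8, so ecdf quantiles
    are k/8 and each quartile holds exactly two genes. BSG and SLC16A1
    are the only surfaceome genes (per ``tiny_catalogue``); BSG sits in
    Q4, SLC16A1 in Q1.
    """
    values = pd.DataFrame(
        {
            "s1": [8.0, 1.0, 5.0, 6.0, 7.0, 2.0, 3.0, 4.0],
            "s2": [7.0, 2.0, 6.0, 5.0, 8.0, 1.0, 4.0, 3.0],
        },
        index=pd.Index(
            ["BSG", "SLC16A1", "G1", "G2", "G3", "G4", "G5", "G6"], name="symbol"
        ),
    )
    samples = (
        SampleMeta("s1", "demo", "neg"),
        SampleMeta("s2", "demo", "neg"),
    )
    return ExpressionDataset(values=values, samples=samples, dataset_id="demo")


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
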