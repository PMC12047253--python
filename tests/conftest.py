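import numpy as np
import pandas as pd
import pytest

import longsnv as L


@pytest.fixture(scope="session")
def default_sim():
    """Reference synthetic dataset (default study conditions, seed 7)."""
    return L.simulate(L.SimConfig())


@pytest.fixture(scope="session")
def default_resources(default_sim):
    return L.AnnotationResources(gnomad_freq=default_sim.gnomad_freq)


@pytest.fixture(scope="session")
def default_result(default_sim, default_resources):
    """Full two-pass pipeline run on the reference dataset, with scWGS."""
    return L.run_pipeline(default_sim.table, default_resources,
                          fusion_table=default_sim.fusion_table,
                          scwgs_clone_counts=default_sim.clone_counts)


def make_table(rows, cell_types, droplets=()):
    """Build a BaseCountTable from (chrom, pos, ref, barcode, A, C, G, T, other)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "barcode",
                                     "A", "C", "G", "T", "other"])
    return L.BaseCountTable(df, cell_types, droplet_barcodes=droplets)


@pytest.fixture
def tiny_table():
    """Two cancer + two noncancer cells over two nuclear loci."""
    rows = [
        ("chr1", 100, "A", "c1", 2, 4, 0, 0, 0),
        ("chr1", 100, "A", "c2", 3, 3, 0, 0, 0),
        ("chr1", 100, "A", "n1", 6, 0, 0, 0, 0),
        ("chr1", 100, "A", "n2", 5, 0, 0, 0, 0),
        ("chr1", 50_000, "G", "c1", 0, 0, 5, 0, 0),
        ("chr1", 50_000, "G", "n1", 0, 0, 7, 0, 0),
    ]
    return make_table(rows, {"c1": "cancer", "c2": "cancer",
                             "n1": "noncancer", "n2": "noncancer"})
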