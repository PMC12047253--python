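"""Single-cell genotyping, MCF, and the cell-variant matrix."""

import numpy as np
import pandas as pd
import pytest

import longsnv as L
from longsnv.fusions import FusionCall
from longsnv.genotyping import (MISSING, MUTATED, WILDTYPE, build_matrix,
                                genotype_cell_mt, genotype_cell_snv)
from longsnv.snv_calling import VariantRecord
from tests.conftest import make_table


def test_genotype_snv_rules():
    assert genotype_cell_snv(0, 0) == MISSING
    assert genotype_cell_snv(0, 10) == WILDTYPE          # p = 1
    assert genotype_cell_snv(6, 4) == MUTATED            # tail << 0.01


@pytest.mark.parametrize("alt,depth,expected", [
    (31, 100, MUTATED),    # VAF 0.31
    (30, 100, WILDTYPE),   # VAF 0.30 exactly: strict >
    (0, 0, MISSING),
])
def test_genotype_mt_vaf_threshold(alt, depth, expected):
    assert genotype_cell_mt(alt, depth) == expected


def test_compute_mcf_counts_covered_cells_only():
    """6 mutated of 8 covered of 10 group cells -> MCF 0.75."""
    rows = []
    for i in range(6):
        rows.append(("chr1", 100, "A", f"m{i}", 5, 5, 0, 0, 0))   # mutated
    for i in range(2):
        rows.append(("chr1", 100, "A", f"w{i}", 10, 0, 0, 0, 0))  # wildtype
    ct = {f"m{i}": "cancer" for i in range(6)}
    ct.update({f"w{i}": "cancer" for i in range(2)})
    ct.update({f"u{i}": "cancer" for i in range(2)})   # no coverage
    t = make_table(rows, ct)
    mcf, n_cov, flag = L.compute_mcf(t, "chr1", 100, "A", "C", set(ct))
    assert mcf == pytest.approx(0.75) and n_cov == 8 and not flag


def test_compute_mcf_no_coverage_flag():
    t = make_table([("chr1", 100, "A", "c1", 5, 5, 0, 0, 0)], {"c1": "cancer",
                                                               "c2": "cancer"})
    mcf, n_cov, flag = L.compute_mcf(t, "chr2", 100, "A", "C", {"c2"})
    assert mcf == 0.0 and n_cov == 0 and flag


def test_compute_mcf_all_covered_mutated():
    t = make_table([("chr1", 100, "A", "c1", 0, 10, 0, 0, 0)], {"c1": "cancer"})
    mcf, n_cov, _ = L.compute_mcf(t, "chr1", 100, "A", "C", {"c1"})
    assert mcf == 1.0 and n_cov == 1


# -- matrix ----------------------------------------------------------------

def _matrix_fixture(n_cells_covering_snv=6, fusion_cells=3):
    """One SNV row, one fusion row, over 8 cells with tunable coverage."""
    cells = [f"c{i}" for i in range(8)]
    rows = []
    for i in range(n_cells_covering_snv):
        alt = 8 if i % 2 == 0 else 0
        rows.append(("chr1", 100, "A", cells[i], 10 - alt, alt, 0, 0, 0))
    # a second SNV so every cell keeps >= 3 variants via fusions
    for bc in cells:
        rows.append(("chr1", 50_000, "G", bc, 0, 0, 10, 0, 0))
        rows.append(("chr1", 90_000, "T", bc, 0, 0, 0, 10, 0))
    ct = {bc: "cancer" for bc in cells}
    t = make_table(rows, ct)
    snvs = [VariantRecord("chr1", 100, "A", "C"),
            VariantRecord("chr1", 50_000, "G", "A"),
            VariantRecord("chr1", 90_000, "T", "A")]
    fus = [FusionCall("F--G", frozenset(cells[:fusion_cells]))]
    return t, snvs, fus


def test_matrix_row_filters_snv_5_fusion_3():
    t, snvs, fus = _matrix_fixture(n_cells_covering_snv=4)  # SNV in 4 cells
    m = build_matrix(snvs, [], fus, t)
    assert "chr1:100:A>C" not in m.values.index          # < 5 cells
    assert "F--G" in m.values.index                      # 3 cells: inclusive
    t2, snvs2, fus2 = _matrix_fixture(n_cells_covering_snv=5, fusion_cells=2)
    m2 = build_matrix(snvs2, [], fus2, t2)
    assert "chr1:100:A>C" in m2.values.index
    assert "F--G" not in m2.values.index                 # 2 detected cells


def test_matrix_column_filter_drops_sparse_cells():
    t, snvs, fus = _matrix_fixture()
    # a ninth cell covering only 2 variants
    extra = t.counts.iloc[:0]
    rows = pd.DataFrame([("chr1", 50_000, "G", "c8", 0, 0, 10, 0, 0),
                         ("chr1", 90_000, "T", "c8", 0, 0, 0, 10, 0)],
                        columns=t.counts.columns)
    ct = dict(t.cell_types, c8="cancer")
    t2 = L.BaseCountTable(pd.concat([t.counts, rows]), ct)
    m = build_matrix(snvs, [], [], t2, min_cell_variants=3)
    assert "c8" not in m.values.columns


def test_matrix_missing_state_and_fusion_never_missing():
    t, snvs, fus = _matrix_fixture(n_cells_covering_snv=6)
    m = build_matrix(snvs, [], fus, t)
    row = m.values.loc["chr1:100:A>C"]
    assert (row[["c6", "c7"]] == MISSING).all()
    assert (m.values.loc["F--G"] != MISSING).all()


def test_matrix_filters_reach_fixed_point(default_sim, default_result):
    m = default_result.matrix
    kinds = m.variant_meta.set_index("variant")["kind"]
    row_cov = m.row_coverage()
    det = (m.values == MUTATED).sum(axis=1)
    for vid in m.values.index:
        if kinds[vid] == "fusion":
            assert det[vid] >= 3
        else:
            assert row_cov[vid] >= 5
    assert (m.col_coverage() >= 3).all()


def test_matrix_tsv_roundtrip(tmp_path, default_result):
    m = default_result.matrix
    path = tmp_path / "matrix.tsv"
    m.to_tsv(path)
    back = L.CellVariantMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(back.values, m.values)


def test_empty_matrix_warns():
    t = make_table([("chr1", 100, "A", "c1", 5, 5, 0, 0, 0)], {"c1": "cancer"})
    with pytest.warns(RuntimeWarning):
        m = build_matrix([], [], [], t)
    assert m.n_variants == 0


def test_two_subclone_structure_separable():
    """Private variant sets of two cancer subclones separate the cells
    (baseline agglomerative clustering is a test utility, not shipped)."""
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.metrics import adjusted_rand_score

    cfg = L.SimConfig(subclone_fractions=(0.5, 0.5), mislabel_fraction=0.0,
                      n_noise_sites=50, seed=11)
    sim = L.simulate(cfg)
    result = L.run_pipeline(sim.table,
                            L.AnnotationResources(gnomad_freq=sim.gnomad_freq))
    m = result.matrix
    cancer_cols = [bc for bc in m.values.columns
                   if sim.truth.cell_labels.get(bc) == "cancer"]
    vals = m.values[cancer_cols].T.to_numpy().astype(float)
    vals[vals == MISSING] = 0.5
    pred = AgglomerativeClustering(n_clusters=2).fit_predict(vals)
    truth = [sim.truth.subclone_of_cell[bc] for bc in cancer_cols]
    assert adjusted_rand_score(truth, pred) >= 0.9
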