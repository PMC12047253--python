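"""High-confidence cancer variant selection and cell-type reannotation."""

import numpy as np
import pytest

import longsnv as L
from longsnv.fusions import FusionCall
from longsnv.hccv import select_hccv_fusions, select_hccv_mtsnvs, select_hccv_snvs
from longsnv.snv_calling import VariantRecord
from tests.conftest import make_table


def hrec(**kw):
    """A record that passes the whole HCCV chain unless overridden."""
    base = dict(chrom="chr1", pos=1_000_000, ref="A", alt="G",
                cancer_alt=15, cancer_depth=30, cancer_other=0,
                noncancer_alt=1, noncancer_depth=30,
                mcf_cancer=0.8, mcf_noncancer=0.1)
    base.update(kw)
    return VariantRecord(**base)


EMPTY = L.AnnotationResources()


def test_hccv_depth_boundary():
    assert select_hccv_snvs([hrec(noncancer_depth=19)], EMPTY) == []
    assert len(select_hccv_snvs([hrec(noncancer_depth=20)], EMPTY)) == 1
    assert select_hccv_snvs([hrec(cancer_depth=19, cancer_alt=10)], EMPTY) == []


def test_hccv_noncancer_vaf_boundary():
    # VAF_noncancer 0.25 -> rejected; 0.15 with dMCF 0.5 -> retained
    assert select_hccv_snvs([hrec(noncancer_alt=10, noncancer_depth=40)],
                            EMPTY) == []
    kept = select_hccv_snvs([hrec(noncancer_alt=6, noncancer_depth=40,
                                  mcf_cancer=0.6, mcf_noncancer=0.1)], EMPTY)
    assert len(kept) == 1


def test_hccv_delta_mcf_strictly_above_040():
    at = hrec(mcf_cancer=0.5, mcf_noncancer=0.1)     # dMCF exactly 0.4
    assert select_hccv_snvs([at], EMPTY) == []
    above = hrec(mcf_cancer=0.51, mcf_noncancer=0.1)
    assert len(select_hccv_snvs([above], EMPTY)) == 1


def test_hccv_distance_rule_applies_to_survivors():
    a, b = hrec(pos=1_000_000), hrec(pos=1_005_000)
    assert select_hccv_snvs([a, b], EMPTY) == []
    c, d = hrec(pos=1_000_000), hrec(pos=1_020_000)
    assert len(select_hccv_snvs([c, d], EMPTY)) == 2


def test_hccv_resource_filters():
    res = L.AnnotationResources(
        gnomad_freq={("chr1", 1_000_000, "G"): 0.05},
        editing_sites={("chr1", 1_000_001)},
        pon_sr={("chr1", 1_000_002)})
    assert select_hccv_snvs([hrec()], res) == []                 # gnomAD
    assert select_hccv_snvs([hrec(pos=1_000_001)], res) == []    # editing
    assert select_hccv_snvs([hrec(pos=1_000_002)], res) == []    # SR PoN


def test_mt_hccv_ignores_sr_pon_and_distance():
    res = L.AnnotationResources(pon_sr={("chrM", 3_000)})
    mt_in_sr_pon = hrec(chrom="chrM", pos=3_000)
    assert len(select_hccv_mtsnvs([mt_in_sr_pon], res)) == 1
    # ... but the LR PoN still applies
    res_lr = L.AnnotationResources(pon_lr={("chrM", 3_000)})
    assert select_hccv_mtsnvs([mt_in_sr_pon], res_lr) == []
    # no distance rule: two nearby mt variants both survive
    pair = [hrec(chrom="chrM", pos=3_000), hrec(chrom="chrM", pos=3_500)]
    assert len(select_hccv_mtsnvs(pair, EMPTY)) == 2


def test_mt_hccv_delta_mcf_still_applies():
    bad = hrec(chrom="chrM", pos=3_000, mcf_cancer=0.3, mcf_noncancer=0.1)
    assert select_hccv_mtsnvs([bad], EMPTY) == []


@pytest.mark.parametrize("mc,mn,expected", [
    (0.06, 0.005, True),
    (0.05, 0.005, False),   # strict >
    (0.10, 0.01, False),    # strict <
])
def test_hccv_fusion_boundaries(mc, mn, expected):
    f = FusionCall("X--Y", frozenset({"c1"}), mcf_cancer=mc, mcf_noncancer=mn)
    assert (len(select_hccv_fusions([f])) == 1) is expected


# -- reannotation ----------------------------------------------------------

def _reannotation_fixture():
    """Three cells over four HCCV loci with hand-constructed genotypes."""
    loci = [(f"chr{i}", 1_000_000, "A") for i in range(1, 5)]
    rows = []
    # cellA covers all 4, mutated at exactly one (5 alt / 5 ref) -> 25%
    rows.append(("chr1", 1_000_000, "A", "cellA", 5, 5, 0, 0, 0))
    for chrom, pos, ref in loci[1:]:
        rows.append((chrom, pos, ref, "cellA", 10, 0, 0, 0, 0))
    # cellB covers only 2 loci -> filtered
    rows.append(("chr1", 1_000_000, "A", "cellB", 10, 0, 0, 0, 0))
    rows.append(("chr2", 1_000_000, "A", "cellB", 10, 0, 0, 0, 0))
    # cellC covers all 4, zero mutated -> noncancer
    for chrom, pos, ref in loci:
        rows.append((chrom, pos, ref, "cellC", 10, 0, 0, 0, 0))
    table = make_table(rows, {"cellA": "noncancer", "cellB": "noncancer",
                              "cellC": "noncancer"})
    hccvs = [VariantRecord(chrom, pos, ref, "C") for chrom, pos, ref in loci]
    return table, L.HCCVSet(snvs=hccvs)


def test_reannotation_25_percent_boundary_is_inclusive():
    table, hccv = _reannotation_fixture()
    reann = L.reannotate_cells(table, hccv)
    assert reann.labels == {"cellA": "cancer", "cellB": "filtered",
                            "cellC": "noncancer"}
    prov = reann.provenance.set_index("barcode")
    assert prov.loc["cellA", "n_hccv_covered"] == 4
    assert prov.loc["cellA", "fraction"] == pytest.approx(0.25)


def test_fusion_hccvs_count_in_every_cell():
    table, hccv = _reannotation_fixture()
    hccv.fusions = [FusionCall("F--G", frozenset({"cellB"}))]
    reann = L.reannotate_cells(table, hccv)
    # cellB now covers 3 (2 SNVs + fusion) and is mutated at the fusion: 1/3
    assert reann.labels["cellB"] == "cancer"
    prov = reann.provenance.set_index("barcode")
    assert prov.loc["cellB", "n_hccv_covered"] == 3
    assert prov.loc["cellC", "n_hccv_covered"] == 5


def test_reannotation_recovers_mislabeled_cells(default_sim, default_result):
    """>= 95% of mislabeled cancer cells relabeled, <= 1% noncancer flips."""
    truth = default_sim.truth.cell_labels
    input_labels = default_sim.table.cell_types
    labels = default_result.labels
    mislabeled = [bc for bc, lab in input_labels.items()
                  if lab == "noncancer" and truth[bc] == "cancer"]
    assert len(mislabeled) == 10
    recovered = sum(labels[bc] == "cancer" for bc in mislabeled)
    assert recovered / len(mislabeled) >= 0.95
    true_noncancer = [bc for bc, lab in truth.items() if lab == "noncancer"]
    flips = sum(labels.get(bc) == "cancer" for bc in true_noncancer)
    assert flips / len(true_noncancer) <= 0.01


def test_reannotation_idempotent(default_sim, default_resources, default_result):
    """Re-running selection + reannotation on reannotated labels changes
    fewer than 1% of labels."""
    sim = default_sim
    labels1 = default_result.labels
    table2 = sim.table.with_cell_types(labels1)
    pb = L.aggregate_pseudobulk(table2, table2.barcodes_of_type("cancer"),
                                "cancer")
    nuc = L.detect_candidates(pb, table2)
    mt = L.detect_candidates(pb, table2, mt=True)
    hccv = L.HCCVSet(
        snvs=select_hccv_snvs(nuc, default_resources),
        mtsnvs=select_hccv_mtsnvs(mt, default_resources))
    labels2 = L.reannotate_cells(table2, hccv).labels
    changed = sum(labels2[bc] != labels1[bc] for bc in labels1)
    assert changed / len(labels1) < 0.01


def test_confusion_matrix_shape(default_sim, default_result):
    cm = default_result.reannotation.confusion_matrix(default_sim.table.cell_types)
    assert cm.to_numpy().sum() == len(default_sim.table.cell_types)
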