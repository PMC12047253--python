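"""Nuclear SNV candidate detection and the 10-filter battery."""

import itertools
import random

import numpy as np
import pytest

import longsnv as L
from longsnv.error_model import DEFAULT_LR_OTHER, DEFAULT_LR_PRIMARY
from longsnv.snv_calling import (VariantRecord, apply_filters, filter_alt_support,
                                 filter_coverage, filter_distance,
                                 filter_editing, filter_germline, filter_gnomad,
                                 filter_homopolymer, filter_noise_cancer,
                                 filter_other_allele_noise, filter_pon)
from tests.conftest import make_table


def rec(**kw):
    base = dict(chrom="chr1", pos=1_000_000, ref="A", alt="G")
    base.update(kw)
    return VariantRecord(**base)


# -- candidate detection ---------------------------------------------------

def test_candidate_requires_five_reads_and_one_alt():
    rows = [("chr1", 100, "A", "c1", 4, 1, 0, 0, 0),   # depth 5, 1 alt -> candidate
            ("chr1", 200, "A", "c1", 2, 2, 0, 0, 0),   # depth 4 -> too shallow
            ("chr1", 300, "A", "c1", 7, 0, 0, 0, 0)]   # no alt read
    t = make_table(rows, {"c1": "cancer", "n1": "noncancer"})
    pb = L.aggregate_pseudobulk(t, {"c1"}, "cancer")
    cands = L.detect_candidates(pb, t, compute_mcfs=False)
    assert [c.pos for c in cands] == [100]
    assert cands[0].alt == "C" and cands[0].cancer_depth == 5


def test_candidate_alt_tiebreak_base_order():
    """Equal C and G support resolves to C (A < C < G < T)."""
    rows = [("chr1", 100, "A", "c1", 4, 3, 3, 0, 0)]
    t = make_table(rows, {"c1": "cancer"})
    pb = L.aggregate_pseudobulk(t, {"c1"}, "cancer")
    cands = L.detect_candidates(pb, t, compute_mcfs=False)
    assert cands[0].alt == "C"


def test_candidates_route_mt_separately():
    rows = [("chrM", 100, "A", "c1", 4, 6, 0, 0, 0),
            ("chr1", 100, "A", "c1", 4, 6, 0, 0, 0)]
    t = make_table(rows, {"c1": "cancer"})
    pb = L.aggregate_pseudobulk(t, {"c1"}, "cancer")
    assert [c.chrom for c in L.detect_candidates(pb, t, compute_mcfs=False)] \
        == ["chr1"]
    assert [c.chrom for c in L.detect_candidates(pb, t, mt=True,
                                                 compute_mcfs=False)] == ["chrM"]


# -- per-filter boundaries -------------------------------------------------

@pytest.mark.parametrize("cd,nd,expected", [
    (10, 4, False),   # noncancer below 5
    (5, 5, True),     # boundary inclusive
    (0, 50, False),
    (4, 10, False),
])
def test_filter_coverage_boundaries(cd, nd, expected):
    assert filter_coverage(rec(cancer_depth=cd, noncancer_depth=nd)) is expected


@pytest.mark.parametrize("n_cells,expected", [(2, True), (1, False), (0, False)])
def test_filter_alt_support(n_cells, expected):
    assert filter_alt_support(rec(n_cancer_cells_alt3=n_cells)) is expected


def test_filter_noise_cancer():
    assert not filter_noise_cancer(rec(cancer_alt=0, cancer_depth=20),
                                   DEFAULT_LR_PRIMARY)      # p = 1
    assert filter_noise_cancer(rec(cancer_alt=10, cancer_depth=20),
                               DEFAULT_LR_PRIMARY)          # p << 0.001
    # p exactly at the threshold fails (strict <): uniform model, tail(2,4)=0.6
    uniform = L.BetaParams(1.0, 1.0)
    assert not filter_noise_cancer(rec(cancer_alt=2, cancer_depth=4),
                                   uniform, threshold=0.6)


def test_filter_other_allele_noise():
    clean = rec(cancer_alt=10, cancer_depth=20, cancer_other=0)
    assert filter_other_allele_noise(clean, DEFAULT_LR_OTHER)
    noisy = rec(cancer_alt=10, cancer_depth=30, cancer_other=5)
    assert not filter_other_allele_noise(noisy, DEFAULT_LR_OTHER)
    vacuous = rec(cancer_alt=20, cancer_depth=20, cancer_other=0)
    assert filter_other_allele_noise(vacuous, DEFAULT_LR_OTHER)


def test_filter_homopolymer_distance():
    res = L.AnnotationResources(homopolymer_tracts={"chr1": [(100, 110, "A")]})
    assert not filter_homopolymer(rec(pos=105), res)   # inside the tract
    assert not filter_homopolymer(rec(pos=113), res)   # 4 bp beyond the end
    assert filter_homopolymer(rec(pos=114), res)       # 5 bp beyond
    assert filter_homopolymer(rec(chrom="chr2", pos=105), res)


def test_filter_editing_and_pon():
    res = L.AnnotationResources(editing_sites={("chr1", 50)},
                                pon_sr={("chr1", 60)}, pon_lr={("chr1", 70)})
    assert not filter_editing(rec(pos=50), res)
    assert filter_editing(rec(pos=51), res)
    assert not filter_pon(rec(pos=60), res)            # SR only
    assert not filter_pon(rec(pos=70), res)            # LR only
    assert filter_pon(rec(pos=70), res, use_lr=False)  # LR ignored
    assert filter_pon(rec(pos=80), res)


def test_filter_germline():
    assert filter_germline(rec(noncancer_alt=0, noncancer_depth=20),
                           DEFAULT_LR_PRIMARY)
    het = rec(noncancer_alt=8, noncancer_depth=16)     # germline heterozygote
    assert not filter_germline(het, DEFAULT_LR_PRIMARY)
    # p exactly at the threshold passes (strict <)
    uniform = L.BetaParams(1.0, 1.0)
    assert filter_germline(rec(noncancer_alt=2, noncancer_depth=4), uniform,
                           threshold=0.6)


@pytest.mark.parametrize("af,expected", [(0.01, False), (0.009, True),
                                         (None, True)])
def test_filter_gnomad_boundary(af, expected):
    freq = {} if af is None else {("chr1", 1_000_000, "G"): af}
    res = L.AnnotationResources(gnomad_freq=freq)
    assert filter_gnomad(rec(), res) is expected


# -- distance filter -------------------------------------------------------

def brute_force_distance(records, max_dist=10_000):
    keep = []
    for r in records:
        close = any(s is not r and s.chrom == r.chrom
                    and abs(s.pos - r.pos) <= max_dist for s in records)
        if not close:
            keep.append(r)
    return keep


def test_distance_filter_removes_both_members():
    a, b = rec(pos=1_000), rec(pos=9_000)
    assert filter_distance([a, b]) == []
    c, d = rec(pos=9_000), rec(pos=25_000)
    assert {r.pos for r in filter_distance([c, d])} == {9_000, 25_000}
    assert filter_distance([rec(pos=5)]) == [rec(pos=5)]


def test_distance_filter_matches_bruteforce_oracle():
    rng = random.Random(42)
    for _ in range(20):
        n = rng.randint(0, 200)
        records = [rec(chrom=rng.choice(["chr1", "chr2"]),
                       pos=rng.randint(1, 500_000)) for _ in range(n)]
        got = {(r.chrom, r.pos) for r in filter_distance(records)}
        want = {(r.chrom, r.pos) for r in brute_force_distance(records)}
        assert got == want


def test_distance_filter_order_independent():
    rng = random.Random(7)
    records = [rec(pos=rng.randint(1, 300_000)) for _ in range(50)]
    base = {(r.chrom, r.pos) for r in filter_distance(records)}
    shuffled = records[:]
    rng.shuffle(shuffled)
    assert {(r.chrom, r.pos) for r in filter_distance(shuffled)} == base


# -- ledger / funnel -------------------------------------------------------

def _random_records(rng, n=60):
    out = []
    for i in range(n):
        out.append(rec(
            pos=rng.randint(1, 10_000_000),
            cancer_alt=rng.randint(0, 20), cancer_depth=rng.randint(0, 40),
            cancer_other=rng.randint(0, 3),
            noncancer_alt=rng.randint(0, 10), noncancer_depth=rng.randint(0, 40),
            n_cancer_cells_alt3=rng.randint(0, 4)))
    for r in out:  # keep counts consistent
        r.cancer_depth = max(r.cancer_depth, r.cancer_alt + r.cancer_other)
        r.noncancer_depth = max(r.noncancer_depth, r.noncancer_alt)
    return out


def test_funnel_conservation_and_full_ledger():
    rng = random.Random(3)
    records = _random_records(rng)
    res = L.AnnotationResources()
    apply_filters(records, res, DEFAULT_LR_PRIMARY, DEFAULT_LR_OTHER)
    cs = L.CallSet(records)
    funnel = cs.funnel()
    for i in range(1, len(funnel)):
        assert funnel.loc[i, "n_in"] == funnel.loc[i - 1, "n_pass"]
    assert (funnel["n_in"] == funnel["n_pass"] + funnel["n_fail"]).all()
    assert all(len(r.filter_ledger) == 10 for r in records)
    # nothing dropped silently
    assert len(cs.records) == len(records)


def test_per_record_filters_commute():
    """Any order of filters 1-9 leaves the same surviving set."""
    rng = random.Random(9)
    records = _random_records(rng, n=40)
    res = L.AnnotationResources(editing_sites={("chr1", records[0].pos)})
    fns = [lambda r: filter_coverage(r),
           lambda r: filter_alt_support(r),
           lambda r: filter_noise_cancer(r, DEFAULT_LR_PRIMARY),
           lambda r: filter_other_allele_noise(r, DEFAULT_LR_OTHER),
           lambda r: filter_homopolymer(r, res),
           lambda r: filter_editing(r, res),
           lambda r: filter_pon(r, res),
           lambda r: filter_germline(r, DEFAULT_LR_PRIMARY),
           lambda r: filter_gnomad(r, res)]
    baseline = {id(r) for r in records if all(f(r) for f in fns)}
    for _ in range(5):
        order = fns[:]
        rng.shuffle(order)
        assert {id(r) for r in records
                if all(f(r) for f in order)} == baseline


# -- full calling on synthetic truth ---------------------------------------

def test_call_somatic_snvs_on_planted_truth(default_sim, default_resources):
    """With true labels, germline is excluded and somatic recovered."""
    sim = default_sim
    cs = L.call_somatic_snvs(sim.table, sim.truth.cell_labels,
                             default_resources)
    score = L.score_against_truth(cs.passed, sim.truth)
    assert score["germline_calls"] == 0
    assert score["sensitivity"] >= 0.9
    funnel = cs.funnel()
    for i in range(1, len(funnel)):
        assert funnel.loc[i, "n_in"] == funnel.loc[i - 1, "n_pass"]


def test_germline_heterozygotes_rejected():
    """Planted het sites (VAF 0.5 both populations) are essentially always
    removed by the germline or population-frequency filter."""
    cfg = L.SimConfig(n_somatic_sites=0, n_noise_sites=0,
                      n_germline_sites=40, n_mt_sites=0,
                      mislabel_fraction=0.0, seed=13)
    sim = L.simulate(cfg)
    cs = L.call_somatic_snvs(sim.table, sim.truth.cell_labels,
                             L.AnnotationResources(gnomad_freq=sim.gnomad_freq))
    assert len(cs.passed) == 0


def test_close_pair_of_true_somatic_removed():
    """Two genuine somatic variants 5 kb apart eliminate each other."""
    cfg = L.SimConfig(n_somatic_sites=2, n_germline_sites=0, n_noise_sites=0,
                      n_mt_sites=0, mislabel_fraction=0.0, site_spacing=5_000,
                      seed=3)
    sim = L.simulate(cfg)
    cs = L.call_somatic_snvs(sim.table, sim.truth.cell_labels,
                             L.AnnotationResources())
    assert len(cs.passed) == 0
    assert {r.filter_ledger["distance"] for r in cs.records
            if r.filter_ledger.get("distance") != "not_evaluated"} <= {"fail"}


def test_vcf_output_carries_filters(tmp_path, default_sim, default_resources):
    cs = L.call_somatic_snvs(default_sim.table, default_sim.truth.cell_labels,
                             default_resources)
    path = tmp_path / "out.vcf"
    cs.write_vcf(path)
    text = path.read_text()
    assert text.startswith("##fileformat=VCFv4.2")
    body = [l for l in text.splitlines() if not l.startswith("#")]
    assert len(body) == len(cs.records)
    assert sum(1 for l in body if "\tPASS\t" in l) == len(cs.passed)
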