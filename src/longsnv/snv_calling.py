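"""Nuclear somatic SNV calling: candidate detection and the 10-filter battery.

Candidates are every locus with at least one alternative-allele read and at
least five reads of coverage in the aggregated (pseudo-bulk) cancer cells.
Each candidate then passes through an ordered ledger of ten filters:

1.  coverage          — >= 5 reads in both cancer and noncancer pseudo-bulks
2.  alt_support       — >= 3 alt reads in each of >= 2 distinct cancer cells
3.  noise_cancer      — beta-binomial upper tail in cancer < 0.001
4.  other_allele      — residual non-alt nonreference reads NOT significant
                        at 0.05 under the other-allele error model
5.  homopolymer       — not inside or within 4 bp of a mononucleotide tract
6.  editing           — not a known RNA-editing site
7.  pon               — not in the short-read or long-read panel of normals
8.  germline          — beta-binomial upper tail in noncancer NOT < 0.05
                        (deliberately stricter than the 0.001 a noise test
                        would use, to remove germline polymorphisms)
9.  gnomad            — population allele frequency < 1%
10. distance          — no other surviving candidate within 10,000 bp

Filters 1-9 are per-record and commute; filter 10 is a set-level rule that
removes *both* members of every close pair. Candidates on mitochondrial
contigs are excluded here and routed to the dedicated mitochondrial caller.

Every candidate keeps a full per-filter ledger (pass / fail / not_evaluated)
so the funnel — how many loci survive each successive step — is exactly
reconstructable, and pass(i) + fail(i) = pass(i-1) at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import (BetaParams, DEFAULT_LR_OTHER, DEFAULT_LR_PRIMARY,
                          betabinom_tail)
from .genotyping import compute_mcf
from .io_counts import (AnnotationResources, BASES, BaseCountTable, COUNT_COLS,
                        MT_CONTIGS, PseudoBulk, aggregate_pseudobulk)

logger = logging.getLogger("longsnv")

FILTER_ORDER = ("coverage", "alt_support", "noise_cancer", "other_allele",
                "homopolymer", "editing", "pon", "germline", "gnomad",
                "distance")

# Shipped thresholds (each is a keyword of call_somatic_snvs).
MIN_GROUP_DEPTH = 5
MIN_ALT_READS_PER_CELL = 3
MIN_CELLS_WITH_ALT = 2
NOISE_THRESHOLD = 1e-3
OTHER_ALLELE_THRESHOLD = 0.05
GERMLINE_THRESHOLD = 0.05
GNOMAD_MAX_AF = 0.01
HOMOPOLYMER_FLANK = 4
MIN_SNV_DISTANCE = 10_000

__all__ = [
    "FILTER_ORDER",
    "VariantRecord",
    "CallSet",
    "detect_candidates",
    "filter_coverage",
    "filter_alt_support",
    "filter_noise_cancer",
    "filter_other_allele_noise",
    "filter_homopolymer",
    "filter_editing",
    "filter_pon",
    "filter_germline",
    "filter_gnomad",
    "filter_distance",
    "apply_filters",
    "call_somatic_snvs",
]


@dataclass
class VariantRecord:
    """A candidate (locus, alt) with per-group statistics and a filter ledger."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cancer_alt: int = 0
    cancer_depth: int = 0
    cancer_other: int = 0          # nonreference reads excluding alt, cancer
    noncancer_alt: int = 0
    noncancer_depth: int = 0
    n_cancer_cells_alt3: int = 0   # cancer cells with >= 3 alt reads
    mcf_cancer: float = 0.0
    mcf_noncancer: float = 0.0
    filter_ledger: dict[str, str] = field(default_factory=dict)

    @property
    def vaf_cancer(self) -> float:
        return self.cancer_alt / self.cancer_depth if self.cancer_depth else 0.0

    @property
    def vaf_noncancer(self) -> float:
        return (self.noncancer_alt / self.noncancer_depth
                if self.noncancer_depth else 0.0)

    @property
    def delta_mcf(self) -> float:
        return self.mcf_cancer - self.mcf_noncancer

    @property
    def is_mt(self) -> bool:
        return self.chrom in MT_CONTIGS

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def passed_all(self) -> bool:
        return bool(self.filter_ledger) and all(
            v == "pass" for v in self.filter_ledger.values())

    @property
    def first_fail(self) -> str | None:
        for name, status in self.filter_ledger.items():
            if status == "fail":
                return name
        return None


@dataclass
class CallSet:
    """All candidates with their ledgers, plus the per-filter funnel."""

    records: list[VariantRecord]
    filter_order: tuple[str, ...] = FILTER_ORDER

    @property
    def passed(self) -> list[VariantRecord]:
        return [r for r in self.records if r.passed_all]

    def funnel(self) -> pd.DataFrame:
        """Per-filter in/pass/fail counts; pass(i) = pass(i-1) - fail(i)."""
        n_in = len(self.records)
        rows = []
        for name in self.filter_order:
            statuses = [r.filter_ledger.get(name, "not_evaluated")
                        for r in self.records]
            n_pass = statuses.count("pass")
            n_fail = statuses.count("fail")
            rows.append((name, n_in, n_pass, n_fail))
            n_in = n_pass
        return pd.DataFrame(rows, columns=["filter", "n_in", "n_pass", "n_fail"])

    def write_funnel_tsv(self, path) -> None:
        self.funnel().to_csv(path, sep="\t", index=False)

    def write_vcf(self, path, sample: str = "sample", mt_flag: bool = False) -> None:
        """Write VCF 4.2; FILTER carries the first failing step or PASS."""
        lines = [
            "##fileformat=VCFv4.2",
            "##source=longsnv",
            '##INFO=<ID=DP_C,Number=1,Type=Integer,Description="Cancer pseudo-bulk depth">',
            '##INFO=<ID=DP_N,Number=1,Type=Integer,Description="Noncancer pseudo-bulk depth">',
            '##INFO=<ID=VAF_C,Number=1,Type=Float,Description="Cancer pseudo-bulk VAF">',
            '##INFO=<ID=VAF_N,Number=1,Type=Float,Description="Noncancer pseudo-bulk VAF">',
            '##INFO=<ID=MCF_C,Number=1,Type=Float,Description="Cancer mutated cell fraction">',
            '##INFO=<ID=MCF_N,Number=1,Type=Float,Description="Noncancer mutated cell fraction">',
            '##INFO=<ID=DMCF,Number=1,Type=Float,Description="MCF_C - MCF_N">',
            '##INFO=<ID=MT,Number=0,Type=Flag,Description="Mitochondrial variant">',
        ]
        for name in self.filter_order:
            lines.append(f'##FILTER=<ID={name},Description="Failed {name} filter">')
        for chrom in sorted({r.chrom for r in self.records}):
            lines.append(f"##contig=<ID={chrom}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for r in sorted(self.records, key=lambda r: (r.chrom, r.pos)):
            filt = r.first_fail or "PASS"
            info = (f"DP_C={r.cancer_depth};DP_N={r.noncancer_depth};"
                    f"VAF_C={r.vaf_cancer:.6g};VAF_N={r.vaf_noncancer:.6g};"
                    f"MCF_C={r.mcf_cancer:.6g};MCF_N={r.mcf_noncancer:.6g};"
                    f"DMCF={r.delta_mcf:.6g}")
            if mt_flag or r.is_mt:
                info += ";MT"
            lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t{info}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def detect_candidates(cancer_pb: PseudoBulk, table: BaseCountTable,
                      genotype_params: BetaParams = DEFAULT_LR_PRIMARY,
                      min_depth: int = MIN_GROUP_DEPTH, min_alt: int = 1,
                      mt: bool = False,
                      compute_mcfs: bool = True) -> list[VariantRecord]:
    """Candidate variants from the cancer pseudo-bulk.

    One record per locus with cancer depth >= ``min_depth`` and >= ``min_alt``
    reads of the most frequent nonreference base (ties broken A < C < G < T;
    multi-allelic candidates collapse to the major alternative). With
    ``mt=False`` mitochondrial contigs are skipped (and vice versa); MCFs are
    computed with the matching single-cell genotyping rule.
    """
    records: list[VariantRecord] = []
    if cancer_pb.counts.empty:
        return records
    cancer_cells = table.barcodes_of_type("cancer")
    noncancer_cells = table.barcodes_of_type("noncancer")
    noncancer_pb = aggregate_pseudobulk(table, noncancer_cells, "noncancer") \
        if noncancer_cells else None

    nc_counts = noncancer_pb.counts if noncancer_pb is not None else None
    for (chrom, pos, ref), row in cancer_pb.counts.iterrows():
        if (chrom in MT_CONTIGS) != mt:
            continue
        depth = int(row["depth"])
        if depth < min_depth:
            continue
        alt_bases = [b for b in BASES if b != ref]
        alt_counts = {b: int(row[b]) for b in alt_bases}
        alt = max(alt_bases, key=lambda b: (alt_counts[b], -BASES.index(b)))
        # tie-break: max on (count, -base_index) keeps the earliest base
        if alt_counts[alt] < min_alt:
            continue
        rec = VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                            cancer_alt=alt_counts[alt], cancer_depth=depth,
                            cancer_other=sum(alt_counts.values()) - alt_counts[alt])
        if nc_counts is not None and (chrom, pos, ref) in nc_counts.index:
            nrow = nc_counts.loc[(chrom, pos, ref)]
            rec.noncancer_depth = int(nrow["depth"])
            rec.noncancer_alt = int(nrow[alt])
        cells = table.locus_cells(chrom, int(pos))
        ccells = cells[cells["barcode"].isin(cancer_cells)]
        rec.n_cancer_cells_alt3 = int(
            (ccells[alt] >= MIN_ALT_READS_PER_CELL).sum())
        if compute_mcfs:
            rec.mcf_cancer, _, _ = compute_mcf(
                table, chrom, int(pos), ref, alt, cancer_cells,
                genotype_params, mt=mt)
            rec.mcf_noncancer, _, _ = compute_mcf(
                table, chrom, int(pos), ref, alt, noncancer_cells,
                genotype_params, mt=mt)
        records.append(rec)
    return records


# -- per-record filters (True = pass) --------------------------------------


def filter_coverage(rec: VariantRecord, min_depth: int = MIN_GROUP_DEPTH) -> bool:
    """Step 1: fail iff either pseudo-bulk has < ``min_depth`` reads."""
    return rec.cancer_depth >= min_depth and rec.noncancer_depth >= min_depth


def filter_alt_support(rec: VariantRecord,
                       min_cells: int = MIN_CELLS_WITH_ALT) -> bool:
    """Step 2: require >= 3 alt reads in each of >= ``min_cells`` cancer cells.

    The per-cell read threshold (3) is applied at candidate detection, where
    per-cell counts are in hand, and carried as ``n_cancer_cells_alt3``.
    """
    return rec.n_cancer_cells_alt3 >= min_cells


def filter_noise_cancer(rec: VariantRecord, params1: BetaParams,
                        threshold: float = NOISE_THRESHOLD) -> bool:
    """Step 3: pass iff the cancer alt counts are significantly above noise."""
    return betabinom_tail(rec.cancer_alt, rec.cancer_depth, params1) < threshold


def filter_other_allele_noise(rec: VariantRecord, params2: BetaParams,
                              threshold: float = OTHER_ALLELE_THRESHOLD) -> bool:
    """Step 4: fail iff residual non-alt nonreference reads are significant.

    Ignoring reads carrying the candidate allele, the remaining nonreference
    counts are tested against the other-allele error model; a significant
    excess marks a generally noisy locus.
    """
    n_resid = rec.cancer_depth - rec.cancer_alt
    if n_resid <= 0:
        return True
    return not betabinom_tail(rec.cancer_other, n_resid, params2) < threshold


def filter_homopolymer(rec: VariantRecord, resources: AnnotationResources,
                       flank: int = HOMOPOLYMER_FLANK) -> bool:
    """Step 5: fail iff inside or within ``flank`` bp of a mononucleotide tract."""
    return not resources.near_homopolymer(rec.chrom, rec.pos, flank)


def filter_editing(rec: VariantRecord, resources: AnnotationResources) -> bool:
    """Step 6: fail iff the locus is a known RNA-editing site."""
    return (rec.chrom, rec.pos) not in resources.editing_sites


def filter_pon(rec: VariantRecord, resources: AnnotationResources,
               use_sr: bool = True, use_lr: bool = True) -> bool:
    """Step 7: fail iff the locus is in the short-read or long-read PoN."""
    key = (rec.chrom, rec.pos)
    if use_sr and key in resources.pon_sr:
        return False
    if use_lr and key in resources.pon_lr:
        return False
    return True


def filter_germline(rec: VariantRecord, params1: BetaParams,
                    threshold: float = GERMLINE_THRESHOLD) -> bool:
    """Step 8: fail iff noncancer alt counts are significant at ``threshold``."""
    if rec.noncancer_depth == 0:
        return True
    return not betabinom_tail(rec.noncancer_alt, rec.noncancer_depth,
                              params1) < threshold


def filter_gnomad(rec: VariantRecord, resources: AnnotationResources,
                  max_af: float = GNOMAD_MAX_AF) -> bool:
    """Step 9: fail iff the population allele frequency is >= ``max_af``."""
    af = resources.gnomad_af(rec.chrom, rec.pos, rec.alt)
    return af is None or af < max_af


def filter_distance(records: Sequence[VariantRecord],
                    max_dist: int = MIN_SNV_DISTANCE) -> list[VariantRecord]:
    """Step 10: remove *both* members of every same-chromosome pair <= 10 kb apart.

    Close pairs are typically misalignment artifacts in low-complexity regions
    or allele-specific-expression shadows, so neither member is trusted.
    Symmetric and order-independent.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    keep: list[VariantRecord] = []
    for chrom_records in by_chrom.values():
        srt = sorted(chrom_records, key=lambda r: r.pos)
        bad = set()
        for a, b in zip(srt, srt[1:]):
            if b.pos - a.pos <= max_dist:
                bad.add(id(a))
                bad.add(id(b))
        keep.extend(r for r in srt if id(r) not in bad)
    return sorted(keep, key=lambda r: (r.chrom, r.pos))


def apply_filters(records: Sequence[VariantRecord],
                  resources: AnnotationResources,
                  params1: BetaParams, params2: BetaParams,
                  **thresholds) -> list[VariantRecord]:
    """Run filters 1-10 over candidates, recording the ledger in order.

    Each record is evaluated against filters 1-9 sequentially; after the
    first failure later per-record filters are marked ``not_evaluated``.
    The distance filter runs on the survivors and completes the ledger.
    Returns the records (ledger filled in place).
    """
    per_record = [
        ("coverage", lambda r: filter_coverage(
            r, thresholds.get("min_group_depth", MIN_GROUP_DEPTH))),
        ("alt_support", lambda r: filter_alt_support(
            r, thresholds.get("min_cells_with_alt", MIN_CELLS_WITH_ALT))),
        ("noise_cancer", lambda r: filter_noise_cancer(
            r, params1, thresholds.get("noise_threshold", NOISE_THRESHOLD))),
        ("other_allele", lambda r: filter_other_allele_noise(
            r, params2, thresholds.get("other_allele_threshold",
                                       OTHER_ALLELE_THRESHOLD))),
        ("homopolymer", lambda r: filter_homopolymer(
            r, resources, thresholds.get("homopolymer_flank", HOMOPOLYMER_FLANK))),
        ("editing", lambda r: filter_editing(r, resources)),
        ("pon", lambda r: filter_pon(r, resources)),
        ("germline", lambda r: filter_germline(
            r, params1, thresholds.get("germline_threshold", GERMLINE_THRESHOLD))),
        ("gnomad", lambda r: filter_gnomad(
            r, resources, thresholds.get("gnomad_max_af", GNOMAD_MAX_AF))),
    ]
    survivors = []
    for rec in records:
        rec.filter_ledger = {}
        failed = False
        for name, fn in per_record:
            if failed:
                rec.filter_ledger[name] = "not_evaluated"
            else:
                ok = bool(fn(rec))
                rec.filter_ledger[name] = "pass" if ok else "fail"
                failed = not ok
        if not failed:
            survivors.append(rec)
    kept = {id(r) for r in filter_distance(
        survivors, thresholds.get("min_snv_distance", MIN_SNV_DISTANCE))}
    survivor_ids = {id(r) for r in survivors}
    for rec in records:
        if id(rec) in survivor_ids:
            rec.filter_ledger["distance"] = "pass" if id(rec) in kept else "fail"
        else:
            rec.filter_ledger["distance"] = "not_evaluated"
    return list(records)


def call_somatic_snvs(table: BaseCountTable, cell_types: Mapping[str, str],
                      resources: AnnotationResources,
                      params1: BetaParams = DEFAULT_LR_PRIMARY,
                      params2: BetaParams = DEFAULT_LR_OTHER,
                      **thresholds) -> CallSet:
    """Full nuclear somatic SNV calling pass.

    ``cell_types`` should be the *reannotated* labels; cells labeled
    ``"filtered"`` belong to neither pseudo-bulk. Returns a :class:`CallSet`
    whose records all carry a complete ledger (no candidate is silently
    dropped) and whose funnel counts are conserved step to step.
    """
    table = table.with_cell_types(dict(cell_types))
    cancer = table.barcodes_of_type("cancer")
    cancer_pb = aggregate_pseudobulk(table, cancer, "cancer")
    candidates = detect_candidates(
        cancer_pb, table, genotype_params=params1,
        min_depth=thresholds.get("min_group_depth", MIN_GROUP_DEPTH), mt=False)
    apply_filters(candidates, resources, params1, params2, **thresholds)
    logger.info("nuclear SNV calling: %d candidates, %d somatic",
                len(candidates), sum(r.passed_all for r in candidates))
    return CallSet(candidates)
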