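"""Somatic mitochondrial SNV calling.

Ambient mitochondrial RNA released by dead and dying cancer cells
contaminates noncancer droplets, so called mt variants show low but nonzero
noncancer VAFs (observed range roughly 0.1-3% per cell). A nuclear-style
germline test would reject every such locus — at mitochondrial depths even a
1% noncancer VAF is statistically significant — so mitochondrial candidates
take a dedicated, contamination-robust path:

1. candidate detection — >= 1 alt read and >= 5 reads in aggregated cancer
   cells (shared with the nuclear caller, restricted to mt contigs)
2. coverage  — >= 100 reads in both cancer and noncancer pseudo-bulks
3. gnomad    — population allele frequency < 1%
4. delta_mcf — fail iff dMCF < 0.35 (a locus at exactly 0.35 is retained)
5. vaf       — fail iff VAF_cancer < 0.1

MCFs here use the per-cell VAF > 0.3 genotype rule, which low-level ambient
contamination cannot trip, so dMCF stays near 1 for true cancer variants
however deep the noncancer pseudo-bulk is.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import BetaParams, DEFAULT_LR_PRIMARY
from .io_counts import AnnotationResources, BaseCountTable, COUNT_COLS
from .snv_calling import CallSet, VariantRecord, filter_gnomad

logger = logging.getLogger("longsnv")

MT_FILTER_ORDER = ("coverage", "gnomad", "delta_mcf", "vaf")

MT_MIN_DEPTH = 100
MT_MIN_DELTA_MCF = 0.35
MT_MIN_VAF_CANCER = 0.1

__all__ = [
    "MT_FILTER_ORDER",
    "call_somatic_mtsnvs",
    "mt_contamination_profile",
]


def call_somatic_mtsnvs(candidates: Sequence[VariantRecord],
                        resources: AnnotationResources,
                        min_depth: int = MT_MIN_DEPTH,
                        min_delta_mcf: float = MT_MIN_DELTA_MCF,
                        min_vaf_cancer: float = MT_MIN_VAF_CANCER) -> CallSet:
    """Apply the mitochondrial filter chain to chrM candidates.

    ``candidates`` must be restricted to mitochondrial contigs with MCFs and
    VAFs computed from reannotated labels (and with the per-cell VAF
    genotyping rule). Boundary semantics follow the printed rules: loci are
    *failed* when dMCF < 0.35 or VAF_cancer < 0.1, so values exactly at the
    threshold are retained.
    """
    steps = [
        ("coverage", lambda r: r.cancer_depth >= min_depth
                               and r.noncancer_depth >= min_depth),
        ("gnomad", lambda r: filter_gnomad(r, resources)),
        ("delta_mcf", lambda r: not r.delta_mcf < min_delta_mcf),
        ("vaf", lambda r: not r.vaf_cancer < min_vaf_cancer),
    ]
    for rec in candidates:
        if not rec.is_mt:
            raise ValueError(f"non-mitochondrial candidate {rec.variant_id} "
                             "routed to the mtSNV caller")
        rec.filter_ledger = {}
        failed = False
        for name, fn in steps:
            if failed:
                rec.filter_ledger[name] = "not_evaluated"
            else:
                ok = bool(fn(rec))
                rec.filter_ledger[name] = "pass" if ok else "fail"
                failed = not ok
    callset = CallSet(list(candidates), filter_order=MT_FILTER_ORDER)
    logger.info("mtSNV calling: %d candidates, %d somatic",
                len(candidates), len(callset.passed))
    return callset


def mt_contamination_profile(table: BaseCountTable,
                             loci: Sequence[tuple[str, int, str, str]],
                             groups: Mapping[str, Iterable[str]] | None = None
                             ) -> pd.DataFrame:
    """Per-cell VAF distributions of called mt variants, by cell group.

    ``loci`` are (chrom, pos, ref, alt) tuples of called mtSNVs; ``groups``
    maps group name -> barcodes (defaults to the table's cancer / noncancer
    labels). Returns one row per (locus, group, cell) with the cell's VAF,
    plus the group mean in a ``group_mean_vaf`` column — the diagnostic
    behind the per-cell VAF genotyping threshold.
    """
    if groups is None:
        groups = {"cancer": table.barcodes_of_type("cancer"),
                  "noncancer": table.barcodes_of_type("noncancer")}
    rows = []
    for chrom, pos, _ref, alt in loci:
        cells = table.locus_cells(chrom, pos)
        depth = cells[COUNT_COLS].sum(axis=1)
        for gname, members in groups.items():
            members = set(members)
            sub = cells["barcode"].isin(members) & (depth > 0)
            vafs = (cells.loc[sub, alt] / depth[sub]).to_numpy()
            mean = float(vafs.mean()) if len(vafs) else 0.0
            for bc, v in zip(cells.loc[sub, "barcode"], vafs):
                rows.append((chrom, pos, alt, gname, bc, float(v), mean))
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "group",
                                       "barcode", "vaf", "group_mean_vaf"])
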