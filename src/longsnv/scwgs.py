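"""Validation against single-cell whole-genome sequencing (scWGS).

Copy-number-derived scWGS clones serve as orthogonal ground truth: aneuploid
clones are treated as cancer, fully diploid clones as noncancer, and each
side is pooled because per-clone coverage is low. Two uses:

* **Support classification** — each locus called in scRNA-seq is labelled
  somatic (mutated in the aneuploid pool only), germline (mutated in the
  diploid pool), or uncalled (mutated in neither), where "mutated" means a
  beta-binomial upper tail < 0.01 in that pool. Loci are eligible only with
  at least one mutated read or at least 17 reads of coverage (the printed
  disjunction, asymmetric as it is, is applied verbatim).
* **De novo truth set** — sites with >= 5 reads in both scRNA pseudo-bulks
  and both scWGS pools, >= 3 mutated reads in >= 2 aneuploid cells, tail
  P < 0.001 in the aneuploid pool and P > 0.05 in the diploid pool are
  somatic ground truth, against which sensitivity, precision and F1 of the
  scRNA-seq calls are computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import BetaParams, DEFAULT_LR_PRIMARY, betabinom_tail
from .io_counts import BASES, PseudoBulk

logger = logging.getLogger("longsnv")

SUPPORT_THRESHOLD = 0.01
SUPPORT_MIN_DEPTH = 17
DENOVO_P_ANEUPLOID = 0.001
DENOVO_P_DIPLOID = 0.05
DENOVO_MIN_DEPTH = 5
DENOVO_MIN_ALT_READS = 3
DENOVO_MIN_ALT_CELLS = 2

__all__ = [
    "CloneCounts",
    "classify_support",
    "call_scwgs_denovo",
    "performance",
]


@dataclass
class CloneCounts:
    """Pooled per-locus base counts for the aneuploid and diploid scWGS clones.

    ``pooled`` has columns chrom, pos, ref, pool ("aneuploid" | "diploid"),
    A, C, G, T, other. ``per_cell`` optionally carries aneuploid per-cell
    rows (chrom, pos, ref, barcode, A, C, G, T, other) for the de novo
    multi-cell support rule; without it that sub-filter is skipped with a
    logged caveat.
    """

    pooled: pd.DataFrame
    per_cell: pd.DataFrame | None = None

    def pool_counts(self, pool: str) -> pd.DataFrame:
        sub = self.pooled[self.pooled["pool"] == pool].copy()
        sub["depth"] = sub[["A", "C", "G", "T", "other"]].sum(axis=1)
        return sub.set_index(["chrom", "pos"])

    @classmethod
    def from_tsv(cls, pooled_path, per_cell_path=None) -> "CloneCounts":
        pooled = pd.read_csv(pooled_path, sep="\t", dtype={"chrom": str})
        per_cell = (pd.read_csv(per_cell_path, sep="\t", dtype={"chrom": str})
                    if per_cell_path is not None else None)
        return cls(pooled, per_cell)

    def to_tsv(self, pooled_path, per_cell_path=None) -> None:
        self.pooled.to_csv(pooled_path, sep="\t", index=False)
        if per_cell_path is not None and self.per_cell is not None:
            self.per_cell.to_csv(per_cell_path, sep="\t", index=False)


def _pool_stats(clone_counts: CloneCounts, pool: str, chrom: str, pos: int,
                alt: str) -> tuple[int, int]:
    """(alt reads, depth) at one locus in one pool; (0, 0) if uncovered."""
    sub = clone_counts.pool_counts(pool)
    if (chrom, pos) not in sub.index:
        return 0, 0
    row = sub.loc[(chrom, pos)]
    if isinstance(row, pd.DataFrame):
        row = row.iloc[0]
    return int(row[alt]), int(row["depth"])


def classify_support(chrom: str, pos: int, alt: str,
                     clone_counts: CloneCounts,
                     params: BetaParams = DEFAULT_LR_PRIMARY,
                     threshold: float = SUPPORT_THRESHOLD,
                     min_depth: int = SUPPORT_MIN_DEPTH) -> str:
    """Label one scRNA-called locus by its scWGS support.

    Returns ``"ineligible"`` unless the locus has >= 1 mutated read or
    >= ``min_depth`` reads of pooled scWGS coverage (across both pools);
    otherwise ``"somatic"`` (significant in the aneuploid pool only),
    ``"germline"`` (significant in the diploid pool), or ``"uncalled"``.
    """
    alt_a, depth_a = _pool_stats(clone_counts, "aneuploid", chrom, pos, alt)
    alt_d, depth_d = _pool_stats(clone_counts, "diploid", chrom, pos, alt)
    if not (alt_a + alt_d >= 1 or depth_a + depth_d >= min_depth):
        return "ineligible"
    sig_a = depth_a > 0 and betabinom_tail(alt_a, depth_a, params) < threshold
    sig_d = depth_d > 0 and betabinom_tail(alt_d, depth_d, params) < threshold
    if sig_d:
        return "germline"
    if sig_a:
        return "somatic"
    return "uncalled"


def call_scwgs_denovo(clone_counts: CloneCounts,
                      rna_cancer_pb: PseudoBulk, rna_noncancer_pb: PseudoBulk,
                      params: BetaParams = DEFAULT_LR_PRIMARY,
                      p_aneuploid: float = DENOVO_P_ANEUPLOID,
                      p_diploid: float = DENOVO_P_DIPLOID,
                      min_depth: int = DENOVO_MIN_DEPTH,
                      min_alt_reads: int = DENOVO_MIN_ALT_READS,
                      min_alt_cells: int = DENOVO_MIN_ALT_CELLS
                      ) -> pd.DataFrame:
    """Build a de novo scWGS somatic truth set.

    Eligible sites have >= ``min_depth`` reads in both scRNA pseudo-bulks and
    both scWGS pools, and >= ``min_alt_reads`` mutated reads in each of
    >= ``min_alt_cells`` aneuploid cells (skipped with a caveat when only
    pooled counts are available). A site is somatic iff its aneuploid-pool
    tail is < ``p_aneuploid`` AND its diploid-pool tail is > ``p_diploid``.

    Returns one row per evaluated site with columns chrom, pos, ref, alt,
    p_aneuploid, p_diploid, somatic (bool).
    """
    aneu = clone_counts.pool_counts("aneuploid")
    dipl = clone_counts.pool_counts("diploid")
    rna_c = rna_cancer_pb.counts.reset_index().set_index(["chrom", "pos"])
    rna_n = rna_noncancer_pb.counts.reset_index().set_index(["chrom", "pos"])
    per_cell = clone_counts.per_cell
    if per_cell is None:
        logger.warning("no per-cell aneuploid counts: the >=%d mutated reads "
                       "in >=%d cells rule is skipped", min_alt_reads,
                       min_alt_cells)
    rows = []
    for (chrom, pos) in aneu.index:
        if (chrom, pos) not in dipl.index:
            continue
        if (chrom, pos) not in rna_c.index or (chrom, pos) not in rna_n.index:
            continue
        arow, drow = aneu.loc[(chrom, pos)], dipl.loc[(chrom, pos)]
        if isinstance(arow, pd.DataFrame):
            arow = arow.iloc[0]
        if isinstance(drow, pd.DataFrame):
            drow = drow.iloc[0]
        if (arow["depth"] < min_depth or drow["depth"] < min_depth
                or rna_c.loc[(chrom, pos), "depth"] < min_depth
                or rna_n.loc[(chrom, pos), "depth"] < min_depth):
            continue
        ref = arow["ref"]
        alts = [b for b in BASES if b != ref]
        alt = max(alts, key=lambda b: (int(arow[b]), -BASES.index(b)))
        if int(arow[alt]) == 0:
            continue
        if per_cell is not None:
            cells = per_cell[(per_cell["chrom"] == chrom)
                             & (per_cell["pos"] == pos)]
            if (cells[alt] >= min_alt_reads).sum() < min_alt_cells:
                continue
        pa = betabinom_tail(int(arow[alt]), int(arow["depth"]), params)
        pd_ = betabinom_tail(int(drow[alt]), int(drow["depth"]), params)
        rows.append((chrom, int(pos), ref, alt, pa, pd_,
                     pa < p_aneuploid and pd_ > p_diploid))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "p_aneuploid", "p_diploid", "somatic"])


def performance(calls: set, truth: set,
                eligible: set | None = None) -> dict[str, float]:
    """Sensitivity, precision and F1 of scRNA calls against the truth set.

    ``calls`` and ``truth`` are sets of hashable variant keys (for example
    ``(chrom, pos, alt)``); with ``eligible`` given, both are restricted to
    it first. With zero calls, precision is undefined and reported as 0.0
    with ``precision_undefined`` set — a documented convention so F1 stays
    computable.
    """
    calls, truth = set(calls), set(truth)
    if eligible is not None:
        eligible = set(eligible)
        calls &= eligible
        truth &= eligible
    tp = len(calls & truth)
    fp = len(calls - truth)
    fn = len(truth - calls)
    out: dict[str, float] = {
        "tp": float(tp), "fp": float(fp), "fn": float(fn),
        "precision_undefined": 0.0,
    }
    if tp + fp == 0:
        out["precision"] = 0.0
        out["precision_undefined"] = 1.0
    else:
        out["precision"] = tp / (tp + fp)
    out["sensitivity"] = tp / (tp + fn) if tp + fn else 0.0
    p, r = out["precision"], out["sensitivity"]
    out["f1"] = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return out
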