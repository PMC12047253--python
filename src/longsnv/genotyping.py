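"""Single-cell genotyping and the cell-variant matrix.

A cell is genotyped at a nuclear SNV by testing its alternative-allele reads
against its reference-allele reads with the background beta-binomial model
(significance threshold 0.01): significant means *mutated*, non-significant
*wildtype*, and no reads at all *missing*. Mitochondrial SNVs instead use a
hard per-cell VAF threshold (> 0.3) to stay robust to ambient-mtRNA
contamination, which inflates low-level alt reads in noncancer cells.

The mutated-cell fraction (MCF) of a group is the fraction of its cells
genotyped mutated among cells with at least one read at the locus; the
cancer-enrichment statistic dMCF = MCF_cancer - MCF_noncancer drives both
high-confidence-variant selection and mitochondrial calling.

The cell-variant matrix (variants x cells; mutated / wildtype / missing)
is the export consumed by external clonal clustering: SNV rows must be
covered in >= 5 cells, fusion rows detected in >= 3 cells, and cells with
< 3 non-missing variants are dropped, iterated to a fixed point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import BetaParams, DEFAULT_LR_PRIMARY, betabinom_tail
from .io_counts import BaseCountTable, COUNT_COLS

logger = logging.getLogger("longsnv")

MUTATED, WILDTYPE, MISSING = 1, 0, 3  # export encoding, documented in header

GENOTYPE_THRESHOLD = 0.01   # beta-binomial significance for nuclear SNVs
MT_VAF_THRESHOLD = 0.3      # per-cell VAF for mitochondrial SNVs

__all__ = [
    "MUTATED",
    "WILDTYPE",
    "MISSING",
    "genotype_cell_snv",
    "genotype_cell_mt",
    "genotype_cells_at_locus",
    "compute_mcf",
    "CellVariantMatrix",
    "build_matrix",
]


def genotype_cell_snv(alt_reads: int, ref_reads: int,
                      params: BetaParams = DEFAULT_LR_PRIMARY,
                      threshold: float = GENOTYPE_THRESHOLD) -> int:
    """Genotype one cell at a nuclear SNV from alt vs ref read counts.

    Missing if ``alt + ref == 0``; mutated iff the beta-binomial upper tail
    of ``alt`` out of ``alt + ref`` is strictly below ``threshold``; else
    wildtype. Reads supporting other alleles do not enter the test.
    """
    n = alt_reads + ref_reads
    if n == 0:
        return MISSING
    return MUTATED if betabinom_tail(alt_reads, n, params) < threshold else WILDTYPE


def genotype_cell_mt(alt_reads: int, depth: int,
                     vaf_threshold: float = MT_VAF_THRESHOLD) -> int:
    """Genotype one cell at a mitochondrial SNV: mutated iff VAF > 0.3 (strict)."""
    if depth == 0:
        return MISSING
    return MUTATED if alt_reads / depth > vaf_threshold else WILDTYPE


def genotype_cells_at_locus(table: BaseCountTable, chrom: str, pos: int,
                            ref: str, alt: str,
                            params: BetaParams = DEFAULT_LR_PRIMARY,
                            mt: bool = False,
                            threshold: float = GENOTYPE_THRESHOLD,
                            mt_vaf_threshold: float = MT_VAF_THRESHOLD
                            ) -> pd.Series:
    """Vectorized genotypes for every cell with a count row at one locus.

    Returns a barcode-indexed series of {MUTATED, WILDTYPE, MISSING}; cells
    without a row at the locus are absent (callers treat absence as missing).
    """
    cells = table.locus_cells(chrom, pos)
    if cells.empty:
        return pd.Series(dtype=np.int64)
    alt_reads = cells[alt].to_numpy()
    depth = cells[COUNT_COLS].sum(axis=1).to_numpy()
    out = np.full(len(cells), WILDTYPE, dtype=np.int64)
    if mt:
        covered = depth > 0
        with np.errstate(invalid="ignore"):
            vaf = np.where(covered, alt_reads / np.maximum(depth, 1), 0.0)
        out[vaf > mt_vaf_threshold] = MUTATED
        out[~covered] = MISSING
    else:
        ref_reads = cells[ref].to_numpy()
        n = alt_reads + ref_reads
        covered = n > 0
        if covered.any():
            p = np.atleast_1d(
                betabinom_tail(alt_reads[covered], n[covered], params))
            mut = np.zeros(len(cells), dtype=bool)
            mut[np.flatnonzero(covered)[p < threshold]] = True
            out[mut] = MUTATED
        out[~covered] = MISSING
    # A cell with depth 0 everywhere has no row, but an all-zero row can occur.
    out[depth == 0] = MISSING
    return pd.Series(out, index=cells["barcode"].to_numpy())


def compute_mcf(table: BaseCountTable, chrom: str, pos: int, ref: str, alt: str,
                group: Iterable[str], params: BetaParams = DEFAULT_LR_PRIMARY,
                mt: bool = False) -> tuple[float, int, bool]:
    """Mutated-cell fraction of ``group`` at one variant.

    MCF = (cells genotyped mutated) / (cells with depth >= 1 at the locus),
    restricted to the group. Returns ``(mcf, n_covered, no_coverage_flag)``;
    with no covered cells MCF is reported as 0.0 with the flag set.
    """
    group = set(group)
    geno = genotype_cells_at_locus(table, chrom, pos, ref, alt, params, mt=mt)
    geno = geno[geno.index.isin(group)]
    covered = geno[geno != MISSING]
    if len(covered) == 0:
        return 0.0, 0, True
    return float((covered == MUTATED).mean()), int(len(covered)), False


@dataclass
class CellVariantMatrix:
    """Variants x cells genotype matrix with explicit missing state.

    ``values`` holds the export encoding (1 mutated, 0 wildtype, 3 missing);
    rows are variant identifiers ("chrom:pos:ref>alt" or fusion names),
    columns cell barcodes. ``variant_meta`` carries one metadata row per
    variant (kind, chrom, pos, ref, alt).
    """

    values: pd.DataFrame
    variant_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    HEADER = ("# cell-variant matrix: 1 = mutated, 0 = wildtype (reference), "
              "3 = missing (no coverage)")

    def __post_init__(self) -> None:
        self.values.index.name = "variant"
        self.values.columns.name = None

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def row_coverage(self) -> pd.Series:
        """Non-missing entries per variant row."""
        return (self.values != MISSING).sum(axis=1)

    def col_coverage(self) -> pd.Series:
        """Non-missing entries per cell column."""
        return (self.values != MISSING).sum(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.HEADER + "\n")
            self.values.to_csv(fh, sep="\t", index_label="variant")

    @classmethod
    def from_tsv(cls, path) -> "CellVariantMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="variant")
        return cls(df.astype(np.int64))


def _variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def build_matrix(snv_records: Sequence, mt_records: Sequence,
                 fusions: Sequence, table: BaseCountTable,
                 params: BetaParams = DEFAULT_LR_PRIMARY,
                 min_snv_cells: int = 5, min_fusion_cells: int = 3,
                 min_cell_variants: int = 3,
                 cell_barcodes: Iterable[str] | None = None
                 ) -> CellVariantMatrix:
    """Assemble and filter the cell-variant matrix for clonal clustering.

    Rows are genotyped with the single-cell rules (nuclear test, mt VAF,
    fusion detected-or-not; fusion entries are never missing). Row filters
    (SNV/mtSNV rows: >= ``min_snv_cells`` non-missing cells; fusion rows:
    >= ``min_fusion_cells`` detected cells) are applied before the column
    filter (cells with < ``min_cell_variants`` non-missing entries dropped),
    and both are re-applied until a fixed point.
    """
    if cell_barcodes is None:
        cell_barcodes = [bc for bc, lab in table.cell_types.items()
                         if lab in ("cancer", "noncancer")]
    cell_barcodes = list(cell_barcodes)
    rows: dict[str, pd.Series] = {}
    meta_rows = []
    for rec, is_mt in ([(r, False) for r in snv_records]
                       + [(r, True) for r in mt_records]):
        geno = genotype_cells_at_locus(table, rec.chrom, rec.pos, rec.ref,
                                       rec.alt, params, mt=is_mt)
        vid = _variant_id(rec.chrom, rec.pos, rec.ref, rec.alt)
        rows[vid] = geno.reindex(cell_barcodes, fill_value=MISSING)
        meta_rows.append((vid, "mtSNV" if is_mt else "SNV", rec.chrom, rec.pos,
                          rec.ref, rec.alt))
    for fus in fusions:
        detected = pd.Series(
            [MUTATED if bc in fus.cells_detected else WILDTYPE
             for bc in cell_barcodes],
            index=cell_barcodes, dtype=np.int64)
        rows[fus.name] = detected
        meta_rows.append((fus.name, "fusion", "", 0, "", ""))

    if not rows:
        warnings.warn("no variants to genotype: empty cell-variant matrix",
                      RuntimeWarning, stacklevel=2)
        return CellVariantMatrix(pd.DataFrame(), pd.DataFrame(
            columns=["variant", "kind", "chrom", "pos", "ref", "alt"]))

    values = pd.DataFrame(rows).T.astype(np.int64)
    values = values[cell_barcodes]
    meta = pd.DataFrame(meta_rows,
                        columns=["variant", "kind", "chrom", "pos", "ref", "alt"]
                        ).set_index("variant")

    def row_ok(vals: pd.DataFrame) -> pd.Series:
        kinds = meta.loc[vals.index, "kind"]
        nonmissing = (vals != MISSING).sum(axis=1)
        detected = (vals == MUTATED).sum(axis=1)
        return pd.Series(
            np.where(kinds == "fusion", detected >= min_fusion_cells,
                     nonmissing >= min_snv_cells),
            index=vals.index)

    # Rows first, then columns, repeated to a fixed point.
    prev_shape = None
    while values.shape != prev_shape:
        prev_shape = values.shape
        values = values[row_ok(values)]
        if values.empty:
            break
        keep_cols = (values != MISSING).sum(axis=0) >= min_cell_variants
        values = values.loc[:, keep_cols]
        if values.shape[1] == 0:
            break

    if values.empty or values.shape[1] == 0:
        warnings.warn("cell-variant matrix is empty after filtering",
                      RuntimeWarning, stacklevel=2)
    return CellVariantMatrix(values, meta.loc[meta.index.isin(values.index)]
                             .reset_index())
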