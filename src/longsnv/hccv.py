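"""High-confidence cancer variants (HCCVs) and cell-type reannotation.

Marker-gene cell annotations are imperfect: even a few cancer cells labeled
noncancer push a variant's noncancer allele fraction up until the germline
filter rejects it, producing false negatives. Before definitive calling we
therefore select a stringent set of cancer-enriched variants (HCCVs) from
the *original* labels and re-derive each cell's type from its mutational
profile over them.

HCCV SNV chain (in order): pseudo-bulk depth >= 20 in both groups;
other-allele residual noise not significant at 0.05; not near a homopolymer;
population allele frequency < 1%; not an RNA-editing site; not in the SR or
LR panel of normals; VAF_noncancer < 0.2 (low enough to exclude germline
polymorphism, nonzero to tolerate misannotated cells); dMCF > 0.4; finally
no second surviving HCCV within 10 kb. Mitochondrial HCCVs use the same
chain minus the distance rule and with the panel restricted to the long-read
PoN. Fusions are HCCVs iff MCF_cancer > 0.05 and MCF_noncancer < 0.01.

Reannotation: a cell covering < 3 HCCVs is *filtered* (excluded from both
pseudo-bulks downstream); a cell with >= 25% of its covered HCCVs mutated is
*cancer*; otherwise *noncancer*. Fusion HCCVs count as covered in every cell
(detection has no per-cell coverage notion) and mutated where detected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import BetaParams, DEFAULT_LR_OTHER, DEFAULT_LR_PRIMARY
from .genotyping import (MISSING, MUTATED, genotype_cells_at_locus)
from .io_counts import AnnotationResources, BaseCountTable
from .snv_calling import (VariantRecord, filter_distance, filter_editing,
                          filter_gnomad, filter_homopolymer,
                          filter_other_allele_noise, filter_pon)

logger = logging.getLogger("longsnv")

HCCV_MIN_DEPTH = 20
HCCV_MAX_VAF_NONCANCER = 0.2
HCCV_MIN_DELTA_MCF = 0.4
FUSION_HCCV_MIN_MCF_CANCER = 0.05
FUSION_HCCV_MAX_MCF_NONCANCER = 0.01
REANNOTATE_MIN_COVERED = 3
REANNOTATE_CANCER_FRACTION = 0.25

__all__ = [
    "HCCVSet",
    "Reannotation",
    "select_hccv_snvs",
    "select_hccv_mtsnvs",
    "select_hccv_fusions",
    "reannotate_cells",
]


@dataclass
class HCCVSet:
    """Selected high-confidence cancer variants of all three kinds."""

    snvs: list[VariantRecord] = field(default_factory=list)
    mtsnvs: list[VariantRecord] = field(default_factory=list)
    fusions: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snvs) + len(self.mtsnvs) + len(self.fusions)


@dataclass
class Reannotation:
    """Barcode -> {cancer, noncancer, filtered} with per-cell provenance."""

    labels: dict[str, str]
    provenance: pd.DataFrame  # barcode, n_hccv_covered, n_hccv_mutated, fraction

    def to_tsv(self, path, old_labels: Mapping[str, str] | None = None) -> None:
        df = self.provenance.copy()
        df["new_label"] = df["barcode"].map(self.labels)
        if old_labels is not None:
            df["old_label"] = df["barcode"].map(dict(old_labels))
            df = df[["barcode", "old_label", "new_label", "n_hccv_covered",
                     "n_hccv_mutated", "fraction"]]
        df.to_csv(path, sep="\t", index=False)

    def confusion_matrix(self, old_labels: Mapping[str, str]) -> pd.DataFrame:
        """Old-vs-new label cross-tabulation."""
        old = pd.Series({bc: dict(old_labels).get(bc, "absent")
                         for bc in self.labels})
        new = pd.Series(self.labels)
        return pd.crosstab(old, new, rownames=["marker_based"],
                           colnames=["reannotated"])


def _hccv_chain(rec: VariantRecord, resources: AnnotationResources,
                params2: BetaParams, min_depth: int, max_vaf_noncancer: float,
                min_delta_mcf: float, lr_pon_only: bool) -> bool:
    """Per-record HCCV filters (everything except the distance rule)."""
    if rec.cancer_depth < min_depth or rec.noncancer_depth < min_depth:
        return False
    if not filter_other_allele_noise(rec, params2):
        return False
    if not filter_homopolymer(rec, resources):
        return False
    if not filter_gnomad(rec, resources):
        return False
    if not filter_editing(rec, resources):
        return False
    if not filter_pon(rec, resources, use_sr=not lr_pon_only, use_lr=True):
        return False
    if not rec.vaf_noncancer < max_vaf_noncancer:
        return False
    if not rec.delta_mcf > min_delta_mcf:   # strict: dMCF == 0.4 is rejected
        return False
    return True


def select_hccv_snvs(candidates: Sequence[VariantRecord],
                     resources: AnnotationResources,
                     params1: BetaParams = DEFAULT_LR_PRIMARY,
                     params2: BetaParams = DEFAULT_LR_OTHER,
                     min_depth: int = HCCV_MIN_DEPTH,
                     max_vaf_noncancer: float = HCCV_MAX_VAF_NONCANCER,
                     min_delta_mcf: float = HCCV_MIN_DELTA_MCF,
                     min_distance: int = 10_000) -> list[VariantRecord]:
    """Nuclear HCCVs from candidates called under the original labels."""
    survivors = [r for r in candidates
                 if not r.is_mt and _hccv_chain(r, resources, params2,
                                                min_depth, max_vaf_noncancer,
                                                min_delta_mcf, lr_pon_only=False)]
    return filter_distance(survivors, min_distance)


def select_hccv_mtsnvs(candidates: Sequence[VariantRecord],
                       resources: AnnotationResources,
                       params2: BetaParams = DEFAULT_LR_OTHER,
                       min_depth: int = HCCV_MIN_DEPTH,
                       max_vaf_noncancer: float = HCCV_MAX_VAF_NONCANCER,
                       min_delta_mcf: float = HCCV_MIN_DELTA_MCF
                       ) -> list[VariantRecord]:
    """Mitochondrial HCCVs: same chain, no distance rule, LR PoN only."""
    return [r for r in candidates
            if r.is_mt and _hccv_chain(r, resources, params2, min_depth,
                                       max_vaf_noncancer, min_delta_mcf,
                                       lr_pon_only=True)]


def select_hccv_fusions(fusion_calls: Sequence,
                        min_mcf_cancer: float = FUSION_HCCV_MIN_MCF_CANCER,
                        max_mcf_noncancer: float = FUSION_HCCV_MAX_MCF_NONCANCER
                        ) -> list:
    """Fusion HCCVs: MCF_cancer > 0.05 and MCF_noncancer < 0.01 (both strict)."""
    return [f for f in fusion_calls
            if f.mcf_cancer > min_mcf_cancer
            and f.mcf_noncancer < max_mcf_noncancer]


def reannotate_cells(table: BaseCountTable, hccv: HCCVSet,
                     params: BetaParams = DEFAULT_LR_PRIMARY,
                     min_covered: int = REANNOTATE_MIN_COVERED,
                     cancer_fraction: float = REANNOTATE_CANCER_FRACTION
                     ) -> Reannotation:
    """Relabel every cell from its mutational profile over the HCCVs.

    Deterministic: covered < ``min_covered`` -> filtered; mutated fraction
    >= ``cancer_fraction`` (inclusive) -> cancer; else noncancer. SNV and
    mitochondrial HCCVs count as covered where the cell has >= 1 read and as
    mutated per the single-cell genotyping rules; every fusion HCCV counts
    as covered in every cell and as mutated where detected.
    """
    barcodes = [bc for bc in table.cell_types]
    covered = pd.Series(0, index=barcodes, dtype=np.int64)
    mutated = pd.Series(0, index=barcodes, dtype=np.int64)
    for rec, mt in ([(r, False) for r in hccv.snvs]
                    + [(r, True) for r in hccv.mtsnvs]):
        geno = genotype_cells_at_locus(table, rec.chrom, rec.pos, rec.ref,
                                       rec.alt, params, mt=mt)
        geno = geno[geno.index.isin(covered.index)]
        has_cov = geno[geno != MISSING]
        covered.loc[has_cov.index] += 1
        mutated.loc[has_cov[has_cov == MUTATED].index] += 1
    for fus in hccv.fusions:
        covered += 1
        detected = [bc for bc in barcodes if bc in fus.cells_detected]
        mutated.loc[detected] += 1

    with np.errstate(invalid="ignore"):
        fraction = np.where(covered > 0, mutated / covered.replace(0, 1), 0.0)
    labels: dict[str, str] = {}
    for bc, cov, mut, frac in zip(barcodes, covered, mutated, fraction):
        if cov < min_covered:
            labels[bc] = "filtered"
        elif frac >= cancer_fraction:
            labels[bc] = "cancer"
        else:
            labels[bc] = "noncancer"
    n_filtered = sum(1 for v in labels.values() if v == "filtered")
    if n_filtered:
        logger.info("reannotation: %d cells filtered (<%d HCCVs covered)",
                    n_filtered, min_covered)
    prov = pd.DataFrame({
        "barcode": barcodes,
        "n_hccv_covered": covered.to_numpy(),
        "n_hccv_mutated": mutated.to_numpy(),
        "fraction": fraction,
    })
    return Reannotation(labels, prov)
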