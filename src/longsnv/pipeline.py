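"""Two-pass workflow orchestration.

Pass 1 (under the marker-based input labels): detect nuclear and
mitochondrial candidates, select high-confidence cancer variants, and
reannotate every cell from its mutational profile. Pass 2 (under the
reannotated labels, with *filtered* cells excluded from both pseudo-bulks):
definitive nuclear SNV calling through the 10-filter battery, mitochondrial
calling through the contamination-robust chain, fusion selection, single-cell
genotyping and cell-variant matrix export, and — when paired scWGS clone
counts are supplied — support classification and benchmark metrics.

Reannotation can be disabled, which collapses the workflow to a single pass
on the input labels (the configuration used for A/B comparisons against a
reannotation-free caller).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .error_model import (BetaParams, DEFAULT_LR_OTHER, DEFAULT_LR_PRIMARY)
from .fusions import (FusionCall, fusion_calls_from_table, select_somatic_fusions,
                      write_fusion_tsv)
from .genotyping import CellVariantMatrix, build_matrix
from .hccv import (HCCVSet, Reannotation, reannotate_cells, select_hccv_fusions,
                   select_hccv_mtsnvs, select_hccv_snvs)
from .io_counts import (AnnotationResources, BaseCountTable,
                        aggregate_pseudobulk)
from .mtsnv import call_somatic_mtsnvs
from .scwgs import CloneCounts, call_scwgs_denovo, classify_support, performance
from .snv_calling import CallSet, call_somatic_snvs, detect_candidates

logger = logging.getLogger("longsnv")

RECOMMENDED_MIN_MAPPED_BASES = 2_000_000_000  # advisory, high-quality data

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_from_config"]


@dataclass
class RunConfig:
    """File-based run configuration (every threshold exposed, with the
    printed defaults); serialized into the output directory for provenance."""

    counts_tsv: str = ""
    cell_types_tsv: str = ""
    fusion_tsv: str | None = None
    gnomad_path: str | None = None
    editing_path: str | None = None
    pon_sr_path: str | None = None
    pon_lr_path: str | None = None
    reference_fasta: str | None = None
    scwgs_pooled_tsv: str | None = None
    scwgs_cells_tsv: str | None = None
    out_dir: str = "longsnv_out"
    reannotate: bool = True
    seed: int = 0
    log_level: str = "INFO"
    alpha1: float = DEFAULT_LR_PRIMARY.alpha
    beta1: float = DEFAULT_LR_PRIMARY.beta
    alpha2: float = DEFAULT_LR_OTHER.alpha
    beta2: float = DEFAULT_LR_OTHER.beta
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


@dataclass
class PipelineResult:
    labels: dict[str, str]
    reannotation: Reannotation | None
    hccv: HCCVSet | None
    snv_callset: CallSet
    mt_callset: CallSet
    fusions: list[FusionCall]
    matrix: CellVariantMatrix
    validation: dict | None
    out_dir: Path | None


def _scale_guardrails(table: BaseCountTable) -> None:
    total_bases = int(table.depth.sum())
    if total_bases < RECOMMENDED_MIN_MAPPED_BASES:
        logger.warning(
            "dataset has %.3g mapped bases in counted pileups; the "
            "recommended scale for high-quality data is >= 2e9 mapped bases "
            "per cell type with >= 5 reads per locus per cell type — results "
            "on smaller data are exploratory", total_bases)


def run_pipeline(table: BaseCountTable,
                 resources: AnnotationResources,
                 fusion_table: pd.DataFrame | None = None,
                 params1: BetaParams = DEFAULT_LR_PRIMARY,
                 params2: BetaParams = DEFAULT_LR_OTHER,
                 reannotate: bool = True,
                 scwgs_clone_counts: CloneCounts | None = None,
                 out_dir=None,
                 **thresholds) -> PipelineResult:
    """Run the full two-pass workflow on in-memory inputs.

    Deterministic: no stage draws random numbers. Outputs (reannotation TSV,
    nuclear and mitochondrial VCFs, selected-fusion TSV, cell-variant matrix,
    funnel TSV, metrics JSON) are written when ``out_dir`` is given; any
    stage failure propagates with partial outputs preserved on disk.
    """
    _scale_guardrails(table)
    original_labels = dict(table.cell_types)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    reannotation = None
    hccv = None
    if reannotate:
        logger.info("pass 1: candidate detection under input labels")
        cancer_pb = aggregate_pseudobulk(
            table, table.barcodes_of_type("cancer"), "cancer")
        nuc_cand = detect_candidates(cancer_pb, table, genotype_params=params1)
        mt_cand = detect_candidates(cancer_pb, table, genotype_params=params1,
                                    mt=True)
        hccv = HCCVSet(
            snvs=select_hccv_snvs(nuc_cand, resources, params1, params2),
            mtsnvs=select_hccv_mtsnvs(mt_cand, resources, params2),
            fusions=(select_hccv_fusions(
                fusion_calls_from_table(fusion_table, original_labels))
                if fusion_table is not None else []),
        )
        logger.info("HCCVs: %d SNVs, %d mtSNVs, %d fusions",
                    len(hccv.snvs), len(hccv.mtsnvs), len(hccv.fusions))
        reannotation = reannotate_cells(table, hccv, params1)
        labels = reannotation.labels
        if out_dir is not None:
            reannotation.to_tsv(out_dir / "reannotation.tsv", original_labels)
            reannotation.confusion_matrix(original_labels).to_csv(
                out_dir / "reannotation_confusion.tsv", sep="\t")
    else:
        labels = original_labels

    logger.info("pass 2: definitive calling under %s labels",
                "reannotated" if reannotate else "input")
    table2 = table.with_cell_types(labels)
    snv_callset = call_somatic_snvs(table2, labels, resources, params1,
                                    params2, **thresholds)
    cancer_pb2 = aggregate_pseudobulk(
        table2, table2.barcodes_of_type("cancer"), "cancer")
    mt_cand2 = detect_candidates(cancer_pb2, table2, genotype_params=params1,
                                 mt=True)
    mt_callset = call_somatic_mtsnvs(mt_cand2, resources)
    fusions = (select_somatic_fusions(fusion_table, labels)
               if fusion_table is not None else [])

    matrix = build_matrix(snv_callset.passed, mt_callset.passed, fusions,
                          table2, params1)

    validation = None
    if scwgs_clone_counts is not None:
        noncancer_pb2 = aggregate_pseudobulk(
            table2, table2.barcodes_of_type("noncancer"), "noncancer")
        called = {(r.chrom, r.pos, r.alt) for r in snv_callset.passed}
        support = {
            f"{c}:{p}:{a}": classify_support(c, p, a, scwgs_clone_counts,
                                             params1)
            for (c, p, a) in sorted(called)
        }
        denovo = call_scwgs_denovo(scwgs_clone_counts, cancer_pb2,
                                   noncancer_pb2, params1)
        truth = {(r.chrom, int(r.pos), r.alt)
                 for r in denovo.itertuples() if r.somatic}
        eligible = {(r.chrom, int(r.pos), r.alt) for r in denovo.itertuples()}
        validation = {
            "support_labels": support,
            "n_truth_somatic": len(truth),
            **performance(called, truth, eligible | called),
        }

    if out_dir is not None:
        snv_callset.write_vcf(out_dir / "somatic_snvs.vcf")
        snv_callset.write_funnel_tsv(out_dir / "snv_funnel.tsv")
        mt_callset.write_vcf(out_dir / "somatic_mtsnvs.vcf", mt_flag=True)
        mt_callset.write_funnel_tsv(out_dir / "mtsnv_funnel.tsv")
        write_fusion_tsv(fusions, out_dir / "somatic_fusions.tsv")
        matrix.to_tsv(out_dir / "cell_variant_matrix.tsv")
        if not matrix.variant_meta.empty:
            matrix.variant_meta.to_csv(out_dir / "variant_metadata.tsv",
                                       sep="\t", index=False)
        if validation is not None:
            with open(out_dir / "scwgs_metrics.json", "w") as fh:
                json.dump(validation, fh, indent=1)
    return PipelineResult(labels, reannotation, hccv, snv_callset, mt_callset,
                          fusions, matrix, validation, out_dir)


def run_from_config(config: RunConfig) -> PipelineResult:
    """Load every input named in ``config`` and run the workflow."""
    from .io_counts import load_resources

    logging.basicConfig(level=config.log_level)
    cell_types = pd.read_csv(config.cell_types_tsv, sep="\t",
                             dtype=str).set_index("barcode")["cell_type"].to_dict()
    table = BaseCountTable.from_tsv(config.counts_tsv, cell_types)
    resources = load_resources(config.gnomad_path, config.editing_path,
                               config.pon_sr_path, config.pon_lr_path,
                               config.reference_fasta)
    fusion_table = (pd.read_csv(config.fusion_tsv, sep="\t", dtype=str)
                    if config.fusion_tsv else None)
    clone_counts = (CloneCounts.from_tsv(config.scwgs_pooled_tsv,
                                         config.scwgs_cells_tsv)
                    if config.scwgs_pooled_tsv else None)
    params1 = BetaParams(config.alpha1, config.beta1, source="default_LR")
    params2 = BetaParams(config.alpha2, config.beta2, source="default_LR")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    return run_pipeline(table, resources, fusion_table, params1, params2,
                        reannotate=config.reannotate,
                        scwgs_clone_counts=clone_counts, out_dir=out_dir,
                        **config.thresholds)
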