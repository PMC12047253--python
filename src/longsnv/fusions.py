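"""Somatic fusion selection from an external fusion caller's per-cell table.

Fusion detection itself is out of scope: a long-read fusion caller
(CTAT-LR-fusion-like) provides a per-cell table with at least the columns
``fusion_name`` and ``cell_barcode``. A fusion is somatic iff it is detected
in more than 5% of cancer cells and in fewer than 1% of noncancer cells
(both strict); the nonzero noncancer tolerance exists because ambient cancer
RNA can deposit fusion reads in noncancer droplets. MCF denominators are all
cells of the type — detection has no per-cell coverage notion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("longsnv")

FUSION_MIN_MCF_CANCER = 0.05
FUSION_MAX_MCF_NONCANCER = 0.01

__all__ = [
    "FusionCall",
    "read_fusion_table",
    "fusion_calls_from_table",
    "select_somatic_fusions",
    "write_fusion_tsv",
]


@dataclass
class FusionCall:
    """One gene fusion ("GENEA--GENEB") with the cells it was detected in."""

    name: str
    cells_detected: frozenset = field(default_factory=frozenset)
    mcf_cancer: float = 0.0
    mcf_noncancer: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mcf_cancer <= 1.0 and 0.0 <= self.mcf_noncancer <= 1.0):
            raise ValueError("fusion MCFs must lie in [0, 1]")


def read_fusion_table(path) -> pd.DataFrame:
    """Read a per-cell fusion TSV (columns fusion_name, cell_barcode, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("fusion_name", "cell_barcode"):
        if col not in df.columns:
            raise ValueError(f"fusion table missing required column {col!r}")
    return df


def fusion_calls_from_table(calls: pd.DataFrame,
                            cell_types: Mapping[str, str]) -> list[FusionCall]:
    """Aggregate per-cell rows into :class:`FusionCall` objects with MCFs.

    Duplicate (fusion, cell) rows are counted once; barcodes absent from
    ``cell_types`` are ignored with a warning. Output is sorted by name,
    independent of input row order.
    """
    cell_types = dict(cell_types)
    n_cancer = sum(1 for v in cell_types.values() if v == "cancer")
    n_noncancer = sum(1 for v in cell_types.values() if v == "noncancer")
    dedup = calls[["fusion_name", "cell_barcode"]].drop_duplicates()
    unknown = set(dedup["cell_barcode"]) - set(cell_types)
    if unknown:
        warnings.warn(
            f"{len(unknown)} fusion-table barcodes absent from cell types "
            f"(e.g. {sorted(unknown)[:3]}); ignored", RuntimeWarning,
            stacklevel=2)
        dedup = dedup[~dedup["cell_barcode"].isin(unknown)]
    out = []
    for name, grp in sorted(dedup.groupby("fusion_name")):
        cells = frozenset(grp["cell_barcode"])
        in_cancer = sum(1 for bc in cells if cell_types.get(bc) == "cancer")
        in_noncancer = sum(1 for bc in cells if cell_types.get(bc) == "noncancer")
        out.append(FusionCall(
            name=name, cells_detected=cells,
            mcf_cancer=in_cancer / n_cancer if n_cancer else 0.0,
            mcf_noncancer=in_noncancer / n_noncancer if n_noncancer else 0.0))
    return out


def select_somatic_fusions(calls, cell_types: Mapping[str, str] | None = None,
                           min_mcf_cancer: float = FUSION_MIN_MCF_CANCER,
                           max_mcf_noncancer: float = FUSION_MAX_MCF_NONCANCER
                           ) -> list[FusionCall]:
    """Keep fusions with MCF_cancer > 0.05 and MCF_noncancer < 0.01 (strict).

    ``calls`` may be a per-cell DataFrame (then ``cell_types`` — the
    reannotated labels — is required to compute MCFs) or a pre-aggregated
    list of :class:`FusionCall`.
    """
    if isinstance(calls, pd.DataFrame):
        if cell_types is None:
            raise ValueError("cell_types required when passing a per-cell table")
        calls = fusion_calls_from_table(calls, cell_types)
    selected = [f for f in calls
                if f.mcf_cancer > min_mcf_cancer
                and f.mcf_noncancer < max_mcf_noncancer]
    logger.info("fusion selection: %d of %d fusions somatic",
                len(selected), len(list(calls)))
    return selected


def write_fusion_tsv(fusions: Sequence[FusionCall], path) -> None:
    pd.DataFrame(
        [(f.name, len(f.cells_detected), f.mcf_cancer, f.mcf_noncancer)
         for f in fusions],
        columns=["fusion_name", "n_cells_detected", "mcf_cancer",
                 "mcf_noncancer"],
    ).to_csv(path, sep="\t", index=False)
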