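"""Per-cell base counts, pseudo-bulk aggregation, and annotation resources.

The atomic evidence unit of the whole package is the :class:`BaseCountTable`:
for every (locus, cell barcode) pair, the number of reads supporting each of
A, C, G, T and anything else, after mapping- and base-quality filtering.
Pseudo-bulks sum these counts over a named cell group (cancer, noncancer,
a scWGS clone, an empty-droplet set) and are the substrate of candidate
detection and of every aggregated statistical test.

Coordinates are 1-based and fully closed, matching VCF; the only half-open
intervals are the internal homopolymer tracts (documented on
:class:`AnnotationResources`).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .error_model import BetaParams, betabinom_tail

logger = logging.getLogger("longsnv")

BASES = ("A", "C", "G", "T")
COUNT_COLS = ["A", "C", "G", "T", "other"]
TABLE_COLS = ["chrom", "pos", "ref", "barcode"] + COUNT_COLS

#: Contig names recognized as mitochondrial.
MT_CONTIGS = frozenset({"chrM", "MT", "chrMT"})

#: Cell-barcode tags tried in order, then UMI tags (duplicate handling only).
BARCODE_TAGS = ("CB", "XC")
UMI_TAGS = ("UB", "XM")

__all__ = [
    "BASES",
    "COUNT_COLS",
    "MT_CONTIGS",
    "Locus",
    "BaseCountTable",
    "PseudoBulk",
    "AnnotationResources",
    "read_bam_pileup",
    "aggregate_pseudobulk",
    "build_lr_pon",
    "load_resources",
    "empty_droplet_vaf",
]


@dataclass(frozen=True, order=True)
class Locus:
    """A genomic coordinate with its reference base (1-based, closed)."""

    chrom: str
    pos: int
    ref: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES:
            raise ValueError(f"ref must be one of {BASES}, got {self.ref!r}")

    @property
    def is_mitochondrial(self) -> bool:
        return self.chrom in MT_CONTIGS


class BaseCountTable:
    """Per (locus, cell) counts of A/C/G/T/other reads passing quality filters.

    Parameters
    ----------
    counts
        Frame with columns chrom, pos, ref, barcode, A, C, G, T, other.
        One row per (locus, barcode); counts are non-negative integers.
    cell_types
        Barcode -> label map; labels are ``"cancer"`` / ``"noncancer"``
        (``"filtered"`` appears after reannotation). Every barcode present in
        ``counts`` must appear here or in ``droplet_barcodes``.
    droplet_barcodes
        Barcodes declared as empty droplets (kept out of every cell group).
    min_mapping_quality
        The mapping-quality threshold used at construction (provenance only).
    """

    def __init__(self, counts: pd.DataFrame, cell_types: Mapping[str, str],
                 min_mapping_quality: int = 60,
                 droplet_barcodes: Iterable[str] = ()) -> None:
        counts = counts.copy()
        missing = [c for c in TABLE_COLS if c not in counts.columns]
        if missing:
            raise ValueError(f"counts frame missing columns {missing}")
        counts = counts[TABLE_COLS]
        for c in COUNT_COLS:
            counts[c] = counts[c].astype(np.int64)
            if (counts[c] < 0).any():
                raise ValueError(f"negative counts in column {c}")
        counts["pos"] = counts["pos"].astype(np.int64)
        self.counts = counts.reset_index(drop=True)
        self.cell_types = dict(cell_types)
        self.droplet_barcodes = frozenset(droplet_barcodes)
        self.min_mapping_quality = int(min_mapping_quality)
        known = set(self.cell_types) | self.droplet_barcodes
        unknown = set(self.counts["barcode"].unique()) - known
        if unknown:
            raise ValueError(
                f"{len(unknown)} barcodes in counts are neither typed cells nor "
                f"declared droplets (e.g. {sorted(unknown)[:3]})"
            )
        self._locus_groups: dict | None = None

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def depth(self) -> pd.Series:
        """Per-row total depth (sum of the five count columns)."""
        return self.counts[COUNT_COLS].sum(axis=1)

    def barcodes_of_type(self, label: str) -> set[str]:
        return {bc for bc, lab in self.cell_types.items() if lab == label}

    def loci(self) -> pd.DataFrame:
        """Unique (chrom, pos, ref) rows, sorted."""
        return (self.counts[["chrom", "pos", "ref"]]
                .drop_duplicates()
                .sort_values(["chrom", "pos"])
                .reset_index(drop=True))

    def locus_cells(self, chrom: str, pos: int) -> pd.DataFrame:
        """Per-cell count rows at one locus (cached index, O(1) after build)."""
        if self._locus_groups is None:
            self._locus_groups = {
                key: df for key, df in self.counts.groupby(["chrom", "pos"], sort=False)
            }
        return self._locus_groups.get(
            (chrom, pos),
            self.counts.iloc[0:0],
        )

    def subset_cells(self, barcodes: Iterable[str]) -> "BaseCountTable":
        barcodes = set(barcodes)
        sub = self.counts[self.counts["barcode"].isin(barcodes)]
        return BaseCountTable(
            sub,
            {bc: lab for bc, lab in self.cell_types.items() if bc in barcodes},
            self.min_mapping_quality,
            self.droplet_barcodes & barcodes,
        )

    def with_cell_types(self, cell_types: Mapping[str, str]) -> "BaseCountTable":
        """Same counts under new labels (used after reannotation)."""
        return BaseCountTable(self.counts, cell_types, self.min_mapping_quality,
                              self.droplet_barcodes)

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the count table in the package TSV dialect (header, tab-sep)."""
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cell_types: Mapping[str, str],
                 min_mapping_quality: int = 60,
                 droplet_barcodes: Iterable[str] = ()) -> "BaseCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "barcode": str})
        return cls(df, cell_types, min_mapping_quality, droplet_barcodes)


@dataclass
class PseudoBulk:
    """Per-locus counts aggregated over a named cell group.

    ``counts`` is indexed by (chrom, pos, ref) and carries the five base
    columns plus ``depth`` (their sum) and ``n_cells_covered`` (member cells
    with depth >= 1 at the locus).
    """

    group_name: str
    n_cells: int
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.empty and (self.counts["n_cells_covered"] > self.n_cells).any():
            raise ValueError("n_cells_covered exceeds group size")

    def ref_alt_counts(self) -> pd.DataFrame:
        """Reference count, nonreference count and depth per locus."""
        df = self.counts
        ref = df.index.get_level_values("ref")
        base = np.stack([df[b].to_numpy() for b in BASES], axis=1)
        ridx = np.searchsorted(np.array(BASES), np.asarray(ref))
        ref_counts = base[np.arange(len(df)), ridx]
        out = pd.DataFrame(
            {"ref_count": ref_counts, "depth": df["depth"].to_numpy()},
            index=df.index,
        )
        out["nonref_count"] = out["depth"] - out["ref_count"]
        return out


def aggregate_pseudobulk(table: BaseCountTable, group: Iterable[str],
                         name: str) -> PseudoBulk:
    """Sum per-cell counts over ``group`` into a named pseudo-bulk.

    Pseudo-bulk depth at every locus equals the sum of member-cell depths
    (conservation); ``n_cells_covered`` counts member cells with depth >= 1.
    An empty group yields an empty pseudo-bulk with a warning.
    """
    group = set(group)
    extra = group - set(table.cell_types) - table.droplet_barcodes
    if extra:
        raise ValueError(f"group contains unknown barcodes, e.g. {sorted(extra)[:3]}")
    if not group:
        warnings.warn(f"pseudo-bulk {name!r} built from an empty group",
                      RuntimeWarning, stacklevel=2)
    sub = table.counts[table.counts["barcode"].isin(group)]
    if sub.empty:
        empty = pd.DataFrame(
            columns=COUNT_COLS + ["depth", "n_cells_covered"],
            index=pd.MultiIndex.from_arrays([[], [], []],
                                            names=["chrom", "pos", "ref"]),
        )
        return PseudoBulk(name, len(group), empty)
    depth = sub[COUNT_COLS].sum(axis=1)
    work = sub.assign(_depth=depth, _cov=(depth >= 1).astype(np.int64))
    agg = work.groupby(["chrom", "pos", "ref"], sort=True).agg(
        {**{c: "sum" for c in COUNT_COLS}, "_depth": "sum", "_cov": "sum"}
    )
    agg = agg.rename(columns={"_depth": "depth", "_cov": "n_cells_covered"})
    return PseudoBulk(name, len(group), agg)


def build_lr_pon(normal_pileups: Sequence[PseudoBulk], params: BetaParams,
                 alpha_level: float = 0.05) -> set[tuple[str, int]]:
    """Long-read panel of normals: loci recurrently noisy in normal samples.

    A locus enters the panel iff its nonreference counts are significantly
    higher than the background error rate (beta-binomial upper tail,
    strictly below ``alpha_level``) in *any* of the normal pseudo-bulks.
    Matched samples of the patient under analysis must be excluded by the
    caller (leave-one-patient-out).
    """
    if not normal_pileups:
        warnings.warn("no normal samples provided: empty long-read PoN",
                      RuntimeWarning, stacklevel=2)
        return set()
    pon: set[tuple[str, int]] = set()
    for pb in normal_pileups:
        ra = pb.ref_alt_counts()
        if ra.empty:
            continue
        p = betabinom_tail(ra["nonref_count"].to_numpy(),
                           ra["depth"].to_numpy(), params)
        sig = np.atleast_1d(p) < alpha_level
        for (chrom, pos, _ref), s in zip(ra.index, np.atleast_1d(sig)):
            if s:
                pon.add((chrom, int(pos)))
    return pon


@dataclass
class AnnotationResources:
    """Static filtering resources.

    ``homopolymer_tracts`` maps chrom -> list of (start, end, base) with
    half-open 1-based coordinates: the tract occupies positions
    start .. end-1 inclusive. All other coordinates in the package are
    closed 1-based.
    """

    gnomad_freq: dict[tuple[str, int, str], float] = field(default_factory=dict)
    editing_sites: set[tuple[str, int]] = field(default_factory=set)
    pon_sr: set[tuple[str, int]] = field(default_factory=set)
    pon_lr: set[tuple[str, int]] = field(default_factory=set)
    homopolymer_tracts: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for af in self.gnomad_freq.values():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"population allele frequency out of [0,1]: {af}")

    def gnomad_af(self, chrom: str, pos: int, alt: str) -> float | None:
        return self.gnomad_freq.get((chrom, pos, alt))

    def homopolymer_tree(self, chrom: str, flank: int) -> IntervalTree:
        """Interval tree of tracts extended by ``flank`` bp on each side."""
        key = (chrom, flank)
        if key not in self._trees:
            tree = IntervalTree()
            for start, end, _base in self.homopolymer_tracts.get(chrom, []):
                tree.addi(start - flank, end + flank)  # half-open
            self._trees[key] = tree
        return self._trees[key]

    def near_homopolymer(self, chrom: str, pos: int, flank: int = 4) -> bool:
        """True iff ``pos`` is inside a tract or within ``flank`` bp of one."""
        return bool(self.homopolymer_tree(chrom, flank)[pos])


def _scan_homopolymers(seq: str, tract_min: int) -> list[tuple[int, int, str]]:
    """Maximal mononucleotide runs of length >= tract_min, half-open 1-based."""
    out = []
    for m in re.finditer(r"A{%d,}|C{%d,}|G{%d,}|T{%d,}" % ((tract_min,) * 4),
                         seq.upper()):
        out.append((m.start() + 1, m.end() + 1, seq[m.start()].upper()))
    return out


def _read_site_file(path) -> set[tuple[str, int]]:
    """Read a site list from 3-column BED (0-based half-open) or chrom/pos TSV."""
    path = Path(path)
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if parts[0] in ("chrom", "chr"):  # header
                continue
            try:
                if path.suffix.lower() == ".bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    sites.update((chrom, p) for p in range(start + 1, end + 1))
                else:
                    chrom, pos = parts[0], int(parts[1])
                    sites.add((chrom, pos))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed record {line!r}") from exc
    return sites


def _read_gnomad(path) -> dict[tuple[str, int, str], float]:
    """Population allele frequencies from a VCF (AF INFO) or 4-column TSV."""
    path = Path(path)
    freqs: dict[tuple[str, int, str], float] = {}
    if path.suffix.lower() in (".vcf", ".gz", ".bcf") or ".vcf" in path.suffixes:
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                afs = rec.info.get("AF")
                if afs is None:
                    continue
                if not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    freqs[(rec.chrom, rec.pos, alt)] = float(af)
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("chrom"):
                    continue
                try:
                    chrom, pos, alt, af = line.split("\t")[:4]
                    freqs[(chrom, int(pos), alt)] = float(af)
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{ln}: malformed record {line!r}") from exc
    return freqs


def load_resources(gnomad_path=None, editing_path=None, pon_sr_path=None,
                   pon_lr_path=None, reference_fasta=None,
                   tract_min: int = 4) -> AnnotationResources:
    """Load gnomAD frequencies, RNA-editing sites, PoN site lists, homopolymers.

    Any missing optional resource yields an empty set with a warning.
    Homopolymer tracts are computed from the reference as maximal
    mononucleotide runs of length >= ``tract_min``.
    """
    res = AnnotationResources()
    if gnomad_path is not None:
        res.gnomad_freq = _read_gnomad(gnomad_path)
    else:
        warnings.warn("no population-frequency resource: gnomAD filter is a no-op",
                      RuntimeWarning, stacklevel=2)
    if editing_path is not None:
        res.editing_sites = _read_site_file(editing_path)
    if pon_sr_path is not None:
        res.pon_sr = _read_site_file(pon_sr_path)
    if pon_lr_path is not None:
        res.pon_lr = _read_site_file(pon_lr_path)
    if reference_fasta is not None:
        if isinstance(reference_fasta, Mapping):
            seqs = reference_fasta.items()
            res.homopolymer_tracts = {
                name: _scan_homopolymers(str(seq), tract_min) for name, seq in seqs
            }
        else:
            from pyfaidx import Fasta

            with Fasta(str(reference_fasta)) as fa:
                res.homopolymer_tracts = {
                    name: _scan_homopolymers(str(fa[name][:]), tract_min)
                    for name in fa.keys()
                }
    return res


# -- BAM ingest ------------------------------------------------------------


def read_bam_pileup(alignment_path, cell_types: Mapping[str, str],
                    min_mq: int = 60, min_bq: int = 20,
                    droplet_barcodes: Iterable[str] = (),
                    barcode_tags: Sequence[str] = BARCODE_TAGS,
                    reference=None,
                    max_depth: int = 1_000_000) -> BaseCountTable:
    """Pile up a barcoded, indexed BAM/CRAM into a :class:`BaseCountTable`.

    Only reads with mapping quality >= ``min_mq`` and bases with quality >=
    ``min_bq`` are counted; unmapped, secondary, supplementary, QC-fail and
    duplicate-flagged reads are excluded (UMI duplicates are therefore counted
    once when duplicate flags are present). Reads whose barcode tag is absent
    or maps to no known cell or declared droplet are skipped and tallied in a
    skip log.

    ``reference`` may be a chrom -> sequence mapping or a FASTA path and
    provides the reference base per locus; without it the majority base
    across all reads is used (adequate only for error-dominated loci).
    """
    import pysam

    droplet_barcodes = frozenset(droplet_barcodes)
    known = set(cell_types) | droplet_barcodes
    ref_lookup = None
    if reference is not None:
        if isinstance(reference, Mapping):
            ref_lookup = {k: str(v).upper() for k, v in reference.items()}
        else:
            from pyfaidx import Fasta

            fa = Fasta(str(reference))
            ref_lookup = {name: str(fa[name][:]).upper() for name in fa.keys()}

    af = pysam.AlignmentFile(str(alignment_path))
    try:
        if not af.has_index():
            raise FileNotFoundError(
                f"{alignment_path} has no index; run `samtools index` first"
            )
        tallies: dict[tuple[str, int, str], np.ndarray] = {}
        skipped = {"no_barcode": 0, "unknown_barcode": 0}
        flag_filter = (pysam.FUNMAP | pysam.FSECONDARY | pysam.FQCFAIL
                       | pysam.FDUP | pysam.FSUPPLEMENTARY)
        base_idx = {b: i for i, b in enumerate(BASES)}
        for col in af.pileup(min_base_quality=min_bq,
                             min_mapping_quality=min_mq,
                             flag_filter=flag_filter,
                             max_depth=max_depth,
                             stepper="samtools",
                             ignore_overlaps=False,
                             ignore_orphans=False):
            chrom, pos = col.reference_name, col.reference_pos + 1
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                read = pr.alignment
                barcode = None
                for tag in barcode_tags:
                    if read.has_tag(tag):
                        barcode = read.get_tag(tag)
                        break
                if barcode is None:
                    skipped["no_barcode"] += 1
                    continue
                if barcode not in known:
                    skipped["unknown_barcode"] += 1
                    continue
                base = read.query_sequence[pr.query_position].upper()
                key = (chrom, pos, barcode)
                if key not in tallies:
                    tallies[key] = np.zeros(5, dtype=np.int64)
                tallies[key][base_idx.get(base, 4)] += 1
    finally:
        af.close()

    if any(skipped.values()):
        logger.warning("read_bam_pileup skipped reads: %s", skipped)

    rows = []
    for (chrom, pos, barcode), counts in tallies.items():
        if ref_lookup is not None:
            ref = ref_lookup[chrom][pos - 1]
        else:
            ref = BASES[int(np.argmax(counts[:4]))]
        if ref not in BASES:
            continue
        rows.append((chrom, pos, ref, barcode, *counts.tolist()))
    df = pd.DataFrame(rows, columns=TABLE_COLS)
    if not df.empty:
        df = df.sort_values(["chrom", "pos", "barcode"]).reset_index(drop=True)
    table = BaseCountTable(df, cell_types, min_mq, droplet_barcodes)
    table.skipped_reads = skipped  # type: ignore[attr-defined]
    return table


def empty_droplet_vaf(table: BaseCountTable, droplet_barcodes: Iterable[str],
                      loci: Sequence[tuple[Locus, str]]) -> pd.DataFrame:
    """VAF of given (locus, alt) pairs in each empty droplet.

    Droplets with zero depth at a locus are omitted. Returns a frame with
    columns barcode, chrom, pos, alt, alt_reads, depth, vaf.
    """
    droplet_barcodes = set(droplet_barcodes)
    overlap = droplet_barcodes & set(table.cell_types)
    if overlap:
        raise ValueError("droplet barcodes must be disjoint from cell barcodes")
    rows = []
    for locus, alt in loci:
        cells = table.locus_cells(locus.chrom, locus.pos)
        cells = cells[cells["barcode"].isin(droplet_barcodes)]
        if cells.empty:
            continue
        depth = cells[COUNT_COLS].sum(axis=1)
        for (_, row), d in zip(cells.iterrows(), depth):
            if d == 0:
                continue
            rows.append((row["barcode"], locus.chrom, locus.pos, alt,
                         int(row[alt]), int(d), row[alt] / d))
    return pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "alt",
                                       "alt_reads", "depth", "vaf"])
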