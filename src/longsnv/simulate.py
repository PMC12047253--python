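"""Synthetic datasets with full ground truth.

The generator emulates the statistical structure of a droplet long-read
scRNA-seq tumor biopsy at desk scale: a cancer population and a roughly
three-fold larger noncancer microenvironment population with a ~3.6x
depth advantage for cancer cells (mirroring the UMI-per-cell ratio of the
data the method was developed on), germline heterozygous sites (alt fraction
~0.5 in both populations), cancer-only somatic sites, deep mitochondrial
loci, ambient-RNA cross-contamination (each read in a true noncancer cell is
cancer-derived with probability rho, so noncancer VAF at a cancer variant is
rho times the cancer VAF — the observed noncancer mt VAF range is 0.1-3%),
beta-binomially overdispersed sequencing error at every site, and a
configurable fraction of cancer cells mislabeled noncancer at input.

Per-(cell, locus) depths are negative binomial (dispersion 2 by default);
only medians are reported for the real data, and any overdispersed count law
serves. Site classes, true cell labels, and subclone assignments are written
alongside every dataset as a truth set. A paired synthetic scWGS experiment
(pooled aneuploid/diploid clone counts plus per-cell aneuploid counts) is
generated from the same truth for the validation module.

Everything is deterministic given the seed: two runs with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .error_model import BetaParams, DEFAULT_LR_PRIMARY
from .io_counts import BASES, BaseCountTable, TABLE_COLS

logger = logging.getLogger("longsnv")

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimResult",
    "simulate",
    "write_toy_bam",
    "reference_from_table",
    "score_against_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the package's reference conditions: 100 cancer + 300
    noncancer cells; 20 somatic, 20 germline and 200 pure-noise nuclear
    sites plus 5 mitochondrial somatic sites; nuclear depth means 8 / 3
    reads per cell (cancer / noncancer), mitochondrial mean 150 (deep in
    every cell); somatic and germline VAF 0.5, mitochondrial heteroplasmy
    0.6; ambient contamination rho = 0.01 (geometric middle of the observed
    0.1-3% noncancer mt VAF range); 10% of cancer cells mislabeled at input;
    shipped long-read error parameters.
    """

    n_cancer_cells: int = 100
    n_noncancer_cells: int = 300
    n_germline_sites: int = 20
    n_somatic_sites: int = 20
    n_noise_sites: int = 200
    n_mt_sites: int = 5
    mean_depth_cancer: float = 8.0
    mean_depth_noncancer: float = 3.0
    mean_depth_mt: float = 150.0
    nb_dispersion: float = 2.0
    somatic_vaf: float = 0.5
    germline_vaf: float = 0.5
    mt_vaf: float = 0.6
    ambient_contamination: float = 0.01
    mislabel_fraction: float = 0.1
    error_params: BetaParams = field(default_factory=lambda: DEFAULT_LR_PRIMARY)
    subclone_fractions: tuple = (1.0,)
    n_fusions: int = 2
    fusion_cancer_fraction: float = 0.3
    fusion_ambient_fraction: float = 0.002
    n_background_fusions: int = 1
    background_fusion_fraction: float = 0.02
    n_scwgs_aneuploid_cells: int = 30
    scwgs_cell_depth: float = 8.0
    scwgs_diploid_depth: float = 240.0
    chrom: str = "chr1"
    mt_chrom: str = "chrM"
    site_spacing: int = 20_000
    gnomad_af_germline: float = 0.3
    seed: int = 7

    def validate(self) -> None:
        for name in ("ambient_contamination", "mislabel_fraction",
                     "somatic_vaf", "germline_vaf", "mt_vaf",
                     "fusion_cancer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.subclone_fractions) - 1.0) > 1e-9:
            raise ValueError("subclone_fractions must sum to 1")
        if len(self.subclone_fractions) > max(self.n_somatic_sites, 1):
            raise ValueError("more subclones than somatic sites to make "
                             "private: infeasible configuration")
        for name in ("n_cancer_cells", "n_noncancer_cells", "n_germline_sites",
                     "n_somatic_sites", "n_noise_sites", "n_mt_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthSet:
    """Ground truth written alongside every generated dataset."""

    sites: pd.DataFrame          # chrom,pos,ref,alt,site_class,vaf,subclone
    cell_labels: dict[str, str]  # barcode -> true label
    somatic_fusions: list[str]
    subclone_of_cell: dict[str, int]

    def somatic_keys(self) -> set[tuple[str, int, str]]:
        sub = self.sites[self.sites["site_class"] == "somatic"]
        return {(c, int(p), a) for c, p, a in
                zip(sub["chrom"], sub["pos"], sub["alt"])}

    def mt_somatic_keys(self) -> set[tuple[str, int, str]]:
        sub = self.sites[self.sites["site_class"] == "mt_somatic"]
        return {(c, int(p), a) for c, p, a in
                zip(sub["chrom"], sub["pos"], sub["alt"])}

    def germline_keys(self) -> set[tuple[str, int, str]]:
        sub = self.sites[self.sites["site_class"] == "germline"]
        return {(c, int(p), a) for c, p, a in
                zip(sub["chrom"], sub["pos"], sub["alt"])}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "sites": self.sites.to_dict(orient="records"),
                "cell_labels": self.cell_labels,
                "somatic_fusions": self.somatic_fusions,
                "subclone_of_cell": self.subclone_of_cell,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(pd.DataFrame(d["sites"]), d["cell_labels"],
                   d["somatic_fusions"],
                   {k: int(v) for k, v in d["subclone_of_cell"].items()})


@dataclass
class SimResult:
    """Everything one synthetic experiment produces."""

    table: BaseCountTable        # labels as *input* (with mislabels)
    truth: TruthSet
    fusion_table: pd.DataFrame   # per-cell rows: fusion_name, cell_barcode
    clone_counts: object         # scwgs.CloneCounts
    gnomad_freq: dict            # germline sites at population frequency
    config: SimConfig


def _nb_depths(rng, mean: float, shape, dispersion: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(shape, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape).astype(np.int64)


def _assemble_counts(rng, depths: np.ndarray, vaf: np.ndarray,
                     ref_idx: np.ndarray, alt_idx: np.ndarray,
                     p_err: np.ndarray) -> np.ndarray:
    """Per-(cell, site) counts over A,C,G,T given planted VAF and error rate.

    Planted alt reads are binomial in the VAF; every remaining read flips to
    a uniformly chosen nonreference base with the site's error probability.
    Returns an (n_cells, n_sites, 4) array.
    """
    n_cells, n_sites = depths.shape
    if n_sites == 0:
        return np.zeros((n_cells, 0, 4), dtype=np.int64)
    k_alt = rng.binomial(depths, vaf)
    errors = rng.binomial(depths - k_alt, p_err[None, :])
    counts = np.zeros((n_cells, n_sites, 4), dtype=np.int64)
    cols = np.arange(n_sites)
    # error reads split uniformly over the three nonreference bases
    split = rng.multinomial(errors, [1 / 3] * 3)
    others = np.array([[b for b in range(4) if b != r] for r in ref_idx])
    for m in range(3):
        counts[:, cols, others[:, m]] += split[:, :, m]
    counts[:, cols, alt_idx] += k_alt
    counts[:, cols, ref_idx] += depths - k_alt - errors
    return counts


def _counts_to_rows(chrom_arr, pos_arr, ref_arr, barcodes, counts) -> pd.DataFrame:
    depths = counts.sum(axis=2)
    ci, si = np.nonzero(depths > 0)
    df = pd.DataFrame({
        "chrom": np.asarray(chrom_arr)[si],
        "pos": np.asarray(pos_arr)[si],
        "ref": np.asarray(ref_arr)[si],
        "barcode": np.asarray(barcodes)[ci],
        "A": counts[ci, si, 0], "C": counts[ci, si, 1],
        "G": counts[ci, si, 2], "T": counts[ci, si, 3],
    })
    df["other"] = 0
    return df[TABLE_COLS]


def simulate(config: SimConfig = SimConfig()) -> SimResult:
    """Generate one fully-labeled synthetic dataset (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nC, nN = config.n_cancer_cells, config.n_noncancer_cells
    cancer_bcs = [f"CA{i:05d}" for i in range(nC)]
    noncancer_bcs = [f"NC{i:05d}" for i in range(nN)]
    barcodes = np.array(cancer_bcs + noncancer_bcs)
    is_cancer = np.array([True] * nC + [False] * nN)

    # subclone assignment of cancer cells (contiguous blocks by fraction)
    bounds = np.cumsum(np.round(np.array(config.subclone_fractions) * nC)
                       ).astype(int)
    bounds[-1] = nC
    subclone = np.zeros(nC, dtype=int)
    start = 0
    for k, b in enumerate(bounds):
        subclone[start:b] = k
        start = b
    subclone_of_cell = {bc: int(s) for bc, s in zip(cancer_bcs, subclone)}

    # nuclear site layout
    nG, nS, nX = (config.n_germline_sites, config.n_somatic_sites,
                  config.n_noise_sites)
    n_nuc = nG + nS + nX
    pos = 100_000 + config.site_spacing * np.arange(n_nuc)
    classes = np.array(["germline"] * nG + ["somatic"] * nS + ["noise"] * nX)
    rng.shuffle(classes)
    ref_idx = rng.integers(0, 4, size=n_nuc)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_nuc)) % 4
    site_subclone = np.full(n_nuc, -1)
    som_sites = np.flatnonzero(classes == "somatic")
    site_subclone[som_sites] = np.arange(len(som_sites)) % len(
        config.subclone_fractions)
    p_err = rng.beta(config.error_params.alpha, config.error_params.beta,
                     size=n_nuc)

    mean_depth = np.where(is_cancer, config.mean_depth_cancer,
                          config.mean_depth_noncancer)
    depths = np.stack([
        _nb_depths(rng, m, n_nuc, config.nb_dispersion) for m in mean_depth
    ])

    rho = config.ambient_contamination
    vaf = np.zeros((nC + nN, n_nuc))
    vaf[:, classes == "germline"] = config.germline_vaf
    for j in som_sites:
        carriers = np.zeros(nC + nN, dtype=bool)
        carriers[:nC] = subclone == site_subclone[j]
        vaf[carriers, j] = config.somatic_vaf
        vaf[nC:, j] = rho * config.somatic_vaf  # ambient leak into noncancer
    counts = _assemble_counts(rng, depths, vaf, ref_idx, alt_idx, p_err)
    nuc_df = _counts_to_rows([config.chrom] * n_nuc, pos,
                             [BASES[i] for i in ref_idx], barcodes, counts)

    # mitochondrial sites: deep in every cell, heteroplasmic in cancer
    nM = config.n_mt_sites
    mt_pos = 1_000 + 500 * np.arange(nM)
    mt_ref_idx = rng.integers(0, 4, size=nM)
    mt_alt_idx = (mt_ref_idx + rng.integers(1, 4, size=nM)) % 4
    mt_p_err = rng.beta(config.error_params.alpha, config.error_params.beta,
                        size=nM)
    mt_depths = _nb_depths(rng, config.mean_depth_mt, (nC + nN, nM),
                           config.nb_dispersion)
    mt_vaf = np.zeros((nC + nN, nM))
    mt_vaf[:nC, :] = config.mt_vaf
    mt_vaf[nC:, :] = rho * config.mt_vaf
    mt_counts = _assemble_counts(rng, mt_depths, mt_vaf, mt_ref_idx,
                                 mt_alt_idx, mt_p_err)
    mt_df = _counts_to_rows([config.mt_chrom] * nM, mt_pos,
                            [BASES[i] for i in mt_ref_idx], barcodes,
                            mt_counts)

    all_df = (pd.concat([nuc_df, mt_df], ignore_index=True)
              .sort_values(["chrom", "pos", "barcode"])
              .reset_index(drop=True))

    # input labels: a fraction of cancer cells arrives mislabeled noncancer
    n_mis = int(round(config.mislabel_fraction * nC))
    mislabeled = set(rng.choice(cancer_bcs, size=n_mis, replace=False)) \
        if n_mis else set()
    input_labels = {bc: ("noncancer" if bc in mislabeled else "cancer")
                    for bc in cancer_bcs}
    input_labels.update({bc: "noncancer" for bc in noncancer_bcs})
    true_labels = {bc: "cancer" for bc in cancer_bcs}
    true_labels.update({bc: "noncancer" for bc in noncancer_bcs})

    table = BaseCountTable(all_df, input_labels)

    # fusions: somatic ones in a cancer subpopulation, plus ambient leakage
    # and a background fusion present at low frequency in both types
    fusion_rows = []
    somatic_fusions = []
    for i in range(config.n_fusions):
        name = f"FUSA{i}--FUSB{i}"
        somatic_fusions.append(name)
        det_c = rng.random(nC) < config.fusion_cancer_fraction
        det_n = rng.random(nN) < config.fusion_ambient_fraction
        for bc in np.concatenate([np.array(cancer_bcs)[det_c],
                                  np.array(noncancer_bcs)[det_n]]):
            fusion_rows.append((name, bc))
    for i in range(config.n_background_fusions):
        name = f"BGA{i}--BGB{i}"
        det = rng.random(nC + nN) < config.background_fusion_fraction
        for bc in barcodes[det]:
            fusion_rows.append((name, bc))
    fusion_table = pd.DataFrame(fusion_rows,
                                columns=["fusion_name", "cell_barcode"])

    # paired scWGS experiment from the same truth
    from .scwgs import CloneCounts  # local import to avoid a cycle

    nA = config.n_scwgs_aneuploid_cells
    wgs_bcs = [f"WG{i:04d}" for i in range(nA)]
    wgs_depths = _nb_depths(rng, config.scwgs_cell_depth, (nA, n_nuc),
                            config.nb_dispersion)
    wgs_vaf = np.zeros((nA, n_nuc))
    wgs_vaf[:, classes == "germline"] = config.germline_vaf
    wgs_vaf[:, classes == "somatic"] = config.somatic_vaf
    wgs_counts = _assemble_counts(rng, wgs_depths, wgs_vaf, ref_idx, alt_idx,
                                  p_err)
    per_cell = _counts_to_rows([config.chrom] * n_nuc, pos,
                               [BASES[i] for i in ref_idx], wgs_bcs,
                               wgs_counts)
    pooled_an = per_cell.groupby(["chrom", "pos", "ref"], as_index=False)[
        ["A", "C", "G", "T", "other"]].sum()
    pooled_an.insert(3, "pool", "aneuploid")
    dip_depths = _nb_depths(rng, config.scwgs_diploid_depth, (1, n_nuc),
                            config.nb_dispersion)
    dip_vaf = np.zeros((1, n_nuc))
    dip_vaf[0, classes == "germline"] = config.germline_vaf
    dip_counts = _assemble_counts(rng, dip_depths, dip_vaf, ref_idx, alt_idx,
                                  p_err)
    pooled_di = _counts_to_rows([config.chrom] * n_nuc, pos,
                                [BASES[i] for i in ref_idx], ["pool"],
                                dip_counts).drop(columns="barcode")
    pooled_di.insert(3, "pool", "diploid")
    clone_counts = CloneCounts(
        pd.concat([pooled_an, pooled_di], ignore_index=True), per_cell)

    sites = pd.DataFrame({
        "chrom": [config.chrom] * n_nuc + [config.mt_chrom] * nM,
        "pos": np.concatenate([pos, mt_pos]).astype(int),
        "ref": [BASES[i] for i in np.concatenate([ref_idx, mt_ref_idx])],
        "alt": [BASES[i] for i in np.concatenate([alt_idx, mt_alt_idx])],
        "site_class": np.concatenate([classes, ["mt_somatic"] * nM]),
        "vaf": np.concatenate([
            np.select(
                [classes == "germline", classes == "somatic"],
                [config.germline_vaf, config.somatic_vaf], 0.0),
            np.full(nM, config.mt_vaf)]),
        "subclone": np.concatenate([site_subclone, np.full(nM, -1)]).astype(int),
    })
    gnomad = {(config.chrom, int(p), BASES[a]): config.gnomad_af_germline
              for p, a, cl in zip(pos, alt_idx, classes) if cl == "germline"}
    truth = TruthSet(sites, true_labels, somatic_fusions, subclone_of_cell)
    return SimResult(table, truth, fusion_table, clone_counts, gnomad, config)


def reference_from_table(table: BaseCountTable, fill: str = "A",
                         pad: int = 10) -> dict[str, str]:
    """A minimal reference: each contig filled with ``fill``, the known
    reference base planted at every locus of the table."""
    ref: dict[str, str] = {}
    loci = table.loci()
    for chrom, grp in loci.groupby("chrom"):
        length = int(grp["pos"].max()) + pad
        seq = np.full(length, fill, dtype="<U1")
        seq[grp["pos"].to_numpy() - 1] = grp["ref"].to_numpy()
        ref[str(chrom)] = "".join(seq)
    return ref


def write_toy_bam(table: BaseCountTable, reference: Mapping[str, str],
                  path) -> None:
    """Write a coordinate-sorted, indexed BAM reproducing the table's counts.

    Each counted read becomes a single-base alignment at its locus with
    mapping quality 60, base quality 40, a CB barcode tag and a unique UB
    tag, so ``read_bam_pileup(write_toy_bam(t)) == t`` at default thresholds
    ('other' counts are emitted as N bases).
    """
    import pysam

    loci = table.loci()
    for chrom, grp in loci.groupby("chrom"):
        if chrom not in reference:
            raise ValueError(f"reference lacks contig {chrom!r}")
        if int(grp["pos"].max()) > len(reference[str(chrom)]):
            raise ValueError(f"reference contig {chrom!r} shorter than the "
                             "highest locus position")
    contigs = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    entries = []
    serial = 0
    for _, row in table.counts.sort_values(["chrom", "pos", "barcode"]).iterrows():
        for base_col, emitted in (("A", "A"), ("C", "C"), ("G", "G"),
                                  ("T", "T"), ("other", "N")):
            for _ in range(int(row[base_col])):
                entries.append((tid[row["chrom"]], int(row["pos"]) - 1,
                                emitted, row["barcode"], serial))
                serial += 1
    entries.sort(key=lambda e: (e[0], e[1], e[4]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for t, pos0, base, barcode, serial in entries:
            a = pysam.AlignedSegment()
            a.query_name = f"read{serial:08d}"
            a.query_sequence = base
            a.query_qualities = pysam.qualitystring_to_array("I")
            a.reference_id = t
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = "1M"
            a.flag = 0
            a.set_tag("CB", barcode)
            a.set_tag("UB", f"UMI{serial:08d}")
            bam.write(a)
    pysam.index(str(path))


def score_against_truth(passed_records: Sequence, truth: TruthSet,
                        mt: bool = False) -> dict[str, float]:
    """Precision / sensitivity of a call set against the planted truth."""
    from .scwgs import performance

    calls = {(r.chrom, r.pos, r.alt) for r in passed_records}
    truth_keys = truth.mt_somatic_keys() if mt else truth.somatic_keys()
    out = performance(calls, truth_keys)
    out["germline_calls"] = float(len(calls & truth.germline_keys()))
    return out
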