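# Methods

## Background error model

Nonreference allele counts at homozygous-reference sites are overdispersed
relative to a binomial: error propensity varies by site (sequence context,
mapping difficulty, ambient RNA). We model the per-site error rate P as
Beta(α, β) and counts as K | P ~ Binomial(n, P), i.e. K ~ BetaBinomial(n, α,
β). All significance statements are the one-sided upper tail P(K ≥ k),
computed as the beta-binomial survival function; the tail is exactly 1 at
k = 0 and monotone non-increasing in k.

Two parameter sets are kept: a *primary* set applied to the candidate
allele (shipped long-read default α = 0.21, β = 104.95; mean error rate
≈ 0.20%) and an *other-allele* set applied to residual nonreference reads
after removing the candidate allele (default α = 0.25, β = 162.04). Both
can be refit with `fit_background`: maximum likelihood on (log α, log β)
with Nelder–Mead, started from method-of-moments estimates, over unique
(k, n) pairs with multiplicities. Training sites are selected from a
pseudo-bulk as depth ≥ 10 and pooled nonreference fraction < 0.05 —
thresholds that are our declared choice, since "homozygous reference" needs
an operational definition — and subsampled to 500,000 with a fixed,
configurable seed. A fit is refused below 1,000 usable sites and degenerates
to the shipped defaults (with a warning) when every count is zero. On
100,000 simulated sites at depth ~30 the fit recovers α within a few percent
(the acceptance script reports the realized error).

## Filter semantics and numerical choices

Thresholds follow a uniform convention: significance comparisons are
*strict* (`p < level`; a p-value exactly at the level is not significant),
count and coverage thresholds are *inclusive* ("at least" semantics), and
the mitochondrial rules are expressed as printed fail conditions
(fail iff ΔMCF < 0.35, fail iff VAF_cancer < 0.1), so boundary values are
retained. One alternative allele is kept per locus — the most frequent
nonreference base, ties broken A < C < G < T — because every downstream
statistic is biallelic.

The homopolymer rule is implemented as: a tract is a maximal mononucleotide
run of length ≥ 4 in the reference; a variant fails if it lies inside a
tract or within 4 bp of either end. The source phrasing ("within 4 bp or
more of mononucleotide tracts") is ambiguous; this reading matches the
filter's purpose — indel-slippage artifacts cluster in and at the flanks of
tracts — and both the tract length and the flank are configurable.
Homopolymer tracts are the package's only half-open intervals; every other
coordinate is 1-based closed, matching VCF.

The 10 kb distance filter removes *both* members of a close pair: close
pairs are characteristically misalignment or allele-specific-expression
artifacts, so neither member is trusted. It is applied to the survivors of
the per-record filters, making it symmetric and order-independent; the
per-record filters 1–9 commute, and their fixed ledger order exists only
for reporting and funnel accounting (pass(i) + fail(i) = pass(i−1) at every
step; records failing early are marked `not_evaluated` downstream).

For high-confidence cancer variants we keep candidates with VAF_noncancer
< 0.2 *and* ΔMCF > 0.4. HCCV selection tolerates nonzero noncancer VAF
deliberately — that is what lets mislabeled cells be recovered — while the
0.2 cap excludes genuine heterozygous polymorphisms. Mitochondrial HCCVs
skip the distance rule and consult only the long-read panel of normals;
the RNA-editing filter still applies. Cells covering fewer than 3 HCCVs are
labeled *filtered* and excluded from both pseudo-bulks in the second pass:
they are evidence for neither side. The ≥ 25% mutated-fraction rule for
relabeling a cell cancer is inclusive.

Single-cell genotypes: a nuclear call tests alt vs ref reads only
(beta-binomial tail < 0.01; other-allele reads do not enter), a
mitochondrial call uses per-cell VAF > 0.3 — a hard threshold that ambient
contamination (per-cell VAFs of a few percent) cannot trip. The cell-variant
matrix keeps SNV/mtSNV rows covered in ≥ 5 cells (mtSNV rows use the SNV
rule — they are SNVs; configurable) and fusion rows detected in ≥ 3 cells,
then drops cells with < 3 non-missing entries, re-applying both passes to a
fixed point (the printed procedure states a single order; iterating is the
conservative completion and changes nothing on our test data). Export
encoding is 1 / 0 / 3 for mutated / wildtype / missing, the convention of
Bayesian nonparametric clonal clustering inputs; the clustering itself is
external.

scWGS validation follows the printed rules verbatim, including the
asymmetric eligibility disjunction (≥ 1 mutated read OR ≥ 17 reads of
coverage) and the two distinct threshold sets: support classification tests
each pool at 0.01, the de novo truth set requires p < 0.001 in the
aneuploid pool and p > 0.05 in the diploid pool at ≥ 5 reads everywhere,
with ≥ 3 mutated reads in ≥ 2 aneuploid cells. The multi-cell rule needs
per-cell counts; with pooled-only input it is skipped with a logged caveat.
With zero calls, precision is undefined and reported as 0 with an explicit
flag. Diploid-pool significance takes precedence over aneuploid
significance when labeling (a locus mutated in both pools is germline).

## Synthetic data: what it emulates, and what it does not

The generator instantiates the data structure the method assumes, at desk
scale: two populations (default 100 cancer, 300 noncancer cells) with a
~3.6× per-cell depth ratio (nuclear means 8 vs 3 reads per cell,
mirroring the UMI ratio of the tissue the method targets), germline
heterozygous sites (alt fraction 0.5 in both populations), somatic sites
private to cancer (VAF 0.5), pure-noise sites, and deep mitochondrial loci
(mean 150 reads per cell in *every* cell, heteroplasmy 0.6 in cancer —
within the 10–98% per-cell range reported for real tumors). Sequencing
error is planted at every site: a per-site rate drawn from the shipped
Beta(0.21, 104.95), with erroneous reads split uniformly over the three
nonreference bases. Depths are negative binomial with dispersion 2 — only
medians are reported for the real data, and any overdispersed law serves;
the law and dispersion are config keys.

Ambient contamination is modeled at read level: each read of a true
noncancer cell is cancer-derived with probability ρ, so the expected
noncancer VAF at a cancer-private variant is ρ × VAF_cancer. The default
ρ = 0.01 is the geometric middle of the 0.1–3% noncancer mitochondrial VAF
range observed in real biopsies. By default 10% of cancer cells arrive
mislabeled noncancer — the regime reannotation exists for. Sites are spaced
20 kb apart so the distance filter does not interact with site placement;
a paired synthetic scWGS experiment (30 aneuploid cells at ~8 reads per
site, one pooled diploid sample at ~240) is drawn from the same truth.

What the generator does *not* emulate: expression structure (no genes,
isoforms, or UMI duplication), alignment artifacts (homopolymer slippage,
multimapping — the corresponding filters are exercised with constructed
resources instead), copy-number variation, doublets, and real panels of
normals. Passing tests therefore demonstrate the statistical logic of the
filters and the reannotation mechanism, not robustness to alignment
pathology on real data.

Problem sizes throughout (cell counts, site counts, 100k-site fits) were
chosen so the full test suite and the acceptance script each run in a few
minutes on a single CPU while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* No indel calling (deletions in the source data were curated manually) and
  no multi-allelic records.
* Strand is ignored; no strand-bias filter is defined.
* The base-quality cutoff for pileups (default Q20) is inherited from
  upstream read preprocessing rather than stated by the calling procedure
  itself; it is configurable.
* Reference bases at pileup time come from a FASTA when provided; the
  majority-base fallback is adequate only for error-dominated loci.
* The candidate detector implements the documented thresholds (≥ 1 alt
  read, ≥ 5 reads); any undocumented heuristics of external candidate
  callers are out of scope.
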