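# longsnv

De novo somatic variant selection from high-quality long-read single-cell
RNA-seq of tumor biopsies — **without a matched normal sample**.

Tumor biopsies contain both cancer cells and noncancer microenvironment
cells. `longsnv` leverages the noncancer cells as an internal control:
per-cell base counts from a barcoded alignment are aggregated into cancer
and noncancer pseudo-bulks, and candidate loci are pushed through a battery
of statistical tests and hard filters that separate true somatic
single-nucleotide variants (SNVs) from sequencing noise, germline
polymorphisms, RNA editing, and technology artifacts. The package also
selects somatic mitochondrial SNVs (mtSNVs) with contamination-robust rules,
selects somatic gene fusions from an external fusion caller's per-cell
table, genotypes every cell at every called variant, and exports a
cells × variants matrix for clonal reconstruction.

## The model

Nonreference counts *K* at an error-only locus of depth *n* are
beta-binomial:

    K | P ~ Binomial(n, P),   P ~ Beta(α, β)

Every decision in the package is a one-sided tail test P(K ≥ k) under this
background (shipped long-read parameters α₁ = 0.21, β₁ = 104.95 for the
candidate allele, α₂ = 0.25, β₂ = 162.04 for residual other-allele noise;
both can be refit from homozygous-reference sites with `fit_background`).

Key statistics per candidate locus:

* **VAF** — alt reads / depth, per cell or pseudo-bulk;
* **MCF** — fraction of a group's cells genotyped mutated, among cells with
  ≥ 1 read at the locus;
* **ΔMCF = MCF_cancer − MCF_noncancer** — the cancer-enrichment statistic.

Nuclear candidates (≥ 1 alt read, ≥ 5 reads in the cancer pseudo-bulk) pass
ten ordered filters: pseudo-bulk coverage ≥ 5 in both groups; ≥ 3 alt reads
in ≥ 2 cancer cells; beta-binomial noise test in cancer (p < 0.001);
other-allele noise test (p ≥ 0.05); homopolymer proximity; RNA-editing
sites; short- and long-read panels of normals; germline test in noncancer
(p ≥ 0.05); population allele frequency < 1%; and removal of both members of
any pair of calls within 10 kb.

Marker-gene cell annotations are imperfect, and mislabeled cancer cells push
somatic variants into the germline filter. Before definitive calling,
`longsnv` therefore selects stringent **high-confidence cancer variants**
(depth ≥ 20, VAF_noncancer < 0.2, ΔMCF > 0.4, plus resource filters) and
**reannotates** every cell: < 3 HCCVs covered → filtered; ≥ 25% of covered
HCCVs mutated → cancer; else noncancer. Calling then runs a second pass on
the corrected labels.

Mitochondria are handled separately because ambient mtRNA from dying cancer
cells contaminates noncancer droplets (typical noncancer VAFs 0.1–3%): at
mitochondrial depths that leak is statistically significant, so a germline
test would reject every true mt variant. The mt path instead requires
coverage ≥ 100 in both pseudo-bulks, population frequency < 1%, ΔMCF ≥ 0.35
and VAF_cancer ≥ 0.1, with per-cell genotypes defined by VAF > 0.3.

When paired single-cell WGS clone counts are available, calls are validated
against copy-number-derived aneuploid (cancer) and diploid (noncancer)
pools, and sensitivity / precision / F1 are computed against a de novo
scWGS truth set.

## Worked example

The built-in generator produces a fully labeled dataset (100 cancer + 300
noncancer cells, 20 somatic / 20 germline / 200 noise nuclear sites, 5 deep
mitochondrial sites, 1% ambient contamination, 10% of cancer cells
mislabeled at input):

```python
import longsnv as L

sim = L.simulate(L.SimConfig(seed=7))
resources = L.AnnotationResources(gnomad_freq=sim.gnomad_freq)
result = L.run_pipeline(sim.table, resources, fusion_table=sim.fusion_table,
                        scwgs_clone_counts=sim.clone_counts)
score = L.score_against_truth(result.snv_callset.passed, sim.truth)
print(result.snv_callset.funnel().to_string(index=False))
```

which prints

```
somatic SNVs called: 19
mtSNVs called:       5
fusions selected:    ['FUSA0--FUSB0', 'FUSA1--FUSB1']
precision=1.00  sensitivity=0.95  germline leaks=0
      filter  n_in  n_pass  n_fail
    coverage   113     113       0
 alt_support   113      40      73
noise_cancer    40      40       0
other_allele    40      38       2
 homopolymer    38      38       0
     editing    38      38       0
         pon    38      38       0
    germline    38      19      19
      gnomad    19      19       0
    distance    19      19       0
matrix: 26 variants x 400 cells
```

Reading the funnel: 113 candidate loci enter; the per-cell alt-read filter
removes 73 noise loci; the germline test removes the 19 heterozygous
germline sites that reached it (one more was lost earlier); 19 of the 20
planted somatic SNVs survive all ten steps with no germline contamination.
All five mitochondrial variants and both planted fusions are recovered, and
all ten mislabeled cells were relabeled cancer before the second pass —
with reannotation disabled the same data yields zero somatic calls, because
the mislabeled cells make every somatic variant look germline.

The same workflow is available from the shell:

```bash
longsnv simulate --seed 7 --out-dir data/
longsnv run-all --counts data/counts.tsv --cell-types data/cell_types.tsv \
    --fusions data/fusions.tsv --gnomad data/gnomad.tsv \
    --scwgs-pooled data/scwgs_pooled.tsv --scwgs-cells data/scwgs_cells.tsv \
    --out-dir run/
```

Outputs: reannotation table, nuclear and mitochondrial VCFs (FILTER column
carries the first failing step), funnel TSVs, selected-fusion TSV, the
cell-variant matrix (1 = mutated, 0 = wildtype, 3 = missing), and, with
scWGS input, a metrics JSON.

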