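# methprog

Stage-wise CpG-island methylome progression analysis for two-color
methyl-CpG-immunoprecipitation (MCIp) arrays.

## The problem

In myeloid leukemia models driven by knockdown of a hematopoietic
transcription factor, aberrant promoter CpG-island (CGI) hypermethylation
begins before overt disease and expands massively as it progresses. The
measurement is a two-color CGI tiling array: MCIp-enriched, highly methylated
DNA from a knockdown (kd) animal and from an age/gender-matched wildtype (wt)
animal are labelled in different dyes and co-hybridised, so each probe yields
a log-ratio **M = log2(kd/wt)** that is positive where the knockdown has
gained methylation. `methprog` provides, as reusable tested components, the
full analysis chain such a study needs:

- **NormExp background correction** — each channel is modelled as
  X = B + S with B ~ N(μ, σ²) and exponential signal S (mean α); the
  corrected value is E[S | X = x] = μ_sx + σ·φ(μ_sx/σ)/Φ(μ_sx/σ) with
  μ_sx = x − μ − σ²/α, floored at 0.5, plus an offset (default 50).
- **Rank-invariant LOESS normalization** — intensity-dependent dye bias is
  removed by a tricube local-linear fit of M on A = ½(log2 R + log2 G)
  estimated on rank-invariant probes and negative controls only.
- **One-class SAM** — per disease stage, d_i = m̄_i/(s_i + s0) tested
  against a sign-flip permutation null with an FDR-calibrated threshold Δ
  (target 5%); stages are assigned from bone-marrow blast counts
  (<20% preleukemic, 20–50% early, >50% late leukemic) and compared by full
  Venn set algebra.
- **Genomic annotation** — strand-aware promoter (−2,000/+500 bp around the
  TSS), gene-body and downstream assignment; gene-level calls at ≥1- and
  ≥2-probe stringency; gene-list overlap with hypergeometric enrichment.
- **Peak/motif enrichment** — IUPAC consensus motif scanning (e.g. the ETS
  core GAGGAA), interval overlap counting, a uniform per-chromosome shuffle
  permutation null (empirical p with the add-one rule) and Fisher's exact
  test on the island-level 2×2 table.
- **Quantitative validation** — amplicon-level methylation means with
  missingness, exact/asymptotic Mann-Whitney tests, hierarchical clustering
  (Euclidean, average linkage) with multiscale-bootstrap BP/AU support, and
  PCA of M-value matrices.
- **A synthetic-data generator** — a scaled-down probe-tiled CGI landscape
  with planted stage-wise methylation changes, enrichment-biased peak
  placement, planted motifs, dye bias and amplicon tables, with full ground
  truth, so every statistical claim is testable against known answers.

See `docs/methods.md` for models, parameters and design choices.

## Worked example

Run the default synthetic study end to end (simulate → normalize → SAM →
annotate → enrich → validate; ~10 s):

```bash
methprog run --out run1 --seed 1
```

The command prints the per-stage differential-probe counts and writes
`run1/report.json` plus every intermediate artifact (FASTA/BED/TSV/JSON).
With seed 1 the report contains:

```
dmp_counts      preleukemic:   169 hyper,  86 hypo   (Δ = 2.04, π0 = 0.80)
                early_leukemic: 11 hyper,   3 hypo   (Δ = 9.07, π0 = 0.82)
                late_leukemic: 529 hyper, 358 hypo   (Δ = 1.27, π0 = 0.28)
venn (hyper)    74 unique preleukemic, 435 unique late, 5 common to all stages
features        1158 promoter, 428 gene body, 18 downstream, 196 unknown
truth_eval      preleukemic hyper: sensitivity 0.994, FDP 0.024
enrichment      peaks∩hyper-CGIs: 39 observed vs 6.6 ± 2.5 expected,
                empirical p = 0.001 (B = 1000);
                ≥2-probe stringency: 22/30 islands with a peak,
                Fisher odds 16.3, p = 3.2e-11
motif           476 GAGGAA sites genome-wide, 30 in hyper islands vs
                12.9 expected, empirical p = 0.001
validation      6/10 amplicons significant (Mann-Whitney, preleukemic vs wt);
                kd/wt cluster split: BP 0.99, AU 0.9997; PC1 explains 38%
```

Read: the preleukemic stage already carries a compact hypermethylation
signature (recovered essentially completely against the generator's planted
truth), the late stage shows the characteristic ~20-fold expansion, binding
peaks and the consensus motif are strongly enriched in the hypermethylated
islands, and the quantitative amplicon data separate knockdown from wildtype
animals with near-certain cluster support.

Each step is also available standalone (`methprog simulate / normalize /
sam / annotate / enrich / quant`, see `--help`) and as library functions:

```python
from methprog import call_dmps, permutation_enrichment, scan_motif
```

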