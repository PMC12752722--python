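# allobcr

B-cell receptor (BCR) repertoire analytics for renal-allograft biopsies:
from clonotype tables to clonality bins, isotype-hierarchy abundance, CPK
diversity, IGHV gene usage, correlation-based candidate-gene discovery,
cell-type-resolved repertoire statistics and graft-survival stratification.

## The problem

After kidney transplantation, T cell-mediated rejection (TCMR) biopsies show
a massive clonal expansion of intragraft B-cell receptors — dominated by
IgG, and IgG1 in particular — carried largely by infiltrating plasma cells.
`allobcr` packages the downstream analysis of such repertoires as a tested,
reusable pipeline. It consumes clonotype tables as produced by TRUST4 (its
report dialect or AIRR Rearrangement TSV), a normalized expression matrix,
immune-infiltration score tables, per-barcode cell-type annotations, and
survival tables; assembling repertoires from FASTQ is out of scope.

## The statistics at its core

For a sample with clonotypes indexed by level *L* of the chain hierarchy
(total → heavy/light → IGHA/D/E/G/M → IGHG1–4, IGHA1–2):

* **absolute abundance** — the number of distinct clonotypes at *L*;
* **CPK** — clonotypes per thousand CDR3 reads,
  `CPK_L = 1000 · n_clonotypes(L) / n_reads(L)`, the diversity statistic
  (CPK ≤ 1000; lower CPK at fixed reads means clonal expansion);
* **clonality bins** — the partition of clonotype copy counts into
  {0–1, 2–10, 11–50, 51–100, ≥101};
* **expansion fold** — ratio of group means of a per-sample statistic
  (e.g. TCMR/STA);
* **candidate genes** — genes with |r| > 0.7 against both IGHG abundance and
  IGHG CPK *and* Hochberg-adjusted differential-expression p < 0.05
  (two-sample tests are normality-gated: Shapiro–Wilk at α = 0.05 selects
  Student's t / Pearson or Wilcoxon / Spearman);
* **graft survival** — Kaplan–Meier curves, log-rank tests at configurable
  high:low stratification ratios, and multivariate Cox proportional-hazards
  fits (Efron ties) reporting per-unit hazard ratios.

A first-class synthetic-cohort generator (`allobcr.synthetic`) produces
bulk cohorts, barcoded single-cell samples, expression matrices with
implanted correlations, infiltration scores and proportional-hazards
survival data with known ground truth, so the whole pipeline runs and is
tested without any sequencing download.

## Worked example

```python
import allobcr as ab
from allobcr.synthetic import SyntheticConfig, generate_repertoire_cohort

cfg = SyntheticConfig(seed=1)              # 18 TCMR + 16 STA samples
samples, truth = generate_repertoire_cohort(cfg)
summaries = [ab.summarize(s) for s in samples]

total = ab.compare_groups(summaries, "TCMR", "STA", metric="abundance", level="total")
g1    = ab.compare_groups(summaries, "TCMR", "STA", metric="abundance", level="IGHG1")
cpk   = ab.compare_groups(summaries, "TCMR", "STA", metric="cpk", level="IGHG")
print(f"total abundance fold (TCMR/STA): {total.fold:.1f}   p = {total.p_value:.1e} ({total.test})")
print(f"IGHG1 abundance fold:            {g1.fold:.1f}")
print(f"IGHG CPK: TCMR {cpk.values_a.mean():.0f} vs STA {cpk.values_b.mean():.0f}   p = {cpk.p_value:.1e}")

m = ab.build_usage(samples)
kept, dropped = ab.exclude_low_expression(m, "TCMR", frac=0.10)
print("top 3 IGHV genes in TCMR:", ", ".join(ab.top_genes(kept, "TCMR", 3)))
```

prints

```
total abundance fold (TCMR/STA): 36.8   p = 2.4e-51 (t)
IGHG1 abundance fold:            48.0
IGHG CPK: TCMR 227 vs STA 435   p = 5.9e-04
top 3 IGHV genes in TCMR: IGHV3-23, IGHV3-30, IGHV4-59
```

The fold ratios recover this cohort's generator parameters (38 total, 51
for IGHG1) up to sampling error; CPK drops in TCMR because expanded clones
concentrate reads into fewer clonotypes; and the top IGHV genes are the
ones the generator's usage weights favour.

A command-line interface mirrors the library:

```sh
allobcr simulate --seed 3 --out fixture/
allobcr summarize --sample-sheet fixture/sample_sheet.tsv --data-dir fixture --out summaries.tsv
allobcr celltype  --airr fixture/single_cell.airr.tsv --annotation fixture/cell_annotation.tsv
allobcr survival  --table fixture/survival.csv --covariates gene,rejection --ratio 1:3
```

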