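# Methods

This note records the statistical model behind `allobcr`, the defaults that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the underlying analysis conventions were genuinely
open.

## Repertoire model and statistics

A clonotype is one assembled receptor chain identified by the key
(CDR3 nucleotide sequence, V call, J call, C call), plus the cell barcode in
single-cell mode. Allele suffixes (`*01`) are trimmed before every gene-name
comparison, so all gene-level statistics are at gene, not allele, resolution.
Duplicate keys are merged at read time by summing read counts; merging is a
no-op for downstream statistics (summaries are invariant to splitting any
record into two records with the same key — a property test enforces this).
The D call is carried but never part of the identity key, because it is
frequently unresolvable in short-read assembly.

The chain hierarchy is fixed: total → {heavy, light}; heavy →
{IGHA, IGHD, IGHE, IGHG, IGHM}; IGHG → IGHG1–4 and IGHA → IGHA1–2. IGHD,
IGHE and IGHM have no subclass level. A heavy chain whose constant gene is
missing counts at the heavy level but at no isotype level; isotype
denominators therefore contain only isotype-resolved reads. This avoids
inventing isotypes for unresolved constant regions.

Per level: abundance = number of distinct clonotypes, reads = summed read
counts, and CPK = 1000 × clonotypes / reads using only that level's records.
CPK on a zero-read level is undefined (NaN), never 0 — reporting 0 would
read as a spurious total collapse of diversity on isotypes that are simply
not detected (IGHE in most biopsies).

**Completeness filter.** By default, records with an empty CDR3, or whose
amino-acid CDR3 carries a stop (`*`), out-of-frame (`_`) or partial (`?`)
marker, are dropped with a per-reason tally; the filter can be disabled.
Class-level antibody statistics presuppose productive chains, but since no
universal convention exists the filter is explicit and optional.

**Clonality bins.** The copy-count partition defaults to
{0–1, 2–10, 11–50, 51–100, ≥101}. Only the outer edges of such binnings are
conventionally fixed; the middle edges here are round decades and are fully
user-overridable.

**Group comparisons.** The gate is Shapiro–Wilk at α = 0.05 on each group;
Student's t runs only when both groups pass, otherwise the Wilcoxon rank-sum
test with midranks and no continuity correction. The rank test uses the
exact permutation null whenever the pooled values are tie-free and number at
most 20, so for small groups its p-value equals full enumeration (tested
against a brute-force enumerator for all group sizes ≤ 8). The expansion
fold is the ratio of group means of the per-sample statistic — reported
explicitly because "expanded k-fold" is otherwise ambiguous. Undefined
(NaN) per-sample values are excluded with a reported count.

**Isotype composition** is reported two ways per group: pooled (summing
reads across samples before dividing) and mean-of-samples — published
composition figures rarely say which was used, so both are emitted.

## IGHV usage

Usage matrices hold read counts per allele-trimmed IGHV gene per sample with
a log2(x+1) view for reporting. The low-expression exclusion rule as adopted
drops every gene whose abundance is low (default: exactly zero) in at least
10% of the designated group's samples. This is an aggressive rule — a gene
absent in 2 of 18 samples is dropped — and the more common complementary
reading ("keep if expressed in ≥ 10%") is available via `rule=
"keep-if-expressed"`. "Low" defaults to zero abundance because that is the
only threshold requiring no normalization assumptions; it is numerically
configurable. Top genes are ranked by group-mean abundance with ties broken
lexicographically (deterministic output), and cross-dataset intersection
preserves the first list's rank order.

## Candidate-gene discovery

Three criteria are intersected: correlation with per-sample IGHG clonotype
abundance, correlation with IGHG CPK, and differential expression between
the clinical groups at Hochberg-adjusted p < 0.05 (step-up:
adj(i) = min(adj(i+1), (m−i+1)·p(i)), capped at 1; implemented via
statsmodels and verified against a brute-force implementation of the
definition).

The correlation threshold applies to |r| by default. An expansion-linked
gene is expected to correlate *positively* with IGHG abundance and
*negatively* with IGHG CPK (more expansion → lower diversity); a literal
one-sided rule r > 0.7 would reject exactly the biologically expected
signature, so the signed variant is available but not the default.

The DE test defaults to Wilcoxon — expression values rarely pass a
normality gate at n ≈ 34, and a fixed choice makes results reproducible —
with `auto` (gated) and `t` available. Correlations default to the gated
auto method; when validating implanted Pearson targets the method is pinned
to `pearson`, since the targets are defined on the Pearson scale.
Correlations are computed across all samples of a dataset by default
(a group-restrict option exists): correlation criteria of this kind are
usually evaluated on the full cohort axis spanning both groups.

## Cell-type context

Single-cell clonotypes are partitioned by an externally supplied barcode →
cell-type annotation; clustering and annotation themselves are consumed,
never computed. The plasma-vs-B fold is the ratio of pooled read counts,
with "B" meaning naive + memory combined (per-subtype folds and per-cell
normalization are options). Pooled reads match the absolute-abundance
framing; per-cell means answer a different question and are offered, not
defaulted. Infiltration scores are consumed as given (absolute-mode
deconvolution contract: non-negative), and correlated per (cell type,
isotype) pair with the gated method.

## Survival

Kaplan–Meier, log-rank and Cox fits are thin contract-enforcing wrappers
over lifelines. Ties are handled with Efron's method (less biased than
Breslow; stated so results are reproducible). Confidence intervals are Wald
at 95%. Ratio stratification "a:b" assigns the top a/(a+b) fraction by
covariate value to "high", cutting at the ⌈n·a/(a+b)⌉-th largest value
with ties going to "high" — quantile cut rules are rarely published, so
this one is documented and tested. Degenerate (constant) covariates refuse
to stratify.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
defaults set to the study conditions:

* **Bulk cohort** — 18 TCMR / 16 STA samples. Clonotype counts are Poisson
  (STA mean 100/sample; TCMR scaled by the total expansion fold, default
  38), so the expected TCMR/STA abundance ratio equals the fold parameter
  exactly. Isotype mixtures encode per-category folds: with the IGHG1 fold
  at 51, the TCMR mixture puts 51% of clonotypes in IGHG1 (the
  more-than-half IgG1 dominance of rejecting grafts) against 38% in STA,
  with the remaining STA mass IGHM/IGHD/light-weighted.
* **Clone sizes** are 1 + negative binomial (dispersion 0.3 — a heavy right
  tail that populates the ≥101 clonality bin), around a per-sample mean
  that is lognormal (σ = 0.35) about 2.5 (STA) or 5.0 (TCMR). Clone-size
  distributions of assembled repertoires are an empirical property of the
  assembler, not something the analysis specifies; this choice reproduces
  the qualitative bin-occupancy pattern and makes CPK fall where abundance
  rises, giving the cohort-level abundance–CPK anticorrelation
  (empirically ρ ≈ −0.7) that the joint correlation implant requires to be
  feasible. One consequence: the read-total fold (≈ 76) exceeds the
  clonotype fold (38); "abundance" in this package always means clonotype
  counts.
* **Single cell** — 993 naive B, 620 memory B, 76 plasma cells. B cells
  carry one clonotype with 1 + Poisson(0.2) reads and an IgM/IgD-weighted
  mixture; plasma cells carry ~10 clonotypes whose per-cell read totals are
  gamma (CV 0.25) with mean set so the expected pooled plasma:B ratio
  equals the read-ratio parameter (default 182). The plasma mixture is
  parametrized by shares: heavy fraction 0.89, IGHG within heavy 0.68,
  IGHG1 within IGHG 0.919. The heavy fraction is set heavy-dominant:
  published composition figures for plasma-cell BCR quote an 11% figure
  whose numerator is ambiguous, and TRUST4 read mass in plasma cells is
  overwhelmingly heavy-chain; both heavy/total and light/total are reported
  downstream so either reading is checkable.
* **Expression** — null genes are i.i.d. standard normal. An implanted gene
  is built as y = Z·b + σ·ε with b = R⁻¹t (R the empirical correlation of
  the standardized IGHG abundance and CPK metrics, t the target
  correlations, default 0.891 and −0.703) and σ² = 1 − tᵀR⁻¹t, with ε
  residualized in-sample against the metrics and standardized. This makes
  the realized sample correlations equal the targets *exactly* in every
  cohort, not just in expectation. The in-sample-exact construction is
  deliberate: a target of |r| = 0.703 sits 0.003 above the 0.7 selection
  threshold, and under expectation-only implanting the sampling noise of r
  at n = 34 (≈ 0.09 SD) would make threshold crossing a coin flip — the
  recovery experiment would measure noise, not the procedure. Feasibility
  (σ² > 0, i.e. the implied 3×3 correlation matrix is positive definite)
  is checked and raises a config error otherwise. A group mean-shift can be
  added for DE-only implants, at the cost of that exactness.
* **Survival** — exponential baseline hazard (0.15/month) multiplied by
  exp(β·x) with a continuous standard-normal "gene" covariate (true HR
  2.421) and a binary "rejection" covariate (HR 1.8), n = 282. Censoring
  is Uniform(0, u) with u solved numerically so the expected censored
  fraction is 0.4 (≈ 60% events); censoring fraction 0 observes every
  event.

All randomness flows from one integer seed through `numpy`'s
`default_rng`/`SeedSequence`; identical config + seed give byte-identical
output files, and ground truth is always emitted alongside so recovery
tests read truth from the manifest, not constants.

**What the generator does not emulate:** V(D)J junction biology (CDR3s are
random in-frame placeholders without stop codons — no germline templates,
no somatic hypermutation), lineage structure, batch effects, library-size
variation in expression, or dependence between the expression noise and
the repertoire beyond the implanted genes. Passing recovery tests
therefore demonstrates that the pipeline's estimators are unbiased and
correctly wired under the assumed structure — not that real biopsy data
meet those assumptions.

## Numerical choices and degenerate inputs

* Shapiro–Wilk is skipped (gate fails) for n < 3 or constant vectors.
* Identical constant groups in the rank test return p = 1 rather than NaN.
* Constant genes get DE p = 1 and undefined correlations, both flagged.
* Hochberg adjustment caps at 1 and is monotone in the step-up order.
* `celltype_fold` returns NaN (flagged undefined) for absent cell types or
  zero denominators instead of raising.
* Empty repertoires are warnings, not errors, and yield all-zero counts
  with undefined CPK.
* Problem sizes in the test-suite recovery experiments are the study
  conditions themselves: 18 + 16 bulk samples, 993/620/76 cells, n = 282
  survival records, with 20 replicate seeds for fold/composition recovery
  and 50 for correlation/hazard recovery.

## Known limitations

* The exact-implant construction fixes in-sample correlations; estimator
  *variance* under noisy implants is not exercised by the recovery tests.
* The Cox recovery averages exp(β̂), which is slightly above the true HR by
  Jensen's inequality (≈ +1% at these sample sizes); this is a property of
  reporting hazard ratios, not a bug.
* TCR analysis is out of scope: TCR loci in TRUST4 reports are counted and
  discarded.
* No diversity indices beyond CPK (Shannon, Gini, D50) and no
  somatic-hypermutation or lineage-tree analysis.
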