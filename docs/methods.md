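# Methods

This note documents the models and procedures `isocall` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Structural classification

A transcript model is an ordered block of exons on one sequence and strand
(0-based, half-open coordinates internally; GTF converts at the boundary).
Its identity for structural comparison is the **junction chain**: the
ordered intron intervals between adjacent exons. Junction identity is the
intron interval `(seq, strand, donor, acceptor)`; exon end coordinates never
participate, so end variation cannot change a category.

Multi-exon queries are decided in a fixed order:

1. chain equals a reference chain → **FSM**;
2. chain is a contiguous, order-preserving sub-chain of some reference
   chain → **ISM** (the matched reference transcript and the offset of the
   sub-chain are recorded, from which the 5′/3′ missing-end flags are
   derived, transcription-direction aware);
3. every splice site annotated (strand- and role-aware: a donor never
   matches an acceptor at the same coordinate) → **NIC**;
4. otherwise, same-strand gene overlap → **NNC**;
5. opposite-strand overlap only → **antisense**;
6. no gene overlap → **intergenic**.

Mono-exon queries: exact interval match to a mono-exon reference transcript
→ FSM; containment within a same-strand annotated exon → ISM; inside a
same-strand gene span but within no exon → other-genic; else antisense /
intergenic as above. The annotation never prescribes mono-exon semantics,
so these mirror the common structural-category convention and are covered
by the brute-force oracle in the tests.

Design choices:

* **Exact splice-site matching (0 bp tolerance).** No wobble window is
  applied; this keeps the decision procedure equivalent to a literal
  enumeration oracle, and the generator places novel sites ≥ 10 bp from
  every annotated site so NNC can never collide with NIC under any
  tolerance.
* **ISM requires a contiguous sub-chain.** Non-contiguous subsets (exon
  skipping) are novel combinations and fall through to NIC/NNC.
* **Gene assignment** is the same-strand gene sharing the most junctions
  with the query; ties break by exonic overlap bp, then lexicographic gene
  id. Antisense calls are assigned the opposite-strand gene with the most
  exonic overlap. When both same-strand and opposite-strand overlaps exist,
  same-strand categories take precedence.
* The five-way reporting convention maps *others* = antisense ∪ intergenic
  ∪ other-genic.

## Artifact-filter cascade

Order: classify → junction support → intrapriming → ISM 3′-ends → merge →
replicate filter. Per-sample evidence filters run before the cross-sample
merge so occurrence counts reflect surviving observations.

* **Junction support** (`min_junction_reads`, default 1): every junction of
  a multi-exon model must reach the pooled short-read support threshold;
  mono-exon models pass vacuously. The support-file dialect is the common
  aligner junction output: 5 tab-separated columns with 1-based inclusive
  intron coordinates; a `.` strand matches either strand.
* **Intrapriming** (`polyA_window` = 20 bp, `polyA_min_A` = 16): for every
  non-FSM category, count adenines on the transcript strand in the window
  genomically downstream of the 3′ end (+ strand: `[end, end+20)` as-is;
  − strand: `[start−20, start)` reverse-complemented); fail at ≥ 16. FSM
  models are exempt. Windows truncated by sequence bounds are counted as-is
  and flagged.
* **ISM 3′-end filter** (`filter_ism_ends`, default on): ISM models whose
  missing region is at the 3′ end *only* are removed — the canonical
  RNA-degradation / incomplete-RT artifact. 5′-truncated and doubly
  truncated ISMs are kept (subject to the intrapriming rule like any other
  non-FSM model). Mono-exon ISMs are treated as missing both ends and are
  therefore retained by this rule.
* **Merge**: multi-exon models with identical chains collapse to one record
  with the outermost observed ends (internal exon boundaries are fixed by
  the chain); mono-exon models merge by single-linkage at ≥ 50% reciprocal
  overlap on the same strand. The merged record keeps the lexicographically
  smallest contributing transcript id, making the merge independent of
  sample ordering.
* **Replicate filter** (`min_replicates`, default 2): occurrence count is
  the number of distinct samples contributing to a merged record.

All three thresholds are monotone: tightening any of them can only shrink
the final set (property-tested over random datasets).

## Differential expression

Two-sided Wilcoxon rank-sum per feature. The exact null distribution is
used when both groups have ≤ 12 samples and no value is shared *between*
the groups — within-group ties leave the rank sum and its permutation null
unchanged, which is what makes the complete-separation case
(p = 2/C(20,10) ≈ 1.08 × 10⁻⁵ at 10 vs 10) exact. Cross-group ties or
larger groups use the normal approximation with tie and continuity
correction. A paired (signed-rank) mode is available by flag; the default
is unpaired, matching the named test.

Fold change is computed on group means with pseudocount ε = 0.01,
`log2((mean_a + ε)/(mean_b + ε))`, keeping zero-expression features finite.
Benjamini–Hochberg runs across all features tested at that level in that
run (one family; no gene-wise nesting). Significance: |log2 FC| > 1 and
FDR < 0.05. Gene TPM is the sum of member transcript TPMs; ISM transcripts
are removed before testing (at either level) whenever structural calls are
supplied. The DET/DEG decomposition calls a gene DET-positive when ≥ 1
member transcript is significant and splits genes into DET-specific /
DEG-specific / shared.

## SRT callers

Tumour SRTs: (i) median tumour TPM ≥ `fold_threshold` (10) × maximum TPM
over all normal samples, **and** median > 0 — the guard exists because at
max-normal = 0 the bare inequality would admit all-zero transcripts; the
comparison is inclusive ("at least 10-fold"); (ii) TPM > 0.5 in strictly
more than 5% of tumour samples. Adding a normal sample can only remove
calls (the maximum is monotone), and scaling tumours up never removes a
criterion-(i) call; both are property-tested.

Metastasis-specific transcripts: strict `>` on the pseudocounted ratio of
group medians, `(median_met + ε)/(median_primary + ε) > 10`, with the same
prevalence rule over metastasis samples. The inclusive/strict asymmetry
between the two callers is deliberate — each operator is kept as its rule
is stated. An optional third criterion (maximum TPM below 0.5 in supplied
normal groups) is available but off by default.

## Isoform switching

A gene switches when, among its tested transcripts, at least one is
significantly up and one significantly down; significance reuses the DET
thresholds verbatim — no separate switch statistic, and no requirement that
the *major* isoform changes rank. Genes with a single tested transcript are
ineligible. Isoform fractions (transcript TPM / gene TPM per sample;
undefined where the gene TPM is 0) are exported for downstream clustering,
which is out of scope here; fractions are scale-invariant per sample and
sum to 1 where defined.

## Panel evaluation

Features are log2(TPM + 1)-transformed panel rows. Samples are split 4:1
(stratified, seeded); a 500-tree random forest is scored by 5-fold
cross-validation on the training set (AUC over pooled out-of-fold
probabilities), then refit on the full training set and scored on the
held-out samples. AUC is the Mann–Whitney rank statistic — the probability
a random positive outranks a random negative, ties counting ½ — which
equals trapezoidal integration of the empirical ROC step curve (asserted
against an independent implementation in the tests). The classifier is
specified behaviourally (bagged trees with per-tree feature subsampling);
any standard implementation satisfies the contract, and scikit-learn's is
used.

`cross_validated_auc` scores *all* samples by k-fold cross-validation
without a held-out split. It exists for calibration studies: the null
sampling sd of the AUC scales like √((n₁+n₂+1)/(12 n₁ n₂)), so on a
200-sample null cohort the pooled out-of-fold AUC (sd ≈ 0.04–0.05 including
forest noise) is a far more stable calibration readout than a 40-sample
held-out AUC (sd ≈ 0.09). The calibration tests therefore assert the mean
null AUC across 20 replicates lies in [0.40, 0.60]; a per-replicate
assertion at that band would be a coin flip at these sample sizes
regardless of implementation.

## Synthetic-data generator

One seed produces a complete study: a uniform-random ACGT genome (2 × 500 kb
by default), ~30 genes laid out with ≥ 25 kb spacing, each with a pool of
non-overlapping exons and 1–4 reference transcripts formed as contiguous
exon runs (deduplicated within the gene), ~200 query models, 4 long-read
samples, junction-support tables (Poisson(20)+1 counts), and TPM cohorts of
10 tumour / 10 normal / 10 metastasis / 10 primary samples.

Queries are constructed per intended category — FSM by end-jittering a
reference transcript; ISM by taking a contiguous sub-chain (checked against
the chain index so it cannot equal a full reference chain); NIC by exon
skipping (a new junction between two annotated sites); NNC by shifting one
splice site ≥ 12 bp into an intron and verifying ≥ 10 bp distance from
every annotated site; antisense by strand-flipping a reference chain;
intergenic by placement ≥ 10 kb from every gene span. Every construction is
verified by set membership at build time, so the generated labels are
ground truth by construction, and the classifier's exact recovery of them
is a meaningful cross-check rather than a tautology.

Expression: per-transcript baselines are log-normal (μ = ln 10, σ = 1) with
multiplicative log-normal noise (σ = 0.4 per cell) — the downstream
statistics are rank- and threshold-based, so any right-skewed positive
model suffices. Planted effects:

* **SRTs** (3% of transcripts; effect 50×): tumour cells draw
  baseline × 50 × noise; every normal cell draws uniformly from [0, 0.05],
  so criterion (i) is satisfiable by construction whenever
  baseline × effect ≥ 0.5. Metastasis-SRTs are planted the same way in the
  metastasis/primary cohorts, disjoint from the tumour SRTs.
* **Switch genes** (25% of multi-isoform genes; effect 4×): a reciprocal
  pair with normal means (c, 4c) and tumour means (4c, c) — both
  transcripts clear |log2 FC| > 1 while the gene-level sum is conserved
  exactly in expectation (verified to within 25% per planted gene under
  noise), so switch genes are DET-positive but not DEGs.
* **A-tracts**: 30% of queries get 12–20 adenines written into the genome
  immediately 3′ (strand-aware) of their termination site. Ground truth
  records the *measured* adenine count from the final genome, so
  overlapping plants and random flanking adenines are accounted for.

What the generator does **not** emulate: read-level errors, coverage/length
biases, batch effects, correlated transcript expression within genes,
library-size variation, fusion or readthrough transcripts, and paired
tumour/normal correlation. Passing tests therefore demonstrate that the
implementations compute the stated rules correctly and recover effects that
exceed their thresholds under clean noise — not that the thresholds are
well-calibrated for any particular real cohort.

## Problem sizes and determinism

Default study sizes (200 query models, 10 samples per cohort, 2,000-feature
null cohorts, 20 replicates for calibration checks) were chosen so every
property is measurable with wide margins while the full suite and the
acceptance script each run in minutes on one core. All randomness flows
from `numpy.random.default_rng` seeds; the pipeline derives per-stage
sub-seeds from the global seed by hashing the stage name, so stages are
independently re-runnable and two runs with the same config produce
byte-identical artifacts (summary timings are logged to stderr, not written
to the summary, to keep it deterministic).

## Known limitations

* GTF is the only annotation dialect (no GFF3); BAM/FASTQ handling,
  alignment and quantification are out of scope.
* Unknown (`.`) strand on query models is rejected, not guessed —
  classification is strand-dependent.
* The classifier does not detect fusion/readthrough or RT-switching
  artifacts, and no CAGE/polyA-motif end-support scoring is performed.
* The ISM 3′-end rule is one concrete reading of "filtered based on 3′ or
  5′ end incompleteness"; the flag `filter_ism_ends=False` disables it.
* `call_metastasis_srt` applies the prevalence criterion to the metastasis
  group by default; the strictly-defined criteria exist only for the
  tumour/normal comparison, and the optional normal-silence criterion is
  off unless requested.
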