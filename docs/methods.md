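# Methods

## Weighted methylation level

The central statistic is the weighted methylation level of a region R in a
context c ∈ {CG, CHG, CHH}: the sum of methylated read calls over the sum of
all read calls at R's covered cytosines,

m(R, c) = Σᵢ kᵢ / Σᵢ nᵢ ,

where kᵢ/nᵢ are the methylated/total counts at cytosine i after the
coverage filter (nᵢ ≥ 4 reads). Pooling counts, rather than averaging the
per-cytosine ratios kᵢ/nᵢ, weights each cytosine by its coverage and is
robust to coverage heterogeneity; it is the standard region summary for
bisulfite data. Cytosines on both DNA strands inside the window contribute
regardless of the gene's strand, and strands are never pooled at symmetric
CG dyads — each strand-specific cytosine is its own observation, matching
the per-cytosine report layout consumed. A region with no covered cytosine
of the requested context has an *undefined* level (NA in output), which
propagates to an "undefined" differential call rather than being dropped.

## Analysis windows

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
BED (half-open) convert at the I/O boundary, which removes the usual
off-by-one error class. The gene feature line defines the transcription
start and end sites, so the gene body window (GBR) is the gene span and the
length-L upstream window (UPR, L ∈ {200, 500}) covers the L bases
immediately 5′ of the TSS on the gene's strand. Windows are clipped at
chromosome ends (possibly to empty, which yields undefined levels) and are
*not* trimmed when they overlap a neighbouring gene — no trimming rule is
part of the procedure, and the simulator keeps ≥ 600-bp intergenic gaps so
clean and overlapping layouts can be distinguished in tests. UPR200 nests
inside UPR500 by construction.

## Context calling

On the plus strand a cytosine's context is read from the next two bases
(CG; CHG = C-H-G; CHH, H ∈ {A,C,T}); on the minus strand from the
complemented upstream bases. CG is decided by the adjacent base alone, so a
cytosine one base from the sequence end followed by G is still CG; any
position whose deciding window runs off the sequence or contains N is
treated as not-a-cytosine rather than defaulting to CHH.

## Thresholds and boundaries

- Coverage filter: keep nᵢ ≥ 4 (the boundary record with exactly four reads
  is kept).
- Group classification: group 1 is strictly level > 0.1; the boundary 0.1
  falls in group 2, which is defined as the complement.
- Differential methylation: the delta is absolute percentage points,
  100 × (mutant − wild type), not a ratio — only absolute differences are
  consistent with calls on regions that move from ≈ 0 to large levels.
  Thresholds are inclusive (≥ 10 pp hyper / ≤ −10 pp hypo for UPRs; 5 pp for
  GBRs); both are configurable because upstream windows and gene bodies are
  screened at different stringencies.
- Expression: a gene must reach 1 FPKM in at least one genotype before the
  ratio rule (≥ 1.1 up, ≤ 0.9 down, inclusive) applies; a gene silent in
  the wild type but expressed in the mutant is "up" with an undefined
  ratio, since the zero denominator carries no information beyond the
  direction. The external-DE filter is strict at twofold (fold > 2 or
  < 0.5) and inclusive at FDR ≤ 0.05; the Benjamini–Hochberg adjustment is
  delegated to statsmodels and cross-checked against a brute-force step-up
  oracle in the tests.
- qPCR: replicates are aggregated by mean Ct per condition before
  ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control, the
  conventional comparative-Ct aggregation; the fold change 2^(−ΔΔCt) is
  invariant to constant cycle offsets.

## Synthetic data

The generator emulates a two-genotype (wild type vs. demethylase mutant)
BS-seq + mRNA-seq study:

- **Genome**: i.i.d. bases at GC fraction 0.36 (Arabidopsis-like), default
  two chromosomes × 400 kb.
- **Annotation**: 144 genes of 1–3 kb (the NLR cohort size), random strands,
  packed with ≥ 600-bp gaps so every UPR500 is intergenic; infeasible
  packings raise a configuration error.
- **Methylomes**: per-context baselines CG 0.20, CHG 0.08, CHH 0.03
  (high/mid/low, roughly genome-wide plant levels). Each cytosine draws its
  own methylation probability from Beta(pκ, (1−p)κ) around its region's
  true level p (κ = 20 by default; κ → ∞ recovers the binomial used in
  closed-form checks), coverage from Poisson(λ = 50), and methylated counts
  from a binomial — a beta-binomial observation model for within-region
  heterogeneity. Zero-coverage cytosines are written, as real cytosine
  reports do, so the coverage filter is genuinely exercised. Planted
  effects add a delta (clamped to [0, 1]) to the mutant's true level over a
  chosen (gene, window, context); wild type stays at baseline. Where
  windows nest, the most specific planted window wins per position, and the
  truth table records the per-position truth averaged over each window —
  exactly the quantity the weighted level estimates.
- **Expression**: wild-type FPKMs are lognormal (median 10, σ_log 1, a
  plausible bulk profile for a gene family in which many members are
  weakly expressed); mutant FPKM = wild type × planted ratio ×
  lognormal(0, σ = 0.05) noise.
- **qPCR**: the reference gene sits at Ct 20, targets at Ct 25 shifted by
  −log₂(fold) in the test condition, with N(0, 0.1²) cycle noise per
  replicate (three replicates).

Every generator draws from its own child stream of the configured seed, so
outputs are byte-identical across runs and independent of call order.

What the simulator does **not** model: read-level artifacts (mapping bias,
incomplete bisulfite conversion, PCR duplicates), linkage of methylation
states between neighbouring cytosines, transposable elements and other
genomic features that shape real methylation landscapes, biological
replicate structure (a replicate is emulated by concatenating reports), and
any coupling between methylation and expression other than what is planted.
Passing recovery tests therefore show that the *pipeline arithmetic and
thresholds* recover known effects under realistic sampling noise — not that
the thresholds are optimal for real mutant methylomes.

## Problem sizes and observed behaviour

The default study (144 genes, ~290 k strand-specific cytosines per
genotype, λ = 50) simulates in a few seconds and profiles in well under a
second, so tests and the acceptance script run the full pipeline rather
than a reduced one. Worth knowing when interpreting output:

- At λ = 50 and κ = 20 a 500-bp window holds ≈ 30 CG sites and the level
  estimate has an sd of ≈ 1.5 pp, so +40-pp effects are recovered with
  recall 1.0 and the 10-pp threshold produces essentially no false calls.
- 200-bp windows hold only ≈ 13 CG sites; a −15-pp planted effect at the
  10-pp threshold is *marginal* there (recall ≈ 0.7 in the analysis run) —
  an honest illustration that small windows support only coarse calls.
- Effects planted in a nested window dilute into the enclosing one
  (a UPR200 effect shifts its UPR500 level by ≈ 200/500 of the delta);
  recovery summaries in the analysis scripts exclude such regions from
  their null sets instead of miscounting them as false positives.

## Known limitations

- The per-cytosine coverage filter is applied per strand; a study that
  pooled CG dyad strands before filtering would keep slightly more
  low-coverage dyads.
- Differential calls are fixed-threshold, not statistical tests; no
  Fisher/binomial per-region test and no de-novo DMR segmentation is
  provided.
- DE statistics (dispersion modelling, p-values) are out of scope: the
  expression module classifies supplied FPKMs and filters supplied fold
  changes/FDRs.
- Link tables state co-occurrence of calls, not causation.
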