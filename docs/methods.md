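# Methods

## Scope and model

The package screens for genes whose loss is selectively deleterious to
p53-mutant, MYC-high colorectal cancer cells. It assumes the standard data
shapes of the field: a CRISPR dependency matrix (genes × cell lines, more
negative = stronger dependency), per-study differential-expression
summaries (gene, log2FC, p), and per-cohort expression matrices with
clinical annotation (tumor/normal pairing, p53 status, stage, subtype
labels, relapse-free survival). All statistics are computed from their
textbook formulas; only distribution functions (Student t, F, chi-square,
studentized range, normal) come from scipy.

## Elementary statistics (`stats`)

* Pearson correlation: pairwise-complete pairs; p from
  `t = r·√((n−2)/(1−r²))` on `n−2` df, two-tailed; 95% CI by Fisher z with
  `1.96/√(n−3)`. `|r| = 1` returns p = 0 with a degenerate CI.
* Two-sample t: classical Student by default (the screen's stated method),
  Welch–Satterthwaite by flag. Paired t is the one-sample t of the
  differences; zero-variance differences raise rather than return p = 0.
* One-way ANOVA with a linear-trend post-test: centered stage scores
  (default 1..4) give the contrast `L = Σ cᵢ·meanᵢ`, tested with
  `t = L/√(MSE·Σcᵢ²/nᵢ)` on `N−k` df. On balanced designs this equals the
  OLS slope test (asserted in the suite).
* Tukey–Kramer post-test from the studentized range distribution
  (`k` groups, `N−k` error df).
* Benjamini–Hochberg step-up adjustment is available but **off by
  default** everywhere: the screen's votes and candidate calls use raw
  p < 0.05, matching the conventions of the sources it emulates; the
  option is recorded in output metadata when enabled.
* Missing data: pairwise-complete for correlations, listwise within each
  test otherwise; the n actually used is reported in every result.

## Survival (`survival`)

Kaplan–Meier estimation, the two-group log-rank test with hypergeometric
variance, and the Pike O−E estimator
`HR = exp((O₁−E₁)/V)`, `CI = exp((O₁−E₁)/V ± 1.96/√V)`. The estimator
stays entirely within log-rank quantities; no proportional-hazards model
is fitted (a Cox fit would give slightly different HRs — a deliberate
non-goal). Ties: events precede censorings at equal times.

The optimal cutoff scan evaluates every distinct covariate value whose
split leaves both groups with at least `minprop·n` patients (default
minprop = 0.1) and at least one event, and returns the split maximizing
the log-rank chi-square; ties break toward the smaller covariate value.
Because the maximum over splits inflates the test statistic, the reported
p is **anti-conservative**; every result carries a `selection_bias` flag,
and the suite demonstrates the inflation (null false-positive rate ≫ 5%;
~40% in the shipped simulations). No correction is applied, by design,
since the emulated workflow reports the naive log-rank p. Pooling several
cohorts median-centers expression per cohort before one global scan, a
minimal harmonization for platform offsets; per-cohort scans are also
available since the pooled-versus-per-cohort choice is genuinely open.

## Screen axes

* `dependency`: per-gene Pearson against the driver profile plus a
  wt-vs-mut t-test. "Significant" means raw two-sided p < α combined with
  the required sign, i.e. an `α/2` one-sided condition per axis; under a
  pure-noise null the expected candidate fraction is `(α/2)²` (asserted).
  Genes missing in more than half of the lines are dropped and listed.
  Lineage restriction is the caller's concern (a `restrict_lineage` helper
  exists when annotation is present).
* `perturbation`: votes need `p < α` and `|log2FC| ≥ fc_min`
  (default fc_min = 0 — the sources define no fold-change floor); loss
  studies flip the effective sign. Unmeasured genes contribute neither
  vote nor denominator. The p53 panel admits activation-type studies only.
* `cohorts`: correlation votes use tumor samples only; unknown p53 status
  excludes a sample from the differential vote but not from the
  correlation vote.
* Composite rank: mean of the per-axis ranks, each axis oriented so the
  exemplar profile (driver-coupled, mutant-dependent, driver-induced,
  p53-repressed) ranks first; ties break on the gene identifier. Stages
  are independent: omitting one never changes another's numbers.

## Sequence layer (`motifs`)

Seed matching is strand-specific and purely positional: the 6mer core is
the reverse complement of miRNA positions 2–7; position-8 pairing on the
5′ side and an A opposite position 1 on the 3′ side upgrade the site
(8mer > 7mer-m8 > 7mer-A1 > 6mer; one site per locus at its most specific
type). Coordinates are 0-based half-open. No context scoring, pairing
energetics or 3′-supplementary pairing — the scan answers "is there a
site", as a reporter-mutagenesis workflow needs. Conservation maps the
6-nt seed core into each ortholog by per-species offsets or a gapped
alignment; a site is conserved when ≥ k orthologs (default: a majority)
carry a site of equal or higher specificity at the homologous core, and
unmappable cases return an explicit unknown (tri-state). `mutate_sms`
complements the seed core (length-preserving), verifies by rescanning
that no site of any type remains at the locus, and falls back to
deterministic alternative substitutions in the rare case a substitution
recreates a match. E-box scanning is exact-match on both strands with
palindromes (both defaults are palindromic) reported once per position.

## Synthetic data (`simulate`)

The generators define the validation conditions; every parameter is echoed
into a `SyntheticTruth` JSON.

* **Dependency**: driver profile ~ N(−1, 1) with a mutant shift of 0.6;
  planted co-dependent genes add `0.8 × driver` on top of N(0, 0.3) noise;
  planted mutant-dependent genes shift by −0.6 in mutant lines; 40 lines,
  half mutant. The driver's own mutant shift is what couples the two
  screen axes (driver-tracking genes inherit part of the shift), producing
  the positive genome-wide integration correlation the screen reports and
  making a gene planted with *both* roles detectable on the differential
  axis despite its driver-coupled variance.
* **Perturbation**: per study, 4 replicates per arm on the log2 scale with
  residual sd 0.3 — a typical small-n expression-profiling regime; planted
  effects are ±1 log2 unit, sign-flipped at the data level in loss
  studies; p from the pooled t across replicates. Under zero effect the
  vote rate is α by construction (continuous p).
* **Cohorts**: log2-scale expression, baseline N(8, 0.5) per gene/cohort,
  unit noise; planted driver correlation ρ = 0.5; mutant elevation 1 sd;
  15 cohorts of 100 tumors, p53 status reported in 6 (latent in the rest);
  25 tumor/normal pairs per cohort sharing a gene-specific pair effect
  (sd 0.5) so pairing is informative without inducing cross-gene
  correlation; planted tumor elevation 0.8 log2, stage slope 0.4/stage,
  CMS2 and CRIS-C/D elevation 1.0.
* **Survival**: exponential times with log-hazard `β_status · x` (centered
  expression), β_wt = −0.8 / β_mut = +0.8, baseline hazard 0.02/month,
  uniform censoring on (1, 120) months — the simplest model exhibiting the
  wt/mut sign flip, with closed-form sanity checks.
* **Sequences**: i.i.d. backgrounds at GC 0.4, scrubbed of accidental seed
  cores and motifs (including insert junctions, with planted positions
  protected) so planted coordinates are the exhaustive truth; orthologs
  share the reference background (offset-0 mapping) and copy each site
  with the stated probability, else complement its core.

What the generators deliberately do **not** model: count-level noise
(negative binomial, library size), batch structure, gene–gene correlation
networks, mutation-calling error, or sequence evolution beyond
site-level keep/scramble. Passing tests therefore show the pipeline's
statistics and bookkeeping are correct under clean Gaussian/exponential
conditions, not that real DepMap/GEO/TCGA data would yield the same
power.

## Problem sizes and numerics

The shipped validation runs use 2000 genes × 40 lines, 2 × 20 studies, 15
cohorts × 100 tumors, 20 seeds for recovery rates, 300 patients per
stratum for the survival interaction, and 500–1000 null simulations for
calibration — sizes chosen so the whole suite runs in well under a minute
per property on a laptop-class CPU while keeping Monte-Carlo error small
relative to the asserted margins. Vectorized row-wise tests are asserted
equal to the scalar implementations to ≤ 1e-10; float TSV output uses 8
significant digits, and loader/writer pairs are byte-level fixpoints at
that precision. Degenerate inputs (zero variance, empty groups,
all-censored arms, constant covariates) raise typed errors naming the
cause rather than returning misleading numbers.

## Known limitations

* HRs come from the O−E estimator, not a Cox model; they diverge for
  strong effects (visible in the worked example's extreme strata).
* The naive cutoff-scan p is reported uncorrected (flagged), so
  cross-study comparability of those p-values is limited.
* Gene identifiers join by exact string; synonym resolution is the
  caller's responsibility (an alias map can be applied upstream).
* The cohort pooling strategy (median-centering) removes location offsets
  only, not scale or censoring-distribution differences.
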