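# Methods

This note records the statistical model behind `eaclock`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## The per-CpG test

WGBS gives, per CpG and sample, a methylated count m out of n reads. The
proportion is transformed as

    y = arcsin( sqrt( (m + 1/2) / (n + 1) ) )

which stabilises the binomial sampling variance at approximately 1/(4n)
regardless of the methylation level (the ±1/2 offsets keep y finite and
nearly unbiased at m = 0 or m = n). For a two-group comparison (B − A,
positive = gain of methylation in the older/high-division arm):

* group means ȳ are coverage-weighted (weights n), so deep samples count
  more;
* the per-group variance is the mean sampling term `mean(1/(4(n + 1/2)))`
  plus a **pooled biological variance**: the moment estimator
  `var(y) − mean sampling term` pooled over both groups by degrees of
  freedom and floored at 1e-4;
* `z = (ȳ_B − ȳ_A)/sqrt(v_A/n_A + v_B/n_B)`, with a two-sided normal
  p-value.

This is a deliberate, closed-form stand-in for shrinkage-based
beta-binomial WGBS tests (no smoothing across CpGs, no empirical-Bayes
dispersion prior), and it is **not identical** to them. What it must do is
be calibrated: on a null simulation (no planted differences, beta-binomial
overdispersion φ = 0.02, 50,000 sites, 3 vs 3) the fraction of sites with
p < 0.01 is 0.0059 — slightly conservative, inside the accepted
[0.005, 0.02] band. With only 2–3 samples per group the biological-variance
estimate is noisy; the floor plus the deterministic sampling term keep the
z reference distribution close to normal anyway.

## DMR segmentation and the area statistic

Candidate CpGs (p below the threshold, default 0.01 — sites "higher than
five reads in all samples" are required upstream, i.e. coverage strictly
> 5) are segmented per chromosome into maximal runs of same-sign z with
consecutive gaps ≤ 300 bp; runs with fewer than 3 candidates are dropped;
surviving same-sign regions closer than 100 bp are merged. Only the p
threshold is inherited from the source analysis — the segmentation
parameters resemble common DMR-caller defaults and are all exposed.

Each DMR's **area statistic** is the plain sum of member z values; its sign
is the direction (gain/loss), ties in |area| break by (chrom, start) for
determinism. The signature program is the top K = 150 by |area| (K = 139 is
equally supported; both cardinalities appear in the source material and the
relationship between them is unstated). A region-level p, needed only for
the gene rank metric, is the two-sided normal tail of `area/sqrt(n_cpgs)`
(Stouffer combination) — the simplest defensible choice where no region p
is defined.

Per-gene GSEA ranks are `sign(Δβ) × (−log10 p)` with each gene represented
by its largest-|rank| DMR; p is clamped to the smallest positive double
before the log.

## Scoring and clocks

A sample's methylation over a region is the pooled ratio Σm/Σn across
member CpGs (not the mean of per-CpG betas — deep CpGs count more, and the
value is defined whenever any member has coverage). The signature score is
the unweighted mean over regions, skipping regions with no coverage in that
sample.

Weighted clocks compute `intercept + Σ wᵢ βᵢ`; scores may legitimately be
negative. Missing panel sites default to imputation from the model's
reference means (falling back to the cohort mean of the site), capped at a
20% missing fraction — the usual array/WGBS panel mismatch failure mode;
`drop` and `error` policies are available. Mean-of-sites clocks average the
used betas.

Group comparisons use Welch's unequal-variance two-sided t-test by default
(`pooled=True` restores the classic equal-variance test): with 2–5 samples
per arm and no reason to assume equal variances, Welch is the safer default
for a test described only as "two-sided Student's t".

## Plateau detection

A bounded signature must saturate: once its CpGs approach β = 1 the score
cannot keep rising. This is quantified by fitting

    score = a + b (1 − exp(−c · age)),   c ≥ 0

by nonlinear least squares from five fixed starts (c spanning 0.1–10 over
the observed age range), against an ordinary straight line, compared by
AIC (`n·ln(RSS/n) + 2k`). Numerical notes:

* the best point found is accepted even when the evaluation budget stops
  the search — on exactly linear data the saturating model approaches the
  line only in the limit c → 0, b → ∞, so a "success" flag never fires
  although the fit is numerically exact;
* RSS is floored at `1e-6 · n · var(y)`, so a noiseless nested fit costs
  exactly its extra parameter (ΔAIC = +2) instead of producing −∞;
* `saturation_age = −ln(0.05)/c` is the age at 95% of the asymptote.

## Enrichment statistics

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum: hits add
`|rank|^p` normalised over hits (p = 1 default), misses subtract
`1/(N − N_h)`; ES is the extremum by absolute value; the leading edge is
the hits at or before (after, for negative ES) the extremum. Significance
is by gene-label permutation with the +1 Monte-Carlo correction, and the
p-value is **sign-conditional in both numerator and denominator**:
`p = (1 + #{same-sign ES at least as extreme}) / (1 + #{same-sign ES})`.
Conditioning only the numerator (counting same-sign extremes against all
permutations) halves p under the null and fails uniformity; the
sign-conditional form is standard preranked practice and passes the
binomial-envelope calibration test in the suite.

Region–term enrichment is the one-sided binomial test on merged term
domains: `p_term` = domain bp / genome size, k = query regions whose
midpoints fall inside, p = P(Binomial(n, p_term) ≥ k), no multiple-testing
adjustment. A helper builds basal regulatory domains (TSS −5 kb/+1 kb,
strand-aware, clipped at chromosome ends); the full regulatory-domain
construction of web-based tools is intentionally out of scope — the test
statistic is the reproducible core.

Interval overlap ("≥ 1 bp, counted once per query region") is a sorted
sweep (binary search on starts plus a prefix running-max of ends), kept
in-package because it is ~20 lines and the test oracle — quadratic
all-pairs — must stay independent of it anyway.

## The synthetic generator

`simdata` emulates the serial-transplant design: each sample is a T cell
population with a cumulative division count D (experiential age) living in
a host of age A months. Site classes and surfaces:

| class | default fraction | surface |
|---|---|---|
| gain | 8% (200 runs × 8 CpGs at 20k sites) | `b + (1 − b)(1 − e^{−kD})`, b = 0.05 |
| loss | 10% | `b·e^{−0.02·D}`, b ~ Beta(9,1) |
| hostage | 1% | saturating in A, ≤ 0.1 Δβ over a 30-month lifespan |
| stable | rest | constant; mixture 0.6·Beta(9,1) + 0.3·Beta(1,9) + 0.1·U(0.2, 0.8) |

The default gain rate k = 0.0342/division is fixed by requiring +0.4 β at
D = 16 from baseline 0.05 — the planted effect size of the recovery
benchmark — and implies 95% saturation near D ≈ 88, which is what produces
the plateau phenomenon when a signature trained on the lower half of a
0–120 division ladder is scored on the whole of it. Gain CpGs are planted
in contiguous runs (8 CpGs within 400 bp, background spacing 1 kb) so that
segmentation is genuinely exercised. Coverage is negative binomial (mean
20, dispersion 5 — a typical WGBS-like depth profile; no coverage
distribution is stated anywhere authoritative) and methylated counts are
beta-binomial with intraclass correlation φ = 0.02. One lifetime (LT) is
30 months (a 2.5-year organismal lifespan); divisions-per-boost is a free
parameter (nominal 10) because nothing pins down how many divisions one
boost cycle induces.

The generator does **not** emulate: read-level data or bisulfite
conversion error, strand-resolved CpG dyads, SNP confounding, correlated
methylation beyond the planted runs, batch effects, or cell-type mixtures.
A green recovery test therefore establishes that the pipeline finds
planted, contiguous, coverage-supported drift regions under realistic
count noise — not that it would survive every artefact of real libraries.

## Conventions and degenerate inputs

* Coordinates are 0-based half-open internally; Bismark coverage files
  (1-based inclusive) convert at the I/O boundary. Input is assumed
  strand-collapsed per CpG dyad; no merging is performed.
* The coverage filter is strict: total > 5 in *every* sample ("higher than
  five reads").
* PCA centers per site without unit-variance scaling (covariance-style
  components on betas; whether the original analysis scaled is unstated —
  the flag is the `n_top`/centering behaviour documented here). Component
  sign is fixed by requiring each loading vector to have nonnegative sum.
* β = m/n with no pseudocount; undefined (NaN) exactly where n = 0.
* Ties everywhere break by (chrom, start) or gene name; two runs with the
  same seed are byte-identical, and the pipeline derives per-stage RNG
  substreams from the base seed via a stage-name hash so inserting a stage
  does not reshuffle downstream randomness.
* Feature annotation is midpoint-based with precedence promoter > utr5 >
  utr3 > exon > intron > intergenic; promoter = [TSS − 2000, TSS + 500)
  strand-aware; shores are < 2 kb from a merged island edge, shelves the
  next 2 kb. Midpoint classification trades sensitivity for a unique label
  per region, which the fraction summaries require.

## Known limitations

* The per-CpG test is not DSS: no smoothing, no dispersion shrinkage; its
  power at very low coverage (n ≤ 5) is limited and such sites are
  excluded by the default filter anyway.
* Region p-values (Stouffer) ignore correlation between neighbouring CpGs
  and are used only for ranking, not inference.
* The clock engine consumes externally supplied weight tables; no published
  panel ships with the package.
* The 2×2 decoupling analysis uses marginal Welch tests on a balanced
  design rather than a full two-way model; with unbalanced designs fit the
  factors jointly elsewhere.
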