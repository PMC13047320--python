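# Methods

## Count model and differential expression

Counts are modelled as negative binomial with Var(Y) = μ + αμ², log link
and per-sample offsets log(s_j), where size factors s_j come from the
median-of-ratios estimator (geometric means over genes positive in every
sample; a `poscounts` variant serves sparse matrices). Coefficients are
fitted per gene by IRLS on the natural-log scale (convergence when
max|Δβ| < 1e-8 or 100 iterations; genes that fail to converge are refit
with a ridge term λ = 1e-6 and flagged). The covariance is the inverse
Fisher information at the optimum; the contrast coefficient is tested
with a two-sided Wald statistic against the standard normal. All-zero
genes are flagged degenerate and assigned p = 1. Reported fold changes
are converted to log2 (factor 1/ln 2) only at the reporting boundary.

### Dispersion

Gene-wise dispersion maximizes the Cox–Reid adjusted profile likelihood
— the NB log-likelihood at the current fitted means minus
½·log det(X′WX) — evaluated on a 41-point log-spaced grid over
[1e-8, 10] with one parabolic refinement step in log α, alternating with
a GLM refit (two rounds). The CR adjustment matters: at n = 6 the
unadjusted ML estimate is biased low enough to visibly inflate Wald
statistics.

By default the gene-wise estimates are then moderated: a mean-based
running-average trend in log baseMean order centers a log-normal prior
(a mean, not a median, because the gene-wise estimator is right-skewed;
ceiling-clipped estimates are excluded from the trend), and the prior
variance is chosen by maximum marginal likelihood — the CR likelihood is
integrated against LogNormal(trend, v) on the grid and v maximized over
25 candidates in [1e-3, 4]. This adapts the shrinkage strength to the
data: when the cross-gene spread of gene-wise estimates is pure sampling
noise the prior collapses and estimates go to the trend; when
dispersions genuinely vary the prior widens to match. Estimates more
than two prior SDs above the trend keep their gene-wise value
(dispersion outliers). We made moderation the default after measuring
its effect at the study design (3 vs 3, 2000 genes): without it the
Wald type-I error at nominal 0.05 is ≈ 0.11, with oracle dispersions
≈ 0.044, and with MML-moderated estimates ≈ 0.04–0.07 — the inflation
is entirely dispersion-estimation noise, so unmoderated gene-wise
estimation is simply the wrong default at this sample size.
`moderate=False` restores raw gene-wise estimation.

### log2FC shrinkage

The reported log2FC is the posterior mode under a zero-centered Cauchy
prior with a normal approximation to the likelihood (the apeglm-class
estimator). The mode is found by golden-section search on the interval
between 0 and the raw estimate (the posterior is monotone outside it),
and the reported SE is the posterior curvature at the mode. The prior
scale adapts to the cross-gene distribution by moment matching:
s² = max(mean(β̂²) − mean(se²), 0.05²) on the natural-log scale —
excess observed variance beyond sampling variance is attributed to real
effects. Shrinkage is applied only to the contrast coefficient, never
the intercept; it cannot flip a sign. No independent filtering and no
outlier-count replacement are performed anywhere; replicate
heterogeneity is handled by the within-group filter instead.

### Multiple testing

Benjamini–Hochberg step-up with cumulative-minimum enforcement, capped
at 1, input order preserved, NaN entries excluded from m and propagated.
Hand-written (≈15 lines) because the NA contract differs from
`statsmodels.multipletests`, which nevertheless serves as a test oracle.

## QC cascade

Stages run in fixed order with disjoint attribution: biotype exclusion
(default set: pseudogene classes, TEC, artifact, spike-ins) →
per-cell-type minimum count (every sample ≥ 10; the boundary count 10 is
kept) → within-group filter. The within-group filter contrasts each
sample against the remaining samples of its (cell type × treatment)
group with the same NB engine; a gene is excluded for the cell type if
any comparison gives BH p < 0.05 and |shrunk log2FC| > 0.585. With three
replicates this is a 1-vs-2 contrast, so per-gene dispersion is not
estimable there; a single shared dispersion per cell type (median of
gene-wise CR estimates from the full factorial design) is used, which
keeps the test well-defined and stable. The one-vs-rest contrasts are
refit independently of the main analysis; this is a configurable choice,
not an inherited state.

## Synergy

The interaction design has rows control = (1,0,0,0), CGA = (1,1,0,0),
Tau = (1,0,1,0), CGA+Tau = (1,1,1,1) and requires all four conditions.
Because the design is saturated over the four groups, the per-group
score equations decouple, and with a shared dispersion vector the
jointly fitted interaction coefficient equals the difference of the
separately fitted contrast coefficients exactly (verified to ~1e-14);
with per-contrast dispersion estimation the identity holds only
approximately, which is why the pipeline exposes shared-dispersion
plumbing for exact-identity analyses. The synergy magnitude criterion
uses shrunk log2FCs while the p-value comes from the unshrunk Wald test.
Direction handling: the printed one-sided excess criterion is
sign-asymmetric, so by default the mirrored inequality is applied for
concordant negative effects (`literal` mode applies the '>' as printed).
Interaction tests at 3 replicates/arm are under-powered (≈22% at
interaction log2FC 0.5, ≈60% at 1.0; see
`analysis/04_synergy_power.py`), motivating the two-tier
potential/significant classification with the relaxed BH 0.1 threshold
for the significant tier.

## Enrichment, prioritization, TWAS

ORA uses the exact upper hypergeometric tail (scipy's survival function;
tested against full combinatorial enumeration), one-sided, sets
intersected with the universe first, BH within each source collection.
The universe defaults to the protein-coding genes surviving QC (union
over cell types); this is configurable, since reference tools differ in
their universe conventions. FDR-style BH is used rather than the
stricter g:SCS correction of the g:Profiler family — a documented
divergence.

Aging evidence is a four-way OR; adding a resource can only add flags
(monotonicity is property-tested). GWAS proximity anchors distance to
the gene span (0 inside the span, else distance to the nearer boundary;
strand ignored; a TSS anchor mode exists), with an inclusive ≤ 500 kb
window and strict p < 5e-8 significance; ties on distance break by
smaller p. Regulon edges require grade A confidence by default and both
endpoints in the supplied gene set; the per-TF sign-concordance summary
is a labelled reporting heuristic only, as the input table carries no
mode-of-regulation sign.

TWAS computes Z = w′z/√(w′Σw), skipping genes whose quadratic form is
≤ 1e-12; LD matrices failing positive semi-definiteness during
generation are regularized by +1e-6 on the diagonal and logged. BH runs
within each (tissue, trait) group over exactly the genes tested there.
The dual reliability criterion ("both Z > 3") is read as signed by
default; because effect signs depend on arbitrary allele coding an
`abs` mode (|Z| > 3 for both, concordant signs) is provided.

## Synthetic-data generator

The generator inverts the fitted model: counts ~ NB(s_j · μ0 ·
2^(bC·C + bT·T + bCT·C·T), α) with gene-wise α. Defaults emulate the
reference design at desk scale — 2000 genes, 3 cell types × 4 arms × 3
replicates, 10% DE genes with |log2FC| ~ N(1.5, 0.3²), taurine effects
0.4× the CGA effect in the same direction (mirroring the observed
directional concordance with weaker single-compound responses), 30% of
DE genes with an interaction term of magnitude 1, dispersions
LogNormal(log 0.05, 0.5²) and baselines LogNormal(log 250, 1) as typical
for bulk RNA-seq, size factors LogNormal(0, 0.1²) to exercise
normalization. Effects are planted identically in all cell types (a
simplification; the real system is strongly cell-type-specific).
ModZ signatures give concordant genes |ModZ| above a floor (default 2.5)
with the sign of the true effect at every dose, others N(0,1). GWAS
loci are planted within 500 kb of flagged genes at p < 5e-8; gene
spacing (2.5 Mb) guarantees windows never overlap neighbours, and eQTL
variants are placed inside the ±1 Mb cis window but beyond the 500 kb
proximity window so they cannot create spurious proximity evidence. For
a chosen gene–trait Z*, the GWAS z-vector is solved as z = c·Σw with
c = Z*/√(w′Σw), making the TWAS recovery exact by construction; planted
per-variant eQTL z-scores are proportional to the GWAS z so the
reliability verdict is a deterministic function of the construction.
Every generator takes a mandatory seed; identical seeds give bitwise
identical outputs.

What passing on synthetic data does **not** show: the generator has no
mean–dispersion trend misfit, no batch effects, no library-composition
bias beyond scalar size factors, no correlated genes, and LD comes from
a stylized AR(1) correlation — so calibration results transfer to real
data only to the extent those features are benign.

## Problem sizes and numerics

The shipped tests and drivers use 200–2000 genes per simulation and
500-gene/500-model null studies; these sizes give stable Monte-Carlo
estimates of the calibration quantities (binomial SE on a type-I rate at
2000 genes ≈ 0.005) while a full run of the suite stays under a minute.
Degenerate inputs: all-zero genes get p = 1 and zero coefficients;
dispersion estimates are clipped to [1e-8, 10] with ceiling flags;
η is clipped to ±30 inside IRLS; percentage reporting rounds half to
even at one decimal and always carries the raw ratio alongside, since
printed one-decimal percentages are ambiguous between rounding and
truncation.

## Known limitations

The engine targets the DESeq2-class methodology but is not a numerical
clone (no Cook's-distance handling, parametric-free trend, MML prior
width); the within-group filter's shared-dispersion choice trades
per-gene fidelity for stability at n = 3; ORA ignores gene length and
expression-level bias; TWAS assumes perfectly harmonized alleles
upstream; the CLI's stage commands re-run upstream stages in memory
rather than reloading previous outputs.
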