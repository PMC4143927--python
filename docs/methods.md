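# Methods

This note records the statistical models pqtlkit implements, the
conventions chosen where several were defensible, and what the synthetic
cohort does and does not emulate.

## PEA normalization and detection limits

A PEA plate has 96 wells: 92 samples, one negative control and three
positive controls, and every well carries internal controls (two
incubation, one extension, one detection). Normalization is

    dCq(sample, assay) = Cq(assay) − Cq(extension control of the same well)
    ddCq = correction(assay) − dCq

with the per-assay correction constant (log2 units) supplied by the assay
manufacturer to land ddCq on a positive log2 scale. ddCq is used as-is
downstream — it already lives on a log scale; "linearized" abundance is
2^ddCq. Both formulas are config-overridable conventions in the sense that
vendors document slightly different variants; the round-trip identity with
the plate renderer pins the implemented one.

The limit of detection per assay is mean + 3·SD of the negative-control
ddCq across plates (SD term zero for a single plate; the 3·SD multiplier
is the vendor convention and is a parameter). Cells with ddCq ≤ LOD are
masked, boundary inclusive. Sample QC removes samples whose any internal
control is a robust outlier within its plate (|x − median| >
3·1.4826·MAD; the exact rule is unspecified upstream, so a parameter-light
robust rule was chosen) or with >75% (strict) masked cells; protein QC then
requires ≥200 detected observations. QC is idempotent.

## Covariate models

Each protein's ddCq values are fitted by OLS on all covariates
simultaneously, complete cases only (so n varies per protein with its
censoring). Variance attribution uses sequential (type-I) sums of squares
in the covariate-table column order; this is order-dependent by
construction, so the order is fixed, recorded in the output, and the
orthogonal-design invariance is tested. Aliased or constant terms are
dropped with a warning (incremental QR with a relative tolerance of 1e-8).
Categorical covariates (e.g. ABO group) expand to indicators with
alphabetically first level as reference. Significance per covariate is the
sequential F test against 0.05/m (m = number of covariates).

Adjusted traits are the residuals from the significant-covariate model
mapped through average ranks to Φ⁻¹((rank − 0.5)/n); the result is
invariant to monotone transforms of the input and has mean 0, variance ≈ 1.
Pairwise biomarker correlations are Spearman's rho on pairwise-complete
adjusted values.

## Kinship, Hardy–Weinberg and the polygenic model

Genotype QC: marker call rate ≥ 0.95, individual call rate ≥ 0.98
(inclusive at the boundary), exact Hardy–Weinberg test at a Bonferroni
cutoff of 0.05 over tested markers (hard calls only; dosage-only data skip
HWE with a note), and a minor-allele count of at least one chromosome. The
HWE test is the exact conditional test — the flavour is not dictated by the
QC thresholds themselves — and is verified against full rational-arithmetic
enumeration.

The relationship matrix is the allele-frequency-standardized GRM with
E[K_ij] = 2·kinship (diagonal 1 for non-inbred individuals). Sample
frequencies use complete cases per marker; missing dosages contribute zero
after centering. The absolute scale of K is internal: the polygenic fit
divides K by its mean diagonal, making ĥ² invariant to rescaling K while
σ̂²_g rescales inversely.

The polygenic model `y ~ N(Xβ, σ²(h²K + (1−h²)I))` is fitted by maximum
likelihood (REML available behind a flag): one eigendecomposition of K
(eigenvalues floored at 1e-8), then the profiled likelihood over h² is
maximized on a 41-point grid refined by bounded Brent (xatol 1e-9), keeping
the better of the refined point and the grid optimum — with near-singular K
the likelihood can genuinely peak at the h² boundary, and boundary fits are
returned flagged. A likelihood flat in h² (e.g. K = I) collapses to OLS
with h² = 0. The h² = 0 test refers 2·(ℓ̂ − ℓ₀) to the boundary mixture
½χ²₀ + ½χ²₁, giving p = 0.5 exactly at the boundary and nominal type-I
error under the null (verified by simulation).

## Score test (mmscore) and effect summaries

Variance components are estimated once per trait and held fixed in the
scan. For marker dosage g, the statistic uses gc — g projected onto the
orthogonal complement of the fixed-effect design under the Ω̂⁻¹ inner
product (for an intercept-only design this is centering by the
Ω̂⁻¹-weighted mean):

    β̂ = (gcᵀ Ω̂⁻¹ y*) / (gcᵀ Ω̂⁻¹ gc),  se = (gcᵀ Ω̂⁻¹ gc)^(−1/2),
    χ² = (β̂/se)²

This projection convention makes the statistic algebraically identical to
a GLS Wald refit of the marker at fixed Ω̂, which the tests assert to
relative 1e-6; plain arithmetic-mean centering differs at order 1/n.
Markers with minor-allele count < 3 on the fit sample are skipped.

The per-marker effect summary is variance explained = χ²/N on the adjusted
trait scale; on the raw ddCq scale it is the single-marker regression R².
Under strong relatedness χ²/N is mildly shrunk relative to the generative
fraction (the Ω̂⁻¹ metric down-weights family-shared dosage variation, and
the polygenic fit absorbs part of a cis effect into σ̂²_g); the same
mechanism produces per-trait genomic-control λ slightly below 1 for traits
with large planted effects, while null scans are calibrated (λ within
[0.95, 1.05] at 20,000 markers). A noisy GRM (too few markers) attenuates
ĥ² and inflates this shrinkage — kinship should come from a dense marker
set, not from the scan panel.

The phased design: discovery scan at 0.05/m; replication restricted to
discovery hits at 0.05/(number of discovery hits); combined scan on the
pooled sample (variance components refit on the pool — whether to pool or
reuse cohort fits was an open choice; pooling was adopted) at the
discovery threshold. λ = median(χ²)/0.4549 is reported per genome-wide
scan, and suppressed for replication scans covering only a handful of
markers, where a median over hits estimates nothing. Conditional analysis
refits the polygenic model with the top marker's dosage as a fixed effect
and re-scans the hit chromosome(s) at 5×10⁻⁸.

## ABO typing

The four tag SNPs map to haplotypes by signature: A1 = no tags,
A2 = rs8176704, B = rs8176746, O01 = rs505922, O02 = rs505922 + rs574347.
This table is package data (the published source for the tagging scheme
does not print it; orientations are a stated convention, editable without
code changes). Every complete genotype consistent with the table resolves
to exactly one unordered haplotype pair; missing or inconsistent genotypes
yield "unassigned", so the assignment rate is driven by genotype
completeness. A and B are codominant over O.

## Personalized cutoffs

A reference profile fits a normal distribution (mean, SD on ddCq) within
each stratum of a stratifier (top-SNP genotype, age tertile, sex,
medication use, ABO group) and reports the central 95% interval
(mean ± 1.96·SD) and normal-fit IQR (±0.6745·SD). Strata under 10
individuals are suppressed. The 95% central mass is a package convention —
no numeric cutoff percentile is canonical — and is a labelled parameter.
Age tertiles are the default continuous-covariate binning. Between-stratum
ratios are linearized as 100·2^(Δmean)%.

## Synthetic cohort: what it emulates, and what not

The generator produces a two-cohort family sample (default 130 nuclear
families of 6 plus 120 singletons, 2:1 discovery:replication split by
family, emulating recruitment by village), gene-dropped genotypes (founder
Bernoulli draws at uniform 0.05–0.5 frequencies, Mendelian transmission
with free recombination — chosen over an MVN approximation so Mendelian
and kinship properties are exactly testable), covariates with realistic
collinearity (age uniform 15–90; medication indicators with prevalence
0.2–5.4% rising with age through a logistic link), and traits
y = baseline + Xβ + gβ_snp + batch + u + e with u ~ MVN(0, σ²_g·K_pedigree).
Default trait models span h² 0.2–0.78, cis effects up to 27% of variance,
an age effect up to 27%, a rare-medication effect, cohort batch shifts,
and below-LOD censoring on two proteins — the magnitudes the analysis is
designed to detect. Censoring is realized at plate rendering by placing
the negative control at the target ddCq quantile, so the LOD mask censors
approximately that fraction; censored truth is point-mass missing (no
distributional model below the LOD is assumed).

Not emulated: linkage disequilibrium beyond family co-transmission,
X-chromosome dosage, imputation uncertainty (all dosages are hard calls),
assay drift between plates, and storage-time degradation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to LD structure or to imputed-dosage noise.

## Problem sizes and numerics

Default verification sizes, chosen to make the statistical checks
well-powered at interactive runtimes: heritability recovery at n = 900
with 25 replicates per h² level; null-scan calibration at 20,000 markers
on 450 related individuals; LRT null calibration over 500 replicates at
n = 300; oracle equivalences at n = 60; exhaustive HWE enumeration to
total 50 plus 200–300 randomized tables to total 200. All generators take
explicit seeds; identical seeds give byte-identical pipeline artifacts
(floats serialized at %.10g, manifests contain no wall-clock state).

## Known limitations

- Sequential variance attribution is order-dependent off-orthogonality;
  the recorded column order is part of the result.
- ML (not REML) variance components are biased low in small samples and
  can hit the h² boundary; boundary fits are flagged rather than hidden.
- χ²/N as an effect summary inherits the relatedness shrinkage described
  above; comparisons across cohorts with different family structure should
  use the raw-scale R² alongside it.
- The ABO tag-table orientations follow the published tagging scheme but
  cannot be re-verified from summary text alone; they are data, not code.
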