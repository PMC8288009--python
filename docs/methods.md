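# Methods

`introshell` implements a depth-structured analysis of *Mytilus trossulus*
(MT) introgression in a rope-cultivated blue-mussel stock and of its shell
phenotype consequences. This note records the models, the defaults, the
numerical choices, and what the synthetic data do and do not emulate.

## Introgression statistics

Individuals are genotyped at a panel of biallelic MT-diagnostic SNPs, each
scored as the within-genotype frequency of the diagnostic allele
(0, 0.5, 1, or missing). Over the M non-missing retained loci of an
individual, with nXY loci heterozygous and nXX homozygous for the
diagnostic allele:

    H_O   = nXY / M                    observed heterozygosity
    HI    = (nXY + nXX) / M            hybrid index
    MT_AF = (nXY + 2 nXX) / (2M)       MT allele frequency

so that MT_AF = HI − H_O/2 identically; this identity is asserted in tests
and holds for depth means as well. M counts only non-missing retained
loci, making the statistics robust to per-individual missingness (the
denominator varies across individuals).

MT_AF bins follow the field convention of none / <10% / 10–50% / 50–75% /
>75%. Bin edges are half-open — (0, 0.10), [0.10, 0.50), [0.50, 0.75),
[0.75, 1] — chosen for determinism; note that an exact F1 (MT_AF = 0.5 on a
strict panel) therefore lands in the 50–75% bin. A profile is "F1-like"
when MT_AF ∈ [0.35, 0.5] and at least 80% of its MT-positive loci are
heterozygous, operationalising the qualitative description of
first-generation hybrids as predominantly heterozygous at intermediate
ancestry.

**QC.** Loci are removed first (assay flags: poor clustering, false calls,
ambiguous genotypes; or missing fraction > 0.2), then individuals
(QC flags, or missing fraction over the *retained* panel > 0.2).
Locus-before-individual ordering is a design choice — the alternative
ordering changes which individuals' missing fractions cross the threshold —
and makes the filter idempotent. Ambiguous-genotype loci are an input flag,
not inferred: detecting the shared-nucleotide pattern requires the raw
fluorescence data, which are out of scope.

**Me15/16.** The single nuclear marker produces species-specific fragment
sizes (ME 180 bp, MT 168 bp, MG 126 bp): one fragment → pure species, two →
putative hybrid, zero or three → undetermined (excluded from denominators,
logged rather than raised). Species allele frequencies count two copies per
pure individual and one per hybrid carrying the species.

**MAF detection floor.** `maf_detection_limit(n)` = 1/n, the frequency at
which one allele copy is expected among n sequenced chromosomes of the
discovery sample — 72 ME/MG chromosomes give ≈1.4%, 8 MT chromosomes give
12.5%. Alleles classified as diagnostic may leak below these floors, which
is the rationale for the leaky loci in the generator.

## Depth models

MT-allele presence/absence per individual is modelled with a grouped
binomial logistic regression on depth in metres as a continuous covariate;
the exponentiated slope is the multiplicative change in odds per metre.
Confidence intervals are Wald (symmetric on the log-odds scale) throughout;
profile intervals differ negligibly at these sample sizes (checked against
R's `confint.glm`). Complete separation is raised as an error, never
returned silently.

The quasibinomial variant keeps the same mean model and scales standard
errors by √ɸ, where ɸ is the grouped-binomial Pearson statistic
Σ nᵢ(pᵢ−μᵢ)²/(μᵢ(1−μᵢ)) over (groups − 2) degrees of freedom. ɸ is
computed explicitly from group sizes (validated against R's
`glm(..., family = quasibinomial)`), because the dispersion of proportions
without their binomial denominators is not the quantity of interest.

Class-by-depth contingency tables use Fisher's exact test: exact
hypergeometric for 2×2, and a fixed-margin Monte-Carlo estimate of the
exact p for larger tables (default 100,000 sampled tables, seeded;
reported with its Monte-Carlo SE). Network enumeration was not needed at
these table sizes.

## Shell strength

Puncture force (kg) is normalised by shell length: strength = force/(SL in
cm), units kg cm⁻¹ SL. Candidate linear models of normalised strength
(MT_AF only, depth only, additive, interaction) are compared by Gaussian
AIC with the residual variance counted as a parameter (k = mean parameters
+ 1); since every candidate is fitted to the same n, this offset does not
affect ranking, which is invariant to affine rescaling of predictors.
Model selection by AIC retains the additive model at the theoretical rate
(≈84% under a true additive model — the interaction term wins whenever its
likelihood-ratio improvement exceeds the 2-unit penalty, P(χ²₁>2) ≈ 0.157).
Residual diagnostics (Shapiro/D'Agostino normality, Breusch–Pagan) are
attached to every fit. A collinearity screen (pairwise |r| with a 0.8
default threshold, plus PCA variance shares of the standardised predictors)
precedes multivariable fits; shell length, height and the wet weights are
strongly allometrically linked and the screen recommends dropping the
redundant weights.

The practical weak-shell rule flags strength < 2 kg cm⁻¹ SL **and**
SL:SH > 2, both strictly — boundary cases are excluded, so the rule is
conservative.

## Outline morphometrics

Valve outlines are closed (x, y) polylines, pixel-centre based, y-axis up,
counterclockwise, with implicit closure. Binary masks are traced with
Moore-neighbour boundary following (8-connected, Jacob's stopping
criterion); interior holes are ignored, and zero or multiple foreground
components are errors. Outlines are resampled to 300 uniform arc-length
points (comfortably above the Nyquist needs of ≤32 harmonics), centred on
the centroid and forced counterclockwise.

Elliptic Fourier coefficients follow the Kuhl–Giardina chain integrals,
treating the resampled vertices as uniformly spaced in the curve parameter
(the default; exact for preprocessed outlines, and it makes an exact
ellipse representable by harmonic 1 alone with relative residual power
below 1e-10). Classical chain-length parametrisation is available via
`spacing="arc"`.

Normalisation standardises the first harmonic: the starting point is
rotated onto the first-harmonic semi-major axis, the outline is rotated so
that axis lies along +x, and all coefficients are divided by the semi-major
length, leaving a1 = 1, b1 = c1 = 0. The residual half-turn ambiguity
(which flips the signs of even harmonics only) is resolved by requiring the
first non-negligible even-harmonic coefficient to be positive — a
deterministic convention recorded here because alternative conventions
change coefficient signs, not shapes. Normalised coefficients of rotated,
scaled and start-shifted copies agree to better than 1e-6 (in practice,
machine precision).

Harmonic truncation uses cumulative power shares, power_n =
(aₙ²+bₙ²+cₙ²+dₙ²)/2, choosing the smallest count exceeding the threshold
(default 0.95). The PCA of the coefficient matrix is centred and unscaled;
the entries fixed by the normalisation convention (a1, b1, c1) carry no
information and are dropped, so the shape variables are d1 plus harmonics
2..N. Which harmonic-1 components enter the PCA is convention-dependent
across outline-analysis software; this package keeps d1 (the free
semi-minor component) and documents the choice in output metadata.

MANOVA uses Wilks' Λ = det(E)/det(E+H) from error and hypothesis SSCP
matrices of a multivariate linear model, with Rao's F approximation; the
grouping may be a factor or a continuous covariate (`kind=` forces the
treatment). The implementation is validated against statsmodels' MANOVA
and, in the 2-group/1-response case, against one-way ANOVA exactly.
Pairwise MANOVAs are reported with raw p-values (an optional Bonferroni
column is available).

## Synthetic cohorts

The generator reproduces the statistical structure the analyses assume, at
study scale, with known ground truth.

**Genotypes.** Each individual draws two alleles per locus from the gamete
pools of its two parents: pure classes from one species' allele
frequencies, F1 hybrids one from each species, and first backcrosses one F1
gamete (a fair coin between the grandparental pools at every locus) and one
pure gamete. Later backcross generations are out of scope — the observed
patterns distinguish only predominantly homozygous versus predominantly
heterozygous profiles. On strictly diagnostic loci this law forces exact
patterns: pure MT all-homozygous (MT_AF = 1), F1 ME×MT all-heterozygous
(MT_AF = 0.5, H_O = 1), pure ME/MG all-zero.

**Default study-scale design** (435 individuals; per-depth n = 116, 118,
118, 83 at 1/3/5/7 m): the panel is 33 loci of which 5 leak at 0.014 — the
1.4% detection floor — in ME and MG; per-depth mixtures place pure MT at
(3, 2, 1, 0) individuals, MT backcrosses at (2, 1, 2, 0), ME×MT F1s at
(2, 4, 1, 1), ME×MG hybrids at (11, 21, 18, 13), the rest pure ME. The
within-depth mixture is a modeling choice (no published within-depth MT_AF
variance exists beyond the bin counts); with it, leakage alone produces
≈55 single-allele low-MT_AF individuals (expected: 409 non-MT individuals
× (1 − 0.986¹⁰) ≈ 53), the MT-positive fraction declines with depth, and
the per-metre odds factor fitted on simulated cohorts lands near 0.95.

**Shell traits.** Normalised strength = 2.03 + 0.135·(depth−1) −
1.37·MT_AF + N(0, 0.65) kg cm⁻¹ SL — a non-introgressed 1 m mussel sits at
2.03, strength rises 0.135 per metre and falls 1.37 per unit MT ancestry;
noise is Gaussian on the normalised scale (the strength model is linear on
that scale; simplest compatible noise). Raw force is back-computed as
strength × SL(cm), so re-normalising recovers the model exactly. Shell
length is N(55, 6) mm (typical harvest size); elongation SL:SH = 1.95 +
0.40·MT_AF − 0.02·(depth−1) + N(0, 0.08), placing heavily introgressed
shells above the SL:SH = 2 rule line and giving the weak-shell rule a
sensitivity near 0.92 on the high-introgression group under these
defaults. Wet weights are allometric in SL with lognormal scatter and
exist to give the collinearity screen realistic structure.

**Outlines.** A fixed mussel-like polar template (egg-shaped, drawn-out
posterior, flattened ventral line) is scaled anisotropically so its
bounding-box length:height equals the requested elongation exactly at zero
noise, then perturbed with smoothed radial Gaussian noise of relative
amplitude `noise_sd`. This couples the morphometric pipeline to the same
SL:SH signal as the strength analyses.

**Salinity.** Per-depth i.i.d. Gaussian series (clipped at 0) with
configurable means and variances; the default loch is fresher and more
variable near the surface. Seasonal autocorrelation is not modelled — the
analyses consume only per-depth means and variances.

**Seeding.** One global integer seed is split into per-operation streams
(seed + operation label → `numpy` `SeedSequence`), so stages can be rerun
independently and identical configurations are bit-identical.

## What passing tests do and do not show

The synthetic cohorts have exactly Mendelian genotype laws, exactly linear
phenotype models with Gaussian noise, and outlines generated from the same
template family the morphometrics then analyses. Passing tests therefore
demonstrate correctness of the statistics and transforms, and internal
consistency of the pipeline — not robustness to genotyping artefacts
beyond the modelled flags, non-Gaussian phenotype noise, later-generation
backcrosses, photographic segmentation error, or real biological shape
variation beyond elongation. Real-data quantities that depend on such
structure (PC variance percentages, Wilks' Λ magnitudes, the ~10%/metre
hybrid-proportion decline from an ambiguous weighted-proportions model) are
treated as regime references, not targets.

## Problem sizes

Default runs use the study-scale cohort (435 individuals, 33 loci, 300
outline points, 16 harmonics). Monte-Carlo Fisher tests default to 100,000
tables (20,000 in the analysis drivers); the strength-model recovery study
uses 200 replicates of 430 individuals; the weak-shell sensitivity check
scales the cohort ×50 so the estimate's binomial noise is small relative
to the 0.9 bound.
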