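# Methods

This note records the modeling choices behind `soynam`: what is simulated
and why, how each estimator is defined, where the design was genuinely
open, and what the desk-scale checks do and do not demonstrate.

## Population and genome simulation

**Mating design.** One fully homozygous common (hub) parent is crossed to
each of 40 homozygous founders (17 EL / 15 BX / 8 PI by default). Each
mating is advanced by single-seed descent in its textbook idealization:
one random F2 individual per prospective line, selfed forward with a
single offspring per generation, the final generation (F5 by default)
taken as the line. Residual heterozygosity therefore decays as
(1/2)^(g−1) per locus for an F_g line — 1/16 at F5 — and the test suite
checks this decay directly.

**Meiosis.** Crossovers follow the Haldane map function,
r = (1 − e^(−2d/100))/2 for d in cM, with no interference: recombination
events between adjacent markers are independent Bernoulli draws, i.e. a
Markov chain along the chromosome. Haldane was chosen because it is the
standard no-interference model and has a closed form the simulated gamete
frequencies can be tested against. Parental origin (hub / founder /
heterozygous) is tracked per marker through every meiosis; allele doses
follow by composing origin with the founder's haplotype.

**Genotype coding.** The hub parent carries the reference allele at every
marker; genotypes are doses of the non-hub allele in {0, 1, 2}, −1 for
missing. A founder's haplotype is a Bernoulli(f) draw per marker. The
pipeline default is f = 0.75 because genotyping-chip markers for a NAM
panel are ascertained to segregate in most families, which concentrates
the non-hub allele among founders; experiments that do not model
ascertainment use f = 0.5.

**Trait architecture.** Effects are *homozygous-line substitution
effects*: a line fixed for founder f's allele at QTL q shifts by the
(f, q) table entry relative to a line fixed for the hub allele, so the
genotypic value is Σ_q effect × dose/2 plus a polygenic deviate. The
hub parent's effect is identically zero by construction. Per-founder
effects are drawn from group-specific normals (EL/BX/PI means and SDs),
which is what lets group-level contrasts — elite positive, exotic
negative — re-emerge from the scan. The polygenic term is iid normal by
default; a "genomic" option draws from N(0, σ²K) instead. Note that on a
sparse simulated marker set an N(0, σ²K) draw is itself a sum of marker
effects (it lies in the span of the dose matrix), so marker-free null
experiments must use iid or family-level backgrounds, not the genomic
option.

**Trial design.** Each family's RILs are split into sets of 35 (padded
with checks when a family does not divide evenly, mirroring the practice
of planting a check in an empty plot), augmented with the two family
parents and three checks to 40 entries. A *block* is one set grown in one
environment. Environment coverage can be complete ("all") or a
per-environment count of randomly chosen sets, reproducing unbalanced
multi-site capacity. Planting dates are drawn per environment over a
configurable window (default four weeks) and enter phenotypes through a
per-trait slope; the covariate is centered at the realized mean date,
since no particular centering is canonical. Plot values add independent
normal environment, block and residual effects; checks carry fixed true
values; lodging is clipped to its 1–5 scale; plots go missing completely
at random at a configurable rate.

## Marker preparation

Per-family minor allele frequency is computed on allele counts excluding
missing genotypes. A marker is *monomorphic* at MAF = 0, *distorted*
strictly below the 10% threshold (MAF exactly 0.10 is retained — the rule
is "less than"), and a marker failing in any single family is eliminated
genome-wide; per-family keep-lists are also reported, and a family with no
genotyped lines at a marker is reported distinctly rather than classified.
Filtering is idempotent.

RIL quality control flags lines identical to either parent at every
non-missing marker (likely seed-parent selfs) and lines carrying an allele
absent from both parents (pedigree errors), with the non-parental flag
taking precedence; a family in which a majority of lines carry
non-parental alleles is listed for removal. The 50% family cutoff is a
generalization — the motivating case is a family whose founder was
evidently not the intended line — and is a parameter. On small simulated
genomes (one or two chromosomes) a few percent of clean RILs genuinely fix
one parent's genome end to end and are correctly flagged as identical;
with realistic 20-chromosome genomes this essentially never happens.

Genetic positions for physically placed markers come from linear
interpolation in an ordered (bp, cM) frame; queries beyond the terminal
frame points clamp to the terminal cM values, avoiding negative
extrapolated positions. Dense founder-only markers are projected onto RILs
through the flanking framework markers' origin calls: concordant
homozygous flanks inherit that parent's dense genotype; recombinant,
heterozygous or missing flanks project as missing; intervals are closed
with the left flank winning exact bp ties; markers outside the framework
use the nearest terminal call. The projection can never emit an allele
absent from the two family parents. Its accuracy on simulated truth
(≥95% in the test scenario, ~5 cM framework spacing) depends on framework
density — double crossovers inside an interval are the error mode — and
is measured, not assumed.

## Two-stage BLUP

Both stages are single-grouped-random-intercept REML fits through
statsmodels `MixedLM` (the Python analog of lme4's `lmer`), with variance
components clamped at the zero boundary. Stage 1 uses check plots only:
fixed intercept, centered planting date (dropped automatically when all
dates coincide), fixed check effects (treatment coding), random block.
Blocks with no check data are fully shrunk to zero. Stage 2 uses non-check
entries with the stage-1 shrunken block value and planting date as fixed
covariates, *each with an estimated slope* — the block value is treated as
a covariate rather than a fixed offset, the literal reading of the
two-covariate parameterization. Entries with a single plot are retained
and strongly shrunk; entries with no data are absent, not zero-filled.

On balanced toy designs both models must agree with the closed-form
shrinkage formula û_j = (σ̂²/(σ̂² + σ̂²_res/n_j)) × (group mean − grand
mean) to 1e−6, which the test suite enforces; this is an exact algebraic
property of the BLUP given the fitted components, so it validates the
solver rather than the data.

**Heritability.** Entry-mean basis: H = σ²_g / (σ²_g + σ²_res/ē), ē the
harmonic mean of per-entry environment counts. Family-mean basis:
H = σ²_among / (σ²_among + σ²_within/n̄ + σ²_res/(n̄ē)) with n̄ the harmonic
mean family size; the basis was specified but not the formula, so this
standard decomposition is the package's choice. Confidence intervals are
F-quantile (Knapp-type) bounds built from F = 1/(1 − H) with df₁ =
entries − 1 and df₂ = Σeᵢ − entries; simulation shows ≈95% coverage at
the study's H range (checked at H ∈ {0.82, 0.93} over 100 replicates).
The among-family proportion of genotypic variance is a one-way
random-effects REML decomposition of entry BLUPs on family labels.
Genotypic correlations are product-moment correlations of entry BLUPs on
the intersection of entries — a deliberate approximation to bivariate
REML that matches the deliverable (one number per trait pair).

## Genome scan

The scan models entry genotypic values as υ = μ + Wα + φ + ε with
α ~ N(0, Iσ²_α), φ ~ N(0, Kσ²_φ), ε ~ N(0, Iσ²_ε).

* **W** has one column per family in which the marker segregates, coded as
  the line's founder-allele fraction (dose/2 relative to the hub allele)
  and centered within family. Because the lines are inbred, α_f is then
  directly the expected difference between a line fixed for family f's
  founder allele and one fixed for the hub allele — the same scale as the
  simulator's trait-architecture effects. The within-family centering is
  load-bearing: it makes Wα orthogonal to family means, so
  between-family genetic structure (which a finite-marker K absorbs only
  imperfectly) cannot masquerade as marker variance. Without it the null
  false-positive rate at desk scale is an order of magnitude too high;
  with a dense genome-wide K, as in a real analysis, the two codings
  nearly coincide. Families where the founder carries the hub allele are
  non-segregating by construction and reported as not estimable.
* **K** is a VanRaden matrix, CC′/Σ2p(1−p) on mean-imputed centered
  doses, recomputed for every tested marker with all markers within a
  5 cM window (half-width, configurable) excluded, implemented as a
  rank-update of a precomputed cross-product. A per-chromosome cache mode
  (exclude the whole chromosome) exists but is off by default; a
  fixed-background mode that pins the polygenic ratio at its no-marker
  value is available and labeled approximate.
* **Estimation** is REML, profiled over σ²_ε and the intercept: K is
  eigendecomposed once per marker and the W term handled by a q × q
  Woodbury complement, so each likelihood evaluation is O(nq + q³). The
  two log variance ratios are optimized by Nelder–Mead from the best of a
  coarse grid, with the no-marker model always a candidate, which makes
  the likelihood ratio non-negative by construction.
* **Inference.** H₀: σ²_α = 0 is tested by restricted likelihood ratio
  against the boundary mixture ½χ²₀ + ½χ²₁ — the standard asymptotic null
  for a single variance component, known to be conservative at finite
  sample sizes, which suits a screening statistic. The method label is
  written into the scan metadata. Per-family α̂ are BLUPs with
  prediction-error SDs from σ²_α I − σ²_α²W′PW.

Markers with −log10(p) ≥ 3 are significant — at ≤100 tested 5 cM regions
this bounds the per-trait experiment-wide false-positive probability at
0.1 by Bonferroni, and the null-calibration experiment measures ~0.04.
Significant markers chain into regions at a strict 5 cM gap (exactly 5 cM
stays together), peaks tie-break to the lower cM then the smaller marker
id, and region peaks chain across traits into bins by the same rule.
Allele-effect sign patterns label the estimable effects at a peak
(all-negative, all-but-k, mixed; zeros count as neither, and the
all-but-k boundary defaults to k ≤ 2, a parameter). Group summaries
average every estimable (family, marker) pair with equal weight and flag
markers whose positive alleles come only from BX/PI founders.

## Desk-scale experiment design

The reproducible studies in `soynam.experiments` run in minutes on one
core while keeping family nesting, linkage and polygenic structure:

* *Design counts*: the full 40 × 140 germplasm and 160-set layout, with a
  deliberately light marker map (the counts concern germplasm and layout).
* *Null calibration*: 200 scans of 10 families × 30 RILs on 2 × 100 cM
  chromosomes (60 markers, 40 regions), phenotype = family-level genetic
  background (variance 0.3) + iid noise (0.7). Family-level effects — not
  an N(0, K) draw — keep the null genuinely marker-free while still
  forcing the polygenic term to absorb real between-family structure.
* *Power*: a 150 kg ha⁻¹ QTL shared by all 10 families at 500 RILs,
  noise SD 150; detection requires −log10(p) ≥ 3 at or within two markers
  of the truth.
* *Effect recovery*: one family planted at +239 kg ha⁻¹ among contrasting
  family effects, 8 × 60 RILs on a 20-chromosome genome. The genome size
  matters: markers in LD with the QTL but outside the exclusion window
  then carry only ~5% of K's weight, as on a real map; on a two-chromosome
  toy genome the polygenic term visibly absorbs part of the family
  signal.
* *Heritability coverage* and *among-family recovery* simulate the
  variance structures directly (unbalanced environment counts; 40 × 140
  hierarchy). The among-family proportion from a single 40-family
  replicate has sampling SD ≈ 0.055, so recovery is reported as the mean
  over 10 replicates.

What these do **not** show: behavior under genotyping error, segregation
distortion, selection during line development, GxE interaction, spatial
field trends, or real linkage-disequilibrium ascertainment — none of
which the generator produces (the analysis models assume them away too).

## Numerical conventions and limitations

* One master seed; stage and experiment seeds are spawned via
  `numpy.random.SeedSequence`, making every output bit-reproducible.
* Variance ratios are optimized on the log scale within e^±14; boundary
  fits are reported as exact zeros. LRTs below 1e−10 give p = 1.
* Missing genotypes: mean-imputed for K only; the tested marker's missing
  entries drop that marker's fit; missing trait values drop per trait.
* The scan assumes homoskedastic BLUP inputs; it does not propagate
  stage-2 prediction-error variances (entries differ in replication, so
  weakly replicated entries are over-weighted relative to a full
  one-stage analysis).
* No epistasis, no dominance (the lines are inbred), no multi-trait mixed
  models, no resampling-based thresholds, no candidate-gene annotation.
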