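# soynam

Simulation and mixed-model analysis for soybean **nested association
mapping (NAM)** populations: a desk-scale, fully testable implementation of
the quantitative-genetic workflow used to dissect yield and agronomic
traits in a 40-family soybean NAM experiment — from germplasm and field
trial through two-stage BLUP, heritability, a family-nested random-effect
genome scan with polygenic control, and marker-trait-association (MTA)
binning.

It is written for plant quantitative geneticists and breeding-informatics
developers who want to exercise, validate or extend every stage of such an
analysis without access to the original multi-environment field data: the
`simulate` module generates populations and trials with the same
statistical structure, and every downstream stage is an ordinary library
function with a CLI on top.

## The models

**Design.** One common hub parent is mated to 40 diverse founders in three
groups (17 elite EL, 15 exotic-derived BX, 8 plant-introduction PI); each
mating yields 140 F5 recombinant inbred lines (RILs) by single-seed
descent — 5,600 lines laid out in 160 augmented 40-entry sets (35 RILs,
the two family parents, three checks) across unbalanced multi-environment
trials.

**Stage 1 — check/block model** (check plots only):

    y = Xβ + Cκ + Bπ + ε,   π ~ N(0, Iσ²_blk),  ε ~ N(0, Iσ²_res)

with planting date as fixed covariate (β), fixed check effects (κ) and
random incomplete-block effects (π), whose BLUPs are the *shrunken block
values*.

**Stage 2 — entry model** (RILs and parents):

    y = Xβ + Zυ + ε,   β = [β_pldate, β_blk],   υ ~ N(0, Iσ²_g)

where the stage-1 block value enters as a fixed covariate with its own
slope and υ̂ are the entry genotypic BLUPs. Broad-sense heritability on an
entry-mean basis uses the harmonic mean ē of the per-entry environment
counts, H = σ²_g / (σ²_g + σ²_res/ē), with F-quantile confidence bounds.

**Genome scan** (per marker):

    υ = μ + Wα + φ + ε,   α ~ N(0, Iσ²_α),  φ ~ N(0, Kσ²_φ)

W nests the marker in families (one column per family in which it
segregates, on the founder-allele-fraction scale and centered within
family), so each α_f is that family's allele-substitution effect relative
to the hub parent. K is a VanRaden genomic relationship matrix recomputed
per marker with a 5 cM *linkage window* excluded, so tightly linked markers
do not absorb the tested signal. σ²_α = 0 is tested by restricted
likelihood ratio against the boundary mixture ½χ²₀ + ½χ²₁; markers with
−log10(p) ≥ 3 are significant, regions are chained at a strict 5 cM gap,
and per-family effects are summarized by founder group.

## Worked example

The default demo configuration simulates 5 families × 40 RILs on two
100 cM chromosomes (300 markers), two traits with group-structured QTL
effects, and a three-environment augmented trial:

```python
from soynam import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=1), "demo_run")
```

or equivalently `soynam run-all --seed 1 --out demo_run`. The run writes
every stage table plus a manifest; with seed 1 the variance-component
report (`demo_run/varcomp.tsv`) reads:

```
   trait  sigma2_blk  sigma2_g  sigma2_res     H  H_ci_low  H_ci_high  harmonic_envs  prop_among_families
   yield     902.580  4912.708    2082.225 0.874     0.841      0.901          2.936                0.545
maturity      94.292 10443.252    1963.476 0.940     0.924      0.953          2.922                0.586
```

i.e. entry-mean heritabilities of 0.87 and 0.94 with their 95% intervals,
harmonic-mean environment counts near 3, and 55–59% of the genotypic
variance sitting among families. The yield scan flags one region
(`demo_run/regions.tsv`):

```
   trait chrom  span_lo_cM  span_hi_cM peak_marker  peak_cM  peak_neg_log10_p  n_markers
   yield chr01       62.42       68.46 chr01_m0094    62.42              6.68          3
```

a 3-marker MTA region peaking at 62.4 cM with −log10(p) = 6.7, and the
founder-group effect summary (`demo_run/effect_summary.tsv`) shows the
planted group structure re-emerging from the scan — elite founders
contributing positive yield-allele effects on average (+32 kg ha⁻¹ here)
and exotic PI founders strongly negative ones (−104 kg ha⁻¹), the contrast
the NAM design was built to measure.

Rerunning the same config and seed reproduces every output checksum
bit-for-bit.

## Layout

| module | role |
|---|---|
| `soynam.simulate` | maps, founder panels, SSD RILs, trait architectures, trial designs, plot phenotypes |
| `soynam.genoprep` | per-family MAF filtering, RIL QC, bp→cM interpolation, dense-marker projection |
| `soynam.blup` | two-stage BLUP, heritability, variance partition, genotypic correlations |
| `soynam.gwas` | kinship with linkage-window exclusion, family-nested scan, effect tables |
| `soynam.bins` | MTA regions, cross-trait bins, allele-pattern classes, group summaries |
| `soynam.pipeline` / `soynam.cli` | configuration, orchestration, validation, manifests |
| `soynam.experiments` | the reproducible desk-scale studies used by the tests and acceptance script |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
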