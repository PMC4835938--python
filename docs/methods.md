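# Methods

This note records the models implemented in `lethalscan`, the assumptions
behind the synthetic-data generator, the numerical choices in the REML
engine, and the known limitations of both. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. The inference problem

A recessive lethal allele segregating in a livestock population kills
homozygous conceptuses before or at birth. Live, genotyped animals therefore
contain *no* homozygotes for the causal variant or for any haplotype in
strong linkage disequilibrium with it, while carrier×carrier matings show
excess stillbirth. When the variant is a sub-megabase deletion, array and
sequencing data add orthogonal signatures: hemizygotes are mis-genotyped as
homozygous at every SNP inside the deletion (only one allele is present),
their Log₂R array intensity drops, and their read depth in the interval is
halved. The package implements each of these tests and a simulator that
generates all of the corresponding observables with known ground truth.

## 2. Gene-drop simulator (`simulate`)

**Population structure.** `n_founders` unrelated, non-inbred founders (ids
alternate male/female) are followed by `n_generations` rounds of sire-based
breeding: `n_sires_per_gen` sires are drawn from the previous generation's
live males, each mated to `progeny_per_sire` dams drawn from the previous
generation's live females, one conceptus per mating. This produces the large
paternal half-sib families typical of dairy cattle, with maternal grandsires
identifiable through the dam — the structure the mating-type analysis needs.

**Genome.** One chromosome (default 20 Mb, ~1 bovine-autosome arm's worth of
a 50k-density panel: 400 evenly spaced SNPs) with a deletion at
12.3–12.8 Mb. Meiosis follows a Haldane model: crossover count
Poisson(length × rate), positions uniform, default 1 cM/Mb. The deletion
travels with the segment containing its midpoint. Coordinates are 1-based
inclusive, matching VCF conventions.

**The tag haplotype and LD.** Founder haplotypes are drawn independently per
marker (allele frequencies U(0.08, 0.92)), i.e. there is **no background
LD**. Real populations have extensive LD; in particular, a deletion arises
once on a single founder haplotype and is therefore tagged by the rare
alleles of surrounding SNPs at r² ≈ 1 (observed tag-SNP MAFs in mapped
cattle lethals sit near the haplotype frequency itself, ~0.06). The
generator reproduces exactly this feature and only this feature: the 10 SNPs
flanking the deletion (5 per side — in-deletion SNPs cannot tag reliably
because the deletion corrupts their calls) are given rare alt alleles
(background frequency U(0.01, 0.04)), and every deletion-bearing founder
chromosome carries the all-alt string at those SNPs. Accidental matches on
intact chromosomes are broken by flipping one allele, so the tag is in
complete LD with the deletion at generation 0 and decays only by
recombination (~1 % of carrier chromosomes per meiosis across the ~1-Mb
window). Elsewhere on the chromosome LD is absent, which makes the null
stricter than reality: a flanking marker can only associate with the
phenotype by chance, never through background LD.

**Deletion assignment.** Founders receive the deletion on an exact count of
`round(2·n_founders·p)` chromosomes (drift in the realized frequency then
comes only from transmission, keeping the observed q close to the nominal p
at desk-scale population sizes). A founder drawn homozygous is thinned with
probability `penetrance` — live founders cannot be homozygous for a fully
penetrant lethal, while at penetrance 0 founders remain at Hardy–Weinberg
proportions (the neutral-haplotype control relies on this).

**Lethality and recording.** `penetrance` is the probability that a
homozygous-deletion conceptus is *recorded* as a stillbirth; it deliberately
absorbs late-gestation loss and farmer under-reporting, which are not
separable in calving records. A homozygote that escapes recording is treated
as a live animal downstream (genotyped, with missing calls inside the
deletion, doubled intensity loss, zero in-region depth). All other
conceptuses are stillborn with probability `baseline_stillbirth`
(default 0.04, a typical overall calf-loss rate). Dead calves enter the
calving table but never the genotype, intensity, or depth panels.

**Genotype calls.** Outside the deletion the call equals the true dosage; a
hemizygote is called homozygous for its single present allele at every
in-deletion marker. The per-call error model (`genotype_error`, default
0.01) flips a homozygous call to heterozygous and a heterozygous call to a
random homozygote — the dominant array error mode, and the reason a carrier
is expected homozygous at a fraction (1−e) of in-deletion loci, which is
what the 97 % carrier-calling rule tolerates. Errors are applied to the
phased haplotype pair so the container stays internally consistent; phasing
errors themselves are not modelled (inputs to the real analyses are assumed
phased upstream).

**Intensity and depth.** Log₂R ~ Normal(0, `intensity_sd`) everywhere,
shifted by `intensity_mean_carrier` (default −0.35, a typical single-copy
loss) per deleted copy at in-deletion markers. Windowed read counts are
Poisson(`mean_depth` × window length), with the in-deletion portion of a
window contributing at half rate per deleted copy.

**DRPs.** A bull's de-regressed proof is its true transmitting ability in
additive-genetic-SD units — polygenic value (founders N(0,1), offspring
mid-parent plus N(0, ½) Mendelian sampling) minus δ for carriers — plus
noise of variance (1−r²)/r², with reliabilities U(0.80, 0.995) (capped at
0.98 when converted to weights). δ is the phenotypic stillbirth shift of a
carrier sire, ½ × (mate carrier frequency 2p/(1+p)) × penetrance, divided by
σ_a = √(h²·σ_p²) with `drp_h2_proxy` = 0.04 (a typical direct stillbirth
heritability) and σ_p the Bernoulli SD of the baseline rate. At p ≈ 0.04–0.08
this puts the carrier depression at ~1 additive-genetic SD, the magnitude
reported for mapped cattle lethals.

**Defaults as study conditions.** The default scale (600 founders, two
generations of 40 × 30 half-sib families → ~2,900 live animals, ~1,100
DRP-bearing bulls) is a desk-scale rendition of a national progeny-testing
study; the deletion's causative-allele frequency defaults to 0.08 (carrier
frequency ~15 %, the high end of the 4–16 % range such lethals reach across
populations, and the level at which every evidence channel is informative at
this population size — at p = 0.043 the expected homozygote count in 2,900
animals is only ~2, so the missing-homozygote and HWP channels need the
19,000-animal panels of a full national dataset, exercised separately in the
acceptance checks' closed-form arithmetic).

**What passing tests do and do not show.** The simulator emulates Mendelian
transmission, reliability-weighted pseudo-phenotypes, the deletion's four
data signatures, and rare-allele tagging. It does not emulate background LD,
genotyping batch structure, imputation error, multi-chromosome genomes,
maternal (indirect) genetic effects, or selection. Planted-truth recovery
therefore validates the statistical machinery, not robustness to those
real-data complications — in particular, carrier-calling specificity on real
arrays (waviness, batch effects) will be worse than on simulated intensities.

## 3. Marker QC (`io_formats`)

Markers failing MAF < 0.01, Hardy–Weinberg p < 10⁻⁵ (1-df χ², no continuity
correction), or falling inside an excluded region are removed, in that
order, each marker tallied once under the first criterion it fails (so the
reported tallies are disjoint — published QC tallies are not always stated
this way, and no attempt is made to reproduce any particular study's
counts). Missing genotypes are excluded pairwise from MAF and HWP. One
subtlety found while validating at scale: in a panel of ~10⁴ animals the
SNPs tagging a recessive lethal *themselves* fail an undirected HWP filter —
through heterozygote excess, which is precisely the missing-homozygote
signal. `hwp_direction="deficit_only"` restricts the filter to the
genotyping-artifact signature (homozygote excess); the undirected filter
remains the default because it is the conventional QC.

## 4. REML engine (`mixed_models`)

Model: `y = Xβ + Σ_k Z_k u_k + e`, `u_k ~ N(0, σ_k² A_k)`,
`e ~ N(0, W⁻¹σ_e²)`. The restricted likelihood is profiled over σ_e² and
maximised over log variance ratios θ_k = log(σ_k²/σ_e²) (bounds ±25/15 in
log units, which enforces non-negativity; a ratio at the lower bound is
reported as exactly zero). Two algebraically identical evaluation routes are
chosen by cost: a dense Cholesky of the n×n marginal covariance when levels
outnumber observations (animal model, RHM), or Henderson's mixed-model
equations — Cholesky of the (p+q)×(p+q) coefficient matrix — when
observations dominate (mating model with ~10³–10⁴ records and tens of MGS
levels). One ratio is optimised by bounded Brent (xatol 10⁻¹⁰; on balanced
designs the estimates match closed-form ANOVA components to better than
10⁻⁶ relative), several by Nelder–Mead (xatol 10⁻⁸). Degenerate responses
(zero residual variance) short-circuit to a zero-variance result. Fixed
effects and SEs are GLS at the optimum; BLUPs come from the same
factorisation. A rank-deficient design raises an error naming the aliased
columns (categoricals are reference-coded, first level dropped).

**Wald test.** With thousands of observations the t reference is
indistinguishable from normal, so `wald_test` uses the standard normal
(residual degrees of freedom are not tracked); −log₁₀p is computed in log
space and stays exact far beyond double-precision underflow.

**LRT.** 2Δll clipped at zero against χ²₁. Testing a variance component on
the boundary makes plain χ²₁ conservative (a 50:50 mixture would be less
so); the conservative convention is kept deliberately and the null
simulation in the test suite confirms type-I error below nominal.

**Per-marker scans.** Sire- and animal-model scans share one random-effect
covariance K across markers, so the data are rotated once by the
eigenvectors of W^½KW^½; each marker then costs a 1-D profiled REML on a
diagonal covariance (exact re-estimation per marker, the default). The
`fast` mode profiles the ratio once under the no-marker null and holds it
fixed (score-test-like); it is labelled in the output and used only when
explicitly requested. Missing dosages are mean-imputed per marker;
monomorphic markers are skipped with a reason; a marker collinear with the
cofactor (|r| > 1−10⁻¹⁰) is reported non-estimable.

**Top-SNP selection** for window construction ranks by p ascending with
position ascending as the tie-break.

## 5. Missing-homozygote test (`lethal_scan`)

λ = N·q² with q the observed haplotype frequency among the 2N chromosomes of
live genotyped animals (dead animals are never genotyped, so the live-animal
panel is the correct denominator). The reported probability of observing k
homozygotes is the Poisson CDF at k; both the exact λ and its
nearest-integer rounding are surfaced, because published accounts often
quote the rounded mean (e⁻³⁶ ≈ 2.3×10⁻¹⁶ at the canonical 19,309-animal,
q = 0.043 example) while the exact value (35.70) is the right default for
new analyses. The sliding-window scan reports every haplotype allele with
q ≥ 0.01 and a Bonferroni column over the number of alleles tested; a single
preselected window needs no correction. Expected-count caveat: recombination
between the flanking tag SNPs and the deletion (~1 %/meiosis over a 1-Mb
window) slowly decouples haplotype and deletion, so carrier recall/precision
against the haplotype degrades with pedigree depth.

## 6. Deletion evidence (`deletion_evidence`)

* **HWP scan**: per-marker 1-df χ² against expectations at the sample allele
  frequency (no continuity correction), with the deviation direction; a
  deletion shows `het_deficit` confined to the deleted interval. For small
  samples `method="exact"` substitutes the exact conditional test (the
  heterozygote count given the allele counts; validated against brute-force
  enumeration in the test suite).
* **Intensity rule**: carrier iff mean in-region Log₂R < 0 *and* at least
  ⌈0.97·m⌉ of the m in-region markers are called homozygous. The ceiling
  reproduces the ">134 of 139 loci" operationalisation of the 97 % rule
  (⌈0.97·139⌉ = 135); with few in-region markers the ceiling makes the rule
  harsh (m = 10 demands all ten homozygous), so intensity calling should use
  an HD-density panel — the acceptance checks simulate one (~140 in-region
  loci, ~340 bulls).
* **Depth ratio**: mean in-region per-bp depth over mean off-region per-bp
  depth, windows straddling the boundary excluded; carrier < 0.7,
  noncarrier > 0.85, ambiguous between. The cutoffs are this package's
  choice: at ≥ 8× coverage over ≥ 0.5 Mb the Poisson ratio distributions
  around 0.5 and 1.0 are separated by far more than their spread, so the
  exact values are uncritical. A sample with zero off-region coverage is
  uninformative and raises.
* **Concordance**: 2×2 cross-tabulation over animals informative in both
  channels, ambiguous/anomalous calls excluded and counted; both overall
  agreement and carrier-conditional agreement (the "42 of 47" style figure)
  are reported.

## 7. Mating analysis (`mating_analysis`)

Types: (sire, MGS) carrier status (F,F)→I, (F,T)→II, (T,F)→III, (T,T)→IV.
Expected homozygous-conceptus fractions 0, 0, p/(4(1+p)), (1+p)/(4(2+p))
under HWP and random mating; type IV → 1/8 as p → 0. Dam carrier status is
never used directly — dams are ungenotyped in routine recording, which is
the entire reason for the MGS proxy. The outcome is recoded y = 1 for
stillbirth inside this module (the trait files code survival = 1); the
boundary converts explicitly.

The default model is **linear** on the 0/1 outcome — fixed parity and
insemination month-year effects, random MGS effect with pedigree covariance
A_s — because the estimand is the risk-difference contrast IV−I, directly
comparable to the expected homozygote fraction × penetrance. A
fixed-effects logistic variant is exposed (`model="logistic"`) as a
sensitivity analysis on the odds scale. Caveat of the linear choice: the
homoscedastic residual understates the uncertainty of the rare high-risk
type-IV class (its binomial variance is ~3× the pooled one at full
penetrance); `raw_type_contrast` therefore provides the unadjusted contrast
with a per-type binomial SE, and validation compares the fitted contrast
against theory using that honest SE. Mating types with no records are
reported as absent rather than zero.

## 8. Pipeline (`pipeline`, `cli`)

`run_pipeline` sequences simulate → QC → sire scan → RHM + cofactor re-scan
→ missing-homozygote scan → evidence channels → mating analysis, writing
each stage's artifact (VCF, CSV/TSV tables, JSON contrasts), a manifest with
config and artifact hashes, and a markdown/JSON summary that includes
ground-truth comparisons when the input is simulated. Stage outputs are pure
functions of inputs and config, so a rerun under the same seed is
byte-identical (verified in the tests). A stage failure is logged with the
stage name, downstream stages are skipped, and the report records the
failure. The putative deleted region is a required parameter of the
evidence stages (real analyses must choose between slightly different
intensity- and depth-derived boundaries); on simulated data it defaults to
the simulated deletion.

## 9. Problem sizes used in validation

The test suite exercises the stages at sizes chosen so the full suite runs
in well under five minutes on one CPU: the scan panel has ~2,100 live
animals (~900 bulls) and 400 markers; the missing-homozygote panel ~10,400
live animals at tag frequency ~0.055 (λ ≈ 31, founder-heavy to keep drift in
the realized frequency small); the intensity panel ~340 bulls at HD marker
density (~140 in-region loci); the mating analysis ~4,000 classifiable
records at p = 0.125 (~200 type-IV matings). These are deliberate
scaled-down renditions of national-scale datasets; the closed-form published
quantities (36 expected homozygotes in 19,309 animals, e⁻³⁶, the 8.25
Bonferroni line for 8.9 M tests, the 12.5 % type-IV limit) are checked
exactly at their stated sizes.

## 10. Known limitations

* No background LD in founders (see §2): power and peak sharpness on real
  data, where LD both helps tagging and creates shoulder signal, will differ.
* Phasing is assumed, not performed; phase and imputation error are outside
  scope.
* Single chromosome; no maternal genetic effects on stillbirth; no selection
  or assortative mating across generations.
* The Wald test's normal reference slightly understates p at small n; all
  intended uses have n in the hundreds or more.
* Dense linear algebra throughout: fits are comfortable to ~5,000
  individuals per mixed model; genome-wide sequence-scale scans (millions of
  markers) are out of scope.
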