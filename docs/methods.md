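# Methods

This note documents the models, estimators, numerical conventions and
deliberate design choices behind `kobuspop`, and what the synthetic-data
generators do and do not emulate.

## Markers and their effective sizes

The two marker systems carry different transmission genetics. Nuclear
microsatellites (nSSRs) are diploid and biparentally inherited: a
population of N monoecious individuals holds 2N transmissible gene copies.
The chloroplast is effectively haploid and maternally transmitted, and
because *Magnolia kobus* is monoecious every individual can be a seed
parent, so the chloroplast effective size equals N (not N/2 as it would be
in a dioecious species). All demographic models are parameterized in
diploid individuals and converted per marker at simulation time. For the
same reason, migration through pollen does not move the chloroplast: cpDNA
migration rates are the nuclear per-lineage rates multiplied by a
coefficient β ∈ [0, 1].

## Diversity and differentiation estimators

* **Allelic richness** uses hypergeometric rarefaction to g gene copies
  (default g = 8, i.e. four diploids — the smallest sample in the study
  design): `A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)]`. The implementation is
  exactly the expectation of the subset-enumeration experiment, which the
  tests verify by brute force on all small instances.
* **H_S** is the unweighted mean over populations of the *unbiased*
  within-population gene diversity `n/(n−1)(1 − Σp²)`; **H_T** is computed
  from unweighted mean allele frequencies across populations. This is the
  FSTAT convention and reproduces the published multilocus row (H_S 0.762,
  H_T 0.862 → G'_ST 0.504, D 0.439) to three decimals. The overall G'_ST
  and D are computed from the multilocus-average H_S and H_T, not as means
  of per-locus values — the latter does not reproduce the published
  overall numbers.
* **F_ST** follows Weir & Cockerham (1984) variance components (a, b, c)
  summed over alleles; the multilocus value is Σa/Σ(a+b+c)
  (ratio-of-sums). A monomorphic locus contributes zero components. The
  haploid analogue (mean squares between/within demes) serves for
  haplotype-frequency F_ST of cpDNA.
* **F_IS** is Weir–Cockerham's f over loci within one population; the
  Hardy–Weinberg test re-pairs gene copies at random within
  population × locus and uses the two-sided add-one permutation p-value.
  Permutation p-values are reported per population and Bonferroni-adjusted
  across populations.
* **Isolation by distance**: great-circle distance by haversine on a
  6371-km sphere (the geodesic model is a package choice), log-transformed;
  genetic distance F_ST/(1−F_ST); one-sided Mantel permutation p.
  Coincident populations (log 0) are dropped pairwise with a warning.
* **AMOVA** decomposes squared inter-individual distances across three
  layers (lineages / populations / individuals) with the standard
  unbalanced-design coefficients, reporting variance components as
  percentages plus Φ_CT, Φ_SC, Φ_ST. For nSSRs the default distance is
  allele identity (number of differing alleles per locus, F_ST-like); a
  squared-size-difference metric (R_ST-like) is available because which of
  the two the original Arlequin run used is not recorded. Loci missing in
  either individual are skipped and the distance rescaled. Negative
  variance components are reported as-is with a flag, as is conventional.
  Permutation schemes are layer-specific: populations among lineages
  (Φ_CT), individuals among populations within lineages (Φ_SC),
  individuals among all populations (Φ_ST).
* **Chloroplast summaries**: S counts segregating columns ignoring
  gaps/ambiguities; π is the mean number of pairwise differences with
  pairwise deletion; Tajima's D uses the standard a₁…e₂ constants and is
  undefined (None) at S = 0 or n = 2 (zero variance). Significance comes
  from neutral coalescent genealogies conditioned on (n, S) — mutations are
  dropped on branches proportionally to length — with a two-sided tail on
  |D|. Mono- and dinucleotide repeat stretches (runs ≥ 5 bp, dinucleotide
  repeats ≥ 3 units — slippage-prone, homoplasy-prone) can be masked before
  computing the statistics.
* **Evanno's ΔK** pairs replicates by index:
  `ΔK = mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd_r L(K)`; a zero
  replicate SD yields None with a warning.

## Coalescent simulator

Continuous-time (Kingman) coalescent, not generation-by-generation
Wright–Fisher — the regime in which the study's simulations were run.
Two implementations share one interface:

* a fast single-deme path for SNM/PGM/SRM using exact inversion of the
  piecewise-exponential cumulative hazard (for N(t) = N₀e^{Gt} the hazard
  integral is closed-form; unspent hazard carries across epoch
  boundaries), and
* a generic structured engine (arbitrary demes, constant per-lineage
  backward migration rates, resize/join events) for the divergence models
  and the multi-population island overlay.

Conventions: G is the backward exponential rate (negative G = forward-time
growth; the sign convention matches N(t) = N_CUR·e^{G·t} with t measured
into the past). Backward migration of a lineage in deme i to deme j occurs
at rate Nm_ij/N_i per generation. At T_DIV both lineages merge into an
ancestral deme whose size defaults to N_S — the southern lineage's history
is size-constant, so this is the natural continuation — with an explicit
alternative rule (N_N at T_DIV plus N_S) because the original
supplementary convention is not recorded; the choice only moves root
heights, which a dedicated test demonstrates.

## Mutation models

* **GSM** (microsatellites): Poisson(μ·branch length) mutations; each steps
  the repeat count by ±k with k geometric, `P(k=j) = (1−P)P^{j−1}`, so
  `P(k>1) = P_GSM` exactly as the model is defined verbally; P_GSM = 0 is
  the strict stepwise model. The root allele is fixed at 20 repeats — all
  downstream statistics are translation invariant (tested). A reflecting
  floor at 1 repeat keeps counts physical; it is applied to the per-branch
  net displacement (branch net sums are vectorized), which coincides with
  per-mutation reflection whenever a branch carries few mutations and
  matters only in extreme-θ corners of the prior. No upper boundary is
  imposed.
* **Hyperpriors**: across a simulation the 13 loci share a mean rate
  (log-uniform on [10⁻⁵, 10⁻³] at the prior-sampling level) with per-locus
  μ_l ~ Gamma(shape, shape/mean) (shape uniform on [0.5, 5]) and per-locus
  P_l ~ Beta(a, b) with `a = 0.5 + 199·meanP` and `b = a(1−meanP)/meanP`,
  which pins the Beta mean at meanP analytically. Beta draws are clipped
  below 1 by 10⁻⁹ so the geometric law stays proper.
* **cpDNA**: finite-sites Jukes–Cantor at μ = 2×10⁻⁹
  substitutions/site/generation over L = 3,929 bp. At θ ≪ 1 the choice of
  substitution matrix is immaterial for S and π, which is why the simplest
  model is used. Repeated hits at a site overwrite (at most one segregating
  column per site).

## Summary statistics (ABC)

Single lineage (8): mean and SD over loci of the number of alleles K, the
unbiased expected heterozygosity H and the allele size range R, plus
chloroplast S and π. Two lineages (19): both 8-vectors, the mean over loci
of the pooled-sample allele size range (the "overall range" is interpreted
as one pooled number per locus averaged — the only reading that keeps the
vector at its stated length), multilocus Weir–Cockerham F_ST for nSSRs,
and haplotype-identity F_ST for cpDNA (no sequence-distance weighting).
"Heterozygosity" is *expected* heterozygosity, the convention of the
standard summary-statistic calculators. SDs are sample SDs (ddof = 1).

## ABC inference

Statistics are standardized by the reference-table mean/SD before
Euclidean distances (constant columns dropped). The nearest `tolerance`
fraction is retained with Epanechnikov weights. Parameters are mapped to a
logit scale bounded by their prior box before local-linear (ridge 10⁻⁶,
weighted) regression adjustment toward the observed point, so adjusted
draws can never leave the prior support; a single-hidden-layer
neural-network variant is available. Modes come from a Gaussian KDE
(Silverman bandwidth, 512-point grid); HPD intervals are the shortest
window holding the stated (weighted) mass. Fewer than 50 accepted
simulations is an error (increase the budget or the tolerance); the KDE
refuses fewer than 100 draws.

Model choice fits a random forest on the reference statistics; vote shares
are per-tree classifications of the observed vector, the selected model is
the plurality winner (ties break to the first-listed model, flagged), and
its posterior probability is one minus a regression forest's prediction of
the local out-of-bag misclassification rate (the standard ABC-RF
construction). `ModelChoiceForest` caches the fitted forests so many
pseudo-observed datasets can be classified against one reference.

Structural priors default to broad log-uniform boxes (N: 10³–2×10⁵
diploids; T and T_DIV: 10²–10⁵ generations; Nm: 10⁻²–10²; RN_ANC: 1–10²)
with G uniform on [−10⁻³, 0] and β uniform on [0, 1]; the original prior
table is not public, so every bound lives in configuration. The sequential
design fixes G in the divergence stage at the northern size-change
posterior mode (0 when the selected northern model has no growth
parameter).

Default desk-scale budgets are 2×10⁴ simulations for size change and
5×10⁴ for divergence with samples of 50 diploids and 8 cpDNA sequences per
deme; configuration reaches the full-study budgets (10⁴ for model choice,
5×10⁵/1.5×10⁶ for estimation) when cluster time is available. Recovery
tests therefore demonstrate *statistical correctness at the scaled-down
budgets* (model recovery ≥ 80%, N_CUR coverage ≥ 85% at nominal 95%), not
numerical equality with the original posterior modes, which would require
the unreleased genotypes and the full budget.

## Leaf morphology

EFD coefficients follow Kuhl–Giardina with normalization for size (first
harmonic semi-major axis = 1), rotation and starting point. The curve
parameter advances uniformly per vertex by default, which makes an ellipse
exactly its first harmonic ((1, 0, 0, 0.5) for a 2:1 ellipse) and
coincides with arc-length parameterization for chain-coded or evenly
resampled contours — the expected input; an explicit `arclength` option
exists for irregularly sampled outlines. Self-intersecting contours are
rejected by an O(n²) segment test. Leaf area falls back to the shoelace
formula when not measured.

PCA (shape: covariance; bioclim: correlation) retains components with
variance share strictly greater than 5%. The asymmetry component is used
as log|PC| because its sign carries no biological meaning. Climate
components with |Pearson r| > 0.7 against the ancestry coefficient Q are
screened out to avoid collinearity between environment and history.

The mixed model is linear-Gaussian and fully conjugate, so it is sampled
by Gibbs rather than generic HMC — the target density is identical and the
sufficient statistics (tree means, counts, within-tree sums of squares)
make each sweep O(number of trees). "Non-informative" priors are realized
as improper flats on the coefficients and on both standard deviations
(positive half-line, i.e. p(σ²) ∝ σ⁻¹), giving inverse-gamma conditionals
with shape (n−1)/2; propriety requires more individuals than fixed
effects, asserted at fit time. Defaults mirror the published run: 4 chains
× 4,000 iterations, 1,000 burn-in, thinning 10 → 1,200 retained draws;
split-R̂ > 1.01 triggers a warning but results are still emitted. A
coefficient is "significant" when its 95% HPD excludes zero.

Variety calls: a population is *kobus* (narrow) or *borealis* (wide) when
more than 75% of its trees fall strictly on one side of the 6-cm width
boundary — a quantitative stand-in for the original visual call against
the published ranges (kobus 6–15 × 3–6 cm, borealis 10–20 × 6–10 cm) —
otherwise *intermediate*; fewer than 3 trees yields no call. The 75%
threshold is configurable.

## Synthetic data

The generators produce every pipeline input with the study's structure:
two lineages (default 10 + 13 populations) from an isolation model with
northern growth (defaults near the published posterior modes: N_N = 7.4×10⁴,
N_S = 1.2×10⁵, T_DIV = 1.13×10⁴ generations, G = −1.56×10⁻⁴), a
finite-island overlay inside each lineage (default Nm = 10, giving the
weak within-lineage structure the multi-population statistics need —
the ABC models themselves treat each lineage as one deme), ~20 diploids
and 2 cpDNA sequences per population, 1% missing genotypes, and leaf
tables drawn from the mixed model at the published leaf-area scale
(β_Q = 13, σ_Individual = 11.6, σ_All = 13.1) with a 19-variable climate
table built from a 4-factor model whose first factor correlates with Q at
−0.823 exactly (so the covariate screen has something to catch). Every
generator writes a truth record; recovery tests read truth only from it.

What the generators do **not** emulate: genotyping artifacts (null
alleles, allele dropout, stutter — the null-allele filter of the original
pipeline is honored as a documented preprocessing convention, not
simulated), linkage between loci, chloroplast indels, spatially continuous
isolation by distance within lineages, or real leaf-outline noise
(outlines are superellipses). Passing tests therefore demonstrate
correctness of the estimators and inference machinery under the assumed
generating processes, not robustness to these real-data complications.

## Numerical conventions and limitations

* One global seed; each pipeline stage draws from a fixed spawn-key
  substream, so disabling one stage never shifts another's randomness, and
  the run manifest (config hash + seed + output hashes) makes every
  stochastic output reproducible bit-for-bit.
* Permutation p-values use the add-one convention (1+hits)/(1+n_perm),
  which is exact-level; permutation counts default to 10³.
* GenePop files use 3-digit allele codes holding repeat counts, `000` for
  missing; repeat counts above 999 are rejected at write time.
* The structured engine redraws competing waiting times after every event
  (valid by independence of the underlying Poisson processes); a deme that
  shrinks backward in time (G > 0 single-deme) can exhaust its total
  hazard, which raises an explicit error rather than looping forever.
* The published per-locus G'_ST values for two loci are not reproducible
  from the published 3-decimal H_S/H_T inputs (they were evidently
  computed from unrounded diversities); the package reproduces every value
  that is derivable from the printed inputs.
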