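# kobuspop

Population-genetic and leaf-morphology analysis pipeline for *Magnolia
kobus*, a temperate tree of the Japanese archipelago that splits into a
northern and a southern lineage and into two leaf morphotypes (varieties
*kobus* and *borealis*). The package is aimed at population geneticists who
want to re-run or stress-test the full analysis chain — marker statistics,
demographic inference and morphology — on data with the same structure as
the study design (23 populations, 13 nuclear microsatellite loci, 3,929 bp
of chloroplast sequence, ~10 leaves per tree), including synthetic-data
generators for every input so that everything runs without access to the
original genotypes.

## What it computes

**Diversity and differentiation.** Per population: rarefied allelic
richness A_R (El Mousadik–Petit, g gene copies), unbiased expected
heterozygosity H_E, Weir–Cockerham F_IS with a Hardy–Weinberg randomization
test. Per locus: Nei gene diversities H_S and H_T, Weir–Cockerham F_ST
(multilocus value as a ratio of summed variance components), Hedrick's
standardized differentiation

    G'_ST = G_ST · (k − 1 + H_S) / [(k − 1)(1 − H_S)],   G_ST = (H_T − H_S)/H_T,

and Jost's D = [(H_T − H_S)/(1 − H_S)] · k/(k − 1). Plus Mantel isolation
by distance (log km vs F_ST/(1 − F_ST)), three-level AMOVA
(Φ_CT/Φ_SC/Φ_ST with layer-specific permutations), chloroplast S, π and
Tajima's D (fixed-S coalescent null), and Evanno's ΔK.

**Coalescent simulation.** A backward-in-time simulator for three
size-change models (SNM constant; PGM exponential, N(t) = N_CUR·e^{G·t}
with t in generations backward; SRM instantaneous change at T to
N_CUR·RN_ANC) and four divergence models (ISM and isolation-with-migration
IMM / IMM_NS / IMM_SN, with backward migrant numbers Nm_NS, Nm_SN). Nuclear
loci use 2N gene copies; the chloroplast uses N because the species is
monoecious, with cpDNA migration scaled by β ∈ [0,1] (seed-only dispersal).
Microsatellites mutate under a generalized stepwise model (geometric steps,
P(|step| > 1) = P_GSM) with hierarchical gamma/beta hyperpriors;
chloroplast sequences under finite-sites Jukes–Cantor at 2×10⁻⁹
substitutions/site/generation.

**Sequential ABC.** Reference tables of 8 (single-lineage) or 19
(two-lineage) summary statistics; random-forest model choice with
out-of-bag error and a regression-forest posterior probability; rejection
plus logit-bounded local-linear (or neural-network) regression adjustment;
KDE posterior modes with 95% HPD intervals; posterior predictive checks.
The divergence stage fixes the growth rate G at the northern size-change
posterior mode.

**Morphology.** Elliptic Fourier descriptors of leaf outlines with
size/rotation/start-point normalization, PCA with a strict >5% variance
retention rule, screening of climate principal components against the
ancestry coefficient Q (|r| > 0.7 dropped), a conjugate-Gibbs Bayesian
linear mixed model `Y ~ Normal(β₀[tree] + Xβ, σ_All)` with
`β₀[tree] ~ Normal(β₀_Mean, σ_Individual)`, and variety classification from
tree-average leaf length and width against the 6-cm width boundary.

## Worked example

```python
>>> from kobuspop.stats import gst_prime_hedrick, jost_d
>>> round(gst_prime_hedrick(0.796, 0.917, 23), 3)   # h_s, h_t, k populations
0.67
>>> round(jost_d(0.796, 0.917, 23), 3)
0.62
>>> from kobuspop.abc import generations_to_years
>>> generations_to_years(11_300)                     # 50-year generations
565000.0
```

With H_S = 0.796 and H_T = 0.917 over k = 23 populations, about 13% of the
total gene diversity lies between populations (G_ST ≈ 0.13), but after
standardizing for the high within-population diversity of microsatellites
two thirds of the achievable differentiation is realized (G'_ST = 0.670);
Jost's D = 0.620 says effectively 62% of allelic turnover between
populations. A divergence-time mode of 11,300 generations converts to
565,000 years at 50 years per generation.

On a synthetic two-lineage dataset (generated by the package itself):

```python
import numpy as np
from kobuspop.synth import SyntheticScenario, generate_genetic_data
from kobuspop.stats import differentiation_table

scenario = SyntheticScenario(n_north_demes=3, n_south_demes=3,
                             n_diploids_per_pop=12, n_cp_per_pop=2,
                             n_loci=5, seq_length=1000, n_north=20_000,
                             n_south=30_000, t_div=10_000, island_nm=10.0)
rng = np.random.default_rng(1)
dataset, alignment, truth = generate_genetic_data(scenario, rng)
print(differentiation_table(dataset, n_perm=199, seed=rng).round(3))
```

```
  locus    A   H_S   H_T  F_ST  Gst_prime     D  perm_p
  loc01 19.0 0.857 0.906 0.075      0.446 0.414   0.005
  loc02 19.0 0.877 0.913 0.054      0.379 0.354   0.005
  loc03 14.0 0.866 0.898 0.056      0.311 0.285   0.005
  loc04  7.0 0.712 0.814 0.153      0.498 0.426   0.005
  loc05 19.0 0.890 0.912 0.038      0.256 0.237   0.005
overall 15.6 0.840 0.889 0.074      0.398 0.363     NaN
```

Every locus shows significant differentiation (permutation p = 0.005 at 199
permutations), driven by the deep split between the two simulated lineages;
the overall row uses multilocus-average H_S/H_T and ratio-of-sums F_ST.

A command-line interface mirrors the stages:

```sh
kobuspop synth   --out data --seed 1          # write a synthetic study
kobuspop stats   --config study.yaml          # Tables of diversity stats
kobuspop abc-div --config study.yaml          # sequential ABC, both stages
kobuspop morph   --config study.yaml          # leaf mixed model + varieties
```

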