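"""Synthetic-data generators for every input the pipeline consumes.

The genotype and haplotype data are not public, so the generators emulate the
study design: 23 populations in two diverged lineages (10 northern, 13
southern), 13 microsatellite loci with ~20 diploids per population, 3,929-bp
chloroplast alignments with 1-4 sequences per population, and leaf records
(~10 leaves per tree) drawn from the same linear mixed model the analysis
fits.  Each lineage is one coalescent deme in the ABC models; here a
finite-island overlay subdivides each lineage into populations so the
multi-population statistics see realistic weak within-lineage structure.
Every generator records its full parameterization in a machine-readable
truth dictionary so recovery tests can read the truth without re-deriving
it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .coalescent import _Deme, _EngineDemography, _Event, _simulate
from .datasets import GenotypeDataset, HaplotypeAlignment
from .mutation import (
    CpMutationModel,
    GsmHyperPrior,
    draw_locus_params,
    mutate_microsat,
    mutate_sequence,
    sequences_to_strings,
)


@dataclass
class LeafModelParams:
    """BLMM truth for the default leaf-area response (cm^2 scale)."""

    beta0_mean: float = 46.4
    beta_biopc2: float = -3.8
    beta_biopc3: float = -3.1
    beta_biopc4: float = 3.3
    beta_q: float = 13.0
    sigma_individual: float = 11.6
    sigma_all: float = 13.1


@dataclass
class SyntheticScenario:
    """Complete, JSON-serializable specification of one synthetic study."""

    # demography (ISM with northern growth by default)
    n_north_demes: int = 10
    n_south_demes: int = 13
    n_north: float = 7.4e4           # lineage effective sizes (diploids)
    n_south: float = 1.2e5
    t_div: float = 1.13e4            # generations
    growth_north: float = -1.56e-4   # backward rate; negative = forward growth
    island_nm: float = 10.0          # migrants/generation among demes in a lineage
    # sampling
    n_diploids_per_pop: int = 20
    n_cp_per_pop: int = 2
    n_loci: int = 13
    seq_length: int = 3_929
    missing_rate: float = 0.01
    # mutation
    mean_mu: float = 2.0e-4
    gamma_shape: float = 2.0
    mean_p_gsm: float = 0.3
    # leaves
    trees_per_pop: int = 20
    leaves_per_tree: int = 10
    leaf_model: LeafModelParams = field(default_factory=LeafModelParams)
    biopc1_q_corr: float = -0.823    # exercised by the covariate screen
    q_gradient: float = 0.0          # admixture gradient near the boundary
    # leaf size morphotypes (cm): (length mean, width mean) by lineage
    north_length: float = 13.5
    north_width: float = 7.2
    south_length: float = 10.5
    south_width: float = 5.3
    leaf_dim_tree_sd: float = 0.8
    leaf_dim_leaf_sd: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)
        d["leaf_model"] = LeafModelParams(**d["leaf_model"])
        return cls(**d)

    @property
    def populations(self) -> list[str]:
        return ([f"N{i+1:02d}" for i in range(self.n_north_demes)]
                + [f"S{i+1:02d}" for i in range(self.n_south_demes)])

    @property
    def lineage_map(self) -> dict[str, str]:
        out = {p: "northern" for p in self.populations[: self.n_north_demes]}
        out.update({p: "southern" for p in self.populations[self.n_north_demes:]})
        return out


def _island_demography(scenario: SyntheticScenario, marker: str) -> _EngineDemography:
    """Two-lineage island demography: each population is a deme; demes within
    a lineage exchange migrants symmetrically; lineages are isolated until
    T_DIV, when everything merges into an ancestral deme of the southern
    size (the southern history is size-constant)."""
    f = 2.0 if marker == "nuclear" else 1.0
    kn, ks = scenario.n_north_demes, scenario.n_south_demes
    size_n = f * scenario.n_north / kn
    size_s = f * scenario.n_south / ks
    demes = ([_Deme(size_n, scenario.growth_north) for _ in range(kn)]
             + [_Deme(size_s, 0.0) for _ in range(ks)])
    n_demes = kn + ks
    mig = np.zeros((n_demes, n_demes))
    for group, per_deme_n in (((range(kn)), scenario.n_north / kn),
                              (range(kn, n_demes), scenario.n_south / ks)):
        idx = list(group)
        if len(idx) > 1 and scenario.island_nm > 0:
            rate = scenario.island_nm / per_deme_n / (len(idx) - 1)
            for i in idx:
                for j in idx:
                    if i != j:
                        mig[i, j] = rate
    events = []
    anc = f * scenario.n_south
    # collapse all demes into deme 0 at T_DIV
    for d in range(1, n_demes):
        events.append(_Event(scenario.t_div, "join", d, dest=0, size=anc))
    events.append(_Event(scenario.t_div, "resize", 0, size=anc, growth=0.0))
    return _EngineDemography(demes, events, mig)


def generate_genetic_data(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
) -> tuple[GenotypeDataset, HaplotypeAlignment, dict]:
    """Simulate the genotype dataset and cpDNA alignment for one scenario.

    Returns (dataset, alignment, truth) where ``truth`` records every
    parameter used.
    """
    pops = scenario.populations
    n_demes = len(pops)
    hyper = GsmHyperPrior(scenario.mean_mu, scenario.gamma_shape,
                          scenario.mean_p_gsm)
    mu_l, p_l = draw_locus_params(hyper, scenario.n_loci, rng)

    demog = _island_demography(scenario, "nuclear")
    samples = tuple(2 * scenario.n_diploids_per_pop for _ in range(n_demes))
    genotypes = {p: np.zeros((scenario.n_diploids_per_pop, scenario.n_loci, 2),
                             dtype=np.int64) for p in pops}
    for li in range(scenario.n_loci):
        gen = _simulate(demog, samples, "nuclear", rng)
        tips = mutate_microsat(gen, mu_l[li], p_l[li], rng)
        for d, pop in enumerate(pops):
            alleles = tips[gen.tip_deme == d]
            genotypes[pop][:, li, :] = alleles.reshape(-1, 2)
    if scenario.missing_rate > 0:
        for pop in pops:
            g = genotypes[pop]
            mask = rng.random(g.shape[:2]) < scenario.missing_rate
            g[mask] = 0  # both alleles of the genotype go missing

    cp_demog = _island_demography(scenario, "chloroplast")
    cp_samples = tuple(scenario.n_cp_per_pop for _ in range(n_demes))
    cp_gen = _simulate(cp_demog, cp_samples, "chloroplast", rng)
    cp_model = CpMutationModel(seq_length=scenario.seq_length)
    seq_arr = mutate_sequence(cp_gen, cp_model, rng)
    seq_str = sequences_to_strings(seq_arr)
    sequences = {p: [] for p in pops}
    for tip, pop_idx in enumerate(cp_gen.tip_deme):
        pop = pops[pop_idx]
        sequences[pop].append((f"{pop}_cp{len(sequences[pop]) + 1}", seq_str[tip]))

    coords = _synthetic_coords(scenario)
    dataset = GenotypeDataset(
        populations=pops,
        loci=[f"loc{j+1:02d}" for j in range(scenario.n_loci)],
        genotypes=genotypes,
        lineage=scenario.lineage_map,
        coords=coords,
    )
    alignment = HaplotypeAlignment(populations=pops, sequences=sequences)
    truth = {
        "scenario": json.loads(scenario.to_json()),
        "mu_per_locus": mu_l.tolist(),
        "p_gsm_per_locus": p_l.tolist(),
    }
    return dataset, alignment, truth


def _synthetic_coords(scenario: SyntheticScenario) -> dict[str, tuple[float, float]]:
    """Latitudinal transect: northern demes 40-45N, southern 31-39N."""
    coords = {}
    for i in range(scenario.n_north_demes):
        frac = i / max(scenario.n_north_demes - 1, 1)
        coords[f"N{i+1:02d}"] = (45.0 - 5.0 * frac, 141.0 - 2.0 * frac)
    for i in range(scenario.n_south_demes):
        frac = i / max(scenario.n_south_demes - 1, 1)
        coords[f"S{i+1:02d}"] = (39.0 - 8.0 * frac, 140.0 - 9.0 * frac)
    return coords


# ---------------------------------------------------------------------------
# leaves and covariates


def generate_leaf_data(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Leaf table + 19-variable bioclimatic covariate table + truth record.

    Q is 1 in the north and 0 in the south (optionally a gradient near the
    boundary).  The 19 bioclimatic variables follow a 4-factor model whose
    first factor is correlated with Q at the configured level, so the
    covariate screen has something to catch.  Responses are drawn from the
    random-intercept linear model at the configured coefficients.
    """
    pops = scenario.populations
    k = len(pops)
    lineages = scenario.lineage_map
    q = np.array([1.0 if lineages[p] == "northern" else 0.0 for p in pops])
    if scenario.q_gradient > 0:
        jitter = rng.uniform(0, scenario.q_gradient, size=k)
        q = np.clip(np.where(q > 0.5, q - jitter, q + jitter), 0.0, 1.0)

    r = scenario.biopc1_q_corr
    q_std = (q - q.mean()) / q.std()
    factors = np.empty((k, 4))
    noise = rng.standard_normal(k)
    noise = (noise - noise.mean()) / noise.std()
    # residualize so the empirical correlation is exact by construction
    noise = noise - q_std * (noise @ q_std) / (q_std @ q_std)
    noise /= noise.std()
    factors[:, 0] = r * q_std + np.sqrt(1 - r ** 2) * noise
    factors[:, 1:] = rng.standard_normal((k, 3))
    # spread the 4 factors over 19 observed variables with descending weight
    loadings = np.zeros((4, 19))
    weights = [8.0, 4.0, 2.0, 1.0]
    for f in range(4):
        loadings[f, :] = rng.standard_normal(19) * 0.05
        block = slice(f * 4, f * 4 + 4)
        loadings[f, block] += weights[f]
    bioclim = factors @ loadings + 0.05 * rng.standard_normal((k, 19))
    covariates = pd.DataFrame(bioclim, index=pops,
                              columns=[f"bio{i+1}" for i in range(19)])

    lm = scenario.leaf_model
    rows = []
    for pi, pop in enumerate(pops):
        northern = lineages[pop] == "northern"
        length_mu = scenario.north_length if northern else scenario.south_length
        width_mu = scenario.north_width if northern else scenario.south_width
        for t in range(scenario.trees_per_pop):
            tree_id = f"{pop}_t{t+1:02d}"
            b_j = rng.normal(lm.beta0_mean, lm.sigma_individual)
            tree_len = rng.normal(length_mu, scenario.leaf_dim_tree_sd)
            tree_wid = rng.normal(width_mu, scenario.leaf_dim_tree_sd)
            mean_resp = (b_j
                         + lm.beta_biopc2 * factors[pi, 1]
                         + lm.beta_biopc3 * factors[pi, 2]
                         + lm.beta_biopc4 * factors[pi, 3]
                         + lm.beta_q * q[pi])
            for leaf in range(scenario.leaves_per_tree):
                rows.append({
                    "leaf_id": f"{tree_id}_l{leaf+1:02d}",
                    "tree_id": tree_id,
                    "population": pop,
                    "length_cm": rng.normal(tree_len, scenario.leaf_dim_leaf_sd),
                    "width_cm": rng.normal(tree_wid, scenario.leaf_dim_leaf_sd),
                    "area_cm2": rng.normal(mean_resp, lm.sigma_all),
                    "BioPC2": factors[pi, 1],
                    "BioPC3": factors[pi, 2],
                    "BioPC4": factors[pi, 3],
                    "Q": q[pi],
                })
    leaf_table = pd.DataFrame(rows)
    truth = {
        "scenario": json.loads(scenario.to_json()),
        "q_per_population": dict(zip(pops, q.tolist())),
        "factor_scores": {p: factors[i].tolist() for i, p in enumerate(pops)},
    }
    return leaf_table, covariates, truth


def superellipse_outline(length: float, width: float, n_points: int = 120,
                         exponent: float = 2.5) -> np.ndarray:
    """Closed leaf-like outline: a superellipse with the given dimensions."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    e = 2.0 / exponent
    x = (length / 2) * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    y = (width / 2) * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    return np.stack([x, y], axis=1)


def generate_logprob_table(
    k_values: range | list[int],
    n_reps: int,
    rng: np.random.Generator,
    kink_at: int | None = 2,
    slope: float = 50.0,
    kink_drop: float = 200.0,
    noise_sd: float = 5.0,
) -> dict[int, list[float]]:
    """Clustering log-probability fixture: piecewise-linear mean with an
    optional kink, plus Gaussian replicate noise."""
    ks = list(k_values)
    out = {}
    for k in ks:
        mean = -1000.0 + slope * k
        if kink_at is not None and k > kink_at:
            mean -= kink_drop * (k - kink_at)
        out[k] = (mean + noise_sd * rng.standard_normal(n_reps)).tolist()
    return out
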