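"""Diversity and differentiation statistics for microsatellite and cpDNA data.

Covers per-population diversity (rarefied allelic richness, expected
heterozygosity, F_IS with a Hardy–Weinberg randomization test), per-locus
differentiation (Nei gene diversities, Weir–Cockerham F_ST, Hedrick's
standardized G'_ST, Jost's D), isolation by distance (Mantel test on log-km
vs F_ST/(1-F_ST)), three-level AMOVA with Phi-statistics, chloroplast
sequence summaries (S, pi, Tajima's D with a fixed-S coalescent null), and
the Evanno second-difference statistic for choosing the number of clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset, HaplotypeAlignment

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# allelic richness and gene diversities


def allelic_richness(dataset: GenotypeDataset, locus: str | int, population: str,
                     g: int = 8) -> float:
    """Rarefied allele count: expected number of alleles in ``g`` gene copies.

    Uses the hypergeometric rarefaction
    ``sum_i [1 - C(N - N_i, g) / C(N, g)]`` over alleles, where ``N`` is the
    number of sampled gene copies and ``N_i`` the copies of allele ``i``.
    """
    counts = dataset.allele_counts(population, locus)
    n_total = sum(counts.values())
    if n_total < g:
        raise ValueError(
            f"population {population!r} has only {n_total} gene copies at this "
            f"locus; {g} required for rarefaction"
        )
    denom = math.comb(n_total, g)
    return float(sum(1.0 - math.comb(n_total - ni, g) / denom
                     for ni in counts.values()))


def unbiased_gene_diversity(alleles: np.ndarray) -> float:
    """Nei's unbiased within-population gene diversity, n/(n-1) * (1 - sum p^2)."""
    n = alleles.size
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def gene_diversities(dataset: GenotypeDataset, locus: str | int) -> tuple[float, float]:
    """(H_S, H_T) for one locus.

    H_S is the unweighted mean over populations of the unbiased
    within-population gene diversity; H_T is computed from allele frequencies
    averaged (unweighted) across populations.
    """
    freqs = []
    hs_vals = []
    alleles_union: set[int] = set()
    per_pop_freq: list[dict[int, float]] = []
    for pop in dataset.populations:
        a = dataset.alleles(pop, locus)
        if a.size < 2:
            continue
        hs_vals.append(unbiased_gene_diversity(a))
        vals, counts = np.unique(a, return_counts=True)
        d = dict(zip(vals.tolist(), (counts / a.size).tolist()))
        per_pop_freq.append(d)
        alleles_union |= set(d)
    if len(per_pop_freq) < 2:
        raise ValueError("need data in at least 2 populations")
    k = len(per_pop_freq)
    p_bar = {al: sum(d.get(al, 0.0) for d in per_pop_freq) / k for al in alleles_union}
    h_t = 1.0 - sum(v * v for v in p_bar.values())
    return float(np.mean(hs_vals)), float(h_t)


def gst_prime_hedrick(h_s: float, h_t: float, k: int) -> float | None:
    """Hedrick's standardized G'_ST = G_ST (k-1+H_S) / [(k-1)(1-H_S)]."""
    _check_hs_ht(h_s, h_t, k)
    if h_t == 0.0 or h_s == 1.0:
        return None
    g_st = (h_t - h_s) / h_t
    return g_st * (k - 1 + h_s) / ((k - 1) * (1.0 - h_s))


def jost_d(h_s: float, h_t: float, k: int) -> float | None:
    """Jost's D = [(H_T - H_S)/(1 - H_S)] * [k/(k-1)]."""
    _check_hs_ht(h_s, h_t, k)
    if h_s == 1.0:
        return None
    return (h_t - h_s) / (1.0 - h_s) * k / (k - 1)


def _check_hs_ht(h_s: float, h_t: float, k: int) -> None:
    if not (0.0 <= h_s <= 1.0 and 0.0 <= h_t <= 1.0):
        raise ValueError("gene diversities must lie in [0, 1]")
    if h_s > h_t + 1e-12:
        raise ValueError("H_S cannot exceed H_T")
    if k < 2:
        raise ValueError("need at least 2 subpopulations")


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components


def wc_components_locus(pop_genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one locus.

    ``pop_genos`` is a list of (n_i, 2) genotype arrays (one per population);
    individuals with any missing allele at the locus are dropped.  Components
    are summed over alleles.  A locus monomorphic across all populations
    contributes (0, 0, 0).
    """
    clean = []
    for g in pop_genos:
        g = g[(g != 0).all(axis=1)]
        if g.shape[0] > 0:
            clean.append(g)
    r = len(clean)
    if r < 2:
        raise ValueError("need genotype data in at least 2 populations")
    n = np.array([g.shape[0] for g in clean], dtype=float)
    nbar = n.mean()
    n_c = (r * nbar - np.sum(n * n) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in clean]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p = np.array([np.mean(g == al) for g in clean])
        h = np.array([np.mean((g == al).sum(axis=1) == 1) for g in clean])
        pbar = np.sum(n * p) / (r * nbar)
        s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h) / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(dataset: GenotypeDataset, loci: list[str | int] | None = None) -> float:
    """Multilocus Weir–Cockerham F_ST as a ratio of summed components."""
    loci = list(range(dataset.n_loci)) if loci is None else loci
    num = den = 0.0
    for locus in loci:
        a, b, c = wc_components_locus(
            [dataset.pop_genotypes(p, locus) for p in dataset.populations]
        )
        num += a
        den += a + b + c
    if den == 0.0:
        raise ValueError("all loci monomorphic: F_ST undefined")
    return num / den


def wc_fst_locus(dataset: GenotypeDataset, locus: str | int) -> float:
    a, b, c = wc_components_locus(
        [dataset.pop_genotypes(p, locus) for p in dataset.populations]
    )
    if a + b + c == 0.0:
        raise ValueError("monomorphic locus: F_ST undefined")
    return a / (a + b + c)


def wc_fst_haploid(groups: list[np.ndarray]) -> float:
    """Weir–Cockerham-style F_ST for haploid data (e.g. cpDNA haplotypes).

    ``groups`` holds one integer array of haplotype labels per deme."""
    groups = [g for g in groups if g.size > 0]
    r = len(groups)
    if r < 2:
        raise ValueError("need at least 2 demes")
    n = np.array([g.size for g in groups], dtype=float)
    if (n < 2).any():
        raise ValueError("each deme needs at least 2 sequences")
    nbar = n.mean()
    n_c = (r * nbar - np.sum(n * n) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate(groups))
    num = den = 0.0
    for al in alleles:
        p = np.array([np.mean(g == al) for g in groups])
        pbar = np.sum(n * p) / n.sum()
        msp = np.sum(n * (p - pbar) ** 2) / (r - 1)
        msg = np.sum(n * p * (1 - p)) / np.sum(n - 1)
        a = (msp - msg) / n_c
        num += a
        den += a + msg
    if den == 0.0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# F_IS and the Hardy-Weinberg randomization test


def wc_fis(dataset: GenotypeDataset, population: str) -> float:
    """Weir–Cockerham within-population inbreeding coefficient f over loci."""
    num = den = 0.0
    for locus in range(dataset.n_loci):
        g = dataset.pop_genotypes(population, locus)
        g = g[(g != 0).all(axis=1)]
        n = g.shape[0]
        if n < 2:
            continue
        alleles = np.unique(g)
        if alleles.size < 2:
            continue
        for al in alleles:
            p = np.mean(g == al)
            h = np.mean((g == al).sum(axis=1) == 1)
            b1 = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            num += c
            den += b1 + c
    if den == 0.0:
        raise ValueError("no polymorphic loci: F_IS undefined")
    return 1.0 - num / den


def hwe_randomization_test(
    dataset: GenotypeDataset,
    population: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Randomization test for departure from Hardy-Weinberg equilibrium.

    The observed F_IS (Weir-Cockerham f over loci) is compared with its null
    distribution obtained by re-pairing alleles at random among individuals
    within the population, independently per locus.  Two-sided p-value with
    the add-one permutation correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dataset.genotypes[population].shape[0] < 4:
        warnings.warn(
            f"population {population!r} has fewer than 4 individuals: the "
            "randomization p-value is unreliable", stacklevel=2)
    f_obs = wc_fis(dataset, population)

    locus_alleles = [dataset.alleles(population, l) for l in range(dataset.n_loci)]
    count = 0
    for _ in range(n_perm):
        perm_pop = _permuted_single_pop(locus_alleles, rng, dataset.loci)
        f_perm = wc_fis(perm_pop, "perm")
        if abs(f_perm) >= abs(f_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return f_obs, p


def _permuted_single_pop(locus_alleles: list[np.ndarray], rng: np.random.Generator,
                         loci: list[str]) -> GenotypeDataset:
    n_ind = max((a.size // 2 for a in locus_alleles), default=0)
    g = np.zeros((n_ind, len(locus_alleles), 2), dtype=np.int64)
    for li, a in enumerate(locus_alleles):
        perm = rng.permutation(a)
        k = a.size // 2
        g[:k, li, 0] = perm[:k]
        g[:k, li, 1] = perm[k:2 * k]
    return GenotypeDataset(["perm"], list(loci), {"perm": g})


def bonferroni(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tests)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# isolation by distance


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a 6371-km sphere."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def mantel_ibd(
    fst_matrix: np.ndarray,
    coords: list[tuple[float, float]],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel test of isolation by distance.

    Genetic distance F_ST/(1-F_ST) against log great-circle kilometers; the
    permutation p-value is one-sided for positive correlation.  Returns
    (r_squared, p).  Pairs at identical coordinates are dropped with a
    warning (log 0 undefined).
    """
    fst = np.asarray(fst_matrix, dtype=float)
    k = fst.shape[0]
    if fst.shape != (k, k) or not np.allclose(fst, fst.T):
        raise ValueError("F_ST matrix must be square and symmetric")
    if (fst >= 1).any():
        raise ValueError("F_ST entries must be < 1")
    if k < 4:
        raise ValueError("need at least 4 populations for the Mantel test")
    if len(coords) != k:
        raise ValueError("coords length must match the F_ST matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    geo = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        geo[i, j] = geo[j, i] = haversine_km(*coords[i], *coords[j])
    iu = np.triu_indices(k, 1)
    zero_pairs = geo[iu] <= 0
    if zero_pairs.any():
        warnings.warn(f"dropping {int(zero_pairs.sum())} coincident population "
                      "pair(s) from the Mantel test", stacklevel=2)
    with np.errstate(divide="ignore"):
        logd = np.log(geo)
    gd = fst / (1.0 - fst)

    def mantel_r(order: np.ndarray) -> float:
        x = logd[iu]
        y = gd[np.ix_(order, order)][iu]
        m = np.isfinite(x)
        return float(np.corrcoef(x[m], y[m])[0, 1])

    ident = np.arange(k)
    r_obs = mantel_r(ident)
    count = sum(
        mantel_r(rng.permutation(k)) >= r_obs - 1e-12 for _ in range(n_perm)
    )
    p = (1 + count) / (n_perm + 1)
    return r_obs ** 2, p


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Three-level AMOVA: variance components (% of total) and Phi-statistics."""

    components_pct: dict[str, float]     # among_lineages / among_pops / within_pops
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float]
    negative_components: bool


def _safe_div(a: float, b: float) -> float:
    return a / b if b != 0 else float("nan")


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * idx.size))


def amova_components(
    d2: np.ndarray, pop_labels: np.ndarray, group_of_pop: dict[int, int]
) -> tuple[float, float, float]:
    """Nested variance components (sigma_a, sigma_b, sigma_c) from squared
    inter-individual distances (Excoffier-style sums of squares)."""
    n_tot = d2.shape[0]
    pops = np.unique(pop_labels)
    groups = sorted({group_of_pop[p] for p in pops.tolist()})
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_idx = np.arange(n_tot)
    ss_total = _ss_within(d2, all_idx)
    ss_wp = 0.0
    pop_sizes = {}
    for p in pops:
        idx = all_idx[pop_labels == p]
        pop_sizes[int(p)] = idx.size
        ss_wp += _ss_within(d2, idx)
    ss_wg = 0.0
    group_sizes = {}
    for g in groups:
        idx = all_idx[np.isin(pop_labels, [p for p in pops if group_of_pop[int(p)] == g])]
        group_sizes[g] = idx.size
        ss_wg += _ss_within(d2, idx)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    n_pops, n_groups = len(pops), len(groups)
    df_ag, df_ap, df_wp = n_groups - 1, n_pops - n_groups, n_tot - n_pops
    if df_ap <= 0 or df_wp <= 0:
        raise ValueError("need >=2 populations per group and >1 individual per population")
    sizes = np.array([pop_sizes[int(p)] for p in pops], dtype=float)
    gsz = np.array([group_sizes[g] for g in groups], dtype=float)
    sum_n2_by_group = {
        g: sum(pop_sizes[int(p)] ** 2 for p in pops if group_of_pop[int(p)] == g)
        for g in groups
    }
    n1 = (n_tot - sum(sum_n2_by_group[g] / group_sizes[g] for g in groups)) / df_ap
    n2 = (sum(sum_n2_by_group[g] / group_sizes[g] for g in groups)
          - np.sum(sizes ** 2) / n_tot) / df_ag
    n3 = (n_tot - np.sum(gsz ** 2) / n_tot) / df_ag

    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    ms_ag = ss_ag / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def amova_three_level(
    d2: np.ndarray,
    pop_labels: np.ndarray,
    group_of_pop: dict[int, int],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """Three-level AMOVA (groups / populations / individuals) with
    layer-specific permutation tests.

    ``d2`` is the matrix of squared inter-individual distances, ``pop_labels``
    assigns each individual to a population (integers), and ``group_of_pop``
    maps populations to groups.  Permutations: whole populations among groups
    (Phi_CT), individuals among populations within groups (Phi_SC), and
    individuals among all populations (Phi_ST).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop_labels = np.asarray(pop_labels)
    sa, sb, sc = amova_components(d2, pop_labels, group_of_pop)
    total = sa + sb + sc
    phi_ct = _safe_div(sa, total)
    phi_sc = _safe_div(sb, sb + sc)
    phi_st = _safe_div(sa + sb, total)
    negative = min(sa, sb, sc) < 0
    if negative:
        warnings.warn("negative AMOVA variance component(s) reported as-is",
                      stacklevel=2)

    pops = np.unique(pop_labels).tolist()
    group_ids = sorted(set(group_of_pop.values()))

    def phis(labels: np.ndarray, g_of_p: dict[int, int]) -> tuple[float, float, float]:
        a, b, c = amova_components(d2, labels, g_of_p)
        return _safe_div(a, a + b + c), _safe_div(b, b + c), _safe_div(a + b, a + b + c)

    c_ct = c_sc = c_st = 0
    for _ in range(n_perm):
        # Phi_ST: permute individuals among all populations
        perm = rng.permutation(pop_labels)
        if phis(perm, group_of_pop)[2] >= phi_st - 1e-12:
            c_st += 1
        # Phi_CT: permute populations among groups (keep group sizes in pops)
        perm_pops = rng.permutation(pops)
        g_perm = {int(p): group_of_pop[int(q)] for p, q in zip(perm_pops, pops)}
        if phis(pop_labels, g_perm)[0] >= phi_ct - 1e-12:
            c_ct += 1
        # Phi_SC: permute individuals among populations within each group
        labels = pop_labels.copy()
        for g in group_ids:
            mask = np.isin(pop_labels, [p for p in pops if group_of_pop[int(p)] == g])
            labels[mask] = rng.permutation(pop_labels[mask])
        if phis(labels, group_of_pop)[1] >= phi_sc - 1e-12:
            c_sc += 1

    p = {
        "phi_ct": (1 + c_ct) / (n_perm + 1),
        "phi_sc": (1 + c_sc) / (n_perm + 1),
        "phi_st": (1 + c_st) / (n_perm + 1),
    }
    pct = {
        "among_lineages": 100.0 * sa / total,
        "among_populations": 100.0 * sb / total,
        "within_populations": 100.0 * sc / total,
    }
    return AmovaResult(pct, phi_ct, phi_sc, phi_st, p, negative)


def nssr_distance_matrix(dataset: GenotypeDataset,
                         metric: str = "identity") -> tuple[np.ndarray, np.ndarray]:
    """Squared inter-individual distances for nuclear microsatellites.

    ``identity`` counts differing alleles per locus (F_ST-like); ``size``
    uses squared repeat-count differences under the best pairing of the two
    allele copies (R_ST-like).  Loci missing in either individual are skipped
    and the sum rescaled to the full locus count.  Returns (d2, pop_labels).
    """
    genos = np.concatenate([dataset.genotypes[p] for p in dataset.populations])
    pop_labels = np.concatenate([
        np.full(dataset.genotypes[p].shape[0], i)
        for i, p in enumerate(dataset.populations)
    ])
    n = genos.shape[0]
    n_loci = dataset.n_loci
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.0
            used = 0
            for l in range(n_loci):
                a = genos[i, l]
                b = genos[j, l]
                if (a == 0).any() or (b == 0).any():
                    continue
                used += 1
                if metric == "identity":
                    shared = 0
                    bb = list(b)
                    for x in a:
                        if x in bb:
                            bb.remove(x)
                            shared += 1
                    s += 2 - shared
                else:
                    d_same = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
                    d_swap = (a[0] - b[1]) ** 2 + (a[1] - b[0]) ** 2
                    s += min(d_same, d_swap)
            if used:
                s *= n_loci / used
            d2[i, j] = d2[j, i] = s
    return d2, pop_labels


def haplotype_distance_matrix(alignment: HaplotypeAlignment) -> tuple[np.ndarray, np.ndarray]:
    """0/1 haplotype-identity distances for cpDNA sequences, plus pop labels."""
    idx, pops = alignment.haplotype_indices()
    pop_index = {p: i for i, p in enumerate(alignment.populations)}
    labels = np.array([pop_index[p] for p in pops])
    d2 = (idx[:, None] != idx[None, :]).astype(float)
    return d2, labels


# ---------------------------------------------------------------------------
# chloroplast sequence summaries


@dataclass
class CpDnaSummary:
    s: int                      # segregating sites
    pi: float                   # mean pairwise differences per sequence pair
    tajima_d: float | None
    tajima_p: float | None
    n_sequences: int
    masked_columns: int = 0


def _encode_alignment(seqs: list[str]) -> np.ndarray:
    arr = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])
    return arr


_ACGT = frozenset(b"ACGT")


def repeat_column_mask(seqs: list[str], mono_min: int = 5, di_min_units: int = 3) -> np.ndarray:
    """Columns inside mono- or di-nucleotide repeat runs, in any sequence.

    Mononucleotide runs of >= ``mono_min`` identical bases and dinucleotide
    repeats of >= ``di_min_units`` units are flagged; such stretches mutate by
    slippage and are prone to homoplasy."""
    L = len(seqs[0])
    mask = np.zeros(L, dtype=bool)
    for s in seqs:
        s = s.upper()
        i = 0
        while i < L:
            j = i
            while j < L and s[j] == s[i] and s[i] in "ACGT":
                j += 1
            if j - i >= mono_min:
                mask[i:j] = True
            i = max(j, i + 1)
        # dinucleotide repeats
        i = 0
        while i + 1 < L:
            unit = s[i:i + 2]
            if unit[0] == unit[1] or not set(unit) <= set("ACGT"):
                i += 1
                continue
            j = i + 2
            while j + 1 < L and s[j:j + 2] == unit:
                j += 2
            n_units = (j - i) // 2
            if n_units >= di_min_units:
                mask[i:i + 2 * n_units] = True
                i = j
            else:
                i += 1
    return mask


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajima_d_from_counts(n: int, s: int, pi: float) -> float | None:
    """Tajima's D from sample size, segregating sites, and mean pairwise
    differences; None when there is no polymorphism."""
    if s == 0:
        return None
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        return None   # e.g. n = 2: the test has no power and D is undefined
    return (pi - s / c["a1"]) / math.sqrt(var)


def _seg_and_pi(arr: np.ndarray) -> tuple[int, float]:
    """Segregating sites and mean pairwise differences, ignoring gap/ambiguity
    characters (excluded per column for S and per pair of sequences for pi)."""
    n = arr.shape[0]
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    s = 0
    for col in range(arr.shape[1]):
        vals = arr[valid[:, col], col]
        if vals.size >= 2 and np.unique(vals).size >= 2:
            s += 1
    total = 0.0
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        total += int(np.sum(arr[i, both] != arr[j, both]))
    pi = total / (n * (n - 1) / 2)
    return s, pi


def cpdna_summary(
    alignment: HaplotypeAlignment,
    mask_repeats: bool = False,
    n_null: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CpDnaSummary:
    """S, pi and Tajima's D for an alignment, with a fixed-S coalescent null.

    With ``mask_repeats`` the columns inside mono-/di-nucleotide repeat runs
    are excluded before computing statistics.  The Tajima p-value is the
    two-sided tail probability of |D| under neutral coalescent genealogies
    conditioned on the observed n and S.
    """
    seqs = [s for _, _, s in alignment.all_sequences()]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    arr = _encode_alignment(seqs)
    masked = 0
    if mask_repeats:
        mask = repeat_column_mask(seqs)
        masked = int(mask.sum())
        arr = arr[:, ~mask]
    s, pi = _seg_and_pi(arr)
    d = tajima_d_from_counts(arr.shape[0], s, pi)
    p = None
    if d is not None and n_null > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = simulate_tajima_null(arr.shape[0], s, n_null, rng)
        null = null[np.isfinite(null)]
        if null.size:
            p = float(np.mean(np.abs(null) >= abs(d)))
    return CpDnaSummary(s=s, pi=pi, tajima_d=d, tajima_p=p,
                        n_sequences=arr.shape[0], masked_columns=masked)


def simulate_tajima_null(n: int, s: int, n_reps: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Null distribution of Tajima's D conditioned on n and S.

    Neutral Kingman genealogies are simulated; S mutations are placed on
    branches with probability proportional to branch length, and each
    mutation on a branch with i descendant tips contributes i(n-i) pairwise
    differences."""
    from .coalescent import DemographyModel, SampleConfig, simulate_genealogy

    model = DemographyModel(kind="SNM", n_cur=1.0)
    cfg = SampleConfig(n_diploids=(1,), n_cp=(n,), n_loci=1, seq_length=1)
    out = np.empty(n_reps)
    pairs = n * (n - 1) / 2
    for rep in range(n_reps):
        gen = simulate_genealogy(model, cfg, "chloroplast", rng)
        blen = gen.branch_lengths()
        # descendant tip count below each branch
        desc = np.zeros(gen.n_nodes, dtype=np.int64)
        desc[: gen.n_tips] = 1
        for v in range(gen.n_nodes - 1):
            desc[gen.parent[v]] += desc[v]
        counts = rng.multinomial(s, blen / blen.sum())
        i_m = desc[: gen.n_nodes - 1]
        pi = float(np.sum(counts * i_m * (n - i_m)) / pairs)
        d = tajima_d_from_counts(n, s, pi)
        out[rep] = d if d is not None else np.nan
    return out


# ---------------------------------------------------------------------------
# Evanno's Delta K


def evanno_delta_k(logprob_table: dict[int, list[float]]) -> dict[int, float | None]:
    """Second-difference statistic Delta K for choosing the cluster number.

    ``logprob_table`` maps K to replicate log-probabilities (equal replicate
    counts).  Delta K(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r L(K)
    for interior K; None where the replicate standard deviation is zero.
    """
    ks = sorted(logprob_table)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    n_reps = {len(v) for v in logprob_table.values()}
    if len(n_reps) != 1 or n_reps.pop() < 2:
        raise ValueError("need the same number (>= 2) of replicates for every K")
    table = {k: np.asarray(v, dtype=float) for k, v in logprob_table.items()}
    out: dict[int, float | None] = {}
    for k in ks[1:-1]:
        sd = float(np.std(table[k], ddof=1))
        if sd == 0.0:
            warnings.warn(f"zero replicate SD at K={k}: Delta K undefined",
                          stacklevel=2)
            out[k] = None
            continue
        second = np.abs(table[k + 1] - 2 * table[k] + table[k - 1])
        out[k] = float(np.mean(second) / sd)
    return out


# ---------------------------------------------------------------------------
# table builders (per-population diversity, per-locus differentiation)


def diversity_table(
    dataset: GenotypeDataset,
    g: int = 8,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-population diversity: A_R (rarefied to g copies), H_E, F_IS and the
    HWE randomization p-value (raw and Bonferroni-adjusted)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for pop in dataset.populations:
        ar_vals = []
        for locus in range(dataset.n_loci):
            try:
                ar_vals.append(allelic_richness(dataset, locus, pop, g=g))
            except ValueError:
                warnings.warn(
                    f"population {pop!r} has < {g} copies at locus "
                    f"{dataset.loci[locus]!r}: excluded from A_R", stacklevel=2)
        he_vals = []
        for locus in range(dataset.n_loci):
            a = dataset.alleles(pop, locus)
            if a.size >= 2:
                he_vals.append(unbiased_gene_diversity(a))
        fis, p = hwe_randomization_test(dataset, pop, n_perm=n_perm, seed=rng)
        rows.append({
            "population": pop,
            "lineage": dataset.lineage.get(pop),
            "n_individuals": dataset.genotypes[pop].shape[0],
            "A_R": float(np.mean(ar_vals)) if ar_vals else np.nan,
            "H_E": float(np.mean(he_vals)) if he_vals else np.nan,
            "F_IS": fis,
            "hwe_p": p,
        })
    df = pd.DataFrame(rows)
    df["hwe_p_bonferroni"] = bonferroni(df["hwe_p"].to_numpy())
    return df


def differentiation_table(
    dataset: GenotypeDataset,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-locus differentiation (A, H_S, H_T, F_ST, G'_ST, D, permutation p)
    plus the overall row computed from multilocus averages.

    The overall H_S and H_T are unweighted means over loci; the overall
    G'_ST and D are computed from those multilocus means, and the overall
    F_ST is the ratio of summed variance components."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = dataset.n_populations
    rows = []
    comp_sums = np.zeros(3)
    for li, locus in enumerate(dataset.loci):
        alleles = np.unique(np.concatenate(
            [dataset.alleles(p, li) for p in dataset.populations]))
        h_s, h_t = gene_diversities(dataset, li)
        comps = wc_components_locus(
            [dataset.pop_genotypes(p, li) for p in dataset.populations])
        comp_sums += comps
        fst = comps[0] / sum(comps) if sum(comps) else np.nan
        p_val = _locus_permutation_p(dataset, li, fst, n_perm, rng)
        rows.append({
            "locus": locus, "A": alleles.size, "H_S": h_s, "H_T": h_t,
            "F_ST": fst, "Gst_prime": gst_prime_hedrick(h_s, h_t, k),
            "D": jost_d(h_s, h_t, k), "perm_p": p_val,
        })
    df = pd.DataFrame(rows)
    hs_bar = float(df["H_S"].mean())
    ht_bar = float(df["H_T"].mean())
    overall = {
        "locus": "overall", "A": float(df["A"].mean()),
        "H_S": hs_bar, "H_T": ht_bar,
        "F_ST": comp_sums[0] / comp_sums.sum(),
        "Gst_prime": gst_prime_hedrick(hs_bar, ht_bar, k),
        "D": jost_d(hs_bar, ht_bar, k), "perm_p": np.nan,
    }
    return pd.concat([df, pd.DataFrame([overall])], ignore_index=True)


def _locus_permutation_p(dataset: GenotypeDataset, locus: int, fst_obs: float,
                         n_perm: int, rng: np.random.Generator) -> float:
    """Permute individuals (genotypes) among populations; one-sided p for
    F_ST > 0 at this locus."""
    if not np.isfinite(fst_obs):
        return float("nan")
    genos = np.concatenate([dataset.pop_genotypes(p, locus)
                            for p in dataset.populations])
    sizes = [dataset.genotypes[p].shape[0] for p in dataset.populations]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(genos.shape[0])
        split = np.split(perm, np.cumsum(sizes)[:-1])
        comps = wc_components_locus([genos[s] for s in split])
        f = comps[0] / sum(comps) if sum(comps) else -np.inf
        if f >= fst_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
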