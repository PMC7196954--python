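"""The 8- and 19-element ABC summary-statistic vectors.

Single-lineage vector (order fixed):
    mean_K, sd_K      -- number of alleles per locus
    mean_H, sd_H      -- unbiased expected heterozygosity per locus
    mean_R, sd_R      -- allele size range (max - min repeat count) per locus
    cp_S, cp_pi       -- chloroplast segregating sites and mean pairwise
                         differences

Two-lineage vector: the 8 northern stats, the 8 southern stats, the mean over
loci of the pooled-sample allele size range, the multilocus Weir-Cockerham
F_ST for nSSRs, and the haplotype-frequency F_ST for cpDNA (19 elements).

"Heterozygosity" is the unbiased expected heterozygosity (the Arlequin
summary-statistic convention), not observed heterozygosity.  Standard
deviations are sample SDs (ddof=1) over loci.
"""

from __future__ import annotations

import numpy as np

from .datasets import GenotypeDataset, HaplotypeAlignment
from .stats import (
    unbiased_gene_diversity,
    wc_components_locus,
    wc_fst_haploid,
)

SINGLE_STAT_NAMES = ["mean_K", "sd_K", "mean_H", "sd_H", "mean_R", "sd_R",
                     "cp_S", "cp_pi"]
PAIR_STAT_NAMES = (
    [f"north_{s}" for s in SINGLE_STAT_NAMES]
    + [f"south_{s}" for s in SINGLE_STAT_NAMES]
    + ["pooled_mean_R", "fst_nssr", "fst_cp"]
)


def _locus_stats(alleles: np.ndarray) -> tuple[int, float, int]:
    """(K, H, R) for one locus from an array of gene copies."""
    if alleles.size < 2:
        raise ValueError("need at least 2 gene copies per locus")
    vals = np.unique(alleles)
    k = vals.size
    h = unbiased_gene_diversity(alleles) if k > 1 else 0.0
    r = int(vals.max() - vals.min())
    return k, h, r


def _cp_counts(seqs: np.ndarray) -> tuple[int, float]:
    """(S, pi) from an (n, L) array of base codes."""
    n = seqs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 chloroplast sequences")
    s = int(np.count_nonzero((seqs != seqs[0]).any(axis=0)))
    total = 0
    for i in range(n - 1):
        total += int((seqs[i + 1:] != seqs[i]).sum())
    pi = total / (n * (n - 1) / 2)
    return s, pi


def sumstats_single(msat_loci: list[np.ndarray], cp_seqs: np.ndarray) -> np.ndarray:
    """8-element vector from per-locus allele arrays and a cp sequence array."""
    ks, hs, rs = zip(*(_locus_stats(a) for a in msat_loci))
    s, pi = _cp_counts(cp_seqs)
    return np.array([
        np.mean(ks), np.std(ks, ddof=1),
        np.mean(hs), np.std(hs, ddof=1),
        np.mean(rs), np.std(rs, ddof=1),
        s, pi,
    ])


def sumstats_pair(
    msat_north: list[np.ndarray],
    msat_south: list[np.ndarray],
    cp_north: np.ndarray,
    cp_south: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """19-element vector for the two-lineage (divergence) analysis.

    Nuclear F_ST pairs gene copies into diploid individuals at random union
    of gametes (copies are exchangeable under the coalescent, so consecutive
    pairing is used).
    """
    v_n = sumstats_single(msat_north, cp_north)
    v_s = sumstats_single(msat_south, cp_south)
    pooled_r = np.mean([
        int(max(a.max(), b.max()) - min(a.min(), b.min()))
        for a, b in zip(msat_north, msat_south)
    ])
    num = den = 0.0
    for a, b in zip(msat_north, msat_south):
        comps = wc_components_locus([a.reshape(-1, 2), b.reshape(-1, 2)])
        num += comps[0]
        den += sum(comps)
    fst_nssr = num / den if den else 0.0
    fst_cp = _haplotype_fst(cp_north, cp_south)
    return np.concatenate([v_n, v_s, [pooled_r, fst_nssr, fst_cp]])


def _haplotype_fst(cp_north: np.ndarray, cp_south: np.ndarray) -> float:
    all_seqs = np.concatenate([cp_north, cp_south])
    _, hap_idx = np.unique(all_seqs, axis=0, return_inverse=True)
    n = cp_north.shape[0]
    return wc_fst_haploid([hap_idx[:n], hap_idx[n:]])


# ---------------------------------------------------------------------------
# dataset front-ends (observed data)


def _pooled_msat(dataset: GenotypeDataset, pops: list[str]) -> list[np.ndarray]:
    out = []
    for li in range(dataset.n_loci):
        out.append(np.concatenate([dataset.alleles(p, li) for p in pops]))
    return out


def _cp_array(alignment: HaplotypeAlignment, pops: list[str]) -> np.ndarray:
    seqs = [s for p in pops for _, s in alignment.sequences.get(p, [])]
    if not seqs:
        raise ValueError("no chloroplast sequences in the requested populations")
    return np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])


def sumstats_single_dataset(
    dataset: GenotypeDataset,
    alignment: HaplotypeAlignment,
    populations: list[str] | None = None,
) -> np.ndarray:
    """Observed 8-vector, pooling the listed populations into one deme."""
    pops = populations if populations is not None else dataset.populations
    return sumstats_single(_pooled_msat(dataset, pops), _cp_array(alignment, pops))


def sumstats_pair_dataset(
    dataset: GenotypeDataset,
    alignment: HaplotypeAlignment,
    north_pops: list[str],
    south_pops: list[str],
) -> np.ndarray:
    """Observed 19-vector, pooling each lineage's populations into one deme.

    Diploid genotypes are used as sampled for the nuclear F_ST; missing
    alleles are dropped before pooling per-locus copies."""
    msat_n = _pooled_msat(dataset, north_pops)
    msat_s = _pooled_msat(dataset, south_pops)
    v_n = sumstats_single(msat_n, _cp_array(alignment, north_pops))
    v_s = sumstats_single(msat_s, _cp_array(alignment, south_pops))
    pooled_r = np.mean([
        int(max(a.max(), b.max()) - min(a.min(), b.min()))
        for a, b in zip(msat_n, msat_s)
    ])
    num = den = 0.0
    for li in range(dataset.n_loci):
        north_g = np.concatenate([dataset.pop_genotypes(p, li) for p in north_pops])
        south_g = np.concatenate([dataset.pop_genotypes(p, li) for p in south_pops])
        comps = wc_components_locus([north_g, south_g])
        num += comps[0]
        den += sum(comps)
    fst_nssr = num / den if den else 0.0
    fst_cp = _haplotype_fst(_cp_array(alignment, north_pops),
                            _cp_array(alignment, south_pops))
    return np.concatenate([v_n, v_s, [pooled_r, fst_nssr, fst_cp]])
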