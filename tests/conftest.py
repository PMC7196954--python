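"""Shared fixtures: tiny deterministic datasets built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from kobuspop.datasets import GenotypeDataset, HaplotypeAlignment


def build_dataset(pop_genos: dict[str, list[list[tuple[int, int]]]],
                  loci: list[str] | None = None,
                  lineage: dict[str, str] | None = None,
                  coords: dict[str, tuple[float, float]] | None = None
                  ) -> GenotypeDataset:
    """Dataset from {pop: [per-individual [(a, b) per locus]]} literals."""
    pops = list(pop_genos)
    n_loci = len(pop_genos[pops[0]][0])
    genotypes = {
        p: np.array(rows, dtype=np.int64).reshape(len(rows), n_loci, 2)
        for p, rows in pop_genos.items()
    }
    return GenotypeDataset(
        populations=pops,
        loci=loci or [f"L{i+1}" for i in range(n_loci)],
        genotypes=genotypes,
        lineage=lineage or {},
        coords=coords or {},
    )


def build_alignment(pop_seqs: dict[str, list[str]]) -> HaplotypeAlignment:
    return HaplotypeAlignment(
        populations=list(pop_seqs),
        sequences={p: [(f"{p}_cp{i+1}", s) for i, s in enumerate(seqs)]
                   for p, seqs in pop_seqs.items()},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def hw_dataset(rng):
    """Two populations drawn at Hardy-Weinberg with shared allele frequencies."""
    freqs = np.array([0.4, 0.3, 0.2, 0.1])
    alleles = np.arange(10, 14)

    def sample_pop(n):
        g = rng.choice(alleles, size=(n, 3, 2), p=freqs)
        return [[tuple(g[i, l]) for l in range(3)] for i in range(n)]

    return build_dataset({"A": sample_pop(40), "B": sample_pop(40)})
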