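"""In-memory containers for the two marker datasets.

``GenotypeDataset`` holds diploid microsatellite genotypes as repeat counts,
indexed by population / individual / locus, with optional lineage labels and
geographic coordinates.  Missing alleles are coded 0 (the GenePop "000"
convention).  ``HaplotypeAlignment`` holds aligned chloroplast sequences per
population.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

IUPAC = set("ACGTURYSWKMBDHVN-")


@dataclass
class GenotypeDataset:
    """Diploid repeat-count genotypes for a set of populations.

    ``genotypes[pop]`` is an ``(n_individuals, n_loci, 2)`` integer array of
    repeat counts with 0 marking a missing allele.  Allele order within a
    genotype is not meaningful.
    """

    populations: list[str]
    loci: list[str]
    genotypes: dict[str, np.ndarray]
    individuals: dict[str, list[str]] = field(default_factory=dict)
    lineage: dict[str, str] = field(default_factory=dict)
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for pop in self.populations:
            g = self.genotypes[pop]
            if g.ndim != 3 or g.shape[1] != len(self.loci) or g.shape[2] != 2:
                raise ValueError(f"bad genotype array shape for population {pop!r}")
            if g.shape[0] == 0:
                raise ValueError(f"population {pop!r} is empty")
            if (g < 0).any():
                raise ValueError("repeat counts must be non-negative (0 = missing)")
            if pop not in self.individuals:
                self.individuals[pop] = [f"{pop}_{i+1}" for i in range(g.shape[0])]

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str | int) -> int:
        return locus if isinstance(locus, int) else self.loci.index(locus)

    def alleles(self, pop: str, locus: str | int) -> np.ndarray:
        """Non-missing gene copies for one population at one locus."""
        li = self.locus_index(locus)
        a = self.genotypes[pop][:, li, :].ravel()
        return a[a != MISSING]

    def allele_counts(self, pop: str, locus: str | int) -> Counter:
        return Counter(self.alleles(pop, locus).tolist())

    def pop_genotypes(self, pop: str, locus: str | int) -> np.ndarray:
        """(n_individuals, 2) genotypes at one locus, missing rows included."""
        return self.genotypes[pop][:, self.locus_index(locus), :]

    def subset(self, populations: list[str]) -> "GenotypeDataset":
        return GenotypeDataset(
            populations=list(populations),
            loci=list(self.loci),
            genotypes={p: self.genotypes[p] for p in populations},
            individuals={p: list(self.individuals[p]) for p in populations},
            lineage={p: self.lineage[p] for p in populations if p in self.lineage},
            coords={p: self.coords[p] for p in populations if p in self.coords},
        )

    def lineage_populations(self, lineage: str) -> list[str]:
        return [p for p in self.populations if self.lineage.get(p) == lineage]

    def equals(self, other: "GenotypeDataset") -> bool:
        if self.populations != other.populations or self.loci != other.loci:
            return False
        for pop in self.populations:
            a = np.sort(self.genotypes[pop], axis=2)
            b = np.sort(other.genotypes[pop], axis=2)
            if a.shape != b.shape or (a != b).any():
                return False
            if self.individuals[pop] != other.individuals[pop]:
                return False
        return True


@dataclass
class HaplotypeAlignment:
    """Aligned chloroplast sequences grouped by population."""

    populations: list[str]
    sequences: dict[str, list[tuple[str, str]]]  # pop -> [(seq_id, sequence)]
    length: int = 0

    def __post_init__(self):
        lengths = {len(s) for seqs in self.sequences.values() for _, s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if lengths:
            self.length = lengths.pop()
        for seqs in self.sequences.values():
            for sid, s in seqs:
                bad = set(s.upper()) - IUPAC
                if bad:
                    raise ValueError(
                        f"non-IUPAC characters {sorted(bad)} in sequence {sid!r}"
                    )

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.sequences.values())

    def all_sequences(self) -> list[tuple[str, str, str]]:
        """Flat list of (population, seq_id, sequence)."""
        return [(p, sid, s) for p in self.populations for sid, s in self.sequences[p]]

    def gap_columns(self) -> np.ndarray:
        """Boolean mask of columns containing a gap in any sequence."""
        mask = np.zeros(self.length, dtype=bool)
        for _, _, s in self.all_sequences():
            mask |= np.frombuffer(s.encode(), dtype=np.uint8) == ord("-")
        return mask

    def collapse_haplotypes(self) -> pd.DataFrame:
        """Merge identical sequences into haplotypes.

        Returns a table with one row per (haplotype, population) giving the
        count in that population; haplotypes are labeled ``hap1`` .. in order
        of first appearance.  Populations without sequences get no rows.
        """
        labels: dict[str, str] = {}
        rows = []
        for pop, sid, s in self.all_sequences():
            key = s.upper()
            if key not in labels:
                labels[key] = f"hap{len(labels) + 1}"
            rows.append({"population": pop, "haplotype": labels[key]})
        if not rows:
            return pd.DataFrame(columns=["haplotype", "population", "count"])
        df = (
            pd.DataFrame(rows)
            .value_counts(["haplotype", "population"])
            .rename("count")
            .reset_index()
            .sort_values(["haplotype", "population"])
            .reset_index(drop=True)
        )
        return df

    def haplotype_indices(self) -> tuple[np.ndarray, list[str]]:
        """Per-sequence haplotype index and the population of each sequence."""
        seen: dict[str, int] = {}
        idx, pops = [], []
        for pop, _, s in self.all_sequences():
            key = s.upper()
            idx.append(seen.setdefault(key, len(seen)))
            pops.append(pop)
        return np.array(idx, dtype=np.int64), pops
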