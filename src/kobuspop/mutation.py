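"""Mutation models layered on genealogies, and the hierarchical hyperpriors.

Microsatellites mutate under a generalized stepwise mutation model (GSM):
mutations arrive as a Poisson process along branches and each mutation moves
the repeat count by ``±k`` where ``k`` is geometric,
``P(k = j) = (1 - P_GSM) * P_GSM**(j-1)`` for ``j >= 1``, so
``P(k > 1) = P_GSM`` and ``P_GSM = 0`` recovers the strict stepwise model.

Chloroplast sequences mutate under a finite-sites Jukes–Cantor model at the
fixed rate ``2.0e-9`` substitutions/site/generation over ``L = 3,929`` bp.

The ABC hyperpriors are hierarchical: the 13 loci share a mean mutation rate
(log-uniform across simulations) with per-locus rates Gamma(shape, shape/mean)
and per-locus GSM parameters Beta(a, b) with ``a = 0.5 + 199 * mean_P`` and
``b = a * (1 - mean_P) / mean_P``, which fixes the Beta mean at ``mean_P``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import Genealogy

ROOT_ALLELE = 20  # reference repeat count at the root; all statistics are
                  # translation invariant so the constant is arbitrary
MIN_ALLELE = 1    # reflecting floor: repeat counts below 1 are unphysical

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GsmHyperPrior:
    """Hierarchical hyperparameters of the microsatellite mutation model."""

    mean_mu: float
    shape: float
    mean_p_gsm: float

    def __post_init__(self):
        if self.mean_mu <= 0:
            raise ValueError("mean_mu must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if not (0.0 <= self.mean_p_gsm < 1.0):
            raise ValueError("mean_P_GSM must lie in [0, 1)")

    @property
    def rate(self) -> float:
        return self.shape / self.mean_mu

    @property
    def beta_a(self) -> float:
        return 0.5 + 199.0 * self.mean_p_gsm

    @property
    def beta_b(self) -> float:
        if self.mean_p_gsm == 0.0:
            return float("inf")
        return self.beta_a * (1.0 - self.mean_p_gsm) / self.mean_p_gsm


@dataclass(frozen=True)
class CpMutationModel:
    """Chloroplast substitution model (Jukes–Cantor, fixed clock)."""

    mu: float = 2.0e-9          # substitutions / site / generation
    seq_length: int = 3_929

    def __post_init__(self):
        if self.mu < 0 or self.seq_length <= 0:
            raise ValueError("invalid chloroplast mutation model")


def draw_locus_params(
    hyper: GsmHyperPrior, n_loci: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-locus (mu_l, P_l) from the hierarchical hyperprior."""
    mu = rng.gamma(hyper.shape, scale=hyper.mean_mu / hyper.shape, size=n_loci)
    if hyper.mean_p_gsm == 0.0:
        # degenerate Beta: strict stepwise model at every locus
        p = np.zeros(n_loci)
    else:
        # Beta draws can round to 1.0 when b is small; keep strictly < 1 so
        # the geometric step law stays proper
        p = np.minimum(rng.beta(hyper.beta_a, hyper.beta_b, size=n_loci),
                       1.0 - 1e-9)
    return mu, p


def _preorder(gen: Genealogy) -> np.ndarray:
    """Node ids in an order where parents precede children (root first)."""
    # internal nodes are appended in coalescence (time) order, so reversed
    # node index order already visits parents before children
    return np.arange(gen.n_nodes - 1, -1, -1)


def mutate_microsat(
    gen: Genealogy,
    mu: float,
    p_gsm: float,
    rng: np.random.Generator,
    root_allele: int = ROOT_ALLELE,
) -> np.ndarray:
    """Drop GSM mutations on a genealogy; return tip repeat counts.

    The per-branch net displacement is the sum of signed geometric steps of
    the branch's Poisson(mu * length) mutations.  A reflecting floor at
    ``MIN_ALLELE`` is applied to node values (sizes below the floor are folded
    back), keeping repeat counts physical without an upper bound.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not (0.0 <= p_gsm < 1.0):
        raise ValueError("P_GSM must lie in [0, 1)")
    blen = gen.branch_lengths()
    n_mut = rng.poisson(mu * blen)
    total = int(n_mut.sum())
    net = np.zeros(gen.n_nodes - 1, dtype=np.int64)
    if total:
        steps = rng.geometric(1.0 - p_gsm, size=total)
        signs = rng.integers(0, 2, size=total) * 2 - 1
        branch_of = np.repeat(np.arange(gen.n_nodes - 1), n_mut)
        np.add.at(net, branch_of, steps * signs)
    value = np.empty(gen.n_nodes, dtype=np.int64)
    value[gen.root] = root_allele
    for v in range(gen.n_nodes - 2, -1, -1):
        x = value[gen.parent[v]] + net[v]
        if x < MIN_ALLELE:
            x = 2 * MIN_ALLELE - x  # fold at the floor
        value[v] = x
    return value[: gen.n_tips].copy()


def mutate_sequence(
    gen: Genealogy,
    cp_model: CpMutationModel,
    rng: np.random.Generator,
    root_seq: np.ndarray | None = None,
) -> np.ndarray:
    """Drop finite-sites Jukes–Cantor mutations; return tip sequences.

    Returns an ``(n_tips, L)`` uint8 array of base codes 0..3.  Repeated hits
    at a site overwrite earlier states, so a site contributes at most one
    segregating column regardless of the number of hits.
    """
    L = cp_model.seq_length
    if root_seq is None:
        root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    elif root_seq.shape != (L,):
        raise ValueError("root sequence length does not match the model")
    blen = gen.branch_lengths()
    n_mut = rng.poisson(cp_model.mu * L * blen)
    muts: list[tuple[np.ndarray, np.ndarray]] = []
    for v in range(gen.n_nodes - 1):
        m = int(n_mut[v])
        if m:
            sites = rng.integers(0, L, size=m)
            shifts = rng.integers(1, 4, size=m).astype(np.uint8)
            muts.append((sites, shifts))
        else:
            muts.append((None, None))  # type: ignore[arg-type]

    kids = gen.children()
    seqs = np.empty((gen.n_tips, L), dtype=np.uint8)
    current = root_seq.astype(np.uint8).copy()

    def visit(v: int) -> None:
        if v < gen.n_tips:
            seqs[v] = current
            return
        for c in kids[v]:
            sites, shifts = muts[c]
            if sites is not None:
                saved = current[sites].copy()
                # apply sequentially so repeated hits at one site chain
                for s, sh in zip(sites, shifts):
                    current[s] = (current[s] + sh) % 4
                visit(c)
                current[sites] = saved
            else:
                visit(c)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 2 * gen.n_nodes + 100))
    try:
        visit(gen.root)
    finally:
        sys.setrecursionlimit(old_limit)
    return seqs


def sequences_to_strings(seqs: np.ndarray) -> list[str]:
    """Decode 0..3 base codes to ACGT strings (FASTA-ready)."""
    return [BASES[row].tobytes().decode("ascii") for row in seqs]
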