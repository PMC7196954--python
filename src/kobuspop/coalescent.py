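"""Structured coalescent simulator for single-deme size-change and two-deme
divergence demographies.

The simulator works backward in time on gene copies.  Population sizes are
expressed internally in *gene copies*: a nuclear locus in a monoecious diploid
population of ``N`` individuals has ``2N`` copies, while the chloroplast is
effectively haploid and maternally transmitted, so a population of ``N``
monoecious individuals carries ``N`` chloroplast copies.  Demographic models
are specified in diploid individuals and converted per marker.

Seven demographic models are supported:

``SNM``
    standard neutral model, one deme of constant size ``N_CUR``.
``PGM``
    population growth model, ``N(t) = N_CUR * exp(G * t)`` with ``t``
    measured backward in generations; a negative ``G`` means the population
    grew forward in time (it shrinks toward the past).
``SRM``
    size reduction model, size ``N_CUR`` until time ``T``, then
    ``N_ANC = N_CUR * RN_ANC`` (``RN_ANC > 1``).
``ISM``
    isolation model: northern deme ``N_N`` growing at rate ``G``, southern
    deme ``N_S`` constant, merging at ``T_DIV``.
``IMM``, ``IMM_NS``, ``IMM_SN``
    isolation with (bidirectional / one-way) migration; ``Nm_NS`` and
    ``Nm_SN`` are numbers of migrants per generation in the backward-in-time
    direction, converted to per-lineage rates ``Nm / N`` of the source deme.
    For chloroplast loci migration rates are multiplied by ``beta`` in
    ``[0, 1]`` because only seed movement carries the chloroplast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

ModelKind = Literal["SNM", "PGM", "SRM", "ISM", "IMM", "IMM_NS", "IMM_SN"]
Marker = Literal["nuclear", "chloroplast"]

SIZE_CHANGE_MODELS = ("SNM", "PGM", "SRM")
DIVERGENCE_MODELS = ("ISM", "IMM", "IMM_NS", "IMM_SN")
ALL_MODELS = SIZE_CHANGE_MODELS + DIVERGENCE_MODELS


@dataclass(frozen=True)
class DemographyModel:
    """Tagged structural-parameter set for one demographic model.

    Sizes are diploid individuals; times are generations.  Only the fields of
    the declared ``kind`` may be set; :meth:`validate` enforces this.
    """

    kind: ModelKind
    n_cur: float | None = None
    growth: float | None = None      # G: backward exponential rate
    t_change: float | None = None    # T (SRM)
    rn_anc: float | None = None      # RN_ANC > 1 (SRM)
    n_north: float | None = None
    n_south: float | None = None
    t_div: float | None = None
    nm_ns: float = 0.0               # migrants/generation, backward N->S
    nm_sn: float = 0.0               # migrants/generation, backward S->N
    beta: float = 1.0                # cpDNA migration scaling in [0, 1]
    ancestral_rule: Literal["south", "sum"] = "south"

    _FIELDS_BY_KIND = {
        "SNM": {"n_cur"},
        "PGM": {"n_cur", "growth"},
        "SRM": {"n_cur", "t_change", "rn_anc"},
        "ISM": {"n_north", "n_south", "t_div", "growth"},
        "IMM": {"n_north", "n_south", "t_div", "growth", "nm_ns", "nm_sn", "beta"},
        "IMM_NS": {"n_north", "n_south", "t_div", "growth", "nm_ns", "beta"},
        "IMM_SN": {"n_north", "n_south", "t_div", "growth", "nm_sn", "beta"},
    }

    def validate(self) -> "DemographyModel":
        if self.kind not in ALL_MODELS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        allowed = self._FIELDS_BY_KIND[self.kind]
        structural = {
            "n_cur": self.n_cur, "growth": self.growth, "t_change": self.t_change,
            "rn_anc": self.rn_anc, "n_north": self.n_north, "n_south": self.n_south,
            "t_div": self.t_div,
        }
        for name in allowed & structural.keys():
            if structural[name] is None:
                raise ValueError(f"model {self.kind} requires field {name!r}")
        for name, value in structural.items():
            if name not in allowed and value is not None:
                raise ValueError(f"model {self.kind} does not take field {name!r}")
        for name in ("n_cur", "n_north", "n_south"):
            v = structural[name]
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.kind == "SRM":
            if self.rn_anc is None or self.rn_anc <= 1:
                raise ValueError("SRM requires RN_ANC > 1")
            if self.t_change is None or self.t_change <= 0:
                raise ValueError("SRM requires T > 0")
        if self.kind in DIVERGENCE_MODELS:
            if self.t_div is None or self.t_div <= 0:
                raise ValueError("divergence models require T_DIV > 0")
            if self.kind == "ISM" and (self.nm_ns != 0 or self.nm_sn != 0):
                raise ValueError("ISM admits no migration")
            if self.kind == "IMM_NS" and self.nm_sn != 0:
                raise ValueError("IMM_NS admits only N->S migration")
            if self.kind == "IMM_SN" and self.nm_ns != 0:
                raise ValueError("IMM_SN admits only S->N migration")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.nm_ns < 0 or self.nm_sn < 0:
            raise ValueError("migration rates must be non-negative")
        return self

    @property
    def n_demes(self) -> int:
        return 2 if self.kind in DIVERGENCE_MODELS else 1


@dataclass(frozen=True)
class SampleConfig:
    """Sample sizes per deme plus locus bookkeeping.

    ``n_diploids``/``n_cp`` are tuples with one entry per deme (length 1 for
    size-change models, 2 for divergence models, order north then south).
    """

    n_diploids: tuple[int, ...]
    n_cp: tuple[int, ...]
    n_loci: int = 13
    seq_length: int = 3_929

    def validate(self, n_demes: int) -> "SampleConfig":
        if len(self.n_diploids) != n_demes or len(self.n_cp) != n_demes:
            raise ValueError(f"sample config must list {n_demes} deme(s)")
        if any(n <= 0 for n in self.n_diploids + self.n_cp):
            raise ValueError("sample sizes must be positive")
        if self.n_loci <= 0 or self.seq_length <= 0:
            raise ValueError("n_loci and seq_length must be positive")
        return self


@dataclass
class Genealogy:
    """A realized coalescent tree.

    Nodes ``0 .. n_tips-1`` are tips at time 0; internal nodes are appended in
    coalescence order, so node times are non-decreasing with index and the
    last node is the root.  ``parent[root] == -1``.
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    tip_deme: np.ndarray
    marker: Marker

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (generations)."""
        idx = np.arange(self.n_nodes - 1)
        return self.time[self.parent[idx]] - self.time[idx]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            kids[self.parent[v]].append(v)
        return kids

    def to_newick(self, precision: int = 6) -> str:
        """Newick string with branch lengths in generations (for debugging)."""
        kids = self.children()

        def fmt(v: int) -> str:
            if v < self.n_tips:
                label = f"t{v}"
            else:
                label = ""
            if kids[v]:
                inner = ",".join(fmt(c) for c in kids[v])
                label = f"({inner}){label}"
            if v == self.root:
                return label
            blen = self.time[self.parent[v]] - self.time[v]
            return f"{label}:{blen:.{precision}f}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# low-level engine


@dataclass
class _Deme:
    size: float     # gene copies at epoch reference time t0
    growth: float   # N(t) = size * exp(growth * (t - t0)), t backward
    t0: float = 0.0

    def size_at(self, t: float) -> float:
        if self.growth == 0.0:
            return self.size
        return self.size * math.exp(self.growth * (t - self.t0))


@dataclass(frozen=True)
class _Event:
    """Demographic event at a point in backward time.

    kind 'resize': set deme ``deme`` to ``size`` copies and growth ``growth``.
    kind 'join': move all lineages of deme ``deme`` into deme ``dest`` and
    optionally resize the destination.
    """

    time: float
    kind: Literal["resize", "join"]
    deme: int
    dest: int = 0
    size: float | None = None
    growth: float = 0.0


@dataclass
class _EngineDemography:
    demes: list[_Deme]
    events: list[_Event] = field(default_factory=list)
    # migration[i][j]: per-lineage backward rate of moving from deme i to j
    migration: np.ndarray | None = None


def _draw_coal_time(k: int, deme: _Deme, t: float, rng: np.random.Generator) -> float:
    """Waiting time to next coalescence among k lineages in a deme whose size
    follows ``N(s) = N(t) * exp(G (s - t))`` from the current time onward.

    Uses inversion of the cumulative hazard, which is available in closed form
    for exponential size trajectories."""
    if k < 2:
        return math.inf
    pair_rate = k * (k - 1) / 2.0
    n_now = deme.size_at(t)
    if n_now <= 0:
        raise ValueError("non-positive deme size encountered")
    e = rng.exponential()
    g = deme.growth
    if g == 0.0:
        return e * n_now / pair_rate
    # Lambda(w) = pair_rate / n_now * (1 - exp(-g w)) / g  == e
    arg = 1.0 - e * g * n_now / pair_rate
    if arg <= 0.0:
        return math.inf  # shrinking hazard: coalescence may never happen
    w = -math.log(arg) / g
    if not math.isfinite(w):
        raise OverflowError(
            f"rescaled coalescence time overflowed (G={g}, N={n_now}, k={k})"
        )
    return w


def simulate_genealogy(
    model: DemographyModel,
    sample_config: SampleConfig,
    marker: Marker,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under ``model`` for the given marker.

    Nuclear loci sample ``2 * n_diploids`` copies from demes of ``2N`` copies;
    chloroplast loci sample ``n_cp`` copies from demes of ``N`` copies (the
    species is monoecious, so every individual carries one transmissible
    chloroplast copy).
    """
    model.validate()
    sample_config.validate(model.n_demes)
    if marker == "nuclear":
        samples = tuple(2 * n for n in sample_config.n_diploids)
    else:
        samples = tuple(sample_config.n_cp)
    if model.n_demes == 1:
        # single-deme piecewise-exponential demography: closed-form epoch
        # hazards allow a much faster sampler than the generic engine
        f = 2.0 if marker == "nuclear" else 1.0
        if model.kind == "SNM":
            epochs = [(0.0, f * model.n_cur, 0.0)]
        elif model.kind == "PGM":
            epochs = [(0.0, f * model.n_cur, model.growth)]
        else:  # SRM
            epochs = [(0.0, f * model.n_cur, 0.0),
                      (model.t_change, f * model.n_cur * model.rn_anc, 0.0)]
        return _simulate_single_deme(epochs, samples[0], marker, rng)
    demog = _build_engine_demography(model, marker)
    return _simulate(demog, samples, marker, rng)


def _simulate_single_deme(
    epochs: list[tuple[float, float, float]],
    n_tips: int,
    marker: Marker,
    rng: np.random.Generator,
) -> Genealogy:
    """Kingman coalescent in one deme with piecewise-exponential size.

    ``epochs`` lists (start_time, size_in_copies_at_start, growth); the last
    epoch extends to infinity.  Exact inversion of the per-epoch cumulative
    hazard; unspent hazard carries across epoch boundaries.
    """
    if n_tips < 2:
        raise ValueError("need at least two sampled copies")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    active = list(range(n_tips))
    t = 0.0
    e_idx = 0
    exp_draws = rng.exponential(size=n_tips - 1)
    for next_node in range(n_tips, n_nodes):
        k = len(active)
        pair_rate = k * (k - 1) / 2.0
        e = exp_draws[next_node - n_tips]
        while True:
            t0e, n0, g = epochs[e_idx]
            t_end = epochs[e_idx + 1][0] if e_idx + 1 < len(epochs) else math.inf
            if g == 0.0:
                lam_max = pair_rate * (t_end - t) / n0
                if e <= lam_max or math.isinf(t_end):
                    t = t + e * n0 / pair_rate
                    break
            else:
                a = math.exp(-g * (t - t0e))
                if math.isinf(t_end):
                    lam_max = pair_rate / (g * n0) * a if g > 0 else math.inf
                else:
                    lam_max = pair_rate / (g * n0) * (a - math.exp(-g * (t_end - t0e)))
                if e <= lam_max or (math.isinf(t_end) and g < 0):
                    val = a - e * g * n0 / pair_rate
                    t = t0e - math.log(val) / g
                    break
                if math.isinf(t_end):
                    raise RuntimeError(
                        "lineages cannot coalesce: backward-growing deme "
                        f"(G={g}) exhausted its total hazard")
            e -= lam_max
            t = t_end
            e_idx += 1
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a_node, b_node = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        parent[a_node] = next_node
        parent[b_node] = next_node
        time[next_node] = t
        active.append(next_node)
    return Genealogy(parent=parent, time=time, n_tips=n_tips,
                     tip_deme=np.zeros(n_tips, dtype=np.int64), marker=marker)


def _build_engine_demography(model: DemographyModel, marker: Marker) -> _EngineDemography:
    f = 2.0 if marker == "nuclear" else 1.0
    if model.kind == "SNM":
        return _EngineDemography([_Deme(f * model.n_cur, 0.0)])
    if model.kind == "PGM":
        return _EngineDemography([_Deme(f * model.n_cur, model.growth)])
    if model.kind == "SRM":
        ev = _Event(model.t_change, "resize", 0,
                    size=f * model.n_cur * model.rn_anc, growth=0.0)
        return _EngineDemography([_Deme(f * model.n_cur, 0.0)], [ev])
    # divergence models: deme 0 = north (growing), deme 1 = south (constant)
    demes = [_Deme(f * model.n_north, model.growth or 0.0), _Deme(f * model.n_south, 0.0)]
    mig = np.zeros((2, 2))
    scale = model.beta if marker == "chloroplast" else 1.0
    mig[0, 1] = scale * model.nm_ns / model.n_north
    mig[1, 0] = scale * model.nm_sn / model.n_south
    if model.ancestral_rule == "south":
        anc = f * model.n_south
    else:  # 'sum': northern size at T_DIV plus southern size
        n_n_at_div = model.n_north * math.exp((model.growth or 0.0) * model.t_div)
        anc = f * (n_n_at_div + model.n_south)
    ev = _Event(model.t_div, "join", 0, dest=1, size=anc, growth=0.0)
    return _EngineDemography(demes, [ev], mig)


def _simulate(
    demog: _EngineDemography,
    samples: Sequence[int],
    marker: Marker,
    rng: np.random.Generator,
) -> Genealogy:
    n_tips = int(sum(samples))
    if n_tips < 2:
        raise ValueError("need at least two sampled copies")
    demes = [replace(d) for d in demog.demes]
    events = sorted(demog.events, key=lambda e: e.time)
    mig = None
    if demog.migration is not None and demog.migration.any():
        mig = demog.migration.copy()

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    tip_deme = np.concatenate(
        [np.full(n, d, dtype=np.int64) for d, n in enumerate(samples)]
    )

    # active lineages per deme (node ids)
    active: list[list[int]] = [[] for _ in demes]
    for node, d in enumerate(tip_deme):
        active[d].append(node)
    next_node = n_tips
    t = 0.0
    ev_idx = 0

    while next_node < n_nodes:
        n_active = sum(len(a) for a in active)
        # candidate waiting times
        w_coal = [_draw_coal_time(len(a), demes[d], t, rng) for d, a in enumerate(active)]
        if mig is not None:
            out_rate = mig.sum(axis=1)
            lam = sum(len(a) * out_rate[d] for d, a in enumerate(active))
            w_mig = rng.exponential() / lam if lam > 0 else math.inf
        else:
            w_mig = math.inf
        w_event = events[ev_idx].time - t if ev_idx < len(events) else math.inf

        w_min = min(min(w_coal), w_mig, w_event)
        if not math.isfinite(w_min):
            raise RuntimeError(
                "no finite next event: lineages cannot coalesce under this "
                f"demography (t={t}, active={n_active})"
            )
        if w_event <= w_min:
            ev = events[ev_idx]
            ev_idx += 1
            t = ev.time
            if ev.kind == "resize":
                d = demes[ev.deme]
                demes[ev.deme] = _Deme(ev.size if ev.size is not None else d.size_at(t),
                                       ev.growth, t)
            else:  # join
                active[ev.dest].extend(active[ev.deme])
                active[ev.deme] = []
                dd = demes[ev.dest]
                demes[ev.dest] = _Deme(ev.size if ev.size is not None else dd.size_at(t),
                                       ev.growth, t)
                if mig is not None:
                    mig[ev.deme, :] = 0.0
                    mig[:, ev.deme] = 0.0
                    if not mig.any():
                        mig = None
            continue
        t += w_min
        if w_mig < min(w_coal):
            # choose a lineage weighted by deme out-rates
            weights = np.array([len(a) * out_rate[d] for d, a in enumerate(active)])
            src = rng.choice(len(demes), p=weights / weights.sum())
            dest_p = mig[src] / mig[src].sum()
            dest = rng.choice(len(demes), p=dest_p)
            i = rng.integers(len(active[src]))
            active[dest].append(active[src].pop(i))
            continue
        d = int(np.argmin(w_coal))
        pool = active[d]
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        for idx in sorted((i, j), reverse=True):
            pool.pop(idx)
        parent[a] = next_node
        parent[b] = next_node
        time[next_node] = t
        pool.append(next_node)
        next_node += 1

    return Genealogy(parent=parent, time=time, n_tips=n_tips,
                     tip_deme=tip_deme, marker=marker)


def ancestral_merge_rule(model: DemographyModel, marker: Marker = "nuclear") -> float:
    """Deme size (gene copies) of the merged ancestral population after T_DIV.

    The default rule keeps the southern size (the southern lineage's history
    is size-constant); the alternative 'sum' rule adds the northern size at
    T_DIV.  Both are exposed because the convention is a modeling choice."""
    if model.kind not in DIVERGENCE_MODELS:
        raise ValueError("ancestral merge rule applies to divergence models only")
    demog = _build_engine_demography(model.validate(), marker)
    ev = [e for e in demog.events if e.kind == "join"][0]
    return float(ev.size)
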