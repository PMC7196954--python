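"""File formats, configuration and stage orchestration.

Genotypes travel as GenePop files (3-digit allele codes holding repeat
counts, ``000`` = missing), chloroplast alignments as FASTA, and everything
tabular as CSV with JSON sidecars.  ``run_pipeline`` executes the enabled
stages in their scientific order -- diversity/differentiation statistics,
size-change ABC per lineage, divergence ABC (which consumes the northern
growth-rate posterior mode), then morphology -- and emits a manifest that
fully determines every stochastic output (one global seed spawns fixed
per-stage substreams, so disabling one stage does not shift the randomness
of another).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PopGen.GenePop import read as _genepop_read
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .datasets import GenotypeDataset, HaplotypeAlignment

ALLELE_DIGITS = 3
STAGE_STREAMS = {"synth": 0, "stats": 1, "abc_size_northern": 2,
                 "abc_size_southern": 3, "abc_div": 4, "morph": 5}


# ---------------------------------------------------------------------------
# GenePop


class GenePopError(ValueError):
    pass


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a GenePop file of repeat-count genotypes.

    Populations are named from the shared ``<pop>_`` prefix of their
    individual IDs when one exists, else ``pop1`` ... in file order.
    Raises :class:`GenePopError` on malformed allele fields (naming the
    line) or duplicated individual IDs.
    """
    path = Path(path)
    text = path.read_text()
    _validate_genepop_text(text)
    rec = _genepop_read(_as_handle(text))
    loci = list(rec.loci_list)
    populations, genotypes, individuals = [], {}, {}
    seen_ids: set[str] = set()
    for pi, pop in enumerate(rec.populations):
        names = [name for name, _ in pop]
        for name in names:
            if name in seen_ids:
                raise GenePopError(f"duplicated individual ID {name!r}")
            seen_ids.add(name)
        pop_name = _population_name(names, pi, populations)
        g = np.zeros((len(pop), len(loci), 2), dtype=np.int64)
        for i, (_, genos) in enumerate(pop):
            for li, pair in enumerate(genos):
                a, b = pair[0], pair[1]
                g[i, li, 0] = 0 if a is None else a
                g[i, li, 1] = 0 if b is None else b
        populations.append(pop_name)
        genotypes[pop_name] = g
        individuals[pop_name] = names
    return GenotypeDataset(populations=populations, loci=loci,
                           genotypes=genotypes, individuals=individuals)


def _as_handle(text: str):
    from io import StringIO
    return StringIO(text)


def _population_name(names: list[str], index: int, taken: list[str]) -> str:
    prefixes = {n.rsplit("_", 1)[0] for n in names if "_" in n}
    if len(prefixes) == 1:
        cand = prefixes.pop()
        if cand not in taken:
            return cand
    return f"pop{index + 1}"


def _validate_genepop_text(text: str) -> None:
    lines = text.splitlines()
    if len(lines) < 3:
        raise GenePopError("file too short to be GenePop")
    in_pop = False
    for ln, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped.lower() == "pop":
            in_pop = True
            continue
        if not in_pop or not stripped:
            continue
        if "," not in stripped:
            raise GenePopError(f"line {ln}: expected 'name, genotypes'")
        _, _, rest = stripped.partition(",")
        for tok in rest.split():
            if len(tok) != 2 * ALLELE_DIGITS or not tok.isdigit():
                raise GenePopError(
                    f"line {ln}: malformed genotype field {tok!r} "
                    f"(expected {2 * ALLELE_DIGITS} digits)")


def write_genepop(dataset: GenotypeDataset, path: str | Path,
                  title: str = "kobuspop genotypes") -> None:
    """Write a GenePop file with 3-digit repeat-count allele codes."""
    path = Path(path)
    if max((int(dataset.genotypes[p].max()) for p in dataset.populations),
           default=0) > 10 ** ALLELE_DIGITS - 1:
        raise GenePopError("repeat count does not fit in 3-digit allele codes")
    out = [title]
    out.extend(dataset.loci)
    for pop in dataset.populations:
        out.append("Pop")
        g = dataset.genotypes[pop]
        for i, ind in enumerate(dataset.individuals[pop]):
            fields = [f"{g[i, li, 0]:0{ALLELE_DIGITS}d}{g[i, li, 1]:0{ALLELE_DIGITS}d}"
                      for li in range(dataset.n_loci)]
            out.append(f"{ind}, " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path: str | Path,
                         population_of: dict[str, str] | None = None
                         ) -> HaplotypeAlignment:
    """Read an aligned FASTA into per-population sequence sets.

    Populations come from ``population_of`` (seq-id -> population) when
    given, else from the ``<pop>_`` prefix of each sequence ID.  Length and
    alphabet checks happen in :class:`HaplotypeAlignment`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    sequences: dict[str, list[tuple[str, str]]] = {}
    populations: list[str] = []
    for rec in records:
        sid = rec.id
        pop = (population_of or {}).get(sid) or sid.rsplit("_", 1)[0]
        if pop not in sequences:
            sequences[pop] = []
            populations.append(pop)
        sequences[pop].append((sid, str(rec.seq).upper()))
    return HaplotypeAlignment(populations=populations, sequences=sequences)


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="")
               for _, sid, s in alignment.all_sequences()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular inputs


def read_population_table(path: str | Path) -> tuple[dict[str, str],
                                                     dict[str, tuple[float, float]]]:
    """CSV with columns population, latitude, longitude, lineage."""
    df = pd.read_csv(path)
    need = {"population", "latitude", "longitude", "lineage"}
    if not need <= set(df.columns):
        raise ValueError(f"population table lacks columns {sorted(need - set(df.columns))}")
    lineage = dict(zip(df["population"], df["lineage"]))
    coords = {p: (float(la), float(lo))
              for p, la, lo in zip(df["population"], df["latitude"], df["longitude"])}
    return lineage, coords


def read_leaf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"leaf_id", "tree_id", "population", "length_cm", "width_cm"}
    if not need <= set(df.columns):
        raise ValueError(f"leaf table lacks columns {sorted(need - set(df.columns))}")
    return df


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        raise ValueError("missing cells in covariate table")
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Validated run configuration; one global seed drives everything."""

    out_dir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["stats"])
    genotype_path: str | None = None
    fasta_path: str | None = None
    population_table_path: str | None = None
    leaf_path: str | None = None
    covariate_path: str | None = None
    # statistics settings
    n_perm: int = 1000
    rarefaction_g: int = 8
    # ABC settings
    n_sims_size: int = 20_000
    n_sims_div: int = 50_000
    n_trees: int = 1000
    tolerance_size: float = 0.005
    tolerance_div: float = 0.002
    abc_sample_diploids: int = 50
    abc_sample_cp: int = 8
    ppc_n: int = 0
    # MCMC settings
    chains: int = 4
    iterations: int = 4_000
    burn_in: int = 1_000
    thinning: int = 10
    # overrides for the synthetic-data scenario (synth stage)
    synth_scenario: dict | None = None

    def validate(self) -> "StudyConfig":
        known = {"synth", "stats", "abc_size", "abc_div", "morph"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        for tol in (self.tolerance_size, self.tolerance_div):
            if not (0.0 < tol < 1.0):
                raise ValueError("tolerances must lie in (0, 1)")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if "abc_div" in self.stages and "abc_size" not in self.stages:
            raise ValueError(
                "stage 'abc_div' requires stage 'abc_size' (the divergence "
                "analysis fixes G at the size-change posterior mode)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {})).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible substream for one stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(STAGE_STREAMS[stage],)))


@dataclass
class ResultBundle:
    """Outputs of one pipeline run plus full provenance."""

    stages: dict[str, dict]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hashes = {}
        for stage, artifacts in self.stages.items():
            for name, obj in artifacts.items():
                if isinstance(obj, pd.DataFrame):
                    p = out / f"{name}.csv"
                    obj.to_csv(p, index=False)
                else:
                    p = out / f"{name}.json"
                    p.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                            default=_jsonify))
                hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        self.manifest["output_hashes"] = dict(sorted(hashes.items()))
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: StudyConfig) -> ResultBundle:
    """Execute the enabled stages in order and collect their outputs."""
    from . import abc as abc_mod
    from . import morphology as morph_mod
    from . import stats as stats_mod
    from . import sumstats as ss_mod
    from .coalescent import SampleConfig
    from .synth import SyntheticScenario, generate_genetic_data, generate_leaf_data

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "version": __version__,
    }

    dataset = alignment = leaf_table = covariates = None
    lineage = coords = None

    if "synth" in config.stages:
        rng = config.stage_rng("synth")
        scenario = SyntheticScenario(**(config.synth_scenario or {}),
                                     seed=config.seed)
        dataset, alignment, truth = generate_genetic_data(scenario, rng)
        leaf_table, covariates, leaf_truth = generate_leaf_data(scenario, rng)
        write_genepop(dataset, out / "genotypes.gen")
        write_fasta_alignment(alignment, out / "cpdna.fasta")
        leaf_table.to_csv(out / "leaves.csv", index=False)
        covariates.to_csv(out / "covariates.csv")
        pop_rows = [{"population": p, "latitude": dataset.coords[p][0],
                     "longitude": dataset.coords[p][1],
                     "lineage": dataset.lineage[p]} for p in dataset.populations]
        pd.DataFrame(pop_rows).to_csv(out / "populations.csv", index=False)
        (out / "truth.json").write_text(json.dumps(
            {"genetic": truth, "leaves": leaf_truth}, indent=2, sort_keys=True))
        stages["synth"] = {"synth_scenario": json.loads(scenario.to_json())}
        lineage, coords = dataset.lineage, dataset.coords

    if dataset is None and config.genotype_path:
        dataset = read_genepop(config.genotype_path)
        if config.population_table_path:
            lineage, coords = read_population_table(config.population_table_path)
            dataset.lineage.update(lineage)
            dataset.coords.update(coords)
    if alignment is None and config.fasta_path:
        alignment = read_fasta_alignment(config.fasta_path)
    if leaf_table is None and config.leaf_path:
        leaf_table = read_leaf_table(config.leaf_path)
    if covariates is None and config.covariate_path:
        covariates = read_covariate_table(config.covariate_path)

    if "stats" in config.stages:
        if dataset is None:
            raise ValueError("stats stage needs genotype data")
        rng = config.stage_rng("stats")
        div = stats_mod.diversity_table(dataset, g=config.rarefaction_g,
                                        n_perm=config.n_perm, seed=rng)
        diff = stats_mod.differentiation_table(dataset, n_perm=config.n_perm,
                                               seed=rng)
        artifacts = {"diversity": div, "differentiation": diff}
        if dataset.lineage:
            d2, pops = stats_mod.nssr_distance_matrix(dataset)
            group = {i: 0 if dataset.lineage[p] == "northern" else 1
                     for i, p in enumerate(dataset.populations)}
            amova = stats_mod.amova_three_level(d2, pops, group,
                                                n_perm=min(config.n_perm, 200),
                                                seed=rng)
            artifacts["amova"] = {
                "components_pct": amova.components_pct,
                "phi_ct": amova.phi_ct, "phi_sc": amova.phi_sc,
                "phi_st": amova.phi_st, "p_values": amova.p_values,
            }
        if alignment is not None:
            cp = stats_mod.cpdna_summary(alignment, seed=rng)
            artifacts["cpdna"] = {
                "S": cp.s, "pi": cp.pi, "tajima_d": cp.tajima_d,
                "tajima_p": cp.tajima_p, "n_sequences": cp.n_sequences,
            }
            artifacts["haplotypes"] = alignment.collapse_haplotypes()
        stages["stats"] = artifacts

    g_mode: float | None = None
    obs_cache: dict[str, np.ndarray] = {}
    if "abc_size" in config.stages:
        if dataset is None or alignment is None:
            raise ValueError("abc_size stage needs genotype and cpDNA data")
        stages["abc_size"] = {}
        for lin in ("northern", "southern"):
            pops = dataset.lineage_populations(lin)
            if not pops:
                raise ValueError(f"no populations assigned to lineage {lin!r}")
            obs = ss_mod.sumstats_single_dataset(dataset, alignment, pops)
            obs_cache[lin] = obs
            n_dip = sum(dataset.genotypes[p].shape[0] for p in pops)
            n_cp = sum(len(alignment.sequences.get(p, [])) for p in pops)
            sc = SampleConfig(n_diploids=(n_dip,), n_cp=(n_cp,),
                              n_loci=dataset.n_loci,
                              seq_length=alignment.length)
            report = abc_mod.run_abc_stage(
                list(abc_mod.SIZE_CHANGE_MODELS), obs, sc,
                config.n_sims_size, config.stage_rng(f"abc_size_{lin}"),
                tolerance=config.tolerance_size, n_trees=config.n_trees,
                ppc_n=config.ppc_n)
            stages["abc_size"][f"abc_size_{lin}"] = _stage_report_dict(report)
            if lin == "northern":
                g_mode = float(report.posterior.mode.get("G", 0.0))

    if "abc_div" in config.stages:
        if g_mode is None:
            raise ValueError("abc_div stage requires the abc_size stage output")
        north = dataset.lineage_populations("northern")
        south = dataset.lineage_populations("southern")
        obs = ss_mod.sumstats_pair_dataset(dataset, alignment, north, south)
        sc = SampleConfig(
            n_diploids=(sum(dataset.genotypes[p].shape[0] for p in north),
                        sum(dataset.genotypes[p].shape[0] for p in south)),
            n_cp=(sum(len(alignment.sequences.get(p, [])) for p in north),
                  sum(len(alignment.sequences.get(p, [])) for p in south)),
            n_loci=dataset.n_loci, seq_length=alignment.length)
        report = abc_mod.run_abc_stage(
            list(abc_mod.DIVERGENCE_MODELS), obs, sc, config.n_sims_div,
            config.stage_rng("abc_div"), tolerance=config.tolerance_div,
            n_trees=config.n_trees, fixed={"G": g_mode}, ppc_n=config.ppc_n)
        stages["abc_div"] = {"abc_div": _stage_report_dict(report),
                             "abc_div_g_fixed": {"G": g_mode}}

    if "morph" in config.stages:
        if leaf_table is None:
            raise ValueError("morph stage needs a leaf table")
        rng = config.stage_rng("morph")
        artifacts = {}
        table = leaf_table.copy()
        cov_cols = [c for c in table.columns if c.startswith("BioPC")]
        if not cov_cols:
            if covariates is None:
                raise ValueError("morph stage needs BioPC columns or a "
                                 "covariate table")
            pca = morph_mod.bioclim_pca(covariates)
            biopc = pd.DataFrame(
                pca.scores, index=covariates.index,
                columns=[f"BioPC{i+1}" for i in range(pca.scores.shape[1])])
            table = table.join(biopc, on="population")
            cov_cols = list(biopc.columns)
        if "Q" not in table.columns:
            raise ValueError("leaf table needs a Q (northern membership) column")
        pop_level = table.groupby("population")[cov_cols + ["Q"]].first()
        retained, corr = morph_mod.screen_covariates(
            pop_level[cov_cols], pop_level["Q"].to_numpy())
        artifacts["covariate_screen"] = {
            "correlations_with_Q": corr.to_dict(), "retained": retained}
        spec = morph_mod.BlmmSpec(covariates=retained + ["Q"],
                                  chains=config.chains,
                                  iterations=config.iterations,
                                  burn_in=config.burn_in,
                                  thinning=config.thinning)
        response = "area_cm2" if "area_cm2" in table.columns else "length_cm"
        fit = morph_mod.fit_blmm(table, response, spec, seed=rng)
        artifacts[f"blmm_{response}"] = {
            "mode": fit.mode,
            "hpd": {k: list(v) for k, v in fit.hpd.items()},
            "significant": fit.significant,
            "rhat": fit.rhat,
            "converged": fit.converged,
        }
        artifacts["variety_calls"] = morph_mod.classify_variety(table)
        stages["morph"] = artifacts

    bundle = ResultBundle(stages, manifest)
    bundle.write(out)
    return bundle


def _stage_report_dict(report) -> dict:
    d = {
        "selected_model": report.model_choice.selected,
        "vote_share": report.model_choice.vote_share,
        "posterior_probability": report.model_choice.posterior_probability,
        "oob_error": report.model_choice.oob_error,
        "posterior_mode": report.posterior.mode,
        "posterior_hpd": {k: list(v) for k, v in report.posterior.hpd.items()},
    }
    if report.ppc is not None:
        d["ppc"] = report.ppc.table.to_dict(orient="records")
    return d
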