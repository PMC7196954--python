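"""Sequential approximate Bayesian computation.

Stage 1 fits the three single-deme size-change models (SNM / PGM / SRM) to
each lineage; stage 2 fixes the growth rate G at the northern posterior mode
and compares the four divergence models (ISM / IMM / IMM_NS / IMM_SN) on the
joint two-lineage data.  Model choice uses a random-forest classifier on the
summary statistics with the posterior probability of the selected model
estimated by a second regression forest trained on out-of-bag
misclassification indicators.  Parameter estimation uses rejection on
standardized Euclidean distance followed by regression adjustment on a logit
scale bounded by the prior limits, so adjusted draws can never leave the
prior support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalescent import (
    DIVERGENCE_MODELS,
    SIZE_CHANGE_MODELS,
    DemographyModel,
    SampleConfig,
    simulate_genealogy,
)
from .mutation import (
    CpMutationModel,
    GsmHyperPrior,
    draw_locus_params,
    mutate_microsat,
    mutate_sequence,
)
from .sumstats import PAIR_STAT_NAMES, SINGLE_STAT_NAMES, sumstats_pair, sumstats_single

GENERATION_TIME_YEARS = 50.0


def generations_to_years(generations: float,
                         generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in generations to years (default 50 years/generation)."""
    return generations * generation_time


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Prior bounds for structural and mutation hyperparameters.

    Structural priors are log-uniform except G (uniform, includes 0) and beta
    (uniform on [0, 1]); the mutation hyperpriors follow the hierarchical
    scheme: mean mu log-uniform on [1e-5, 1e-3], gamma shape uniform on
    [0.5, 5], mean P_GSM uniform on [0, 1].
    """

    n_bounds: tuple[float, float] = (1e3, 2e5)          # N_CUR, N_N, N_S
    g_bounds: tuple[float, float] = (-1e-3, 0.0)        # growth rate G
    t_bounds: tuple[float, float] = (1e2, 1e5)          # T (SRM)
    rn_anc_bounds: tuple[float, float] = (1.0, 1e2)     # RN_ANC
    t_div_bounds: tuple[float, float] = (1e2, 1e5)      # T_DIV
    nm_bounds: tuple[float, float] = (1e-2, 1e2)        # Nm per generation
    beta_bounds: tuple[float, float] = (0.0, 1.0)
    mean_mu_bounds: tuple[float, float] = (1e-5, 1e-3)
    shape_bounds: tuple[float, float] = (0.5, 5.0)
    mean_p_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name in ("n_bounds", "t_bounds", "rn_anc_bounds", "t_div_bounds",
                     "nm_bounds", "mean_mu_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi) and name != "rn_anc_bounds":
                raise ValueError(f"inconsistent bounds for {name}: ({lo}, {hi})")
        for name in ("g_bounds", "beta_bounds", "shape_bounds", "mean_p_bounds"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"inconsistent bounds for {name}: ({lo}, {hi})")

    def bounds_for(self, param: str) -> tuple[float, float]:
        return {
            "N_CUR": self.n_bounds, "N_N": self.n_bounds, "N_S": self.n_bounds,
            "G": self.g_bounds, "T": self.t_bounds, "RN_ANC": self.rn_anc_bounds,
            "T_DIV": self.t_div_bounds, "Nm_NS": self.nm_bounds,
            "Nm_SN": self.nm_bounds, "beta": self.beta_bounds,
            "mean_mu": self.mean_mu_bounds, "shape": self.shape_bounds,
            "mean_P_GSM": self.mean_p_bounds,
        }[param]

    def is_log_scale(self, param: str) -> bool:
        return param in {"N_CUR", "N_N", "N_S", "T", "RN_ANC", "T_DIV",
                         "Nm_NS", "Nm_SN", "mean_mu"}


STRUCTURAL_PARAMS = {
    "SNM": ["N_CUR"],
    "PGM": ["N_CUR", "G"],
    "SRM": ["N_CUR", "T", "RN_ANC"],
    "ISM": ["N_N", "N_S", "T_DIV"],
    "IMM": ["N_N", "N_S", "T_DIV", "Nm_NS", "Nm_SN", "beta"],
    "IMM_NS": ["N_N", "N_S", "T_DIV", "Nm_NS", "beta"],
    "IMM_SN": ["N_N", "N_S", "T_DIV", "Nm_SN", "beta"],
}
HYPER_PARAMS = ["mean_mu", "shape", "mean_P_GSM"]


def _draw(param: str, priors: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = priors.bounds_for(param)
    if priors.is_log_scale(param):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return rng.uniform(lo, hi, size=n)


def sample_priors(
    model_kind: str,
    n: int,
    rng: np.random.Generator,
    priors: PriorSpec | None = None,
    fixed: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw n structural + mutation hyperparameter vectors for one model.

    ``fixed`` pins parameters (e.g. G during the divergence stage)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    priors = priors or PriorSpec()
    fixed = fixed or {}
    cols: dict[str, np.ndarray] = {}
    for param in STRUCTURAL_PARAMS[model_kind] + HYPER_PARAMS:
        if param in fixed:
            cols[param] = np.full(n, fixed[param])
        else:
            cols[param] = _draw(param, priors, n, rng)
    for param, val in fixed.items():
        if param not in cols:   # e.g. G pinned during the divergence stage
            cols[param] = np.full(n, val)
    df = pd.DataFrame(cols)
    df.insert(0, "model", model_kind)
    return df


def model_from_row(row: pd.Series | dict, kind: str | None = None) -> DemographyModel:
    kind = kind or row["model"]
    get = row.get if hasattr(row, "get") else row.__getitem__
    if kind in SIZE_CHANGE_MODELS:
        return DemographyModel(
            kind=kind,
            n_cur=get("N_CUR"),
            growth=get("G") if kind == "PGM" else None,
            t_change=get("T") if kind == "SRM" else None,
            rn_anc=get("RN_ANC") if kind == "SRM" else None,
        )
    return DemographyModel(
        kind=kind,
        n_north=get("N_N"), n_south=get("N_S"), t_div=get("T_DIV"),
        growth=get("G"),
        nm_ns=float(get("Nm_NS") or 0.0) if kind in ("IMM", "IMM_NS") else 0.0,
        nm_sn=float(get("Nm_SN") or 0.0) if kind in ("IMM", "IMM_SN") else 0.0,
        beta=float(get("beta")) if kind != "ISM" else 1.0,
    )


# ---------------------------------------------------------------------------
# reference-table simulation


def simulate_stat_vector(
    model: DemographyModel,
    sample_config: SampleConfig,
    hyper: GsmHyperPrior,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one dataset under ``model`` and return its summary vector."""
    mu_l, p_l = draw_locus_params(hyper, sample_config.n_loci, rng)
    cp_model = CpMutationModel(seq_length=sample_config.seq_length)
    n_demes = model.n_demes
    msat: list[list[np.ndarray]] = [[] for _ in range(n_demes)]
    for mu, p in zip(mu_l, p_l):
        gen = simulate_genealogy(model, sample_config, "nuclear", rng)
        tips = mutate_microsat(gen, mu, p, rng)
        for d in range(n_demes):
            msat[d].append(tips[gen.tip_deme == d])
    gen = simulate_genealogy(model, sample_config, "chloroplast", rng)
    seqs = mutate_sequence(gen, cp_model, rng)
    if n_demes == 1:
        return sumstats_single(msat[0], seqs)
    return sumstats_pair(msat[0], msat[1],
                         seqs[gen.tip_deme == 0], seqs[gen.tip_deme == 1])


@dataclass
class ReferenceTable:
    """Rows of (model, parameters, summary statistics) plus bookkeeping."""

    table: pd.DataFrame
    stat_names: list[str]
    param_names: dict[str, list[str]]      # per model kind
    priors: PriorSpec
    seed_used: int | None = None

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.table["model"]))

    def stats_matrix(self) -> np.ndarray:
        return self.table[self.stat_names].to_numpy(dtype=float)

    def for_model(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["model"] == kind].reset_index(drop=True)


def make_reference_table(
    model_kinds: list[str],
    n_sims: int,
    sample_config: SampleConfig,
    rng: np.random.Generator,
    priors: PriorSpec | None = None,
    fixed: dict[str, float] | None = None,
) -> ReferenceTable:
    """Simulate ``n_sims`` datasets per model and collect parameters + stats."""
    priors = priors or PriorSpec()
    two_deme = model_kinds[0] in DIVERGENCE_MODELS
    stat_names = PAIR_STAT_NAMES if two_deme else SINGLE_STAT_NAMES
    frames = []
    for kind in model_kinds:
        params = sample_priors(kind, n_sims, rng, priors, fixed)
        stats = np.empty((n_sims, len(stat_names)))
        for i in range(n_sims):
            model = model_from_row(params.iloc[i], kind)
            hyper = GsmHyperPrior(params["mean_mu"].iloc[i],
                                  params["shape"].iloc[i],
                                  params["mean_P_GSM"].iloc[i])
            stats[i] = simulate_stat_vector(model, sample_config, hyper, rng)
        frames.append(pd.concat(
            [params, pd.DataFrame(stats, columns=stat_names)], axis=1))
    table = pd.concat(frames, ignore_index=True)
    if table[stat_names].isna().any().any():
        raise RuntimeError("missing summary statistics in the reference table")
    pnames = {k: STRUCTURAL_PARAMS[k] + HYPER_PARAMS for k in model_kinds}
    return ReferenceTable(table, list(stat_names), pnames, priors)


# ---------------------------------------------------------------------------
# random-forest model choice


@dataclass
class ModelChoiceResult:
    vote_share: dict[str, float]
    selected: str
    posterior_probability: float
    oob_error: float
    confusion: pd.DataFrame
    tie: bool = False


class ModelChoiceForest:
    """A fitted model-choice forest, reusable over many observed vectors.

    Fits the classification forest and the Pudlo-style regression forest
    (trained on out-of-bag misclassification indicators) once, then
    classifies any number of observed statistic vectors.
    """

    def __init__(self, reference: ReferenceTable, n_trees: int = 1000,
                 seed: int | np.random.Generator = 0):
        models = reference.models
        if len(models) < 2:
            raise ValueError("need at least 2 models in the reference table")
        if n_trees < 1:
            raise ValueError("n_trees must be positive")
        if n_trees < 100:
            warnings.warn("fewer than 100 trees: vote shares will be "
                          "high-variance", stacklevel=2)
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        rs = int(rng.integers(2**31 - 1))
        self.reference = reference
        self.models = models

        X = reference.stats_matrix()
        y = reference.table["model"].to_numpy()
        counts = pd.Series(y).value_counts()
        if counts.max() > 10 * counts.min():
            warnings.warn("model class imbalance exceeds 10:1", stacklevel=2)

        self.clf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=rs, n_jobs=1,
            bootstrap=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny forests lack OOB coverage
            self.clf.fit(X, y)

        has_oob = ~np.isnan(self.clf.oob_decision_function_).any(axis=1)
        oob_pred = np.full(y.shape, None, dtype=object)
        oob_pred[has_oob] = self.clf.classes_[
            self.clf.oob_decision_function_[has_oob].argmax(axis=1)]
        mis = (oob_pred[has_oob] != y[has_oob]).astype(float)
        self.oob_error = float(mis.mean()) if mis.size else float("nan")
        self.confusion = pd.crosstab(
            pd.Series(y[has_oob], name="true"),
            pd.Series(oob_pred[has_oob].astype(str), name="oob_predicted"))

        self.reg = RandomForestRegressor(n_estimators=min(n_trees, 500),
                                         random_state=rs + 1, n_jobs=1)
        self.reg.fit(X[has_oob], mis)

    def classify(self, observed_stats: np.ndarray) -> ModelChoiceResult:
        obs = np.asarray(observed_stats, dtype=float)
        if obs.shape != (len(self.reference.stat_names),):
            raise ValueError("observed vector length does not match the reference")
        obs = obs.reshape(1, -1)
        # per-tree votes for the observed point
        proba = np.stack([t.predict_proba(obs)[0] for t in self.clf.estimators_])
        tree_votes = self.clf.classes_[proba.argmax(axis=1)]
        share = {m: float(np.mean(tree_votes == m)) for m in self.models}
        best_share = max(share.values())
        tied = [m for m in self.models if share[m] == best_share]
        selected = tied[0]
        posterior = float(np.clip(1.0 - self.reg.predict(obs)[0], 0.0, 1.0))
        return ModelChoiceResult(share, selected, posterior, self.oob_error,
                                 self.confusion, tie=len(tied) > 1)


def rf_model_choice(
    reference: ReferenceTable,
    observed_stats: np.ndarray,
    n_trees: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ModelChoiceResult:
    """Random-forest model choice on the summary statistics.

    Votes are the per-tree classifications of the observed vector; the
    posterior probability of the selected model is one minus the local
    out-of-bag misclassification rate predicted by a regression forest at the
    observed point.  Ties break toward the model listed first, with a flag.
    For many observed vectors against one reference, build one
    :class:`ModelChoiceForest` and call ``classify`` repeatedly.
    """
    return ModelChoiceForest(reference, n_trees=n_trees, seed=seed).classify(
        observed_stats)


# ---------------------------------------------------------------------------
# posterior estimation


@dataclass
class PosteriorEstimate:
    samples: pd.DataFrame             # adjusted (or accepted) draws
    weights: np.ndarray
    mode: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    flagged: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "mode": self.mode[p],
             "hpd_low": self.hpd[p][0], "hpd_high": self.hpd[p][1]}
            for p in self.samples.columns
        ]
        return pd.DataFrame(rows)


def _logit(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    u = np.clip((x - lo) / (hi - lo), 1e-10, 1 - 1e-10)
    return np.log(u / (1 - u))


def _inv_logit(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def estimate_posterior(
    reference: ReferenceTable,
    model_kind: str,
    observed_stats: np.ndarray,
    tolerance: float = 0.005,
    method: str = "loclinear",
    seed: int | np.random.Generator = 0,
    hpd_level: float = 0.95,
) -> PosteriorEstimate:
    """Rejection + regression-adjusted posterior for one model's parameters.

    The nearest ``tolerance`` fraction of simulations (standardized Euclidean
    distance on the summary statistics) is retained with Epanechnikov
    weights.  ``loclinear`` applies a ridge-regularized weighted local-linear
    adjustment on logit-transformed parameters (bounded by the prior), the
    ``neuralnet`` option uses a single-hidden-layer nonlinear regression on
    the same transformed scale, and ``rejection`` skips adjustment.
    """
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must lie in (0, 1]")
    if method not in ("rejection", "loclinear", "neuralnet"):
        raise ValueError(f"unknown method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = reference.for_model(model_kind)
    if sub.empty:
        raise ValueError(f"no simulations for model {model_kind!r}")
    stats = sub[reference.stat_names].to_numpy(dtype=float)
    mean = stats.mean(axis=0)
    sd = stats.std(axis=0)
    keep = sd > 0
    z = (stats[:, keep] - mean[keep]) / sd[keep]
    obs = (np.asarray(observed_stats, dtype=float)[keep] - mean[keep]) / sd[keep]
    dist = np.sqrt(((z - obs) ** 2).sum(axis=1))
    n_acc = int(np.ceil(tolerance * len(sub)))
    if n_acc < 50:
        raise ValueError(
            f"tolerance {tolerance} retains only {n_acc} simulations; "
            "increase the simulation budget or the tolerance")
    order = np.argsort(dist, kind="stable")[:n_acc]
    d_acc = dist[order]
    d_max = d_acc[-1]
    w = 1.0 - (d_acc / d_max) ** 2 if d_max > 0 else np.ones(n_acc)
    w = np.maximum(w, 1e-12)

    param_names = [p for p in reference.param_names[model_kind]]
    out = {}
    flagged = []
    X = z[order] - obs          # centered at the observed point
    for p in param_names:
        theta = sub[p].to_numpy(dtype=float)[order]
        lo, hi = reference.priors.bounds_for(p)
        if np.ptp(theta) == 0.0 or method == "rejection":
            out[p] = theta
            continue
        zt = _logit(theta, lo, hi)
        if method == "loclinear":
            adj = _loclinear_adjust(zt, X, w)
        else:
            adj = _neuralnet_adjust(zt, z[order], obs, rng)
        out[p] = _inv_logit(adj, lo, hi)

    samples = pd.DataFrame(out)
    mode = {}
    hpd = {}
    for p in param_names:
        m, (l, h) = posterior_mode_hpd(samples[p].to_numpy(), level=hpd_level,
                                       weights=w)
        mode[p] = m
        hpd[p] = (l, h)
        if not (l <= m <= h):
            flagged.append(p)
    return PosteriorEstimate(samples, w, mode, hpd, flagged)


def _loclinear_adjust(zt: np.ndarray, X: np.ndarray, w: np.ndarray,
                      ridge: float = 1e-6) -> np.ndarray:
    """Weighted local-linear regression adjustment toward the observed point.

    X is centered at the observed statistics, so the fitted intercept is the
    conditional estimate at the observation and the adjusted draws are
    ``z - X @ beta``."""
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    wd = design * w[:, None]
    gram = design.T @ wd
    gram += ridge * np.eye(gram.shape[0]) * max(np.trace(gram), 1.0)
    coef = np.linalg.solve(gram, wd.T @ zt)
    return zt - X @ coef[1:]


def _neuralnet_adjust(zt: np.ndarray, S: np.ndarray, obs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    from sklearn.neural_network import MLPRegressor

    net = MLPRegressor(hidden_layer_sizes=(10,), max_iter=5000,
                       random_state=int(rng.integers(2**31 - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(S, zt)
    return zt - (net.predict(S) - net.predict(obs.reshape(1, -1))[0])


def posterior_mode_hpd(
    samples: np.ndarray,
    level: float = 0.95,
    weights: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """KDE mode (Silverman bandwidth, 512-point grid) and shortest interval
    containing ``level`` of the (weighted) posterior mass."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError("need at least 100 posterior samples")
    if np.ptp(samples) == 0.0:
        x = float(samples[0])
        return x, (x, x)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    kde = gaussian_kde(samples, bw_method="silverman", weights=weights)
    lo, hi = samples.min(), samples.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    mode = float(grid[np.argmax(kde(grid))])

    order = np.argsort(samples)
    xs = samples[order]
    if weights is None:
        m = int(np.ceil(level * xs.size))
        widths = xs[m - 1:] - xs[: xs.size - m + 1]
        i = int(np.argmin(widths))
        return mode, (float(xs[i]), float(xs[i + m - 1]))
    ws = weights[order]
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    best = (float(xs[0]), float(xs[-1]))
    best_w = np.inf
    j = 0
    for i in range(xs.size):
        while j < xs.size and cum[j + 1] - cum[i] < level:
            j += 1
        if j >= xs.size:
            break
        if xs[j] - xs[i] < best_w:
            best_w = xs[j] - xs[i]
            best = (float(xs[i]), float(xs[j]))
    return mode, best


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass
class PpcResult:
    table: pd.DataFrame    # per statistic: observed, quantiles, tail probability


def posterior_predictive_check(
    model_kind: str,
    posterior: PosteriorEstimate,
    observed_stats: np.ndarray,
    sample_config: SampleConfig,
    stat_names: list[str],
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    fixed: dict[str, float] | None = None,
) -> PpcResult:
    """Simulate from posterior draws and locate the observed statistics.

    Tail probabilities are two-tailed: ``2 * min(P(sim <= obs), P(sim >= obs))``
    capped at 1."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed = fixed or {}
    probs = posterior.weights / posterior.weights.sum()
    idx = rng.choice(len(posterior.samples), size=n, p=probs, replace=True)
    sims = np.empty((n, len(stat_names)))
    for r, i in enumerate(idx):
        row = dict(posterior.samples.iloc[i])
        row.update(fixed)
        model = model_from_row(row, model_kind)
        hyper = GsmHyperPrior(row["mean_mu"], row["shape"], row["mean_P_GSM"])
        sims[r] = simulate_stat_vector(model, sample_config, hyper, rng)
    obs = np.asarray(observed_stats, dtype=float)
    rows = []
    for j, name in enumerate(stat_names):
        lo_tail = float(np.mean(sims[:, j] <= obs[j]))
        hi_tail = float(np.mean(sims[:, j] >= obs[j]))
        rows.append({
            "stat": name, "observed": obs[j],
            "sim_q025": float(np.quantile(sims[:, j], 0.025)),
            "sim_median": float(np.quantile(sims[:, j], 0.5)),
            "sim_q975": float(np.quantile(sims[:, j], 0.975)),
            "tail_probability": min(1.0, 2.0 * min(lo_tail, hi_tail)),
        })
    return PpcResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# sequential pipeline


@dataclass
class AbcStageReport:
    model_choice: ModelChoiceResult
    posterior: PosteriorEstimate
    ppc: PpcResult | None


@dataclass
class SequentialReport:
    north: AbcStageReport
    south: AbcStageReport
    divergence: AbcStageReport
    g_fixed: float


def run_abc_stage(
    model_kinds: list[str],
    observed_stats: np.ndarray,
    sample_config: SampleConfig,
    n_sims: int,
    rng: np.random.Generator,
    priors: PriorSpec | None = None,
    tolerance: float = 0.005,
    n_trees: int = 1000,
    method: str = "loclinear",
    fixed: dict[str, float] | None = None,
    ppc_n: int = 0,
) -> AbcStageReport:
    """One ABC stage: reference table, model choice, posterior, optional PPC."""
    reference = make_reference_table(model_kinds, n_sims, sample_config, rng,
                                     priors, fixed)
    choice = rf_model_choice(reference, observed_stats, n_trees=n_trees, seed=rng)
    posterior = estimate_posterior(reference, choice.selected, observed_stats,
                                   tolerance=tolerance, method=method, seed=rng)
    ppc = None
    if ppc_n > 0:
        ppc = posterior_predictive_check(
            choice.selected, posterior, observed_stats, sample_config,
            reference.stat_names, n=ppc_n, seed=rng, fixed=fixed)
    return AbcStageReport(choice, posterior, ppc)


def sequential_pipeline(
    obs_north: np.ndarray,
    obs_south: np.ndarray,
    obs_joint: np.ndarray,
    sample_north: SampleConfig,
    sample_south: SampleConfig,
    sample_joint: SampleConfig,
    rng: np.random.Generator,
    n_sims_size: int = 20_000,
    n_sims_div: int = 50_000,
    tolerance_size: float = 0.005,
    tolerance_div: float = 0.002,
    n_trees: int = 1000,
    method: str = "loclinear",
    priors: PriorSpec | None = None,
    ppc_n: int = 1000,
) -> SequentialReport:
    """Two-stage sequential ABC.

    Stage 1 fits SNM/PGM/SRM per lineage; stage 2 fixes G at the northern
    posterior mode (0 when the northern best model has no growth parameter)
    and compares ISM/IMM/IMM_NS/IMM_SN on the joint statistics.
    """
    north = run_abc_stage(list(SIZE_CHANGE_MODELS), obs_north, sample_north,
                          n_sims_size, rng, priors, tolerance_size, n_trees,
                          method, ppc_n=ppc_n)
    south = run_abc_stage(list(SIZE_CHANGE_MODELS), obs_south, sample_south,
                          n_sims_size, rng, priors, tolerance_size, n_trees,
                          method, ppc_n=ppc_n)
    g_fixed = float(north.posterior.mode.get("G", 0.0)) \
        if "G" in north.posterior.mode else 0.0
    divergence = run_abc_stage(list(DIVERGENCE_MODELS), obs_joint, sample_joint,
                               n_sims_div, rng, priors, tolerance_div, n_trees,
                               method, fixed={"G": g_fixed}, ppc_n=ppc_n)
    return SequentialReport(north, south, divergence, g_fixed)
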