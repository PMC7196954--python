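"""Leaf-shape quantification and the Bayesian linear mixed model.

Leaf outlines are decomposed into elliptic Fourier descriptors (EFD,
Kuhl-Giardina formulation) normalized for size, rotation and starting point;
shape and bioclimatic covariates are reduced by PCA retaining components that
explain more than 5% of the variance.  A Bayesian linear mixed model relates
each shape response to climate principal components and the northern-lineage
membership coefficient Q with a random intercept per individual tree:

    Y_obs[i]   ~ Normal(beta0[j(i)] + X[i] @ beta, sigma_all)
    beta0[j]   ~ Normal(beta0_mean, sigma_individual)

with flat priors on the regression coefficients and on the standard
deviations (positive half-line).  The model is linear-Gaussian and fully
conjugate, so it is sampled by Gibbs; four chains of 4,000 iterations with
1,000 burn-in and thinning 10 give 300 x 4 = 1,200 retained draws, summarized
by the KDE posterior mode and the 95% highest posterior density interval.
A coefficient is called significant when its 95% HPD excludes zero.

Populations are assigned to varieties from tree-average leaf length and
width: width 3-6 cm with length 6-15 cm is the *kobus* morphotype, width
6-10 cm with length 10-20 cm is *borealis*, and populations whose trees
straddle the 6-cm width boundary are called intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc import posterior_mode_hpd


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors


@dataclass
class EfdCoefficients:
    """Harmonic coefficients (a_n, b_n, c_n, d_n), one row per harmonic."""

    coeffs: np.ndarray          # (n_harmonics, 4)
    normalized: bool
    a0: float = 0.0
    c0: float = 0.0

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flatten(self, drop_degenerate: bool = True) -> np.ndarray:
        """Coefficient vector for PCA; with ``drop_degenerate`` the first
        three normalized entries (fixed at 1, 0, 0) are omitted."""
        flat = self.coeffs.ravel()
        return flat[3:] if (drop_degenerate and self.normalized) else flat


def _contour_edges(outline: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("outline must be an (n >= 3, 2) point array")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if (dt == 0).any():
        keep = dt > 0
        pts, d, dt = pts[keep], d[keep], dt[keep]
        if pts.shape[0] < 3:
            raise ValueError("outline degenerates to fewer than 3 distinct points")
    return pts, d, dt


def _is_simple_polygon(pts: np.ndarray) -> bool:
    """Reject self-intersecting outlines (O(n^2) segment test)."""
    n = pts.shape[0]
    seg = np.vstack([pts, pts[:1]])

    def ccw(p, q, r):
        return (r[1] - p[1]) * (q[0] - p[0]) - (q[1] - p[1]) * (r[0] - p[0])

    for i in range(n):
        a1, a2 = seg[i], seg[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through wrap-around
            b1, b2 = seg[j], seg[j + 1]
            if (ccw(a1, a2, b1) * ccw(a1, a2, b2) < 0
                    and ccw(b1, b2, a1) * ccw(b1, b2, a2) < 0):
                return False
    return True


def elliptic_fourier(outline: np.ndarray, n_harmonics: int = 20,
                     normalize: bool = True,
                     check_simple: bool = True,
                     parameterization: str = "uniform") -> EfdCoefficients:
    """Kuhl-Giardina elliptic Fourier descriptors of a closed outline.

    With ``normalize`` the coefficients are standardized for size, rotation
    and starting point so the first harmonic becomes (1, 0, 0, +-e) with e
    the axis ratio of its ellipse.

    ``parameterization`` sets the curve parameter: ``uniform`` advances it
    equally per vertex (an ellipse is then exactly its first harmonic), while
    ``arclength`` uses segment lengths.  For chain-coded or evenly resampled
    contours -- the normal input from outline tracing -- the two coincide.
    """
    pts, d, dt = _contour_edges(outline)
    if parameterization == "uniform":
        dt = np.ones_like(dt)
    elif parameterization != "arclength":
        raise ValueError(f"unknown parameterization {parameterization!r}")
    if pts.shape[0] < 3 * n_harmonics:
        raise ValueError(
            f"need at least {3 * n_harmonics} contour points for "
            f"{n_harmonics} harmonics")
    if check_simple and not _is_simple_polygon(pts):
        raise ValueError("self-intersecting outline")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, n_harmonics + 1)[:, None]
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * np.pi ** 2 * n.ravel() ** 2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const * (dcos @ dx_dt)
    b = const * (dsin @ dx_dt)
    c = const * (dcos @ dy_dt)
    dd = const * (dsin @ dy_dt)
    coeffs = np.stack([a, b, c, dd], axis=1)
    if not normalize:
        return EfdCoefficients(coeffs, normalized=False)
    return _normalize_efd(coeffs)


def _normalize_efd(coeffs: np.ndarray) -> EfdCoefficients:
    a1, b1, c1, d1 = coeffs[0]
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1),
                             a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
    c_t, s_t = np.cos(theta), np.sin(theta)
    a1s = a1 * c_t + b1 * s_t
    c1s = c1 * c_t + d1 * s_t
    scale = np.hypot(a1s, c1s)
    psi = np.arctan2(c1s, a1s)
    c_p, s_p = np.cos(psi), np.sin(psi)
    rot_psi = np.array([[c_p, s_p], [-s_p, c_p]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        m = coeffs[i].reshape(2, 2)
        ang = (i + 1) * theta
        rot_theta = np.array([[np.cos(ang), -np.sin(ang)],
                              [np.sin(ang), np.cos(ang)]])
        out[i] = (rot_psi @ m @ rot_theta).ravel() / scale
    return EfdCoefficients(out, normalized=True)


def efd_reconstruct(efd: EfdCoefficients, n_points: int = 200) -> np.ndarray:
    """Inverse transform: reconstruct the outline from the harmonics."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    x = efd.a0 + efd.coeffs[:, 0] @ cos_nt + efd.coeffs[:, 1] @ sin_nt
    y = efd.c0 + efd.coeffs[:, 2] @ cos_nt + efd.coeffs[:, 3] @ sin_nt
    return np.stack([x, y], axis=1)


def outline_area(outline: np.ndarray) -> float:
    """Polygon area by the shoelace formula (used when area is not supplied)."""
    pts, _, _ = _contour_edges(outline)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


# ---------------------------------------------------------------------------
# PCA with the >5% retention rule


@dataclass
class PcaResult:
    scores: np.ndarray            # (n_samples, n_retained)
    loadings: np.ndarray          # (n_features, n_retained)
    variance_share: np.ndarray    # all components
    retained: list[int]           # indices of retained components (0-based)
    mean: np.ndarray
    scale: np.ndarray | None = None


def _pca(x: np.ndarray, standardize: bool, threshold: float) -> PcaResult:
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    scale = None
    if standardize:
        scale = xc.std(axis=0, ddof=1)
        if (scale == 0).any():
            raise ValueError("constant column: cannot standardize")
        xc = xc / scale
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    if var.sum() == 0:
        raise ValueError("constant matrix: no principal components")
    share = var / var.sum()
    retained = [i for i, v in enumerate(share) if v > threshold]
    scores = u[:, retained] * s[retained]
    return PcaResult(scores, vt[retained].T, share, retained, mean, scale)


def shape_pca(coeff_matrix: np.ndarray, threshold: float = 0.05) -> PcaResult:
    """PCA of stacked EFD coefficient vectors; components retained when their
    variance share is strictly greater than ``threshold`` (default 5%)."""
    return _pca(coeff_matrix, standardize=False, threshold=threshold)


def bioclim_pca(covariates: pd.DataFrame, threshold: float = 0.05) -> PcaResult:
    """Standardized PCA of the per-population bioclimatic table."""
    if covariates.isna().any().any():
        raise ValueError("missing cells in the covariate table")
    return _pca(covariates.to_numpy(dtype=float), standardize=True,
                threshold=threshold)


def log_abs_pc(scores: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """log|PC| transform used for the asymmetry component (sign carries no
    biological meaning)."""
    return np.log(np.maximum(np.abs(scores), floor))


def screen_covariates(
    biopcs: pd.DataFrame, q: np.ndarray, threshold: float = 0.7
) -> tuple[list[str], pd.Series]:
    """Drop BioPCs whose |Pearson r| with the ancestry coefficient Q exceeds
    ``threshold``; returns (retained names, all correlations)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    q = np.asarray(q, dtype=float)
    corr = {}
    for col in biopcs.columns:
        corr[col] = float(np.corrcoef(biopcs[col].to_numpy(dtype=float), q)[0, 1])
    corr_s = pd.Series(corr)
    retained = [c for c in biopcs.columns if abs(corr[c]) <= threshold]
    return retained, corr_s


# ---------------------------------------------------------------------------
# Bayesian linear mixed model (conjugate Gibbs)


@dataclass(frozen=True)
class BlmmSpec:
    covariates: list[str] = field(default_factory=lambda: ["BioPC2", "BioPC3",
                                                           "BioPC4", "Q"])
    chains: int = 4
    iterations: int = 4_000
    burn_in: int = 1_000
    thinning: int = 10
    hpd_level: float = 0.95

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be smaller than iterations")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class BlmmResult:
    samples: pd.DataFrame           # retained draws, all chains stacked
    mode: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    significant: dict[str, bool]    # HPD excludes zero (beta parameters)
    rhat: dict[str, float]
    converged: bool

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in self.samples.columns:
            rows.append({
                "parameter": p, "mode": self.mode[p],
                "hpd_low": self.hpd[p][0], "hpd_high": self.hpd[p][1],
                "significant": self.significant.get(p),
                "rhat": self.rhat[p],
            })
        return pd.DataFrame(rows)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over (n_chains, n_draws) retained draws."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    var_b = n * np.var(means, ddof=1)
    var_w = np.mean(np.var(segs, axis=1, ddof=1))
    if var_w == 0:
        return 1.0
    var_hat = (n - 1) / n * var_w + var_b / n
    return float(np.sqrt(var_hat / var_w))


def fit_blmm(
    leaf_table: pd.DataFrame,
    response: str,
    spec: BlmmSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> BlmmResult:
    """Gibbs sampler for the random-intercept linear mixed model.

    ``leaf_table`` must hold one row per leaf with columns ``tree_id``, the
    response, and the covariate columns of ``spec`` (population-level values
    broadcast to leaves).  Flat priors on coefficients and on both standard
    deviations; the posterior is proper when there are more individuals than
    fixed effects, which is asserted.
    """
    spec = spec or BlmmSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [c for c in [response, "tree_id", *spec.covariates]
               if c not in leaf_table.columns]
    if missing:
        raise ValueError(f"leaf table lacks columns {missing}")
    y = leaf_table[response].to_numpy(dtype=float)
    X = leaf_table[spec.covariates].to_numpy(dtype=float)
    tree_codes, tree_index = pd.factorize(leaf_table["tree_id"])
    n_trees = tree_index.size
    n_leaves = y.size
    p = X.shape[1]
    if n_trees <= p + 1:
        raise ValueError("posterior is improper: need more individuals than "
                         "fixed effects")

    # sufficient statistics: covariates are constant within a tree
    counts = np.bincount(tree_codes).astype(float)
    y_sum = np.bincount(tree_codes, weights=y)
    y_bar = y_sum / counts
    X_tree = np.empty((n_trees, p))
    for j in range(n_trees):
        X_tree[j] = X[tree_codes == j][0]
    if not np.allclose(X_tree[tree_codes], X):
        raise ValueError("covariates must be constant within each individual")
    ssw = float(np.sum((y - y_bar[tree_codes]) ** 2))  # invariant across draws

    param_names = (["beta0_mean"] + [f"beta_{c}" for c in spec.covariates]
                   + ["sigma_individual", "sigma_all"])
    kept = np.empty((spec.chains, spec.draws_per_chain, len(param_names)))

    for chain in range(spec.chains):
        beta = np.zeros(p)
        beta0_mean = float(y.mean())
        b = y_bar - X_tree @ beta
        sigma2_all = max(np.var(y), 1e-6)
        sigma2_ind = max(np.var(y_bar), 1e-6)
        k = 0
        for it in range(spec.iterations):
            # random intercepts b_j | rest
            prec = counts / sigma2_all + 1.0 / sigma2_ind
            mu_b = (counts * (y_bar - X_tree @ beta) / sigma2_all
                    + beta0_mean / sigma2_ind) / prec
            b = mu_b + rng.standard_normal(n_trees) / np.sqrt(prec)
            # beta0_mean | b
            beta0_mean = float(b.mean()
                               + rng.standard_normal() * np.sqrt(sigma2_ind / n_trees))
            # beta | rest: weighted LS on tree means with weights n_j
            resid_target = y_bar - b
            wts = counts / sigma2_all
            xtw = X_tree.T * wts
            gram = xtw @ X_tree
            mean_beta = np.linalg.solve(gram, xtw @ resid_target)
            cov = np.linalg.inv(gram)
            beta = rng.multivariate_normal(mean_beta, cov, method="cholesky")
            # variances (flat prior on sigma => shape (n-1)/2 on sigma^2)
            fitted_mean = b + X_tree @ beta
            ss_all = ssw + float(np.sum(counts * (y_bar - fitted_mean) ** 2))
            sigma2_all = ss_all / (2.0 * rng.gamma((n_leaves - 1) / 2.0))
            ss_ind = float(np.sum((b - beta0_mean) ** 2))
            sigma2_ind = ss_ind / (2.0 * rng.gamma((n_trees - 1) / 2.0))
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                if k < spec.draws_per_chain:
                    kept[chain, k] = [beta0_mean, *beta,
                                      np.sqrt(sigma2_ind), np.sqrt(sigma2_all)]
                    k += 1

    flat = kept.reshape(-1, len(param_names))
    samples = pd.DataFrame(flat, columns=param_names)
    mode, hpd, sig, rhat = {}, {}, {}, {}
    converged = True
    for i, name in enumerate(param_names):
        m, interval = posterior_mode_hpd(flat[:, i], level=spec.hpd_level)
        mode[name] = m
        hpd[name] = interval
        rhat[name] = _split_rhat(kept[:, :, i])
        if rhat[name] > 1.01:
            converged = False
        if name.startswith("beta_") or name == "beta0_mean":
            sig[name] = not (interval[0] <= 0.0 <= interval[1])
    if not converged:
        warnings.warn("split-R-hat exceeds 1.01 for at least one parameter; "
                      "results reported anyway", stacklevel=2)
    return BlmmResult(samples, mode, hpd, sig, rhat, converged)


# ---------------------------------------------------------------------------
# variety classification


KOBUS_RANGE = {"length": (6.0, 15.0), "width": (3.0, 6.0)}
BOREALIS_RANGE = {"length": (10.0, 20.0), "width": (6.0, 10.0)}
WIDTH_BOUNDARY = 6.0


def classify_variety(
    leaf_table: pd.DataFrame,
    majority: float = 0.75,
    min_trees: int = 3,
) -> pd.DataFrame:
    """Assign each population to a variety from tree-average leaf dimensions.

    A population is called *kobus* (narrow leaves) or *borealis* (wide
    leaves) when more than ``majority`` of its trees fall strictly on one
    side of the 6-cm width boundary; populations whose trees straddle the
    boundary are ``intermediate``.  Populations with fewer than ``min_trees``
    trees get no call.
    """
    req = {"population", "tree_id", "length_cm", "width_cm"}
    if not req <= set(leaf_table.columns):
        raise ValueError(f"leaf table lacks columns {sorted(req - set(leaf_table.columns))}")
    tree_means = (leaf_table
                  .groupby(["population", "tree_id"])[["length_cm", "width_cm"]]
                  .mean().reset_index())
    rows = []
    for pop, sub in tree_means.groupby("population"):
        if len(sub) < min_trees:
            warnings.warn(f"population {pop!r} has fewer than {min_trees} "
                          "trees: no variety call", stacklevel=2)
            rows.append({"population": pop, "variety": None,
                         "mean_length_cm": sub["length_cm"].mean(),
                         "mean_width_cm": sub["width_cm"].mean()})
            continue
        wide = float(np.mean(sub["width_cm"] > WIDTH_BOUNDARY))
        narrow = float(np.mean(sub["width_cm"] < WIDTH_BOUNDARY))
        if wide > majority:
            call = "borealis"
        elif narrow > majority:
            call = "kobus"
        else:
            call = "intermediate"
        rows.append({"population": pop, "variety": call,
                     "mean_length_cm": float(sub["length_cm"].mean()),
                     "mean_width_cm": float(sub["width_cm"].mean())})
    return pd.DataFrame(rows)
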