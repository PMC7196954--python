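"""Leaf-shape descriptors, PCA retention, covariate screen, BLMM, varieties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kobuspop.morphology import (
    BlmmSpec,
    bioclim_pca,
    classify_variety,
    efd_reconstruct,
    elliptic_fourier,
    fit_blmm,
    log_abs_pc,
    outline_area,
    screen_covariates,
    shape_pca,
)
from kobuspop.synth import superellipse_outline


def ellipse(a=2.0, b=1.0, k=256, phase=0.0, rot=0.0):
    t = np.linspace(0, 2 * np.pi, k, endpoint=False) + phase
    x, y = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(rot), np.sin(rot)
    return np.stack([c * x - s * y, s * x + c * y], axis=1)


class TestEfd:
    def test_circle_has_null_higher_harmonics(self):
        efd = elliptic_fourier(ellipse(1, 1), n_harmonics=8)
        assert np.abs(efd.coeffs[1:]).max() < 1e-6

    def test_two_to_one_ellipse_closed_form(self):
        efd = elliptic_fourier(ellipse(2, 1), n_harmonics=5)
        assert efd.coeffs[0] == pytest.approx([1, 0, 0, 0.5], abs=1e-6)

    def test_normalization_removes_rotation_and_start(self):
        a = elliptic_fourier(ellipse(2, 1), n_harmonics=4).coeffs
        b = elliptic_fourier(ellipse(2, 1, phase=1.1, rot=0.7),
                             n_harmonics=4).coeffs
        assert np.abs(np.abs(a) - np.abs(b)).max() < 1e-9

    def test_mirror_flips_c_coefficients(self):
        out = superellipse_outline(10, 5, n_points=180)
        mirrored = out * np.array([1.0, -1.0])
        a = elliptic_fourier(out, n_harmonics=6, normalize=False)
        b = elliptic_fourier(mirrored, n_harmonics=6, normalize=False)
        # y -> -y negates the two y-coefficients, leaves the x ones alone
        assert b.coeffs[:, 2] == pytest.approx(-a.coeffs[:, 2], abs=1e-9)
        assert b.coeffs[:, 3] == pytest.approx(-a.coeffs[:, 3], abs=1e-9)
        assert b.coeffs[:, :2] == pytest.approx(a.coeffs[:, :2], abs=1e-9)

    def test_self_intersecting_rejected(self):
        bow = np.array([[0, 0], [2, 2], [2, 0], [0, 2], [0.1, 1.8], [0, 1]],
                       dtype=float)
        with pytest.raises(ValueError, match="self-intersect"):
            elliptic_fourier(bow, n_harmonics=2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="contour points"):
            elliptic_fourier(ellipse(k=10), n_harmonics=5)

    def test_reconstruction_converges_with_harmonics(self):
        out = superellipse_outline(10, 5, n_points=360)
        errs = []
        for h in (2, 6, 16):
            efd = elliptic_fourier(out, n_harmonics=h, normalize=False)
            rec = efd_reconstruct(efd, n_points=360)
            rec = rec - rec.mean(axis=0) + out.mean(axis=0)
            errs.append(np.abs(rec - out).max())
        assert errs[0] > errs[1] > errs[2]

    def test_area_shoelace(self):
        sq = np.array([[0, 0], [2, 0], [2, 3], [0, 3]], dtype=float)
        assert outline_area(sq) == pytest.approx(6.0)


class TestShapePca:
    def test_single_factor_retains_one_component(self, rng):
        coeffs = []
        for _ in range(60):
            ratio = rng.uniform(1.2, 3.0)
            efd = elliptic_fourier(ellipse(ratio, 1), n_harmonics=6)
            coeffs.append(efd.flatten())
        res = shape_pca(np.array(coeffs))
        assert len(res.retained) == 1
        assert res.variance_share.sum() == pytest.approx(1.0)

    def test_retention_strictly_greater_than_threshold(self, rng):
        x = rng.standard_normal((50, 4))
        res = shape_pca(x, threshold=0.05)
        assert all(res.variance_share[i] > 0.05 for i in res.retained)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            shape_pca(np.ones((10, 3)))

    def test_log_abs_transform(self):
        x = np.array([-1.0, 0.5, 2.0])
        assert log_abs_pc(x) == pytest.approx(np.log([1.0, 0.5, 2.0]))


class TestBioclimPca:
    def test_four_factor_structure_retains_four(self, rng):
        from kobuspop.synth import SyntheticScenario, generate_leaf_data
        scenario = SyntheticScenario(n_north_demes=6, n_south_demes=7,
                                     trees_per_pop=2, leaves_per_tree=2)
        _, cov, _ = generate_leaf_data(scenario, rng)
        res = bioclim_pca(cov)
        assert len(res.retained) == 4

    def test_loadings_orthonormal(self, rng):
        cov = pd.DataFrame(rng.standard_normal((20, 6)))
        res = bioclim_pca(cov, threshold=0.01)
        gram = res.loadings.T @ res.loadings
        assert gram == pytest.approx(np.eye(gram.shape[0]), abs=1e-10)

    def test_duplicated_rows_get_identical_scores(self, rng):
        base = rng.standard_normal((10, 5))
        cov = pd.DataFrame(np.vstack([base, base[:1]]))
        res = bioclim_pca(cov, threshold=0.01)
        assert res.scores[0] == pytest.approx(res.scores[-1])

    def test_missing_cells_rejected(self):
        cov = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            bioclim_pca(cov)


class TestCovariateScreen:
    def test_strongly_correlated_component_dropped(self, rng):
        q = rng.random(23)
        target = -0.823
        noise = rng.standard_normal(23)
        qs = (q - q.mean()) / q.std()
        noise -= qs * (noise @ qs) / (qs @ qs)
        biopc1 = target * qs + np.sqrt(1 - target**2) * noise / noise.std()
        pcs = pd.DataFrame({"BioPC1": biopc1,
                            "BioPC2": rng.standard_normal(23)})
        retained, corr = screen_covariates(pcs, q)
        assert "BioPC1" not in retained
        assert corr["BioPC1"] == pytest.approx(target, abs=0.02)

    def test_weakly_correlated_retained(self, rng):
        q = np.repeat([0.0, 1.0], 12)
        pcs = pd.DataFrame({f"BioPC{i}": rng.standard_normal(24)
                            for i in range(2, 5)})
        retained, corr = screen_covariates(pcs, q)
        if corr.abs().max() < 0.213:  # the emulated weak-correlation regime
            assert retained == list(pcs.columns)

    def test_threshold_one_drops_nothing(self, rng):
        q = rng.random(10)
        pcs = pd.DataFrame({"BioPC1": q * 2})  # |r| = 1 > any threshold < 1
        retained, _ = screen_covariates(pcs, q, threshold=1.0)
        assert retained == ["BioPC1"]


def simulate_blmm_table(rng, beta_q=13.0, betas=(-3.8, -3.1, 3.3),
                        sigma_ind=11.6, sigma_all=13.1, n_pops=22,
                        trees_per_pop=20, leaves_per_tree=10,
                        beta0=46.4):
    rows = []
    q_pop = (np.arange(n_pops) < n_pops // 2).astype(float)
    x_pop = rng.standard_normal((n_pops, 3))
    for p in range(n_pops):
        for t in range(trees_per_pop):
            b = rng.normal(beta0, sigma_ind)
            mu = b + x_pop[p] @ np.array(betas) + beta_q * q_pop[p]
            for l in range(leaves_per_tree):
                rows.append({
                    "tree_id": f"p{p}_t{t}",
                    "population": f"p{p}",
                    "BioPC2": x_pop[p, 0], "BioPC3": x_pop[p, 1],
                    "BioPC4": x_pop[p, 2], "Q": q_pop[p],
                    "area_cm2": rng.normal(mu, sigma_all),
                })
    return pd.DataFrame(rows)


class TestBlmm:
    SPEC = BlmmSpec(chains=2, iterations=1200, burn_in=400, thinning=4)

    def test_recovers_generating_coefficients(self, rng):
        table = simulate_blmm_table(rng)
        fit = fit_blmm(table, "area_cm2", self.SPEC, seed=rng)
        lo, hi = fit.hpd["beta_Q"]
        assert lo <= 13.0 <= hi
        assert fit.mode["sigma_all"] == pytest.approx(13.1, rel=0.1)
        assert fit.mode["sigma_individual"] == pytest.approx(11.6, rel=0.25)
        assert fit.significant["beta_Q"]

    def test_null_covariates_not_significant(self, rng):
        table = simulate_blmm_table(rng, beta_q=0.0, betas=(0, 0, 0),
                                    n_pops=16, trees_per_pop=10,
                                    leaves_per_tree=6)
        fit = fit_blmm(table, "area_cm2", self.SPEC, seed=rng)
        flags = [fit.significant[f"beta_{c}"]
                 for c in ("BioPC2", "BioPC3", "BioPC4", "Q")]
        assert sum(flags) <= 1  # at most one accidental 5%-level exclusion

    def test_sigmas_always_positive(self, rng):
        table = simulate_blmm_table(rng, n_pops=8, trees_per_pop=6,
                                    leaves_per_tree=4)
        fit = fit_blmm(table, "area_cm2", self.SPEC, seed=rng)
        assert (fit.samples["sigma_all"] > 0).all()
        assert (fit.samples["sigma_individual"] > 0).all()

    def test_rhat_reported_and_near_one(self, rng):
        table = simulate_blmm_table(rng, n_pops=10, trees_per_pop=8,
                                    leaves_per_tree=5)
        fit = fit_blmm(table, "area_cm2", self.SPEC, seed=rng)
        assert all(r < 1.1 for r in fit.rhat.values())

    def test_gls_limit_matches_closed_form(self, rng):
        """With both variances effectively known (huge data), the posterior
        mean of beta approaches the GLS estimate computed independently."""
        table = simulate_blmm_table(rng, n_pops=24, trees_per_pop=12,
                                    leaves_per_tree=8)
        fit = fit_blmm(table, "area_cm2", self.SPEC, seed=rng)
        # independent GLS oracle on tree means with the true variances
        g = table.groupby("tree_id")
        ybar = g["area_cm2"].mean()
        n_j = g.size()
        X = g[["BioPC2", "BioPC3", "BioPC4", "Q"]].first()
        X = np.hstack([np.ones((len(X), 1)), X.to_numpy()])
        v = 11.6**2 + 13.1**2 / n_j.to_numpy()
        w = 1 / v
        beta_gls = np.linalg.solve(X.T @ (X * w[:, None]),
                                   X.T @ (ybar.to_numpy() * w))
        for i, name in enumerate(["beta0_mean", "beta_BioPC2", "beta_BioPC3",
                                  "beta_BioPC4", "beta_Q"]):
            post_mean = fit.samples[name].mean()
            post_sd = fit.samples[name].std()
            assert abs(post_mean - beta_gls[i]) < 4 * post_sd

    def test_improper_posterior_rejected(self, rng):
        table = simulate_blmm_table(rng, n_pops=1, trees_per_pop=4,
                                    leaves_per_tree=2)
        with pytest.raises(ValueError, match="improper"):
            fit_blmm(table, "area_cm2", self.SPEC, seed=rng)


class TestVarietyClassification:
    def _table(self, rows):
        return pd.DataFrame([
            {"population": p, "tree_id": f"{p}_t{i}", "leaf_id": f"{p}_{i}_{j}",
             "length_cm": l, "width_cm": w}
            for p, trees in rows.items()
            for i, (l, w) in enumerate(trees)
            for j in range(1)
        ])

    def test_wide_leaf_population_called_borealis(self):
        # tree-average width 7.3, length 14.1: the wide-leaf morphotype
        table = self._table({"P2": [(14.1, 7.3 + d) for d in
                                    (-0.4, -0.2, 0.0, 0.2, 0.4)]})
        res = classify_variety(table)
        assert res.loc[0, "variety"] == "borealis"

    def test_narrow_leaf_population_called_kobus(self):
        # tree-average width 5.3, length 9.9
        table = self._table({"P15": [(9.9, 5.3 + d) for d in
                                     (-0.4, -0.2, 0.0, 0.2, 0.4)]})
        res = classify_variety(table)
        assert res.loc[0, "variety"] == "kobus"

    def test_straddling_population_intermediate(self):
        widths = np.linspace(5.0, 7.0, 10)
        table = self._table({"P19": [(12.0, w) for w in widths]})
        res = classify_variety(table)
        assert res.loc[0, "variety"] == "intermediate"

    def test_too_few_trees_no_call(self):
        table = self._table({"P": [(12.0, 7.0), (12.0, 7.1)]})
        with pytest.warns(UserWarning, match="fewer"):
            res = classify_variety(table)
        assert res.loc[0, "variety"] is None

    def test_invariant_to_leaf_order_and_subsampling(self, rng):
        from kobuspop.synth import SyntheticScenario, generate_leaf_data
        # trees well clear of the 6-cm boundary so the call is stable
        scenario = SyntheticScenario(n_north_demes=3, n_south_demes=3,
                                     trees_per_pop=8, leaves_per_tree=8,
                                     north_width=8.0, south_width=4.5,
                                     leaf_dim_tree_sd=0.3)
        table, _, _ = generate_leaf_data(scenario, rng)
        full = classify_variety(table)
        shuffled = classify_variety(table.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(
            full.sort_values("population").reset_index(drop=True),
            shuffled.sort_values("population").reset_index(drop=True))
        sub = table.groupby("tree_id", group_keys=False).head(5)
        subsampled = classify_variety(sub)
        pd.testing.assert_frame_equal(
            full[["population", "variety"]].sort_values("population")
                .reset_index(drop=True),
            subsampled[["population", "variety"]].sort_values("population")
                .reset_index(drop=True))
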