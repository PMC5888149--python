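import numpy as np
import pandas as pd
import pytest

import pyrodiv as pv
from pyrodiv.car_model import (
    CV_COVARIATES,
    MEANS_COVARIATES,
    RichnessCARModel,
    build_design,
    effects_table,
    format_effects,
    split_rhat,
    waic,
)
from pyrodiv.grids import GridSpec, queen_adjacency

from conftest import make_model_cells


def toy_cells(n=24, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "npp": rng.random(n),
            "topo_het": rng.random(n) * 100,
            "is_wet": rng.random(n) < 0.5,
            "pyrodiversity": rng.random(n) * 20,
            "mean_logarea": rng.normal(size=n),
            "mean_fireday": rng.normal(size=n),
            "mean_logfri": rng.normal(size=n),
            "mean_logfrp": rng.normal(size=n),
            "cv_area": rng.random(n),
            "cv_fireday": rng.random(n),
            "cv_fri": rng.random(n),
            "cv_frp": rng.random(n),
            "richness": rng.poisson(10, n),
            "in_analysis": True,
        }
    )


class TestDesign:
    def test_no_fire_covariates_baseline_columns(self):
        cells = toy_cells()
        X, y, ids, info = build_design(cells, "richness", fire_covariates=())
        assert info.names == ["intercept", "npp_spline_1", "npp_spline_2",
                              "npp_spline_3", "npp_spline_4", "npp_spline_5",
                              "topo_het", "wet"]
        assert np.allclose(X[:, 0], 1.0)

    def test_stratum_columns_zero_off_stratum(self):
        cells = toy_cells()
        X, y, ids, info = build_design(cells, "richness",
                                       fire_covariates=("pyrodiversity",),
                                       min_stratum=1)
        wet = cells["is_wet"].to_numpy()
        jw = info.names.index("pyrodiversity:wet")
        jd = info.names.index("pyrodiversity:dry")
        assert np.all(X[~wet, jw] == 0)
        assert np.all(X[wet, jd] == 0)
        # on-stratum entries equal the z-scored covariate
        z = (cells["pyrodiversity"] - cells["pyrodiversity"].mean()) / cells["pyrodiversity"].std(ddof=0)
        assert np.allclose(X[wet, jw], z[wet])

    def test_hand_built_oracle_small_table(self):
        """Non-spline columns reproduce an explicitly enumerated design."""
        cells = toy_cells(n=6, seed=3)
        X, y, ids, info = build_design(cells, "richness",
                                       fire_covariates=("pyrodiversity",),
                                       quadratic=True, min_stratum=1)
        wet = cells["is_wet"].to_numpy()
        topo = cells["topo_het"].to_numpy()
        tz = (topo - topo.mean()) / topo.std()
        p = cells["pyrodiversity"].to_numpy()
        pz = (p - p.mean()) / p.std()
        expected = {
            "intercept": np.ones(6),
            "topo_het": tz,
            "wet": wet.astype(float),
            "pyrodiversity:wet": pz * wet,
            "pyrodiversity:dry": pz * ~wet,
            "pyrodiversity^2:wet": pz**2 * wet,
            "pyrodiversity^2:dry": pz**2 * ~wet,
        }
        for name, col in expected.items():
            assert np.allclose(X[:, info.names.index(name)], col), name
        assert np.array_equal(y, cells["richness"].to_numpy())

    def test_spline_basis_partition_of_unity(self):
        cells = toy_cells(n=60, seed=4)
        X, _, _, info = build_design(cells, "richness", fire_covariates=())
        spline = X[:, 1:6]
        # dropped first column: total = 1 - B0, so all rows in [0, 1]
        assert (spline.sum(axis=1) <= 1 + 1e-9).all()
        assert (spline >= -1e-12).all()

    def test_small_stratum_rejected(self):
        cells = toy_cells()
        cells["is_wet"] = True
        with pytest.raises(ValueError, match="dry stratum"):
            build_design(cells, "richness", fire_covariates=("pyrodiversity",))

    def test_means_cv_never_mixed(self):
        cells = toy_cells()
        with pytest.raises(ValueError, match="mixed"):
            build_design(cells, "richness", model_class="means",
                         fire_covariates=("pyrodiversity", "cv_area"),
                         min_stratum=1)

    def test_default_covariate_sets(self):
        cells = toy_cells(n=40, seed=5)
        _, _, _, info_m = build_design(cells, "richness", model_class="means",
                                       min_stratum=1)
        _, _, _, info_c = build_design(cells, "richness", model_class="cv",
                                       min_stratum=1)
        assert info_m.fire_covariates == MEANS_COVARIATES
        assert info_c.fire_covariates == CV_COVARIATES


class TestWaic:
    def test_single_draw_no_penalty(self):
        ll = np.array([[-1.0, -2.0, -0.5]])
        assert waic(ll) == pytest.approx(-2 * ll.sum())

    def test_duplicating_draws_invariant(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-2, 0.3, (50, 20))
        assert waic(np.vstack([ll, ll])) == pytest.approx(waic(ll))

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        ll = rng.normal(-2, 0.3, (2, 100, 15))
        idata = az.from_dict(log_likelihood={"y": ll})
        theirs = az.waic(idata, scale="deviance").elpd_waic
        assert waic(ll.reshape(200, 15)) == pytest.approx(theirs, abs=1e-6)


def test_split_rhat_detects_disagreement():
    rng = np.random.default_rng(2)
    same = np.stack([rng.normal(0, 1, 400), rng.normal(0, 1, 400)])
    apart = np.stack([rng.normal(0, 1, 400), rng.normal(3, 1, 400)])
    assert split_rhat(same) < 1.05
    assert split_rhat(apart) > 1.5


class TestModelValidation:
    def test_noninteger_response_rejected(self):
        A, _ = queen_adjacency(5, 5)
        with pytest.raises(ValueError, match="integer"):
            RichnessCARModel(np.full(25, 1.5), np.ones((25, 1)), A)

    def test_negative_response_rejected(self):
        A, _ = queen_adjacency(5, 5)
        y = np.zeros(25, int)
        y[0] = -1
        with pytest.raises(ValueError):
            RichnessCARModel(y, np.ones((25, 1)), A)

    def test_asymmetric_adjacency_rejected(self):
        from scipy import sparse
        A = sparse.csr_matrix(np.triu(np.ones((9, 9)), 1))
        with pytest.raises(ValueError, match="symmetric"):
            RichnessCARModel(np.ones(9, int), np.ones((9, 1)), A)


class TestSampler:
    def test_intercept_only_analytic_limit(self):
        """Constant counts: intercept posterior concentrates at ln k and the
        spatial field shrinks."""
        A, _ = queen_adjacency(10, 20)
        y = np.full(200, 7)
        m = RichnessCARModel(y, np.ones((200, 1)), A, names=["intercept"])
        res = m.fit(chains=2, iterations=1200, burn_in=500, seed=0)
        assert np.median(res.beta[:, 0]) == pytest.approx(np.log(7), abs=0.05)
        assert res.spatial_sd() < 0.3

    def test_gaussian_conjugate_matches_gls(self):
        """With known precisions the Gaussian-mode posterior mean of β matches
        the closed-form GLS solution (ICAR covariance via pseudo-inverse)."""
        nr, nc = 8, 8
        A, _ = queen_adjacency(nr, nc)
        n = nr * nc
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(0, 0.5, n)
        tau_eps, tau_phi = 4.0, 2.0
        m = RichnessCARModel(y, X, A, family="gaussian",
                             fixed_tau=(tau_eps, tau_phi))
        res = m.fit(chains=2, iterations=3000, burn_in=1000, seed=0)
        L = m.L.toarray()
        V = np.linalg.pinv(L) / tau_phi + np.eye(n) / tau_eps
        Vi = np.linalg.inv(V)
        prec = X.T @ Vi @ X + np.eye(2) / 100.0
        gls = np.linalg.solve(prec, X.T @ Vi @ y)
        assert np.allclose(res.beta.mean(axis=0), gls, rtol=0.01, atol=0.01)

    def test_icar_sum_to_zero_every_draw(self):
        A, _ = queen_adjacency(6, 6)
        rng = np.random.default_rng(4)
        y = rng.poisson(8, 36)
        m = RichnessCARModel(y, np.ones((36, 1)), A)
        res = m.fit(chains=1, iterations=400, burn_in=200, seed=1)
        assert np.abs(res.phi.mean(axis=1)).max() < 1e-10

    def test_permutation_invariance(self):
        """Permuting cells (with adjacency permuted consistently) leaves
        posterior summaries unchanged within Monte Carlo error."""
        nr, nc = 6, 6
        A, _ = queen_adjacency(nr, nc)
        n = nr * nc
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.poisson(np.exp(1.5 + 0.3 * X[:, 1]))
        m1 = RichnessCARModel(y, X, A)
        r1 = m1.fit(chains=2, iterations=1500, burn_in=700, seed=2)
        perm = rng.permutation(n)
        A2 = A[perm][:, perm]
        m2 = RichnessCARModel(y[perm], X[perm], A2)
        r2 = m2.fit(chains=2, iterations=1500, burn_in=700, seed=7)
        med1 = np.median(r1.beta, axis=0)
        med2 = np.median(r2.beta, axis=0)
        assert np.allclose(med1, med2, atol=0.08)

    def test_unconverged_flagged_not_silent(self):
        A, _ = queen_adjacency(5, 5)
        rng = np.random.default_rng(6)
        y = rng.poisson(5, 25)
        m = RichnessCARModel(y, np.ones((25, 1)), A)
        res = m.fit(chains=2, iterations=60, burn_in=20, seed=0)
        assert isinstance(res.converged, bool)  # present either way
        single = m.fit(chains=1, iterations=60, burn_in=20, seed=0)
        assert not single.converged  # one chain can never certify convergence


class TestResults:
    @pytest.fixture(scope="class")
    def fitted(self):
        g = GridSpec(n_rows=10, n_cols=10)
        env = pv.gen_environment(g, 21)
        truth = pv.SyntheticTruth(beta_pyro_wet=0.15, beta_pyro_dry=0.0)
        cells = make_model_cells(g, env, truth, seed=22)
        m = RichnessCARModel.from_cells(cells, "mammals_all", g,
                                        fire_covariates=("pyrodiversity",))
        return m, m.fit(chains=2, iterations=900, burn_in=400, seed=23)

    def test_quantile_order(self, fitted):
        _, res = fitted
        tbl = res.coef_table()
        assert (tbl["q025"] <= tbl["median"]).all()
        assert (tbl["median"] <= tbl["q975"]).all()
        assert np.isfinite(res.waic())

    def test_quantiles_match_sorted_draw_oracle(self, fitted):
        _, res = fitted
        j = res.names.index("pyrodiversity:wet")
        draws = np.sort(res.beta[:, j])
        tbl = res.coef_table().set_index("coef")
        assert tbl.loc["pyrodiversity:wet", "median"] == pytest.approx(
            np.percentile(draws, 50))
        assert tbl.loc["pyrodiversity:wet", "q025"] == pytest.approx(
            np.percentile(draws, 2.5))

    def test_effects_table_support_flags(self):
        class Fake:
            names = ["intercept", "pyrodiversity:wet", "pyrodiversity:dry"]
            def coef_table(self):
                return pd.DataFrame({
                    "coef": self.names,
                    "median": [1.0, 0.5, 0.0],
                    "q025": [0.9, 0.5, -0.4],
                    "q975": [1.1, 0.5, 0.4],
                    "supported": [True, True, False],
                    "rhat": [1.0] * 3,
                })
        eff = effects_table({"mammals": Fake()})
        assert len(eff) == 2  # intercept has no stratum
        wet = eff[eff["stratum"] == "wet"].iloc[0]
        assert wet["supported"] and wet["median"] == 0.5
        dry = eff[eff["stratum"] == "dry"].iloc[0]
        assert not dry["supported"]
        assert "mammals" in format_effects(eff)

    def test_predicted_curve_monotone_for_positive_effect(self, fitted):
        _, res = fitted
        grid_vals = np.linspace(5, 25, 15)
        cur = res.predicted_richness_curve("pyrodiversity", grid_vals, "wet")
        med = cur["median"].to_numpy()
        # wet effect is strongly positive in truth: fitted curve rises
        assert med[-1] > med[0]
        assert (cur["lo"] <= cur["median"]).all()
        assert (cur["median"] <= cur["hi"]).all()

    def test_predicted_curve_band_matches_draw_oracle(self, fitted):
        model, res = fitted
        grid_vals = np.array([10.0, 20.0])
        cur = res.predicted_richness_curve("pyrodiversity", grid_vals, "dry")
        info = model.design_info
        base = info.stratum_means["dry"].copy()
        gz = (grid_vals - info.centers["pyrodiversity"]) / info.scales["pyrodiversity"]
        for i, v in enumerate(gz):
            row = base.copy()
            row[res.names.index("pyrodiversity:dry")] = v
            row[res.names.index("pyrodiversity:wet")] = 0.0
            mu = np.exp(row @ res.beta.T)
            assert cur["median"].iloc[i] == pytest.approx(np.percentile(mu, 50))

    def test_summary_smoke(self, fitted):
        _, res = fitted
        s = res.summary()
        assert "wAIC" in s and "pyrodiversity:wet" in s

    def test_plot_smoke(self, fitted):
        import matplotlib
        matplotlib.use("Agg")
        _, res = fitted
        ax = res.plot_richness_curve("pyrodiversity", np.linspace(5, 25, 8))
        assert len(ax.lines) == 2
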