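import numpy as np
import pandas as pd
import pytest

from treeresp import animal_model, orchard_sim
from treeresp.animal_model import (
    Design,
    ModelError,
    ModelSpec,
    REMLProblem,
    VarianceComponents,
    build_design,
    genetic_correlation,
    gxe_diagnostic,
    heritability,
    site_contrasts,
    solve_mme,
)
from treeresp.pedigree import (
    RelationshipMatrix,
    numerator_relationship_matrix,
    validate_pedigree,
)

SPEC2 = ModelSpec(("mai", "density"))


def _founder_pedigree(n):
    return validate_pedigree([(f"I{i}", None, None) for i in range(n)])


def _sire_family_data(rng, n_sires=10, per_sire=5, sites=("a", "b", "c"),
                      va=4.0, ve=6.0):
    """Univariate half-sib dataset with known truth (offspring phenotyped)."""
    records = [(f"S{i}", None, None) for i in range(n_sires)]
    rows = []
    u_sire = rng.normal(0, np.sqrt(va), n_sires)
    k = 0
    for i in range(n_sires):
        for _ in range(per_sire):
            ind = f"O{k}"
            records.append((ind, f"S{i}", None))
            u = 0.5 * u_sire[i] + rng.normal(0, np.sqrt(0.75 * va))
            site = sites[k % len(sites)]
            mu = {"a": 10.0, "b": 12.0, "c": 9.0}.get(site, 10.0)
            rows.append((ind, site, mu + u + rng.normal(0, np.sqrt(ve))))
            k += 1
    ped = validate_pedigree(records)
    phen = pd.DataFrame(rows, columns=["individual", "site", "mai"])
    return ped, phen


class TestBuildDesign:
    def test_two_sites_two_traits(self):
        ped = _founder_pedigree(4)
        phen = pd.DataFrame(
            {
                "individual": ["I0", "I1", "I2", "I3"],
                "site": ["a", "a", "b", "b"],
                "mai": [1.0, 2.0, 3.0, 4.0],
                "density": [0.1, 0.2, 0.3, 0.4],
            }
        )
        d = build_design(SPEC2, phen, ped.ids)
        X, _ = d.x_rows()
        assert X.shape == (8, 4)
        assert np.linalg.matrix_rank(X) == 4
        assert d.complete

    def test_missing_trait_drops_row(self):
        ped = _founder_pedigree(4)
        phen = pd.DataFrame(
            {
                "individual": ["I0", "I1", "I2", "I3"],
                "site": ["a", "a", "b", "b"],
                "mai": [1.0, 2.0, 3.0, 4.0],
                "density": [0.1, np.nan, 0.3, 0.4],
            }
        )
        d = build_design(SPEC2, phen, ped.ids)
        assert not d.complete
        assert len(d.trait_y[0]) == 4 and len(d.trait_y[1]) == 3

    def test_individual_absent_from_pedigree(self):
        ped = _founder_pedigree(2)
        phen = pd.DataFrame(
            {"individual": ["I0", "ghost"], "site": ["a", "a"],
             "mai": [1.0, 2.0], "density": [0.1, 0.2]}
        )
        with pytest.raises(ModelError, match="absent from pedigree"):
            build_design(SPEC2, phen, ped.ids)

    def test_empty_cell_error(self):
        ped = _founder_pedigree(3)
        phen = pd.DataFrame(
            {
                "individual": ["I0", "I1", "I2"],
                "site": ["a", "a", "b"],
                "mai": [1.0, 2.0, 3.0],
                "density": [0.1, 0.2, np.nan],  # no density at site b
            }
        )
        with pytest.raises(ModelError, match="no density records"):
            build_design(SPEC2, phen, ped.ids)

    def test_all_missing_trait_reduces_to_univariate(self):
        ped = _founder_pedigree(3)
        phen = pd.DataFrame(
            {
                "individual": ["I0", "I1", "I2"],
                "site": ["a", "a", "a"],
                "mai": [1.0, 2.0, 3.0],
                "density": [np.nan] * 3,
            }
        )
        d = build_design(SPEC2, phen, ped.ids)
        assert d.spec.traits == ("mai",)


class TestREML:
    def test_balanced_oneway_closed_form(self):
        """REML on a balanced one-way layout equals the ANOVA closed form.

        Groups are encoded as blocks of perfectly correlated additive effects
        (A = I_g kron J_k), which makes the animal model the classical
        one-way random-effects model with sigma2_u = sigma2_a.
        """
        rng = np.random.default_rng(5)
        g, k = 8, 5
        vu, ve = 3.0, 2.0
        u = rng.normal(0, np.sqrt(vu), g)
        y = np.repeat(u, k) + rng.normal(0, np.sqrt(ve), g * k)
        phen = pd.DataFrame(
            {
                "individual": [f"I{i}" for i in range(g * k)],
                "site": "s",
                "mai": y,
            }
        )
        spec = ModelSpec(("mai",))
        d = build_design(spec, phen, phen["individual"].tolist())
        A = np.kron(np.eye(g), np.ones((k, k)))
        vc = REMLProblem(d, A).fit(compute_vcov=False)

        groups = y.reshape(g, k)
        mse = float(np.sum((groups - groups.mean(axis=1, keepdims=True)) ** 2)) / (
            g * (k - 1)
        )
        msb = k * float(np.sum((groups.mean(axis=1) - y.mean()) ** 2)) / (g - 1)
        sigma_u = (msb - mse) / k
        assert vc.R0[0, 0] == pytest.approx(mse, rel=1e-4)
        assert vc.G0[0, 0] == pytest.approx(sigma_u, rel=1e-4)

    def test_likelihood_grid_oracle(self, oracle):
        """REML optimum matches a brute-force restricted-likelihood grid."""
        rng = np.random.default_rng(21)
        ped, phen = _sire_family_data(rng, n_sires=10, per_sire=5)
        A = numerator_relationship_matrix(ped)
        spec = ModelSpec(("mai",))
        d = build_design(spec, phen, ped.ids)
        vc = REMLProblem(d, A).fit(compute_vcov=False)

        A_oo = A.submatrix(d.obs_ids)
        X, _ = d.x_rows()
        y = d.y_stacked()
        vp = float(np.var(y))
        grid = np.linspace(0.02 * vp, 2.0 * vp, 100)
        best, best_ll = None, -np.inf
        for va in grid:
            for ve in grid:
                V = va * A_oo + ve * np.eye(len(y))
                ll = oracle.dense_reml_loglik(y, X, V)
                if ll > best_ll:
                    best, best_ll = (va, ve), ll
        step = grid[1] - grid[0]
        assert abs(vc.G0[0, 0] - best[0]) <= step
        assert abs(vc.R0[0, 0] - best[1]) <= step
        # and the solver's criterion value at its optimum beats the grid's
        assert vc.loglik >= best_ll - 1e-6

    def test_eigen_path_matches_dense_oracle(self, oracle):
        """Fast-path likelihood equals the direct dense formula (bivariate)."""
        cfg = orchard_sim.SimConfig(n_parents=6, n_sites=3, offspring_per_site=8,
                                    seed=9)
        ds = orchard_sim.simulate_dataset(cfg)
        phen = oracle.add_mai(ds.phenotypes)
        A = numerator_relationship_matrix(ds.pedigree)
        d = build_design(SPEC2, phen, ds.pedigree.ids)
        prob = REMLProblem(d, A)
        G0 = np.array([[5.0, 1.0], [1.0, 0.4]])
        R0 = np.array([[60.0, 0.5], [0.5, 0.8]])
        A_oo = A.submatrix(d.obs_ids)
        n_o = len(d.obs_ids)
        V = np.kron(G0, A_oo) + np.kron(R0, np.eye(n_o))
        X, _ = d.x_rows()
        y = d.y_stacked()
        assert prob.loglik(G0, R0) == pytest.approx(
            oracle.dense_reml_loglik(y, X, V), abs=1e-6
        )

    def test_univariate_reduction(self, oracle):
        """Second trait all-missing reproduces the univariate fit."""
        rng = np.random.default_rng(2)
        ped, phen = _sire_family_data(rng, n_sires=12, per_sire=6)
        phen["density"] = np.nan
        A = numerator_relationship_matrix(ped)
        vc_bi = animal_model.reml_fit(SPEC2, phen, A, compute_vcov=False)
        vc_uni = animal_model.reml_fit(ModelSpec(("mai",)), phen, A,
                                       compute_vcov=False)
        assert vc_bi.traits == ("mai",)
        assert vc_bi.G0[0, 0] == pytest.approx(vc_uni.G0[0, 0], abs=1e-6)
        assert vc_bi.R0[0, 0] == pytest.approx(vc_uni.R0[0, 0], abs=1e-6)
        assert vc_bi.loglik == pytest.approx(vc_uni.loglik, abs=1e-6)

    def test_basis_invariance(self, oracle):
        """The REML criterion is invariant to reparameterizing X."""
        rng = np.random.default_rng(13)
        ped, phen = _sire_family_data(rng, n_sires=6, per_sire=4)
        A = numerator_relationship_matrix(ped)
        d = build_design(ModelSpec(("mai",)), phen, ped.ids)
        A_oo = A.submatrix(d.obs_ids)
        X, _ = d.x_rows()
        y = d.y_stacked()
        V = 2.0 * A_oo + 3.0 * np.eye(len(y))
        T = rng.normal(size=(X.shape[1], X.shape[1])) + 4 * np.eye(X.shape[1])
        ll1 = oracle.dense_reml_loglik(y, X, V)
        ll2 = oracle.dense_reml_loglik(y, X @ T, V)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_identity_A_warns(self):
        ped = _founder_pedigree(20)
        rng = np.random.default_rng(1)
        phen = pd.DataFrame(
            {
                "individual": [f"I{i}" for i in range(20)],
                "site": "s",
                "mai": rng.normal(size=20),
            }
        )
        d = build_design(ModelSpec(("mai",)), phen, ped.ids)
        A = numerator_relationship_matrix(ped)
        with pytest.warns(UserWarning, match="not separable"):
            REMLProblem(d, A)

    def test_missing_data_general_path(self, oracle):
        """Partially missing records fit through the dense path."""
        cfg = orchard_sim.SimConfig(n_parents=8, n_sites=3, offspring_per_site=15,
                                    seed=14)
        ds = orchard_sim.simulate_dataset(cfg)
        phen = oracle.add_mai(ds.phenotypes)
        phen.loc[phen.index[::7], "density"] = np.nan
        A = numerator_relationship_matrix(ds.pedigree)
        d = build_design(SPEC2, phen, ds.pedigree.ids)
        assert not d.complete
        vc = REMLProblem(d, A).fit(compute_vcov=False)
        assert vc.converged
        assert np.linalg.eigvalsh(vc.G0).min() >= -1e-10


class TestMME:
    @staticmethod
    def _fixed_vc(G0, R0, traits=("mai", "density")):
        return VarianceComponents(tuple(traits), np.asarray(G0, float),
                                  np.asarray(R0, float), 0.0, True, 0)

    def test_constant_within_sites(self):
        """y equal to its cell means gives a-hat = 0 and b-hat = cell means."""
        ped = _founder_pedigree(6)
        phen = pd.DataFrame(
            {
                "individual": [f"I{i}" for i in range(6)],
                "site": ["a", "a", "a", "b", "b", "b"],
                "mai": [5.0, 5.0, 5.0, 8.0, 8.0, 8.0],
                "density": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
            }
        )
        A = numerator_relationship_matrix(ped)
        d = build_design(SPEC2, phen, ped.ids)
        vc = self._fixed_vc([[1.0, 0.0], [0.0, 1.0]], [[2.0, 0.0], [0.0, 2.0]])
        res = solve_mme(d, ped, A, vc, compute_pev=False)
        bv = res.breeding_values[["bv_mai", "bv_density"]].to_numpy()
        np.testing.assert_allclose(bv, 0.0, atol=1e-10)
        assert res.fixed["mai:a"] == pytest.approx(5.0)
        assert res.fixed["density:b"] == pytest.approx(2.0)

    def test_direct_gls_blup_oracle(self, oracle):
        """MME solution equals GLS/BLUP from inverting the joint covariance."""
        cfg = orchard_sim.SimConfig(n_parents=5, n_sites=3, offspring_per_site=6,
                                    seed=4)
        ds = orchard_sim.simulate_dataset(cfg)
        phen = oracle.add_mai(ds.phenotypes)
        ped = ds.pedigree
        A = numerator_relationship_matrix(ped)
        d = build_design(SPEC2, phen, ped.ids)
        vc = self._fixed_vc([[20.0, 1.0], [1.0, 0.25]], [[70.0, 0.6], [0.6, 0.7]])
        res = solve_mme(d, ped, A, vc, compute_pev=False)

        # oracle: y ~ N(Xb, Z G Z' + R), direct inversion over ALL pedigree BVs
        n_ped = len(ped)
        X, which = d.x_rows()
        y = d.y_stacked()
        ped_idx = {v: i for i, v in enumerate(ped.ids)}
        obs_ped = [ped_idx[i] for i in d.obs_ids]
        m = len(y)
        Z = np.zeros((m, 2 * n_ped))
        for r, (t, i) in enumerate(which):
            Z[r, t * n_ped + obs_ped[i]] = 1.0
        G = np.kron(vc.G0, A.values)
        R = np.zeros((m, m))
        for r1, (t1, i1) in enumerate(which):
            for r2, (t2, i2) in enumerate(which):
                if i1 == i2:
                    R[r1, r2] = vc.R0[t1, t2]
        V = Z @ G @ Z.T + R
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a = G @ Z.T @ Vi @ (y - X @ b)
        np.testing.assert_allclose(res.fixed.to_numpy(), b, atol=1e-8)
        est = np.concatenate(
            [res.breeding_values["bv_mai"], res.breeding_values["bv_density"]]
        )
        np.testing.assert_allclose(est, a, atol=1e-8)

    def test_mme_residual_identity(self, oracle):
        """Z' R^-1 (y - Xb - Za) = G^-1 a at the MME solution."""
        cfg = orchard_sim.SimConfig(n_parents=5, n_sites=3, offspring_per_site=5,
                                    seed=6)
        ds = orchard_sim.simulate_dataset(cfg)
        phen = oracle.add_mai(ds.phenotypes)
        ped = ds.pedigree
        A = numerator_relationship_matrix(ped)
        d = build_design(SPEC2, phen, ped.ids)
        vc = self._fixed_vc([[10.0, 0.5], [0.5, 0.3]], [[60.0, 0.4], [0.4, 0.6]])
        res = solve_mme(d, ped, A, vc, compute_pev=False)

        n_ped = len(ped)
        X, which = d.x_rows()
        y = d.y_stacked()
        ped_idx = {v: i for i, v in enumerate(ped.ids)}
        obs_ped = [ped_idx[i] for i in d.obs_ids]
        m = len(y)
        Z = np.zeros((m, 2 * n_ped))
        for r, (t, i) in enumerate(which):
            Z[r, t * n_ped + obs_ped[i]] = 1.0
        R = np.zeros((m, m))
        for r1, (t1, i1) in enumerate(which):
            for r2, (t2, i2) in enumerate(which):
                if i1 == i2:
                    R[r1, r2] = vc.R0[t1, t2]
        a = np.concatenate(
            [res.breeding_values["bv_mai"], res.breeding_values["bv_density"]]
        )
        resid = y - X @ res.fixed.to_numpy() - Z @ a
        lhs = Z.T @ np.linalg.solve(R, resid)
        Ginv = np.kron(np.linalg.inv(vc.G0), np.linalg.inv(A.values))
        np.testing.assert_allclose(lhs, Ginv @ a, atol=1e-7)

    def test_blup_calibration(self, small_dataset, small_A, small_cfg, oracle):
        """Regression of true BV on BLUP at the true components has slope 1."""
        phen = oracle.add_mai(small_dataset.phenotypes)
        d = build_design(SPEC2, phen, small_dataset.pedigree.ids)
        vc = self._fixed_vc(small_cfg.G0, small_cfg.R0)
        res = solve_mme(d, small_dataset.pedigree, small_A, vc, compute_pev=False)
        est = res.breeding_values.set_index("individual")["bv_mai"]
        tru = small_dataset.true_breeding_values.set_index("individual")["bv_mai"]
        x = est.loc[tru.index].to_numpy()
        y = tru.to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.std(resid) / (np.std(x) * np.sqrt(len(x)))
        assert abs(slope - 1.0) <= 3 * se

    def test_pev_positive(self, small_fit):
        bv = small_fit.mme.breeding_values
        assert (bv["se_mai"] > 0).all() and (bv["se_density"] > 0).all()


class TestSummaries:
    def test_h2_zero_additive(self):
        vc = VarianceComponents(("mai",), np.array([[0.0]]), np.array([[5.0]]),
                                0.0, True, 0)
        assert heritability(vc, "mai")[0] == 0.0

    def test_h2_direct_ratio(self):
        vc = VarianceComponents(("mai",), np.array([[27.0]]), np.array([[73.0]]),
                                0.0, True, 0)
        assert heritability(vc, "mai")[0] == pytest.approx(0.27)

    def test_h2_zero_phenotypic_variance(self):
        vc = VarianceComponents(("mai",), np.array([[0.0]]), np.array([[0.0]]),
                                0.0, True, 0)
        with pytest.raises(ModelError, match="zero phenotypic"):
            heritability(vc, "mai")

    def test_ra_zero_covariance(self):
        vc = VarianceComponents(("mai", "density"),
                                np.array([[4.0, 0.0], [0.0, 9.0]]),
                                np.eye(2), 0.0, True, 0)
        assert genetic_correlation(vc)[0] == 0.0

    def test_ra_direct_ratio(self):
        vc = VarianceComponents(("mai", "density"),
                                np.array([[4.0, 1.8], [1.8, 9.0]]),
                                np.eye(2), 0.0, True, 0)
        assert genetic_correlation(vc)[0] == pytest.approx(0.30)

    def test_ra_boundary(self):
        vc = VarianceComponents(("mai", "density"),
                                np.array([[0.0, 0.0], [0.0, 9.0]]),
                                np.eye(2), 0.0, True, 0)
        with pytest.raises(ModelError, match="boundary"):
            genetic_correlation(vc)

    def test_h2_in_unit_interval(self, small_fit):
        for t in ("mai", "density"):
            h2, se = small_fit.h2[t]
            assert 0.0 <= h2 <= 1.0
            assert se > 0
        ra, se = small_fit.r_a
        assert abs(ra) <= 1.0

    def test_delta_se_vs_bootstrap(self, oracle):
        """Delta-method h2 SE within 10% of the parametric-bootstrap SD."""
        rng = np.random.default_rng(8)
        ped, phen = _sire_family_data(rng, n_sires=40, per_sire=10,
                                      va=4.0, ve=6.0)
        A = numerator_relationship_matrix(ped)
        spec = ModelSpec(("mai",))
        d = build_design(spec, phen, ped.ids)
        prob = REMLProblem(d, A)
        vc = prob.fit()
        h2, se_delta = heritability(vc, "mai")

        # simulate new responses at the REML estimates and refit
        A_oo = A.submatrix(d.obs_ids)
        L = np.linalg.cholesky(A_oo + 1e-10 * np.eye(len(A_oo)))
        X, _ = d.x_rows()
        b = np.linalg.lstsq(X, d.y_stacked(), rcond=None)[0]
        mean = X @ b
        sa, se_ = np.sqrt(vc.G0[0, 0]), np.sqrt(vc.R0[0, 0])
        h2_boot = []
        for _ in range(200):
            a = sa * (L @ rng.standard_normal(len(A_oo)))
            y = mean + a + se_ * rng.standard_normal(len(A_oo))
            vcb = prob.with_response([y]).fit(compute_vcov=False)
            h2_boot.append(vcb.G0[0, 0] / (vcb.G0[0, 0] + vcb.R0[0, 0]))
        sd_boot = float(np.std(h2_boot, ddof=1))
        assert se_delta == pytest.approx(sd_boot, rel=0.10)


class TestSiteContrasts:
    def test_identical_sites(self):
        ped = _founder_pedigree(6)
        phen = pd.DataFrame(
            {
                "individual": [f"I{i}" for i in range(6)],
                "site": ["a", "a", "a", "b", "b", "b"],
                "mai": [4.0, 5.0, 6.0, 4.0, 5.0, 6.0],
            }
        )
        A = numerator_relationship_matrix(ped)
        d = build_design(ModelSpec(("mai",)), phen, ped.ids)
        vc = VarianceComponents(("mai",), np.array([[1.0]]), np.array([[2.0]]),
                                0.0, True, 0)
        res = solve_mme(d, ped, A, vc, compute_pev=False)
        table, frac = site_contrasts(res, "mai")
        assert table["difference"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert frac == 0.0

    def test_pair_count(self, small_fit):
        table, _ = site_contrasts(small_fit.mme, "mai")
        k = len(small_fit.mme.design.sites)
        assert len(table) == k * (k - 1) // 2


class TestGxEDiagnostic:
    def test_runs_and_is_calibratedish(self, small_dataset, oracle):
        phen = oracle.add_mai(small_dataset.phenotypes)
        out = gxe_diagnostic(phen, small_dataset.pedigree, "mai")
        assert out["lrt"] >= 0.0
        assert 0.0 <= out["p_value"] <= 1.0
        assert out["loglik_full"] >= out["loglik_reduced"] - 1e-6
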