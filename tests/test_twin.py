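"""Twin model: design construction, REML oracles, Fisher information, rho_c."""

import numpy as np
import pytest
import scipy.optimize

import heritkit as hk
from heritkit.errors import DataError, PedigreeError
from tests.conftest import make_pedigree


def twin_model(n_mz, n_dz, sa2, sc2, sd2, se2, seed, covar=False):
    y, ped = hk.simulate_twin_cohort(n_mz, n_dz, sa2, sc2, sd2, se2, seed=seed)
    rng = np.random.default_rng(seed + 999)
    if covar:
        X = np.column_stack([np.ones(len(y)), rng.normal(size=len(y))])
        y = y + X @ np.array([0.3, 0.8])
    else:
        X = np.ones((len(y), 1))
    model = hk.TraitModel(y=y, X=X, sample_ids=ped.ids)
    return model, hk.build_twin_design(ped), ped


class TestBuildDesign:
    def test_cohort_pair_counts(self):
        """479 MZ + 112 DZ pairs give 958 and 224 indicator entries."""
        y, ped = hk.simulate_twin_cohort(479, 112, 0.5, 0.2, 0.0, 0.3, seed=0)
        d = hk.build_twin_design(ped)
        assert d.A.nnz == 958
        assert d.B.nnz == 224
        assert d.n_mz_pairs == 479 and d.n_dz_pairs == 112

    def test_no_twins_gives_zero_matrices(self):
        ped = make_pedigree([("f", "a", "0", "0", "1", "."), ("f", "b", "0", "0", "2", ".")])
        d = hk.build_twin_design(ped)
        assert d.A.nnz == 0 and d.B.nnz == 0 and d.n_singletons == 2

    def test_one_mz_pair_two_entries(self):
        ped = make_pedigree(
            [
                ("f1", "a", "0", "0", "1", "MZ"),
                ("f1", "b", "0", "0", "1", "MZ"),
                ("f2", "c", "0", "0", "2", "."),
                ("f2", "d", "0", "0", "2", "."),
            ]
        )
        d = hk.build_twin_design(ped)
        assert d.A.nnz == 2 and d.n_mz_pairs == 1 and d.n_singletons == 2

    def test_three_member_group_rejected(self):
        ped = make_pedigree(
            [
                ("f1", "a", "0", "0", "1", "MZ"),
                ("f1", "b", "0", "0", "1", "MZ"),
                ("f1", "c", "0", "0", "1", "MZ"),
            ]
        )
        with pytest.raises(PedigreeError, match="3 members"):
            hk.build_twin_design(ped)


def dense_neg_restricted_ll(params, y, X, A, B):
    """Independent from-scratch restricted likelihood (dense matrices)."""
    s2 = np.exp(params[0])
    rmz, rdz = np.tanh(params[1]), np.tanh(params[2])
    n = len(y)
    S = s2 * (np.eye(n) + rmz * A + rdz * B)
    Si = np.linalg.inv(S)
    C = X.T @ Si @ X
    beta = np.linalg.solve(C, X.T @ Si @ y)
    r = y - X @ beta
    return 0.5 * (np.linalg.slogdet(S)[1] + np.linalg.slogdet(C)[1] + r @ Si @ r)


class TestFitTwinReml:
    def test_duplicated_mz_members_push_r_to_boundary(self):
        """y identical within MZ pairs, DZ members independent."""
        rng = np.random.default_rng(2)
        rows, y = [], []
        for i in range(30):
            rows += [(f"m{i}", f"m{i}_1", "0", "0", "0", "MZ"),
                     (f"m{i}", f"m{i}_2", "0", "0", "0", "MZ")]
            v = rng.normal()
            y += [v, v]
        for i in range(30):
            rows += [(f"d{i}", f"d{i}_1", "0", "0", "0", "DZ"),
                     (f"d{i}", f"d{i}_2", "0", "0", "0", "DZ")]
            y += [rng.normal(), rng.normal()]
        ped = make_pedigree(rows)
        model = hk.TraitModel(y=np.array(y), X=np.ones((len(y), 1)), sample_ids=ped.ids)
        fit = hk.fit_twin_reml(model, hk.build_twin_design(ped))
        assert fit.r_mz > 0.99
        assert fit.boundary
        assert abs(fit.r_dz) < 3 / np.sqrt(30)

    def test_matches_dense_direct_maximization_oracle(self):
        """n = 40 cohort: AI-REML equals an independent Nelder-Mead fit to 1e-4."""
        model, design, ped = twin_model(12, 8, 0.5, 0.3, 0.0, 0.4, seed=4, covar=True)
        fit = hk.fit_twin_reml(model, design)
        A, B = design.A.toarray(), design.B.toarray()
        best = None
        for start in ([0.0, 0.5, 0.3], [np.log(np.var(model.y)), 0.0, 0.0]):
            res = scipy.optimize.minimize(
                dense_neg_restricted_ll, start, args=(model.y, model.X, A, B),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 10000, "maxfev": 10000},
            )
            if best is None or res.fun < best.fun:
                best = res
        assert fit.sigma_Y2 == pytest.approx(np.exp(best.x[0]), abs=1e-4)
        assert fit.r_mz == pytest.approx(np.tanh(best.x[1]), abs=1e-4)
        assert fit.r_dz == pytest.approx(np.tanh(best.x[2]), abs=1e-4)

    def test_parameter_recovery(self):
        """sigma_Y2=1, r_MZ=0.8, r_DZ=0.55 recovered across replicates."""
        ests = []
        for rep in range(20):
            model, design, _ = twin_model(800, 800, 0.5, 0.3, 0.0, 0.2, seed=50 + rep)
            fit = hk.fit_twin_reml(model, design)
            ests.append([fit.sigma_Y2, fit.r_mz, fit.r_dz])
        ests = np.array(ests)
        for j, truth in enumerate([1.0, 0.8, 0.55]):
            se = ests[:, j].std(ddof=1) / np.sqrt(len(ests))
            assert ests[:, j].mean() == pytest.approx(truth, abs=3 * se)

    def test_invariant_to_pair_relabeling_and_member_swap(self):
        model, design, ped = twin_model(20, 20, 0.5, 0.2, 0.0, 0.3, seed=6)
        fit = hk.fit_twin_reml(model, design)
        # swap members within every pair (exchange adjacent rows)
        perm = np.arange(design.n).reshape(-1, 2)[:, ::-1].ravel()
        tab = ped.table.iloc[perm].reset_index(drop=True)
        ped2 = hk.Pedigree(tab)
        model2 = hk.TraitModel(y=model.y[perm], X=model.X[perm], sample_ids=ped2.ids)
        fit2 = hk.fit_twin_reml(model2, hk.build_twin_design(ped2))
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)
        assert fit2.r_mz == pytest.approx(fit.r_mz, abs=1e-8)

    def test_mz_only_matches_anova_intraclass(self):
        """With no DZ pairs the fit reduces to an intraclass correlation."""
        model, design, _ = twin_model(500, 0, 0.6, 0.2, 0.0, 0.2, seed=7)
        fit = hk.fit_twin_reml(model, design)
        assert fit.dropped == ["r_dz"]
        yp = model.y.reshape(-1, 2)
        n = len(yp)
        msb = 2 * np.var(yp.mean(axis=1), ddof=1)
        msw = (np.diff(yp, axis=1) ** 2 / 2).sum() / n
        icc = (msb - msw) / (msb + msw)
        assert fit.r_mz == pytest.approx(icc, abs=3 * 0.03 / np.sqrt(n) + 0.01)


class TestFisherInformation:
    def test_no_twins_only_variance_entry(self):
        n, p = 10, 1
        X = np.ones((n, p))
        Z = np.zeros((n, n))
        s2 = 0.7
        psi = hk.twin_fisher_information(X, s2, 0.0, 0.0, Z, Z)
        expected = np.zeros((3, 3))
        expected[0, 0] = (n - p) / (2 * s2**2)
        assert psi == pytest.approx(expected, abs=1e-12)

    def test_variance_entry_scaling(self):
        model, design, _ = twin_model(10, 10, 0.5, 0.2, 0.0, 0.3, seed=9)
        A, B = design.A, design.B
        psi1 = hk.twin_fisher_information(model.X, 1.0, 0.5, 0.3, A, B)
        psi2 = hk.twin_fisher_information(model.X, 2.0, 0.5, 0.3, A, B)
        assert psi2[0, 0] == pytest.approx(psi1[0, 0] / 4)

    def test_matches_curvature_of_expected_restricted_ll(self):
        """Psi equals minus the Hessian of E[l_R(theta)] at the true theta
        (the defining property of Fisher information), by central FD."""
        model, design, _ = twin_model(15, 15, 0.5, 0.3, 0.0, 0.2, seed=10, covar=True)
        A, B = design.A.toarray(), design.B.toarray()
        X = model.X
        n = design.n
        theta0 = np.array([0.9, 0.7, 0.45])
        S0 = theta0[0] * (np.eye(n) + theta0[1] * A + theta0[2] * B)

        def expected_ll(t):
            S = t[0] * (np.eye(n) + t[1] * A + t[2] * B)
            Si = np.linalg.inv(S)
            C = X.T @ Si @ X
            P = Si - Si @ X @ np.linalg.inv(C) @ X.T @ Si
            return -0.5 * (
                np.linalg.slogdet(S)[1] + np.linalg.slogdet(C)[1] + np.trace(P @ S0)
            )

        h = np.array([1e-4, 5e-5, 5e-5])
        H = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei = np.eye(3)[i] * h[i]
                ej = np.eye(3)[j] * h[j]
                H[i, j] = (
                    expected_ll(theta0 + ei + ej)
                    - expected_ll(theta0 + ei - ej)
                    - expected_ll(theta0 - ei + ej)
                    + expected_ll(theta0 - ei - ej)
                ) / (4 * h[i] * h[j])
        psi = hk.twin_fisher_information(X, theta0[0], theta0[1], theta0[2], A, B)
        assert np.abs(psi + H).max() <= 1e-4 * np.abs(psi).max()


class TestCommonEnvProportion:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [
            (0.970, 0.832, 0.694),  # height
            (0.677, 0.476, 0.275),  # HDL
            (0.656, 0.342, 0.028),  # LDL
            (0.646, 0.585, 0.524),  # DBP
        ],
    )
    def test_published_twin_correlations(self, r_mz, r_dz, expected):
        assert hk.rho_c_lower_bound(r_mz, r_dz) == pytest.approx(expected, abs=5e-4)

    def test_cancellation(self):
        assert hk.rho_c_lower_bound(0.8, 0.4) == 0.0

    def test_estimator_unbiased_without_dominance(self):
        """rho_c estimates sigma_c^2/sigma_Y^2 when sigma_d^2 = 0."""
        rhos = []
        for rep in range(20):
            model, design, _ = twin_model(800, 800, 0.5, 0.3, 0.0, 0.2, seed=300 + rep)
            fit = hk.fit_twin_reml(model, design)
            rhos.append(fit.rho_c)
        rhos = np.array(rhos)
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert rhos.mean() == pytest.approx(0.3, abs=3 * se)

    def test_missing_pair_type_raises(self):
        model, design, _ = twin_model(50, 0, 0.5, 0.2, 0.0, 0.3, seed=12)
        fit = hk.fit_twin_reml(model, design)
        with pytest.raises(DataError):
            hk.common_env_proportion(fit)
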