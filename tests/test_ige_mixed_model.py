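import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from socsurv.ige_mixed_model import (
    RemlConfig,
    VarianceComponents,
    blup_solve,
    build_design,
    derived_parameters,
    reml_fit,
    reml_loglik,
    total_breeding_value,
)
from socsurv.pedigree import Pedigree
from socsurv.simulate import SimConfig, simulate_dataset


def _founder_frame(n, days=None):
    ped = Pedigree([f"a{i}" for i in range(n)], np.full(n, -1), np.full(n, -1))
    df = pd.DataFrame({
        "animal": ped.ids, "cage": [f"c{i // 4}" for i in range(n)],
        "house": "H1", "row": "R1", "level": "L1", "line": "X",
        "days": days if days is not None else np.arange(10, 10 + n, dtype=float),
        "event": 1,
    })
    return ped, df


class TestBuildDesign:
    def test_single_cage_zs(self):
        ped, df = _founder_frame(4)
        d = build_design(df, ped, "lam_direct")
        Zs = d.Z_S.toarray()[:, d.obs_idx]
        assert np.array_equal(Zs, np.ones((4, 4)) - np.eye(4))

    def test_two_cages_block_diagonal(self):
        ped, df = _founder_frame(8)
        d = build_design(df, ped, "lam_direct")
        Zs = d.Z_S.toarray()[:, d.obs_idx]
        expected = linalg.block_diag(*[np.ones((4, 4)) - np.eye(4)] * 2)
        assert np.array_equal(Zs, expected)

    def test_classical_mode_drops_zs(self):
        ped, df = _founder_frame(8)
        assert build_design(df, ped, "classical").Z_S is None

    def test_incomplete_cage_rejected(self):
        ped, df = _founder_frame(7)
        with pytest.raises(ValueError, match="incomplete cages"):
            build_design(df, ped, "lam_direct")


class TestBlupSolve:
    def _dense_mme(self, design, A, vc):
        """Henderson's mixed-model equations assembled densely (oracle)."""
        n_obs = len(design.y)
        n_ped = A.shape[0]
        Zd = np.zeros((n_obs, n_ped))
        Zd[np.arange(n_obs), design.obs_idx] = 1.0
        Zs = design.Z_S.toarray()
        Z = np.hstack([Zd, Zs])
        G = np.kron(vc.G0(), A)
        w = design.weights
        R = np.diag(vc.sigma2_e / w)
        for pos in design.cages:
            for i in pos:
                for j in pos:
                    if i != j:
                        R[i, j] = vc.rho * vc.sigma2_e / np.sqrt(w[i] * w[j])
        Ri = np.linalg.inv(R)
        X = design.X
        C = np.block([
            [X.T @ Ri @ X, X.T @ Ri @ Z],
            [Z.T @ Ri @ X, Z.T @ Ri @ Z + np.linalg.inv(G)],
        ])
        rhs = np.concatenate([X.T @ Ri @ design.y, Z.T @ Ri @ design.y])
        sol = np.linalg.solve(C, rhs)
        p = X.shape[1]
        return sol[:p], sol[p:p + n_ped], sol[p + n_ped:]

    def test_matches_dense_mme_oracle(self):
        rng = np.random.default_rng(3)
        ped, df = _founder_frame(8, days=rng.uniform(10, 60, 8).round())
        design = build_design(df, ped, "lam_direct")
        design.weights = rng.uniform(0.5, 2.0, 8)  # heterogeneous weights
        vc = VarianceComponents(sigma2_AD=3.0, sigma2_AS=0.8, sigma_ADS=0.6,
                                rho=0.2, sigma2_e=5.0)
        a_D, a_S, beta = blup_solve(design, ped, vc)
        fb, fd, fs = self._dense_mme(design, ped.relationship_matrix(), vc)
        assert np.abs(beta - fb).max() < 1e-8
        assert np.abs(a_D - fd).max() < 1e-8
        assert np.abs(a_S - fs).max() < 1e-8

    def test_tiny_genetic_variance_shrinks_to_zero(self):
        ped, df = _founder_frame(8, days=np.full(8, 30.0))
        design = build_design(df, ped, "lam_direct")
        vc = VarianceComponents(sigma2_AD=1e-8, sigma2_AS=1e-9, sigma_ADS=0.0,
                                rho=0.0, sigma2_e=1.0)
        a_D, a_S, _ = blup_solve(design, ped, vc)
        assert np.abs(a_D).max() < 1e-6 and np.abs(a_S).max() < 1e-6

    def test_spread_of_social_ebvs_grows_with_variance(self):
        rng = np.random.default_rng(4)
        ped, df = _founder_frame(16, days=rng.uniform(10, 60, 16).round())
        design = build_design(df, ped, "lam_direct")
        spreads = []
        for s2as in (0.1, 1.0, 5.0):
            vc = VarianceComponents(sigma2_AD=2.0, sigma2_AS=s2as, sigma_ADS=0.0,
                                    rho=0.0, sigma2_e=10.0)
            _, a_S, _ = blup_solve(design, ped, vc)
            spreads.append(a_S.var())
        assert spreads[0] <= spreads[1] <= spreads[2]


class TestRemlFit:
    def test_nested_classical_consistency(self):
        # no social effects in truth: classical and social fits agree on
        # the direct variance within 2 SE
        g = np.array([[900.0, 0.0], [0.0, 1e-12]])
        cfg = SimConfig(n_sires=8, dams_per_sire=8, mean_offspring_per_dam=10,
                        scale="linear", G0_true=g, rho_true=0.05,
                        sigma2_e_true=8000.0, houses=2, rows=2, levels=2,
                        study_end_day=None, seed=31)
        data, ped, _ = simulate_dataset(cfg)
        ped = ped.ensure(data["animal"])
        full = reml_fit(build_design(data, ped, "lam_direct"), ped)
        cls = reml_fit(build_design(data, ped, "classical"), ped)
        tol = 2 * max(full.se["sigma2_AD"], cls.se["sigma2_AD"])
        assert abs(full.vc.sigma2_AD - cls.vc.sigma2_AD) < tol

    def test_optimum_beats_truth(self, small_linear_sim):
        data, ped, truth = small_linear_sim
        design = build_design(data, ped, "lam_direct")
        fit = reml_fit(design, ped)
        vc_true = VarianceComponents(truth["sigma2_AD"], truth["sigma2_AS"],
                                     truth["sigma_ADS"], truth["rho"],
                                     truth["sigma2_e"])
        assert fit.loglik >= reml_loglik(design, ped.relationship_matrix(), vc_true) - 1e-6

    def test_unit_weights_two_step_equals_lam(self):
        # with all weights one, sigma2_e free, and a single fixed-effect
        # class, the weighted pseudo-record machinery is the plain model
        rng = np.random.default_rng(6)
        ped, df = _founder_frame(32, days=rng.uniform(100, 400, 32).round())
        pseudo = pd.DataFrame({"animal": ped.ids, "y_tilde": df["days"].astype(float),
                               "weight": 1.0, "delta": 1})
        d_ts = build_design(df, ped, "two_step", pseudo=pseudo)
        d_lam = build_design(df, ped, "lam_direct")
        cfg = RemlConfig(fix_sigma2_e=False,
                         init=VarianceComponents(2000.0, 100.0, 0.0, 0.02, 8000.0))
        f1 = reml_fit(d_ts, ped, cfg)
        f2 = reml_fit(d_lam, ped, cfg)
        assert abs(f1.loglik - f2.loglik) < 1e-5

    def test_mme_residual_at_solution(self, small_linear_sim):
        # EBVs and fixed solutions satisfy the mixed-model equations
        data, ped, _ = small_linear_sim
        sub = data[data["cage"].isin(sorted(data["cage"].unique())[:20])].reset_index(drop=True)
        ped_sub = ped.ensure(sub["animal"])
        design = build_design(sub, ped_sub, "lam_direct")
        fit = reml_fit(design, ped_sub)
        oracle = TestBlupSolve()._dense_mme(design, ped_sub.relationship_matrix(), fit.vc)
        assert np.abs(fit.a_D - oracle[1]).max() / max(np.abs(oracle[1]).max(), 1e-12) < 1e-6
        assert np.abs(fit.a_S - oracle[2]).max() / max(np.abs(oracle[2]).max(), 1e-12) < 1e-6


class TestDerivedParameters:
    def test_moderate_negative_covariance_line(self):
        s2ad, s2as, r_a = 0.30, 0.028, -0.20
        vc = VarianceComponents(s2ad, s2as, r_a * np.sqrt(s2ad * s2as), 0.0, 1.0)
        d = derived_parameters(vc, 4)
        assert round(d.sigma2_TBV, 2) == 0.44
        assert round(d.sigma2_P, 2) == 1.38

    def test_strong_social_line(self):
        s2ad, s2as, r_a = 0.12, 0.049, 0.55
        vc = VarianceComponents(s2ad, s2as, r_a * np.sqrt(s2ad * s2as), 0.0, 1.0)
        d = derived_parameters(vc, 4)
        assert round(d.sigma2_TBV, 2) == 0.81
        assert round(d.T2, 2) == 0.64

    def test_classical_limit(self):
        vc = VarianceComponents(0.4, 0.0, 0.0, 0.0, 1.0)
        d = derived_parameters(vc, 4)
        assert d.sigma2_TBV == pytest.approx(0.4)
        assert d.T2 == pytest.approx(d.h2_direct)
        assert d.r_A is None

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            derived_parameters(VarianceComponents(1.0), 1)

    def test_tbv_formula(self):
        assert total_breeding_value(1.0, 0.5, 4) == pytest.approx(2.5)
        assert total_breeding_value(1.3, 0.0, 4) == pytest.approx(1.3)

    def test_tbv_variance_matches_derived(self):
        # variance of simulated true TBVs equals the closed form
        from socsurv.simulate import simulate_breeding_values
        n = 2000
        ped = Pedigree([f"f{i}" for i in range(n)], np.full(n, -1), np.full(n, -1))
        G0 = np.array([[0.31, 0.015], [0.015, 0.041]])
        ad, as_ = simulate_breeding_values(ped, G0, np.random.default_rng(9))
        tbv = total_breeding_value(ad, as_, 4)
        vc = VarianceComponents(G0[0, 0], G0[1, 1], G0[0, 1], 0.0, 1.0)
        d = derived_parameters(vc, 4)
        se = d.sigma2_TBV * np.sqrt(2.0 / n)
        assert abs(tbv.var(ddof=1) - d.sigma2_TBV) < 3 * se

    def test_delta_method_ses_reported(self, small_linear_sim):
        data, ped, _ = small_linear_sim
        fit = reml_fit(build_design(data, ped, "lam_direct"), ped)
        assert set(fit.derived.se) >= {"sigma2_TBV", "sigma2_P", "T2"}
        assert fit.derived.se["sigma2_TBV"] > 0
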