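import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socsurv.crossval import (
    approximate_accuracy,
    censored_rank_correlation,
    extreme_groups,
    fit_fold,
    group_summary,
    make_folds,
    overlap_percentage,
    predict_phenotype,
)
from socsurv.ige_mixed_model import VarianceComponents
from socsurv.simulate import SimConfig, simulate_dataset


def _one_class_data(n_cages, seed=0, days=None):
    rng = np.random.default_rng(seed)
    n = 4 * n_cages
    return pd.DataFrame({
        "animal": [f"a{i}" for i in range(n)],
        "cage": [f"c{i // 4}" for i in range(n)],
        "house": "H1", "row": "R1", "level": "L1", "line": "X",
        "days": days if days is not None else rng.integers(10, 400, n),
        "event": rng.integers(0, 2, n),
    })


class TestMakeFolds:
    def test_partition(self):
        data = _one_class_data(10)
        plan = make_folds(data, k=5, seed=1)
        held = [set(plan.held_out(f)) for f in range(1, 6)]
        assert set().union(*held) == set(data["cage"])
        assert sum(len(h) for h in held) == data["cage"].nunique()
        assert all(len(h) == 2 for h in held)

    def test_determinism_and_seed_sensitivity(self):
        data = _one_class_data(10)
        a = make_folds(data, k=5, seed=3).fold_of_cage
        b = make_folds(data, k=5, seed=3).fold_of_cage
        c = make_folds(data, k=5, seed=4).fold_of_cage
        assert a == b
        assert a != c


class TestPredictPhenotype:
    def _setup(self):
        data = _one_class_data(1)
        ebvs = pd.DataFrame({
            "a_D": [1.0, 2.0, 3.0, 4.0],
            "a_S": [0.1, 0.2, 0.3, 0.4],
        }, index=["a0", "a1", "a2", "a3"])
        return data, ebvs

    def test_sbv_is_sum_of_cage_mates(self):
        data, ebvs = self._setup()
        p = predict_phenotype(ebvs, data, "SBV")
        assert p["a0"] == pytest.approx(0.2 + 0.3 + 0.4)

    def test_dsbv_is_dbv_plus_sbv(self):
        data, ebvs = self._setup()
        dbv = predict_phenotype(ebvs, data, "DBV")
        sbv = predict_phenotype(ebvs, data, "SBV")
        dsbv = predict_phenotype(ebvs, data, "DSBV")
        assert np.allclose(dsbv, dbv + sbv)

    def test_zero_social_makes_dsbv_rank_like_dbv(self):
        data, ebvs = self._setup()
        ebvs["a_S"] = 0.0
        dbv = predict_phenotype(ebvs, data, "DBV")
        dsbv = predict_phenotype(ebvs, data, "DSBV")
        assert list(dbv.sort_values().index) == list(dsbv.sort_values().index)

    def test_hazard_scale_flips_sign(self):
        data, ebvs = self._setup()
        assert np.allclose(predict_phenotype(ebvs, data, "DBV", hazard_scale=True),
                           -predict_phenotype(ebvs, data, "DBV"))

    def test_missing_ebv_uses_zero(self):
        data, ebvs = self._setup()
        p = predict_phenotype(ebvs.drop(index="a3"), data, "SBV")
        assert p["a0"] == pytest.approx(0.2 + 0.3)


class TestExtremeGroups:
    def test_quartile_selection(self):
        preds = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        best, worst = extreme_groups(preds, 0.25)
        assert best == {"a"} and worst == {"d"}

    def test_sign_flip_swaps_groups(self):
        preds = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        b1, w1 = extreme_groups(preds, 0.25)
        b2, w2 = extreme_groups(-preds, 0.25)
        assert b1 == w2 and w1 == b2

    def test_half_fraction_disjoint(self):
        preds = pd.Series(np.arange(8.0), index=[f"x{i}" for i in range(8)])
        best, worst = extreme_groups(preds, 0.5)
        assert len(best) == len(worst) == 4 and not best & worst

    def test_too_few_animals(self):
        with pytest.raises(ValueError):
            extreme_groups(pd.Series([1.0, 2.0], index=["a", "b"]), 0.25)


class TestGroupSummary:
    def test_difference(self):
        data = _one_class_data(1, days=[10, 20, 5, 5])
        data["event"] = 1
        out = group_summary(data, {"a0", "a1"}, {"a2", "a3"})
        assert out["difference"] == pytest.approx(10.0)
        assert out["best_mean"] == pytest.approx(15.0)

    def test_identical_groups_zero_difference(self):
        data = _one_class_data(1, days=[10, 20, 5, 5])
        out = group_summary(data, {"a0", "a1"}, {"a0", "a1"})
        assert out["difference"] == 0.0

    def test_km_curves_included(self):
        data = _one_class_data(2)
        data["event"] = 1
        out = group_summary(data, {"a0", "a1"}, {"a2", "a3"})
        assert "times" in out["km_best"] and "survival" in out["km_worst"]


class TestOverlap:
    def test_identical(self):
        assert overlap_percentage({"a", "b"}, {"a", "b"}) == 100.0

    def test_disjoint(self):
        assert overlap_percentage({"a", "b"}, {"c", "d"}) == 0.0

    def test_half_shared(self):
        assert overlap_percentage({"a", "b", "c", "d"}, {"a", "b", "x", "y"}) == 50.0

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            overlap_percentage({"a"}, {"a", "b"})


class TestCensoredRankCorrelation:
    def test_no_censoring_monotone_transform(self):
        obs = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        pred = np.exp(obs / 3.0)
        assert censored_rank_correlation(obs, np.ones(5, int), pred) == pytest.approx(1.0)

    def test_no_censoring_equals_spearman(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=20)
        pred = rng.normal(size=20)
        ours = censored_rank_correlation(obs, np.ones(20, int), pred)
        assert ours == pytest.approx(stats.spearmanr(obs, pred).statistic, abs=1e-12)

    def _averaged_spearman(self, obs, events, pred, exact_limit=6, n_mc=10000, seed=0):
        """Oracle: average plain Spearman over orderings of censored animals."""
        n = len(obs)
        unc = np.flatnonzero(events == 1)
        cen = np.flatnonzero(events == 0)
        base = np.empty(n)
        base[unc] = stats.rankdata(obs[unc])
        top = np.arange(len(unc) + 1, n + 1, dtype=float)
        rng = np.random.default_rng(seed)
        pr = stats.rankdata(pred)
        vals = []
        if len(cen) <= exact_limit:
            orderings = itertools.permutations(range(len(cen)))
        else:
            orderings = (rng.permutation(len(cen)) for _ in range(n_mc))
        for perm in orderings:
            r = base.copy()
            r[cen] = top[list(perm)]
            vals.append(np.corrcoef(r, pr)[0, 1])
        return np.asarray(vals)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_average_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        obs = rng.normal(size=n)
        events = np.array([1] * 5 + [0] * 4)
        pred = rng.normal(size=n)
        vals = self._averaged_spearman(obs, events, pred)
        ours = censored_rank_correlation(obs, events, pred)
        assert ours == pytest.approx(vals.mean(), abs=1e-10)

    def test_mc_average_larger_instance(self):
        rng = np.random.default_rng(7)
        n = 12
        obs = rng.normal(size=n)
        events = np.array([1] * 5 + [0] * 7)
        pred = rng.normal(size=n)
        vals = self._averaged_spearman(obs, events, pred, exact_limit=0, seed=11)
        ours = censored_rank_correlation(obs, events, pred)
        assert abs(ours - vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        n = 30
        obs = rng.normal(size=n)
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        pred = rng.normal(size=n)
        corrs = []
        for _ in range(1000):
            corrs.append(censored_rank_correlation(obs, events, rng.permutation(pred)))
        assert abs(np.mean(corrs)) < 3 / np.sqrt(1000)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            censored_rank_correlation([1.0, 2.0], [0, 0], [1.0, 2.0])
        with pytest.raises(ValueError):
            censored_rank_correlation([1.0, 2.0], [1, 1], [1.0, 1.0])


class TestApproximateAccuracy:
    VC = VarianceComponents(sigma2_AD=915.0, sigma2_AS=134.0, sigma_ADS=63.0,
                            rho=0.08, sigma2_e=11530.0)

    def test_rho_max_value(self):
        from socsurv.crossval import rho_max
        assert round(rho_max(self.VC, 4), 2) == 0.32

    def test_printed_accuracy(self):
        assert round(approximate_accuracy(0.149, self.VC, 4), 2) == 0.47

    def test_full_accuracy_limit(self):
        from socsurv.crossval import rho_max
        r = rho_max(self.VC, 4)
        assert approximate_accuracy(r, self.VC, 4) == pytest.approx(1.0)


class TestLeakage:
    def test_heldout_phenotypes_do_not_touch_training(self):
        cfg = SimConfig(n_sires=4, dams_per_sire=6, mean_offspring_per_dam=8,
                        scale="linear", houses=2, rows=2, levels=1,
                        study_end_day=None, seed=17)
        data, ped, _ = simulate_dataset(cfg)
        held = sorted(data["cage"].unique())[:5]
        f1 = fit_fold(data, ped, held, methods=("lam",), needs_classical=False)
        poked = data.copy()
        mask = poked["cage"].isin(held)
        poked.loc[mask, "days"] = poked.loc[mask, "days"] * 3 + 17
        f2 = fit_fold(poked, ped, held, methods=("lam",), needs_classical=False)
        assert np.array_equal(f1.ebvs["lam"]["a_D"].to_numpy(),
                              f2.ebvs["lam"]["a_D"].to_numpy())
        assert np.array_equal(f1.ebvs["lam"]["a_S"].to_numpy(),
                              f2.ebvs["lam"]["a_S"].to_numpy())
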