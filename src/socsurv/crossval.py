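"""Cage-wise cross-validation comparing the two-step and direct linear routes.

Whole cages are dealt into k folds within each fixed-effect class, so every
class is represented in every training set and each cage is held out exactly
once. Per fold, the evaluation is refit on the training 80% and the held-out
animals' phenotypes are predicted from combinations of estimated breeding
values:

* CBV  — classical direct-only EBV (survival-model â on the two-step route,
         a direct animal model on the linear route);
* DBV  — own direct EBV â_D,i;
* SBV  — Σ of cage mates' associative EBVs;
* DSBV — DBV + SBV.

Two-step predictions are on the log-hazard scale and are multiplied by −1
before ranking (low hazard = good). Evaluation uses extreme 25% groups
(observed mean survival days, Kaplan-Meier curves, best−worst difference,
between-method overlap) and a censoring-aware rank correlation: uncensored
animals are ranked by their fixed-effect-adjusted days and every censored
animal receives the average of the remaining ranks, which equals the
expectation of Spearman's correlation over random orderings of the censored
animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ige_mixed_model import (
    IGEFit,
    RemlConfig,
    VarianceComponents,
    build_design,
    reml_fit,
)
from .pedigree import Pedigree
from .pseudo_records import compute_pseudo_records
from .survival_model import CoxConfig, CoxFit, fit_cox_animal, kaplan_meier

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "make_folds",
    "predict_phenotype",
    "extreme_groups",
    "group_summary",
    "overlap_percentage",
    "censored_rank_correlation",
    "approximate_accuracy",
    "run_crossval",
]

MODES = ("CBV", "DBV", "SBV", "DSBV")


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    fold_of_cage: dict[str, int]   # cage → fold 1..k
    k: int
    seed: int

    def held_out(self, fold: int) -> list[str]:
        return [c for c, f in self.fold_of_cage.items() if f == fold]


def make_folds(data: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldPlan:
    """Deal cages round-robin into k folds within each fixed-effect class."""
    rng = np.random.default_rng(seed)
    cls = (
        data["house"].astype(str)
        + ":" + data["row"].astype(str)
        + ":" + data["level"].astype(str)
    )
    cage_class = pd.DataFrame({"cage": data["cage"], "cls": cls}).drop_duplicates("cage")
    fold_of_cage: dict[str, int] = {}
    for c, grp in cage_class.groupby("cls"):
        cages = sorted(grp["cage"])
        if len(cages) < k:
            logger.warning("class %s has only %d cages (< %d folds)", c, len(cages), k)
        order = rng.permutation(len(cages))
        start = int(rng.integers(k))  # rotate so small classes still reach all folds
        for pos, j in enumerate(order):
            fold_of_cage[cages[j]] = (start + pos) % k + 1
    return FoldPlan(fold_of_cage, k, seed)


# ---------------------------------------------------------------------------
# Predictions from EBVs
# ---------------------------------------------------------------------------


def predict_phenotype(
    ebvs: pd.DataFrame,
    data: pd.DataFrame,
    mode: str,
    classical: pd.Series | None = None,
    hazard_scale: bool = False,
) -> pd.Series:
    """Predicted phenotype per animal in ``data`` from training EBVs.

    ``ebvs`` is indexed by animal with columns a_D and a_S. Cage mates
    lacking an EBV contribute 0 (the mean) and are logged. With
    ``hazard_scale`` the prediction is multiplied by −1 so that larger is
    always better for ranking.
    """
    if mode not in MODES:
        raise ValueError(f"unknown prediction mode {mode!r}")
    if mode == "CBV":
        if classical is None:
            raise ValueError("CBV predictions need the classical EBV series")
        pred = data["animal"].map(classical)
        missing = pred.isna()
    else:
        a_d = data["animal"].map(ebvs["a_D"])
        a_s_own = data["animal"].map(ebvs["a_S"])
        missing = a_d.isna() | a_s_own.isna()
        a_d = a_d.fillna(0.0)
        a_s_own = a_s_own.fillna(0.0)
        cage_sum = a_s_own.groupby(data["cage"].values).transform("sum")
        sbv = cage_sum - a_s_own
        pred = {"DBV": a_d, "SBV": sbv, "DSBV": a_d + sbv}[mode]
    if missing.any():
        logger.warning("%d animals lacked an EBV; using 0", int(missing.sum()))
        pred = pred.fillna(0.0)
    out = pd.Series(pred.to_numpy(float), index=data["animal"].to_numpy())
    return -out if hazard_scale else out


def extreme_groups(predictions: pd.Series, fraction: float = 0.25):
    """Best/worst ``fraction`` of animals by prediction (larger = better).

    Ties are broken by stable animal-id order.
    """
    n = len(predictions)
    if n < 4:
        raise ValueError("need at least 4 animals to form extreme groups")
    m = int(np.floor(fraction * n))
    df = pd.DataFrame({"animal": predictions.index, "pred": predictions.to_numpy()})
    df = df.sort_values(["pred", "animal"], ascending=[False, True], kind="stable")
    best = set(df["animal"].head(m))
    worst = set(df.sort_values(["pred", "animal"], ascending=[True, True],
                               kind="stable")["animal"].head(m))
    return best, worst


def group_summary(data: pd.DataFrame, best: set, worst: set) -> dict:
    """Observed mean survival days (±SE over animals), their difference, and
    Kaplan-Meier curves for the two extreme groups."""
    if not best or not worst:
        raise ValueError("extreme groups must be non-empty")
    out = {}
    for label, grp in (("best", best), ("worst", worst)):
        sub = data[data["animal"].isin(grp)]
        days = sub["days"].to_numpy(float)
        km = kaplan_meier(days, sub["event"].to_numpy(int))
        out[f"{label}_mean"] = float(days.mean())
        out[f"{label}_se"] = float(days.std(ddof=1) / np.sqrt(len(days)))
        out[f"km_{label}"] = {
            "times": km.times.tolist(),
            "survival": km.survival.tolist(),
        }
    out["difference"] = out["best_mean"] - out["worst_mean"]
    return out


def overlap_percentage(best_a: set, best_b: set) -> float:
    """100·|A∩B|/|A| for equally sized best groups of two methods."""
    if not best_a or not best_b:
        raise ValueError("sets must be non-empty")
    if len(best_a) != len(best_b):
        raise ValueError("sets must have equal size")
    return 100.0 * len(best_a & best_b) / len(best_a)


# ---------------------------------------------------------------------------
# Censoring-aware rank correlation and approximate accuracy
# ---------------------------------------------------------------------------


def censored_rank_correlation(observed, events, predictions) -> float:
    """Rank correlation giving all censored animals the average censored rank.

    Uncensored animals are ranked 1..n by the (fixed-effect-adjusted)
    observed values; censored animals occupy ranks n+1..N in unknown order
    and each receives their average (n+1+N)/2. The Pearson correlation of
    these ranks with the prediction ranks equals the expectation of the
    plain Spearman correlation over uniformly random orderings of the
    censored animals. With no censoring it reduces to Spearman exactly.
    """
    obs = np.asarray(observed, dtype=float)
    ev = np.asarray(events, dtype=int)
    pred = np.asarray(predictions, dtype=float)
    N = obs.size
    if N == 0 or not ev.any():
        raise ValueError("rank correlation undefined: no uncensored animals")
    if np.ptp(pred) == 0:
        raise ValueError("rank correlation undefined: constant predictions")
    unc = ev == 1
    n_unc = int(unc.sum())
    r_obs = np.empty(N)
    r_obs[unc] = stats.rankdata(obs[unc], method="average")
    r_obs[~unc] = (n_unc + 1 + N) / 2.0
    r_pred = stats.rankdata(pred, method="average")
    # Each censored ordering is a permutation of the ranks n+1..N, so every
    # ordering shares the same rank variance; averaging Spearman over
    # orderings therefore averages only the numerator. The denominator must
    # use the *untied* observed-rank variance (censored ranks n+1..N spread
    # out), not the variance after collapsing them to their mean.
    r_full = r_obs.copy()
    r_full[~unc] = np.arange(n_unc + 1, N + 1, dtype=float)
    sd_obs = r_full.std()
    sd_pred = r_pred.std()
    if sd_obs == 0:
        raise ValueError("rank correlation undefined: constant observed ranks")
    num = float(np.mean((r_obs - r_obs.mean()) * (r_pred - r_pred.mean())))
    return num / (sd_obs * sd_pred)


def approximate_accuracy(
    rank_corr: float,
    vc: VarianceComponents,
    n: int,
    sigma2_P: float | None = None,
) -> float:
    """Approximate EBV accuracy r_IH = r̂ / ρ_max.

    ρ_max = √((σ²_AD + (n−1)σ²_AS)/σ²_P) is the ceiling of the
    observed-vs-predicted correlation when breeding values are known without
    error; dividing the realized rank correlation by it rescales to an
    accuracy of the genetic prediction itself. Components are taken on the
    observed (survival-days) scale.
    """
    if sigma2_P is None:
        sigma2_P = vc.sigma2_AD + (n - 1) * vc.sigma2_AS + vc.sigma2_e
    rho_max = float(np.sqrt((vc.sigma2_AD + (n - 1) * vc.sigma2_AS) / sigma2_P))
    if rho_max <= 0:
        raise ValueError("rho_max is zero; accuracy undefined")
    return rank_corr / rho_max


def rho_max(vc: VarianceComponents, n: int, sigma2_P: float | None = None) -> float:
    if sigma2_P is None:
        sigma2_P = vc.sigma2_AD + (n - 1) * vc.sigma2_AS + vc.sigma2_e
    return float(np.sqrt((vc.sigma2_AD + (n - 1) * vc.sigma2_AS) / sigma2_P))


# ---------------------------------------------------------------------------
# Full cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class FoldFits:
    """EBV tables and fits from one training fold."""

    ebvs: dict[str, pd.DataFrame]          # method → frame indexed by animal
    classical: dict[str, pd.Series]        # method → classical EBV series
    lam_fit: IGEFit | None
    two_step_fit: IGEFit | None
    cox_fit: CoxFit | None


def fit_fold(
    data: pd.DataFrame,
    ped: Pedigree,
    held_out_cages: list[str],
    methods=("two_step", "lam"),
    n_per_cage: int = 4,
    cox_config: CoxConfig | None = None,
    reml_config: RemlConfig | None = None,
    init: dict[str, VarianceComponents] | None = None,
    needs_classical: bool = True,
) -> FoldFits:
    """Refit the chosen methods on the training cages only."""
    train = data[~data["cage"].isin(set(held_out_cages))].reset_index(drop=True)
    ebvs: dict[str, pd.DataFrame] = {}
    classical: dict[str, pd.Series] = {}
    lam_fit = two_step_fit = cox_fit = None
    init = init or {}
    for method in methods:
        if method == "two_step":
            cox_fit = fit_cox_animal(train, ped, cox_config)
            pseudo = compute_pseudo_records(cox_fit, train)
            design = build_design(train, ped, "two_step", pseudo=pseudo,
                                  n_per_cage=n_per_cage)
            cfg = reml_config or RemlConfig()
            if "two_step" in init:
                cfg = RemlConfig(**{**cfg.__dict__, "init": init["two_step"]})
            two_step_fit = reml_fit(design, ped.ensure(data["animal"]), cfg)
            frame = two_step_fit.ebv_frame().set_index("animal")
            ebvs["two_step"] = frame
            classical["two_step"] = pd.Series(
                cox_fit.a_hat, index=cox_fit.animal_ids
            )
        elif method == "lam":
            design = build_design(train, ped, "lam_direct", n_per_cage=n_per_cage)
            cfg = reml_config or RemlConfig()
            if "lam" in init:
                cfg = RemlConfig(**{**cfg.__dict__, "init": init["lam"]})
            lam_fit = reml_fit(design, ped.ensure(data["animal"]), cfg)
            ebvs["lam"] = lam_fit.ebv_frame().set_index("animal")
            if needs_classical:
                cdesign = build_design(train, ped, "classical", n_per_cage=n_per_cage)
                ccfg = RemlConfig(**{**(reml_config or RemlConfig()).__dict__,
                                     "init": None})
                cfit = reml_fit(cdesign, ped.ensure(data["animal"]), ccfg)
                classical["lam"] = pd.Series(cfit.a_D, index=cdesign.animal_ids)
        else:
            raise ValueError(f"unknown method {method!r}")
    return FoldFits(ebvs, classical, lam_fit, two_step_fit, cox_fit)


def _adjusted_observed(data: pd.DataFrame, lam_fit: IGEFit | None) -> np.ndarray:
    """Observed days minus the linear-model fixed-effect estimates.

    Falls back to the raw days when no linear fit is available. Censoring
    status is carried separately; adjustment never changes who is censored.
    """
    days = data["days"].to_numpy(float)
    if lam_fit is None or lam_fit.design.fixed_design is None:
        return days
    from .survival_model import FixedDesign

    fd = FixedDesign.build(data, template=lam_fit.design.fixed_design)
    # intercept is a common shift; ranks are unaffected, so drop it
    return days - fd.X @ np.asarray(lam_fit.fixed[1:], dtype=float)


def run_crossval(
    data: pd.DataFrame,
    ped: Pedigree,
    k: int = 5,
    seed: int = 0,
    methods=("two_step", "lam"),
    modes=MODES,
    fraction: float = 0.25,
    n_per_cage: int = 4,
    cox_config: CoxConfig | None = None,
    reml_config: RemlConfig | None = None,
) -> dict:
    """k-fold cage-wise cross-validation report.

    Extreme groups are selected per fold and pooled; rank correlations are
    averaged over folds with SE = SD/√k; the approximate accuracy uses the
    linear-model components averaged over folds (observed-day scale) for
    both methods.
    """
    plan = make_folds(data, k=k, seed=seed)
    preds: dict[tuple[str, str], list[pd.Series]] = {
        (m, md): [] for m in methods for md in modes
    }
    rank_corrs: dict[tuple[str, str], list[float]] = {
        (m, md): [] for m in methods for md in modes
    }
    between_method: dict[str, list[float]] = {md: [] for md in modes}
    overlaps: dict[str, list[float]] = {md: [] for md in modes}
    best_sets: dict[tuple[str, str], set] = {(m, md): set() for m in methods for md in modes}
    worst_sets: dict[tuple[str, str], set] = {(m, md): set() for m in methods for md in modes}
    lam_vcs: list[VarianceComponents] = []

    init: dict[str, VarianceComponents] = {}
    for fold in range(1, k + 1):
        held = plan.held_out(fold)
        fits = fit_fold(
            data, ped, held, methods=methods, n_per_cage=n_per_cage,
            cox_config=cox_config, reml_config=reml_config, init=init,
            needs_classical="CBV" in modes,
        )
        if fits.lam_fit is not None:
            lam_vcs.append(fits.lam_fit.vc)
            init["lam"] = fits.lam_fit.vc
        if fits.two_step_fit is not None:
            init["two_step"] = fits.two_step_fit.vc
        test = data[data["cage"].isin(set(held))].reset_index(drop=True)
        adj = _adjusted_observed(test, fits.lam_fit)
        ev = test["event"].to_numpy(int)
        fold_pred: dict[tuple[str, str], pd.Series] = {}
        for m in methods:
            hazard = m == "two_step"
            for md in modes:
                p = predict_phenotype(
                    fits.ebvs[m], test, md,
                    classical=fits.classical.get(m), hazard_scale=hazard,
                )
                fold_pred[(m, md)] = p
                preds[(m, md)].append(p)
                rank_corrs[(m, md)].append(
                    censored_rank_correlation(adj, ev, p.to_numpy())
                )
                b, w = extreme_groups(p, fraction)
                best_sets[(m, md)] |= b
                worst_sets[(m, md)] |= w
        if len(methods) == 2:
            for md in modes:
                a, b = fold_pred[(methods[0], md)], fold_pred[(methods[1], md)]
                between_method[md].append(
                    float(stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic)
                )
                ba, _ = extreme_groups(a, fraction)
                bb, _ = extreme_groups(b, fraction)
                overlaps[md].append(overlap_percentage(ba, bb))

    vc_lam = None
    if lam_vcs:
        vc_lam = VarianceComponents(
            sigma2_AD=float(np.mean([v.sigma2_AD for v in lam_vcs])),
            sigma2_AS=float(np.mean([v.sigma2_AS for v in lam_vcs])),
            sigma_ADS=float(np.mean([v.sigma_ADS for v in lam_vcs])),
            rho=float(np.mean([v.rho for v in lam_vcs])),
            sigma2_e=float(np.mean([v.sigma2_e for v in lam_vcs])),
        )

    report: dict = {
        "k": k,
        "seed": seed,
        "fraction": fraction,
        "n_per_cage": n_per_cage,
        "mean_days": float(data["days"].mean()),
        "methods": {},
        "overlap_best_pct": {md: (float(np.mean(v)) if v else None)
                             for md, v in overlaps.items()},
        "between_method_rank_correlation": {
            md: (float(np.mean(v)) if v else None) for md, v in between_method.items()
        },
    }
    if vc_lam is not None:
        report["lam_components"] = vc_lam.as_dict()
    for m in methods:
        mm: dict = {"modes": {}}
        for md in modes:
            rc = np.asarray(rank_corrs[(m, md)])
            entry = {
                "rank_correlation": float(rc.mean()),
                "rank_correlation_se": float(rc.std(ddof=1) / np.sqrt(len(rc)))
                if len(rc) > 1 else None,
            }
            entry.update(group_summary(data, best_sets[(m, md)], worst_sets[(m, md)]))
            if vc_lam is not None:
                entry["accuracy"] = approximate_accuracy(
                    float(rc.mean()), vc_lam, n_per_cage
                )
            mm["modes"][md] = entry
        report["methods"][m] = mm
    return report
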