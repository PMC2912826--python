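"""Step 1: Kaplan-Meier estimation and the Cox animal model.

The Cox animal model is a proportional-hazards model with a log-normal
pedigree frailty: hazard λ_i(t) = λ_0(t)·exp(x_i'β + a_i) with
a ~ N(0, σ²_a A). Fixed effects are the house × row × level class (one
effect per combination, first class in sort order as reference) and the
mean survival days of the back cage. (β, a) is obtained by maximizing the
Breslow-ties penalized partial log-likelihood with Newton steps (step
halving); σ²_a by a golden-section search of the Laplace-approximate
marginal likelihood on log σ²_a. The baseline cumulative hazard Λ̂_0 is the
Breslow estimator at the optimum, and each animal's weight
ω_i = Λ̂_0(t_i)·exp(x_i'β̂ + â_i) is its estimated cumulative risk to death
or censoring — the quantity that turns the fit into pseudo-records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "KaplanMeier",
    "kaplan_meier",
    "cox_partial_loglik",
    "CoxConfig",
    "CoxFit",
    "fit_cox_animal",
    "cumulative_risk",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KaplanMeier:
    """Product-limit estimate with risk/death counts per distinct event time."""

    times: np.ndarray      # distinct event (death) times
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # risk-set size at each event time
    deaths: np.ndarray     # deaths at each event time

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation; S(t) = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:  # no deaths observed
            out = np.ones_like(t)
        else:
            k = np.searchsorted(self.times, t, side="right")
            out = np.where(k == 0, 1.0, self.survival[np.maximum(k - 1, 0)])
        return out if out.size > 1 else float(out[0])


def kaplan_meier(days, events) -> KaplanMeier:
    """Kaplan-Meier estimator of the survival function.

    Censored observations leave the risk set after their time point
    (deaths-before-censorings tie convention).
    """
    days = np.asarray(days, dtype=float)
    events = np.asarray(events, dtype=int)
    if days.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if days.shape != events.shape:
        raise ValueError("days and events must have the same length")
    times = np.unique(days[events == 1])
    at_risk = np.array([(days >= t).sum() for t in times], dtype=float)
    deaths = np.array([((days == t) & (events == 1)).sum() for t in times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - deaths / at_risk)
    return KaplanMeier(times, surv, at_risk, deaths)


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery
# ---------------------------------------------------------------------------


class _BreslowData:
    """Pre-sorted arrays for Breslow-ties partial likelihood computations."""

    def __init__(self, days: np.ndarray, events: np.ndarray):
        self.order = np.argsort(days, kind="stable")
        self.t = days[self.order]
        self.d = events[self.order]
        dt = self.t[self.d == 1]
        self.event_times = np.unique(dt)
        self.d_k = np.array([(dt == tk).sum() for tk in self.event_times], dtype=float)
        # first index (in sorted order) still at risk at each event time
        self.first_at_risk = np.searchsorted(self.t, self.event_times, side="left")

    def risk_sums(self, e_sorted: np.ndarray) -> np.ndarray:
        """S_k = Σ_{j: t_j ≥ t_k} exp(η_j) for every distinct event time."""
        suffix = np.cumsum(e_sorted[::-1])[::-1]
        return suffix[self.first_at_risk]

    def cumhaz_at(self, S_k: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Breslow Λ̂_0 evaluated at arbitrary times."""
        steps = np.cumsum(self.d_k / S_k)
        k = np.searchsorted(self.event_times, times, side="right")
        return np.where(k == 0, 0.0, steps[np.maximum(k - 1, 0)])


def cox_partial_loglik(eta, days, events) -> float:
    """Breslow-ties log partial likelihood Σ_deaths [η_i − log S(t_i)]."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    days = np.asarray(days, dtype=float)
    events = np.asarray(events, dtype=int)
    bd = _BreslowData(days, events)
    e_sorted = np.exp(eta[bd.order])
    S_k = bd.risk_sums(e_sorted)
    death_eta = eta[events == 1].sum()
    return float(death_eta - np.sum(bd.d_k * np.log(S_k)))


def _pl_derivatives(bd: _BreslowData, eta: np.ndarray):
    """(logPL, gradient wrt η, Hessian of -logPL wrt η, ω, Λ0 steps)."""
    e = np.exp(eta)
    e_sorted = e[bd.order]
    S_k = bd.risk_sums(e_sorted)
    n = eta.size
    # ω_i = Λ0(t_i) e^{η_i}
    lam0 = bd.cumhaz_at(S_k, bd.t)  # at sorted times
    omega_sorted = lam0 * e_sorted
    omega = np.empty(n)
    omega[bd.order] = omega_sorted
    events_full = np.empty(n, dtype=int)
    events_full[bd.order] = bd.d
    logpl = float(eta[events_full == 1].sum() - np.sum(bd.d_k * np.log(S_k)))
    grad = (events_full == 1).astype(float) - omega
    # Hessian of -logPL: diag(ω) - P' diag(d_k) P with p_k = e·1{risk}/S_k
    K = bd.event_times.size
    M = np.zeros((K, n))
    for k in range(K):
        j0 = bd.first_at_risk[k]
        M[k, j0:] = e_sorted[j0:] / S_k[k]
    W = M * np.sqrt(bd.d_k)[:, None]
    H_sorted = np.diag(omega_sorted) - W.T @ W
    inv = np.argsort(bd.order)
    H = H_sorted[np.ix_(inv, inv)]
    return logpl, grad, H, omega, S_k


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of columns linearly independent of each other and of a
    constant (the intercept is implicit: absorbed by the baseline hazard in
    the Cox model, explicit in the linear model)."""
    n = X.shape[0]
    basis = [np.ones(n) / np.sqrt(n)]
    keep: list[int] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        nrm0 = np.linalg.norm(v) or 1.0
        for b in basis:
            v = v - (b @ v) * b
        if np.linalg.norm(v) > tol * nrm0:
            basis.append(v / np.linalg.norm(v))
            keep.append(j)
    return keep


@dataclass
class FixedDesign:
    """House×row×level class dummies (reference = first class in sort order)
    plus the centered back-cage covariate; rank-deficient columns (given an
    implicit intercept) are dropped and logged."""

    X: np.ndarray
    names: list[str]
    reference_class: str
    classes: list[str]
    covariate_mean: float | None
    keep: list[int]

    @classmethod
    def build(cls, data: pd.DataFrame, template: "FixedDesign | None" = None) -> "FixedDesign":
        cl = (data["house"].astype(str) + ":" + data["row"].astype(str)
              + ":" + data["level"].astype(str))
        if template is None:
            classes = sorted(cl.unique())
            cov_mean = (
                float(data["back_cage_mean"].mean())
                if "back_cage_mean" in data.columns else None
            )
        else:
            classes = template.classes
            cov_mean = template.covariate_mean
        ref = classes[0]
        cols, names = [], []
        for c in classes[1:]:
            cols.append((cl == c).to_numpy(float))
            names.append(f"class[{c}]")
        if cov_mean is not None:
            cols.append(data["back_cage_mean"].to_numpy(float) - cov_mean)
            names.append("back_cage_mean")
        X = np.column_stack(cols) if cols else np.zeros((len(data), 0))
        if template is None:
            keep = _independent_columns(X) if X.shape[1] else []
            if len(keep) < X.shape[1]:
                dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
                logger.warning("dropping %d collinear fixed-effect columns: %s",
                               len(dropped), dropped[:5])
        else:
            keep = template.keep
        X = X[:, keep]
        names = [names[j] for j in keep]
        return cls(X, names, ref, classes, cov_mean, keep)


# ---------------------------------------------------------------------------
# Cox animal model
# ---------------------------------------------------------------------------


@dataclass
class CoxConfig:
    sigma2_a: float | None = None      # fix the genetic variance; None = estimate
    sigma2_method: str = "pseudo_reml"  # "pseudo_reml" | "laplace"
    sigma2_bounds: tuple[float, float] = (1e-4, 10.0)
    golden_tol: float = 1e-3           # tolerance in log σ²_a
    max_newton: int = 50
    newton_tol: float = 1e-9           # |Δ penalized loglik|
    max_outer: int = 25                # linearization refits for pseudo_reml
    genetic: bool = True               # False → plain fixed-effect Cox
    weights: str = "full"              # "full" | "fixed_only" linear predictor in ω


@dataclass
class CoxFit:
    """Converged Cox animal model fit."""

    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    design: FixedDesign
    a_hat: np.ndarray                  # per pedigree animal, log-hazard scale
    animal_ids: list[str]
    sigma2_a: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    loglik: float                      # penalized partial loglik at optimum
    marginal_loglik: float
    omega: np.ndarray                  # per record, same order as input data
    n_iter: int
    converged: bool
    weights_mode: str = "full"
    _ped: Pedigree = field(default=None, repr=False)

    def a_of(self, animals) -> np.ndarray:
        idx = self._ped.indices(animals)
        return self.a_hat[idx]

    def linear_predictor(self, data: pd.DataFrame, include_genetic: bool = True) -> np.ndarray:
        X = FixedDesign.build(data, template=self.design).X
        eta = X @ self.beta
        if include_genetic:
            eta = eta + self.a_of(data["animal"])
        return eta

    def cumhaz_at(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        k = np.searchsorted(self.baseline_times, times, side="right")
        return np.where(k == 0, 0.0, self.baseline_cumhaz[np.maximum(k - 1, 0)])

    def report(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "loglik": self.loglik,
            "marginal_loglik": self.marginal_loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "reference_class": self.design.reference_class,
            "weights_mode": self.weights_mode,
            "beta": {n: float(b) for n, b in zip(self.beta_names, self.beta)},
            "beta_se": {n: float(s) for n, s in zip(self.beta_names, self.beta_se)},
        }


def _working_model_reml_sigma2(
    y: np.ndarray,
    w: np.ndarray,
    A_obs: np.ndarray,
    bounds: tuple[float, float],
    tol: float,
) -> float:
    """REML estimate of σ²_a in the univariate working model
    y = 1μ + a + e with Var(a) = σ²·A_obs and Var(e) = diag(1/w).

    One eigendecomposition of the whitened kernel makes the restricted
    log-likelihood O(n) per candidate σ², so a golden-section search on
    log σ² is cheap and exact.
    """
    sw = np.sqrt(w)
    B = sw[:, None] * A_obs * sw[None, :]
    lam, U = np.linalg.eigh(B)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ (sw * y)
    xt = U.T @ sw  # transformed intercept column
    logdetD = -float(np.sum(np.log(w)))

    def rll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        dvec = s2 * lam + 1.0
        xVx = float(np.sum(xt**2 / dvec))
        xVy = float(np.sum(xt * yt / dvec))
        yVy = float(np.sum(yt**2 / dvec))
        yPy = yVy - xVy**2 / xVx
        return -0.5 * (logdetD + float(np.sum(np.log(dvec))) + np.log(xVx) + yPy)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = rll(c), rll(d)
    while hi - lo > tol:
        if fc >= fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = rll(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = rll(d)
    return float(np.exp(c if fc >= fd else d))


class CoxConvergenceError(RuntimeError):
    def __init__(self, msg, beta=None, a=None, grad_norm=None):
        super().__init__(msg)
        self.beta, self.a, self.grad_norm = beta, a, grad_norm


def _newton_mode(
    bd: _BreslowData,
    X: np.ndarray,
    obs_idx: np.ndarray,
    Ainv: sparse.csr_matrix | None,
    sigma2: float,
    beta0: np.ndarray,
    a0: np.ndarray,
    config: CoxConfig,
):
    """Joint (β, a) mode of the penalized partial log-likelihood at fixed σ²_a."""
    n_obs, p = X.shape
    n_ped = a0.size
    beta, a = beta0.copy(), a0.copy()
    Ainv_d = Ainv.toarray() if Ainv is not None else None

    def penalized(logpl, a):
        pen = 0.0
        if Ainv is not None:
            pen = 0.5 * float(a @ (Ainv @ a)) / sigma2
        return logpl - pen

    eta = X @ beta + (a[obs_idx] if Ainv is not None else 0.0)
    logpl, grad_eta, H, omega, _ = _pl_derivatives(bd, eta)
    f = penalized(logpl, a)
    it = 0
    for it in range(1, config.max_newton + 1):
        g_beta = X.T @ grad_eta
        if Ainv is not None:
            g_a = np.zeros(n_ped)
            np.add.at(g_a, obs_idx, grad_eta)
            g_a -= (Ainv @ a) / sigma2
            HX = H @ X
            Hbb = X.T @ HX
            Hba = np.zeros((p, n_ped))
            if p:
                np.add.at(Hba.T, obs_idx, HX)
            Haa = Ainv_d / sigma2
            Haa[np.ix_(obs_idx, obs_idx)] += H
            full_H = np.block([[Hbb, Hba], [Hba.T, Haa]])
            g = np.concatenate([g_beta, g_a])
        else:
            full_H = X.T @ (H @ X)
            g = g_beta
        try:
            cf = linalg.cho_factor(full_H + 1e-10 * np.eye(full_H.shape[0]))
            step = linalg.cho_solve(cf, g)
        except linalg.LinAlgError:
            step = np.linalg.lstsq(full_H, g, rcond=None)[0]
        # step halving on the penalized objective
        t = 1.0
        for _ in range(30):
            beta_n = beta + t * step[:p]
            a_n = a + t * step[p:] if Ainv is not None else a
            eta_n = X @ beta_n + (a_n[obs_idx] if Ainv is not None else 0.0)
            logpl_n, grad_n, H_n, omega_n, _ = _pl_derivatives(bd, eta_n)
            f_n = penalized(logpl_n, a_n)
            if f_n >= f - 1e-12:
                break
            t /= 2.0
        else:
            raise CoxConvergenceError(
                "Newton step halving failed", beta, a, float(np.abs(g).max())
            )
        delta = f_n - f
        beta, a, f, logpl = beta_n, a_n, f_n, logpl_n
        grad_eta, H, omega = grad_n, H_n, omega_n
        if abs(delta) < config.newton_tol and float(np.abs(g).max()) < 1e-5 * max(1.0, abs(f)):
            break
    return beta, a, f, logpl, grad_eta, H, omega, it


def fit_cox_animal(data: pd.DataFrame, ped: Pedigree, config: CoxConfig | None = None) -> CoxFit:
    """Fit the Cox animal model; estimate σ²_a by Laplace marginal likelihood.

    ``data`` must carry animal, house, row, level, days, event (and
    optionally back_cage_mean). Animals absent from the pedigree are flagged
    unknown-pedigree and treated as founders.
    """
    config = config or CoxConfig()
    ped = ped.ensure(data["animal"])
    design = FixedDesign.build(data)
    X = design.X
    days = data["days"].to_numpy(float)
    events = data["event"].to_numpy(int)
    if set(np.unique(events)) - {0, 1}:
        raise ValueError("event codes must be 0/1")
    bd = _BreslowData(days, events)
    obs_idx = ped.indices(data["animal"])

    # warn on fully censored fixed-effect classes (possible separation)
    cl = data["house"].astype(str) + ":" + data["row"].astype(str) + ":" + data["level"].astype(str)
    dead = pd.Series(events).groupby(cl.values).sum()
    for c, ndead in dead.items():
        if ndead == 0:
            logger.warning("fixed-effect class %s has no observed deaths", c)

    if not config.genetic:
        beta, a, f, logpl, grad_eta, H, omega, it = _newton_mode(
            bd, X, obs_idx, None, 1.0, np.zeros(X.shape[1]), np.zeros(ped.n), config
        )
        sigma2_hat, marg = 0.0, logpl
        a = np.zeros(ped.n)
    else:
        Ainv = ped.a_inverse()
        state = {"beta": np.zeros(X.shape[1]), "a": np.zeros(ped.n)}
        cache: dict[float, tuple] = {}

        def marginal(log_s2: float) -> float:
            if log_s2 in cache:
                return cache[log_s2][0]
            s2 = float(np.exp(log_s2))
            beta, a, f, logpl, grad_eta, H, omega, it = _newton_mode(
                bd, X, obs_idx, Ainv, s2, state["beta"], state["a"], config
            )
            state["beta"], state["a"] = beta, a  # warm start
            Kaa = Ainv.toarray() / s2
            Kaa[np.ix_(obs_idx, obs_idx)] += H
            sign, logdet = np.linalg.slogdet(Kaa)
            m = f - 0.5 * (ped.n * log_s2 + logdet)
            cache[log_s2] = (m, beta, a, f, logpl, H, omega, it)
            return m

        if config.sigma2_a is not None:
            x_opt = float(np.log(config.sigma2_a))
            marginal(x_opt)
        elif config.sigma2_method == "pseudo_reml":
            # Iterated linearization: at the current σ², compute the mode and
            # the working records (ỹ, ω), re-estimate σ² by exact REML on the
            # univariate working model, and refit until the fixed point.
            # The naive Laplace marginal is biased upward here (one record
            # per frailty); the working-model REML is the estimator the
            # pseudo-record construction itself implies.
            A_obs = ped.relationship_matrix()[np.ix_(obs_idx, obs_idx)]
            s2 = 0.2
            for _ in range(config.max_outer):
                beta_m, a_m, f_m, logpl_m, grad_m, H_m, omega_m, it_m = _newton_mode(
                    bd, X, obs_idx, Ainv, s2, state["beta"], state["a"], config
                )
                state["beta"], state["a"] = beta_m, a_m
                keep = omega_m > 0
                a_obs = a_m[obs_idx]
                y_work = a_obs[keep] + (events[keep] - omega_m[keep]) / omega_m[keep]
                s2_new = _working_model_reml_sigma2(
                    y_work, omega_m[keep], A_obs[np.ix_(keep, keep)],
                    config.sigma2_bounds, config.golden_tol,
                )
                done = abs(np.log(s2_new) - np.log(s2)) < config.golden_tol
                s2 = s2_new
                if done:
                    break
            else:
                logger.warning("sigma2_a fixed-point did not settle in %d refits",
                               config.max_outer)
            x_opt = float(np.log(s2))
            marginal(x_opt)
        else:
            lo, hi = np.log(config.sigma2_bounds[0]), np.log(config.sigma2_bounds[1])
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            c = hi - invphi * (hi - lo)
            d = lo + invphi * (hi - lo)
            fc, fd = marginal(c), marginal(d)
            while hi - lo > config.golden_tol:
                if fc >= fd:
                    hi, d, fd = d, c, fc
                    c = hi - invphi * (hi - lo)
                    fc = marginal(c)
                else:
                    lo, c, fc = c, d, fd
                    d = lo + invphi * (hi - lo)
                    fd = marginal(d)
            x_opt = c if fc >= fd else d
        marg, beta, a, f, logpl, H, omega, it = cache[x_opt]
        sigma2_hat = float(np.exp(x_opt))

    # Breslow baseline at the optimum
    eta = X @ beta + (a[obs_idx] if config.genetic else 0.0)
    e_sorted = np.exp(eta[bd.order])
    S_k = bd.risk_sums(e_sorted)
    baseline = np.cumsum(bd.d_k / S_k)

    # β standard errors from the observed information (β block of full Hessian)
    p = X.shape[1]
    if p:
        if config.genetic:
            Ainv = ped.a_inverse()
            Haa = Ainv.toarray() / sigma2_hat
            Haa[np.ix_(obs_idx, obs_idx)] += H
            HX = H @ X
            Hba = np.zeros((p, ped.n))
            np.add.at(Hba.T, obs_idx, HX)
            full_H = np.block([[X.T @ HX, Hba], [Hba.T, Haa]])
        else:
            full_H = X.T @ (H @ X)
        cov = np.linalg.inv(full_H + 1e-10 * np.eye(full_H.shape[0]))
        beta_se = np.sqrt(np.diag(cov)[:p])
    else:
        beta_se = np.zeros(0)

    if config.weights == "fixed_only":
        eta_w = X @ beta
    else:
        eta_w = eta
    omega_out = bd.cumhaz_at(S_k, days) * np.exp(eta_w)

    fit = CoxFit(
        beta=beta,
        beta_se=beta_se,
        beta_names=design.names,
        design=design,
        a_hat=a,
        animal_ids=list(ped.ids),
        sigma2_a=sigma2_hat,
        baseline_times=bd.event_times,
        baseline_cumhaz=baseline,
        loglik=f,
        marginal_loglik=marg,
        omega=omega_out,
        n_iter=it,
        converged=True,
        weights_mode=config.weights,
        _ped=ped,
    )
    return fit


def cumulative_risk(fit: CoxFit, data: pd.DataFrame) -> np.ndarray:
    """ω_i = Λ̂_0(t_i)·exp(x_i'β̂ + â_i): estimated cumulative risk to t_i.

    Records with t_i before the first event time get ω = 0 and are flagged
    (they carry no information for the linearized second step).
    """
    include_genetic = fit.weights_mode != "fixed_only"
    eta = fit.linear_predictor(data, include_genetic=include_genetic)
    omega = fit.cumhaz_at(data["days"].to_numpy(float)) * np.exp(eta)
    n_zero = int((omega <= 0).sum())
    if n_zero:
        logger.warning("%d records precede the first event time (ω=0); "
                       "they will be excluded from step 2", n_zero)
    return omega
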