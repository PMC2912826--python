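"""Step 2 and the direct linear animal model: REML/BLUP with social effects.

The model is y = Xb + Z_D a_D + Z_S a_S + e, where a_D holds direct and a_S
associative (indirect/social) breeding values with genetic covariance

    Var([a_D; a_S]) = G0 ⊗ A,   G0 = [[σ²_AD, σ_ADS], [σ_ADS, σ²_AS]],

Z_S links each observation to the associative values of its n−1 cage mates,
and residuals of cage mates are correlated: with observation weights w_i,
Var(e_i) = σ²_e / w_i and Cov(e_i, e_j) = ρ σ²_e / √(w_i w_j) within a cage
(ρ applies to standardized residuals, keeping each cage block a correlation
matrix after standardization).

Three modes share this machinery:

* ``two_step``  — y are pseudo-records, weights ω from the survival fit,
  intercept-only fixed part, σ²_e fixed to one;
* ``lam_direct`` — y are observed survival days, unit weights, full fixed
  effects, all five components free;
* ``classical`` — Z_S omitted (direct-only animal model).

Estimation is average-information (AI) REML on the phenotypic covariance
V = Σ_k θ_k V_k, with step halving when an AI update leaves the feasible
region (G0 PSD, ρ within its cage-block bound, σ²_e > 0), and standard
errors from the inverse AI matrix at the optimum. BLUPs come from
û = G Z' P y, equivalent to Henderson's mixed-model equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import Pedigree
from .survival_model import FixedDesign

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "DerivedParameters",
    "Design",
    "IGEFit",
    "build_design",
    "reml_fit",
    "reml_loglik",
    "blup_solve",
    "derived_parameters",
    "total_breeding_value",
    "RemlConfig",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_AD: float
    sigma2_AS: float = 0.0
    sigma_ADS: float = 0.0
    rho: float = 0.0
    sigma2_e: float = 1.0

    def G0(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_AD, self.sigma_ADS], [self.sigma_ADS, self.sigma2_AS]]
        )

    def validate(self, n_per_cage: int) -> None:
        w = np.linalg.eigvalsh(self.G0())
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("G0 is not positive semidefinite")
        lo = -1.0 / (n_per_cage - 1)
        if not (lo < self.rho < 1.0):
            raise ValueError(f"rho must lie in ({lo:.3f}, 1)")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")

    def as_dict(self) -> dict:
        return {
            "sigma2_AD": self.sigma2_AD,
            "sigma2_AS": self.sigma2_AS,
            "sigma_ADS": self.sigma_ADS,
            "rho": self.rho,
            "sigma2_e": self.sigma2_e,
        }


@dataclass
class DerivedParameters:
    sigma2_TBV: float
    sigma2_P: float
    T2: float
    r_A: float | None
    h2_direct: float
    se: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "sigma2_TBV": self.sigma2_TBV,
            "sigma2_P": self.sigma2_P,
            "T2": self.T2,
            "r_A": self.r_A,
            "h2_direct": self.h2_direct,
        }
        if self.se:
            d["se"] = self.se
        return d


@dataclass
class Design:
    """Assembled design for one analysis."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    obs_idx: np.ndarray          # pedigree index of each observation's animal
    Z_S: sparse.csr_matrix | None  # n_obs × n_ped cage-mate incidence
    weights: np.ndarray
    cages: list[np.ndarray]      # observation positions per cage
    n_per_cage: int
    mode: str
    animal_ids: list[str]        # pedigree ids (column space of Z's)
    fixed_design: FixedDesign | None = None  # template for out-of-sample X


@dataclass
class IGEFit:
    vc: VarianceComponents
    se: dict
    cov_vc: np.ndarray
    free_names: list[str]
    a_D: np.ndarray              # per pedigree animal
    a_S: np.ndarray | None
    fixed: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool
    design: Design = field(repr=False)
    derived: DerivedParameters | None = None

    def ebv_frame(self) -> pd.DataFrame:
        n = self.design.n_per_cage
        a_s = self.a_S if self.a_S is not None else np.zeros_like(self.a_D)
        return pd.DataFrame(
            {
                "animal": self.design.animal_ids,
                "a_D": self.a_D,
                "a_S": a_s,
                "TBV": total_breeding_value(self.a_D, a_s, n),
            }
        )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(
    data: pd.DataFrame,
    ped: Pedigree,
    mode: str,
    pseudo: pd.DataFrame | None = None,
    n_per_cage: int = 4,
) -> Design:
    """Assemble (y, X, Z_D, Z_S, weights, cage blocks) for the chosen mode.

    ``two_step`` requires the pseudo-record table; cages that lost members to
    zero-weight records are dropped whole (the social structure needs the
    complete cage). Other modes use observed survival days directly.
    """
    if mode not in ("two_step", "lam_direct", "classical"):
        raise ValueError(f"unknown mode {mode!r}")
    df = data.copy()
    if mode == "two_step":
        if pseudo is None:
            raise ValueError("two_step mode needs pseudo-records")
        df = df.merge(pseudo, on="animal", how="inner", validate="1:1")

    sizes = df.groupby("cage")["animal"].size()
    bad = sizes[sizes != n_per_cage]
    if len(bad):
        if mode == "two_step" and pseudo is not None and len(df) < len(data):
            logger.warning("dropping %d incomplete cages after step-1 exclusions",
                           len(bad))
            df = df[~df["cage"].isin(bad.index)].reset_index(drop=True)
        else:
            raise ValueError(
                f"incomplete cages (expected {n_per_cage} animals): "
                f"{list(bad.index[:10])}"
            )
    df = df.reset_index(drop=True)
    ped = ped.ensure(df["animal"])
    obs_idx = ped.indices(df["animal"])

    fd = None
    if mode == "two_step":
        y = df["y_tilde"].to_numpy(float)
        w = df["weight"].to_numpy(float)
        X = np.ones((len(df), 1))
        fixed_names = ["intercept"]
    else:
        y = df["days"].to_numpy(float)
        w = np.ones(len(df))
        fd = FixedDesign.build(df)
        X = np.column_stack([np.ones(len(df)), fd.X])
        fixed_names = ["intercept"] + fd.names

    cages = [np.asarray(pos) for _, pos in sorted(df.groupby("cage").indices.items())]
    Z_S = None
    if mode != "classical":
        rows, cols = [], []
        for pos in cages:
            for i in pos:
                for j in pos:
                    if i != j:
                        rows.append(i)
                        cols.append(obs_idx[j])
        Z_S = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(df), ped.n)
        )
    return Design(
        y=y,
        X=X,
        fixed_names=fixed_names,
        obs_idx=obs_idx,
        Z_S=Z_S,
        weights=w,
        cages=cages,
        n_per_cage=n_per_cage,
        mode=mode,
        animal_ids=list(ped.ids),
        fixed_design=fd,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


@dataclass
class RemlConfig:
    max_iter: int = 30           # AI iterations before the quasi-Newton polish
    tol_loglik: float = 1e-8
    tol_grad: float = 1e-6       # on the scale-standardized gradient
    fix_sigma2_e: bool | None = None   # default: True for two_step
    init: VarianceComponents | None = None
    verbose: bool = False


class _Kernels:
    """Covariance building blocks for V(θ) = Σ θ_k V_k."""

    def __init__(self, design: Design, A: np.ndarray):
        ids = design.obs_idx
        self.K_DD = A[np.ix_(ids, ids)]
        if design.Z_S is not None:
            B = design.Z_S @ A                     # n_obs × n_ped
            K_DS = B[:, ids].T                     # Z_D A Z_S'
            self.K_DSs = K_DS + K_DS.T
            self.K_SS = design.Z_S @ B.T
            self.K_DS = K_DS
        else:
            self.K_DS = self.K_DSs = self.K_SS = None
        w = design.weights
        self.D = np.diag(1.0 / w)
        C = np.zeros((len(w), len(w)))
        s = 1.0 / np.sqrt(w)
        for pos in design.cages:
            block = np.outer(s[pos], s[pos])
            np.fill_diagonal(block, 0.0)
            C[np.ix_(pos, pos)] = block
        self.C = C

    def V(self, vc: VarianceComponents) -> np.ndarray:
        V = vc.sigma2_AD * self.K_DD + vc.sigma2_e * (self.D + vc.rho * self.C)
        if self.K_SS is not None:
            V = V + vc.sigma_ADS * self.K_DSs + vc.sigma2_AS * self.K_SS
        return V


def _free_param_layout(design: Design, fix_e: bool):
    names = ["sigma2_AD"]
    if design.Z_S is not None:
        names += ["sigma_ADS", "sigma2_AS"]
    names += ["rho"]
    if not fix_e:
        names += ["sigma2_e"]
    return names


def _vc_from_theta(theta: np.ndarray, names: list[str], sigma2_e_fixed: float) -> VarianceComponents:
    d = dict(zip(names, theta))
    return VarianceComponents(
        sigma2_AD=d["sigma2_AD"],
        sigma2_AS=d.get("sigma2_AS", 0.0),
        sigma_ADS=d.get("sigma_ADS", 0.0),
        rho=d["rho"],
        sigma2_e=d.get("sigma2_e", sigma2_e_fixed),
    )


def _feasible(vc: VarianceComponents, n_per_cage: int, scale: float) -> bool:
    eps = 1e-10 * scale
    if vc.sigma2_AD < eps or vc.sigma2_e < eps:
        return False
    if vc.sigma2_AS < 0.0:
        return False
    if vc.sigma2_AS > 0 and vc.sigma_ADS**2 > 0.9999 * vc.sigma2_AD * vc.sigma2_AS:
        return False
    if vc.sigma2_AS == 0.0 and vc.sigma_ADS != 0.0:
        return False
    lo = -1.0 / (n_per_cage - 1)
    return lo + 1e-6 < vc.rho < 1.0 - 1e-6


def _reml_pieces(kern: _Kernels, design: Design, vc: VarianceComponents):
    V = kern.V(vc)
    n = V.shape[0]
    cf = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vi = linalg.cho_solve(cf, np.eye(n))
    X = design.X
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cfx = linalg.cho_factor(XtViX)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    P = Vi - ViX @ linalg.cho_solve(cfx, ViX.T)
    Py = P @ design.y
    ll = -0.5 * (logdetV + logdetX + float(design.y @ Py))
    beta = linalg.cho_solve(cfx, X.T @ (Vi @ design.y))
    return ll, P, Py, Vi, beta, XtViX


def reml_loglik(design: Design, A: np.ndarray, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at given variance components (constants
    dropped)."""
    kern = _Kernels(design, A)
    ll, *_ = _reml_pieces(kern, design, vc)
    return ll


def reml_fit(
    design: Design,
    ped_or_A: Pedigree | np.ndarray,
    config: RemlConfig | None = None,
) -> IGEFit:
    """Average-information REML with step-halving fallback.

    Estimates the free components (σ²_AD[, σ_ADS, σ²_AS], ρ[, σ²_e]) and
    returns BLUPs of a_D and a_S for every pedigree animal, standard errors
    from the inverse AI matrix, and the restricted log-likelihood.
    """
    config = config or RemlConfig()
    A = ped_or_A.relationship_matrix() if isinstance(ped_or_A, Pedigree) else ped_or_A
    fix_e = config.fix_sigma2_e
    if fix_e is None:
        fix_e = design.mode == "two_step"
    names = _free_param_layout(design, fix_e)
    kern = _Kernels(design, A)
    scale = float(np.var(design.y)) or 1.0

    if config.init is not None:
        vc = replace(config.init)
    elif fix_e:
        # residual scale is fixed: components live on the same O(1) scale
        vc = VarianceComponents(
            sigma2_AD=0.3,
            sigma2_AS=(0.02 if design.Z_S is not None else 0.0),
            sigma_ADS=0.0,
            rho=0.01,
            sigma2_e=1.0,
        )
    else:
        vc = VarianceComponents(
            sigma2_AD=0.25 * scale,
            sigma2_AS=(0.02 * scale if design.Z_S is not None else 0.0),
            sigma_ADS=0.0,
            rho=0.02,
            sigma2_e=0.6 * scale,
        )
    social = design.Z_S is not None
    rho_lo = -1.0 / (design.n_per_cage - 1)
    PSI_LIM = 20.0

    # transformed coordinates ψ: G0 = LL' with L = [[e^l11, 0], [l21, e^l22]]
    # (log-Cholesky, PSD by construction), ρ = lo + (1−lo)·logistic(z),
    # σ²_e = e^w — every iterate is feasible, and a singular G0 is reached
    # smoothly as l22 → −∞ instead of crashing into a constraint.
    def psi_to_theta(psi: np.ndarray) -> np.ndarray:
        i = 0
        l11 = psi[i]; i += 1
        theta = [np.exp(2 * l11)]
        if social:
            l21, l22 = psi[i], psi[i + 1]; i += 2
            theta += [np.exp(l11) * l21, l21**2 + np.exp(2 * l22)]
        z = psi[i]; i += 1
        s = 1.0 / (1.0 + np.exp(-z))
        theta += [rho_lo + (1.0 - rho_lo) * s]
        if not fix_e:
            theta += [np.exp(psi[i])]
        return np.asarray(theta)

    def jacobian(psi: np.ndarray) -> np.ndarray:
        k = len(names)
        J = np.zeros((k, k))
        i = 0
        l11 = psi[i]
        J[0, 0] = 2 * np.exp(2 * l11)
        i = 1
        if social:
            l21, l22 = psi[1], psi[2]
            J[1, 0] = np.exp(l11) * l21
            J[1, 1] = np.exp(l11)
            J[2, 1] = 2 * l21
            J[2, 2] = 2 * np.exp(2 * l22)
            i = 3
        z = psi[i]
        s = 1.0 / (1.0 + np.exp(-z))
        J[i, i] = (1.0 - rho_lo) * s * (1 - s)
        if not fix_e:
            J[i + 1, i + 1] = np.exp(psi[i + 1])
        return J

    def vc_to_psi(v: VarianceComponents) -> np.ndarray:
        s2ad = max(v.sigma2_AD, 1e-8 * scale)
        psi = [0.5 * np.log(s2ad)]
        if social:
            l21 = v.sigma_ADS / np.sqrt(s2ad)
            resid = max(v.sigma2_AS - l21**2, 1e-4 * max(v.sigma2_AS, 1e-6 * scale))
            psi += [l21, 0.5 * np.log(resid)]
        frac = np.clip((v.rho - rho_lo) / (1.0 - rho_lo), 1e-6, 1 - 1e-6)
        psi += [float(np.log(frac / (1 - frac)))]
        if not fix_e:
            psi += [float(np.log(max(v.sigma2_e, 1e-10 * scale)))]
        return np.asarray(psi)

    def theta_to_vc(th):
        return _vc_from_theta(th, names, vc.sigma2_e if fix_e else th[-1])

    def _dV_list(cur: VarianceComponents) -> list[np.ndarray]:
        dV = []
        for nm in names:
            if nm == "sigma2_AD":
                dV.append(kern.K_DD)
            elif nm == "sigma_ADS":
                dV.append(kern.K_DSs)
            elif nm == "sigma2_AS":
                dV.append(kern.K_SS)
            elif nm == "rho":
                dV.append(cur.sigma2_e * kern.C)
            elif nm == "sigma2_e":
                dV.append(kern.D + cur.rho * kern.C)
        return dV

    def _grad_theta(cur: VarianceComponents, P: np.ndarray, Py: np.ndarray):
        dV = _dV_list(cur)
        k = len(names)
        grad = np.empty(k)
        v = [M @ Py for M in dV]
        for a in range(k):
            grad[a] = -0.5 * (float(np.sum(P * dV[a])) - float(Py @ v[a]))
        return grad, v

    psi = vc_to_psi(vc)
    theta = psi_to_theta(psi)
    ll, P, Py, Vi, beta, XtViX = _reml_pieces(kern, design, theta_to_vc(theta))
    converged = False
    boundary = False
    AI = np.eye(len(names))
    grad = np.zeros(len(names))
    it = 0
    for it in range(1, config.max_iter + 1):
        cur = theta_to_vc(theta)
        k = len(names)
        grad, v = _grad_theta(cur, P, Py)
        AI = np.empty((k, k))
        Pv = [P @ va for va in v]
        for a in range(k):
            for b in range(a, k):
                AI[a, b] = AI[b, a] = 0.5 * float(v[a] @ Pv[b])

        J = jacobian(psi)
        g_psi = J.T @ grad
        AI_psi = J.T @ AI @ J
        ridge = 1e-10 * max(float(np.trace(AI_psi)) / k, 1.0)
        try:
            step = np.linalg.solve(AI_psi + ridge * np.eye(k), g_psi)
        except np.linalg.LinAlgError:
            step = g_psi / max(float(np.diag(AI_psi).max()), 1e-12)
        big = float(np.abs(step).max())
        if big > 3.0:  # log-scale coordinates: cap jump size
            step *= 3.0 / big

        # step halving on the restricted loglik (feasibility is automatic)
        accepted = None
        t = 1.0
        for _ in range(40):
            psi_new = np.clip(psi + t * step, -PSI_LIM, PSI_LIM)
            try:
                pieces = _reml_pieces(kern, design, theta_to_vc(psi_to_theta(psi_new)))
            except linalg.LinAlgError:
                t /= 2.0
                continue
            if pieces[0] >= ll - 1e-10:
                accepted = (psi_new, pieces)
                break
            t /= 2.0
        if accepted is None:
            logger.warning("no ascent step found; stopping at current iterate")
            boundary = True
            break
        psi_new, (ll_new, P_new, Py_new, Vi_new, beta_new, XtViX_new) = accepted
        delta = ll_new - ll
        psi, theta, ll = psi_new, psi_to_theta(psi_new), ll_new
        P, Py, Vi, beta, XtViX = P_new, Py_new, Vi_new, beta_new, XtViX_new
        if config.verbose:
            logger.info("iter %d ll=%.8f delta=%.2e", it, ll, delta)
        if abs(delta) < config.tol_loglik and t == 1.0:
            converged = True
            break
        if float(np.abs(g_psi).max()) < config.tol_grad * len(design.y) and abs(delta) < 1e-6:
            converged = True
            break
        if np.any(np.abs(psi) >= PSI_LIM):
            boundary = True
            converged = True
            break

    if not converged:
        # AI creeps near a singular G0 (the boundary turns into an asymptote
        # in ψ); polish with a quasi-Newton search on the same surface.
        from scipy import optimize

        def negll(psi_x):
            try:
                pieces = _reml_pieces(kern, design, theta_to_vc(psi_to_theta(psi_x)))
            except linalg.LinAlgError:
                return 1e30, np.zeros_like(psi_x)
            ll_x, P_x, Py_x = pieces[0], pieces[1], pieces[2]
            g_theta, _ = _grad_theta(theta_to_vc(psi_to_theta(psi_x)), P_x, Py_x)
            return -ll_x, -(jacobian(psi_x).T @ g_theta)

        res = optimize.minimize(
            negll, psi, jac=True, method="L-BFGS-B",
            bounds=[(-PSI_LIM, PSI_LIM)] * len(names),
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        if -res.fun < ll - 1e-6:
            raise RuntimeError(
                f"REML did not converge (AI stalled at ll={ll:.6f}, "
                f"polish returned {-res.fun:.6f})"
            )
        psi = np.asarray(res.x)
        theta = psi_to_theta(psi)
        ll, P, Py, Vi, beta, XtViX = _reml_pieces(kern, design, theta_to_vc(theta))
        converged = True
        boundary = boundary or bool(np.any(np.abs(psi) >= PSI_LIM - 1e-6))
        # refresh the information matrix at the polished optimum
        cur = theta_to_vc(theta)
        grad, v = _grad_theta(cur, P, Py)
        Pv = [P @ va for va in v]
        k = len(names)
        AI = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                AI[a, b] = AI[b, a] = 0.5 * float(v[a] @ Pv[b])

    vc_hat = theta_to_vc(theta)
    # near-boundary G0 flag
    if design.Z_S is not None and vc_hat.sigma2_AS > 0:
        r2 = vc_hat.sigma_ADS**2 / (vc_hat.sigma2_AD * vc_hat.sigma2_AS)
        if r2 > 0.998:
            boundary = True

    try:
        cov_vc = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_vc = np.linalg.pinv(AI)
    se = {nm: float(np.sqrt(max(cov_vc[i, i], 0.0))) for i, nm in enumerate(names)}

    a_D, a_S = _ebv_from_Py(design, A, vc_hat, Py)
    derived = derived_parameters(
        vc_hat, design.n_per_cage, cov_vc=cov_vc, free_names=names
    )
    return IGEFit(
        vc=vc_hat,
        se=se,
        cov_vc=cov_vc,
        free_names=names,
        a_D=a_D,
        a_S=a_S if design.Z_S is not None else None,
        fixed=beta,
        fixed_names=design.fixed_names,
        loglik=ll,
        converged=converged,
        n_iter=it,
        boundary=boundary,
        design=design,
        derived=derived,
    )


def _ebv_from_Py(design: Design, A: np.ndarray, vc: VarianceComponents, Py: np.ndarray):
    """û = G Z' P y with G = G0 ⊗ A (BLUP, equivalent to Henderson's MME)."""
    n_ped = A.shape[0]
    t_D = np.zeros(n_ped)
    np.add.at(t_D, design.obs_idx, Py)
    if design.Z_S is not None:
        t_S = np.asarray(design.Z_S.T @ Py).ravel()
    else:
        t_S = np.zeros(n_ped)
    a_D = A @ (vc.sigma2_AD * t_D + vc.sigma_ADS * t_S)
    a_S = A @ (vc.sigma_ADS * t_D + vc.sigma2_AS * t_S)
    return a_D, a_S


def blup_solve(
    design: Design, ped_or_A: Pedigree | np.ndarray, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """BLUP (a_D, a_S) and GLS fixed effects at given variance components."""
    vc.validate(design.n_per_cage)
    A = ped_or_A.relationship_matrix() if isinstance(ped_or_A, Pedigree) else ped_or_A
    kern = _Kernels(design, A)
    ll, P, Py, Vi, beta, XtViX = _reml_pieces(kern, design, vc)
    a_D, a_S = _ebv_from_Py(design, A, vc, Py)
    return a_D, (a_S if design.Z_S is not None else None), beta


# ---------------------------------------------------------------------------
# Derived social-genetics parameters
# ---------------------------------------------------------------------------


def total_breeding_value(a_D, a_S, n: int):
    """TBV_i = a_D,i + (n−1)·a_S,i — total heritable impact on the group."""
    if n < 2:
        raise ValueError("group size must be at least 2")
    return np.asarray(a_D, dtype=float) + (n - 1) * np.asarray(a_S, dtype=float)


def _derived_values(p: np.ndarray, n: int) -> np.ndarray:
    """(σ²_TBV, σ²_P, T², h²) from p = (σ²_AD, σ_ADS, σ²_AS, σ²_e)."""
    s2ad, sads, s2as, s2e = p
    tbv = s2ad + 2 * (n - 1) * sads + (n - 1) ** 2 * s2as
    s2p = s2ad + (n - 1) * s2as + s2e
    return np.array([tbv, s2p, tbv / s2p, s2ad / s2p])


def derived_parameters(
    vc: VarianceComponents,
    n: int,
    cov_vc: np.ndarray | None = None,
    free_names: list[str] | None = None,
) -> DerivedParameters:
    """Total heritable variance and its phenotypic-variance ratio.

    σ²_TBV = σ²_AD + 2(n−1)σ_ADS + (n−1)²σ²_AS is the variance of total
    breeding values among unrelated individuals; σ²_P = σ²_AD + (n−1)σ²_AS
    + σ²_e is the phenotypic variance with unrelated cage mates (the
    residual correlation ρ does not enter an individual's own variance);
    T² = σ²_TBV/σ²_P generalizes heritability to social interactions and may
    exceed 1. Standard errors are first-order delta-method on the inverse AI
    matrix when supplied.
    """
    if n < 2:
        raise ValueError("group size must be at least 2")
    p = np.array([vc.sigma2_AD, vc.sigma_ADS, vc.sigma2_AS, vc.sigma2_e])
    tbv, s2p, t2, h2 = _derived_values(p, n)
    if vc.sigma2_AD > 0 and vc.sigma2_AS > 0:
        r_a = float(vc.sigma_ADS / np.sqrt(vc.sigma2_AD * vc.sigma2_AS))
    else:
        r_a = None

    se: dict = {}
    if cov_vc is not None and free_names is not None:
        order = ["sigma2_AD", "sigma_ADS", "sigma2_AS", "sigma2_e"]
        S = np.zeros((4, 4))
        for i, ni in enumerate(order):
            for j, nj in enumerate(order):
                if ni in free_names and nj in free_names:
                    S[i, j] = cov_vc[free_names.index(ni), free_names.index(nj)]
        h = 1e-6 * np.maximum(np.abs(p), 1.0)
        J = np.zeros((4, 4))
        for j in range(4):
            up, dn = p.copy(), p.copy()
            up[j] += h[j]
            dn[j] -= h[j]
            J[:, j] = (_derived_values(up, n) - _derived_values(dn, n)) / (2 * h[j])
        var = J @ S @ J.T
        labels = ["sigma2_TBV", "sigma2_P", "T2", "h2_direct"]
        se = {k: float(np.sqrt(max(var[i, i], 0.0))) for i, k in enumerate(labels)}
        if r_a is not None:
            g = np.zeros(4)
            s2ad, sads, s2as, _ = p
            denom = np.sqrt(s2ad * s2as)
            g[0] = -0.5 * sads / (denom * s2ad)
            g[1] = 1.0 / denom
            g[2] = -0.5 * sads / (denom * s2as)
            se["r_A"] = float(np.sqrt(max(g @ S @ g, 0.0)))
    return DerivedParameters(
        sigma2_TBV=float(tbv),
        sigma2_P=float(s2p),
        T2=float(t2),
        r_A=r_a,
        h2_direct=float(h2),
        se=se,
    )
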