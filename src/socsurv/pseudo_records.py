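"""Pseudo-records: the linearization bridging survival analysis and BLUP.

A converged Cox animal model fit is turned into one weighted linear record
per animal,

    ỹ_i = â_i + (δ_i − ω_i) / ω_i,   weight ω_i,

the IRLS working variable on the animal-effect scale (δ_i censoring code,
ω_i cumulative risk). The defining property — and this module's validity
check — is that a univariate animal-model BLUP on (ỹ, ω) with residual
variance 1/ω_i and genetic variance σ²_a·A reproduces the survival-model
breeding values exactly: the Breslow score equation gives
δ − ω = A⁻¹â/σ²_a at the optimum, which is precisely the mixed-model
equation for â on the pseudo-records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .survival_model import CoxFit

logger = logging.getLogger(__name__)

__all__ = ["compute_pseudo_records", "verify_equivalence", "EquivalenceResult"]


def compute_pseudo_records(fit: CoxFit, data: pd.DataFrame) -> pd.DataFrame:
    """Pseudo-record table (animal, y_tilde, weight, delta).

    Records with ω_i = 0 (censored before the first event time) carry no
    information for the linearized analysis; they are dropped and logged.
    """
    omega = np.asarray(fit.omega, dtype=float)
    if len(omega) != len(data):
        raise ValueError("fit and data are misaligned")
    a = fit.a_of(data["animal"])
    delta = data["event"].to_numpy(int)
    keep = omega > 0
    if (~keep).any():
        dropped = data.loc[~keep, "animal"].tolist()
        logger.warning("dropping %d zero-weight pseudo-records: %s",
                       len(dropped), dropped[:10])
    with np.errstate(divide="ignore", invalid="ignore"):
        y = a + (delta - omega) / omega
    out = pd.DataFrame(
        {
            "animal": data["animal"].to_numpy(),
            "y_tilde": y,
            "weight": omega,
            "delta": delta,
        }
    )
    return out.loc[keep].reset_index(drop=True)


@dataclass
class EquivalenceResult:
    correlation: float
    max_abs_diff: float
    mu_hat: float
    ebv_blup: np.ndarray
    ebv_survival: np.ndarray


def verify_equivalence(
    pseudo: pd.DataFrame,
    ped: Pedigree,
    sigma2_a: float,
    fit: CoxFit | None = None,
    a_hat: np.ndarray | None = None,
    intercept: bool = True,
) -> EquivalenceResult:
    """BLUP the pseudo-records and correlate with the survival-model EBVs.

    Solves the single-trait animal model ỹ = 1μ + Za + e with
    Var(e) = diag(1/ω) (residual scale fixed to one) and Var(a) = σ²_a·A via
    Henderson's mixed-model equations, then returns the Pearson correlation
    between the resulting EBVs and the survival-model â over all pedigree
    animals. A correlation of one certifies the linearization.
    """
    if a_hat is None:
        if fit is None:
            raise ValueError("supply the CoxFit or the survival EBVs")
        a_hat = fit.a_hat
    idx = ped.indices(pseudo["animal"])
    w = pseudo["weight"].to_numpy(float)
    y = pseudo["y_tilde"].to_numpy(float)
    if np.any(w <= 0):
        raise ValueError("pseudo-record weights must be positive")
    n = ped.n
    Ainv = ped.a_inverse().toarray()

    k = 1 if intercept else 0
    C = np.zeros((k + n, k + n))
    rhs = np.zeros(k + n)
    if intercept:
        C[0, 0] = w.sum()
        np.add.at(C[0, 1:], idx, w)
        C[1:, 0] = C[0, 1:]
        rhs[0] = float(w @ y)
    diag = np.zeros(n)
    np.add.at(diag, idx, w)
    C[k:, k:] = Ainv / sigma2_a
    C[k + np.arange(n), k + np.arange(n)] += diag
    np.add.at(rhs, k + idx, w * y)
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular mixed-model equations") from exc
    mu = float(sol[0]) if intercept else 0.0
    ebv = sol[k:]
    r = float(np.corrcoef(ebv, a_hat)[0, 1])
    return EquivalenceResult(
        correlation=r,
        max_abs_diff=float(np.abs(ebv - a_hat).max()),
        mu_hat=mu,
        ebv_blup=ebv,
        ebv_survival=np.asarray(a_hat, dtype=float),
    )
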