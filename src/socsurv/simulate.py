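"""Synthetic populations of group-housed laying hens.

The generator mirrors the structure of a layer survival study: a hierarchical
sire/dam pedigree (~8 dams per sire, ~12.3 offspring per dam), 4-bird cages
of one line assigned at random, house × row × level fixed-effect classes
(2 × 8 × 3), back-to-back cage pairing for the neighbour covariate, and
right-censoring at a common study end around 58 weeks on test, giving the
50-75% censoring typical of such data.

Breeding values for direct (a_D) and associative / social (a_S) effects are
sampled with covariance A ⊗ G0: founders from N(0, G0), descendants by the
additive recursion parent-average + Mendelian sampling.

Survival can be generated on two scales:

* ``hazard`` — proportional hazards with a Weibull baseline; the linear
  predictor on the log-hazard is x'β + a_D,i + Σ_{j∈cage, j≠i} a_S,j.
* ``linear`` — observed days as μ + x'β + a_D,i + Σ a_S,j + e with
  within-cage residual correlation ρ; this is exactly the generative model
  the direct linear animal model (LAM) assumes, so it exercises that path
  under its own assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_breeding_values",
    "assign_cages",
    "simulate_survival",
    "simulate_dataset",
]


def _default_g0() -> np.ndarray:
    # log-hazard scale direct/associative covariance typical of layer lines
    r_a = 0.13
    s2_ad, s2_as = 0.31, 0.041
    cov = r_a * np.sqrt(s2_ad * s2_as)
    return np.array([[s2_ad, cov], [cov, s2_as]])


@dataclass
class SimConfig:
    """Study-structure and genetic parameters of the generator.

    Defaults emulate a single purebred White Leghorn line: hierarchical
    matings (8 dams/sire, Poisson(12.3) female offspring per dam), 4-bird
    cages, 48 house×row×level classes, censoring at day 406 (~58 weeks).
    """

    n_sires: int = 10
    dams_per_sire: int = 8
    mean_offspring_per_dam: float = 12.3
    n_per_cage: int = 4
    houses: int = 2
    rows: int = 8
    levels: int = 3
    line: str = "W1"
    # genetics
    G0_true: np.ndarray = field(default_factory=_default_g0)
    rho_true: float = 0.0
    sigma2_e_true: float = 1.0
    beta_sd: float = 0.1           # SD of fixed house×row×level class effects
    # survival process
    scale: str = "hazard"          # "hazard" | "linear"
    baseline_shape: float = 2.0    # Weibull shape (hazard scale)
    baseline_scale: float = 570.0  # Weibull scale in days (hazard scale)
    mu_days: float = 354.0         # intercept (linear scale)
    study_end_day: float | None = 406.0
    variable_censoring: tuple[float, float] | None = None  # (fraction, day)
    removal_fraction: float = 0.0  # uniform-time censored removals
    seed: int = 0

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> tuple[Pedigree, list[str]]:
    """Two-generation pedigree: founder sires and dams, phenotyped offspring.

    Each sire is mated to ``dams_per_sire`` dams; each dam contributes
    Poisson(``mean_offspring_per_dam``) offspring. Returns the pedigree and
    the ids of the offspring (phenotyped) generation.
    """
    ids: list[str] = []
    sire = []
    dam = []
    sires = [f"S{k}" for k in range(1, config.n_sires + 1)]
    dams = [f"D{k}" for k in range(1, config.n_sires * config.dams_per_sire + 1)]
    for s in sires + dams:
        ids.append(s)
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
    idx = {a: i for i, a in enumerate(ids)}
    offspring: list[str] = []
    counts = rng.poisson(config.mean_offspring_per_dam, size=len(dams))
    kid = 0
    for j, d in enumerate(dams):
        s = sires[j // config.dams_per_sire]  # hierarchical mating
        for _ in range(int(counts[j])):
            kid += 1
            a = f"A{kid}"
            ids.append(a)
            sire.append(idx[s])
            dam.append(idx[d])
            offspring.append(a)
    ped = Pedigree(ids, np.asarray(sire, dtype=np.int64), np.asarray(dam, dtype=np.int64))
    return ped, offspring


def simulate_breeding_values(
    ped: Pedigree, G0_true: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (a_D, a_S) per animal with joint covariance A ⊗ G0.

    Founders ~ N(0, G0); descendants are the parent average plus a Mendelian
    sampling deviation with covariance G0·(0.5 − 0.25(F_s + F_d)) (one known
    parent: 0.75 − 0.25·F_p), so realized covariances match the tabular A
    with inbreeding.
    """
    G0_true = np.asarray(G0_true, dtype=float)
    n = ped.n
    bv = np.zeros((n, 2))
    # Mendelian deviations drawn upfront from N(0, G0), scaled per animal.
    w, V = np.linalg.eigh(G0_true)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 2)) @ L.T
    if not np.any(G0_true):
        return bv[:, 0], bv[:, 1]
    F = ped.inbreeding()
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s == UNKNOWN and d == UNKNOWN:
            bv[i] = z[i]
        else:
            pa = np.zeros(2)
            if s != UNKNOWN and d != UNKNOWN:
                pa = 0.5 * (bv[s] + bv[d])
                m = 0.5 - 0.25 * (F[s] + F[d])
            else:
                p = s if s != UNKNOWN else d
                pa = 0.5 * bv[p]
                m = 0.75 - 0.25 * F[p]
            bv[i] = pa + np.sqrt(m) * z[i]
    return bv[:, 0], bv[:, 1]


def assign_cages(
    animals: list[str], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomly compose cages of ``n_per_cage``, assign fixed-effect classes
    and a symmetric back-to-back cage pairing.

    Animals beyond a whole number of cages are dropped (logged by count via
    the returned frame's length); the cage count is trimmed to an even number
    so every cage has a back neighbour.
    """
    animals = list(animals)
    perm = rng.permutation(len(animals))
    n = config.n_per_cage
    n_cages = len(animals) // n
    if n_cages % 2 == 1:
        n_cages -= 1  # every cage needs a back neighbour
    chosen = [animals[i] for i in perm[: n_cages * n]]
    cages = [f"C{k + 1}" for k in range(n_cages)]
    classes = [
        (f"H{h + 1}", f"R{r + 1}", f"L{l + 1}")
        for h in range(config.houses)
        for r in range(config.rows)
        for l in range(config.levels)
    ]
    rows = []
    # back-to-back pairing: consecutive cages share a class and are neighbours
    for k, cage in enumerate(cages):
        house, row, level = classes[(k // 2) % len(classes)]
        back = cages[k + 1] if k % 2 == 0 else cages[k - 1]
        for a in chosen[k * n : (k + 1) * n]:
            rows.append((a, cage, house, row, level, config.line, back))
    return pd.DataFrame(
        rows, columns=["animal", "cage", "house", "row", "level", "line", "back_cage"]
    )


def _cage_social_sums(frame: pd.DataFrame, a_s: dict[str, float]) -> np.ndarray:
    """Σ of cage mates' associative breeding values per animal."""
    s_by_animal = frame["animal"].map(a_s).to_numpy(float)
    cage_tot = frame.groupby("cage")["animal"].transform(lambda ids: sum(a_s[a] for a in ids))
    return cage_tot.to_numpy(float) - s_by_animal


def simulate_survival(
    frame: pd.DataFrame,
    a_D: dict[str, float],
    a_S: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate survival days and censoring codes for caged animals.

    Returns the frame with ``days`` (integer, ≥1), ``event`` (1 = death
    observed) and the realized ``back_cage_mean`` covariate (mean survival
    days of the paired back cage, computed after simulation — two-pass).
    """
    frame = frame.copy()
    n_rec = len(frame)
    classes = frame["house"] + ":" + frame["row"] + ":" + frame["level"]
    uclasses = sorted(classes.unique())
    beta = config.beta_sd * rng.standard_normal(len(uclasses))
    beta -= beta.mean()
    class_eff = classes.map(dict(zip(uclasses, beta))).to_numpy(float)
    ad = frame["animal"].map(a_D).to_numpy(float)
    social = _cage_social_sums(frame, a_S)

    end = config.study_end_day if config.study_end_day is not None else np.inf
    if config.scale == "hazard":
        eta = class_eff + ad + social
        u = rng.uniform(size=n_rec)
        # invert Λ(t) = (t/scale)^shape · e^η
        t_death = config.baseline_scale * (-np.log(u) / np.exp(eta)) ** (
            1.0 / config.baseline_shape
        )
        days = np.ceil(t_death)
        event = (days <= end).astype(int)
        days = np.minimum(days, end)
    elif config.scale == "linear":
        eta = config.mu_days + class_eff + ad + social
        sd_e = np.sqrt(config.sigma2_e_true)
        rho = config.rho_true
        e = np.empty(n_rec)
        for _, pos in frame.groupby("cage").indices.items():
            m = len(pos)
            R = np.full((m, m), rho) + (1 - rho) * np.eye(m)
            L = np.linalg.cholesky(R)
            e[pos] = sd_e * (L @ rng.standard_normal(m))
        y = eta + e
        days = np.ceil(np.maximum(y, 1.0))
        event = (days <= end).astype(int)
        days = np.minimum(days, end)
    else:
        raise ValueError(f"invalid scale {config.scale!r}")
    days = np.maximum(days, 1.0)

    # removals: a small fraction censored at a uniform time before their death
    if config.removal_fraction > 0:
        rem = rng.uniform(size=n_rec) < config.removal_fraction
        t_max = end if np.isfinite(end) else float(days.max())
        t_rem = np.ceil(rng.uniform(1.0, t_max, size=n_rec))
        hit = rem & (t_rem < days)
        days = np.where(hit, t_rem, days)
        event = np.where(hit, 0, event)

    # variable-censoring scenario: a fraction of the censored records are
    # re-censored earlier (e.g. half-way the study, day 200)
    if config.variable_censoring is not None:
        frac, day = config.variable_censoring
        cens = np.flatnonzero(event == 0)
        pick = rng.choice(cens, size=int(round(frac * len(cens))), replace=False)
        days[pick] = day
    frame["days"] = days.astype(int)
    frame["event"] = event.astype(int)

    cage_mean = frame.groupby("cage")["days"].mean()
    frame["back_cage_mean"] = frame["back_cage"].map(cage_mean).astype(float)
    return frame.drop(columns=["back_cage"])


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, Pedigree, dict]:
    """Full generator: pedigree → breeding values → cages → survival.

    Returns (data, pedigree, truth) where truth carries the true breeding
    values and generating parameters for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    ped, offspring = simulate_pedigree(config, rng)
    ad, as_ = simulate_breeding_values(ped, config.G0_true, rng)
    a_D = dict(zip(ped.ids, ad))
    a_S = dict(zip(ped.ids, as_))
    frame = assign_cages(offspring, config, rng)
    data = simulate_survival(frame, a_D, a_S, config, rng)
    g = np.asarray(config.G0_true, dtype=float)
    truth = {
        "a_D": a_D,
        "a_S": a_S,
        "sigma2_AD": float(g[0, 0]),
        "sigma_ADS": float(g[0, 1]),
        "sigma2_AS": float(g[1, 1]),
        "rho": config.rho_true,
        "sigma2_e": config.sigma2_e_true,
        "scale": config.scale,
        "n_per_cage": config.n_per_cage,
        "seed": config.seed,
    }
    return data, ped, truth
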