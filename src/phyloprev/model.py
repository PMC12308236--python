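"""Binomial phylogenetic regression of per-species prevalence.

The model: for species i with n_i necropsies and k_i cases,

    k_i ~ Binomial(n_i, inv_logit(eta_i))
    eta_i = beta0 + sum_m beta_m x_mi (+ beta_int x_1i x_2i) + u_i
    u ~ MVN(0, sigma_phylo^2 R(theta))

where R is an OU or Pagel's-lambda correlation matrix from the tree.
Sampling is adaptive random-walk Metropolis-within-Gibbs on
(beta, log sigma, transformed theta, z) with the species effects
parameterized non-centrally: u = sigma * L(theta) z, L = chol(R).

Predictors are mean-centred internally for mixing; retained draws are
mapped back to the raw-covariate coefficient scale, so reported slopes
and intercepts refer to the uncentred covariates.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, t as student_t

from .tree import (
    PhyloTree,
    cholesky_with_jitter,
    normalize_label,
    shared_path_times,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceDataset",
    "ModelSpec",
    "MCMCConfig",
    "PriorConfig",
    "PosteriorFit",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "fit_all_specs",
]

PREDICTORS = ("log10_mass", "log10_longevity")
INTERACTION = "log10_mass:log10_longevity"
RESPONSES = ("neoplasia", "malignant", "lethal")


# --------------------------------------------------------------------------
# data containers


@dataclass
class PrevalenceDataset:
    """Per-species necropsy counts, case counts by tumour type, covariates."""

    species: list[str]
    n_necropsies: np.ndarray
    k_cases: dict[str, np.ndarray]
    log10_mass: np.ndarray
    log10_longevity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_necropsies = np.asarray(self.n_necropsies, dtype=int)
        self.log10_mass = np.asarray(self.log10_mass, dtype=float)
        self.log10_longevity = np.asarray(self.log10_longevity, dtype=float)
        self.k_cases = {k: np.asarray(v, dtype=int) for k, v in self.k_cases.items()}
        self.validate()

    def validate(self) -> None:
        S = len(self.species)
        if len(set(self.species)) != S:
            raise ValueError("duplicate species in dataset")
        if self.n_necropsies.shape != (S,):
            raise ValueError("n_necropsies length mismatch")
        if (self.n_necropsies < 1).any():
            raise ValueError("all species need at least one necropsy")
        for name, k in self.k_cases.items():
            if k.shape != (S,):
                raise ValueError(f"k_cases[{name!r}] length mismatch")
            if (k < 0).any() or (k > self.n_necropsies).any():
                bad = np.where((k < 0) | (k > self.n_necropsies))[0]
                raise ValueError(
                    f"counts out of range for {name!r} at species "
                    f"{[self.species[i] for i in bad]}"
                )
        for name, x in (
            ("log10_mass", self.log10_mass),
            ("log10_longevity", self.log10_longevity),
        ):
            if x.shape != (S,):
                raise ValueError(f"{name} length mismatch")
            if not np.isfinite(x).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def covariate(self, name: str) -> np.ndarray:
        if name == "log10_mass":
            return self.log10_mass
        if name == "log10_longevity":
            return self.log10_longevity
        raise KeyError(name)

    def prevalence(self, response: str) -> np.ndarray:
        return self.k_cases[response] / self.n_necropsies

    def subset(self, index: Sequence[int]) -> "PrevalenceDataset":
        idx = list(index)
        return PrevalenceDataset(
            species=[self.species[i] for i in idx],
            n_necropsies=self.n_necropsies[idx],
            k_cases={k: v[idx] for k, v in self.k_cases.items()},
            log10_mass=self.log10_mass[idx],
            log10_longevity=self.log10_longevity[idx],
            meta=dict(self.meta),
        )

    def data_hash(self, response: Optional[str] = None) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.species).encode())
        h.update(self.n_necropsies.tobytes())
        keys = [response] if response else sorted(self.k_cases)
        for key in keys:
            h.update(key.encode())
            h.update(self.k_cases[key].tobytes())
        h.update(np.round(self.log10_mass, 12).tobytes())
        h.update(np.round(self.log10_longevity, 12).tobytes())
        return h.hexdigest()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PrevalenceDataset":
        """Build from the CSV schema
        ``species,n_necropsies,k_*,body_mass_kg,max_longevity_months``.

        Rows with missing covariates or counts are dropped with a logged
        count (recorded in ``meta['n_dropped_missing']``).
        """
        required = {"species", "n_necropsies", "body_mass_kg", "max_longevity_months"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        k_cols = [c for c in frame.columns if c.startswith("k_")]
        if not k_cols:
            raise ValueError("dataset needs at least one k_<type> column")
        use = frame[["species", "n_necropsies", "body_mass_kg", "max_longevity_months"]
                    + k_cols]
        complete = use.dropna()
        n_dropped = len(use) - len(complete)
        if n_dropped:
            logger.warning("dropped %d rows with missing values", n_dropped)
        if (complete["body_mass_kg"] <= 0).any() or (
            complete["max_longevity_months"] <= 0
        ).any():
            raise ValueError("body mass and longevity must be positive")
        k_cases = {c[2:]: complete[c].to_numpy(dtype=int) for c in k_cols}
        return cls(
            species=[normalize_label(s) for s in complete["species"].astype(str)],
            n_necropsies=complete["n_necropsies"].to_numpy(dtype=int),
            k_cases=k_cases,
            log10_mass=np.log10(complete["body_mass_kg"].to_numpy(dtype=float)),
            log10_longevity=np.log10(
                complete["max_longevity_months"].to_numpy(dtype=float)
            ),
            meta={"n_dropped_missing": n_dropped},
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "species": self.species,
            "n_necropsies": self.n_necropsies,
        }
        for name, k in self.k_cases.items():
            cols[f"k_{name}"] = k
        cols["body_mass_kg"] = 10.0 ** self.log10_mass
        cols["max_longevity_months"] = 10.0 ** self.log10_longevity
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ModelSpec:
    """Which response, predictors, and phylogenetic structure to fit."""

    response: str = "neoplasia"
    predictors: tuple[str, ...] = ("log10_mass",)
    include_interaction: bool = False
    structure_family: str = "OU"  # OU | LAMBDA
    structure_mode: str = "estimate"  # "estimate" or "fixed"
    structure_value: Optional[float] = None  # required when fixed

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("at least one predictor required")
        for p in self.predictors:
            if p not in PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}")
        if self.include_interaction and len(self.predictors) != 2:
            raise ValueError("interaction requires both predictors")
        if self.structure_family.upper() not in ("OU", "LAMBDA"):
            raise ValueError("structure_family must be OU or LAMBDA")
        if self.structure_mode not in ("estimate", "fixed"):
            raise ValueError("structure_mode must be 'estimate' or 'fixed'")
        if self.structure_mode == "fixed" and self.structure_value is None:
            raise ValueError("fixed structure_mode requires structure_value")

    @property
    def family(self) -> str:
        return self.structure_family.upper()

    @property
    def coef_names(self) -> tuple[str, ...]:
        names = ["intercept", *self.predictors]
        if self.include_interaction:
            names.append(INTERACTION)
        return tuple(names)

    @property
    def structure_param_name(self) -> str:
        return "alpha" if self.family == "OU" else "lambda"

    def label(self) -> str:
        preds = "+".join(self.predictors)
        if self.include_interaction:
            preds += "+interaction"
        return f"{self.response}~{preds}[{self.family}]"


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 5000
    burn_in: int = 2000
    thin: int = 5
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("at least 2 chains required")

    @property
    def n_kept_per_chain(self) -> int:
        # draws are taken at burn_in + thin, burn_in + 2*thin, ...
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative defaults standing in for 'default uninformative'.

    Normal(0, 10) on regression coefficients, half-Student-t(3, 0, 2.5) on
    the phylogenetic SD, half-Normal(0, 5) on OU alpha (depth-1 tree),
    Uniform(0, 1) on Pagel's lambda.
    """

    beta_loc: tuple[float, ...] | float = 0.0
    beta_scale: tuple[float, ...] | float = 10.0
    sigma_df: float = 3.0
    sigma_scale: float = 2.5
    alpha_scale: float = 5.0

    def beta_params(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        loc = np.broadcast_to(np.asarray(self.beta_loc, dtype=float), (p,)).copy()
        scale = np.broadcast_to(np.asarray(self.beta_scale, dtype=float), (p,)).copy()
        return loc, scale


# --------------------------------------------------------------------------
# likelihood and priors


def design_matrix(dataset: PrevalenceDataset, spec: ModelSpec) -> np.ndarray:
    cols = [np.ones(dataset.n_species)]
    for p in spec.predictors:
        cols.append(dataset.covariate(p))
    if spec.include_interaction:
        cols.append(dataset.covariate(spec.predictors[0])
                    * dataset.covariate(spec.predictors[1]))
    return np.column_stack(cols)


def _binom_const(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _binom_loglik_eta(
    eta: np.ndarray, k: np.ndarray, n: np.ndarray, const: np.ndarray
) -> np.ndarray:
    # k*log(p) + (n-k)*log(1-p) = k*eta - n*log(1+exp(eta))
    return const + k * eta - n * np.logaddexp(0.0, eta)


def log_likelihood(
    beta: np.ndarray,
    u: np.ndarray,
    dataset: PrevalenceDataset,
    spec: ModelSpec,
) -> float:
    """Binomial log likelihood (including the binomial coefficient)."""
    X = design_matrix(dataset, spec)
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]}")
    if u.shape != (dataset.n_species,):
        raise ValueError("u must align with species order")
    k = dataset.k_cases[spec.response]
    n = dataset.n_necropsies
    eta = X @ beta + u
    return float(_binom_loglik_eta(eta, k, n, _binom_const(k, n)).sum())


def log_prior(
    beta: np.ndarray,
    sigma_phylo: float,
    structure_param: float,
    spec: ModelSpec,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Sum of independent log prior densities; -inf outside support."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    loc, scale = priors.beta_params(len(beta))
    lp = float(norm.logpdf(beta, loc=loc, scale=scale).sum())
    if sigma_phylo < 0:
        return -np.inf
    lp += float(
        np.log(2.0)
        + student_t.logpdf(sigma_phylo, df=priors.sigma_df, scale=priors.sigma_scale)
    )
    if spec.family == "OU":
        if structure_param < 0:
            return -np.inf
        lp += float(np.log(2.0) + norm.logpdf(structure_param, scale=priors.alpha_scale))
    else:
        if not 0.0 <= structure_param <= 1.0:
            return -np.inf
        # Uniform(0,1): log density 0
    return lp


# --------------------------------------------------------------------------
# posterior fit container


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus diagnostics and provenance."""

    draws: dict[str, np.ndarray]  # scalar params: (chains, kept); "u": (chains, kept, S)
    pointwise_loglik: np.ndarray  # (chains, kept, S)
    spec: ModelSpec
    mcmc: MCMCConfig
    species: list[str]
    data_hash: str
    diagnostics: dict[str, dict] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def scalar_params(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: (chains*kept,) or (chains*kept, S)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    @property
    def n_draws(self) -> int:
        return int(np.prod(self.pointwise_loglik.shape[:2]))

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log likelihood as (total draws, S)."""
        c, k, S = self.pointwise_loglik.shape
        return self.pointwise_loglik.reshape(c * k, S)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.scalar_params:
            x = self.stacked(name)
            q = np.quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975])
            row = {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "q97.5": q[4],
            }
            row.update({k: v for k, v in self.diagnostics.get(name, {}).items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def draws_long(self) -> pd.DataFrame:
        frames = []
        for name in self.scalar_params:
            v = self.draws[name]
            c, k = v.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), k),
                        "iter": np.tile(np.arange(k), c),
                        "parameter": name,
                        "value": v.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# sampler


class SamplingError(RuntimeError):
    pass


def _align_species(dataset: PrevalenceDataset, tree: PhyloTree) -> np.ndarray:
    tip_index = {lab: i for i, lab in enumerate(tree.tips)}
    missing = [s for s in dataset.species if normalize_label(s) not in tip_index]
    if missing:
        raise ValueError(
            f"{len(missing)} dataset species absent from tree tips, e.g. "
            f"{missing[:5]}"
        )
    return np.array([tip_index[normalize_label(s)] for s in dataset.species])


def _structure_matrix_factory(tree: PhyloTree, spec: ModelSpec, sp_idx: np.ndarray):
    """Closure param -> correlation submatrix for the dataset's species.

    A principal submatrix of a valid correlation matrix is the marginal
    correlation of the corresponding species, so no tree pruning is needed.
    """
    T = tree.depth
    t_full = shared_path_times(tree)
    t_sub = t_full[np.ix_(sp_idx, sp_idx)]
    if spec.family == "OU":
        def build(alpha: float) -> np.ndarray:
            if alpha <= 1e-8:
                R = t_sub / T
            else:
                a2 = 2.0 * alpha
                R = (
                    np.exp(-a2 * (T - t_sub))
                    * (-np.expm1(-a2 * t_sub))
                    / (-np.expm1(-a2 * T))
                )
            R = np.asarray(R)
            np.fill_diagonal(R, 1.0)
            return R
    else:
        bm = t_sub / T

        def build(lam: float) -> np.ndarray:
            R = lam * bm
            np.fill_diagonal(R, 1.0)
            return R

    return build


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_ADAPT_WINDOW = 50
_TARGET_ACC = 0.44


def _run_chain(
    rng: np.random.Generator,
    Xc: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    build_R,
    spec: ModelSpec,
    mcmc: MCMCConfig,
    priors: PriorConfig,
    beta_init: np.ndarray,
):
    S = len(n)
    p = Xc.shape[1]
    const = _binom_const(k, n)
    loc, scale = priors.beta_params(p)

    # -- state
    beta = beta_init + 0.2 * rng.standard_normal(p)
    log_sigma = float(np.log(0.5) + 0.3 * rng.standard_normal())
    estimate_theta = spec.structure_mode == "estimate"
    if spec.family == "OU":
        param = spec.structure_value if not estimate_theta else float(
            np.exp(rng.normal(0.0, 0.5))
        )
        theta = np.log(max(param, 1e-6))
    else:
        param = spec.structure_value if not estimate_theta else float(
            rng.uniform(0.2, 0.8)
        )
        param = min(max(param, 1e-6), 1 - 1e-6)
        theta = float(np.log(param) - np.log1p(-param))
    z = np.zeros(S)

    L = cholesky_with_jitter(build_R(param))
    sigma = float(np.exp(log_sigma))
    v = L @ z
    xb = Xc @ beta
    eta = xb + sigma * v
    llv = _binom_loglik_eta(eta, k, n, const)

    def prior_beta(b):
        return float(norm.logpdf(b, loc=loc, scale=scale).sum())

    def prior_sigma(ls):
        s = np.exp(ls)
        return float(
            np.log(2.0)
            + student_t.logpdf(s, df=priors.sigma_df, scale=priors.sigma_scale)
            + ls  # Jacobian of sigma = exp(ls)
        )

    def theta_to_param(th):
        if spec.family == "OU":
            return float(np.exp(th))
        return float(1.0 / (1.0 + np.exp(-th)))

    def prior_theta(th):
        if spec.family == "OU":
            a = np.exp(th)
            return float(np.log(2.0) + norm.logpdf(a, scale=priors.alpha_scale) + th)
        lam = 1.0 / (1.0 + np.exp(-th))
        return float(np.log(lam) + np.log1p(-lam))  # Uniform + logit Jacobian

    lp_beta = prior_beta(beta)
    lp_sigma = prior_sigma(log_sigma)
    lp_theta = prior_theta(theta) if estimate_theta else 0.0

    # -- adaptive step sizes
    s_beta = np.full(p, 0.2)
    s_sigma = 0.4
    s_theta = 0.5
    s_z = np.full(S, 0.8)
    acc_beta = np.zeros(p)
    acc_sigma = 0.0
    acc_theta = 0.0
    acc_z = np.zeros(S)
    n_acc_total = 0

    kept = mcmc.n_kept_per_chain
    out_beta = np.empty((kept, p))
    out_sigma = np.empty(kept)
    out_param = np.empty(kept)
    out_u = np.empty((kept, S))
    out_ll = np.empty((kept, S))
    out_lp = np.empty(kept)
    kept_i = 0

    Lcols = [np.ascontiguousarray(L[j:, j]) for j in range(S)]

    for it in range(1, mcmc.iterations + 1):
        # beta coordinates
        for d in range(p):
            db = s_beta[d] * rng.standard_normal()
            beta_prop = beta.copy()
            beta_prop[d] = beta[d] + db
            eta_prop = eta + Xc[:, d] * db
            llv_prop = _binom_loglik_eta(eta_prop, k, n, const)
            lp_prop = prior_beta(beta_prop)
            if np.log(rng.random()) < (llv_prop.sum() - llv.sum() + lp_prop - lp_beta):
                beta = beta_prop
                eta = eta_prop
                llv = llv_prop
                lp_beta = lp_prop
                xb = xb + Xc[:, d] * db
                acc_beta[d] += 1
                n_acc_total += 1

        # log sigma
        ls_prop = log_sigma + s_sigma * rng.standard_normal()
        sig_prop = float(np.exp(ls_prop))
        eta_prop = xb + sig_prop * v
        llv_prop = _binom_loglik_eta(eta_prop, k, n, const)
        lp_prop = prior_sigma(ls_prop)
        if np.log(rng.random()) < (llv_prop.sum() - llv.sum() + lp_prop - lp_sigma):
            log_sigma, sigma = ls_prop, sig_prop
            eta, llv, lp_sigma = eta_prop, llv_prop, lp_prop
            acc_sigma += 1
            n_acc_total += 1

        # structure parameter
        if estimate_theta:
            th_prop = theta + s_theta * rng.standard_normal()
            param_prop = theta_to_param(th_prop)
            try:
                L_prop = cholesky_with_jitter(build_R(param_prop))
            except np.linalg.LinAlgError:
                L_prop = None
            if L_prop is not None:
                v_prop = L_prop @ z
                eta_prop = xb + sigma * v_prop
                llv_prop = _binom_loglik_eta(eta_prop, k, n, const)
                lp_prop = prior_theta(th_prop)
                if np.log(rng.random()) < (
                    llv_prop.sum() - llv.sum() + lp_prop - lp_theta
                ):
                    theta, param = th_prop, param_prop
                    L, v = L_prop, v_prop
                    eta, llv, lp_theta = eta_prop, llv_prop, lp_prop
                    Lcols = [np.ascontiguousarray(L[j:, j]) for j in range(S)]
                    acc_theta += 1
                    n_acc_total += 1

        # species effects, coordinate-wise on the whitened scale
        zsn = rng.standard_normal(S)
        zu = rng.random(S)
        for j in range(S):
            dz = s_z[j] * zsn[j]
            dcol = (sigma * dz) * Lcols[j]
            eta_tail = eta[j:] + dcol
            llv_tail = _binom_loglik_eta(eta_tail, k[j:], n[j:], const[j:])
            dll = llv_tail.sum() - llv[j:].sum()
            dlp = -0.5 * ((z[j] + dz) ** 2 - z[j] ** 2)
            if np.log(zu[j]) < dll + dlp:
                z[j] += dz
                eta[j:] = eta_tail
                llv[j:] = llv_tail
                v[j:] += dz * Lcols[j]
                acc_z[j] += 1
                n_acc_total += 1

        # adaptation during burn-in only
        if it <= mcmc.burn_in and it % _ADAPT_WINDOW == 0:
            w = _ADAPT_WINDOW
            s_beta *= np.exp(np.clip(acc_beta / w - _TARGET_ACC, -0.5, 0.5))
            s_sigma *= np.exp(np.clip(acc_sigma / w - _TARGET_ACC, -0.5, 0.5))
            s_theta *= np.exp(np.clip(acc_theta / w - _TARGET_ACC, -0.5, 0.5))
            s_z *= np.exp(np.clip(acc_z / w - _TARGET_ACC, -0.5, 0.5))
            np.clip(s_beta, 1e-3, 10.0, out=s_beta)
            s_sigma = float(np.clip(s_sigma, 1e-3, 10.0))
            s_theta = float(np.clip(s_theta, 1e-3, 10.0))
            np.clip(s_z, 1e-3, 10.0, out=s_z)
            acc_beta[:] = 0
            acc_sigma = 0.0
            acc_theta = 0.0
            acc_z[:] = 0

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            if kept_i < kept:
                out_beta[kept_i] = beta
                out_sigma[kept_i] = sigma
                out_param[kept_i] = param
                out_u[kept_i] = sigma * v
                out_ll[kept_i] = llv
                out_lp[kept_i] = (
                    llv.sum()
                    + lp_beta
                    + lp_sigma
                    + lp_theta
                    - 0.5 * float(z @ z)
                )
                kept_i += 1

    if n_acc_total == 0:
        raise SamplingError(
            "no proposal was ever accepted; step-size adaptation failed "
            f"(final scales: beta={s_beta}, sigma={s_sigma}, z median={np.median(s_z)})"
        )
    return out_beta, out_sigma, out_param, out_u, out_ll, out_lp


def sample_posterior(
    dataset: PrevalenceDataset,
    tree: PhyloTree,
    spec: ModelSpec,
    mcmc: MCMCConfig,
    priors: PriorConfig = PriorConfig(),
    compute_diagnostics: bool = True,
) -> PosteriorFit:
    """Draw from the posterior of the binomial phylogenetic regression.

    Reproducible: the same seed, data and settings give identical draws.
    """
    if dataset.n_species < 5:
        raise ValueError("need at least 5 species to fit")
    if spec.response not in dataset.k_cases:
        raise ValueError(f"response {spec.response!r} not in dataset")
    sp_idx = _align_species(dataset, tree)
    X = design_matrix(dataset, spec)
    col_sd = X[:, 1:].std(axis=0)
    if (col_sd < 1e-12).any():
        bad = [spec.coef_names[1:][i] for i in np.where(col_sd < 1e-12)[0]]
        raise ValueError(f"zero-variance predictor(s): {bad}")

    # centre non-intercept columns; map draws back to raw scale afterwards
    means = X[:, 1:].mean(axis=0)
    Xc = X.copy()
    Xc[:, 1:] -= means

    build_R = _structure_matrix_factory(tree, spec, sp_idx)
    k = dataset.k_cases[spec.response]
    n = dataset.n_necropsies

    p = X.shape[1]
    beta_init = np.zeros(p)
    pooled = (k.sum() + 0.5) / (n.sum() + 1.0)
    beta_init[0] = float(np.log(pooled / (1 - pooled)))

    kept = mcmc.n_kept_per_chain
    if kept < 1:
        raise ValueError("MCMC settings retain no draws")

    C = mcmc.chains
    S = dataset.n_species
    betas = np.empty((C, kept, p))
    sigmas = np.empty((C, kept))
    params = np.empty((C, kept))
    us = np.empty((C, kept, S))
    lls = np.empty((C, kept, S))
    lps = np.empty((C, kept))
    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, c]))
        b, s, q, u, ll, lp = _run_chain(
            rng, Xc, k, n, build_R, spec, mcmc, priors, beta_init
        )
        betas[c], sigmas[c], params[c], us[c], lls[c], lps[c] = b, s, q, u, ll, lp

    # un-centre the coefficients: eta = a0 + sum a_m (x_m - mu_m) + a_int c1 c2
    raw = np.empty_like(betas)
    raw[...] = betas
    if spec.include_interaction:
        m1, m2 = means[0], means[1]
        a0, a1, a2, a12 = (betas[..., i] for i in range(4))
        raw[..., 0] = a0 - a1 * m1 - a2 * m2 + a12 * m1 * m2
        raw[..., 1] = a1 - a12 * m2
        raw[..., 2] = a2 - a12 * m1
        raw[..., 3] = a12
    else:
        raw[..., 0] = betas[..., 0] - betas[..., 1:] @ means

    draws: dict[str, np.ndarray] = {}
    for i, name in enumerate(spec.coef_names):
        draws[name] = raw[..., i]
    draws["sigma_phylo"] = sigmas
    draws[spec.structure_param_name] = params
    draws["lp__"] = lps
    draws["u"] = us

    fit = PosteriorFit(
        draws=draws,
        pointwise_loglik=lls,
        spec=spec,
        mcmc=mcmc,
        species=list(dataset.species),
        data_hash=dataset.data_hash(spec.response),
        meta={"covariate_means": dict(zip(spec.coef_names[1:], means))},
    )
    if compute_diagnostics:
        from . import evaluation

        for name in fit.scalar_params:
            if name == "lp__":
                continue
            x = fit.draws[name]
            fit.diagnostics[name] = {
                "rhat": evaluation.split_rhat(x),
                "ess_bulk": evaluation.ess(x, kind="bulk"),
                "ess_tail": evaluation.ess(x, kind="tail"),
                "lag1_autocorr": evaluation.lag_autocorr(x, lag=1),
            }
    return fit


def fit_all_specs(
    dataset: PrevalenceDataset,
    tree: PhyloTree,
    responses: Sequence[str],
    mcmc: MCMCConfig,
    structure_family: str = "OU",
    priors: PriorConfig = PriorConfig(),
) -> list[PosteriorFit]:
    """Mass-only, longevity-only, both, and interaction fits per response."""
    predictor_sets = [
        (("log10_mass",), False),
        (("log10_longevity",), False),
        (("log10_mass", "log10_longevity"), False),
        (("log10_mass", "log10_longevity"), True),
    ]
    fits = []
    for response in responses:
        for preds, interact in predictor_sets:
            spec = ModelSpec(
                response=response,
                predictors=preds,
                include_interaction=interact,
                structure_family=structure_family,
            )
            try:
                fits.append(sample_posterior(dataset, tree, spec, mcmc, priors))
            except Exception as exc:
                raise SamplingError(f"fit failed for {spec.label()}: {exc}") from exc
    return fits
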