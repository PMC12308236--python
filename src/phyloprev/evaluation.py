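"""Convergence gates, information criteria and posterior predictive checks.

Diagnostics follow the split-chain / rank-normalization conventions of
modern MCMC practice; WAIC and PSIS-LOO are computed from the pointwise
log-likelihood matrix with log-sum-exp stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp, ndtri
from scipy.stats import binom, kstest, rankdata

__all__ = [
    "ConvergenceReport",
    "ICReport",
    "split_rhat",
    "ess",
    "lag_autocorr",
    "waic",
    "psis_loo",
    "information_criteria",
    "compare_structures",
    "posterior_predictive_check",
    "convergence_report",
]


def _as_chains(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws with shape (chains, iterations)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    return x


def _split_chains(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    half = n // 2
    return np.vstack([x[:, :half], x[:, half: 2 * half]])


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Constant chains return 1.0 with a warning (zero within-variance
    convention).
    """
    x = _split_chains(_as_chains(chains))
    m, n = x.shape
    if np.ptp(x) == 0:
        warnings.warn("constant chains: Rhat defined as 1", RuntimeWarning)
        return 1.0
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        warnings.warn("zero within-chain variance: Rhat defined as 1", RuntimeWarning)
        return 1.0
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance (biased, divided by n) via FFT."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=nfft, axis=1)[:, :n].real
    return acov / n


def _ess_core(x: np.ndarray) -> float:
    """ESS with Geyer's initial monotone positive sequence, split chains."""
    x = _split_chains(x)
    m, n = x.shape
    if np.ptp(x) == 0:
        return 0.0
    acov = _autocov(x)
    chain_means = x.mean(axis=1)
    mean_var = acov[:, 0].mean() * n / (n - 1)
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += chain_means.var(ddof=1)
    if var_plus == 0:
        return 0.0

    rho = np.zeros(n)
    rho[0] = 1.0
    t = 1
    # pair sums of autocorrelations, stopped at first negative pair
    while t < n - 1:
        r_even = 1.0 - (mean_var - acov[:, t].mean()) / var_plus
        r_odd = 1.0 - (mean_var - acov[:, t + 1].mean()) / var_plus
        if r_even + r_odd < 0:
            break
        rho[t] = r_even
        rho[t + 1] = r_odd
        t += 2
    max_t = t
    # enforce monotone non-increasing pair sums
    prev = rho[1] + rho[2] if max_t > 2 else np.inf
    for s in range(3, max_t, 2):
        pair = rho[s] + rho[s + 1]
        if pair > prev:
            scalef = prev / pair
            rho[s] *= scalef
            rho[s + 1] *= scalef
            pair = prev
        prev = pair
    tau = 1.0 + 2.0 * rho[1:max_t].sum()
    tau = max(tau, 1.0 / np.log10(m * n + 10))
    return float(m * n / tau)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, axis=None).reshape(x.shape)
    return ndtri((r - 0.375) / (x.size + 0.25))


def ess(chains: np.ndarray, kind: str = "bulk") -> float:
    """Bulk (rank-normalized) or tail (5%/95% indicator) effective sample size.

    Capped at 1.5x the total number of draws; constant chains give 0 with
    a warning.
    """
    x = _as_chains(chains)
    total = x.size
    if np.ptp(x) == 0:
        warnings.warn("constant chains: ESS defined as 0", RuntimeWarning)
        return 0.0
    if kind == "bulk":
        value = _ess_core(_rank_normalize(x))
    elif kind == "tail":
        q05, q95 = np.quantile(x, [0.05, 0.95])
        ess_q = []
        for q in (q05, q95):
            ind = (x <= q).astype(float)
            if np.ptp(ind) == 0:
                continue
            ess_q.append(_ess_core(ind))
        value = min(ess_q) if ess_q else 0.0
    else:
        raise ValueError("kind must be 'bulk' or 'tail'")
    return float(min(value, 1.5 * total))


def lag_autocorr(chains: np.ndarray, lag: int = 1) -> float:
    """Mean across chains of the lag-``lag`` autocorrelation of retained draws."""
    x = _as_chains(chains)
    vals = []
    for row in x:
        if np.ptp(row) == 0:
            vals.append(0.0)
            continue
        a = row[:-lag] - row[:-lag].mean()
        b = row[lag:] - row[lag:].mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        vals.append(float((a * b).sum() / denom) if denom > 0 else 0.0)
    return float(np.mean(vals))


# --------------------------------------------------------------------------
# convergence report


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    lag1_autocorr: dict[str, float]
    passed: bool
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "ess_tail": self.ess_tail,
            "lag1_autocorr": self.lag1_autocorr,
            "passed": self.passed,
            "thresholds": self.thresholds,
        }


def convergence_report(
    fit,
    rhat_tol: float = 0.01,
    ess_min: float = 1000.0,
    autocorr_max: float = 0.1,
    params: Optional[list[str]] = None,
) -> ConvergenceReport:
    """Apply the convergence gates to a fit's scalar parameters."""
    names = params or [p for p in fit.scalar_params if p != "lp__"]
    rhat, eb, et, ac = {}, {}, {}, {}
    for name in names:
        d = fit.diagnostics.get(name)
        if d is None:
            x = fit.draws[name]
            d = {
                "rhat": split_rhat(x),
                "ess_bulk": ess(x, "bulk"),
                "ess_tail": ess(x, "tail"),
                "lag1_autocorr": lag_autocorr(x, 1),
            }
        rhat[name] = d["rhat"]
        eb[name] = d["ess_bulk"]
        et[name] = d["ess_tail"]
        ac[name] = d["lag1_autocorr"]
    passed = (
        all(abs(v - 1.0) <= rhat_tol for v in rhat.values())
        and all(v > ess_min for v in eb.values())
        and all(v > ess_min for v in et.values())
        and all(abs(v) < autocorr_max for v in ac.values())
    )
    return ConvergenceReport(
        rhat=rhat,
        ess_bulk=eb,
        ess_tail=et,
        lag1_autocorr=ac,
        passed=passed,
        thresholds={
            "rhat_tol": rhat_tol,
            "ess_min": ess_min,
            "autocorr_max": autocorr_max,
        },
    )


# --------------------------------------------------------------------------
# information criteria


@dataclass
class ICReport:
    waic: float
    p_waic: float
    se_waic: float
    looic: Optional[float] = None
    pareto_k: Optional[np.ndarray] = None

    @property
    def n_high_pareto_k(self) -> int:
        if self.pareto_k is None:
            return 0
        finite = self.pareto_k[np.isfinite(self.pareto_k)]
        return int((finite > 0.7).sum())

    def to_dict(self) -> dict:
        return {
            "waic": self.waic,
            "p_waic": self.p_waic,
            "se_waic": self.se_waic,
            "looic": self.looic,
            "pareto_k": None
            if self.pareto_k is None
            else [float(v) for v in self.pareto_k],
            "n_high_pareto_k": self.n_high_pareto_k,
        }


def _as_ll_matrix(pointwise_loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, S)")
    if not np.isfinite(ll).all():
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    return ll


def waic(pointwise_loglik: np.ndarray) -> ICReport:
    """Widely applicable information criterion from a (draws, S) matrix."""
    ll = _as_ll_matrix(pointwise_loglik)
    ndraw, S = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(ndraw)
    p_i = ll.var(axis=0, ddof=1) if ndraw > 1 else np.zeros(S)
    elpd_i = lppd_i - p_i
    value = -2.0 * elpd_i.sum()
    se = 2.0 * np.sqrt(S * elpd_i.var(ddof=1)) if S > 1 else 0.0
    return ICReport(waic=float(value), p_waic=float(p_i.sum()), se_waic=float(se))


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Generalized-Pareto (k, sigma) by the Zhang--Stephens posterior mean."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    jj = np.arange(1, m + 1, dtype=float)
    b = 1.0 - np.sqrt(m / (jj - 0.5))
    b /= prior_bs * x[max(int(n / 4 + 0.5) - 1, 0)]
    b += 1.0 / x[-1]
    k_j = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        log_lik = n * (np.log(-b / k_j) - k_j - 1.0)
        weights = 1.0 / np.nansum(
            np.exp(np.clip(log_lik[None, :] - log_lik[:, None], -700, 700)), axis=1
        )
    weights[~np.isfinite(weights)] = 0.0
    keep = weights >= 10 * np.finfo(float).eps
    if keep.any():
        weights, b = weights[keep], b[keep]
    weights = weights / weights.sum()
    b_post = float((b * weights).sum())
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return float(k_post), float(sigma)


def _gpd_quantiles(prob: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-prob)
    return sigma * np.expm1(-k * np.log1p(-prob)) / k


def psis_loo(pointwise_loglik: np.ndarray) -> ICReport:
    """Pareto-smoothed importance-sampling LOO.

    Raw importance weights per species are 1/p(y_i | theta_s); the top-20%
    tail of the log weights is smoothed with a fitted generalized Pareto.
    Degenerate (constant) weights are flagged with k = -inf.
    """
    ll = _as_ll_matrix(pointwise_loglik)
    ndraw, S = ll.shape
    if ndraw < 100:
        warnings.warn(
            f"PSIS-LOO with only {ndraw} draws; >=100 recommended", RuntimeWarning
        )
    elpd = np.empty(S)
    khat = np.empty(S)
    n_tail = max(int(np.ceil(0.2 * ndraw)), 5)
    n_tail = min(n_tail, ndraw - 1) if ndraw > 1 else 0
    for i in range(S):
        lw = -ll[:, i]
        lw = lw - lw.max()
        if np.ptp(lw) == 0 or n_tail < 5:
            khat[i] = -np.inf
            elpd[i] = logsumexp(ll[:, i]) - np.log(ndraw)
            continue
        order = np.argsort(lw)
        tail_idx = order[-n_tail:]
        cutoff = lw[order[-n_tail - 1]]
        exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
        if np.ptp(exceed) == 0:
            khat[i] = -np.inf
        else:
            kfit, sigma = _gpd_fit(exceed[exceed > 0] if (exceed > 0).any() else exceed)
            khat[i] = kfit
            probs = (np.arange(1, n_tail + 1) - 0.5) / n_tail
            smoothed = np.log(
                _gpd_quantiles(probs, kfit, sigma) + np.exp(cutoff)
            )
            # keep the original draw order within the tail
            ranks = np.argsort(np.argsort(lw[tail_idx]))
            lw = lw.copy()
            lw[tail_idx] = np.minimum(smoothed[ranks], 0.0)
        elpd[i] = logsumexp(lw + ll[:, i]) - logsumexp(lw)
    report = waic(ll)
    report.looic = float(-2.0 * elpd.sum())
    report.pareto_k = khat
    return report


def information_criteria(fit) -> ICReport:
    """WAIC and PSIS-LOO for a posterior fit."""
    return psis_loo(fit.loglik_matrix())


def compare_structures(fit_ou, fit_lambda) -> dict:
    """Compare OU- and lambda-structured fits of the same data by WAIC/LOOIC.

    Deltas are signed as (lambda - OU); |delta WAIC| < 2 is flagged
    indistinguishable but still resolved by the lower WAIC.
    """
    if fit_ou.data_hash != fit_lambda.data_hash:
        raise ValueError("fits were made on different data (hash mismatch)")
    ic_ou = psis_loo(fit_ou.loglik_matrix())
    ic_lam = psis_loo(fit_lambda.loglik_matrix())
    delta_waic = ic_lam.waic - ic_ou.waic
    delta_looic = ic_lam.looic - ic_ou.looic
    preferred = fit_ou.spec.family if delta_waic >= 0 else fit_lambda.spec.family
    return {
        "preferred": preferred,
        "delta_waic": float(delta_waic),
        "delta_looic": float(delta_looic),
        "indistinguishable": bool(abs(delta_waic) < 2.0),
        "waic_ou": ic_ou.waic,
        "waic_lambda": ic_lam.waic,
        "looic_ou": ic_ou.looic,
        "looic_lambda": ic_lam.looic,
    }


# --------------------------------------------------------------------------
# posterior predictive checks


def posterior_predictive_check(fit, dataset, seed: int = 0) -> dict:
    """Randomized-quantile PIT residuals against the posterior predictive.

    For species i, r_i ~ Uniform(F(k_i - 1), F(k_i)) with F the
    draw-averaged binomial CDF; under a well-specified model the r_i are
    uniform (Kolmogorov--Smirnov p-value reported).
    """
    rng = np.random.default_rng(seed)
    from .model import design_matrix  # local import avoids a cycle

    X = design_matrix(dataset, fit.spec)
    beta = np.column_stack([fit.stacked(nm) for nm in fit.spec.coef_names])
    u = fit.stacked("u")
    eta = beta @ X.T + u  # (draws, S)
    p = 1.0 / (1.0 + np.exp(-eta))
    k_obs = dataset.k_cases[fit.spec.response]
    n = dataset.n_necropsies
    ndraw, S = p.shape

    pit = np.empty(S)
    flags = np.zeros(S, dtype=bool)
    for i in range(S):
        cdf_hi = binom.cdf(k_obs[i], n[i], p[:, i]).mean()
        cdf_lo = binom.cdf(k_obs[i] - 1, n[i], p[:, i]).mean() if k_obs[i] > 0 else 0.0
        if cdf_hi <= cdf_lo:  # degenerate predictive
            pit[i] = np.clip(cdf_hi, 0.0, 1.0)
            flags[i] = True
        else:
            pit[i] = rng.uniform(cdf_lo, cdf_hi)
    uniformity_p = float(kstest(pit, "uniform").pvalue) if S > 1 else 1.0

    # replicated summary statistics from a subsample of draws
    n_rep = min(200, ndraw)
    sel = rng.choice(ndraw, size=n_rep, replace=False)
    k_rep = rng.binomial(n[None, :], p[sel])
    prev_rep = k_rep / n[None, :]
    return {
        "pit_residuals": pit,
        "degenerate_flags": flags,
        "uniformity_p": uniformity_p,
        "summary_stats": {
            "observed_zero_fraction": float((k_obs == 0).mean()),
            "replicated_zero_fraction": float((k_rep == 0).mean()),
            "observed_max_prevalence": float((k_obs / n).max()),
            "replicated_max_prevalence_mean": float(prev_rep.max(axis=1).mean()),
        },
    }
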