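"""Posterior effect summaries: odds ratios, marginal curves, Jeffreys CIs.

Significance everywhere means the central 95% credible interval of a
logit-scale slope excludes zero (equivalently, the OR interval excludes 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist, binom

__all__ = [
    "EffectSummary",
    "MarginalCurve",
    "odds_ratio_summary",
    "marginal_effect_curve",
    "jeffreys_interval",
    "ci_width_curve",
]

_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class EffectSummary:
    coefficient: str
    beta_median: float
    beta_quantiles: dict[float, float]
    odds_ratio: float
    or_quantiles: dict[float, float]
    significant: bool
    direction: int  # +1, -1 or 0

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "beta_median": self.beta_median,
            "beta_quantiles": {str(k): v for k, v in self.beta_quantiles.items()},
            "odds_ratio": self.odds_ratio,
            "or_quantiles": {str(k): v for k, v in self.or_quantiles.items()},
            "significant": self.significant,
            "direction": self.direction,
        }


def odds_ratio_summary(fit, coefficient: str) -> EffectSummary:
    """Quantiles of a slope's draws, exponentiated to the odds-ratio scale."""
    if coefficient not in fit.draws:
        raise KeyError(
            f"unknown coefficient {coefficient!r}; have {fit.scalar_params}"
        )
    draws = fit.stacked(coefficient)
    q = {lev: float(np.quantile(draws, lev)) for lev in _QUANTILES}
    significant = q[0.025] > 0 or q[0.975] < 0
    direction = 0
    if significant:
        direction = 1 if q[0.5] > 0 else -1
    return EffectSummary(
        coefficient=coefficient,
        beta_median=q[0.5],
        beta_quantiles=q,
        odds_ratio=float(np.exp(q[0.5])),
        or_quantiles={lev: float(np.exp(v)) for lev, v in q.items()},
        significant=bool(significant),
        direction=direction,
    )


@dataclass
class MarginalCurve:
    predictor: str
    grid: np.ndarray
    median: np.ndarray
    bands: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev, (lo, hi) in sorted(self.bands.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "predictor_value": self.grid,
                        "level": lev,
                        "lower": lo,
                        "median": self.median,
                        "upper": hi,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def marginal_effect_curve(
    fit,
    dataset,
    predictor: str,
    grid_size: int = 50,
    levels: tuple[int, ...] = (50, 75, 95),
) -> MarginalCurve:
    """Posterior prevalence curve over one predictor.

    Other covariates are held at their in-sample means, the species effect
    at zero; per grid point the bands are central posterior quantiles.
    """
    spec = fit.spec
    if predictor not in spec.predictors:
        raise KeyError(f"predictor {predictor!r} not in model {spec.coef_names}")
    x = dataset.covariate(predictor)
    grid = np.linspace(x.min(), x.max(), grid_size)

    b0 = fit.stacked("intercept")
    eta = np.tile(b0[:, None], (1, grid_size))
    eta += fit.stacked(predictor)[:, None] * grid[None, :]
    others = [p for p in spec.predictors if p != predictor]
    for other in others:
        xbar = float(dataset.covariate(other).mean())
        eta += fit.stacked(other)[:, None] * xbar
    if spec.include_interaction:
        from .model import INTERACTION

        xbar_other = float(dataset.covariate(others[0]).mean())
        eta += fit.stacked(INTERACTION)[:, None] * grid[None, :] * xbar_other
    prev = 1.0 / (1.0 + np.exp(-eta))

    median = np.quantile(prev, 0.5, axis=0)
    bands = {}
    for lev in levels:
        a = (1.0 - lev / 100.0) / 2.0
        bands[int(lev)] = (
            np.quantile(prev, a, axis=0),
            np.quantile(prev, 1.0 - a, axis=0),
        )
    return MarginalCurve(predictor=predictor, grid=grid, median=median, bands=bands)


def jeffreys_interval(k, n, level: float = 0.95):
    """Jeffreys-prior credible interval for a binomial proportion.

    Quantiles of Beta(k + 1/2, n - k + 1/2), with the boundary rule
    lo = 0 when k = 0 and hi = 1 when k = n.  Vectorizes over k and n.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("need 0 <= k <= n")
    if np.any(n_arr < 1):
        raise ValueError("need n >= 1")
    tail = (1.0 - level) / 2.0
    lo = beta_dist.ppf(tail, k_arr + 0.5, n_arr - k_arr + 0.5)
    hi = beta_dist.ppf(1.0 - tail, k_arr + 0.5, n_arr - k_arr + 0.5)
    lo = np.where(k_arr == 0, 0.0, lo)
    hi = np.where(k_arr == n_arr, 1.0, hi)
    if np.isscalar(k) and np.isscalar(n):
        return float(lo), float(hi)
    return lo, hi


def ci_width_curve(
    p_true: float, n_grid, level: float = 0.95
) -> np.ndarray:
    """Exact expected Jeffreys-interval width at each sample size.

    For each n, E_k[hi - lo] with k ~ Binomial(n, p_true), computed by
    summing over all k.  Strictly decreasing in n for fixed p.
    """
    if not 0.0 < p_true < 1.0:
        raise ValueError("p_true must be in (0, 1)")
    widths = []
    for n in n_grid:
        n = int(n)
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        ks = np.arange(n + 1)
        lo, hi = jeffreys_interval(ks, np.full(n + 1, n), level=level)
        pmf = binom.pmf(ks, n, p_true)
        widths.append(float((pmf * (hi - lo)).sum()))
    return np.asarray(widths)
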