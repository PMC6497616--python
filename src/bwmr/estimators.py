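"""Univariable two-sample MR estimators.

Every estimator consumes a set of harmonised instruments (per-SNP exposure
beta ``bx``, outcome beta ``by``, outcome SE ``sy``) and returns a causal
effect on the log-odds-per-SD scale. The five methods trade power for
robustness to invalid instruments:

- **IVW**: zero-intercept regression of by on bx weighted by 1/sy^2;
  efficient when every SNP is a valid instrument. The multiplicative
  random-effects variant inflates the SE by the residual scale
  sqrt(Q/(L-1)), floored at 1, when between-SNP heterogeneity exceeds
  chance.
- **MR-Egger**: the same regression with a free intercept; the slope is a
  consistent causal estimate when pleiotropic effects are independent of
  instrument strength (InSIDE), and the intercept estimates the average
  directional pleiotropic effect.
- **Weighted median**: the weighted median of per-SNP Wald ratios;
  consistent when valid instruments carry over half the weight.
- **Weighted mode**: the mode of the kernel-smoothed weighted Wald-ratio
  density; consistent when the largest cluster of similar ratios comes
  from valid instruments.
- **Penalised robust IVW**: IVW with chi-square-tail down-weighting of
  outlying ratios plus a bounded-influence (Tukey biweight) fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from bwmr.instruments import InstrumentSet
from bwmr.summary_data import HarmonisedInstrument

logger = logging.getLogger("bwmr.estimators")

__all__ = [
    "MREstimate",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "ivw_penalised_robust",
    "estimate_all",
]

Instruments = Union[InstrumentSet, Sequence[HarmonisedInstrument]]

#: 95% two-sided normal critical value used for all confidence intervals.
Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is on the log-odds (binary outcome) or SD (quantitative
    outcome) scale per 1-SD higher exposure; ``or_scale`` exponentiates
    the estimate and its confidence interval.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) on the odds-ratio scale."""
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)

    def as_dict(self) -> dict:
        or_, lo, hi = self.or_scale
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "n_snps": self.n_snps,
        }
        d.update(self.extras)
        return d


def _arrays(instruments: Instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    items = list(instruments)
    bx = np.array([i.beta_exposure for i in items], dtype=float)
    sx = np.array([i.se_exposure for i in items], dtype=float)
    by = np.array([i.beta_outcome for i in items], dtype=float)
    sy = np.array([i.se_outcome for i in items], dtype=float)
    return bx, sx, by, sy


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Return (theta, fixed-effects se, Cochran's Q) for the IVW fit."""
    w = 1.0 / sy**2
    sww = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / sww
    fe_se = sww**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, fe_se, q


def ivw(instruments: Instruments, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to the weighted average of per-SNP Wald ratios with weights
    1/wald_se^2, and to zero-intercept weighted regression of outcome betas
    on exposure betas with weights 1/se_outcome^2. With ``random_effects``
    the SE is multiplied by max(1, sqrt(Q/(L-1))) — the multiplicative
    random-effects model. A single instrument degrades to its Wald ratio.
    """
    bx, _, by, sy = _arrays(instruments)
    L = bx.size
    if L < 1:
        raise ValueError("ivw requires at least one instrument")
    if L == 1:
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        p = 2 * stats.norm.sf(abs(beta) / se)
        return MREstimate("IVW", beta, se, p, 1, extras={"q": 0.0, "re_scale_factor": 1.0})
    theta, fe_se, q = _ivw_core(bx, by, sy)
    scale = max(1.0, math.sqrt(q / (L - 1))) if random_effects else 1.0
    se = fe_se * scale
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate(
        "IVW",
        theta,
        se,
        p,
        L,
        extras={"q": q, "re_scale_factor": scale, "fe_se": fe_se},
    )


def mr_egger(
    instruments: Instruments,
    random_effects: bool = True,
    ci: str = "normal",
) -> MREstimate:
    """MR-Egger regression: weighted regression of by on bx with a free intercept.

    Rows are internally oriented so every exposure beta is positive (the
    intercept is only meaningful for a fixed orientation). The slope is
    the causal estimate; the intercept, its SE and two-sided p (t with
    L-2 df) land in ``extras`` as ``egger_intercept*``. Random-effects
    scaling uses the residual sum with L-2 df, floored at 1.

    ``ci``: "normal" (default) or "t" critical values for the interval.
    """
    bx, _, by, sy = _arrays(instruments)
    L = bx.size
    if L < 3:
        raise ValueError("egger_underdetermined: MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    cov_unscaled = np.linalg.inv(X.T @ (X * w[:, None]))
    scale = max(1.0, math.sqrt(rss / (L - 2))) if random_effects else 1.0
    se_int, se_slope = scale * np.sqrt(np.diag(cov_unscaled))
    slope, intercept = float(coef[1]), float(coef[0])

    p_slope = 2 * stats.t.sf(abs(slope) / se_slope, df=L - 2)
    p_int = 2 * stats.t.sf(abs(intercept) / se_int, df=L - 2)
    crit = stats.t.ppf(0.975, df=L - 2) if ci == "t" else Z95
    return MREstimate(
        "MR_Egger",
        slope,
        float(se_slope),
        float(p_slope),
        L,
        ci_low=slope - crit * se_slope,
        ci_high=slope + crit * se_slope,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": float(se_int),
            "egger_intercept_p": float(p_int),
            "re_scale_factor": scale,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    # lexicographic sort keeps tied ratios in a canonical (weight) order, so
    # the interpolation is invariant to the input ordering of the SNPs
    order = np.lexsort((weights, ratios))
    b = ratios[order]
    s = weights[order] / weights.sum()
    # cumulative midpoint position of each ratio on the weight axis
    p = np.cumsum(s) - s / 2
    if 0.5 <= p[0]:
        return float(b[0])
    if 0.5 >= p[-1]:
        return float(b[-1])
    return float(np.interp(0.5, p, b))


def _ratio_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ratios = by / bx
    wald_se = sy / np.abs(bx)
    return ratios, 1.0 / wald_se**2


def _bootstrap_se(
    point,
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    seed: Optional[int],
) -> float:
    """Parametric bootstrap: resample betas from their sampling normals."""
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s[bx_s == 0] = np.finfo(float).tiny
        ratios, weights = _ratio_weights(bx_s, by_s, sy)
        est[i] = point(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(
    instruments: Instruments,
    n_boot: int = 5000,
    seed: Optional[int] = 0,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are ordered, weights (inverse Wald-ratio variance) normalised to
    sum 1, and the estimate is the linear interpolation of ratio against
    cumulative midpoint weight at 0.5. The SE comes from a parametric
    bootstrap (``n_boot`` resamples of the betas from their sampling
    distributions); ``n_boot=0`` skips it (SE/CI/p reported as NaN), which
    is useful in simulation loops that only need point estimates.
    """
    bx, sx, by, sy = _arrays(instruments)
    if bx.size < 2:
        raise ValueError("weighted_median requires at least 2 instruments")
    ratios, weights = _ratio_weights(bx, by, sy)
    beta = _weighted_median_point(ratios, weights)
    if n_boot > 0:
        se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, n_boot, seed)
        p = 2 * stats.norm.sf(abs(beta) / se)
    else:
        se = p = float("nan")
    return MREstimate("weighted_median", beta, se, p, bx.size, extras={"n_boot": n_boot})


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, scaled MAD) L^(-1/5), times ``factor``."""
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return factor * 0.9 * spread * ratios.size ** (-1 / 5)


def _weighted_mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float = 1.0,
    n_grid: int = 1024,
) -> float:
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    if h <= 0:
        return float(ratios[0])  # all ratios identical
    w = weights / weights.sum()

    def density(x: np.ndarray) -> np.ndarray:
        z = (x[:, None] - ratios[None, :]) / h
        return (np.exp(-0.5 * z**2) * w[None, :]).sum(axis=1)

    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    j = int(np.argmax(density(grid)))
    # refine around the coarse argmax with one fine pass
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_grid - 1)]
    fine = np.linspace(lo, hi, 201)
    return float(fine[np.argmax(density(fine))])


def weighted_mode(
    instruments: Instruments,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: Optional[int] = 0,
) -> MREstimate:
    """Mode of the kernel-smoothed weighted density of Wald ratios.

    A normal kernel with the modified-Silverman bandwidth (times
    ``bandwidth_factor``) is placed at each ratio, weighted by inverse
    Wald-ratio variance; the estimate is the density argmax on a 1024-point
    grid spanning the ratios +/- 3 bandwidths, refined by a 201-point local
    pass. If every ratio is identical (zero bandwidth) the common ratio is
    returned. SE by the same parametric bootstrap as the weighted median.
    """
    bx, sx, by, sy = _arrays(instruments)
    if bx.size < 3:
        raise ValueError("weighted_mode requires at least 3 instruments")
    ratios, weights = _ratio_weights(bx, by, sy)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)

    def point(r, w):
        return _weighted_mode_point(r, w, bandwidth_factor, n_grid=512)

    if n_boot > 0:
        se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
        p = 2 * stats.norm.sf(abs(beta) / se)
    else:
        se = p = float("nan")
    return MREstimate(
        "weighted_mode", beta, se, p, bx.size, extras={"n_boot": n_boot, "bandwidth_factor": bandwidth_factor}
    )


def ivw_penalised_robust(
    instruments: Instruments,
    penalty_alpha: float = 0.05,
    tuning_constant: float = 4.685,
) -> MREstimate:
    """Penalised robust IVW.

    Stage 1 down-weights SNPs with outlying Wald ratios: each SNP's
    heterogeneity tail probability p_j comes from its Cochran's Q
    contribution against chi-square(1), and its weight is multiplied by
    min(1, p_j / penalty_alpha) — with the default penalty_alpha = 0.05
    this is min(1, 20 p_j), so SNPs whose Q contribution is unremarkable
    (p_j >= 0.05) keep their full weight. Stage 2 fits a bounded-influence
    robust regression (Tukey biweight, default tuning constant 4.685 for
    95% efficiency under normality) of by on bx through the origin with
    the penalised weights. The SE is the robust-fit SE floored at the
    fixed-effects IVW SE; if the robust fit fails to converge the
    penalised (non-robust) IVW is returned with a logged warning.
    """
    import statsmodels.api as sm

    bx, _, by, sy = _arrays(instruments)
    L = bx.size
    if L < 2:
        raise ValueError("ivw_penalised_robust requires at least 2 instruments")
    theta, fe_se, _ = _ivw_core(bx, by, sy)
    ratios, w = _ratio_weights(bx, by, sy)
    q_j = w * (ratios - theta) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    w_pen = w * np.minimum(1.0, p_j / penalty_alpha)

    sw = np.sqrt(w_pen)
    method = "IVW_penalised_robust"
    try:
        rlm = sm.RLM(by * sw, (bx * sw)[:, None], M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
        fit = rlm.fit()
        beta = float(fit.params[0])
        se = float(fit.bse[0])
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
            raise ValueError("robust fit produced non-finite estimates")
    except Exception as exc:  # fall back to penalised non-robust IVW
        logger.warning("robust fit failed (%s); falling back to penalised IVW", exc)
        sww = float(np.sum(w_pen * bx**2))
        beta = float(np.sum(w_pen * bx * by)) / sww
        se = sww**-0.5
        method = "IVW_penalised"
    se = max(se, fe_se)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        method,
        beta,
        se,
        p,
        L,
        extras={"penalty_alpha": penalty_alpha, "n_penalised": int(np.sum(w_pen < w))},
    )


_METHODS = {
    "ivw": ivw,
    "mr_egger": mr_egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
    "ivw_penalised_robust": ivw_penalised_robust,
}


def estimate_all(
    instruments: Instruments,
    methods: Iterable[str] = ("ivw", "mr_egger", "weighted_median", "weighted_mode", "ivw_penalised_robust"),
    n_boot: int = 5000,
    seed: Optional[int] = 0,
) -> list[MREstimate]:
    """Run several estimators on one instrument set with shared bootstrap settings."""
    out = []
    for name in methods:
        fn = _METHODS.get(name)
        if fn is None:
            raise ValueError(f"unknown MR method {name!r}; choose from {sorted(_METHODS)}")
        if name in ("weighted_median", "weighted_mode"):
            out.append(fn(instruments, n_boot=n_boot, seed=seed))
        else:
            out.append(fn(instruments))
    return out
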