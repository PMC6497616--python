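"""Heterogeneity and influence diagnostics for the IVW model.

Under homogeneity every SNP's Wald ratio estimates the same causal effect,
and Cochran's Q — the weighted sum of squared deviations of the ratios
from the pooled IVW estimate — is chi-square with L-1 degrees of freedom.
Excess Q signals that some SNPs act on the outcome through pathways other
than the exposure. Four complementary procedures localise the signal:

- stepwise pruning: greedily remove the largest Q contributor, refit, and
  repeat until Q is no longer significant;
- Cook's distance on the zero-intercept weighted IVW regression, flagged
  above 4/L;
- leave-one-out: the IVW estimate recomputed without each SNP in turn;
- externally studentised residuals of the IVW regression, flagged beyond
  +/- 2.

All influence measures are computed on the same zero-intercept weighted
regression that defines the IVW estimator, so a flagged SNP is influential
for the estimate actually reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from bwmr.estimators import Instruments, MREstimate, _arrays, _ivw_core, ivw
from bwmr.instruments import InstrumentSet

__all__ = [
    "HeterogeneityReport",
    "cochran_q",
    "stepwise_q_prune",
    "cooks_influence",
    "leave_one_out",
    "studentised_outliers",
]


@dataclass
class HeterogeneityReport:
    """Cochran's Q with its per-SNP decomposition and flagged-SNP sets."""

    q: float
    df: int
    pvalue: float
    per_snp_q: dict[str, float]
    flagged: dict[str, set[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "q": self.q,
            "df": self.df,
            "pvalue": self.pvalue,
            "per_snp_q": self.per_snp_q,
            "flagged": {k: sorted(v) for k, v in self.flagged.items()},
        }


def _snp_ids(instruments: Instruments) -> list[str]:
    return [ins.snp_id for ins in instruments]


def cochran_q(instruments: Instruments) -> HeterogeneityReport:
    """Cochran's Q from the Wald ratios against the IVW estimate.

    q_j = (ratio_j - theta_IVW)^2 / wald_se_j^2; Q = sum q_j, compared to
    chi-square with L-1 df. Identical ratios give Q = 0, p = 1.
    """
    bx, _, by, sy = _arrays(instruments)
    L = bx.size
    if L < 2:
        raise ValueError("cochran_q requires at least 2 instruments")
    theta, _, _ = _ivw_core(bx, by, sy)
    ratios = by / bx
    wald_se = sy / np.abs(bx)
    q_j = (ratios - theta) ** 2 / wald_se**2
    q = float(q_j.sum())
    p = float(stats.chi2.sf(q, df=L - 1))
    return HeterogeneityReport(q=q, df=L - 1, pvalue=p, per_snp_q=dict(zip(_snp_ids(instruments), q_j)))


def stepwise_q_prune(
    instruments: InstrumentSet,
    alpha: float = 0.05,
    refit: bool = True,
) -> tuple[InstrumentSet, list[str]]:
    """Greedy stepwise-downward pruning on Cochran's Q.

    While the Q test is significant at ``alpha``, remove the SNP with the
    largest per-SNP Q contribution (ties broken by SNP id, lexicographic)
    and recompute. ``refit=False`` keeps the original pooled estimate when
    ranking contributions instead of refitting each round. Pruning that
    would leave fewer than 2 instruments stops and reports non-convergence.

    Returns the pruned set and the removal order.
    """
    if len(instruments) < 3:
        raise ValueError("stepwise_q_prune requires at least 3 instruments")
    current = list(instruments.instruments)
    removed: list[str] = []
    theta0 = None
    if not refit:
        bx, _, by, sy = _arrays(current)
        theta0, _, _ = _ivw_core(bx, by, sy)
    while True:
        if refit:
            report = cochran_q(current)
            per = report.per_snp_q
            pval = report.pvalue
        else:
            per = {ins.snp_id: (ins.wald_ratio - theta0) ** 2 / ins.wald_se**2 for ins in current}
            pval = float(stats.chi2.sf(sum(per.values()), df=len(current) - 1))
        if pval >= alpha:
            break
        if len(current) <= 2:
            raise RuntimeError(
                f"stepwise pruning failed to converge: {len(current)} instruments left, Q p={pval:.3g}"
            )
        # ties broken lexicographically: smallest id among maximal contributions
        top = max(per.values())
        worst_id = min(k for k, v in per.items() if v == top)
        current = [ins for ins in current if ins.snp_id != worst_id]
        removed.append(worst_id)
    pruned = InstrumentSet(
        name=f"{instruments.name}_pruned", instruments=current, filter_log=list(instruments.filter_log)
    )
    return pruned, removed


def _weighted_fit_pieces(instruments: Instruments):
    """Transformed-scale residuals and leverages of the zero-intercept weighted fit.

    With x* = sqrt(w) bx and y* = sqrt(w) by (w = 1/sy^2) the IVW estimate
    is the OLS slope of y* on x*; standard OLS influence formulas then
    apply with p = 1 parameter.
    """
    bx, _, by, sy = _arrays(instruments)
    w = 1.0 / sy**2
    xs = np.sqrt(w) * bx
    ys = np.sqrt(w) * by
    sxx = float(np.sum(xs**2))
    theta = float(np.sum(xs * ys)) / sxx
    resid = ys - theta * xs
    leverage = xs**2 / sxx
    return theta, resid, leverage, xs.size


def cooks_influence(instruments: Instruments, threshold: Optional[float] = None) -> set[str]:
    """SNPs whose Cook's distance on the IVW regression exceeds ``threshold``.

    Default threshold is the conventional 4/L. Exact-fit data have zero
    distances everywhere.
    """
    ids = _snp_ids(instruments)
    d = cooks_distances(instruments)
    L = len(ids)
    if threshold is None:
        threshold = 4.0 / L
    return {sid for sid in ids if d[sid] > threshold}


def cooks_distances(instruments: Instruments) -> dict[str, float]:
    """Cook's distance of each SNP for the zero-intercept weighted IVW fit."""
    _, resid, leverage, L = _weighted_fit_pieces(instruments)
    if L < 3:
        raise ValueError("cooks_distances requires at least 3 instruments")
    s2 = float(np.sum(resid**2)) / (L - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = resid**2 * leverage / (s2 * (1 - leverage) ** 2)
    d = np.where(s2 > 0, d, 0.0)
    return dict(zip(_snp_ids(instruments), d))


def leave_one_out(instruments: InstrumentSet, random_effects: bool = True) -> list[MREstimate]:
    """IVW re-estimated with each SNP removed in turn, plus the full-set row.

    Returns L+1 estimates; each leave-one-out row carries the omitted SNP
    id in ``extras["omitted"]`` and the final row has ``omitted = None``.
    """
    if len(instruments) < 3:
        raise ValueError("leave_one_out requires at least 3 instruments")
    rows = []
    items = instruments.instruments
    for j, ins in enumerate(items):
        est = ivw([x for k, x in enumerate(items) if k != j], random_effects=random_effects)
        est.extras["omitted"] = ins.snp_id
        rows.append(est)
    full = ivw(items, random_effects=random_effects)
    full.extras["omitted"] = None
    rows.append(full)
    return rows


def studentised_outliers(instruments: Instruments, threshold: float = 2.0) -> set[str]:
    """SNPs with externally studentised IVW residuals beyond ±``threshold``.

    External studentisation re-estimates the residual variance with the
    SNP removed, so a gross outlier cannot mask itself by inflating the
    pooled variance.
    """
    ids = _snp_ids(instruments)
    t = studentised_residuals(instruments)
    return {sid for sid in ids if abs(t[sid]) > threshold}


def studentised_residuals(instruments: Instruments) -> dict[str, float]:
    """Externally studentised residuals of the zero-intercept weighted fit."""
    _, resid, leverage, L = _weighted_fit_pieces(instruments)
    if L < 3:
        raise ValueError("studentised_residuals requires at least 3 instruments")
    rss = float(np.sum(resid**2))
    out = {}
    for sid, e, h in zip(_snp_ids(instruments), resid, leverage):
        s2_loo = (rss - e**2 / (1 - h)) / (L - 2)
        if s2_loo <= 0:
            t = 0.0 if e == 0 else math.copysign(math.inf, e)
        else:
            t = e / math.sqrt(s2_loo * (1 - h))
        out[sid] = float(t)
    return out
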