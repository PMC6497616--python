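"""Instrument strength and a-priori power for a binary outcome.

The share of exposure variance an instrument explains (r^2) drives both
the F-statistic — the conventional weak-instrument gauge, with F < 10
flagging a weak instrument — and the power of a two-sample MR test on a
case/control outcome. Two r^2 routes are provided: recovering each SNP's
1-df F statistic from its p-value and the exposure sample size (usable
when allele frequencies are missing), and the allele-frequency formula
sum 2 f (1-f) beta^2 for standardised traits (the generator's
ground-truth route).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("bwmr.power")

__all__ = [
    "PowerSpec",
    "variance_explained_pn",
    "variance_explained_freq",
    "f_statistic",
    "binary_outcome_power",
]

#: smallest p-value used when recovering F statistics (underflow floor)
P_FLOOR = 1e-300


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a binary-outcome power calculation.

    or_detect is the odds ratio per 1-SD higher exposure the study should
    detect; alpha the two-sided significance level.
    """

    r2: float
    n_cases: int
    n_controls: int
    or_detect: float
    alpha: float = 0.05
    n_exposure: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.r2 < 1):
            raise ValueError(f"r2 must be in (0,1), got {self.r2}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.or_detect <= 0:
            raise ValueError(f"or_detect must be positive, got {self.or_detect}")


def variance_explained_pn(p_values: Sequence[float], n: int) -> float:
    """Instrument r^2 from per-SNP exposure p-values and the GWAS sample size.

    Each p is inverted through the upper tail of F(1, n-2) to the SNP's
    1-df F statistic, converted to r^2_j = F/(n-2+F), and summed over the
    (independent) SNPs. The quantile is evaluated through the exact
    identity F(1, nu) = t(nu)^2, which stays finite far into the tail
    where the direct F inverse overflows. p-values at or below the
    underflow floor are clipped with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        n_clip = int(np.sum(p <= 0))
        if np.any(p >= 1):
            raise ValueError("p-values must be < 1")
        if n_clip:
            logger.warning("clipping %d underflowed p-value(s) to %.0e", n_clip, P_FLOOR)
        p = np.clip(p, P_FLOOR, None)
    f = stats.t.isf(p / 2, n - 2) ** 2
    r2_j = f / (n - 2 + f)
    return float(r2_j.sum())


def variance_explained_freq(betas: Sequence[float], eafs: Sequence[float]) -> float:
    """Instrument r^2 as sum 2 f (1-f) beta^2 for a standardised (unit-variance) trait."""
    b = np.asarray(list(betas), dtype=float)
    f = np.asarray(list(eafs), dtype=float)
    if b.shape != f.shape:
        raise ValueError("betas and eafs must have the same length")
    if np.any(np.isnan(f)):
        raise ValueError("missing eaf: the frequency method needs every allele frequency")
    return float(np.sum(2.0 * f * (1.0 - f) * b**2))


def f_statistic(r2: float, n: int, k: int) -> tuple[float, bool]:
    """Instrument-strength F-statistic and the weak-instrument flag.

    F = (r^2/(1-r^2)) * ((n-k-1)/k) for k SNPs jointly explaining r^2 of
    the exposure in a sample of n. Returns ``(F, weak)`` with ``weak``
    True when F < 10.
    """
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    f = (r2 / (1.0 - r2)) * ((n - k - 1) / k)
    return f, f < 10.0


def binary_outcome_power(spec: PowerSpec) -> float:
    """Power of a two-sample MR test on a case/control outcome.

    With N = n_cases + n_controls, case fraction phi, and b = |ln OR| per
    1-SD exposure:

        power = Phi( b * sqrt(N * r2 * phi * (1-phi)) - z_{1-alpha/2} )

    The normal-approximation formula for the Wald test of the IVW
    estimate. At OR = 1 this degenerates to alpha/2 (the one-sided
    rejection mass). Depends on OR only through |ln OR|, so it is
    symmetric in OR and 1/OR by construction.
    """
    n_total = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n_total
    b = abs(math.log(spec.or_detect))
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(b * math.sqrt(n_total * spec.r2 * phi * (1.0 - phi)) - z_crit))
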