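"""Multivariable Mendelian randomisation.

Where univariable MR regresses outcome betas on one exposure's betas,
MVMR regresses them jointly on K exposures' betas — here birth weight
plus the co-measured traits (birth length, adult height, adult BMI, age
at menarche, age at menopause) — so the primary exposure's coefficient is
its direct effect on the outcome, adjusted for pathways through the other
traits. The fit is inverse-variance weighted (weights 1/se_outcome^2)
with multiplicative random effects; the Egger extension adds a free
intercept whose deviation from zero tests for directional pleiotropy not
captured by the included traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bwmr.estimators import MREstimate, Z95

__all__ = ["MVInstrumentTable", "mvmr_ivw", "mvmr_egger"]


@dataclass
class MVInstrumentTable:
    """Per-SNP outcome and multi-exposure summary effects, aligned and oriented.

    ``exposure_betas`` is an (L, K) array; column order matches
    ``exposures``, whose first entry is the primary exposure. All rows are
    oriented to the primary exposure-increasing allele.
    """

    snp_ids: list[str]
    exposures: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_betas = np.asarray(self.exposure_betas, dtype=float)
        self.exposure_ses = np.asarray(self.exposure_ses, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        L, K = self.exposure_betas.shape
        if K < 1 or len(self.exposures) != K:
            raise ValueError("exposure names must match exposure beta columns")
        if len(self.snp_ids) != L or self.beta_outcome.shape != (L,) or self.se_outcome.shape != (L,):
            raise ValueError("inconsistent row counts in MVInstrumentTable")
        if np.isnan(self.exposure_betas).any():
            raise ValueError("missing exposure betas are not allowed in MVMR")

    @property
    def n_snps(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]

    def oriented_to_primary(self) -> "MVInstrumentTable":
        """Flip each row's betas jointly so the primary exposure's beta is positive."""
        flip = np.sign(self.exposure_betas[:, 0])
        flip[flip == 0] = 1.0
        return MVInstrumentTable(
            snp_ids=list(self.snp_ids),
            exposures=list(self.exposures),
            exposure_betas=self.exposure_betas * flip[:, None],
            exposure_ses=self.exposure_ses.copy(),
            beta_outcome=self.beta_outcome * flip,
            se_outcome=self.se_outcome.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp": self.snp_ids})
        for k, name in enumerate(self.exposures):
            df[f"beta_{name}"] = self.exposure_betas[:, k]
            df[f"se_{name}"] = self.exposure_ses[:, k]
        df["beta_outcome"] = self.beta_outcome
        df["se_outcome"] = self.se_outcome
        return df


def _check_rank(X: np.ndarray, exposures: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{exposures[i]}~{exposures[j]}"
            for i in range(len(exposures))
            for j in range(i + 1, len(exposures))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(
            "rank-deficient MVMR design; collinear exposure columns: " + (", ".join(pairs) or "unidentified")
        )


def _mv_fit(
    table: MVInstrumentTable,
    intercept: bool,
    random_effects: bool,
) -> list[MREstimate]:
    L, K = table.n_snps, table.n_exposures
    min_rows = K + (2 if intercept else 1)
    if L < min_rows:
        raise ValueError(f"MVMR needs at least {min_rows} SNPs for {K} exposures, got {L}")
    X = table.exposure_betas
    names = list(table.exposures)
    if intercept:
        X = np.column_stack([np.ones(L), X])
        names = ["(intercept)"] + names
    _check_rank(table.exposure_betas, table.exposures)
    w = 1.0 / table.se_outcome**2
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], table.beta_outcome * sw, rcond=None)
    resid = table.beta_outcome - X @ coef
    rss = float(np.sum(w * resid**2))
    df_resid = L - X.shape[1]
    scale = max(1.0, math.sqrt(rss / df_resid)) if random_effects else 1.0
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    ses = scale * np.sqrt(np.diag(cov))

    estimates = []
    for name, b, s in zip(names, coef, ses):
        if intercept:
            p = 2 * stats.t.sf(abs(b) / s, df=df_resid)
        else:
            p = 2 * stats.norm.sf(abs(b) / s)
        method = "MVMR_Egger" if intercept else "MVMR_IVW"
        est = MREstimate(
            method,
            float(b),
            float(s),
            float(p),
            L,
            extras={"exposure": name, "re_scale_factor": scale, "df_resid": df_resid},
        )
        estimates.append(est)
    if intercept:
        inter = estimates.pop(0)
        for est in estimates:
            est.extras["egger_intercept"] = inter.beta
            est.extras["egger_intercept_se"] = inter.se
            est.extras["egger_intercept_p"] = inter.pvalue
    return estimates


def mvmr_ivw(table: MVInstrumentTable, random_effects: bool = True) -> list[MREstimate]:
    """Multivariable IVW: weighted multiple regression of outcome betas on all
    exposure betas with no intercept.

    Returns one estimate per exposure, in the table's exposure order; the
    primary exposure's coefficient (first entry) is the headline estimate.
    With K = 1 this reduces exactly to univariable IVW on the same rows.
    """
    return _mv_fit(table, intercept=False, random_effects=random_effects)


def mvmr_egger(table: MVInstrumentTable, random_effects: bool = True) -> list[MREstimate]:
    """Multivariable MR-Egger: as :func:`mvmr_ivw` with a free intercept.

    Rows are oriented to the primary exposure-increasing allele before
    fitting. The intercept estimate, SE and two-sided p (t with L-K-1 df)
    are attached to every exposure's ``extras``.
    """
    return _mv_fit(table.oriented_to_primary(), intercept=True, random_effects=random_effects)
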