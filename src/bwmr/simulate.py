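"""Synthetic two-sample GWAS summary statistics with known truth.

The generator emulates the birth-weight / breast-cancer setting: a
quantitative exposure measured in one GWAS (standardised, per-allele
effects gamma_j at L independent loci) and a case/control outcome measured
in another. Observed summary statistics are drawn directly at the
summary level:

    se_X_j = 1 / sqrt(2 f_j (1-f_j) n_exposure)
    beta_X_j ~ N(gamma_j, se_X_j^2)
    se_Y_j = sqrt( N / (2 f_j (1-f_j) n_cases n_controls) )
    beta_Y_j ~ N(theta * gamma_j + alpha_j, se_Y_j^2)

where theta is the true causal log-odds per SD and alpha_j a per-SNP
horizontal-pleiotropy effect (zero for valid instruments). Pleiotropy
architectures: ``none``, ``balanced`` (mean-zero), ``directional``
(nonzero mean; InSIDE holds), and ``inside_violating`` (alpha correlated
with gamma). An optional individual-level mode samples genotypes and
phenotypes directly for small-n cross-checks against two-stage least
squares.

By default the latent effects (gamma, maf, alleles) are drawn once per
spec and held fixed across replicates, so replicate-to-replicate variation
isolates sampling noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from bwmr.mvmr import MVInstrumentTable

__all__ = [
    "SyntheticStudySpec",
    "SimulationTruth",
    "generate_two_sample",
    "generate_covariate_table",
    "generate_mv_table",
    "generate_individual_level",
    "summary_stats_from_individual",
]

# non-palindromic allele pairs; harmonisation can always resolve these by letter
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Generative parameters for one synthetic two-sample study.

    Defaults match the scale of the motivating study: 41 independent loci
    jointly explaining 1.3% of a standardised exposure measured in 143,677
    individuals, against an outcome GWAS of 122,977 cases and 105,974
    controls, with a true causal odds ratio of 0.86 per SD.
    """

    n_snps: int = 41
    theta: float = math.log(0.86)
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_beta_range: tuple[float, float] = (0.02, 0.06)
    r2_target: Optional[float] = 0.013
    n_exposure: int = 143_677
    n_cases: int = 122_977
    n_controls: int = 105_974
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    pleio_mean: float = 0.0  # mean pleiotropic effect (directional / inside_violating)
    pleio_sd: float = 0.0  # pleiotropy spread tau
    pleio_corr: float = 0.0  # corr(alpha, gamma) under inside_violating
    n_invalid: int = 0
    flip_fraction: float = 0.3  # outcome rows reported on the swapped allele
    fixed_gamma: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invalid > self.n_snps:
            raise ValueError("n_invalid cannot exceed n_snps")
        if self.pleio_sd < 0:
            raise ValueError("pleio_sd must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")


@dataclass
class SimulationTruth:
    """Latent values behind one generated dataset."""

    theta: float
    snp_ids: list[str]
    maf: list[float]
    gamma: list[float]
    alpha: list[float]
    invalid_ids: list[str]
    r2: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _latent_rng(spec: SyntheticStudySpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0xBEEF])


def _noise_rng(spec: SyntheticStudySpec, rep: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, rep])


def _draw_latents(spec: SyntheticStudySpec, rng: Optional[np.random.Generator] = None):
    rng = rng or _latent_rng(spec)
    L = spec.n_snps
    maf = rng.uniform(*spec.maf_range, size=L)
    gamma = rng.uniform(*spec.exposure_beta_range, size=L)
    if spec.r2_target is not None:
        r2_raw = float(np.sum(2 * maf * (1 - maf) * gamma**2))
        gamma *= math.sqrt(spec.r2_target / r2_raw)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=L)
    invalid = rng.choice(L, size=spec.n_invalid, replace=False) if spec.n_invalid else np.array([], dtype=int)
    snp_ids = [f"rs{100001 + j}" for j in range(L)]
    return maf, gamma, pair_idx, invalid, snp_ids


def _draw_alpha(spec: SyntheticStudySpec, gamma: np.ndarray, invalid: np.ndarray, rng) -> np.ndarray:
    alpha = np.zeros_like(gamma)
    if invalid.size == 0 or spec.pleiotropy == "none":
        return alpha
    g = gamma[invalid]
    if spec.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, spec.pleio_sd, size=invalid.size)
    elif spec.pleiotropy == "directional":
        alpha[invalid] = rng.normal(spec.pleio_mean, spec.pleio_sd, size=invalid.size)
    else:  # inside_violating: alpha correlated with instrument strength
        z = rng.standard_normal(invalid.size)
        g_std = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        rho = spec.pleio_corr
        alpha[invalid] = spec.pleio_mean + spec.pleio_sd * (rho * g_std + math.sqrt(1 - rho**2) * z)
    return alpha


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)


def generate_two_sample(
    spec: SyntheticStudySpec, rep: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (exposure table, outcome table, truth) for one replicate.

    Both tables use the same TSV dialect the readers consume (columns
    ``snp, effect_allele, other_allele, eaf, beta, se, pvalue`` plus
    sample sizes). A ``flip_fraction`` of outcome rows is reported on the
    swapped allele (beta negated, eaf complemented) so harmonisation is
    exercised end to end. Identical ``(spec, rep)`` always produces
    identical tables; with ``fixed_gamma`` (default) the latent effects
    are shared across replicates.
    """
    if spec.fixed_gamma:
        maf, gamma, pair_idx, invalid, snp_ids = _draw_latents(spec)
        rng = _noise_rng(spec, rep)
    else:
        rng = _noise_rng(spec, rep)
        maf, gamma, pair_idx, invalid, snp_ids = _draw_latents(spec, rng)
    alpha = _draw_alpha(spec, gamma, invalid, rng)

    var_g = 2 * maf * (1 - maf)
    se_x = 1.0 / np.sqrt(var_g * spec.n_exposure)
    beta_x = rng.normal(gamma, se_x)
    n_total = spec.n_cases + spec.n_controls
    se_y = np.sqrt(n_total / (var_g * spec.n_cases * spec.n_controls))
    beta_y = rng.normal(spec.theta * gamma + alpha, se_y)

    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    exposure = pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta_x,
            "se": se_x,
            "pvalue": _pvals(beta_x, se_x),
            "n": spec.n_exposure,
        }
    )

    flip = rng.random(spec.n_snps) < spec.flip_fraction
    outcome = pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": np.where(flip, oa, ea),
            "other_allele": np.where(flip, ea, oa),
            "eaf": np.where(flip, 1 - maf, maf),
            "beta": np.where(flip, -beta_y, beta_y),
            "se": se_y,
            "pvalue": _pvals(beta_y, se_y),
            "n_cases": spec.n_cases,
            "n_controls": spec.n_controls,
        }
    )

    truth = SimulationTruth(
        theta=spec.theta,
        snp_ids=snp_ids,
        maf=maf.tolist(),
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        invalid_ids=[snp_ids[j] for j in invalid],
        r2=float(np.sum(var_g * gamma**2)),
    )
    return exposure, outcome, truth


def generate_covariate_table(
    spec: SyntheticStudySpec,
    gamma_cov: np.ndarray,
    n_cov: int,
    trait_seed: int = 1,
    rep: int = 0,
) -> pd.DataFrame:
    """Generate a covariate-trait GWAS sharing the exposure study's loci.

    Uses the same latent SNPs (ids, alleles, frequencies) as
    :func:`generate_two_sample` on the same spec, with the covariate's own
    true per-SNP effects ``gamma_cov`` and sample size ``n_cov``, so the
    resulting table harmonises against the exposure like a real co-measured
    trait. ``trait_seed`` separates the noise streams of different traits.
    """
    maf, _, pair_idx, _, snp_ids = _draw_latents(spec)
    gamma_cov = np.asarray(gamma_cov, dtype=float)
    if gamma_cov.shape != (spec.n_snps,):
        raise ValueError(f"gamma_cov must have length {spec.n_snps}")
    rng = np.random.default_rng([spec.seed, 0xC0FFEE, trait_seed, rep])
    var_g = 2 * maf * (1 - maf)
    se = 1.0 / np.sqrt(var_g * n_cov)
    beta = rng.normal(gamma_cov, se)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    return pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": _pvals(beta, se),
            "n": n_cov,
        }
    )


def generate_mv_table(
    spec: SyntheticStudySpec,
    covariate_gammas: Mapping[str, np.ndarray],
    covariate_thetas: Mapping[str, float],
    covariate_n: Optional[Mapping[str, int]] = None,
    rep: int = 0,
) -> tuple[MVInstrumentTable, SimulationTruth]:
    """Generate a multivariable instrument table with known coefficients.

    ``covariate_gammas`` gives each covariate trait's true per-SNP effects
    (length n_snps); ``covariate_thetas`` their true direct effects on the
    outcome. The outcome betas follow the multivariable linear model

        beta_Y_j ~ N(theta*gamma_j + sum_k theta_k*gamma_kj + alpha_j, se_Y_j^2)

    and each trait's observed betas get their own GWAS noise (sample size
    from ``covariate_n``, default the exposure's). The primary exposure is
    the first column of the returned table.
    """
    if spec.fixed_gamma:
        maf, gamma, _, invalid, snp_ids = _draw_latents(spec)
        rng = _noise_rng(spec, rep)
    else:
        rng = _noise_rng(spec, rep)
        maf, gamma, _, invalid, snp_ids = _draw_latents(spec, rng)
    alpha = _draw_alpha(spec, gamma, invalid, rng)
    covariate_n = covariate_n or {}

    var_g = 2 * maf * (1 - maf)
    names = ["exposure"] + list(covariate_gammas)
    betas = [rng.normal(gamma, 1.0 / np.sqrt(var_g * spec.n_exposure))]
    ses = [1.0 / np.sqrt(var_g * spec.n_exposure)]
    mean_y = spec.theta * gamma + alpha
    for trait, g_k in covariate_gammas.items():
        g_k = np.asarray(g_k, dtype=float)
        if g_k.shape != gamma.shape:
            raise ValueError(f"covariate {trait!r}: expected {gamma.shape[0]} per-SNP effects")
        n_k = covariate_n.get(trait, spec.n_exposure)
        se_k = 1.0 / np.sqrt(var_g * n_k)
        betas.append(rng.normal(g_k, se_k))
        ses.append(se_k)
        mean_y = mean_y + covariate_thetas.get(trait, 0.0) * g_k

    n_total = spec.n_cases + spec.n_controls
    se_y = np.sqrt(n_total / (var_g * spec.n_cases * spec.n_controls))
    beta_y = rng.normal(mean_y, se_y)

    table = MVInstrumentTable(
        snp_ids=snp_ids,
        exposures=names,
        exposure_betas=np.column_stack(betas),
        exposure_ses=np.column_stack(ses),
        beta_outcome=beta_y,
        se_outcome=se_y,
    )
    truth = SimulationTruth(
        theta=spec.theta,
        snp_ids=snp_ids,
        maf=maf.tolist(),
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        invalid_ids=[snp_ids[j] for j in invalid],
        r2=float(np.sum(var_g * gamma**2)),
    )
    return table, truth


def generate_individual_level(
    spec: SyntheticStudySpec,
    n_individuals: int,
    rep: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SimulationTruth]:
    """Slow exactness check: sample genotypes and phenotypes directly.

    Genotypes g_j ~ Binomial(2, f_j); exposure x = sum gamma_j g_j + e with
    e scaled so Var(x) = 1; continuous outcome y = theta * x + noise with
    Var(y) = 1. Returns (genotype matrix, exposure, outcome, truth). Meant
    for small n where summary statistics can be recomputed by per-SNP
    regression and compared against two-stage least squares.
    """
    maf, gamma, _, invalid, snp_ids = _draw_latents(spec)
    rng = _noise_rng(spec, rep + 7_000_000)
    G = rng.binomial(2, maf, size=(n_individuals, spec.n_snps)).astype(float)
    var_genetic = float(np.sum(2 * maf * (1 - maf) * gamma**2))
    x = G @ gamma + rng.normal(0.0, math.sqrt(max(1e-12, 1 - var_genetic)), size=n_individuals)
    resid_var = max(1e-12, 1 - spec.theta**2)
    y = spec.theta * x + rng.normal(0.0, math.sqrt(resid_var), size=n_individuals)
    truth = SimulationTruth(
        theta=spec.theta,
        snp_ids=snp_ids,
        maf=maf.tolist(),
        gamma=gamma.tolist(),
        alpha=[0.0] * spec.n_snps,
        invalid_ids=[snp_ids[j] for j in invalid],
        r2=var_genetic,
    )
    return G, x, y, truth


def summary_stats_from_individual(G: np.ndarray, phenotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression betas and SEs of a phenotype on each genotype."""
    n = G.shape[0]
    gc = G - G.mean(axis=0)
    pc = phenotype - phenotype.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = gc.T @ pc / sxx
    resid_ss = np.sum(pc**2) - beta**2 * sxx
    se = np.sqrt(resid_ss / (n - 2) / sxx)
    return beta, se
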