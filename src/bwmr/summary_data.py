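"""Reading, validation and harmonisation of GWAS summary statistics.

Two-sample MR works entirely from per-SNP summary associations: an effect
size (beta) for the effect allele, its standard error, p-value, allele
frequency and sample size, reported separately for the exposure and the
outcome (and, here, for up to seven covariate traits used in pleiotropy
filtering). Before any estimation the records must be *harmonised*: the
outcome and covariate effects are expressed for the same allele as the
exposure effect, and every record is oriented to the exposure-increasing
allele so that all exposure betas are positive.

Loci absent from a dataset may be represented by a proxy SNP in strong
linkage disequilibrium (r^2 above a configurable threshold) with the lead
SNP; proxy substitutions are recorded as provenance on the harmonised
record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("bwmr.summary_data")

__all__ = [
    "SummaryAssociation",
    "HarmonisedInstrument",
    "ProxyMap",
    "AlleleMismatchError",
    "NullInstrumentError",
    "read_summary_table",
    "write_summary_table",
    "align_alleles",
    "orient_to_exposure_increasing",
    "substitute_proxies",
    "harmonise",
    "write_instruments",
    "read_instruments",
    "COLUMN_ALIASES",
]


class AlleleMismatchError(ValueError):
    """Raised when two records for the same SNP have irreconcilable alleles."""


class NullInstrumentError(ValueError):
    """Raised when an instrument has a zero exposure effect (undefined Wald ratio)."""


#: Recognised header synonyms for each canonical summary-statistic column.
#: Matching is case-insensitive after stripping non-alphanumeric characters.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "snpid", "rsid", "rs", "markername", "variant", "variantid", "id"),
    "effect_allele": ("effectallele", "ea", "a1", "allele1", "testedallele", "riskallele"),
    "other_allele": ("otherallele", "oa", "a2", "allele2", "nonEffectallele", "noneffectallele", "refallele"),
    "eaf": ("eaf", "effectallelefreq", "effectallelefrequency", "freq", "af", "maf", "freq1"),
    "beta": ("beta", "effect", "b", "betacoefficient", "logor"),
    "se": ("se", "stderr", "standarderror", "sebeta"),
    "pvalue": ("pvalue", "p", "pval", "pvalues"),
    "n": ("n", "samplesize", "nsamples", "ntotal"),
    "n_cases": ("ncases", "ncase", "cases"),
    "n_controls": ("ncontrols", "ncontrol", "controls"),
    "info": ("info", "imputationquality", "impquality", "rsq"),
}

_REQUIRED = ("snp", "effect_allele", "other_allele", "beta", "se", "pvalue")

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: in SD units for
    quantitative traits, log-odds for binary traits. ``n`` is the analysis
    sample size; case/control studies may carry ``n_cases``/``n_controls``
    instead (or additionally).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    n_cases: Optional[float] = None
    n_controls: Optional[float] = None
    info: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0,1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) single-base SNPs."""
        pair = {self.effect_allele, self.other_allele}
        return pair in ({"A", "T"}, {"C", "G"})

    def pvalue_consistent(self, log10_tol: float = 0.5) -> bool:
        """Check p against the two-sided normal approximation from beta/se.

        Consistency means the reported p and the Wald-z p agree within
        ``log10_tol`` decades. Summary files sometimes report p-values from
        a different test than the Wald z; inconsistency is a validation
        warning for callers, never an error.
        """
        p_expect = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        if p_expect <= 0:
            return self.pvalue < 1e-300
        return abs(math.log10(self.pvalue) - math.log10(p_expect)) <= log10_tol


@dataclass
class HarmonisedInstrument:
    """One SNP's paired exposure/outcome (and covariate) effects after alignment.

    All betas refer to the same allele, oriented so that ``beta_exposure``
    is positive (the exposure-increasing allele). ``covariate_betas`` maps
    trait name to (beta, se) for traits with full summary statistics;
    ``covariate_pvalues`` maps trait name to p for every tested trait,
    including p-value-only traits.
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: Optional[float] = None
    proxy_of: Optional[str] = None
    proxy_r2: Optional[float] = None
    covariate_betas: dict[str, tuple[float, float]] = field(default_factory=dict)
    covariate_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def wald_ratio(self) -> float:
        """Per-SNP causal estimate beta_outcome / beta_exposure."""
        return self.beta_outcome / self.beta_exposure

    @property
    def wald_se(self) -> float:
        """First-order SE of the Wald ratio: se_outcome / |beta_exposure|."""
        return self.se_outcome / abs(self.beta_exposure)

    @property
    def wald_se_second_order(self) -> float:
        """Delta-rule SE including exposure-side uncertainty."""
        r = self.wald_ratio
        bx = self.beta_exposure
        return math.sqrt(self.se_outcome**2 / bx**2 + r**2 * self.se_exposure**2 / bx**2)


@dataclass(frozen=True)
class ProxyMap:
    """Lead SNP -> (proxy SNP, r^2) lookup for loci absent from a dataset."""

    entries: Mapping[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for lead, (proxy, r2) in self.entries.items():
            if not (0 < r2 <= 1):
                raise ValueError(f"proxy for {lead}: r2 must be in (0,1], got {r2}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t")
        return cls({row.lead_snp: (row.proxy_snp, float(row.r2)) for row in df.itertuples()})

    def lookup(self, lead: str) -> Optional[tuple[str, float]]:
        return self.entries.get(lead)


def _canonical(name: str) -> Optional[str]:
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    for canon, aliases in COLUMN_ALIASES.items():
        if key == canon or key in (a.lower() for a in aliases):
            return canon
    return None


def read_summary_table(path: str | Path, trait_kind: str = "quantitative") -> list[SummaryAssociation]:
    """Read a tab-separated GWAS summary-statistics file.

    Column headers are resolved through :data:`COLUMN_ALIASES` (case- and
    punctuation-insensitive), so files from different consortia load without
    renaming. Rows with missing beta or se are dropped and the count logged.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    trait_kind:
        ``"quantitative"`` or ``"binary"``; binary traits may carry
        case/control counts instead of a single ``n``.
    """
    if trait_kind not in ("quantitative", "binary"):
        raise ValueError(f"trait_kind must be 'quantitative' or 'binary', got {trait_kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise OSError(f"cannot read summary table {path}: {exc}") from exc

    rename = {}
    for col in df.columns:
        canon = _canonical(str(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    df = df.rename(columns=rename)

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: required column(s) not found: {', '.join(missing)}")

    records: list[SummaryAssociation] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        beta = _to_float(row.get("beta"))
        se = _to_float(row.get("se"))
        if beta is None or se is None:
            n_dropped += 1
            continue
        records.append(
            SummaryAssociation(
                snp_id=str(row["snp"]).strip(),
                effect_allele=str(row["effect_allele"]).strip().upper(),
                other_allele=str(row["other_allele"]).strip().upper(),
                beta=beta,
                se=se,
                pvalue=_to_float(row.get("pvalue")) or min(1.0, 2 * stats.norm.sf(abs(beta) / se)),
                eaf=_to_float(row.get("eaf")),
                n=_to_float(row.get("n")),
                n_cases=_to_float(row.get("n_cases")),
                n_controls=_to_float(row.get("n_controls")),
                info=_to_float(row.get("info")),
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing beta or se", path, n_dropped)
    return records


def write_summary_table(records: Iterable[SummaryAssociation], path: str | Path) -> None:
    """Write records in the same TSV dialect :func:`read_summary_table` consumes."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _to_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.upper() in ("NA", "NAN", "NULL", "."):
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    return None if math.isnan(v) else v


def align_alleles(exposure: SummaryAssociation, outcome: SummaryAssociation) -> SummaryAssociation:
    """Express ``outcome`` on the same effect allele as ``exposure``.

    If the outcome's effect allele equals the exposure's other allele the
    outcome beta sign is flipped and its eaf replaced by 1 - eaf; if the
    allele pairs are irreconcilable an :class:`AlleleMismatchError` is
    raised (callers exclude the pair with reason ``"allele_mismatch"``).

    Alignment is by allele letters alone; strand-ambiguous SNPs in curated
    lead-SNP tables are assumed pre-matched (see :func:`harmonise` for the
    optional strict palindrome filter).
    """
    ea, oa = exposure.effect_allele, exposure.other_allele
    if (outcome.effect_allele, outcome.other_allele) == (ea, oa):
        return outcome
    if (outcome.effect_allele, outcome.other_allele) == (oa, ea):
        return replace(
            outcome,
            effect_allele=ea,
            other_allele=oa,
            beta=-outcome.beta,
            eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
        )
    raise AlleleMismatchError(
        f"{exposure.snp_id}: alleles {outcome.effect_allele}/{outcome.other_allele} "
        f"irreconcilable with {ea}/{oa}"
    )


def orient_to_exposure_increasing(record: HarmonisedInstrument) -> HarmonisedInstrument:
    """Flip all betas jointly so the exposure beta is positive.

    The Wald ratio is unchanged by construction. A zero exposure beta has
    no defined orientation (and no defined ratio) and raises
    :class:`NullInstrumentError`.
    """
    if record.beta_exposure == 0:
        raise NullInstrumentError(f"{record.snp_id}: null_instrument")
    if record.beta_exposure > 0:
        return record
    return HarmonisedInstrument(
        snp_id=record.snp_id,
        beta_exposure=-record.beta_exposure,
        se_exposure=record.se_exposure,
        beta_outcome=-record.beta_outcome,
        se_outcome=record.se_outcome,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
        proxy_of=record.proxy_of,
        proxy_r2=record.proxy_r2,
        covariate_betas={t: (-b, s) for t, (b, s) in record.covariate_betas.items()},
        covariate_pvalues=dict(record.covariate_pvalues),
    )


def substitute_proxies(
    lead_ids: Sequence[str],
    available: Mapping[str, SummaryAssociation],
    proxy_map: Optional[ProxyMap],
    min_r2: float = 0.6,
) -> tuple[dict[str, tuple[SummaryAssociation, Optional[str], Optional[float]]], list[str]]:
    """Resolve each lead SNP in one dataset, falling back to qualifying proxies.

    Returns ``(resolved, unmatched)`` where ``resolved`` maps each lead id to
    ``(record, proxy_id_or_None, r2_or_None)`` and ``unmatched`` lists leads
    with neither a direct record nor a proxy with r^2 > ``min_r2`` present.
    Unmatched leads are a reported outcome, not an error.
    """
    if not (0 < min_r2 <= 1):
        raise ValueError(f"min_r2 must be in (0,1], got {min_r2}")
    resolved: dict[str, tuple[SummaryAssociation, Optional[str], Optional[float]]] = {}
    unmatched: list[str] = []
    for lead in lead_ids:
        if lead in available:
            resolved[lead] = (available[lead], None, None)
            continue
        hit = proxy_map.lookup(lead) if proxy_map is not None else None
        if hit is not None:
            proxy_id, r2 = hit
            if r2 > min_r2 and proxy_id in available:
                resolved[lead] = (available[proxy_id], proxy_id, r2)
                continue
        unmatched.append(lead)
    return resolved, unmatched


def harmonise(
    exposure_records: Sequence[SummaryAssociation],
    outcome_records: Sequence[SummaryAssociation],
    covariates: Optional[Mapping[str, Sequence[SummaryAssociation]]] = None,
    pvalue_only_traits: Sequence[str] = (),
    proxy_map: Optional[ProxyMap] = None,
    min_r2: float = 0.6,
    require_all_covariates: bool = False,
    strict_palindromic: bool = False,
    min_info: Optional[float] = None,
) -> tuple[list[HarmonisedInstrument], list[tuple[str, str]]]:
    """Build oriented two-sample instrument records from raw summary tables.

    For every exposure lead SNP, resolve the outcome (and each covariate
    trait) either directly or through a proxy with r^2 > ``min_r2``, align
    alleles to the exposure's effect allele, and orient the whole record to
    the exposure-increasing allele.

    Parameters
    ----------
    require_all_covariates:
        When True, loci not represented (directly or by proxy) in every
        covariate dataset are excluded with reason ``"unrepresented"`` —
        this is how a candidate pool restricted to loci testable against
        all covariate traits is built.
    strict_palindromic:
        When True, drop strand-ambiguous (A/T, C/G) SNPs whose exposure eaf
        lies in [0.42, 0.58], where allele-letter alignment cannot resolve
        strand. Off by default: curated lead-SNP tables are pre-matched.
    min_info:
        Optional imputation-quality floor; default no filtering.

    Returns
    -------
    (instruments, exclusions):
        exclusions is a list of ``(snp_id, reason)`` pairs.
    """
    covariates = covariates or {}
    exclusions: list[tuple[str, str]] = []
    out_by_id = {r.snp_id: r for r in outcome_records}
    cov_by_id = {trait: {r.snp_id: r for r in recs} for trait, recs in covariates.items()}

    lead_ids = [r.snp_id for r in exposure_records]
    out_resolved, out_unmatched = substitute_proxies(lead_ids, out_by_id, proxy_map, min_r2)

    instruments: list[HarmonisedInstrument] = []
    for exp in exposure_records:
        if exp.beta == 0:
            exclusions.append((exp.snp_id, "null_instrument"))
            continue
        if strict_palindromic and exp.is_palindromic and exp.eaf is not None and 0.42 <= exp.eaf <= 0.58:
            exclusions.append((exp.snp_id, "palindromic_ambiguous"))
            continue
        if exp.snp_id in out_unmatched:
            exclusions.append((exp.snp_id, "missing_outcome"))
            continue
        out_rec, proxy_id, proxy_r2 = out_resolved[exp.snp_id]
        if min_info is not None and out_rec.info is not None and out_rec.info < min_info:
            exclusions.append((exp.snp_id, "low_imputation_quality"))
            continue
        try:
            if proxy_id is None:
                out_aligned = align_alleles(exp, out_rec)
            else:
                # A proxy carries its own allele pair; its effect allele is
                # taken as reported (the proxy map is assumed phase-matched,
                # as in curated lead/proxy tables).
                out_aligned = out_rec
        except AlleleMismatchError:
            exclusions.append((exp.snp_id, "allele_mismatch"))
            continue

        cov_betas: dict[str, tuple[float, float]] = {}
        cov_pvalues: dict[str, float] = {}
        unrepresented = False
        for trait, table in cov_by_id.items():
            resolved, unmatched = substitute_proxies([exp.snp_id], table, proxy_map, min_r2)
            if unmatched:
                if require_all_covariates:
                    unrepresented = True
                    break
                continue
            cov_rec, cov_proxy, _ = resolved[exp.snp_id]
            if cov_proxy is None:
                try:
                    cov_rec = align_alleles(exp, cov_rec)
                except AlleleMismatchError:
                    exclusions.append((exp.snp_id, f"allele_mismatch_covariate:{trait}"))
                    continue
            cov_pvalues[trait] = cov_rec.pvalue
            if trait not in pvalue_only_traits:
                cov_betas[trait] = (cov_rec.beta, cov_rec.se)
        if unrepresented:
            exclusions.append((exp.snp_id, "unrepresented"))
            continue

        record = HarmonisedInstrument(
            snp_id=exp.snp_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=out_aligned.beta,
            se_outcome=out_aligned.se,
            eaf=exp.eaf,
            proxy_of=exp.snp_id if proxy_id is not None else None,
            proxy_r2=proxy_r2,
            covariate_betas=cov_betas,
            covariate_pvalues=cov_pvalues,
        )
        if proxy_id is not None:
            record.snp_id = proxy_id
        instruments.append(orient_to_exposure_increasing(record))

    return instruments, exclusions


_INSTRUMENT_COLUMNS = [
    "snp",
    "proxy_of",
    "proxy_r2",
    "eaf",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "wald_ratio",
    "wald_se",
]


def write_instruments(instruments: Iterable[HarmonisedInstrument], path: str | Path) -> None:
    """Serialise harmonised instruments to TSV with a fixed column order.

    Covariate betas/p-values are flattened into ``beta_<trait>``,
    ``se_<trait>`` and ``p_<trait>`` columns after the fixed columns.
    """
    rows = []
    for ins in instruments:
        row = {
            "snp": ins.snp_id,
            "proxy_of": ins.proxy_of if ins.proxy_of is not None else "",
            "proxy_r2": ins.proxy_r2 if ins.proxy_r2 is not None else "",
            "eaf": ins.eaf if ins.eaf is not None else "",
            "beta_exposure": ins.beta_exposure,
            "se_exposure": ins.se_exposure,
            "beta_outcome": ins.beta_outcome,
            "se_outcome": ins.se_outcome,
            "wald_ratio": ins.wald_ratio,
            "wald_se": ins.wald_se,
        }
        for trait, (b, s) in ins.covariate_betas.items():
            row[f"beta_{trait}"] = b
            row[f"se_{trait}"] = s
        for trait, p in ins.covariate_pvalues.items():
            row[f"p_{trait}"] = p
        rows.append(row)
    df = pd.DataFrame(rows)
    fixed = [c for c in _INSTRUMENT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in fixed]
    df[fixed + sorted(extra)].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_instruments(path: str | Path) -> list[HarmonisedInstrument]:
    """Read back a TSV written by :func:`write_instruments`."""
    df = pd.read_csv(path, sep="\t")
    instruments = []
    cov_beta_traits = sorted(c[5:] for c in df.columns if c.startswith("beta_") and c not in ("beta_exposure", "beta_outcome"))
    cov_p_traits = sorted(c[2:] for c in df.columns if c.startswith("p_"))
    for row in df.itertuples(index=False):
        d = row._asdict()
        cov_betas = {}
        for trait in cov_beta_traits:
            b, s = d.get(f"beta_{trait}"), d.get(f"se_{trait}")
            if b is not None and not pd.isna(b):
                cov_betas[trait] = (float(b), float(s))
        cov_p = {}
        for trait in cov_p_traits:
            p = d.get(f"p_{trait}")
            if p is not None and not pd.isna(p):
                cov_p[trait] = float(p)
        instruments.append(
            HarmonisedInstrument(
                snp_id=str(d["snp"]),
                beta_exposure=float(d["beta_exposure"]),
                se_exposure=float(d["se_exposure"]),
                beta_outcome=float(d["beta_outcome"]),
                se_outcome=float(d["se_outcome"]),
                eaf=None if pd.isna(d.get("eaf")) else float(d["eaf"]),
                proxy_of=None if pd.isna(d.get("proxy_of")) else str(d["proxy_of"]) or None,
                proxy_r2=None if pd.isna(d.get("proxy_r2")) else float(d["proxy_r2"]),
                covariate_betas=cov_betas,
                covariate_pvalues=cov_p,
            )
        )
    return instruments
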