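"""Construction of named instrument sets under pleiotropy filters.

An instrumental variable (IV) for MR is a set of independent SNPs robustly
associated with the exposure. Because a SNP associated with another risk
factor for the outcome can act through that factor rather than the
exposure (horizontal pleiotropy), candidate loci are screened against a
panel of covariate traits: a SNP is removed when its association p-value
with any covariate trait falls below a chosen threshold — genome-wide
significance (5e-8) for the main set, or a Bonferroni-corrected level for
a stricter set. Every removal is logged with the offending trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from bwmr.summary_data import HarmonisedInstrument, NullInstrumentError

__all__ = ["InstrumentSet", "FilterRecord", "bonferroni_threshold", "filter_pleiotropic", "wald_ratio"]


@dataclass(frozen=True)
class FilterRecord:
    """One filtering decision: what happened to a SNP and why."""

    snp_id: str
    trait: Optional[str]
    pvalue: Optional[float]
    threshold: Optional[float]
    action: str  # "removed" | "retained" | "not_tested"


@dataclass
class InstrumentSet:
    """A named collection of harmonised instruments with filter provenance."""

    name: str
    instruments: list[HarmonisedInstrument]
    filter_log: list[FilterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ValueError(f"instrument set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [ins.snp_id for ins in self.instruments]

    def subset(self, snp_ids: Iterable[str], name: Optional[str] = None) -> "InstrumentSet":
        keep = set(snp_ids)
        return InstrumentSet(
            name=name or self.name,
            instruments=[ins for ins in self.instruments if ins.snp_id in keep],
            filter_log=list(self.filter_log),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_exposure": [i.beta_exposure for i in self.instruments],
                "se_exposure": [i.se_exposure for i in self.instruments],
                "beta_outcome": [i.beta_outcome for i in self.instruments],
                "se_outcome": [i.se_outcome for i in self.instruments],
                "wald_ratio": [i.wald_ratio for i in self.instruments],
                "wald_se": [i.wald_se for i in self.instruments],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_filter_log(self, path: str | Path) -> None:
        pd.DataFrame([vars(r) for r in self.filter_log]).to_csv(path, sep="\t", index=False)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level controlling family-wise error over m tests."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def filter_pleiotropic(
    candidates: InstrumentSet,
    p_threshold: float,
    name: Optional[str] = None,
) -> InstrumentSet:
    """Remove candidate SNPs associated with any covariate trait below ``p_threshold``.

    Covariate p-values are read from each instrument's ``covariate_pvalues``
    (populated at harmonisation). A trait with no p-value for a SNP counts
    as not tested: the SNP passes for that trait and the gap is logged.

    Raises ``ValueError`` if nothing survives — an empty instrument set
    cannot support MR.
    """
    kept: list[HarmonisedInstrument] = []
    log: list[FilterRecord] = list(candidates.filter_log)
    all_traits = sorted({t for ins in candidates for t in ins.covariate_pvalues})
    for ins in candidates:
        offending = None
        for trait in all_traits:
            p = ins.covariate_pvalues.get(trait)
            if p is None:
                log.append(FilterRecord(ins.snp_id, trait, None, p_threshold, "not_tested"))
                continue
            if p < p_threshold and (offending is None or p < offending[1]):
                offending = (trait, p)
        if offending is not None:
            log.append(FilterRecord(ins.snp_id, offending[0], offending[1], p_threshold, "removed"))
        else:
            log.append(FilterRecord(ins.snp_id, None, None, p_threshold, "retained"))
            kept.append(ins)
    if not kept:
        raise ValueError(
            f"pleiotropy filter at p<{p_threshold:g} removed every candidate; cannot build an instrument"
        )
    return InstrumentSet(name=name or f"{candidates.name}_p{p_threshold:g}", instruments=kept, filter_log=log)


def wald_ratio(instrument: HarmonisedInstrument, second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate and SE.

    estimate = beta_outcome / beta_exposure; the default SE is the
    first-order delta rule se_outcome / |beta_exposure| (exposure-side
    uncertainty ignored, matching inverse-variance weights defined by the
    outcome variance). ``second_order=True`` adds the exposure-side term.
    """
    if instrument.beta_exposure == 0:
        raise NullInstrumentError(f"{instrument.snp_id}: null_instrument")
    est = instrument.beta_outcome / instrument.beta_exposure
    se = instrument.wald_se_second_order if second_order else instrument.wald_se
    return est, se
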