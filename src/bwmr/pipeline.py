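"""End-to-end orchestration: harmonise -> select -> estimate -> diagnose -> MVMR -> power.

One :class:`RunConfig` (loadable from YAML) drives the whole reanalysis
and every threshold defaults to the study's settings: genome-wide
significance 5e-8 for the main pleiotropy filter, Bonferroni alpha 0.05
over the candidate loci for the strict filter, proxy r^2 floors 0.6
(univariable) and 0.8 (MVMR), stepwise alpha 0.05, Cook's threshold 4/L
and studentised threshold 2. The run is deterministic given the config
(all seeds are in the config and logged), and every instrument-set
membership decision is written to a provenance log from which the sets
can be reconstructed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from bwmr import diagnostics as diag
from bwmr import estimators
from bwmr.instruments import InstrumentSet, bonferroni_threshold, filter_pleiotropic
from bwmr.mvmr import MVInstrumentTable, mvmr_egger, mvmr_ivw
from bwmr.power import PowerSpec, binary_outcome_power, f_statistic, variance_explained_pn
from bwmr.summary_data import ProxyMap, harmonise, read_summary_table, write_instruments

logger = logging.getLogger("bwmr.pipeline")

__all__ = ["RunConfig", "run_pipeline", "enrichment_count"]

_ALL_METHODS = ("ivw", "mr_egger", "weighted_median", "weighted_mode", "ivw_penalised_robust")


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one full reanalysis run."""

    exposure_path: str
    outcome_paths: dict[str, str]
    covariate_paths: dict[str, str] = field(default_factory=dict)
    pvalue_only_traits: list[str] = field(default_factory=list)
    proxy_map_path: Optional[str] = None
    output_dir: str = "results/pipeline"

    gw_significance: float = 5e-8
    bonferroni_alpha: float = 0.05
    proxy_r2_univariable: float = 0.6
    proxy_r2_mvmr: float = 0.8
    stepwise_alpha: float = 0.05
    studentised_threshold: float = 2.0
    enrichment_alpha: float = 0.05
    power_or_values: list[float] = field(default_factory=lambda: [1.06, 1.11])

    methods: list[str] = field(default_factory=lambda: list(_ALL_METHODS))
    n_boot: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("config error: empty method list")
        unknown = [m for m in self.methods if m not in _ALL_METHODS]
        if unknown:
            raise ValueError(f"config error: unknown method(s) {unknown}")
        for name, bounds in (
            ("gw_significance", (0, 1)),
            ("bonferroni_alpha", (0, 1)),
            ("stepwise_alpha", (0, 1)),
            ("enrichment_alpha", (0, 1)),
        ):
            v = getattr(self, name)
            if not (bounds[0] < v < bounds[1]):
                raise ValueError(f"config error: {name}={v} outside {bounds}")
        for name in ("proxy_r2_univariable", "proxy_r2_mvmr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"config error: {name}={v} outside (0,1]")
        paths = [self.exposure_path, *self.outcome_paths.values(), *self.covariate_paths.values()]
        if self.proxy_map_path:
            paths.append(self.proxy_map_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config error: missing input file(s): {missing}")


def enrichment_count(p_values, alpha: float = 0.05) -> tuple[int, float, float]:
    """Observed vs chance-expected associations below ``alpha``.

    Returns (observed count, expected count = alpha * m, fold enrichment).
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0,1]")
    observed = int(np.sum(p < alpha))
    expected = alpha * p.size
    return observed, expected, observed / expected


class _Provenance:
    """Structured one-record-per-decision run log."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def log(self, stage: str, **kv) -> None:
        self.records.append({"stage": stage, **kv})

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full reanalysis described by ``config``.

    For every outcome: harmonise, build the full / main / strict instrument
    sets, run the configured estimators, diagnose heterogeneity and
    influence, rerun IVW on the pruned set, fit MVMR when covariate betas
    are available, and report instrument strength, power and the
    SNP-outcome enrichment count. Returns the results bundle (also written
    under ``config.output_dir``): ``estimates`` is one row per
    (iv_set, method, outcome) — the machine-readable analogue of a forest
    plot.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _Provenance()
    prov.log("config", **{k: v for k, v in asdict(config).items()})

    proxy_map = ProxyMap.from_tsv(config.proxy_map_path) if config.proxy_map_path else None
    read = _stage("read")(read_summary_table)
    exposure = read(config.exposure_path, "quantitative")
    covariates = {t: read(p, "quantitative") for t, p in config.covariate_paths.items()}

    estimate_rows: list[dict] = []
    diagnostics_bundle: dict[str, dict] = {}
    power_rows: list[dict] = []
    enrichment: dict[str, dict] = {}
    instrument_sets: dict[str, InstrumentSet] = {}

    for outcome_name, outcome_path in config.outcome_paths.items():
        outcome = read(outcome_path, "binary")

        instruments, exclusions = _stage("harmonise")(harmonise)(
            exposure,
            outcome,
            covariates=covariates,
            pvalue_only_traits=config.pvalue_only_traits,
            proxy_map=proxy_map,
            min_r2=config.proxy_r2_univariable,
        )
        for snp, reason in exclusions:
            prov.log("harmonise", outcome=outcome_name, snp=snp, action="excluded", reason=reason)
        for ins in instruments:
            if ins.proxy_of:
                prov.log(
                    "harmonise",
                    outcome=outcome_name,
                    snp=ins.snp_id,
                    action="proxy_substituted",
                    lead=ins.proxy_of,
                    r2=ins.proxy_r2,
                )

        full = InstrumentSet(f"full_{outcome_name}", instruments)
        n_candidates = len(full)
        main = _stage("select")(filter_pleiotropic)(full, config.gw_significance, name=f"main_{outcome_name}")
        strict_threshold = bonferroni_threshold(config.bonferroni_alpha, n_candidates)
        strict = _stage("select")(filter_pleiotropic)(full, strict_threshold, name=f"strict_{outcome_name}")
        for s in (full, main, strict):
            instrument_sets[s.name] = s
            prov.log("select", set=s.name, outcome=outcome_name, snps=s.snp_ids)
            write_instruments(s.instruments, outdir / f"instruments_{s.name}.tsv")
        for rec in main.filter_log + strict.filter_log:
            prov.log("filter", outcome=outcome_name, **vars(rec))

        run_estimators = _stage("estimate")(estimators.estimate_all)
        for est in run_estimators(main, config.methods, n_boot=config.n_boot, seed=config.seed):
            estimate_rows.append({"iv_set": main.name, "outcome": outcome_name, **est.as_dict()})
        for extra_set in (full, strict):
            est = estimators.ivw(extra_set)
            estimate_rows.append({"iv_set": extra_set.name, "outcome": outcome_name, **est.as_dict()})

        report = _stage("diagnose")(diag.cochran_q)(main)
        report.flagged["cooks"] = diag.cooks_influence(main)
        report.flagged["studentised"] = diag.studentised_outliers(main, config.studentised_threshold)
        loo = diag.leave_one_out(main)
        full_est = loo[-1].beta
        loo_dev = {row.extras["omitted"]: abs(row.beta - full_est) for row in loo[:-1]}
        try:
            pruned, removed = diag.stepwise_q_prune(main, alpha=config.stepwise_alpha)
            report.flagged["stepwise"] = set(removed)
            pruned_est = estimators.ivw(pruned)
            pruned_q = diag.cochran_q(pruned)
            estimate_rows.append(
                {
                    "iv_set": f"pruned_{outcome_name}",
                    "outcome": outcome_name,
                    **pruned_est.as_dict(),
                    "q": pruned_q.q,
                    "q_pvalue": pruned_q.pvalue,
                }
            )
            instrument_sets[f"pruned_{outcome_name}"] = pruned
            prov.log("diagnose", set=f"pruned_{outcome_name}", outcome=outcome_name, removed=removed)
        except RuntimeError as exc:
            prov.log("diagnose", outcome=outcome_name, warning=str(exc))
        diagnostics_bundle[outcome_name] = report.as_dict()
        pd.DataFrame(
            [{"omitted": r.extras["omitted"], **{k: v for k, v in r.as_dict().items() if k != "method"}} for r in loo]
        ).to_csv(outdir / f"leave_one_out_{outcome_name}.tsv", sep="\t", index=False)
        diagnostics_bundle[outcome_name]["leave_one_out_max_dev_snp"] = (
            max(loo_dev, key=loo_dev.get) if loo_dev else None
        )

        beta_traits = sorted(
            {t for ins in full for t in ins.covariate_betas}
        )
        if beta_traits:
            mv_rows = [
                ins
                for ins in full
                if all(t in ins.covariate_betas for t in beta_traits)
                and (ins.proxy_r2 is None or ins.proxy_r2 > config.proxy_r2_mvmr)
            ]
            if len(mv_rows) >= len(beta_traits) + 3:
                table = MVInstrumentTable(
                    snp_ids=[i.snp_id for i in mv_rows],
                    exposures=["exposure"] + beta_traits,
                    exposure_betas=np.column_stack(
                        [[i.beta_exposure for i in mv_rows]]
                        + [[i.covariate_betas[t][0] for i in mv_rows] for t in beta_traits]
                    ).reshape(len(mv_rows), -1),
                    exposure_ses=np.column_stack(
                        [[i.se_exposure for i in mv_rows]]
                        + [[i.covariate_betas[t][1] for i in mv_rows] for t in beta_traits]
                    ).reshape(len(mv_rows), -1),
                    beta_outcome=[i.beta_outcome for i in mv_rows],
                    se_outcome=[i.se_outcome for i in mv_rows],
                )
                prov.log("mvmr", outcome=outcome_name, snps=table.snp_ids, exposures=table.exposures)
                for est in _stage("mvmr")(mvmr_ivw)(table):
                    estimate_rows.append({"iv_set": f"mvmr_{outcome_name}", "outcome": outcome_name, **est.as_dict()})
                for est in _stage("mvmr")(mvmr_egger)(table):
                    estimate_rows.append({"iv_set": f"mvmr_{outcome_name}", "outcome": outcome_name, **est.as_dict()})
            else:
                prov.log("mvmr", outcome=outcome_name, warning="too few rows with all covariate betas")

        # instrument strength and power: exposure p-values recovered from beta/se
        for set_ in (main, full):
            exp_p = [2 * stats.norm.sf(abs(i.beta_exposure) / i.se_exposure) for i in set_]
            r2 = variance_explained_pn(exp_p, n=_exposure_n(exposure))
            f_val, weak = f_statistic(r2, _exposure_n(exposure), len(set_))
            n_cases, n_controls = _case_control_n(outcome)
            for or_detect in config.power_or_values:
                power = binary_outcome_power(
                    PowerSpec(r2=r2, n_cases=n_cases, n_controls=n_controls, or_detect=or_detect)
                )
                power_rows.append(
                    {
                        "iv_set": set_.name,
                        "outcome": outcome_name,
                        "n_snps": len(set_),
                        "r2": r2,
                        "f_statistic": f_val,
                        "weak_instrument": weak,
                        "or_detect": or_detect,
                        "power": power,
                    }
                )

        obs, exp_count, fold = enrichment_count(
            [2 * stats.norm.sf(abs(i.beta_outcome) / i.se_outcome) for i in full],
            config.enrichment_alpha,
        )
        inverse = sum(
            1
            for i in full
            if 2 * stats.norm.sf(abs(i.beta_outcome) / i.se_outcome) < config.enrichment_alpha
            and i.wald_ratio < 0
        )
        enrichment[outcome_name] = {
            "observed": obs,
            "expected": exp_count,
            "fold": fold,
            "inverse_direction": inverse,
        }

    estimates = pd.DataFrame(estimate_rows)
    estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    pd.DataFrame(power_rows).to_csv(outdir / "power.tsv", sep="\t", index=False)
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diagnostics_bundle, fh, indent=2, default=list)
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(enrichment, fh, indent=2)
    prov.write(outdir / "provenance.jsonl")

    return {
        "estimates": estimates,
        "diagnostics": diagnostics_bundle,
        "power": pd.DataFrame(power_rows),
        "enrichment": enrichment,
        "instrument_sets": instrument_sets,
        "provenance": prov.records,
    }


def _exposure_n(records) -> int:
    ns = [r.n for r in records if r.n]
    if not ns:
        raise ValueError("exposure table carries no sample size; cannot compute r2 via the p/n route")
    return int(round(float(np.median(ns))))


def _case_control_n(records) -> tuple[int, int]:
    cases = [r.n_cases for r in records if r.n_cases]
    controls = [r.n_controls for r in records if r.n_controls]
    if not cases or not controls:
        raise ValueError("outcome table carries no case/control counts; cannot compute power")
    return int(round(float(np.median(cases)))), int(round(float(np.median(controls))))
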