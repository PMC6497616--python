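#!/usr/bin/env python
"""Heterogeneity and influence diagnostics on the main instrument set.

Reads the harmonised main-set instruments written by the pipeline run,
reports Cochran's Q with its per-SNP decomposition, the stepwise-pruning
removal order, Cook's-distance and studentised-residual flags, and the
leave-one-out excursions; writes a combined JSON report.
"""

import json
from pathlib import Path

from bwmr import diagnostics as diag
from bwmr.instruments import InstrumentSet
from bwmr.summary_data import read_instruments

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    instruments = InstrumentSet(
        "main", read_instruments(ROOT / "pipeline" / "instruments_main_overall.tsv")
    )
    report = diag.cochran_q(instruments)
    print(f"Cochran's Q = {report.q:.2f} on {report.df} df (p = {report.pvalue:.3g})")

    report.flagged["cooks"] = diag.cooks_influence(instruments)
    report.flagged["studentised"] = diag.studentised_outliers(instruments)
    try:
        pruned, removed = diag.stepwise_q_prune(instruments)
        report.flagged["stepwise"] = set(removed)
        print(f"stepwise pruning removed {len(removed)} SNP(s): {removed or 'none'}")
        q2 = diag.cochran_q(pruned)
        print(f"  pruned set: {len(pruned)} SNPs, Q = {q2.q:.2f} (p = {q2.pvalue:.3g})")
    except (RuntimeError, ValueError) as exc:
        print(f"stepwise pruning: {exc}")

    rows = diag.leave_one_out(instruments)
    full = rows[-1].beta
    worst = max(rows[:-1], key=lambda r: abs(r.beta - full))
    print(
        f"leave-one-out: largest excursion from the full estimate is "
        f"{worst.extras['omitted']} ({worst.beta - full:+.4f} on the log-OR scale)"
    )
    print(f"Cook's flags: {sorted(report.flagged['cooks']) or 'none'}")
    print(f"studentised flags: {sorted(report.flagged['studentised']) or 'none'}")

    out = ROOT / "diagnostics_report.json"
    out.write_text(json.dumps(report.as_dict(), indent=2))
    print(f"full report -> {out}")


if __name__ == "__main__":
    main()
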