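"""Loader for the study's supplementary workbook (optional reanalysis input).

The published reanalysis ships its per-SNP tables as an XLSX workbook:
the lead-SNP exposure/outcome associations with the 41- and 24-SNP
instrument flags (Supplementary Table 2), the covariate-trait lookups at
the 54 represented loci (Table 3), the 49-SNP multivariable table
(Table 4) and the influential-SNP summary (Table 6). When a copy of the
workbook is available locally, :func:`reproduce_reanalysis` reruns the
headline numbers from it; nothing in this package downloads it.

Sheets are located by searching for a column of rsIDs, and headers are
resolved through the same alias table the TSV reader uses, with
outcome-specific suffix conventions (e.g. ``beta.bc`` / ``se.bc``)
handled by a prefix/suffix split. The loader is deliberately tolerant:
workbooks exported from journal supplements often carry title rows above
the header.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import pandas as pd

from bwmr.estimators import ivw
from bwmr.diagnostics import cochran_q
from bwmr.instruments import InstrumentSet
from bwmr.mvmr import MVInstrumentTable, mvmr_ivw  # noqa: F401 (mvmr used in reproduction)
from bwmr.summary_data import HarmonisedInstrument

__all__ = ["load_workbook_tables", "instruments_from_table", "reproduce_reanalysis"]

_RSID = re.compile(r"^rs\d+$")


def _find_header(df: pd.DataFrame) -> Optional[int]:
    """Locate the header row: the row above the first column of rsIDs."""
    for col in df.columns:
        values = df[col].astype(str)
        hits = values.str.match(_RSID)
        if hits.sum() >= 3:
            first = int(hits.idxmax())
            return max(first - 1, 0)
    return None


def load_workbook_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read every sheet of the workbook, trimming title rows above the header."""
    sheets = pd.read_excel(path, sheet_name=None, header=None)
    out = {}
    for name, raw in sheets.items():
        hdr = _find_header(raw)
        if hdr is None:
            continue
        df = raw.iloc[hdr + 1 :].copy()
        df.columns = [str(c).strip() for c in raw.iloc[hdr]]
        out[name] = df.reset_index(drop=True)
    return out


def _pick(df: pd.DataFrame, *fragments: str) -> Optional[str]:
    """First column whose squashed lowercase name contains all fragments."""
    for col in df.columns:
        squashed = re.sub(r"[^a-z0-9]", "", str(col).lower())
        if all(f in squashed for f in fragments):
            return col
    return None


def instruments_from_table(
    df: pd.DataFrame,
    outcome: str = "overall",
    name: str = "supplement",
) -> InstrumentSet:
    """Build an instrument set from a per-SNP supplement sheet.

    Expects an rsID column, exposure beta/se columns (birth weight) and
    outcome beta/se columns suffixed or prefixed by the outcome label
    (``overall``/``erpos``/``erneg`` conventions are tried in turn).
    """
    snp_col = next(
        (c for c in df.columns if df[c].astype(str).str.match(_RSID).sum() >= 3), None
    )
    if snp_col is None:
        raise ValueError("no rsID column found in supplement sheet")
    out_tags = {
        "overall": ("overall", "bc", "breast"),
        "erpos": ("erpos", "erpositive"),
        "erneg": ("erneg", "ernegative"),
    }[outcome]
    bx_col = _pick(df, "beta", "bw") or _pick(df, "beta", "birthweight")
    sx_col = _pick(df, "se", "bw") or _pick(df, "se", "birthweight")
    by_col = sy_col = None
    for tag in out_tags:
        by_col = by_col or _pick(df, "beta", tag) or _pick(df, "logor", tag)
        sy_col = sy_col or _pick(df, "se", tag)
    missing = [n for n, c in (("exposure beta", bx_col), ("exposure se", sx_col), ("outcome beta", by_col), ("outcome se", sy_col)) if c is None]
    if missing:
        raise ValueError(f"supplement sheet lacks recognisable columns: {', '.join(missing)}")
    rows = []
    for _, r in df.iterrows():
        if not _RSID.match(str(r[snp_col])):
            continue
        try:
            ins = HarmonisedInstrument(
                snp_id=str(r[snp_col]),
                beta_exposure=float(r[bx_col]),
                se_exposure=float(r[sx_col]),
                beta_outcome=float(r[by_col]),
                se_outcome=float(r[sy_col]),
            )
        except (TypeError, ValueError):
            continue
        if ins.beta_exposure < 0:
            ins.beta_exposure, ins.beta_outcome = -ins.beta_exposure, -ins.beta_outcome
        rows.append(ins)
    return InstrumentSet(name=name, instruments=rows)


def reproduce_reanalysis(xlsx_path: str | Path, outcome: str = "overall") -> dict:
    """Recompute the headline univariable numbers from the supplement workbook.

    Returns IVW estimates for the full (59-SNP) set and the flagged main
    (41-SNP) and strict (24-SNP) subsets where flag columns are present,
    Cochran's Q, and — when a multivariable sheet is found — the MVMR
    birth-weight estimate. Raises ``FileNotFoundError`` when the workbook
    is absent.
    """
    path = Path(xlsx_path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {path}; place the paper's XLSX there to rerun the reanalysis"
        )
    tables = load_workbook_tables(path)
    results: dict = {}
    for name, df in tables.items():
        try:
            full = instruments_from_table(df, outcome=outcome, name=f"{name}_full")
        except ValueError:
            continue
        results.setdefault("sets", {})[name] = full
        est = ivw(full)
        results.setdefault("ivw", {})[name] = est
        results.setdefault("q", {})[name] = cochran_q(full)
        for flag_tag, set_name in (("41", "main41"), ("24", "strict24")):
            flag_col = _pick(df, "iv", flag_tag) or _pick(df, flag_tag, "snp")
            if flag_col is not None:
                keep = df[flag_col].astype(str).str.lower().isin(("1", "yes", "true", "y", "x"))
                id_col = next(c for c in df.columns if df[c].astype(str).str.match(_RSID).sum() >= 3)
                ids = set(df.loc[keep, id_col].astype(str))
                sub = full.subset(ids, name=set_name)
                if len(sub) >= 3:
                    results["sets"][set_name] = sub
                    results["ivw"][set_name] = ivw(sub)
                    results["q"][set_name] = cochran_q(sub)
        mv = _try_mvmr_table(df, outcome)
        if mv is not None:
            results.setdefault("mvmr", {})[outcome] = mvmr_ivw(mv)[0]
    if not results:
        raise ValueError(f"no usable per-SNP sheets found in {path}")
    return results


_MV_TRAIT_TAGS = {
    "birth_length": ("bl",),
    "height": ("height",),
    "bmi": ("bmi",),
    "menarche": ("menarche",),
    "menopause": ("menopause",),
}


def _try_mvmr_table(df: pd.DataFrame, outcome: str) -> Optional[MVInstrumentTable]:
    """Assemble the multivariable (birth weight + five covariates) table if the
    sheet carries beta/se columns for every covariate trait."""
    cols = {}
    for trait, tags in _MV_TRAIT_TAGS.items():
        b = s = None
        for tag in tags:
            b = b or _pick(df, "beta", tag)
            s = s or _pick(df, "se", tag)
        if b is None or s is None:
            return None
        cols[trait] = (b, s)
    try:
        full = instruments_from_table(df, outcome=outcome, name="mvmr")
    except ValueError:
        return None
    by_id = {i.snp_id: i for i in full}
    snp_col = next(c for c in df.columns if df[c].astype(str).str.match(_RSID).sum() >= 3)
    rows = df[df[snp_col].astype(str).str.match(_RSID)]
    names = ["birth_weight"] + list(cols)
    betas, ses, ids, by, sy = [], [], [], [], []
    for _, r in rows.iterrows():
        sid = str(r[snp_col])
        if sid not in by_id:
            continue
        try:
            row_b = [by_id[sid].beta_exposure] + [float(r[cols[t][0]]) for t in cols]
            row_s = [by_id[sid].se_exposure] + [float(r[cols[t][1]]) for t in cols]
        except (TypeError, ValueError):
            continue
        betas.append(row_b)
        ses.append(row_s)
        ids.append(sid)
        by.append(by_id[sid].beta_outcome)
        sy.append(by_id[sid].se_outcome)
    if len(ids) < len(names) + 2:
        return None
    import numpy as np

    return MVInstrumentTable(
        snp_ids=ids,
        exposures=names,
        exposure_betas=np.asarray(betas),
        exposure_ses=np.asarray(ses),
        beta_outcome=np.asarray(by),
        se_outcome=np.asarray(sy),
    )
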