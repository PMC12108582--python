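"""Cohort-level summaries of per-tunnel morphometry.

Aggregates a per-(patient, compartment) morphometry table into the summary
statistics quoted in clinical reports: per-compartment n, mean, SD, min and
max for each index, plus pooled (femur + tibia) ranges. Statistics are kept
at full precision; rounding (half away from zero, three decimals for
fractions and mm, integers for mm^3) happens only when rendering.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import COMPARTMENTS
from .morphometry import MorphometryResult

METRICS = ("bvtv", "tb_th", "tb_sp", "tb_n", "volume")

#: printed decimal places per metric (mm^3 volumes are whole numbers)
RENDER_DECIMALS = {"bvtv": 3, "tb_th": 3, "tb_sp": 3, "tb_n": 2, "volume": 0, "mgv": 2}


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float | None  # None (rendered blank) when n == 1
    min: float
    max: float


@dataclass
class CohortSummary:
    """Per-compartment stats per metric, plus pooled min/max per metric."""

    groups: dict[tuple[str, str], GroupStats]  # (compartment, metric) -> stats
    pooled: dict[str, tuple[float, float]]     # metric -> (min, max)

    def get(self, compartment: str, metric: str) -> GroupStats:
        return self.groups[(compartment, metric)]


def results_to_table(results: dict[tuple[object, str], MorphometryResult]) -> pd.DataFrame:
    """Assemble per-tunnel results keyed by (patient_id, compartment) into a table."""
    rows = []
    for (pid, comp), res in results.items():
        rows.append({
            "patient_id": pid, "compartment": comp, "bvtv": res.bvtv,
            "tb_th": res.tb_th, "tb_sp": res.tb_sp, "tb_n": res.tb_n,
            "volume": res.volume, "mgv": res.mgv,
        })
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame, sd_mode: str = "sample") -> CohortSummary:
    """Summarize a per-tunnel table by compartment.

    ``sd_mode``: ``"sample"`` (n-1 denominator, default) or ``"population"``.
    A single-row group reports its SD as undefined, not 0.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty cohort table")
    if sd_mode not in ("sample", "population"):
        raise ValueError("sd_mode must be 'sample' or 'population'")
    ddof = 1 if sd_mode == "sample" else 0
    metrics = [m for m in METRICS + ("mgv",) if m in table.columns]

    groups: dict[tuple[str, str], GroupStats] = {}
    for comp in COMPARTMENTS:
        sub = table[table["compartment"] == comp]
        if len(sub) == 0:
            continue
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else None
            groups[(comp, m)] = GroupStats(
                n=int(vals.size), mean=float(vals.mean()), sd=sd,
                min=float(vals.min()), max=float(vals.max()),
            )
    pooled = {}
    for m in metrics:
        vals = table[m].dropna().to_numpy(dtype=float)
        if vals.size:
            pooled[m] = (float(vals.min()), float(vals.max()))
    return CohortSummary(groups=groups, pooled=pooled)


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero at the printed precision."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _rounded_row(comp: str, metric: str, st: GroupStats) -> dict:
    d = RENDER_DECIMALS.get(metric, 3)
    return {
        "compartment": comp,
        "metric": metric,
        "n": st.n,
        "mean": round_half_away(st.mean, d),
        "sd": None if st.sd is None else round_half_away(st.sd, d),
        "min": round_half_away(st.min, d),
        "max": round_half_away(st.max, d),
    }


def render_report(summary: CohortSummary, fmt: str = "csv",
                  path: str | Path | None = None) -> str:
    """Render a summary as CSV (one row per compartment/metric) or JSON.

    Both formats carry identical numeric content; SDs of single-row groups
    render blank (CSV) / null (JSON).
    """
    if not summary.groups:
        raise ValueError("empty summary")
    rows = [_rounded_row(comp, m, st) for (comp, m), st in sorted(summary.groups.items())]
    pooled = {
        m: {"min": round_half_away(lo, RENDER_DECIMALS.get(m, 3)),
            "max": round_half_away(hi, RENDER_DECIMALS.get(m, 3))}
        for m, (lo, hi) in sorted(summary.pooled.items())
    }
    if fmt == "csv":
        df = pd.DataFrame(rows)
        pooled_rows = [
            {"compartment": "overall", "metric": m, "n": "",
             "mean": "", "sd": "", "min": v["min"], "max": v["max"]}
            for m, v in pooled.items()
        ]
        df = pd.concat([df, pd.DataFrame(pooled_rows)], ignore_index=True)
        text = df.to_csv(index=False)
    elif fmt == "json":
        text = json.dumps({"groups": rows, "pooled": pooled}, indent=2)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
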