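"""Productivity metrics for semi-continuous perfusion cultures.

With a full daily medium exchange, each day's harvest titer is one day's
production, so cell-specific productivity reduces to

    qP [pg/cell/day] = titer [ug/mL] / VCD [1e6 cells/mL]

and the cumulative harvested product per mL of culture is the plain sum of
daily titers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import InputError


@dataclass(frozen=True)
class CultureRecord:
    day: int
    vcd: float          # 1e6 viable cells / mL
    viability: float    # fraction in [0, 1]
    titer: float        # ug/mL harvested that day

    def __post_init__(self) -> None:
        if self.vcd < 0:
            raise InputError(f"day {self.day}: VCD must be >= 0")
        if not 0 <= self.viability <= 1:
            raise InputError(f"day {self.day}: viability must lie in [0, 1]")


@dataclass
class CultureTimeseries:
    records: list[CultureRecord]
    temperature_shift_day: int | None = None

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.day)
        days = [r.day for r in self.records]
        if len(set(days)) != len(days):
            raise InputError("duplicate culture days")


@dataclass
class ProcessSummary:
    max_titer: float
    day_of_max: int
    mean_qp: float               # pg/cell/day over production days
    cumulative_product: float    # ug per mL of culture volume
    n_days: int


def daily_qp(titer: float, vcd: float) -> float:
    """Cell-specific productivity in pg/cell/day under full daily exchange."""
    if vcd <= 0:
        raise InputError("VCD must be > 0 to compute qP")
    return titer / vcd


def process_summary(ts: CultureTimeseries) -> ProcessSummary:
    """Max titer, its day, mean post-shift qP, and cumulative product per mL."""
    if not ts.records:
        raise InputError("empty culture time series")
    best = max(ts.records, key=lambda r: r.titer)
    shift = ts.temperature_shift_day
    production = [
        r for r in ts.records
        if (shift is None or r.day > shift) and r.vcd > 0
    ]
    if not production:
        production = [r for r in ts.records if r.vcd > 0]
    qps = [daily_qp(r.titer, r.vcd) for r in production]
    return ProcessSummary(
        max_titer=best.titer,
        day_of_max=best.day,
        mean_qp=sum(qps) / len(qps) if qps else 0.0,
        cumulative_product=sum(r.titer for r in ts.records),
        n_days=len(ts.records),
    )


def read_culture_csv(
    path: str | Path, temperature_shift_day: int | None = None
) -> CultureTimeseries:
    """CSV columns: day, vcd, viability, titer (``#`` comments allowed)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"culture file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("day", "vcd", "viability", "titer") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    records = [
        CultureRecord(int(r.day), float(r.vcd), float(r.viability), float(r.titer))
        for r in df.itertuples()
    ]
    return CultureTimeseries(records, temperature_shift_day=temperature_shift_day)


def write_culture_csv(
    ts: CultureTimeseries, path: str | Path, comments: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("day,vcd,viability,titer\n")
        for r in ts.records:
            fh.write(f"{r.day},{r.vcd:.4f},{r.viability:.4f},{r.titer:.4f}\n")


def write_summary(summary: ProcessSummary, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "max_titer_ug_per_ml": round(summary.max_titer, 3),
                "day_of_max": summary.day_of_max,
                "mean_qp_pg_per_cell_day": round(summary.mean_qp, 4),
                "cumulative_product_ug_per_ml": round(summary.cumulative_product, 3),
                "n_days": summary.n_days,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
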