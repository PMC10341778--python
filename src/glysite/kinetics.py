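"""1:1 Langmuir binding kinetics for biolayer-interferometry sensorgrams.

The pseudo-first-order 1:1 model for a ligand immobilised on the sensor and
an analyte at constant concentration C:

    association:   R(t) = Rmax * C / (C + KD) * (1 - exp(-(kon*C + koff) t))
    dissociation:  R(t) = R(t1) * exp(-koff (t - t1))

with KD = koff / kon. ``global_fit`` shares kon, koff and Rmax across all
analyte concentrations (optionally one additive baseline offset per curve)
and minimises the pooled squared residual with a trust-region least-squares
solver; rate constants are optimised on a log10 scale for conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .core import InputError


class ParameterError(ValueError):
    """Invalid kinetic model parameter."""


@dataclass
class Sensorgram:
    """One BLI trace at one analyte concentration, with phase boundaries."""

    ligand_id: str
    analyte_concentration: float  # molar
    times: np.ndarray             # s, strictly increasing
    signals: np.ndarray           # nm
    t_assoc_start: float
    t_assoc_end: float
    t_dissoc_end: float
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise InputError("times and signals must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("sensorgram times must be strictly increasing")
        if self.t_assoc_end > self.t_dissoc_end:
            raise InputError("association end must precede dissociation end")

    @property
    def phases(self) -> dict[str, np.ndarray]:
        """Boolean masks for baseline / association / dissociation samples."""
        t = self.times
        assoc = (t >= self.t_assoc_start) & (t <= self.t_assoc_end)
        dissoc = t > self.t_assoc_end
        baseline = t < self.t_assoc_start
        return {"baseline": baseline, "association": assoc, "dissociation": dissoc}


@dataclass
class KineticFit:
    """Globally fitted 1:1 kinetic parameters for one ligand."""

    kon: float                   # 1/(M s)
    koff: float                  # 1/s
    rmax: float                  # nm
    per_curve_offset: list = field(default_factory=list)  # nm
    kd: float = 0.0              # M, koff/kon by construction
    residual_sse: float = 0.0
    converged: bool = True
    specific_binding: bool = True
    noise_sd: float = 0.0
    ligand_id: str = ""

    def __post_init__(self) -> None:
        self.kd = self.koff / self.kon


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def kd(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon, in molar."""
    if kon <= 0:
        raise ParameterError("kon must be > 0")
    return koff / kon


def model_association(t, conc: float, kon: float, koff: float, rmax: float):
    """1:1 association signal at time(s) t since association start."""
    if kon <= 0:
        raise ParameterError("kon must be > 0")
    t = np.asarray(t, dtype=float)
    if conc == 0:
        return np.zeros_like(t)
    kobs = kon * conc + koff
    req = rmax * conc / (conc + koff / kon)
    return req * (1.0 - np.exp(-kobs * t))


def model_dissociation(t, r0: float, koff: float, t_start: float = 0.0):
    """Exponential decay from amplitude r0 at the dissociation start."""
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-koff * (t - t_start))


def predict_sensorgram(
    curve: Sensorgram, kon: float, koff: float, rmax: float, offset: float = 0.0
) -> np.ndarray:
    """Piecewise model over baseline, association and dissociation phases."""
    t = curve.times
    out = np.full(t.shape, offset, dtype=float)
    ph = curve.phases
    ta = t[ph["association"]] - curve.t_assoc_start
    out[ph["association"]] += model_association(
        ta, curve.analyte_concentration, kon, koff, rmax
    )
    r_end = float(
        model_association(
            curve.t_assoc_end - curve.t_assoc_start,
            curve.analyte_concentration, kon, koff, rmax,
        )
    )
    td = t[ph["dissociation"]]
    out[ph["dissociation"]] += model_dissociation(td, r_end, koff, curve.t_assoc_end)
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _initial_guess(curves: Sequence[Sensorgram]) -> tuple[float, float, float]:
    """(kon, koff, rmax) start values from phase-wise heuristics.

    koff from a log-linear regression on the dissociation decay of the
    highest-concentration curve; per-curve kobs from the 63.2%-of-plateau
    crossing time; kon from the slope of kobs against concentration.
    """
    top = max(curves, key=lambda c: c.analyte_concentration)
    ph = top.phases
    koff0 = 1e-3
    td, yd = top.times[ph["dissociation"]], top.signals[ph["dissociation"]]
    if td.size >= 3:
        pos = yd > max(1e-12, 0.01 * np.max(np.abs(yd)))
        if np.count_nonzero(pos) >= 3:
            res = linregress(td[pos], np.log(yd[pos]))
            if res.slope < 0:
                koff0 = min(max(-res.slope, 1e-7), 1.0)
    kobs_list, conc_list, plateaus = [], [], []
    for c in curves:
        if c.analyte_concentration <= 0:
            continue
        pm = c.phases["association"]
        ta = c.times[pm] - c.t_assoc_start
        ya = c.signals[pm]
        if ta.size < 5:
            continue
        plateau = float(np.mean(ya[-max(3, ta.size // 10):]))
        plateaus.append((plateau, c.analyte_concentration))
        if plateau <= 0:
            continue
        above = np.nonzero(ya >= (1 - math.exp(-1)) * plateau)[0]
        if above.size and ta[above[0]] > 0:
            kobs_list.append(1.0 / ta[above[0]])
            conc_list.append(c.analyte_concentration)
    kon0 = 1e5
    if len(kobs_list) >= 2:
        res = linregress(conc_list, kobs_list)
        if res.slope > 0:
            kon0 = res.slope
    elif kobs_list:
        kon0 = max(kobs_list[0] / conc_list[0], 1e2)
    kon0 = min(max(kon0, 1e2), 1e8)
    rmax0 = 1.0
    if plateaus:
        plateau, conc = max(plateaus, key=lambda p: p[1])
        kd0 = koff0 / kon0
        rmax0 = max(plateau * (conc + kd0) / conc, 1e-6)
    return kon0, koff0, rmax0


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def global_fit(
    curves: Sequence[Sensorgram],
    fit_offset: bool = True,
    kon_bounds: tuple[float, float] = (1e2, 1e8),
    koff_bounds: tuple[float, float] = (1e-7, 1.0),
    init: tuple[float, float, float] | None = None,
    binding_snr: float = 3.0,
) -> KineticFit:
    """Fit kon, koff and Rmax jointly across all sensorgrams.

    ``init`` overrides the heuristic start values with (kon, koff, rmax).
    A ligand is reported as showing no specific binding when the fitted
    Rmax falls below ``binding_snr`` times the residual noise SD.
    """
    curves = list(curves)
    if not curves:
        raise InputError("global_fit requires at least one sensorgram")
    for c in curves:
        ph = c.phases
        for name in ("association", "dissociation"):
            if not np.any(ph[name]):
                raise InputError(
                    f"curve {c.curve_id or c.ligand_id!r} has no {name} phase"
                )
    kon0, koff0, rmax0 = init if init is not None else _initial_guess(curves)
    kon0 = min(max(kon0, kon_bounds[0]), kon_bounds[1])
    koff0 = min(max(koff0, koff_bounds[0]), koff_bounds[1])
    n_off = len(curves) if fit_offset else 0

    x0 = np.concatenate(
        [[math.log10(kon0), math.log10(koff0), rmax0], np.zeros(n_off)]
    )
    lo = np.concatenate(
        [[math.log10(kon_bounds[0]), math.log10(koff_bounds[0]), 0.0],
         np.full(n_off, -np.inf)]
    )
    hi = np.concatenate(
        [[math.log10(kon_bounds[1]), math.log10(koff_bounds[1]), np.inf],
         np.full(n_off, np.inf)]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        kon, koff, rmax = 10.0 ** x[0], 10.0 ** x[1], x[2]
        res = []
        for i, c in enumerate(curves):
            off = x[3 + i] if fit_offset else 0.0
            res.append(c.signals - predict_sensorgram(c, kon, koff, rmax, off))
        return np.concatenate(res)

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    kon, koff, rmax = 10.0 ** sol.x[0], 10.0 ** sol.x[1], float(sol.x[2])
    offsets = [float(v) for v in sol.x[3:]] if fit_offset else [0.0] * len(curves)
    r = sol.fun
    n_params = 3 + n_off
    dof = max(r.size - n_params, 1)
    noise_sd = float(np.sqrt(np.sum(r**2) / dof))
    return KineticFit(
        kon=kon,
        koff=koff,
        rmax=rmax,
        per_curve_offset=offsets,
        residual_sse=float(np.sum(r**2)),
        converged=bool(sol.success),
        specific_binding=bool(rmax >= binding_snr * noise_sd and sol.success),
        noise_sd=noise_sd,
        ligand_id=curves[0].ligand_id,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SENSORGRAM_COLUMNS = ["time_s", "signal_nm", "conc_M", "phase", "curve_id"]
PHASE_LABELS = ("baseline", "association", "dissociation")


def read_sensorgrams(path: str | Path, ligand_id: str | None = None) -> list[Sensorgram]:
    """Read the sensorgram CSV dialect (time_s, signal_nm, conc_M, phase, curve_id)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"sensorgram file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SENSORGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    bad = set(df["phase"]) - set(PHASE_LABELS)
    if bad:
        raise InputError(f"{path}: unknown phase labels {sorted(bad)}")
    curves = []
    for curve_id, g in df.groupby("curve_id", sort=True):
        g = g.sort_values("time_s")
        assoc = g[g["phase"] == "association"]["time_s"]
        dissoc = g[g["phase"] == "dissociation"]["time_s"]
        curves.append(
            Sensorgram(
                ligand_id=ligand_id or path.stem,
                analyte_concentration=float(g["conc_M"].iloc[0]),
                times=g["time_s"].to_numpy(),
                signals=g["signal_nm"].to_numpy(),
                t_assoc_start=float(assoc.min()) if len(assoc) else 0.0,
                t_assoc_end=float(assoc.max()) if len(assoc) else 0.0,
                t_dissoc_end=float(dissoc.max()) if len(dissoc) else 0.0,
                curve_id=str(curve_id),
            )
        )
    return curves


def write_sensorgrams(
    curves: Sequence[Sensorgram], path: str | Path, comments: Sequence[str] = ()
) -> None:
    rows = []
    for c in curves:
        ph = c.phases
        labels = np.full(c.times.shape, "baseline", dtype=object)
        labels[ph["association"]] = "association"
        labels[ph["dissociation"]] = "dissociation"
        for t, s, lab in zip(c.times, c.signals, labels):
            rows.append(
                {
                    "time_s": round(float(t), 4),
                    "signal_nm": round(float(s), 6),
                    "conc_M": c.analyte_concentration,
                    "phase": lab,
                    "curve_id": c.curve_id,
                }
            )
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=SENSORGRAM_COLUMNS).to_csv(fh, index=False)


def write_fit_report(fits: Sequence[KineticFit], path: str | Path) -> None:
    """TSV of kon, koff, KD (nM) per ligand; non-binders flagged."""
    rows = []
    for f in fits:
        rows.append(
            {
                "ligand": f.ligand_id,
                "kon_per_M_s": f"{f.kon:.4g}",
                "koff_per_s": f"{f.koff:.4g}",
                "KD_nM": f"{f.kd * 1e9:.2f}",
                "rmax_nm": f"{f.rmax:.4g}",
                "converged": f.converged,
                "specific_binding": f.specific_binding,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
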