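"""Removal efficiency and first-order degradation-rate fitting.

Works on :class:`~sipaug.containers.DegradationSeries` objects, phase by
phase: removal efficiency is the relative concentration drop across a dosing
phase, and the rate constant k comes from a least-squares regression of
ln C on t within the phase (so noiseless exponentials are recovered
exactly).  Phase-start concentrations are the post-re-addition records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DegradationSeries

__all__ = ["KineticsFit", "removal_efficiency", "fit_first_order", "kinetics_report"]

#: concentrations below this are treated as 0 (quantification limit, mg/L)
DEFAULT_LOQ = 0.05


@dataclass(frozen=True)
class KineticsFit:
    """First-order fit of one treatment in one dosing phase."""

    treatment: str
    phase: str
    k: float                 # 1/day
    half_life: float         # days; inf when k == 0
    r_squared: float
    n_points: int
    degenerate: bool = False  # constant series: k reported as 0 by convention


def _phase_points(series: DegradationSeries, treatment: str, phase: str) -> pd.DataFrame:
    pts = series.phase_slice(treatment, phase)
    if pts.empty:
        raise ValueError(f"no measurements for treatment {treatment!r} in phase {phase!r}")
    return pts


def removal_efficiency(
    series: DegradationSeries,
    treatment: str,
    phase: str,
    loq: float = DEFAULT_LOQ,
) -> tuple[float, float]:
    """Percent SMX removed across a phase, averaged over replicates.

    Returns ``(mean_percent, sd_percent)`` where each replicate contributes
    ``100 * (C_start - C_end) / C_start``; values below the quantification
    limit count as 0 and the result is clipped to [0, 100].
    """
    pts = _phase_points(series, treatment, phase)
    t0, t1 = series.phase_bounds[phase]
    effs = []
    for rep, grp in pts.groupby("replicate"):
        grp = grp.sort_values("day")
        start = grp[np.isclose(grp["day"], t0)]
        end = grp[np.isclose(grp["day"], t1)]
        if start.empty:
            raise ValueError(
                f"phase {phase!r} lacks a phase-start measurement for "
                f"treatment {treatment!r} replicate {rep}"
            )
        if end.empty:
            raise ValueError(
                f"phase {phase!r} lacks a phase-end measurement for "
                f"treatment {treatment!r} replicate {rep}"
            )
        c0 = float(start["smx_mg_per_l"].iloc[0])
        c1 = float(end["smx_mg_per_l"].iloc[-1])
        if c0 <= loq:
            raise ValueError(
                f"phase-start concentration is below the quantification limit for "
                f"treatment {treatment!r} replicate {rep}"
            )
        if c1 <= loq:
            c1 = 0.0
        effs.append(float(np.clip(100.0 * (c0 - c1) / c0, 0.0, 100.0)))
    effs_arr = np.asarray(effs)
    return float(effs_arr.mean()), float(effs_arr.std(ddof=1)) if len(effs_arr) > 1 else 0.0


def fit_first_order(
    series: DegradationSeries,
    treatment: str,
    phase: str,
    loq: float = DEFAULT_LOQ,
) -> KineticsFit:
    """Least-squares ln C vs t regression within one phase; slope = -k.

    Pools all replicates' measurements.  Points at or below the
    quantification limit are excluded (with a warning); a constant series is
    reported as k = 0 with the ``degenerate`` flag set.
    """
    pts = _phase_points(series, treatment, phase)
    t = pts["day"].to_numpy(float)
    c = pts["smx_mg_per_l"].to_numpy(float)
    keep = c > loq
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} sub-LOQ point(s) from the "
            f"{treatment!r}/{phase!r} log-linear fit"
        )
    t, c = t[keep], c[keep]
    if len(t) < 2:
        raise ValueError(
            f"fewer than 2 quantifiable points for treatment {treatment!r} "
            f"phase {phase!r}"
        )
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time: cannot fit a rate")
    logc = np.log(c)
    if np.allclose(logc, logc[0]):
        return KineticsFit(treatment, phase, 0.0, math.inf, 0.0, len(t), degenerate=True)
    res = stats.linregress(t, logc)
    k = max(0.0, -float(res.slope))
    half_life = math.log(2) / k if k > 0 else math.inf
    return KineticsFit(
        treatment=treatment,
        phase=phase,
        k=k,
        half_life=half_life,
        r_squared=float(res.rvalue**2),
        n_points=len(t),
    )


def kinetics_report(
    series: DegradationSeries,
    reference_treatment: str | None = None,
    loq: float = DEFAULT_LOQ,
) -> pd.DataFrame:
    """Efficiencies and rate fits for every (treatment, phase) in a series.

    When ``reference_treatment`` is given, two comparison columns are added
    per the two readings of an "increased by X%" statement: the absolute
    difference in percentage points and the relative increase in percent of
    the reference efficiency.
    """
    rows = []
    for treatment in series.treatments:
        for phase in series.phase_bounds:
            eff, eff_sd = removal_efficiency(series, treatment, phase, loq=loq)
            try:
                fit = fit_first_order(series, treatment, phase, loq=loq)
                k, hl, r2, npts = fit.k, fit.half_life, fit.r_squared, fit.n_points
            except ValueError:
                k = hl = r2 = float("nan")
                npts = 0
            rows.append((treatment, phase, eff, eff_sd, k, hl, r2, npts))
    out = pd.DataFrame(
        rows,
        columns=[
            "treatment", "phase", "removal_pct", "removal_sd",
            "k_per_day", "half_life_days", "r_squared", "n_points",
        ],
    )
    if reference_treatment is not None:
        ref = out[out["treatment"] == reference_treatment].set_index("phase")["removal_pct"]
        out["removal_vs_ref_abs_pts"] = out.apply(
            lambda r: r["removal_pct"] - ref.get(r["phase"], np.nan), axis=1
        )
        out["removal_vs_ref_rel_pct"] = out.apply(
            lambda r: 100.0 * (r["removal_pct"] - ref.get(r["phase"], np.nan))
            / ref.get(r["phase"], np.nan),
            axis=1,
        )
    return out
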