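"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["CountTable", "DegradationSeries", "GradientFractionSet"]

#: columns every sample-metadata frame must provide
REQUIRED_METADATA = ("treatment", "day", "replicate")


@dataclass
class CountTable:
    """ASV-by-sample count matrix joined to per-sample metadata.

    ``counts`` has ASV ids as the index and sample ids as columns;
    ``metadata`` is indexed by sample id and carries at least treatment,
    day and replicate (plus fraction/buoyant-density columns for SIP
    samples).  Validation runs on construction.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        c, m = self.counts, self.metadata
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated ASV ids: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dup}")
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids in metadata: {dup}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)
        missing = [s for s in c.columns if s not in m.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in REQUIRED_METADATA:
            if col not in m.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        empty = c.columns[self.counts.sum(axis=0) == 0].tolist()
        if empty:
            raise ValueError(f"samples with zero total counts: {empty}")
        # metadata rows for samples absent from the matrix are dropped, loudly
        extra = [s for s in m.index if s not in set(c.columns)]
        if extra:
            warnings.warn(f"dropping metadata rows without counts: {extra}")
        self.metadata = m.loc[list(c.columns)]

    # -- convenience views ---------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(self.counts[ids].copy(), self.metadata.loc[ids].copy())

    def for_treatment(self, treatment: str) -> "CountTable":
        ids = self.metadata.index[self.metadata["treatment"] == treatment]
        if len(ids) == 0:
            raise ValueError(f"no samples for treatment {treatment!r}")
        return self.subset_samples(ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable({len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples)"
        )


@dataclass
class DegradationSeries:
    """Per-treatment SMX concentration trajectories with phase structure.

    ``data`` columns: treatment, replicate, day, phase, smx_mg_per_l.  A
    dosing day carries two records — the pre-dose residual filed under the
    ending phase and the post-dose concentration filed under the phase it
    opens — so phase-start and phase-end concentrations are both available.
    """

    data: pd.DataFrame
    phase_bounds: Mapping[str, tuple[float, float]]
    dose_mg_per_l: float
    dosing_days: tuple[float, ...]

    def __post_init__(self) -> None:
        need = {"treatment", "replicate", "day", "phase", "smx_mg_per_l"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"degradation data lacks columns {sorted(need - set(self.data.columns))}")
        if (self.data["smx_mg_per_l"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        self.data = self.data.sort_values(
            ["treatment", "replicate", "day"], kind="stable"
        ).reset_index(drop=True)

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    def trajectory(self, treatment: str, replicate: int) -> pd.DataFrame:
        sel = (self.data["treatment"] == treatment) & (
            self.data["replicate"] == replicate
        )
        out = self.data[sel]
        if out.empty:
            raise ValueError(f"no trajectory for ({treatment!r}, replicate {replicate})")
        return out

    def phase_slice(self, treatment: str, phase: str) -> pd.DataFrame:
        if phase not in self.phase_bounds:
            raise ValueError(f"unknown phase {phase!r}")
        sel = (self.data["treatment"] == treatment) & (self.data["phase"] == phase)
        return self.data[sel]

    # -- quantities the community generator couples to ------------------
    def cumulative_added(self, day: float) -> float:
        """Total SMX (mg/L) dosed into an SMX-amended microcosm by ``day``."""
        return self.dose_mg_per_l * sum(1 for d in self.dosing_days if d <= day + 1e-12)

    def degraded_fraction(self, treatment: str, replicate: int, day: float) -> float:
        """Fraction of all SMX added so far that has been degraded by ``day``.

        Uses the recorded trajectory (interpolated in time); 0 for
        treatments absent from the series (e.g. the no-antibiotic control).
        """
        added = self.cumulative_added(day)
        if added == 0:
            return 0.0
        try:
            traj = self.trajectory(treatment, replicate)
        except ValueError:
            return 0.0
        conc = float(np.interp(day, traj["day"], traj["smx_mg_per_l"]))
        return float(np.clip((added - conc) / added, 0.0, 1.0))

    def time_depleted(self, treatment: str, replicate: int, day: float,
                      loq: float = 0.05) -> float:
        """Cumulative days up to ``day`` with SMX below the quantification limit.

        Counted interval-wise on the measurement grid: an interval contributes
        its full length when both endpoint concentrations are below ``loq``.
        """
        try:
            traj = self.trajectory(treatment, replicate)
        except ValueError:
            return float(day)  # never dosed: depleted the whole time
        t = traj["day"].to_numpy()
        c = traj["smx_mg_per_l"].to_numpy()
        total = 0.0
        for (t0, c0), (t1, c1) in zip(zip(t, c), zip(t[1:], c[1:])):
            if t0 >= day:
                break
            if c0 < loq and c1 < loq:
                total += min(t1, day) - t0
        return total


@dataclass
class GradientFractionSet:
    """One microcosm's CsCl gradient: fraction densities, qPCR totals, counts.

    ``fractions`` is indexed by fraction number (1..n) with columns
    ``buoyant_density`` (g/mL) and ``total_16s_copies``; ``counts`` holds the
    per-fraction ASV count vectors (ASV index, fraction-number columns).
    ``heavy_first`` declares the indexing convention (fraction 1 = densest);
    paired 13C/12C sets must agree on it.
    """

    microcosm_id: str
    isotope: str
    fractions: pd.DataFrame
    counts: pd.DataFrame
    sequenced_window: tuple[int, int] = (3, 10)
    heavy_first: bool = True

    def __post_init__(self) -> None:
        if self.isotope not in ("13C", "12C"):
            raise ValueError("isotope must be '13C' or '12C'")
        need = {"buoyant_density", "total_16s_copies"}
        if not need.issubset(self.fractions.columns):
            raise ValueError(f"fractions frame lacks {sorted(need - set(self.fractions.columns))}")
        bd = self.fractions["buoyant_density"].to_numpy()
        diffs = np.diff(bd)
        if self.heavy_first:
            if not np.all(diffs < 0):
                raise ValueError("heavy_first=True requires strictly decreasing densities")
        else:
            if not np.all(diffs > 0):
                raise ValueError("heavy_first=False requires strictly increasing densities")
        if (self.fractions["total_16s_copies"] < 0).any():
            raise ValueError("16S copies must be >= 0")
        w0, w1 = self.sequenced_window
        n = len(self.fractions)
        if not (1 <= w0 <= w1 <= n):
            raise ValueError("sequenced_window outside [1, n_fractions]")
        if list(self.counts.columns) != list(self.fractions.index):
            raise ValueError("counts columns must match fraction index")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    def sequenced_fractions(self) -> list[int]:
        w0, w1 = self.sequenced_window
        return [f for f in self.fractions.index if w0 <= f <= w1]

    def densities(self) -> pd.Series:
        return self.fractions["buoyant_density"]

    def compatible_with(self, other: "GradientFractionSet") -> None:
        """Raise unless the two sets share ASV universe and fraction convention."""
        if self.heavy_first != other.heavy_first:
            raise ValueError(
                "fraction-order conventions differ between gradient sets; "
                "declare and harmonize heavy_first explicitly"
            )
        if self.n_fractions != other.n_fractions:
            raise ValueError("fraction counts differ between gradient sets")
        if self.sequenced_window != other.sequenced_window:
            raise ValueError("sequenced windows differ between gradient sets")
        if set(self.counts.index) != set(other.counts.index):
            raise ValueError("ASV universes differ between gradient sets")
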