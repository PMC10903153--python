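"""Identification of 13C-labelled taxa from paired density-gradient profiles.

An actively substrate-assimilating taxon builds 13C into its DNA, which
migrates toward heavier CsCl fractions.  Comparing its qPCR-weighted
abundance profile along the gradient between the 13C-labelled microcosm and
the 12C control reveals the shift.  The caller applies a conjunctive
three-part rule — heavy-fraction enrichment ratio, center-of-mass shift,
and a minimum heavy-fraction abundance — with every component surfaced so
users can relax any of them.  The cutoffs are package defaults chosen for
the synthetic generator's geometry; they are tunable and are not taken from
any particular study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GradientFractionSet

__all__ = [
    "CallParams",
    "qpcr_weighted_profile",
    "profile_matrix",
    "designate_heavy",
    "center_of_mass",
    "identify_labeled",
]


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the labelled-taxon calling rule.

    ratio_min
        Minimum (heavy-fraction mean abundance + eps) ratio, labelled over
        control.
    delta_cm_min
        Minimum center-of-mass shift (g/mL) toward heavy fractions.
    abundance_min
        Minimum qPCR-weighted relative abundance in the labelled heavy
        fractions (0.005 = 0.5 %).
    eps
        Pseudo-abundance guarding the ratio against empty denominators.
    heavy_mode, heavy_threshold, heavy_k
        How heavy fractions are designated: ``by_density`` keeps sequenced
        fractions at least ``heavy_threshold`` g/mL dense; ``by_count``
        keeps the ``heavy_k`` densest sequenced fractions.
    """

    ratio_min: float = 2.0
    delta_cm_min: float = 0.004
    abundance_min: float = 0.005
    eps: float = 1e-4
    heavy_mode: str = "by_density"
    heavy_threshold: float = 1.720
    heavy_k: int = 3

    def __post_init__(self) -> None:
        if self.heavy_mode not in ("by_density", "by_count"):
            raise ValueError("heavy_mode must be 'by_density' or 'by_count'")
        if self.ratio_min < 1 or self.abundance_min < 0 or self.eps <= 0:
            raise ValueError("invalid calling thresholds")


def profile_matrix(fractions: GradientFractionSet) -> pd.DataFrame:
    """qPCR-weighted abundance profiles for every ASV (ASV x fraction).

    Per sequenced fraction: (ASV relative abundance within the fraction) x
    (the fraction's share of total 16S copies across the sequenced window).
    Each ASV's profile sums to its copy-weighted share of the window, and
    the whole matrix sums to 1.  Fractions with zero sequenced counts are
    skipped with a warning.
    """
    seq = fractions.sequenced_fractions()
    counts = fractions.counts[seq]
    totals = counts.sum(axis=0)
    empty = [f for f in seq if totals[f] == 0]
    if empty:
        warnings.warn(f"sequenced fractions with zero total counts skipped: {empty}")
        seq = [f for f in seq if f not in empty]
        counts = counts[seq]
        totals = totals[seq]
    if not seq:
        raise ValueError("no sequenced fraction has nonzero counts")
    copies = fractions.fractions.loc[seq, "total_16s_copies"]
    copy_share = copies / copies.sum()
    rel = counts / totals
    return rel * copy_share


def qpcr_weighted_profile(fractions: GradientFractionSet, asv: str) -> pd.Series:
    """One ASV's qPCR-weighted abundance along the sequenced fractions."""
    mat = profile_matrix(fractions)
    if asv not in mat.index:
        raise ValueError(f"ASV {asv!r} absent from the gradient set")
    return mat.loc[asv]


def designate_heavy(
    fractions: GradientFractionSet,
    mode: str = "by_density",
    threshold: float = 1.720,
    k: int = 3,
) -> list[int]:
    """Heavy-fraction indices among the sequenced fractions.

    ``by_density`` keeps sequenced fractions with buoyant density >=
    ``threshold`` g/mL; ``by_count`` keeps the ``k`` densest sequenced
    fractions.
    """
    seq = fractions.sequenced_fractions()
    bd = fractions.fractions.loc[seq, "buoyant_density"]
    if mode == "by_density":
        return [f for f in seq if bd[f] >= threshold]
    if mode == "by_count":
        return list(bd.sort_values(ascending=False).index[:k])
    raise ValueError("mode must be 'by_density' or 'by_count'")


def center_of_mass(profile: pd.Series, densities: pd.Series) -> float:
    """Buoyant-density center of mass of a profile: sum(BD_f w_f)/sum(w_f)."""
    w = profile.to_numpy(float)
    bd = densities.loc[profile.index].to_numpy(float)
    total = w.sum()
    if total <= 0:
        raise ValueError("profile has zero total mass")
    return float((bd * w).sum() / total)


def identify_labeled(
    labeled: GradientFractionSet,
    control: GradientFractionSet,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Call 13C-labelled ASVs from a paired labelled/control gradient.

    An ASV is labelled iff all three hold:

    1. ``(heavy_mean_labeled + eps) / (heavy_mean_control + eps) >= ratio_min``
    2. ``CM_labeled - CM_control >= delta_cm_min`` (center-of-mass shift)
    3. ``heavy_mean_labeled >= abundance_min``

    Returns one row per ASV with all sub-criteria, ranked by heavy-fraction
    enrichment difference (rank 1 = strongest call).  ASVs with zero counts
    in both sets' sequenced windows are excluded.
    """
    params = params or CallParams()
    labeled.compatible_with(control)
    if labeled.isotope == control.isotope:
        raise ValueError("labelled and control sets carry the same isotope tag")
    prof_l = profile_matrix(labeled)
    prof_c = profile_matrix(control)
    heavy_l = designate_heavy(labeled, params.heavy_mode, params.heavy_threshold, params.heavy_k)
    heavy_c = designate_heavy(control, params.heavy_mode, params.heavy_threshold, params.heavy_k)
    if not heavy_l or not heavy_c:
        raise ValueError("heavy-fraction set is empty; relax the heavy designation")
    dens_l = labeled.densities()
    dens_c = control.densities()
    asvs = sorted(set(prof_l.index) & set(prof_c.index))
    rows = []
    for asv in asvs:
        pl, pc = prof_l.loc[asv], prof_c.loc[asv]
        if pl.sum() <= 0 and pc.sum() <= 0:
            continue
        hm_l = float(pl[heavy_l].mean())
        hm_c = float(pc[heavy_c].mean())
        ratio = (hm_l + params.eps) / (hm_c + params.eps)
        cm_l = center_of_mass(pl, dens_l) if pl.sum() > 0 else np.nan
        cm_c = center_of_mass(pc, dens_c) if pc.sum() > 0 else np.nan
        if np.isnan(cm_l) or np.isnan(cm_c):
            # taxon present in only one set: treat a labelled-only taxon as
            # maximally shifted, a control-only taxon as unshifted
            delta_cm = np.inf if pl.sum() > 0 else 0.0
        else:
            delta_cm = cm_l - cm_c
        ok_ratio = ratio >= params.ratio_min
        ok_shift = delta_cm >= params.delta_cm_min
        ok_abund = hm_l >= params.abundance_min
        rows.append(
            (
                asv, hm_l, hm_c, hm_l - hm_c, ratio, delta_cm,
                ok_ratio, ok_shift, ok_abund,
                ok_ratio and ok_shift and ok_abund,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "asv_id", "heavy_mean_labeled", "heavy_mean_control",
            "enrichment_diff", "enrichment_ratio", "delta_center_of_mass",
            "meets_ratio", "meets_shift", "meets_abundance", "labeled",
        ],
    ).set_index("asv_id")
    order = np.lexsort((out.index, -out["enrichment_diff"].to_numpy()))
    ranks = np.empty(len(out), int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out
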