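"""Synthetic microcosm experiment generator.

Produces the three data products the analysis stages consume, with the
statistical structure those stages assume:

* phase-structured first-order SMX degradation curves with dose re-additions,
* multi-treatment, multi-day ASV count tables with planted responders and an
  inoculant whose abundance tracks substrate availability, and
* paired 13C/12C CsCl density-gradient fraction profiles in which labelled
  taxa shift toward heavier fractions in proportion to their 13C uptake.

All randomness flows from explicit seeds; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import CountTable, DegradationSeries, GradientFractionSet
from .design import (
    CommunityConfig,
    ExperimentDesign,
    KineticsParams,
    LabelConfig,
)

__all__ = [
    "simulate_degradation",
    "simulate_community",
    "simulate_gradient",
    "planted_sip_experiment",
    "random_coalescent_tree",
]

# Schildkraut relation: unlabelled buoyant density of DNA vs GC fraction.
BD_INTERCEPT = 1.660
BD_GC_SLOPE = 0.098


def unlabeled_buoyant_density(gc: float | np.ndarray) -> float | np.ndarray:
    """Buoyant density (g/mL) of unlabelled DNA at GC fraction ``gc``."""
    return BD_INTERCEPT + BD_GC_SLOPE * np.asarray(gc, float)


def _child_rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


# ----------------------------------------------------------------------
# degradation curves
# ----------------------------------------------------------------------

def simulate_degradation(
    design: ExperimentDesign,
    params: KineticsParams,
    seed: int | None = None,
) -> DegradationSeries:
    """Simulate SMX concentration trajectories for every SMX-amended treatment.

    Within each phase the true concentration decays as
    ``C(t) = C_start * exp(-(k_abiotic + k_bio) * dt)`` with the biotic term
    switched on only after the treatment's induction lag; each dosing day
    resets the concentration to residual + dose.  Recorded values carry
    multiplicative Gaussian measurement noise (CV = ``noise_cv``), truncated
    at zero; the noise is observational and does not propagate.
    """
    if seed is None:
        seed = design.seed
    rng = _child_rng(seed, 1)
    records: list[tuple] = []
    for treatment in design.smx_treatments:
        lag = params.lag(treatment)
        for rep in range(1, design.replicates + 1):
            conc = 0.0
            for phase, t0, t1 in design.phases:
                if any(math.isclose(t0, d) for d in design.dosing_days):
                    conc += design.dose_mg_per_l
                k_bio = params.rate(treatment, phase)
                times = sorted(
                    {t for t in design.measurement_days if t0 - 1e-12 <= t <= t1 + 1e-12}
                    | {t0, t1}
                )
                prev = t0
                for t in times:
                    if t > prev:
                        decay = params.k_abiotic * (t - prev)
                        decay += k_bio * max(0.0, t - max(prev, lag))
                        conc *= math.exp(-decay)
                        prev = t
                    obs = conc
                    if params.noise_cv > 0:
                        obs = max(0.0, conc * (1.0 + params.noise_cv * rng.standard_normal()))
                    records.append((treatment, rep, t, phase, obs))
    data = pd.DataFrame(
        records, columns=["treatment", "replicate", "day", "phase", "smx_mg_per_l"]
    )
    return DegradationSeries(
        data=data,
        phase_bounds=dict(design.phase_bounds),
        dose_mg_per_l=design.dose_mg_per_l,
        dosing_days=tuple(design.dosing_days),
    )


# ----------------------------------------------------------------------
# community tables
# ----------------------------------------------------------------------

def latent_abundances(
    design: ExperimentDesign,
    config: CommunityConfig,
    degradation: DegradationSeries,
    treatment: str,
    replicate: int,
    day: float,
    base: np.ndarray,
    jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Expected (latent) relative abundances for one community sample.

    This is the closed-form trajectory underlying the multinomial draws:
    log-normal baselines, responder effects scaled by the fraction of added
    SMX already degraded, and the inoculant share decaying with time spent
    below the quantification limit.  Exposed so tests and users can compare
    sampled counts against their expectation.
    """
    asv_ids = config.asv_ids()
    index = {a: i for i, a in enumerate(asv_ids)}
    latent = base.astype(float).copy()
    if jitter is not None:
        latent = latent * jitter
    f_deg = degradation.degraded_fraction(treatment, replicate, day)
    for resp in config.responders:
        if resp.treatment != treatment:
            continue
        if resp.asv_id not in index:
            raise ValueError(f"responder references unknown ASV {resp.asv_id!r}")
        latent[index[resp.asv_id]] *= math.exp(resp.effect_size * f_deg)
    p = latent / latent.sum()
    inoc = config.inoculants.get(treatment)
    if inoc is not None:
        if inoc.asv_id not in index:
            raise ValueError(f"inoculant references unknown ASV {inoc.asv_id!r}")
        t_dep = degradation.time_depleted(treatment, replicate, day, config.loq_mg_per_l)
        share = inoc.initial_fraction * math.exp(-inoc.decay_per_day * t_dep)
        i = index[inoc.asv_id]
        rest = p.sum() - p[i]
        p = p * (1.0 - share) / rest if rest > 0 else p
        p[i] = share
        p = p / p.sum()
    return p


def simulate_community(
    design: ExperimentDesign,
    config: CommunityConfig,
    degradation: DegradationSeries,
    seed: int | None = None,
) -> CountTable:
    """Draw one ASV count vector per (treatment, sampling day, replicate).

    Counts are multinomial at ``config.depth`` around the latent relative
    abundances of :func:`latent_abundances`.  Two per-sample noise layers sit
    on top of the latent expectations: an independent log-normal jitter
    (sd ``sample_jitter_sd``) and a shared guild factor — each ASV belongs
    to one of ``n_guilds`` guilds and scales with its guild's per-sample
    log-normal factor through a per-ASV coupling weight and sign — which
    plants the correlated co-abundance blocks the network stage looks for.
    """
    if seed is None:
        seed = design.seed
    for resp in config.responders:
        if resp.asv_id not in set(config.asv_ids()):
            raise ValueError(f"responder references unknown ASV {resp.asv_id!r}")
    mu, sd = config.base_lognormal
    base_rng = _child_rng(seed, 2, 0)
    base = base_rng.lognormal(mu, sd, config.n_asvs)
    guild_rng = _child_rng(seed, 2, 2)
    if config.n_guilds > 0:
        guild_of = guild_rng.integers(0, config.n_guilds, config.n_asvs)
        loading = np.where(
            guild_rng.random(config.n_asvs) < config.guild_neg_fraction, -1.0, 1.0
        )
        coupling = guild_rng.uniform(*config.guild_coupling_range, config.n_asvs)
    asv_ids = config.asv_ids()
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    sample_rng = _child_rng(seed, 2, 1)
    for treatment in design.community_treatments:
        for day in design.sampling_days:
            for rep in range(1, design.replicates + 1):
                jitter = (
                    sample_rng.lognormal(0.0, config.sample_jitter_sd, config.n_asvs)
                    if config.sample_jitter_sd > 0
                    else np.ones(config.n_asvs)
                )
                if config.n_guilds > 0 and config.guild_sd > 0:
                    z = sample_rng.normal(0.0, config.guild_sd, config.n_guilds)
                    jitter = jitter * np.exp(loading * coupling * z[guild_of])
                p = latent_abundances(
                    design, config, degradation, treatment, rep, day, base, jitter
                )
                counts = sample_rng.multinomial(config.depth, p)
                sid = f"{treatment}.d{day:g}.r{rep}"
                cols[sid] = counts
                meta_rows.append((sid, treatment, day, rep))
    counts = pd.DataFrame(cols, index=asv_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "treatment", "day", "replicate"]
    ).set_index("sample_id")
    return CountTable(counts, metadata)


# ----------------------------------------------------------------------
# CsCl gradients
# ----------------------------------------------------------------------

def _fraction_edges(config: LabelConfig) -> np.ndarray:
    lo, hi = config.bd_range
    edges = np.linspace(lo, hi, config.n_fractions + 1)
    if config.heavy_first:
        edges = edges[::-1]
    return edges


def fraction_midpoints(config: LabelConfig) -> np.ndarray:
    """Buoyant-density midpoints of the fractions, in index order."""
    edges = _fraction_edges(config)
    return (edges[:-1] + edges[1:]) / 2.0


def _spread_matrix(bd_centers: np.ndarray, config: LabelConfig) -> np.ndarray:
    """Share of each ASV's DNA mass landing in each fraction.

    Gaussian spread (sd ``gradient_sd``) integrated over fraction bins; the
    two outermost bins are extended to +/-inf so mass outside the gradient
    accumulates at the edge fractions (rows sum to 1 exactly).
    """
    edges = _fraction_edges(config)
    n = config.n_fractions
    hi = np.empty(n)
    lo = np.empty(n)
    for j in range(n):
        a, b = edges[j], edges[j + 1]
        hi[j], lo[j] = max(a, b), min(a, b)
    hi[np.argmax(hi)] = np.inf
    lo[np.argmin(lo)] = -np.inf
    z_hi = norm.cdf((hi[None, :] - bd_centers[:, None]) / config.gradient_sd)
    z_lo = norm.cdf((lo[None, :] - bd_centers[:, None]) / config.gradient_sd)
    return z_hi - z_lo


def expected_gradient_profile(
    counts: pd.Series,
    gc_content: pd.Series,
    config: LabelConfig,
    labeled: bool,
) -> pd.DataFrame:
    """Expected per-fraction DNA-mass shares (ASV x fraction), before sampling."""
    asvs = list(counts.index)
    gc = gc_content.loc[asvs].to_numpy(float)
    bd = unlabeled_buoyant_density(gc)
    if labeled:
        shift = np.array(
            [config.atom_fraction_excess.get(a, 0.0) * config.max_density_shift for a in asvs]
        )
        bd = bd + shift
    lo, hi = config.bd_range
    out_of_range = (bd < lo - 1e-12) | (bd > hi + 1e-12)
    if out_of_range.any():
        offenders = [asvs[i] for i in np.flatnonzero(out_of_range)]
        warnings.warn(
            f"{len(offenders)} ASV buoyant densities fall outside the gradient "
            f"range {config.bd_range}; their mass accumulates in the edge fractions "
            f"(e.g. {offenders[:3]})"
        )
    spread = _spread_matrix(bd, config)
    mass_share = counts.to_numpy(float) / counts.to_numpy(float).sum()
    mass = mass_share[:, None] * spread
    return pd.DataFrame(mass, index=asvs, columns=range(1, config.n_fractions + 1))


def _one_gradient(
    counts: pd.Series,
    gc_content: pd.Series,
    config: LabelConfig,
    qpcr_total: float,
    labeled: bool,
    isotope: str,
    microcosm_id: str,
    rng: np.random.Generator,
) -> GradientFractionSet:
    mass = expected_gradient_profile(counts, gc_content, config, labeled)
    frac_mass = mass.sum(axis=0).to_numpy()
    total = frac_mass.sum()
    copies = qpcr_total * frac_mass / total
    # exact conservation: push float residue onto the largest fraction
    copies[np.argmax(copies)] += qpcr_total - copies.sum()
    frac_counts = np.zeros((len(mass), config.n_fractions), dtype=np.int64)
    for j in range(config.n_fractions):
        col = mass.iloc[:, j].to_numpy()
        if col.sum() <= 0:
            continue
        frac_counts[:, j] = rng.multinomial(config.fraction_depth, col / col.sum())
    mids = fraction_midpoints(config)
    fractions = pd.DataFrame(
        {"buoyant_density": mids, "total_16s_copies": copies},
        index=pd.Index(range(1, config.n_fractions + 1), name="fraction"),
    )
    counts_df = pd.DataFrame(
        frac_counts, index=mass.index, columns=fractions.index
    )
    return GradientFractionSet(
        microcosm_id=microcosm_id,
        isotope=isotope,
        fractions=fractions,
        counts=counts_df,
        sequenced_window=config.sequenced_window,
        heavy_first=config.heavy_first,
    )


def simulate_gradient(
    counts: pd.Series,
    gc_content: pd.Series,
    config: LabelConfig,
    qpcr_total: float = 1e8,
    seed: int = 0,
    microcosm_id: str = "microcosm",
) -> tuple[GradientFractionSet, GradientFractionSet]:
    """Simulate a paired (13C-labelled, 12C-control) gradient fractionation.

    ``counts`` is the community sampled into both parallel microcosms;
    labelled ASVs shift by ``atom_fraction_excess * max_density_shift`` in
    the 13C set only.  Per-fraction 16S copies split ``qpcr_total`` by DNA
    mass share (summing to it exactly); per-fraction ASV counts are
    multinomial at ``config.fraction_depth``.
    """
    if counts.sum() <= 0:
        raise ValueError("community sample is empty")
    missing = [a for a in counts.index if a not in gc_content.index]
    if missing:
        raise ValueError(f"ASVs lacking GC content: {missing[:5]}")
    labeled = _one_gradient(
        counts, gc_content, config, qpcr_total, True, "13C", microcosm_id,
        _child_rng(seed, 3, 0),
    )
    control = _one_gradient(
        counts, gc_content, config, qpcr_total, False, "12C", microcosm_id,
        _child_rng(seed, 3, 1),
    )
    return labeled, control


def planted_sip_experiment(
    n_asvs: int = 100,
    n_labeled: int = 5,
    afe_range: tuple[float, float] = (0.5, 1.0),
    labeled_share_range: tuple[float, float] = (0.05, 0.10),
    labeled_gc_range: tuple[float, float] = (0.45, 0.55),
    depth: int = 10_000,
    qpcr_total: float = 1e8,
    seed: int = 0,
    config: LabelConfig | None = None,
) -> tuple[GradientFractionSet, GradientFractionSet, frozenset[str]]:
    """One SIP incubation with known ground truth, for caller evaluation.

    Community abundances are log-normal; the ``n_labeled`` planted
    degraders have bloomed on the substrate (each holding a
    ``labeled_share_range`` share of the community) and carry mid-GC
    genomes (``labeled_gc_range``).  The GC window matters: heavy-fraction
    enrichment can only reveal taxa whose *unlabelled* DNA is light enough
    to stay out of the heavy fractions while their labelled DNA moves in,
    so detectable-by-construction degraders sit in the mid-GC band (an
    intrinsic property of gradient SIP, not of this implementation).  Atom
    fraction excess is uniform over ``afe_range``.  Returns the paired
    13C/12C gradient sets and the planted labelled ASV ids.

    Setting ``afe_range=(0, 0)`` gives the no-label null (every taxon
    unshifted) for false-positive-rate studies.
    """
    rng = _child_rng(seed, 5)
    width = len(str(n_asvs))
    asvs = [f"ASV{i + 1:0{width}d}" for i in range(n_asvs)]
    labeled_ids = list(rng.choice(asvs, size=n_labeled, replace=False))
    base = rng.lognormal(0.0, 1.5, n_asvs)
    p = pd.Series(base / base.sum(), index=asvs)
    shares = rng.uniform(*labeled_share_range, size=n_labeled)
    p[labeled_ids] = 0.0
    p = p / p.sum() * (1.0 - shares.sum())
    p[labeled_ids] = shares
    counts = pd.Series(rng.multinomial(depth, p.to_numpy()), index=asvs)
    gc = pd.Series(rng.uniform(0.3, 0.75, n_asvs), index=asvs)
    gc[labeled_ids] = rng.uniform(*labeled_gc_range, size=n_labeled)
    afe = {a: float(rng.uniform(*afe_range)) for a in labeled_ids}
    base_cfg = config or LabelConfig()
    cfg = LabelConfig(
        atom_fraction_excess=afe,
        max_density_shift=base_cfg.max_density_shift,
        n_fractions=base_cfg.n_fractions,
        bd_range=base_cfg.bd_range,
        gradient_sd=base_cfg.gradient_sd,
        fraction_depth=depth,
        sequenced_window=base_cfg.sequenced_window,
        heavy_first=base_cfg.heavy_first,
    )
    labeled, control = simulate_gradient(
        counts, gc, cfg, qpcr_total=qpcr_total, seed=int(rng.integers(2**31))
    )
    truly = frozenset(a for a, f in afe.items() if f > 0)
    return labeled, control, truly


# ----------------------------------------------------------------------
# phylogeny for the simulated ASVs
# ----------------------------------------------------------------------

def random_coalescent_tree(asv_ids: list[str], seed: int = 0) -> str:
    """Random rooted bifurcating tree over ``asv_ids``, as a newick string.

    Standard coalescent construction: lineages merge pairwise at
    exponentially distributed waiting times with rate C(k, 2); branch
    lengths are differences of node heights.  Used to give simulated ASV
    tables a phylogeny for UniFrac.
    """
    if len(asv_ids) < 2:
        raise ValueError("need at least two taxa")
    rng = _child_rng(seed, 4)
    nodes = [(str(a), 0.0) for a in asv_ids]  # (newick fragment, height)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_i, h_i) = nodes[i]
        (nwk_j, h_j) = nodes[j]
        merged = f"({nwk_i}:{height - h_i:.6f},{nwk_j}:{height - h_j:.6f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"
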