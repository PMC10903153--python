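"""End-to-end workflow: simulate -> kinetics -> community stats -> networks -> SIP.

A :class:`RunConfig` validates every stage's parameters up front, expands
one global seed into per-stage child seeds, executes the selected stages,
and records every output file (with a SHA-256 digest) plus the headline
scalar results in a JSON manifest.  Identical config + seed reproduces
identical digests for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .containers import CountTable
from .design import (
    NON_INOC,
    NON_SMX,
    PAEN_INOC,
    PSEU_INOC,
    CommunityConfig,
    ExperimentDesign,
    Inoculant,
    KineticsParams,
    LabelConfig,
    Responder,
)
from .diversity import alpha_diversity, diff_abundance, pcoa, permanova, weighted_unifrac
from .kinetics import kinetics_report
from .network import (
    build_network,
    classify_topology,
    detect_modules,
    equivalent_random_loss,
    keystone_ids,
    network_properties,
    robustness_random,
    robustness_targeted,
    zi_pi,
)
from .sip import CallParams, identify_labeled
from .synth import (
    random_coalescent_tree,
    simulate_community,
    simulate_degradation,
    simulate_gradient,
)

__all__ = ["RunConfig", "demo_config", "run_pipeline", "load_config"]

STAGES = ("simulate", "kinetics", "commstats", "network", "sip")


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    label: LabelConfig = field(default_factory=LabelConfig)
    #: labelled-ASV count planted per inoculated treatment's SIP incubation
    sip_n_labeled: dict[str, int] = field(
        default_factory=lambda: {PSEU_INOC: 23, PAEN_INOC: 4}
    )
    sip_labeled_total_share: float = 0.6
    rho_threshold: float = 0.6
    min_prevalence: float = 0.5
    n_permutations: int = 999
    n_mc_instances: int = 8
    robustness_reps: int = 50
    qpcr_total: float = 1e8
    call_params: CallParams = field(default_factory=CallParams)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) in config: {unknown}; valid: {list(STAGES)}")
        if not (0 < self.rho_threshold):
            raise ValueError("rho_threshold must be positive")
        if self.n_permutations < 1 or self.robustness_reps < 1:
            raise ValueError("permutations and robustness replicates must be >= 1")
        if not (0 < self.sip_labeled_total_share < 1):
            raise ValueError("sip_labeled_total_share must lie in (0, 1)")
        for trt, n in self.sip_n_labeled.items():
            if trt not in self.design.inoculated_treatments:
                raise ValueError(f"SIP treatment {trt!r} is not inoculated in the design")
            if not (1 <= n < self.community.n_asvs):
                raise ValueError(f"invalid labelled-ASV count for {trt!r}")


def demo_config(outdir, seed: int = 0) -> RunConfig:
    """The bundled demonstration experiment.

    Five treatments, three replicates, 120 ASVs at depth 10^4, with an
    inoculant per bioaugmented treatment (starting near 20 % of the
    community), planted positive and negative responders coupled to SMX
    degradation, and SIP incubations planting 23 (Pseudomonas system) and 4
    (Paenarthrobacter system) labelled ASVs.
    """
    design = ExperimentDesign(seed=seed)
    responders = []
    for trt in (NON_INOC, PSEU_INOC, PAEN_INOC):
        responders += [
            Responder("ASV003", trt, 2.0),    # enriched by SMX in every amended system
            Responder("ASV005", trt, -1.6),   # suppressed by SMX
            Responder("ASV006", trt, -1.2),
        ]
    responders += [
        Responder("ASV004", NON_INOC, 1.6),
        Responder("ASV007", PAEN_INOC, 1.8),
        Responder("ASV008", PSEU_INOC, 1.4),
    ]
    community = CommunityConfig(
        n_asvs=120,
        responders=tuple(responders),
        inoculants={
            PSEU_INOC: Inoculant("ASV001", 0.2, 0.25),
            PAEN_INOC: Inoculant("ASV002", 0.2, 0.3),
        },
        depth=10_000,
    )
    return RunConfig(outdir=Path(outdir), seed=seed, design=design, community=community)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "outdir" not in raw:
        raise ValueError("config must set 'outdir'")
    kwargs["outdir"] = raw.pop("outdir")
    for key, cls in (
        ("design", ExperimentDesign),
        ("kinetics", KineticsParams),
        ("community", CommunityConfig),
        ("label", LabelConfig),
        ("call_params", CallParams),
    ):
        if key in raw:
            section = raw.pop(key)
            if key == "community":
                section = dict(section)
                section["responders"] = tuple(
                    Responder(**r) for r in section.get("responders", [])
                )
                section["inoculants"] = {
                    t: Inoculant(**v) for t, v in section.get("inoculants", {}).items()
                }
            kwargs[key] = cls(**section)
    if "stages" in raw:
        kwargs["stages"] = tuple(raw.pop("stages"))
    kwargs.update(raw)
    return RunConfig(**kwargs)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    echo = clean(config)
    echo.pop("outdir", None)  # implicit in the echo file's location
    return echo


def _sip_community(
    table: CountTable,
    treatment: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, dict[str, float]]:
    """Community of one SIP incubation, with its planted labelled ASVs.

    Starts from the treatment's final-day sample and lets the labelled taxa
    bloom on the 13C substrate: the labelled set (the inoculated degrader of
    the other system plus taxa drawn from the high-GC half of the community,
    where sulfonamide degraders concentrate) takes
    ``sip_labeled_total_share`` of the community, split in proportion to
    atom fraction excess; the rest keeps its final-day composition.
    """
    n_labeled = config.sip_n_labeled[treatment]
    meta = table.metadata
    last_day = meta.loc[meta["treatment"] == treatment, "day"].max()
    sid = meta.index[(meta["treatment"] == treatment) & (meta["day"] == last_day)][0]
    base = table.counts[sid].astype(float)
    gc = _gc_series(config)
    # the indigenous degrader (the Paenarthrobacter-like inoculant) is always
    # labelled; the inoculated Pseudomonas analogue is famously not
    always = [a for a in ("ASV002",) if a in base.index]
    exclude = {"ASV001"}
    # detectable degraders occupy the mid-GC band: their unlabelled DNA must
    # stay out of the heavy fractions while their labelled DNA moves in
    pool = [
        a for a in base.index
        if a not in exclude and a not in always and 0.45 <= gc[a] <= 0.60
    ]
    chosen = always + list(rng.choice(pool, size=n_labeled - len(always), replace=False))
    afe = {a: float(rng.uniform(0.5, 1.0)) for a in chosen}
    weights = np.array([afe[a] * rng.lognormal(0.0, 0.5) for a in chosen])
    labeled_share = config.sip_labeled_total_share * weights / weights.sum()
    p = base / base.sum()
    p[chosen] = 0.0
    p = p / p.sum() * (1.0 - config.sip_labeled_total_share)
    p[chosen] = labeled_share
    counts = pd.Series(
        rng.multinomial(config.community.depth, p.to_numpy()), index=p.index
    )
    return counts, afe


def _gc_series(config: RunConfig) -> pd.Series:
    ids = config.community.asv_ids()
    if config.community.gc_content is not None:
        gc = np.asarray(config.community.gc_content, float)
    else:
        lo, hi = config.community.gc_range
        gc_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
        gc = gc_rng.uniform(lo, hi, len(ids))
    return pd.Series(gc, index=ids)


# ----------------------------------------------------------------------
# the pipeline
# ----------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; return (and write) the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: int(s.generate_state(1)[0] % (2**31))
        for stage, s in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _config_echo(config),
        "files": {},
        "results": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"pipeline stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    table = degradation = tree_newick = None
    gradients = {}

    # --- simulate ------------------------------------------------------
    if "simulate" in config.stages:
        try:
            degradation = simulate_degradation(config.design, config.kinetics,
                                               seed=seeds["simulate"])
            table = simulate_community(config.design, config.community, degradation,
                                       seed=seeds["simulate"])
            tree_newick = random_coalescent_tree(config.community.asv_ids(),
                                                 seed=seeds["simulate"])
            gc = _gc_series(config)
            rng = np.random.default_rng(np.random.SeedSequence([seeds["simulate"], 7]))
            for trt in sorted(config.sip_n_labeled):
                counts, afe = _sip_community(table, trt, config, rng)
                label_cfg = dataclasses.replace(config.label, atom_fraction_excess=afe)
                labeled, control = simulate_gradient(
                    counts, gc, label_cfg, qpcr_total=config.qpcr_total,
                    seed=int(rng.integers(2**31)), microcosm_id=trt,
                )
                gradients[trt] = (labeled, control, set(afe))
        except Exception as exc:  # noqa: BLE001
            raise fail("simulate", exc)
        sio.write_count_table(table, out / "counts.tsv", out / "metadata.tsv")
        sio.write_degradation(degradation, out / "degradation.csv")
        sio.write_tree(tree_newick, out / "tree.nwk")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_echo(config), fh, sort_keys=True)
        record("counts", out / "counts.tsv")
        record("metadata", out / "metadata.tsv")
        record("degradation", out / "degradation.csv")
        record("tree", out / "tree.nwk")
        record("config", out / "config.yaml")
        for trt, (labeled, control, truth) in gradients.items():
            tag = trt.replace(".", "_")
            sio.write_fraction_table(labeled, out / f"sip_{tag}_13C.tsv")
            sio.write_fraction_table(control, out / f"sip_{tag}_12C.tsv")
            record(f"sip_{tag}_13C", out / f"sip_{tag}_13C.tsv")
            record(f"sip_{tag}_12C", out / f"sip_{tag}_12C.tsv")
            manifest["results"][f"sip_{tag}_planted_labeled"] = sorted(truth)

    # --- kinetics ------------------------------------------------------
    if "kinetics" in config.stages:
        if degradation is None:
            raise fail("kinetics", ValueError("no degradation series; run simulate first"))
        try:
            report = kinetics_report(degradation, reference_treatment=NON_INOC)
        except Exception as exc:  # noqa: BLE001
            raise fail("kinetics", exc)
        report.to_csv(out / "kinetics.tsv", sep="\t", index=False)
        record("kinetics", out / "kinetics.tsv")
        manifest["results"]["removal_pct_phase_I"] = {
            row["treatment"]: round(row["removal_pct"], 3)
            for _, row in report[report["phase"] == "I"].iterrows()
        }

    # --- community statistics -----------------------------------------
    if "commstats" in config.stages:
        if table is None:
            raise fail("commstats", ValueError("no count table; run simulate first"))
        try:
            alpha = alpha_diversity(table)
            tree = sio.read_tree(out / "tree.nwk") if tree_newick else None
            dist = weighted_unifrac(table, tree)
            ord_res = pcoa(dist)
            perm = permanova(
                dist, table.metadata["treatment"],
                n_permutations=config.n_permutations, seed=seeds["commstats"],
            )
            comparisons = {}
            meta = table.metadata
            pairs = [(NON_SMX, NON_INOC), (NON_INOC, PSEU_INOC), (NON_INOC, PAEN_INOC)]
            for a, b in pairs:
                ga = list(meta.index[meta["treatment"] == a])
                gb = list(meta.index[meta["treatment"] == b])
                if len(ga) < 2 or len(gb) < 2:
                    continue
                res = diff_abundance(
                    table, ga, gb, n_mc_instances=config.n_mc_instances,
                    seed=seeds["commstats"],
                )
                comparisons[f"{a}_vs_{b}"] = res
        except Exception as exc:  # noqa: BLE001
            raise fail("commstats", exc)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(
            out / "weighted_unifrac.tsv", sep="\t"
        )
        ord_res.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
        record("alpha_diversity", out / "alpha_diversity.tsv")
        record("weighted_unifrac", out / "weighted_unifrac.tsv")
        record("pcoa", out / "pcoa.tsv")
        for name, res in comparisons.items():
            path = out / f"diffabund_{name.replace('.', '_')}.tsv"
            res.to_csv(path, sep="\t")
            record(f"diffabund_{name}", path)
        manifest["results"]["permanova"] = {
            "pseudo_F": round(perm.pseudo_f, 4),
            "R2": round(perm.r_squared, 4),
            "p": perm.p_value,
        }

    # --- networks ------------------------------------------------------
    if "network" in config.stages:
        if table is None:
            raise fail("network", ValueError("no count table; run simulate first"))
        net_results = {}
        for trt in config.design.community_treatments:
            try:
                net = build_network(
                    table, trt,
                    rho_threshold=config.rho_threshold,
                    min_prevalence=config.min_prevalence,
                )
                if net.graph.number_of_edges() == 0:
                    warnings.warn(f"{trt!r} network is empty at |rho|>{config.rho_threshold}")
                    continue
                modules, q = detect_modules(net)
                roles = classify_topology(zi_pi(net, modules))
                ks = keystone_ids(roles)
                props = network_properties(net)
                rand_curve = robustness_random(
                    net, max_removed=len(net.nodes) // 2,
                    n_reps=config.robustness_reps, seed=seeds["network"],
                )
                curves = [rand_curve.to_frame()]
                summary = {"keystones": ks, **{k: round(v, 4) for k, v in props.items()}}
                if ks:
                    curves.append(robustness_targeted(net, ks).to_frame())
                    n_eq, pct = equivalent_random_loss(
                        net, ks, n_reps=config.robustness_reps, seed=seeds["network"],
                    )
                    summary["equivalent_random_loss_n"] = n_eq
                    summary["targeted_drop_pct"] = round(pct, 2)
            except Exception as exc:  # noqa: BLE001
                raise fail("network", exc)
            tag = trt.replace(".", "_")
            sio.write_edge_list(net, out / f"network_{tag}_edges.tsv")
            sio.write_node_attributes(roles, out / f"network_{tag}_nodes.tsv")
            pd.concat(curves, ignore_index=True).to_csv(
                out / f"network_{tag}_robustness.tsv", sep="\t", index=False
            )
            record(f"network_{tag}_edges", out / f"network_{tag}_edges.tsv")
            record(f"network_{tag}_nodes", out / f"network_{tag}_nodes.tsv")
            record(f"network_{tag}_robustness", out / f"network_{tag}_robustness.tsv")
            net_results[trt] = summary
        manifest["results"]["networks"] = net_results

    # --- SIP -----------------------------------------------------------
    if "sip" in config.stages:
        if not gradients:
            raise fail("sip", ValueError("no gradient sets; run simulate first"))
        sip_results = {}
        for trt, (labeled, control, truth) in gradients.items():
            try:
                calls = identify_labeled(labeled, control, config.call_params)
            except Exception as exc:  # noqa: BLE001
                raise fail("sip", exc)
            tag = trt.replace(".", "_")
            calls.to_csv(out / f"sip_{tag}_calls.tsv", sep="\t")
            record(f"sip_{tag}_calls", out / f"sip_{tag}_calls.tsv")
            called = set(calls.index[calls["labeled"]])
            sip_results[trt] = {
                "n_planted": len(truth),
                "n_called": len(called),
                "n_true_positive": len(called & truth),
                "n_false_positive": len(called - truth),
            }
        manifest["results"]["sip"] = sip_results

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
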