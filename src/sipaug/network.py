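"""Co-occurrence networks, topological roles, and spectral robustness.

Builds Pearson-correlation networks per treatment (|rho| above a fixed
threshold, sign retained), detects modules by greedy modularity
maximization, classifies node roles from within-module connectivity (Zi)
and among-module connectivity (Pi), and quantifies structural robustness by
natural connectivity under random versus targeted (keystone) node removal,
including the "equivalent random loss" statistic: how many random removals
the loss of the keystones is worth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import CountTable

__all__ = [
    "EcoNetwork",
    "build_network",
    "detect_modules",
    "zi_pi",
    "classify_topology",
    "keystone_ids",
    "natural_connectivity",
    "robustness_random",
    "robustness_targeted",
    "equivalent_random_loss",
    "network_properties",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
ROLES = ("peripheral", "connector", "module_hub", "network_hub")


@dataclass
class EcoNetwork:
    """Thresholded signed correlation graph for one treatment."""

    graph: nx.Graph
    treatment: str
    rho_threshold: float
    modules: dict[str, int] | None = None
    modularity: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def adjacency(self, nodes: list[str] | None = None) -> np.ndarray:
        """Unsigned, unweighted adjacency matrix in sorted node order."""
        nodes = sorted(self.graph.nodes) if nodes is None else nodes
        return nx.to_numpy_array(self.graph, nodelist=nodes, weight=None)


def build_network(
    table: CountTable,
    treatment: str,
    rho_threshold: float = 0.6,
    min_prevalence: float = 0.5,
    positive_only: bool = False,
) -> EcoNetwork:
    """Pearson co-occurrence network for one treatment's samples.

    Correlations are computed between ASV relative-abundance profiles over
    all of the treatment's samples (time points x replicates).  An edge is
    kept when |rho| exceeds ``rho_threshold`` (strictly); the signed rho is
    stored on the edge.  ASVs present in fewer than ``min_prevalence`` of
    the samples are dropped, constant profiles are excluded (undefined
    correlation), and isolated nodes are removed from the result.
    """
    sub = table.for_treatment(treatment)
    if len(sub.sample_ids) < 5:
        raise ValueError(
            f"treatment {treatment!r} has {len(sub.sample_ids)} samples; >=5 required"
        )
    rel = sub.relative_abundance()
    prevalence = (rel > 0).mean(axis=1)
    rel = rel.loc[prevalence >= min_prevalence]
    profiles = rel.to_numpy()
    keep = profiles.std(axis=1) > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant-abundance ASV(s) "
            f"from the {treatment!r} network (undefined correlation)"
        )
    rel = rel.loc[keep]
    asvs = list(rel.index)
    g = nx.Graph()
    if len(asvs) >= 2:
        rho = np.corrcoef(rel.to_numpy())
        iu, ju = np.triu_indices(len(asvs), k=1)
        for i, j in zip(iu, ju):
            r = rho[i, j]
            if positive_only:
                keep_edge = r > rho_threshold
            else:
                keep_edge = abs(r) > rho_threshold
            if keep_edge:
                g.add_edge(asvs[i], asvs[j], rho=float(r), sign=1 if r > 0 else -1)
    return EcoNetwork(graph=g, treatment=treatment, rho_threshold=rho_threshold)


def detect_modules(net: EcoNetwork, seed: int | None = None) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization on the unsigned graph.

    Deterministic: the greedy agglomeration itself is seedless, and module
    ids are assigned in order of decreasing size with ties broken by lowest
    member node id.  Returns ``(node -> module id, modularity Q)`` and
    stores both on the network.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        net.modules, net.modularity = {}, 0.0
        return {}, 0.0
    comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    modules = {node: i for i, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(g, comms)
    net.modules, net.modularity = modules, float(q)
    return modules, float(q)


def zi_pi(net: EcoNetwork, modules: dict[str, int] | None = None) -> pd.DataFrame:
    """Within-module (Zi) and among-module (Pi) connectivity per node.

    ``Zi = (k_is - mean_s) / sd_s`` where ``k_is`` is the node's degree
    inside its own module ``s`` and mean/sd run over the within-module
    degrees of that module's members (Zi = 0 by convention when sd = 0);
    ``Pi = 1 - sum_t (k_it / k_i)**2`` over modules ``t``.
    """
    modules = modules if modules is not None else net.modules
    if modules is None:
        raise ValueError("run detect_modules first or pass a module assignment")
    g = net.graph
    nodes = sorted(g.nodes)
    within_degree = {
        n: sum(1 for nb in g.neighbors(n) if modules[nb] == modules[n]) for n in nodes
    }
    by_module: dict[int, list[int]] = {}
    for n in nodes:
        by_module.setdefault(modules[n], []).append(within_degree[n])
    mod_stats = {
        m: (float(np.mean(ks)), float(np.std(ks, ddof=0))) for m, ks in by_module.items()
    }
    rows = []
    for n in nodes:
        mean_s, sd_s = mod_stats[modules[n]]
        zi = (within_degree[n] - mean_s) / sd_s if sd_s > 0 else 0.0
        k = g.degree(n)
        per_module: dict[int, int] = {}
        for nb in g.neighbors(n):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((kt / k) ** 2 for kt in per_module.values()) if k > 0 else 0.0
        rows.append((n, modules[n], k, within_degree[n], zi, pi))
    return pd.DataFrame(
        rows, columns=["node", "module", "degree", "within_degree", "zi", "pi"]
    ).set_index("node")


def classify_topology(
    records: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Assign topological roles from (Zi, Pi).

    Network hubs: Zi > 2.5 and Pi > 0.62; module hubs: Zi > 2.5 and
    Pi <= 0.62; connectors: Zi <= 2.5 and Pi > 0.62; peripheral otherwise.
    Both boundaries belong to the peripheral side (strict > semantics).
    Keystones are all non-peripheral nodes.
    """
    zi = records["zi"].to_numpy(float)
    pi = records["pi"].to_numpy(float)
    role = np.where(
        zi > zi_threshold,
        np.where(pi > pi_threshold, "network_hub", "module_hub"),
        np.where(pi > pi_threshold, "connector", "peripheral"),
    )
    out = records.copy()
    out["role"] = role
    out["keystone"] = role != "peripheral"
    return out


def keystone_ids(classified: pd.DataFrame) -> list[str]:
    """Keystone nodes in targeted-removal order.

    Module hubs first, then network hubs, then connectors; ties broken by
    descending degree, then node id.
    """
    priority = {"module_hub": 0, "network_hub": 1, "connector": 2}
    ks = classified[classified["keystone"]]
    order = sorted(
        ks.index,
        key=lambda n: (priority[ks.loc[n, "role"]], -int(ks.loc[n, "degree"]), n),
    )
    return order


# ----------------------------------------------------------------------
# natural connectivity and removal experiments
# ----------------------------------------------------------------------

def _natural_connectivity_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        return 0.0
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(n))


def natural_connectivity(net: EcoNetwork | nx.Graph) -> float:
    """Natural connectivity: ln of the mean of e^lambda over the eigenvalues
    of the unsigned, unweighted adjacency matrix (log-sum-exp, overflow safe).
    Defined as 0 for an empty or edgeless graph.
    """
    g = net.graph if isinstance(net, EcoNetwork) else net
    return _natural_connectivity_adj(nx.to_numpy_array(g, weight=None))


def _removal_curve(adj: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Natural connectivity after removing 0, 1, ... len(order) nodes.

    Isolated nodes are retained: N in the spectral average is the
    post-removal node count.
    """
    n = adj.shape[0]
    out = np.empty(len(order) + 1)
    keep = np.ones(n, bool)
    out[0] = _natural_connectivity_adj(adj)
    for m, idx in enumerate(order, start=1):
        keep[idx] = False
        out[m] = _natural_connectivity_adj(adj[np.ix_(keep, keep)])
    return out


@dataclass
class RobustnessCurve:
    """Natural connectivity as a function of the number of removed nodes."""

    mode: str                       # "random" | "targeted"
    n_removed: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None    # spread over replicates (random mode)
    removed: list[str] = field(default_factory=list)  # targeted order

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"n_removed": self.n_removed, "natural_connectivity": self.mean})
        if self.sd is not None:
            out["sd"] = self.sd
        out["mode"] = self.mode
        return out


def robustness_random(
    net: EcoNetwork,
    max_removed: int | None = None,
    n_reps: int = 200,
    seed: int | None = None,
) -> RobustnessCurve:
    """Mean natural-connectivity decay under uniform random node removal.

    Each replicate removes ``max_removed`` uniformly chosen nodes without
    replacement, recomputing natural connectivity after every removal;
    the curve averages the replicates.
    """
    nodes = net.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    max_removed = n if max_removed is None else min(max_removed, n)
    adj = net.adjacency(nodes)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_reps, max_removed + 1))
    for r in range(n_reps):
        order = rng.permutation(n)[:max_removed]
        curves[r] = _removal_curve(adj, order)
    return RobustnessCurve(
        mode="random",
        n_removed=np.arange(max_removed + 1),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(max_removed + 1),
    )


def robustness_targeted(net: EcoNetwork, keystones: list[str]) -> RobustnessCurve:
    """Natural connectivity after removing the given keystones in order."""
    nodes = net.nodes
    pos = {n: i for i, n in enumerate(nodes)}
    missing = [k for k in keystones if k not in pos]
    if missing:
        raise ValueError(f"keystones absent from the network: {missing}")
    adj = net.adjacency(nodes)
    order = np.array([pos[k] for k in keystones], dtype=int)
    curve = _removal_curve(adj, order)
    return RobustnessCurve(
        mode="targeted",
        n_removed=np.arange(len(keystones) + 1),
        mean=curve,
        removed=list(keystones),
    )


def equivalent_random_loss(
    net: EcoNetwork,
    keystones: list[str],
    n_reps: int = 200,
    seed: int | None = None,
) -> tuple[int, float]:
    """How many random removals the targeted keystone loss is worth.

    Returns ``(n_equiv, percent_drop)``: the percent natural-connectivity
    drop caused by removing the keystones, and the smallest random-removal
    count whose mean drop is at least as large.  An empty keystone set gives
    (0, 0); a network with zero natural connectivity has no defined drop.
    """
    lam0 = natural_connectivity(net)
    if lam0 <= 0:
        raise ValueError("natural connectivity of the intact network is 0; drop undefined")
    if not keystones:
        return 0, 0.0
    lam_t = robustness_targeted(net, keystones).mean[-1]
    drop = lam0 - lam_t
    percent = 100.0 * drop / lam0
    rand = robustness_random(net, max_removed=None, n_reps=n_reps, seed=seed)
    reached = np.flatnonzero(rand.mean <= lam_t + 1e-12)
    n_equiv = int(reached[0]) if len(reached) else len(net.nodes)
    return n_equiv, float(percent)


# ----------------------------------------------------------------------
# summary properties
# ----------------------------------------------------------------------

def network_properties(net: EcoNetwork) -> dict[str, float]:
    """Topological summary: size, average degree, clustering, average path
    distance (over the largest connected component), modularity, module
    count, and percent positive edges."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    props: dict[str, float] = {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n if n else 0.0,
        "average_clustering": nx.average_clustering(g) if n else 0.0,
    }
    if n:
        giant = g.subgraph(max(nx.connected_components(g), key=len))
        props["average_path_distance"] = (
            nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
        )
    else:
        props["average_path_distance"] = 0.0
    if net.modules is None:
        detect_modules(net)
    props["modularity"] = float(net.modularity or 0.0)
    props["n_modules"] = float(len(set(net.modules.values()))) if net.modules else 0.0
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    props["pct_positive_edges"] = 100.0 * pos / e if e else 0.0
    props["natural_connectivity"] = natural_connectivity(net)
    return props
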