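"""Alpha/beta diversity, ordination, PERMANOVA, and differential abundance.

The compositional workflow mirrors common amplicon practice: Shannon/
Pielou/observed-features alpha diversity, CLR transformation with a 0.5
pseudocount, Dirichlet-Monte-Carlo rank-sum differential abundance with
Benjamini-Hochberg correction, Bray-Curtis and normalized weighted UniFrac
distances, classical PCoA, and a permutation PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .containers import CountTable

__all__ = [
    "alpha_diversity",
    "clr_transform",
    "diff_abundance",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "PCoAResult",
    "permanova",
    "PermanovaResult",
]


# ----------------------------------------------------------------------
# alpha diversity
# ----------------------------------------------------------------------

def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed features, Shannon index (natural log) and Pielou evenness.

    Evenness is ``H / ln(observed)``; a single-taxon sample has undefined
    evenness (ln 1 = 0) and is reported as 0 with ``single_taxon`` set.
    """
    rel = table.relative_abundance().to_numpy().T  # samples x asvs
    observed = (rel > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    single = observed == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(single, 0.0, shannon / np.log(observed))
    return pd.DataFrame(
        {
            "observed_features": observed,
            "shannon": shannon,
            "pielou_evenness": evenness,
            "single_taxon": single,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


# ----------------------------------------------------------------------
# CLR and differential abundance
# ----------------------------------------------------------------------

def clr_transform(table: CountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform per sample (rows = ASVs, cols = samples).

    ``log((count + pseudocount) / g(count + pseudocount))`` with g the
    per-sample geometric mean; each sample's CLR values sum to 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = table.counts.to_numpy(float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)


def _clr_rows(mat: np.ndarray) -> np.ndarray:
    """CLR along axis 0 (features) of a strictly positive matrix."""
    logx = np.log(mat)
    return logx - logx.mean(axis=0, keepdims=True)


def diff_abundance(
    table: CountTable,
    group_a: list[str],
    group_b: list[str],
    n_mc_instances: int = 16,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """CLR / Wilcoxon rank-sum / BH differential abundance between two groups.

    With ``n_mc_instances > 0``, each instance draws per-sample Dirichlet
    (counts + ``pseudocount``) compositions, CLR-transforms them, and runs a
    two-sided rank-sum test per ASV; raw p-values are averaged across
    instances before BH correction (the posterior-averaged p of the
    ALDEx2-style procedure).  ``n_mc_instances = 0`` is the deterministic
    single-pass mode on pseudocount CLR values.

    Returns a frame indexed by ASV with ``clr_diff_median`` (group B minus
    group A), ``direction``, ``statistic``, ``p_raw``, ``p_adj`` and
    ``rank`` (1 = most significant; ties broken by larger |effect|).
    """
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) < 2:
            raise ValueError(f"{name} needs at least 2 samples")
        unknown = [s for s in grp if s not in set(table.sample_ids)]
        if unknown:
            raise ValueError(f"{name} references unknown samples: {unknown}")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    counts_a = table.counts[group_a].to_numpy(float)
    counts_b = table.counts[group_b].to_numpy(float)
    rng = np.random.default_rng(seed)

    def one_instance(det: bool) -> tuple[np.ndarray, np.ndarray]:
        if det:
            clr_a = _clr_rows(counts_a + pseudocount)
            clr_b = _clr_rows(counts_b + pseudocount)
        else:
            prop_a = np.column_stack(
                [rng.dirichlet(counts_a[:, j] + pseudocount) for j in range(counts_a.shape[1])]
            )
            prop_b = np.column_stack(
                [rng.dirichlet(counts_b[:, j] + pseudocount) for j in range(counts_b.shape[1])]
            )
            clr_a = _clr_rows(prop_a)
            clr_b = _clr_rows(prop_b)
        res = stats.mannwhitneyu(clr_a, clr_b, axis=1, alternative="two-sided")
        diff = np.median(clr_b, axis=1) - np.median(clr_a, axis=1)
        return np.asarray(res.pvalue, float), diff

    n_inst = max(1, n_mc_instances) if n_mc_instances > 0 else 1
    det = n_mc_instances == 0
    p_acc = np.zeros(len(table.asv_ids))
    d_acc = np.zeros(len(table.asv_ids))
    for _ in range(n_inst):
        p, d = one_instance(det)
        p_acc += p
        d_acc += d
    p_raw = p_acc / n_inst
    diff = d_acc / n_inst
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "clr_diff_median": diff,
            "direction": np.sign(diff).astype(int),
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=pd.Index(table.asv_ids, name="asv_id"),
    )
    order = np.lexsort((-np.abs(diff), p_raw, p_adj))
    ranks = np.empty(len(order), int)
    ranks[order] = np.arange(1, len(order) + 1)
    out["rank"] = ranks
    return out


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = table.relative_abundance().to_numpy().T
    return DistanceMatrix(squareform(pdist(rel, metric="braycurtis")), ids=table.sample_ids)


def _branch_table(tree: TreeNode, table: CountTable) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch descendant-abundance matrix.

    Returns ``(lengths, B)`` where ``B[b, s]`` is the relative abundance in
    sample ``s`` descending branch ``b`` (one branch per non-root node).
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [a for a in table.asv_ids if a not in tip_names]
    if missing:
        raise ValueError(f"ASVs absent from the tree: {missing}")
    rel = table.relative_abundance()
    n_samples = len(table.sample_ids)
    zero = np.zeros(n_samples)
    acc: dict[int, np.ndarray] = {}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = rel.loc[node.name].to_numpy() if node.name in rel.index else zero.copy()
        else:
            vec = zero.copy()
            for child in node.children:
                vec = vec + acc[id(child)]
        acc[id(node)] = vec
        if node.parent is not None:  # a branch hangs above every non-root node
            length = node.length or 0.0
            if length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")
            lengths.append(length)
            rows.append(vec)
    return np.asarray(lengths), np.asarray(rows)


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    ``sum_b len(b) * |p_A(b) - p_B(b)|``, optionally normalized by
    ``sum_b len(b) * (p_A(b) + p_B(b))`` so distances lie in [0, 1]
    (the package default).
    """
    lengths, B = _branch_table(tree, table)
    weighted = (lengths[:, None] * B).T  # samples x branches
    num = cdist(weighted, weighted, metric="cityblock")
    if normalized:
        s = weighted.sum(axis=1)
        den = s[:, None] + s[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
    else:
        d = num
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=table.sample_ids)


# ----------------------------------------------------------------------
# ordination
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame       # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # shares of the positive-eigenvalue total


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical scaling (principal coordinate analysis).

    Double-centers ``-D**2 / 2``; axes are ordered by eigenvalue, negative
    eigenvalues are reported but contribute no coordinates, and each axis's
    sign is fixed by making its largest-magnitude loading positive.
    """
    d2 = np.asarray(dist.data, float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutation multivariate ANOVA on a distance matrix.

    Pseudo-F from among/within sums of squared distances; the p-value uses
    the +1 correction ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    A design with a single group returns R² = 0 (nothing to partition);
    any group with fewer than 2 members raises.
    """
    labels = np.asarray(
        grouping.loc[list(dist.ids)] if isinstance(grouping, pd.Series) else grouping
    )
    n = len(dist.ids)
    if labels.shape != (n,):
        raise ValueError("grouping must give one label per sample")
    uniq, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    if np.any(sizes < 2):
        bad = uniq[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {bad}")
    k = len(uniq)
    d2 = np.asarray(dist.data, float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    if k == 1:
        return PermanovaResult(float("nan"), 0.0, 1.0, 0)

    masks = np.stack([inv == g for g in range(k)]).astype(float)  # k x n

    def ss_within(member: np.ndarray) -> np.ndarray:
        # member: (k, m, n) group masks for m permutations
        quad = np.einsum("kmi,ij,kmj->km", member, d2, member)
        return (quad / (2.0 * sizes[:, None])).sum(axis=0)

    ss_w_obs = float(ss_within(masks[:, None, :])[0])
    ss_a_obs = ss_total - ss_w_obs
    df_a, df_w = k - 1, n - k
    f_obs = (ss_a_obs / df_a) / (ss_w_obs / df_w)
    r2 = ss_a_obs / ss_total

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(np.arange(n), (n_permutations, 1)), axis=1
    )  # m x n sample orders
    member = masks[:, perms]  # k x m x n  (labels carried onto permuted samples)
    ss_w = ss_within(member)
    f_perm = ((ss_total - ss_w) / df_a) / (ss_w / df_w)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)
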