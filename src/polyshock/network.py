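"""WGCNA-style co-expression networks: soft-thresholded adjacency,
topological overlap, module detection and eigengenes, homoeolog expression
connectivity (HEC) with a shared-neighbor hypergeometric test, quadruplet
rewiring classes and per-module subgenome composition tests.

Module detection replaces the dynamic hybrid tree cut with a deterministic
height-sweep cut plus size filter and eigengene merging; module identities
are therefore not comparable with any WGCNA run, only module relationships
(HEC, rewiring) are interpreted downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger("polyshock")

REWIRING_CLASSES = (
    "conserved_same",
    "conserved_different",
    "convergence",
    "divergence",
    "other",
)


@dataclass
class CoexpressionNetwork:
    node_ids: list[str]
    beta: int
    adjacency: np.ndarray  # symmetric, diag 0
    tom: np.ndarray  # symmetric, diag 1
    modules: pd.Series  # node -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules

    def module_of(self, node: str) -> int:
        return int(self.modules.loc[node])


def adjacency_matrix(profiles: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |pearson|^beta with zero diagonal."""
    r = np.corrcoef(profiles)
    np.clip(np.abs(r, out=r), 0.0, 1.0, out=r)
    a = r**beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), diagonal 1."""
    a = adjacency
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(profiles: np.ndarray) -> np.ndarray:
    """First principal component over samples of standardized profiles,
    sign-oriented to correlate positively with the mean profile."""
    x = profiles.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # rows: nodes, columns: samples; eigengene lives in sample space
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return eig


def build_network(
    profiles: pd.DataFrame,
    beta: int,
    min_module_size: int = 30,
    merge_cut: float = 0.25,
    max_cut_candidates: int = 200,
) -> CoexpressionNetwork:
    """Construct the co-expression network and detect modules.

    ``profiles`` is nodes x samples. Constant (zero-variance) nodes are
    dropped with a warning. Average-linkage clustering on 1 - TOM is cut
    at the height (among the linkage merge heights) that maximizes the
    number of clusters of at least ``min_module_size`` members, the finest
    such cut on ties; smaller clusters go to module 0. Modules whose
    eigengenes correlate above ``1 - merge_cut`` are merged iteratively.
    Module ids are 1..K in decreasing size order.
    """
    x = profiles.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant profile(s)")
        x = x[keep]
    node_ids = list(profiles.index[keep])
    n = len(node_ids)
    if n < min_module_size:
        raise ValueError("fewer nodes than min_module_size")

    adj = adjacency_matrix(x, beta)
    tom = tom_matrix(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    lk = linkage(squareform(dist, checks=False), method="average")

    heights = np.unique(lk[:, 2])
    if len(heights) > max_cut_candidates:
        qs = np.linspace(0, 1, max_cut_candidates)
        heights = np.unique(np.quantile(heights, qs))
    # Height sweep: prefer the cut with the most clusters of at least
    # min_module_size; among those, the one assigning the most nodes to such
    # clusters (strays below the size floor go to module 0); finest on ties.
    best = None
    labels = np.ones(n, dtype=int)
    for h in heights:
        cand = fcluster(lk, t=h, criterion="distance")
        sizes = np.bincount(cand)
        valid = sizes[1:] >= min_module_size
        score = (int(valid.sum()), int(sizes[1:][valid].sum()))
        if best is None or score > best:
            best = score
            labels = cand

    sizes = pd.Series(labels).value_counts()
    valid = sizes.index[sizes >= min_module_size]
    # module ids by decreasing size, 0 for unassigned
    remap = {old: i + 1 for i, old in enumerate(valid)}
    modules = pd.Series(
        [remap.get(lab, 0) for lab in labels], index=node_ids, name="module"
    )

    modules = _merge_modules(x, node_ids, modules, merge_cut)
    eigengenes = _module_eigengenes(x, node_ids, modules, profiles.columns)
    log.info(
        "build_network: %d nodes, beta=%d -> %d modules (+%d unassigned)",
        n,
        beta,
        modules[modules > 0].nunique(),
        int((modules == 0).sum()),
    )
    return CoexpressionNetwork(node_ids, beta, adj, tom, modules, eigengenes)


def _module_eigengenes(x, node_ids, modules, sample_ids) -> pd.DataFrame:
    eig = {}
    pos = {nid: i for i, nid in enumerate(node_ids)}
    for m in sorted(modules[modules > 0].unique()):
        idx = [pos[nid] for nid in modules.index[modules == m]]
        eig[m] = _eigengene(x[idx])
    return pd.DataFrame(eig, index=list(sample_ids))


def _merge_modules(x, node_ids, modules: pd.Series, merge_cut: float) -> pd.Series:
    modules = modules.copy()
    while True:
        ids = sorted(modules[modules > 0].unique())
        if len(ids) < 2:
            break
        eig = _module_eigengenes(x, node_ids, modules, range(x.shape[1]))
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= 1.0 - merge_cut:
            break
        a, b = eig.columns[i], eig.columns[j]
        modules[modules == b] = a
    # renumber by decreasing size
    sizes = modules[modules > 0].value_counts()
    remap = {old: rank + 1 for rank, old in enumerate(sizes.index)}
    return modules.map(lambda m: remap.get(m, 0))


def pick_soft_threshold(
    profiles: pd.DataFrame, candidate_betas: list[int], n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free topology fit per candidate soft power.

    For each beta the node connectivities k are binned, the log10 frequency
    is regressed on log10 mean k per bin, and the signed fit index
    ``-sign(slope) * R^2`` is reported with the mean connectivity.
    """
    if len(candidate_betas) < 2:
        raise ValueError("need at least 2 candidate betas")
    x = profiles.to_numpy(dtype=float)
    r = np.corrcoef(x)
    np.clip(np.abs(r, out=r), 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    rows = []
    for beta in candidate_betas:
        k = (r**beta).sum(axis=0)
        mean_k = float(k.mean())
        if np.allclose(k, k[0]):
            rows.append({"beta": beta, "r2": np.nan, "mean_k": mean_k})
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            rows.append({"beta": beta, "r2": np.nan, "mean_k": mean_k})
            continue
        lx = np.log10(centers[ok])
        ly = np.log10(hist[ok] / hist.sum())
        slope, _, rval, _, _ = stats.linregress(lx, ly)
        rows.append({"beta": beta, "r2": -np.sign(slope) * rval**2, "mean_k": mean_k})
    return pd.DataFrame(rows)


def neighbor_set(
    network: CoexpressionNetwork, node: str, neighbor_quantile: float = 0.95, exclude: str | None = None
) -> set[str]:
    """Top-TOM neighbors of a node: all other nodes whose TOM with it
    reaches the per-row ``neighbor_quantile`` quantile."""
    pos = {nid: i for i, nid in enumerate(network.node_ids)}
    i = pos[node]
    row = network.tom[i].copy()
    mask = np.ones(len(row), dtype=bool)
    mask[i] = False
    if exclude is not None:
        mask[pos[exclude]] = False
    vals = row[mask]
    thr = np.quantile(vals, neighbor_quantile)
    return {
        network.node_ids[j]
        for j in np.flatnonzero(mask)
        if row[j] >= thr
    }


def hec_score(
    network: CoexpressionNetwork,
    node_a: str,
    node_b: str,
    neighbor_quantile: float = 0.95,
) -> dict:
    """Homoeolog expression connectivity of a pair.

    Connectivity is the shared-neighbor overlap ``|N(a) & N(b)| /
    min(|N(a)|, |N(b)|)`` over per-node top-TOM neighbor sets (partner
    excluded; population excludes the two pair members). The upper-tail
    hypergeometric p is P(X >= overlap) drawing |N(a)| from a population
    of n-2 containing |N(b)| successes. Groups: A (connectivity > 0.5,
    p < 0.01), B (0.3 < connectivity <= 0.5, p < 0.01), C (connectivity
    < 0.3, p > 0.99), otherwise unclassified.
    """
    na = neighbor_set(network, node_a, neighbor_quantile, exclude=node_b)
    nb = neighbor_set(network, node_b, neighbor_quantile, exclude=node_a)
    n_pop = len(network.node_ids) - 2
    if not na or not nb:
        connectivity, p = 0.0, 1.0
        overlap = 0
    else:
        overlap = len(na & nb)
        connectivity = overlap / min(len(na), len(nb))
        p = float(stats.hypergeom.sf(overlap - 1, n_pop, len(nb), len(na)))
    if connectivity > 0.5 and p < 0.01:
        group = "A"
    elif 0.3 < connectivity <= 0.5 and p < 0.01:
        group = "B"
    elif connectivity < 0.3 and p > 0.99:
        group = "C"
    else:
        group = "unclassified"
    return {
        "connectivity": connectivity,
        "p_hyper": p,
        "group": group,
        "n_neighbors_a": len(na),
        "n_neighbors_b": len(nb),
        "overlap": overlap,
    }


def classify_rewiring(m_ad, m_dd, m_at, m_dt):
    """Quadruplet rewiring class from the four module labels.

    Evaluated in order: conserved_same (all four in one module);
    conserved_different (Ad != Dd, Ad = At, Dd = Dt); convergence
    (Ad != Dd, At = Dt); divergence (Ad = Dd, At != Dt); other. Any
    member in module 0 (unassigned) is classed other. Accepts scalars or
    arrays.
    """
    ad, dd, at, dt = (np.asarray(v) for v in (m_ad, m_dd, m_at, m_dt))
    scalar = ad.ndim == 0
    ad, dd, at, dt = (np.atleast_1d(v) for v in (ad, dd, at, dt))
    out = np.full(ad.shape, "other", dtype=object)
    assigned = (ad > 0) & (dd > 0) & (at > 0) & (dt > 0)
    same_all = (ad == dd) & (dd == at) & (at == dt)
    cons_diff = (ad != dd) & (ad == at) & (dd == dt)
    conv = (ad != dd) & (at == dt)
    div = (ad == dd) & (at != dt)
    out[assigned & div] = "divergence"
    out[assigned & conv] = "convergence"
    out[assigned & cons_diff] = "conserved_different"
    out[assigned & same_all] = "conserved_same"
    return out[0] if scalar else out


def module_subgenome_test(modules: pd.Series, subgenome: pd.Series) -> pd.DataFrame:
    """Two-sided exact binomial test of A-vs-D membership per module
    against an even 0.5 split."""
    rows = []
    for m in sorted(modules[modules > 0].unique()):
        members = modules.index[modules == m]
        labels = subgenome.loc[members]
        n_a = int((labels == "A").sum())
        n = len(members)
        p = stats.binomtest(n_a, n, 0.5, alternative="two-sided").pvalue
        rows.append({"module": m, "n_A": n_a, "n_D": n - n_a, "p_binomial": p})
    return pd.DataFrame(rows)


def divergence_by_group(
    divergence: pd.DataFrame, groups: pd.Series, value_cols: tuple[str, ...] = ("Ka", "Ks", "promoter_pdist")
) -> pd.DataFrame:
    """Reporting utility: one-way ANOVA plus Tukey HSD of sequence
    divergence measures across connectivity groups."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    g = groups.reindex(divergence["pair_id"]).to_numpy()
    for col in value_cols:
        vals = divergence[col].to_numpy()
        ok = ~pd.isna(vals) & ~pd.isna(g)
        levels = pd.unique(g[ok])
        if len(levels) < 2:
            continue
        samples = [vals[ok][g[ok] == lev] for lev in levels]
        f, p = stats.f_oneway(*samples)
        rows.append({"measure": col, "comparison": "ANOVA", "stat": f, "p": p})
        tk = pairwise_tukeyhsd(vals[ok], g[ok])
        for row in tk.summary().data[1:]:
            rows.append(
                {
                    "measure": col,
                    "comparison": f"{row[0]} vs {row[1]}",
                    "stat": float(row[2]),
                    "p": float(row[3]),
                }
            )
    return pd.DataFrame(rows)
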