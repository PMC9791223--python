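"""Correlation-distance network analysis of sphingolipid species.

Per stratum, the species x species Spearman matrix is computed, its
strictly-upper-triangle p-values are Benjamini-Hochberg adjusted, and the
distance d_ij = 1 - |rho_ij| is kept only where p_adj < alpha; the
coefficient of a non-significant pair is zeroed, so its distance is 1 and
it contributes no edge. Clusters are found by agglomerative fast-greedy
modularity maximization (Clauset-Newman-Moore) on the weighted graph with
edge weights |rho|. Interclass distance between two lipid classes is the
mean distance over all cross-class species pairs; differences between
strata are tested by subject-label permutation re-running the whole
pipeline, and whole correlation matrices are compared with a Steiger-type
chi-square over Fisher-z transformed differences.

Because every statistic is rank-based, the entire pipeline is invariant
under strictly monotone per-species transforms of the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lipid_matrix import LipidMatrix

ALPHA = 0.05


# --------------------------------------------------------------------------
# Spearman correlation with BH adjustment
# --------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n: int  # subjects in the stratum
    pair_n: pd.DataFrame | None = None  # pairwise-complete counts

    @property
    def species(self) -> list[str]:
        return list(self.rho.columns)


def _spearman_p(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the t-approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    rho = np.clip(rho, -1.0, 1.0)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.minimum(p, 1.0)


def spearman_complete(values: np.ndarray) -> np.ndarray:
    """Spearman rho matrix of a complete (no-NaN) n x k array via midranks."""
    ranks = stats.rankdata(values, axis=0)
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant column in Spearman computation")
    return np.corrcoef(ranks, rowvar=False)


def spearman_matrix(matrix: LipidMatrix | pd.DataFrame, subjects=None) -> CorrelationResult:
    """Species x species Spearman correlations with BH-adjusted p-values.

    Uses midranks for ties and pairwise-complete observations when values
    are missing; p-values come from the t-approximation. The BH family is
    the strictly-upper-triangle pairs of this one matrix.
    """
    data = matrix.abundances if isinstance(matrix, LipidMatrix) else matrix
    if subjects is not None:
        data = data.loc[subjects]
    if len(data) < 4:
        raise ValueError("need at least 4 subjects for a correlation network")
    cols = list(data.columns)
    k = len(cols)
    vals = data.to_numpy(dtype=float)

    constant = [c for c, v in zip(cols, vals.T) if np.unique(v[~np.isnan(v)]).size <= 1]
    if constant:
        raise ValueError(f"constant species within stratum: {constant}")

    if not np.isnan(vals).any():
        rho = spearman_complete(vals)
        pair_n = np.full((k, k), len(data))
    else:
        rho = np.eye(k)
        pair_n = np.full((k, k), len(data))
        for i, j in combinations(range(k), 2):
            ok = ~(np.isnan(vals[:, i]) | np.isnan(vals[:, j]))
            nij = int(ok.sum())
            if nij < 4:
                raise ValueError(
                    f"species pair ({cols[i]}, {cols[j]}) has fewer than 4 complete observations"
                )
            r, _ = stats.spearmanr(vals[ok, i], vals[ok, j])
            rho[i, j] = rho[j, i] = r
            pair_n[i, j] = pair_n[j, i] = nij

    np.fill_diagonal(rho, 1.0)
    p_raw = _spearman_p(rho, pair_n)
    np.fill_diagonal(p_raw, 0.0)

    iu = np.triu_indices(k, 1)
    p_adj_flat = bh_adjust(p_raw[iu])
    p_adj = np.zeros((k, k))
    p_adj[iu] = p_adj_flat
    p_adj = p_adj + p_adj.T

    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationResult(mk(rho), mk(p_raw), mk(p_adj), n=len(data), pair_n=mk(pair_n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Distance network
# --------------------------------------------------------------------------


@dataclass
class DistanceNetwork:
    d: pd.DataFrame  # 1-|rho| where significant, else 1; zero diagonal
    alpha: float
    graph: nx.Graph = field(repr=False)  # significant edges, weight = |rho|

    @property
    def species(self) -> list[str]:
        return list(self.d.columns)

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": a["rho"],
                "p_adj": a["p_adj"],
                "distance": a["distance"],
                "weight": a["weight"],
            }
            for u, v, a in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "distance", "weight"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_distance_network(corr: CorrelationResult, alpha: float = ALPHA) -> DistanceNetwork:
    """Distance matrix and weighted graph from a correlation result.

    Significant pairs (p_adj < alpha) get d = 1 - |rho| and an edge of
    weight |rho|; non-significant coefficients are zeroed, i.e. d = 1 and
    no edge.
    """
    rho = corr.rho.to_numpy()
    sig = corr.p_adj.to_numpy() < alpha
    d = np.where(sig, 1.0 - np.abs(rho), 1.0)
    np.fill_diagonal(d, 0.0)
    cols = corr.species
    g = nx.Graph()
    g.add_nodes_from(cols)
    for i, j in combinations(range(len(cols)), 2):
        if sig[i, j]:
            g.add_edge(
                cols[i],
                cols[j],
                rho=float(rho[i, j]),
                p_adj=float(corr.p_adj.iat[i, j]),
                distance=float(d[i, j]),
                weight=float(abs(rho[i, j])),
            )
    return DistanceNetwork(pd.DataFrame(d, index=cols, columns=cols), alpha, g)


def distance_matrix_fast(values: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """Distance matrix (1-|rho| where BH-significant, else 1) for complete data.

    Vectorized path used inside the permutation test; equivalent to
    ``build_distance_network(spearman_matrix(...)).d`` on NaN-free input.
    """
    n, k = values.shape
    rho = spearman_complete(values)
    p_raw = _spearman_p(rho, n)
    iu = np.triu_indices(k, 1)
    sig_flat = bh_adjust(p_raw[iu]) < alpha
    d = np.ones((k, k))
    du = np.where(sig_flat, 1.0 - np.abs(rho[iu]), 1.0)
    d[iu] = du
    d.T[iu] = du
    np.fill_diagonal(d, 0.0)
    return d


# --------------------------------------------------------------------------
# Modularity and fast-greedy clustering
# --------------------------------------------------------------------------


def modularity(network: DistanceNetwork | nx.Graph, partition: dict) -> float:
    """Weighted Newman modularity of a node->cluster partition.

    Q = (1/2m) * sum_ij [w_ij - k_i k_j / (2m)] * delta(c_i, c_j)
    with m the total edge weight and k_i the weighted degree.
    """
    g = network.graph if isinstance(network, DistanceNetwork) else network
    m2 = 2.0 * g.size(weight="weight")
    if m2 == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    deg = dict(g.degree(weight="weight"))
    q = 0.0
    for u, v, w in g.edges(data="weight"):
        if partition[u] == partition[v]:
            q += 2.0 * w / m2
    from collections import defaultdict

    a = defaultdict(float)
    for node, d in deg.items():
        a[partition[node]] += d / m2
    q -= sum(x * x for x in a.values())
    return q


@dataclass
class Partition:
    labels: dict  # node -> cluster id (0-based, renumbered by first member)
    q: float

    @property
    def clusters(self) -> list[set]:
        out: dict = {}
        for node, c in self.labels.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": pd.Series(self.labels)}).rename_axis("species_id")


def fast_greedy_partition(network: DistanceNetwork | nx.Graph) -> Partition:
    """Agglomerative Clauset-Newman-Moore modularity clustering.

    Starts from singleton clusters and repeatedly merges the connected
    cluster pair with the largest modularity gain
    dQ = 2*(e_cd - a_c*a_d), stopping the merge path when no two clusters
    remain connected; the partition with maximal Q along the path is
    returned. Ties in dQ are broken by the lexicographically smallest
    cluster-index pair, which makes the procedure deterministic. Nodes
    without any significant edge stay singleton clusters.
    """
    g = network.graph if isinstance(network, DistanceNetwork) else network
    if g.number_of_edges() == 0:
        raise ValueError("cannot cluster an edgeless graph")
    nodes = list(g.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    m2 = 2.0 * g.size(weight="weight")

    # cluster state keyed by smallest member index
    members: dict[int, set] = {i: {node} for node, i in index.items()}
    a = {i: 0.0 for i in members}
    for node, dgr in g.degree(weight="weight"):
        a[index[node]] = dgr / m2
    e: dict[int, dict[int, float]] = {i: {} for i in members}
    for u, v, w in g.edges(data="weight"):
        i, j = index[u], index[v]
        e[i][j] = e[i].get(j, 0.0) + w / m2
        e[j][i] = e[j].get(i, 0.0) + w / m2

    q = -sum(x * x for x in a.values())  # singleton partition
    best_q, best_members = q, {i: set(s) for i, s in members.items()}

    while True:
        best = None  # (dq, i, j)
        for i in sorted(e):
            for j in sorted(e[i]):
                if j <= i:
                    continue
                dq = 2.0 * (e[i][j] - a[i] * a[j])
                if best is None or dq > best[0] + 1e-12:
                    best = (dq, i, j)
                # ties: keep the lexicographically smallest (i, j), which the
                # sorted iteration order already guarantees
        if best is None:
            break
        dq, i, j = best
        members[i] |= members.pop(j)
        a[i] += a.pop(j)
        nbrs_j = e.pop(j)
        for kk, w in nbrs_j.items():
            if kk == i:
                continue
            e[kk].pop(j, None)
            e[i][kk] = e[i].get(kk, 0.0) + w
            e[kk][i] = e[i][kk]
        e[i].pop(j, None)
        for kk in list(e):
            e[kk].pop(j, None)
        q += dq
        if q > best_q + 1e-12:
            best_q, best_members = q, {ii: set(s) for ii, s in members.items()}

    labels: dict = {}
    for new_id, key in enumerate(sorted(best_members)):
        for node in best_members[key]:
            labels[node] = new_id
    return Partition(labels=labels, q=best_q)


# --------------------------------------------------------------------------
# Interclass distances and tests
# --------------------------------------------------------------------------


def _cross_index(species: list[str], class_map, class_a: str, class_b: str):
    cm = dict(class_map)
    ia = [i for i, s in enumerate(species) if cm.get(s) == class_a]
    ib = [i for i, s in enumerate(species) if cm.get(s) == class_b]
    if not ia or not ib:
        raise ValueError(f"class pair ({class_a}, {class_b}) has an empty class in the panel")
    return ia, ib


def interclass_distance(network: DistanceNetwork, class_map, class_a: str, class_b: str) -> float:
    """Mean distance over all cross-class species pairs (order-symmetric)."""
    ia, ib = _cross_index(network.species, class_map, class_a, class_b)
    d = network.d.to_numpy()
    return float(d[np.ix_(ia, ib)].mean())


@dataclass
class InterclassResult:
    class_pair: tuple[str, str]
    mean_distance_a: float
    mean_distance_b: float
    delta: float  # mean_distance_a - mean_distance_b
    p_value: float
    n_perm: int
    seed: int | None
    null_deltas: np.ndarray = field(repr=False, default=None)


def permutation_interclass_test(
    matrix: LipidMatrix,
    subjects_a,
    subjects_b,
    class_pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = ALPHA,
) -> InterclassResult:
    """Permutation test for a between-stratum difference in interclass distance.

    The observed statistic is Delta = D_A - D_B where each D is the
    interclass mean distance computed through the full pipeline (Spearman
    -> BH threshold -> 1-|rho| distance) within one stratum. The null
    reassigns the pooled subjects at random to two pseudo-strata of the
    original sizes and recomputes Delta each repetition; the two-sided
    p-value is (1 + #{|Delta_perm| >= |Delta_obs|}) / (1 + n_perm).

    Subjects with any missing species value are excluded up front so each
    permutation works on complete data.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    class_a, class_b = class_pair
    cm = matrix.class_map
    ia, ib = _cross_index(matrix.species, cm, class_a, class_b)

    sub_a = matrix.abundances.loc[subjects_a].dropna(axis=0)
    sub_b = matrix.abundances.loc[subjects_b].dropna(axis=0)
    na, nb = len(sub_a), len(sub_b)
    if min(na, nb) < 4:
        raise ValueError("each stratum needs at least 4 complete-case subjects")

    def delta_of(va: np.ndarray, vb: np.ndarray) -> float:
        da = distance_matrix_fast(va, alpha)
        db = distance_matrix_fast(vb, alpha)
        return float(da[np.ix_(ia, ib)].mean() - db[np.ix_(ia, ib)].mean())

    va, vb = sub_a.to_numpy(dtype=float), sub_b.to_numpy(dtype=float)
    observed = delta_of(va, vb)

    pooled = np.vstack([va, vb])
    rng = np.random.default_rng(seed)
    count = 0
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(na + nb)
        nulls[b] = delta_of(pooled[perm[:na]], pooled[perm[na:]])
        if abs(nulls[b]) >= abs(observed) - 1e-15:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    da = distance_matrix_fast(va, alpha)[np.ix_(ia, ib)].mean()
    db = distance_matrix_fast(vb, alpha)[np.ix_(ia, ib)].mean()
    return InterclassResult(
        class_pair=(class_a, class_b),
        mean_distance_a=float(da),
        mean_distance_b=float(db),
        delta=observed,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        null_deltas=nulls,
    )


@dataclass
class SteigerResult:
    chi_square: float
    df: int
    p_value: float
    n1: int
    n2: int


def steiger_compare(corr1: CorrelationResult, corr2: CorrelationResult) -> SteigerResult:
    """Steiger-type chi-square comparison of two independent correlation matrices.

    Each off-diagonal pair is Fisher-z transformed (z = atanh(rho)) and the
    squared differences, scaled by the sampling variance
    1/(n1-3) + 1/(n2-3), are summed into a chi-square with k(k-1)/2 degrees
    of freedom.
    """
    if list(corr1.rho.columns) != list(corr2.rho.columns):
        raise ValueError("correlation matrices must share the same species set")
    k = len(corr1.rho)
    iu = np.triu_indices(k, 1)
    r1 = corr1.rho.to_numpy()[iu]
    r2 = corr2.rho.to_numpy()[iu]
    if (np.abs(r1) >= 1.0).any() or (np.abs(r2) >= 1.0).any():
        raise ValueError("off-diagonal |rho| = 1: Fisher z is infinite")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    var = 1.0 / (corr1.n - 3) + 1.0 / (corr2.n - 3)
    chi2 = float(np.sum((z1 - z2) ** 2) / var)
    df = k * (k - 1) // 2
    return SteigerResult(chi2, df, float(stats.chi2.sf(chi2, df)), corr1.n, corr2.n)


def stratum_network(
    matrix: LipidMatrix, subjects, alpha: float = ALPHA
) -> tuple[CorrelationResult, DistanceNetwork, Partition]:
    """Full per-stratum pipeline: Spearman -> BH -> distances -> clusters."""
    corr = spearman_matrix(matrix, subjects)
    net = build_distance_network(corr, alpha)
    part = fast_greedy_partition(net)
    return corr, net, part
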