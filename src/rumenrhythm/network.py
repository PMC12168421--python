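"""Compositional co-occurrence networks and ecological node statistics.

Correlations between taxa are estimated with SparCC, which works on
log-ratio variances ``T_ij = var(log(x_i/x_j))`` of relative abundances and
therefore avoids the spurious negative correlations that closure induces in
naive Pearson correlations on fractions.  Under the assumption that the true
(basis) correlation network is sparse, the basis variances ``w_i`` satisfy
the linear system ``sum_{j != i} T_ij = (D-1) w_i + sum_{j != i} w_j``; the
correlation estimate is ``r_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))``.
Strongly correlated pairs violate the sparsity assumption and are iteratively
excluded from the system before re-solving.  Significance comes from a null
bootstrap: each taxon's samples are resampled with replacement independently,
which preserves marginals while destroying cross-taxon coupling.

Networks keep edges with |r| above a threshold and bootstrap p below a
threshold (strict inequalities, 0.3 / 0.05 by default).  Modules are found by
greedy modularity maximization on |r| weights; node roles follow the
within-module degree z-score (Zi) and participation coefficient (Pi) with the
usual thresholds: network hubs (Zi > 2.5, Pi > 0.62), module hubs (Zi > 2.5),
connectors (Pi > 0.62), peripheral otherwise.  Levins' niche breadth
``B_j = 1 / sum_i P_ij^2`` measures how evenly taxon j spreads over N
communities (1 = specialist, N = uniform generalist).  Community-level
concordance between kingdoms uses Bray-Curtis distances and the Mantel
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "CorrelationEstimate",
    "MicrobialNetwork",
    "NicheBreadth",
    "sparcc",
    "sparcc_bootstrap",
    "build_network",
    "node_features",
    "detect_modules",
    "zi_pi",
    "levins_niche_breadth",
    "bray_curtis",
    "mantel",
    "feature_rhythm_correlation",
]


@dataclass
class CorrelationEstimate:
    """SparCC correlation matrix (and, once bootstrapped, p-values)."""

    taxa: list[str]
    r: pd.DataFrame
    p: pd.DataFrame | None = None
    n_bootstrap: int = 0
    dropped: list[str] = field(default_factory=list)


@dataclass
class MicrobialNetwork:
    """Thresholded signed weighted graph plus module/role annotations."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    modules: dict | None = None
    modularity: float | None = None


@dataclass(frozen=True)
class NicheBreadth:
    """Levins' niche breadth of one taxon across N communities."""

    taxon_id: str
    b: float
    n_communities: int


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    return arr, [f"taxon_{i}" for i in range(arr.shape[1])]


def _logratio_variances(fractions: np.ndarray, pseudocount: float) -> np.ndarray:
    x = fractions + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    d = logx.shape[1]
    T = np.zeros((d, d))
    for i in range(d):
        diff = logx[:, i : i + 1] - logx
        T[i] = diff.var(axis=0, ddof=1)
    return T


def _solve_basis(T: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Basis variances from the log-ratio variance system.

    ``included[i, j]`` marks pairs whose equation is kept (sparsity holds).
    """
    d = T.shape[0]
    A = included.astype(float).copy()
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    M = A.copy()
    M[np.arange(d), np.arange(d)] = deg
    t = (T * A).sum(axis=1)
    omega, *_ = np.linalg.lstsq(M, t, rcond=None)
    return np.clip(omega, 1e-12, None)


def _basis_correlations(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    r = (omega[:, None] + omega[None, :] - T) / denom
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def _sparcc_matrix(
    fractions: np.ndarray,
    exclusion_threshold: float,
    exclusion_rounds: int,
    pseudocount: float,
) -> np.ndarray:
    d = fractions.shape[1]
    T = _logratio_variances(fractions, pseudocount)
    included = np.ones((d, d), dtype=bool)
    np.fill_diagonal(included, False)
    omega = _solve_basis(T, included)
    r = _basis_correlations(T, omega)
    for _ in range(exclusion_rounds):
        masked = np.where(included, np.abs(r), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # Keep every taxon in at least 2 equations so the system stays solvable.
        if included[i].sum() <= 2 or included[j].sum() <= 2:
            break
        included[i, j] = included[j, i] = False
        omega = _solve_basis(T, included)
        r = _basis_correlations(T, omega)
    return r


def sparcc(
    table,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    pseudocount: float = 1e-6,
    rng=None,
) -> CorrelationEstimate:
    """SparCC correlation estimate on a samples-by-taxa fraction table.

    Taxa with zero variance across samples are flagged and dropped (their
    log-ratio variances carry no information).  ``inner_iterations`` and
    ``rng`` are kept for interface parity with the published defaults; with
    the fixed-pseudocount dialect the estimate is deterministic and computed
    in a single pass.
    """
    mat, taxa = _as_matrix(table)
    if mat.shape[1] < 5:
        raise InsufficientDataError(
            f"SparCC needs at least 5 taxa (basis-variance system), got {mat.shape[1]}"
        )
    if mat.shape[0] < 10:
        raise InsufficientDataError(f"SparCC needs at least 10 samples, got {mat.shape[0]}")
    if np.any(mat < 0):
        raise InvalidParameterError("abundances must be nonnegative")

    variances = mat.var(axis=0)
    scale = np.maximum(np.abs(mat).max(axis=0), 1e-300)
    keep = variances > (1e-12 * scale) ** 2
    dropped = [tx for tx, k in zip(taxa, keep) if not k]
    if keep.sum() < 5:
        raise InsufficientDataError("fewer than 5 taxa with nonzero variance")
    mat = mat[:, keep]
    kept_taxa = [tx for tx, k in zip(taxa, keep) if k]

    r = _sparcc_matrix(mat, exclusion_threshold, exclusion_rounds, pseudocount)
    r_df = pd.DataFrame(r, index=kept_taxa, columns=kept_taxa)
    return CorrelationEstimate(taxa=kept_taxa, r=r_df, dropped=dropped)


def sparcc_bootstrap(
    table,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
    **sparcc_kwargs,
) -> CorrelationEstimate:
    """SparCC estimate with null-bootstrap two-sided p-values.

    Each bootstrap resamples every taxon's samples with replacement
    independently (taxa fixed, coupling destroyed) and re-runs SparCC;
    ``p_ij = (1 + #{|r*_ij| >= |r_ij|}) / (n_boot + 1)``, so p is floored at
    ``1/(n_boot+1)`` and capped at 1.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    est = sparcc(table, **sparcc_kwargs)
    mat, taxa = _as_matrix(table)
    kept = [k for k, tx in enumerate(taxa) if tx in set(est.taxa)]
    mat = mat[:, kept]
    n, d = mat.shape
    r_obs = np.abs(est.r.to_numpy())
    count = np.zeros_like(r_obs)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=(n, d))
        null = mat[idx, np.arange(d)]
        r_b = _sparcc_matrix(
            null,
            sparcc_kwargs.get("exclusion_threshold", 0.1),
            sparcc_kwargs.get("exclusion_rounds", 10),
            sparcc_kwargs.get("pseudocount", 1e-6),
        )
        count += np.abs(r_b) >= r_obs
    p = (count + 1.0) / (n_boot + 1.0)
    np.fill_diagonal(p, 0.0)
    est.p = pd.DataFrame(p, index=est.taxa, columns=est.taxa)
    est.n_bootstrap = n_boot
    return est


# ---------------------------------------------------------------------------
# Graph construction and node statistics
# ---------------------------------------------------------------------------


def build_network(
    est: CorrelationEstimate,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    kingdoms: dict[str, str] | None = None,
) -> MicrobialNetwork:
    """Signed weighted graph keeping edges with |r| > r_threshold and p < p_threshold.

    Both inequalities are strict; isolated nodes are retained with degree 0.
    ``kingdoms`` optionally maps taxon ids to kingdom tags stored as node
    attributes.
    """
    G = nx.Graph()
    for tx in est.taxa:
        G.add_node(tx, kingdom=(kingdoms or {}).get(tx, ""))
    r = est.r
    p = est.p
    for i, a in enumerate(est.taxa):
        for b in est.taxa[i + 1 :]:
            rv = float(r.loc[a, b])
            pv = float(p.loc[a, b]) if p is not None else 0.0
            if abs(rv) > r_threshold and pv < p_threshold:
                G.add_edge(a, b, r=rv, weight=abs(rv))
    return MicrobialNetwork(graph=G, r_threshold=r_threshold, p_threshold=p_threshold)


def node_features(net: MicrobialNetwork) -> pd.DataFrame:
    """Degree, weighted degree (sum |r|), closeness, betweenness per node.

    Betweenness is unweighted shortest-path betweenness with endpoints
    excluded; closeness is computed within each connected component as
    (n_comp - 1) / sum of distances, with 0 for isolated nodes.
    """
    G = net.graph
    deg = dict(G.degree())
    wdeg = dict(G.degree(weight="weight"))
    btw = nx.betweenness_centrality(G, normalized=False)
    clo = nx.closeness_centrality(G, wf_improved=False)
    rows = [
        {
            "taxon_id": n,
            "kingdom": G.nodes[n].get("kingdom", ""),
            "degree": deg[n],
            "weighted_degree": wdeg[n],
            "closeness": clo[n],
            "betweenness": btw[n],
        }
        for n in G.nodes
    ]
    return pd.DataFrame(rows).set_index("taxon_id")


def detect_modules(net: MicrobialNetwork, rng=None) -> tuple[dict, float]:
    """Greedy modularity maximization on |r| weights.

    Returns (node -> module index, modularity Q).  The greedy agglomeration
    is deterministic; ``rng`` is accepted for interface uniformity.  An
    edgeless network puts each node in its own module with Q = 0.
    """
    G = net.graph
    if G.number_of_edges() == 0:
        modules = {n: i for i, n in enumerate(G.nodes)}
        net.modules, net.modularity = modules, 0.0
        return modules, 0.0
    communities = nx.algorithms.community.greedy_modularity_communities(G, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c))
    modules = {n: i for i, comm in enumerate(communities) for n in comm}
    q = float(
        nx.algorithms.community.modularity(G, [set(c) for c in communities], weight="weight")
    )
    net.modules, net.modularity = modules, q
    return modules, q


_ROLES = ("peripheral", "connector", "module_hub", "network_hub")


def zi_pi(net: MicrobialNetwork, modules: dict | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi), participation coefficient (Pi), role.

    Zi standardizes a node's within-module degree against its module's mean
    and SD (Zi = 0 when the SD is 0); Pi = 1 - sum_s (k_is / k_i)^2 over
    modules s (0 for isolated nodes).  Roles use strict thresholds:
    network_hub (Zi > 2.5 and Pi > 0.62), module_hub (Zi > 2.5), connector
    (Pi > 0.62), else peripheral.
    """
    G = net.graph
    modules = modules if modules is not None else net.modules
    if modules is None or set(modules) != set(G.nodes):
        raise InvalidParameterError("modules must cover all nodes; run detect_modules first")

    within = {}
    for n in G.nodes:
        within[n] = sum(1 for nb in G.neighbors(n) if modules[nb] == modules[n])
    zi = {}
    for m in set(modules.values()):
        members = [n for n in G.nodes if modules[n] == m]
        ks = np.array([within[n] for n in members], dtype=float)
        mean, sd = ks.mean(), ks.std(ddof=0)
        for n, k in zip(members, ks):
            zi[n] = 0.0 if sd == 0 else (k - mean) / sd

    rows = []
    for n in G.nodes:
        k = G.degree(n)
        if k == 0:
            pi = 0.0
        else:
            per_module: dict = {}
            for nb in G.neighbors(n):
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        z = zi[n]
        if z > 2.5 and pi > 0.62:
            role = "network_hub"
        elif z > 2.5:
            role = "module_hub"
        elif pi > 0.62:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"taxon_id": n, "module": modules[n], "zi": z, "pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# Niche breadth, distances, Mantel
# ---------------------------------------------------------------------------


def levins_niche_breadth(table: pd.DataFrame, communities) -> list[NicheBreadth]:
    """Levins' B_j = 1 / sum_i P_ij^2 for each taxon across communities.

    ``table`` is samples x taxa; ``communities`` maps each sample (index
    entry) to a community label (e.g. a sampling-time stratum).  Samples in
    the same community are averaged first; P_ij is taxon j's community-i
    share of its own total, so 1 <= B_j <= N.
    """
    comm = pd.Series(communities) if not isinstance(communities, pd.Series) else communities
    missing = table.index.difference(comm.index)
    if len(missing):
        raise AlignmentError(f"samples without a community label: {list(missing)[:5]}")
    grouped = table.groupby(comm.loc[table.index]).mean()
    n_comm = grouped.shape[0]
    out = []
    for tx in table.columns:
        vec = grouped[tx].to_numpy(dtype=float)
        total = vec.sum()
        if total <= 0:
            raise UndefinedStatisticError(f"niche breadth undefined for all-zero taxon {tx!r}")
        p = vec / total
        out.append(NicheBreadth(taxon_id=str(tx), b=float(1.0 / np.sum(p**2)), n_communities=n_comm))
    return out


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x - y| / sum(x + y), per sample pair."""
    mat = table.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise InvalidParameterError("abundances must be nonnegative")
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    method: str = "spearman",
    permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices over the same samples.

    r is the rank (or product-moment) correlation of the off-diagonal
    entries; the two-sided p-value is (1 + #{|r*| >= |r|}) / (permutations+1)
    under simultaneous row/column permutations of the second matrix.
    """
    if list(d1.index) != list(d1.columns) or list(d2.index) != list(d2.columns):
        raise AlignmentError("distance matrices must be square with matching labels")
    if set(d1.index) != set(d2.index):
        raise AlignmentError("the two distance matrices cover different samples")
    d2 = d2.loc[d1.index, d1.index]
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    for m, name in ((a, "d1"), (b, "d2")):
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise InvalidParameterError(f"{name} must be symmetric with a zero diagonal")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        if method == "pearson":
            return stats.pearsonr(x, y).statistic
        raise InvalidParameterError(f"unknown method {method!r}")

    r_obs = float(corr(a[iu], b[iu]))
    rng = np.random.default_rng(rng)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = corr(a[iu], b[np.ix_(perm, perm)][iu])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1.0) / (permutations + 1.0)
    return r_obs, float(p)


def feature_rhythm_correlation(features: pd.DataFrame, rhythm_params: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between network node features and rhythm parameters.

    Both frames are indexed by taxon; every (feature, parameter) column pair
    gets a rho and p.  Constant columns yield NaN with ``undefined = True``.
    """
    shared = features.index.intersection(rhythm_params.index)
    if len(shared) < 3:
        raise InsufficientDataError(f"need >= 3 shared taxa, got {len(shared)}")
    f = features.loc[shared].select_dtypes("number")
    r = rhythm_params.loc[shared].select_dtypes("number")
    rows = []
    for fc in f.columns:
        for rc in r.columns:
            x, y = f[fc].to_numpy(float), r[rc].to_numpy(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append(
                    {"feature": fc, "parameter": rc, "rho": np.nan, "p": np.nan, "undefined": True}
                )
                continue
            res = stats.spearmanr(x, y)
            rows.append(
                {
                    "feature": fc,
                    "parameter": rc,
                    "rho": float(res.statistic),
                    "p": float(res.pvalue),
                    "undefined": False,
                }
            )
    return pd.DataFrame(rows)
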