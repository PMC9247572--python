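"""Co-occurrence networks and case/control comparison for driver-taxon calling.

The network stage estimates compositionally robust correlations between
taxa (SparCC), keeps edges passing a correlation and permutation-p
threshold, partitions each state's network into modules by greedy
modularity optimization, and then contrasts the before-treatment (BT)
and after-treatment (AT) networks node by node.  The contrast follows
the NetShift methodology: for each node the Jaccard overlap of its
neighbor sets, a neighbor-shift (NESH) score built from its
case-exclusive neighbors, and the change in normalized betweenness
centrality (DelBet).  Nodes with top-quantile NESH or positive DelBet
are flagged as candidate "driver" taxa.

NESH is computed here as::

    NESH(x) = |B\\A|/|B| + |B\\A|/|A u B| + |B\\A| / max_y |B_y\\A_y|

with A, B the BT and AT neighbor sets of x: the first two terms are the
node's case-exclusive neighbor fraction and union-normalized
exclusivity, the third scales the node's exclusivity against the
network-wide maximum (a network-level normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community

from .asv_tables import CountTable, RelAbundanceTable


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    density: float
    mean_betweenness: float

    def to_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "average_degree": self.average_degree,
            "average_path_length": self.average_path_length,
            "density": self.density,
            "mean_betweenness": self.mean_betweenness,
        }


@dataclass
class CoNetwork:
    """Undirected weighted co-occurrence graph on ASV nodes."""

    graph: nx.Graph
    modules: dict[str, int] = field(default_factory=dict)
    modularity: float | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbor_set(self, node) -> set:
        if node not in self.graph:
            return set()
        return set(self.graph.neighbors(node))


@dataclass
class IndicatorResult:
    per_asv: pd.DataFrame  # columns: indval_<state>, p_<state> per state
    states: tuple[str, str]
    alpha: float = 0.05

    def significant(self, state: str) -> list[str]:
        df = self.per_asv
        best = df[[f"indval_{s}" for s in self.states]].idxmax(axis=1)
        mask = (best == f"indval_{state}") & (df[f"p_{state}"] < self.alpha)
        return list(df.index[mask])


@dataclass
class NetshiftNodeReport:
    node: str
    n_bt: int
    n_at: int
    core_at: int
    shared: int
    exclusive_at: int
    jaccard: float
    nesh: float
    delbet: float
    is_driver: bool


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """T_ij = var(log x_i - log x_j) across samples (rows are components)."""
    v = np.cov(log_fracs)
    dg = np.diag(v)
    return dg[:, None] + dg[None, :] - 2.0 * v


def _basis_correlations(t_mat: np.ndarray, exclusion_threshold: float,
                        n_exclusion_rounds: int) -> np.ndarray:
    """Solve the SparCC basis-variance system with iterative pair exclusion."""
    d = t_mat.shape[0]
    include = ~np.eye(d, dtype=bool)
    excluded: set[tuple[int, int]] = set()
    for _ in range(n_exclusion_rounds + 1):
        m = include.astype(float)
        np.fill_diagonal(m, include.sum(axis=1))
        t_vec = (t_mat * include).sum(axis=1)
        try:
            omega2 = np.linalg.solve(m, t_vec)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("unsolvable basis-variance system after exclusions") from exc
        omega2 = np.maximum(omega2, 1e-12)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t_mat) / (2.0 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # strongest still-included off-diagonal pair
        masked = np.where(include, np.abs(rho), -np.inf)
        np.fill_diagonal(masked, -np.inf)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold or len(excluded) >= n_exclusion_rounds:
            return rho
        include[i, j] = include[j, i] = False
        excluded.add((i, j))
    return rho


def sparcc(
    table: CountTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """SparCC compositional correlation matrix between ASVs.

    Each iteration resamples fractions from a Dirichlet posterior
    (counts + 1 pseudocount) per sample, computes the log-ratio
    variation matrix, solves for basis variances under the sparsity
    assumption (with iterative exclusion of the strongest pairs), and
    forms basis correlations; the final estimate is the element-wise
    median over iterations, clipped to [-1, 1].
    """
    counts = table.matrix
    d = counts.shape[0]
    if d < 4:
        raise ValueError("sparcc needs at least 4 ASVs")
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_iterations, d, d))
    alpha = counts.T + 1.0  # samples x ASVs
    for it in range(n_iterations):
        gam = rng.standard_gamma(alpha)
        fracs = gam / gam.sum(axis=1, keepdims=True)
        t_mat = _variation_matrix(np.log(fracs.T))
        rhos[it] = _basis_correlations(t_mat, exclusion_threshold, n_exclusion_rounds)
    rho = np.clip(np.median(rhos, axis=0), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.asv_ids, columns=table.asv_ids)


def edge_significance(
    table: CountTable,
    rho: pd.DataFrame,
    n_bootstraps: int = 100,
    seed: int = 0,
    n_iterations: int = 5,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Per-pair pseudo p-values for SparCC correlations.

    Null correlation distributions come from tables in which each ASV's
    counts are permuted across samples independently (destroying all
    pairwise association while keeping marginals); the two-sided p for a
    pair is (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_bootstraps).
    """
    if n_bootstraps < 20:
        raise ValueError("n_bootstraps must be >= 20")
    rng = np.random.default_rng(seed)
    counts = table.matrix
    obs = np.abs(rho.to_numpy())
    exceed = np.zeros_like(obs)
    for b in range(n_bootstraps):
        shuffled = counts.copy()
        for i in range(counts.shape[0]):
            shuffled[i] = shuffled[i, rng.permutation(counts.shape[1])]
        null_table = CountTable(
            counts=pd.DataFrame(shuffled, index=table.counts.index, columns=table.counts.columns),
            metadata=table.metadata,
        )
        null_rho = sparcc(
            null_table,
            n_iterations=n_iterations,
            seed=int(rng.integers(2 ** 31)),
            **sparcc_kwargs,
        ).to_numpy()
        exceed += np.abs(null_rho) >= obs
    p = (1.0 + exceed) / (1.0 + n_bootstraps)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=rho.index, columns=rho.columns)


# ---------------------------------------------------------------------------
# Network construction and metrics
# ---------------------------------------------------------------------------

def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame | None = None,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    signed: bool = False,
) -> CoNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    An edge is kept when |rho| > rho_min (strict) and p < alpha.  With
    ``signed=True`` only positive correlations qualify (the literal
    "rho > 0.3" reading); the default uses absolute values since
    negative associations are ecologically meaningful.
    """
    if signed:
        warnings.warn("signed edge rule: only rho > rho_min retained", stacklevel=2)
    ids = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy() if p is not None else np.zeros_like(r)
    g = nx.Graph()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            strength = r[a, b] if signed else abs(r[a, b])
            if strength > rho_min and pv[a, b] < alpha:
                g.add_edge(ids[a], ids[b], weight=float(r[a, b]),
                           abs_weight=float(abs(r[a, b])))
    if g.number_of_edges() == 0:
        warnings.warn("empty co-occurrence network", stacklevel=2)
    return CoNetwork(graph=g)


def detect_modules(net: CoNetwork, seed: int = 0) -> CoNetwork:
    """Greedy (agglomerative) modularity maximization on absolute weights.

    Module ids are assigned in decreasing module size; modularity Q of
    the resulting partition is stored on the network.  The algorithm is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise ValueError("detect_modules needs at least one edge")
    comms = list(nx_community.greedy_modularity_communities(g, weight="abs_weight"))
    comms.sort(key=lambda c: (-len(c), sorted(c)[0]))
    modules = {node: k for k, comm in enumerate(comms) for node in comm}
    q = nx_community.modularity(g, comms, weight="abs_weight")
    net.modules = modules
    net.modularity = float(q)
    return net


def network_metrics(net: CoNetwork) -> NetworkMetrics:
    """Summary metrics: node/edge counts, average degree 2E/N, density,
    average shortest-path length over connected pairs, and mean
    normalized betweenness centrality."""
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network metrics undefined for fewer than 2 nodes")
    e = g.number_of_edges()
    total_len, n_pairs = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for dd in dists.values():
            if dd > 0:
                total_len += dd
                n_pairs += 1
    apl = total_len / n_pairs if n_pairs else float("nan")
    bet = nx.betweenness_centrality(g, normalized=True)
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        average_path_length=apl,
        density=2.0 * e / (n * (n - 1)),
        mean_betweenness=float(np.mean(list(bet.values()))),
    )


# ---------------------------------------------------------------------------
# Indicator species
# ---------------------------------------------------------------------------

def indicator_species(
    table: RelAbundanceTable,
    states=None,
    n_permutations: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> IndicatorResult:
    """Indicator value analysis (IndVal = specificity x fidelity) per state.

    A_ik = mean abundance of taxon i in state k over the sum of its
    state means; B_ik = fraction of state-k samples where it occurs;
    IndVal = A*B.  p-values come from permuting state labels.
    """
    if states is None:
        states = table.states()
    labels = np.asarray(pd.Series(states, index=table.sample_ids).loc[table.sample_ids])
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("indicator_species needs exactly two states")
    x = table.matrix  # ASV x sample
    present_everywhere = x.sum(axis=1) > 0
    rng = np.random.default_rng(seed)

    def indvals(lab):
        out = {}
        means = {}
        for s in uniq:
            mask = lab == s
            means[s] = x[:, mask].mean(axis=1)
        total = means[uniq[0]] + means[uniq[1]]
        total = np.where(total > 0, total, 1.0)
        for s in uniq:
            mask = lab == s
            a = means[s] / total
            b = (x[:, mask] > 0).mean(axis=1)
            out[s] = a * b
        return out

    obs = indvals(labels)
    exceed = {s: np.zeros(x.shape[0]) for s in uniq}
    for _ in range(n_permutations):
        perm = indvals(labels[rng.permutation(labels.size)])
        for s in uniq:
            exceed[s] += perm[s] >= obs[s]
    per = pd.DataFrame(index=table.asv_ids)
    for s in uniq:
        per[f"indval_{s}"] = obs[s]
        per[f"p_{s}"] = (1.0 + exceed[s]) / (1.0 + n_permutations)
    per = per.loc[present_everywhere]
    return IndicatorResult(per_asv=per, states=tuple(uniq), alpha=alpha)


# ---------------------------------------------------------------------------
# NetShift comparison
# ---------------------------------------------------------------------------

def netshift_compare(
    net_bt: CoNetwork,
    net_at: CoNetwork,
    nesh_quantile: float = 0.9,
    rescale_delbet: bool = True,
) -> list[NetshiftNodeReport]:
    """Per-node BT-vs-AT comparison over the union subnetwork.

    For node x with BT neighbor set A and AT neighbor set B:
    shared = |A n B|, exclusive_at = |B \\ A|, jaccard = |A n B|/|A u B|,
    NESH as documented in the module docstring, and DelBet = normalized
    betweenness in AT minus BT (positives rescaled so the maximum is 1
    when ``rescale_delbet``).  Drivers are the union of nodes with NESH
    at or above the ``nesh_quantile`` of all NESH scores and nodes with
    DelBet > 0.
    """
    nodes = sorted(set(net_bt.nodes) | set(net_at.nodes))
    if not nodes:
        return []
    bet_bt = nx.betweenness_centrality(net_bt.graph, normalized=True) if net_bt.nodes else {}
    bet_at = nx.betweenness_centrality(net_at.graph, normalized=True) if net_at.nodes else {}
    rows = []
    for x in nodes:
        a = net_bt.neighbor_set(x)
        b = net_at.neighbor_set(x)
        shared = len(a & b)
        excl = len(b - a)
        union = len(a | b)
        jac = len(a & b) / union if union else 1.0
        core_at = sum(
            1 for y in b
            if net_at.modules and net_at.modules.get(y) == net_at.modules.get(x)
        )
        rows.append({
            "node": x, "n_bt": len(a), "n_at": len(b), "shared": shared,
            "exclusive_at": excl, "union": union, "jaccard": jac, "core_at": core_at,
            "delbet": bet_at.get(x, 0.0) - bet_bt.get(x, 0.0),
        })
    max_excl = max(r["exclusive_at"] for r in rows)
    for r in rows:
        excl = r["exclusive_at"]
        nesh = 0.0
        if excl:
            nesh = excl / r["n_at"] + excl / r["union"] + excl / max_excl
        r["nesh"] = nesh
    if rescale_delbet:
        max_pos = max((r["delbet"] for r in rows if r["delbet"] > 0), default=0.0)
        if max_pos > 0:
            for r in rows:
                if r["delbet"] > 0:
                    r["delbet"] /= max_pos
    flags = driver_flags(
        [r["nesh"] for r in rows], [r["delbet"] for r in rows], nesh_quantile
    )
    return [
        NetshiftNodeReport(
            node=r["node"], n_bt=r["n_bt"], n_at=r["n_at"], core_at=r["core_at"],
            shared=r["shared"], exclusive_at=r["exclusive_at"], jaccard=r["jaccard"],
            nesh=r["nesh"], delbet=r["delbet"], is_driver=bool(flag),
        )
        for r, flag in zip(rows, flags)
    ]


def driver_flags(nesh_values, delbet_values, nesh_quantile: float = 0.9) -> np.ndarray:
    """The driver rule: top-quantile NESH union positive DelBet.

    A node is a driver when its NESH score reaches the ``nesh_quantile``
    of all NESH scores (and is nonzero), or when its betweenness
    centrality increased from control to case (DelBet > 0).
    """
    nesh = np.asarray(nesh_values, dtype=float)
    delbet = np.asarray(delbet_values, dtype=float)
    cut = float(np.quantile(nesh, nesh_quantile))
    return ((nesh >= cut) & (nesh > 0)) | (delbet > 0)


def drivers(reports: list[NetshiftNodeReport]) -> list[str]:
    return [r.node for r in reports if r.is_driver]


def netshift_frame(reports: list[NetshiftNodeReport]) -> pd.DataFrame:
    """Node reports as a table mirroring the standard column order."""
    return pd.DataFrame(
        [
            {
                "node": r.node, "n_bt": r.n_bt, "n_at": r.n_at, "core_at": r.core_at,
                "exclusive": r.exclusive_at, "jaccard": r.jaccard, "nesh": r.nesh,
                "delbet": r.delbet, "is_driver": r.is_driver,
            }
            for r in reports
        ]
    ).set_index("node")


def common_subnetwork(net_bt: CoNetwork, net_at: CoNetwork) -> nx.Graph:
    """Union graph with each edge tagged BT-only / AT-only / both."""
    g = nx.Graph()
    bt_edges = {frozenset(e) for e in net_bt.graph.edges}
    at_edges = {frozenset(e) for e in net_at.graph.edges}
    for e in bt_edges | at_edges:
        u, v = tuple(e)
        src = "both" if e in bt_edges and e in at_edges else (
            "BT-only" if e in bt_edges else "AT-only"
        )
        g.add_edge(u, v, provenance=src)
    return g


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_network(net: CoNetwork, edge_path, graphml_path=None) -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0),
         "module_source": net.modules.get(u, -1), "module_target": net.modules.get(v, -1)}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "module_source",
                                "module_target"]).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        g = net.graph.copy()
        for node, mod in net.modules.items():
            g.nodes[node]["module"] = int(mod)
        nx.write_graphml(g, graphml_path)


def read_network(edge_path) -> CoNetwork:
    df = pd.read_csv(edge_path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]),
                   weight=float(row["weight"]), abs_weight=abs(float(row["weight"])))
    return CoNetwork(graph=g)
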