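"""PPI-supported epistatic gene network: construction, topology, scale-free
testing, Poisson hub calling and modularity decomposition.

An edge requires both a retained epistatic gene pair and a recorded
protein-protein interaction; the graph is simple and undirected.  Hubs are
nodes whose degree exceeds the Poisson expectation (lambda = mean degree)
after Bonferroni correction over nodes; scale-freeness is assessed with a
discrete power-law maximum-likelihood fit and a bootstrapped
Kolmogorov-Smirnov goodness-of-fit p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import zeta

logger = logging.getLogger(__name__)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_network(candidates, ppi: pd.DataFrame) -> nx.Graph:
    """Intersect candidate epistatic gene pairs with the PPI edge table.

    Nodes are all candidate genes (so candidates whose edges lack PPI support
    remain as isolated nodes); edges carry ``supporting_pairs`` and ``min_p``
    from the candidate list.
    """
    ppi_set = {
        _canonical(str(r.gene_a), str(r.gene_b))
        for r in ppi.itertuples(index=False)
        if str(r.gene_a) != str(r.gene_b)
    }
    g = nx.Graph()
    for c in candidates:
        key = _canonical(c.gene_a, c.gene_b)
        g.add_node(key[0])
        g.add_node(key[1])
        if key in ppi_set:
            g.add_edge(*key, supporting_pairs=c.supporting_pairs, min_p=c.min_p)
    return g


def component_census(g: nx.Graph) -> dict[int, int]:
    """Histogram {component size: count}."""
    census: dict[int, int] = {}
    for comp in nx.connected_components(g):
        census[len(comp)] = census.get(len(comp), 0) + 1
    return dict(sorted(census.items()))


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break toward the component containing the lexicographically
    smallest node id.  The component census is logged.
    """
    if g.number_of_nodes() == 0:
        logger.warning("largest_component called on an empty graph")
        return nx.Graph()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    logger.info("component census: %s", component_census(g))
    return g.subgraph(comps[0]).copy()


def topology_stats(g: nx.Graph) -> tuple[pd.DataFrame, dict]:
    """Per-node degree/betweenness/clustering and whole-graph summaries.

    Betweenness is the unnormalized shortest-path count; the diameter is the
    largest finite eccentricity (computed per component on disconnected
    input).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    betw = nx.betweenness_centrality(g, normalized=False)
    clust = nx.clustering(g)
    nodes = sorted(g.nodes)
    node_df = pd.DataFrame(
        {
            "gene": nodes,
            "degree": [g.degree[n] for n in nodes],
            "betweenness": [betw[n] for n in nodes],
            "clustering": [clust[n] for n in nodes],
        }
    )
    diameter = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            ecc = nx.eccentricity(g.subgraph(comp))
            diameter = max(diameter, max(ecc.values()))
    degrees = node_df["degree"].to_numpy()
    hist = np.bincount(degrees) if degrees.size else np.array([0])
    graph_stats = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "density": nx.density(g),
        "diameter": diameter,
        "degree_histogram": hist.tolist(),
    }
    return node_df, graph_stats


# -------------------------------------------------------------- power law


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_D: float
    p_value: float
    n_tail: int
    method: str  # bootstrap | asymptotic


def _plfit_alpha(tail: np.ndarray, xmin: int) -> float:
    """Exact discrete power-law MLE: maximize the Hurwitz-zeta likelihood
    -alpha sum(ln k) - n ln zeta(alpha, xmin) numerically.

    The popular closed-form continuous approximation
    1 + n / sum ln(k/(xmin-0.5)) is strongly biased for xmin = 1 and is not
    used.
    """
    from scipy.optimize import minimize_scalar

    s = float(np.log(tail).sum())
    n = tail.size

    def nll(a: float) -> float:
        return a * s + n * np.log(zeta(a, xmin))

    res = minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def _pl_cdf(ks: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """CDF of the discrete power law p(k) ~ k^-alpha, k >= xmin."""
    z = zeta(alpha, xmin)
    kmax = int(ks.max())
    pmf = np.arange(xmin, kmax + 1, dtype=float) ** (-alpha) / z
    cdf = np.cumsum(pmf)
    return cdf[ks - xmin]


def _ks_D(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """Sup distance between the tail empirical CDF and the fitted CDF."""
    ks = np.arange(xmin, int(tail.max()) + 1)
    ecdf = np.searchsorted(np.sort(tail), ks, side="right") / tail.size
    return float(np.abs(ecdf - _pl_cdf(ks, alpha, xmin)).max())


def _pl_sampler(alpha: float, xmin: int, tail_tol: float = 1e-9, kmax: int = 100_000):
    """Probability table for sampling the fitted discrete power law,
    truncated where the remaining tail mass is negligible."""
    z = zeta(alpha, xmin)
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks ** (-alpha) / z
    cum = np.cumsum(pmf)
    cut = min(int(np.searchsorted(cum, 1.0 - tail_tol)) + 1, pmf.size)
    pmf = pmf[:cut]
    return np.arange(xmin, xmin + cut), pmf / pmf.sum()


def fit_power_law(
    degrees,
    xmin: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "bootstrap",
    select_xmin: bool = False,
) -> PowerLawFit:
    """Fit p(k) ~ k^-alpha to the degree tail k >= xmin and test goodness of fit.

    The bootstrap p-value is the fraction of ``n_boot`` samples drawn from
    the fitted law whose refitted KS distance exceeds the observed one
    (high p: the power law is not rejected).  ``select_xmin`` scans candidate
    xmin values and keeps the one minimizing the KS distance (Clauset-style).
    """
    degrees = np.asarray(degrees, dtype=int)
    if select_xmin:
        best = None
        for cand in np.unique(degrees[degrees >= 1]):
            tail = degrees[degrees >= cand]
            if tail.size < 10 or np.ptp(tail) == 0:
                continue
            a = _plfit_alpha(tail, int(cand))
            d = _ks_D(tail, a, int(cand))
            if best is None or d < best[1]:
                best = (int(cand), d)
        if best is not None:
            xmin = best[0]
    tail = degrees[degrees >= xmin]
    if tail.size < 10:
        raise ValueError("need at least 10 degrees >= xmin")
    if np.ptp(tail) == 0:
        raise ValueError("all tail degrees equal; power-law MLE undefined")
    alpha = _plfit_alpha(tail, xmin)
    D = _ks_D(tail, alpha, xmin)
    n = tail.size
    if method == "asymptotic":
        from scipy.special import kolmogorov

        p = float(kolmogorov(np.sqrt(n) * D))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        support, probs = _pl_sampler(alpha, xmin)
        exceed = 0
        for _ in range(n_boot):
            sample = rng.choice(support, size=n, p=probs)
            if np.ptp(sample) == 0:
                continue
            a_b = _plfit_alpha(sample, xmin)
            if _ks_D(sample, a_b, xmin) >= D:
                exceed += 1
        p = exceed / n_boot
    else:
        raise ValueError(f"unknown method {method!r}")
    return PowerLawFit(
        alpha=float(alpha), xmin=xmin, ks_D=D, p_value=float(p),
        n_tail=int(n), method=method,
    )


# ------------------------------------------------------------------- hubs


@dataclass
class HubResult:
    gene: str
    degree: int
    lam: float
    p_raw: float
    p_adjusted: float
    is_hub: bool


def poisson_tail(degree: int, lam: float) -> float:
    """P(X >= degree) for X ~ Poisson(lam), by direct summation of the
    complement 1 - sum_{j<degree} e^-lam lam^j / j!."""
    if degree <= 0:
        return 1.0
    term = math.exp(-lam)
    cum = term
    for j in range(1, degree):
        term *= lam / j
        cum += term
    return max(0.0, 1.0 - cum)


def hub_test(
    g: nx.Graph, lam: float | None = None, alpha: float = 0.05
) -> list[HubResult]:
    """Poisson connectivity test per node, Bonferroni over the node count.

    ``lam`` defaults to the mean degree 2E/V of the tested (sub)graph.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need at least two nodes")
    n = g.number_of_nodes()
    if lam is None:
        lam = 2.0 * g.number_of_edges() / n
    out = []
    for node in sorted(g.nodes):
        d = g.degree[node]
        p_raw = poisson_tail(d, lam)
        p_adj = min(1.0, p_raw * n)
        out.append(HubResult(node, d, lam, p_raw, p_adj, p_adj < alpha))
    out.sort(key=lambda h: (-h.degree, h.gene))
    return out


def hubs_to_frame(hubs: list[HubResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": h.gene,
                "degree": h.degree,
                "lambda": h.lam,
                "p_raw": h.p_raw,
                "p_adjusted": h.p_adjusted,
                "is_hub": h.is_hub,
            }
            for h in hubs
        ]
    )


# ---------------------------------------------------------------- modules


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity_q: float
    modules: list[dict] = field(default_factory=list)

    def module_nodes(self, module_id: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module_id)


def modularity_q(g: nx.Graph, communities: list[set]) -> float:
    """Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2)."""
    return nx.community.modularity(g, communities)


def _leading_eigenvector_communities(g: nx.Graph) -> list[set]:
    """Newman's leading-eigenvector method: recursive spectral bisection on
    the modularity matrix, stopping when a split no longer increases Q."""
    nodes = sorted(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    k = A.sum(axis=1)
    m2 = k.sum()  # 2m
    if m2 == 0:
        return [{n} for n in nodes]
    B = A - np.outer(k, k) / m2

    def split(indices: np.ndarray) -> list[np.ndarray]:
        if indices.size < 2:
            return [indices]
        Bg = B[np.ix_(indices, indices)]
        Bg = Bg - np.diag(Bg.sum(axis=1))
        w, v = np.linalg.eigh(Bg)
        lead = v[:, -1]
        if w[-1] <= 1e-12:
            return [indices]
        s = np.where(lead >= 0, 1.0, -1.0)
        dq = float(s @ Bg @ s) / (2.0 * m2)
        if dq <= 1e-12 or np.all(s > 0) or np.all(s < 0):
            return [indices]
        left, right = indices[s > 0], indices[s < 0]
        return split(left) + split(right)

    groups = split(np.arange(len(nodes)))
    return [set(nodes[i] for i in grp) for grp in groups]


def decompose_modules(g: nx.Graph, algorithm: str = "fast_greedy") -> ModulePartition:
    """Decompose a network into modules by modularity maximization.

    ``fast_greedy`` is Newman's agglomerative heuristic
    (greedy modularity maximization); ``leading_eigenvector`` the spectral
    bisection variant.  Deterministic given the node set: nodes are processed
    in sorted order and modules are numbered 1..k by decreasing size then
    smallest member.  An edgeless graph yields singleton modules with Q = 0.
    """
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted(_canonical(u, v) for u, v in g.edges))
    if h.number_of_edges() == 0:
        assignment = {n: i + 1 for i, n in enumerate(sorted(h.nodes))}
        modules = [
            {"module": i, "n_nodes": 1, "n_edges": 0, "diameter": 0}
            for i in sorted(set(assignment.values()))
        ]
        return ModulePartition(assignment, 0.0, modules)
    if algorithm == "fast_greedy":
        comms = [set(c) for c in nx.community.greedy_modularity_communities(h)]
    elif algorithm == "leading_eigenvector":
        comms = _leading_eigenvector_communities(h)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    assignment = {n: i + 1 for i, comm in enumerate(comms) for n in comm}
    q = modularity_q(h, [set(c) for c in comms])
    modules = []
    for i, comm in enumerate(comms):
        sub = h.subgraph(comm)
        diam = 0
        for cc in nx.connected_components(sub):
            if len(cc) > 1:
                diam = max(diam, max(nx.eccentricity(sub.subgraph(cc)).values()))
        modules.append(
            {
                "module": i + 1,
                "n_nodes": sub.number_of_nodes(),
                "n_edges": sub.number_of_edges(),
                "diameter": diam,
            }
        )
    return ModulePartition(assignment, float(q), modules)


def module_topology_table(
    g: nx.Graph,
    partition: ModulePartition,
    n_boot: int = 1000,
    seed: int | None = None,
    min_fit_size: int = 10,
) -> pd.DataFrame:
    """Per-module topology rows: size, edges, diameter and — where the module
    is large enough — the power-law fit of its degree sequence."""
    rows = []
    for mod in partition.modules:
        mid = mod["module"]
        nodes = partition.module_nodes(mid)
        sub = g.subgraph(nodes)
        degrees = [d for _, d in sub.degree()]
        alpha = ks_D = p = np.nan
        tail = [d for d in degrees if d >= 1]
        if len(tail) >= min_fit_size and len(set(tail)) > 1:
            try:
                fit = fit_power_law(degrees, xmin=1, n_boot=n_boot, seed=seed)
                alpha, ks_D, p = fit.alpha, fit.ks_D, fit.p_value
            except ValueError:
                pass
        rows.append(
            {
                "module": mid,
                "n_nodes": mod["n_nodes"],
                "n_edges": mod["n_edges"],
                "diameter": mod["diameter"],
                "alpha": alpha,
                "ks_D": ks_D,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
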