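"""Network topology statistics.

Discrete power-law fitting follows the Clauset-Shalizi-Newman recipe:
maximum-likelihood alpha above a KS-minimizing xmin, a log-scale QQ linear
fit R^2, and a semi-parametric bootstrap goodness-of-fit p-value. Module
structure is assessed with Louvain partitions against a null ensemble of
degree-preserving rewired graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special, stats

from .tip import RegulatoryNetwork


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    qq_r2: float
    ks_stat: float
    ks_p: float
    n_bootstrap: int
    n_tail: int


@dataclass
class ModularityResult:
    partition: dict[str, int]
    Q: float
    resolution: float
    null_Q: np.ndarray | None = None
    p: float | None = None


def in_degree_distribution(network: RegulatoryNetwork) -> dict[int, int]:
    """Histogram of in-degree values over target nodes."""
    if not network.edges:
        raise ValueError("empty network")
    return dict(Counter(network.in_degrees().values()))


def _alpha_mle(tail: np.ndarray, xmin: int) -> float:
    """Discrete MLE of the exponent for data >= xmin (Hurwitz-zeta likelihood)."""
    n = tail.size
    slog = float(np.log(tail).sum())

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, xmin)) + alpha * slog

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-6, 12.0), method="bounded")
    return float(res.x)


def _ks_discrete(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between the empirical tail CDF and the fitted model."""
    xmax = int(tail.max())
    support = np.arange(xmin, xmax + 1)
    pmf = support.astype(float) ** (-alpha) / special.zeta(alpha, xmin)
    cdf_model = np.cumsum(pmf)
    values, counts = np.unique(tail, return_counts=True)
    cdf_emp_at = np.cumsum(counts) / tail.size
    idx = values - xmin
    return float(np.max(np.abs(cdf_emp_at - cdf_model[idx])))


def _fit_tail(
    degrees: np.ndarray, xmin_candidates: np.ndarray
) -> tuple[float, int, float]:
    """Scan xmin candidates; return (alpha, xmin, ks) minimizing KS."""
    best = (np.nan, 0, np.inf)
    for xmin in xmin_candidates:
        tail = degrees[degrees >= xmin]
        if tail.size < 10 or np.all(tail == tail[0]):
            continue
        alpha = _alpha_mle(tail, int(xmin))
        ks = _ks_discrete(tail, alpha, int(xmin))
        if ks < best[2]:
            best = (alpha, int(xmin), ks)
    if not np.isfinite(best[2]):
        raise ValueError("degenerate distribution: no viable xmin")
    return best


def _xmin_candidates(degrees: np.ndarray, max_candidates: int = 30) -> np.ndarray:
    uniq = np.unique(degrees)
    uniq = uniq[uniq >= 1]
    capped = uniq[uniq <= np.quantile(degrees, 0.95)]  # leave some tail above xmin
    if capped.size >= 2:
        uniq = capped
    if uniq.size > max_candidates:
        idx = np.unique(
            np.linspace(0, uniq.size - 1, max_candidates).astype(int)
        )
        uniq = uniq[idx]
    return uniq


def _qq_r2(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """R^2 of the log-scale QQ plot of the tail against the fitted model."""
    n = tail.size
    emp = np.sort(tail).astype(float)
    # model quantiles via inverse CDF on the discrete support
    xmax = max(int(emp[-1]) * 4, xmin + 10)
    support = np.arange(xmin, xmax + 1)
    pmf = support.astype(float) ** (-alpha) / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = support[np.clip(np.searchsorted(cdf, probs), 0, support.size - 1)]
    x = np.log(theo.astype(float))
    y = np.log(emp)
    keep = np.isfinite(x) & np.isfinite(y)
    slope, intercept, r, _, _ = stats.linregress(x[keep], y[keep])
    return float(r**2)


def sample_discrete_powerlaw(
    rng: np.random.Generator, alpha: float, xmin: int, size: int
) -> np.ndarray:
    u = rng.random(size)
    return np.floor(
        (xmin - 0.5) * (1 - u) ** (-1.0 / (alpha - 1.0)) + 0.5
    ).astype(np.int64)


def fit_power_law(
    degrees,
    n_bootstrap: int = 1000,
    seed: int = 0,
    max_xmin_candidates: int = 30,
) -> PowerLawFit:
    """Fit a discrete power law and bootstrap its goodness of fit.

    The bootstrap is semi-parametric: each replicate draws the below-xmin
    portion from the empirical data and the tail from the fitted model, then
    refits (alpha, xmin) and records its KS statistic; ks_p is the fraction
    of replicates with KS >= the observed one.
    """
    degrees = np.asarray(list(degrees), dtype=np.int64)
    degrees = degrees[degrees > 0]
    if degrees.size < 50:
        raise ValueError("need at least 50 positive degrees")
    if np.all(degrees == degrees[0]):
        raise ValueError("degenerate distribution: all degrees equal")
    rng = np.random.default_rng(seed)

    candidates = _xmin_candidates(degrees, max_xmin_candidates)
    alpha, xmin, ks = _fit_tail(degrees, candidates)
    tail = degrees[degrees >= xmin]
    body = degrees[degrees < xmin]
    r2 = _qq_r2(tail, alpha, xmin)

    n = degrees.size
    p_tail = tail.size / n
    ks_boot = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        from_tail = rng.random(n) < p_tail
        n_t = int(from_tail.sum())
        sim = np.empty(n, dtype=np.int64)
        sim[:n_t] = sample_discrete_powerlaw(rng, alpha, xmin, n_t)
        if n - n_t > 0:
            if body.size:
                sim[n_t:] = rng.choice(body, size=n - n_t, replace=True)
            else:
                sim[n_t:] = sample_discrete_powerlaw(rng, alpha, xmin, n - n_t)
        sim_candidates = _xmin_candidates(sim, max_xmin_candidates)
        try:
            _, _, ks_i = _fit_tail(sim, sim_candidates)
        except ValueError:
            ks_i = np.inf
        ks_boot[i] = ks_i
    ks_p = float(np.mean(ks_boot >= ks)) if n_bootstrap else float("nan")
    return PowerLawFit(
        alpha=alpha,
        xmin=xmin,
        qq_r2=r2,
        ks_stat=ks,
        ks_p=ks_p,
        n_bootstrap=n_bootstrap,
        n_tail=int(tail.size),
    )


def identify_hubs(
    network: RegulatoryNetwork, percentile: float = 99.0
) -> list[str]:
    """Target nodes at or above the in-degree percentile (ties included)."""
    deg = network.in_degrees()
    if len(deg) < 100:
        raise ValueError("need >= 100 target nodes for a stable 99th percentile")
    values = np.array(list(deg.values()))
    threshold = np.percentile(values, percentile)
    return sorted(g for g, d in deg.items() if d >= threshold)


def _to_digraph(network: RegulatoryNetwork) -> nx.DiGraph:
    G = nx.DiGraph()
    for tf, gene, w in network.edges:
        G.add_edge(tf, gene, weight=w)
    return G


def detect_modules(
    network: RegulatoryNetwork | nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
) -> ModularityResult:
    """Louvain partition of the undirected projection.

    Q is always reported at the resolution-1 definition, whatever resolution
    steered the partition.
    """
    G = network if isinstance(network, nx.Graph) else _to_digraph(network)
    U = nx.Graph(G.to_undirected() if G.is_directed() else G)
    communities = nx.community.louvain_communities(
        U, resolution=resolution, seed=seed, weight=None
    )
    partition = {
        node: i for i, comm in enumerate(communities) for node in comm
    }
    Q = nx.community.modularity(U, communities, weight=None, resolution=1.0)
    return ModularityResult(partition=partition, Q=float(Q), resolution=resolution)


def resolution_sweep(
    network: RegulatoryNetwork | nx.Graph,
    resolutions=(0.7, 0.8, 0.9, 1.0, 1.1, 1.2),
    seed: int = 0,
) -> dict[float, ModularityResult]:
    return {r: detect_modules(network, resolution=r, seed=seed) for r in resolutions}


def rewire_null(
    network: RegulatoryNetwork | nx.DiGraph,
    n_graphs: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Maximum-modularity values of degree-preserving rewired graphs.

    Each null graph is generated by attempted directed double-edge swaps
    (``swaps_per_edge x |E|`` attempts), which preserve every node's in- and
    out-degree exactly; modularity is computed with the same Louvain
    partitioner as for the observed graph.
    """
    G = network if isinstance(network, nx.DiGraph) else _to_digraph(network)
    if G.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    null_q = np.empty(n_graphs)
    n_attempts = swaps_per_edge * G.number_of_edges()
    for i in range(n_graphs):
        H = G.copy()
        try:
            nx.directed_edge_swap(
                H,
                nswap=n_attempts,
                max_tries=n_attempts * 100,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # ran out of tries; keep the partial rewiring
        res = detect_modules(H, resolution=resolution, seed=int(rng.integers(2**31)))
        null_q[i] = res.Q
    return null_q


def modularity_significance(
    network: RegulatoryNetwork | nx.DiGraph,
    n_graphs: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
    resolution: float = 1.0,
) -> ModularityResult:
    """Observed Louvain modularity against the rewired-graph null ensemble."""
    observed = detect_modules(network, resolution=resolution, seed=seed)
    null_q = rewire_null(
        network, n_graphs=n_graphs, swaps_per_edge=swaps_per_edge, seed=seed,
        resolution=resolution,
    )
    p = (1 + int(np.sum(null_q >= observed.Q))) / (n_graphs + 1)
    return ModularityResult(
        partition=observed.partition,
        Q=observed.Q,
        resolution=resolution,
        null_Q=null_q,
        p=p,
    )


def module_summary(
    network: RegulatoryNetwork | nx.Graph, partition: dict[str, int]
) -> tuple[dict[int, float], float]:
    """Per-module node share (percent) and intra-module edge fraction."""
    G = network if isinstance(network, nx.Graph) else _to_digraph(network)
    nodes = list(G.nodes)
    missing = [n for n in nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    counts = Counter(partition[n] for n in nodes)
    shares = {m: 100.0 * c / len(nodes) for m, c in counts.items()}
    edges = list(G.edges)
    intra = sum(partition[u] == partition[v] for u, v in edges)
    return shares, intra / len(edges) if edges else float("nan")


def modularity_oracle_free(G: nx.Graph, partition: dict) -> float:
    """Newman modularity via networkx, for CLI/report use."""
    comms: dict[int, set] = {}
    for node, m in partition.items():
        comms.setdefault(m, set()).add(node)
    return float(nx.community.modularity(G, comms.values(), weight=None))
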