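"""Signed co-occurrence networks: construction, topology, stability, roles.

Networks are built from Pearson correlations of log(count+1)-transformed
abundances among prevalent taxa (≥ 40 % occurrence by default), thresholded
either at a fixed |r| cutoff or by a random-matrix-theory (RMT) criterion:
the smallest cutoff at which the nearest-neighbour spacing distribution of
the thresholded adjacency spectrum follows Poisson statistics (uncorrelated
eigenvalues, modular structure) rather than the Wigner-Dyson statistics of a
dense random matrix.

All topology and stability metrics operate on the unweighted adjacency;
signed correlation weights are kept as edge attributes. The stability panel
follows the common molecular-ecological-network workflow: Maslov-Sneppen
degree-preserving rewiring for null ensembles, random node-removal
robustness, natural connectivity, and Zi-Pi node roles (module hubs at
Zi ≥ 2.5, connectors at Pi ≥ 0.62).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .io import AbundanceTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# construction


def filter_prevalence(table: AbundanceTable, min_fraction: float = 0.4) -> AbundanceTable:
    """Keep taxa occurring in at least ``ceil(min_fraction · n_samples)`` samples."""
    need = int(np.ceil(min_fraction * table.n_samples))
    keep = table.presence().sum(axis=1) >= need
    if not keep.any():
        raise ValueError(
            f"no taxa present in ≥ {need} of {table.n_samples} samples "
            f"(max occupancy {int(table.presence().sum(axis=1).max())})"
        )
    return table.subset_taxa(keep)


def correlation_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pearson correlation of ln(count + 1) abundances between taxa."""
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for correlations")
    log_counts = np.log1p(table.counts.astype(float))
    variable = log_counts.std(axis=1) > 0
    if not variable.all():
        logger.warning("dropping %d zero-variance taxa", int((~variable).sum()))
    log_counts = log_counts[variable]
    taxa = [t for t, v in zip(table.taxon_ids, variable) if v]
    r = np.corrcoef(log_counts)
    return pd.DataFrame(r, index=taxa, columns=taxa)


# -- RMT thresholding -------------------------------------------------------


def _nnsd_chi2(eigenvalues: np.ndarray, n_bins: int = 20, s_max: float = 3.0):
    """χ² distances of the NNSD to Poisson and to the GOE Wigner surmise.

    Eigenvalues are unfolded with a low-order polynomial fit to the empirical
    cumulative spectral function so that mean spacing is 1; near-degenerate
    eigenvalues are collapsed first.
    """
    lam = np.sort(eigenvalues)
    lam = lam[np.concatenate(([True], np.diff(lam) > 1e-8))]
    n = len(lam)
    if n < 20:
        return None
    degree = min(7, max(3, n // 20))
    coeffs = np.polynomial.polynomial.polyfit(lam, np.arange(n) / (n - 1), degree)
    unfolded = n * np.polynomial.polynomial.polyval(lam, coeffs)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) < 10:
        return None
    spacings = spacings / spacings.mean()
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(np.clip(spacings, 0, s_max - 1e-9), bins=edges)
    observed = observed / len(spacings)
    mid_lo, mid_hi = edges[:-1], edges[1:]
    poisson = np.exp(-mid_lo) - np.exp(-mid_hi)
    goe = np.exp(-np.pi * mid_lo**2 / 4.0) - np.exp(-np.pi * mid_hi**2 / 4.0)
    chi2_p = float(np.sum((observed - poisson) ** 2 / np.maximum(poisson, 1e-12)))
    chi2_g = float(np.sum((observed - goe) ** 2 / np.maximum(goe, 1e-12)))
    return chi2_p, chi2_g


def rmt_threshold(
    corr: pd.DataFrame,
    t_min: float = 0.3,
    t_max: float = 0.95,
    step: float = 0.01,
    chi2_accept: float = 1.5,
    min_nodes: int = 20,
    fallback: float = 0.8,
) -> float:
    """RMT-guided choice of the |r| cutoff.

    Scans thresholds from ``t_min`` upward; at each, the spectrum of the
    largest connected component's adjacency is unfolded and its
    nearest-neighbour spacing distribution compared (χ², 20 bins) to the
    Poisson law ``exp(−s)`` and the GOE Wigner surmise. The smallest
    threshold where Poisson fits better *and* its χ² falls below
    ``chi2_accept`` is returned. If no candidate qualifies (including when no
    component reaches ``min_nodes``), ``fallback`` is returned with a
    warning.
    """
    r = corr.to_numpy(float).copy()
    np.fill_diagonal(r, 0.0)
    for t in np.arange(t_min, t_max + step / 2, step):
        adjacency = (np.abs(r) >= t).astype(float)
        g = nx.from_numpy_array(adjacency)
        components = list(nx.connected_components(g))
        if not components:
            continue
        biggest = max(components, key=len)
        if len(biggest) < min_nodes:
            continue
        sub = adjacency[np.ix_(sorted(biggest), sorted(biggest))]
        fit = _nnsd_chi2(np.linalg.eigvalsh(sub))
        if fit is None:
            continue
        chi2_poisson, chi2_goe = fit
        if chi2_poisson < chi2_goe and chi2_poisson < chi2_accept:
            return float(round(t, 10))
    warnings.warn(
        f"RMT scan found no Poisson-consistent threshold; using fallback {fallback}",
        stacklevel=2,
    )
    return float(fallback)


def build_network(
    corr: pd.DataFrame, threshold: float, annotation: pd.DataFrame | None = None
) -> nx.Graph:
    """Threshold the correlation matrix into a signed undirected graph.

    Edge iff |r| ≥ threshold (i ≠ j); edge weight = r, sign = ±1. Isolated
    nodes are removed; trophic-group attributes attached when available.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    taxa = list(corr.index)
    r = corr.to_numpy(float)
    net = nx.Graph()
    rows, cols = np.nonzero(np.triu(np.abs(r) >= threshold, k=1))
    for i, j in zip(rows, cols):
        net.add_edge(taxa[i], taxa[j], weight=float(r[i, j]), sign=1 if r[i, j] > 0 else -1)
    if net.number_of_edges() == 0:
        raise ValueError(f"no edges at threshold {threshold}")
    if annotation is not None and "trophic_group" in annotation.columns:
        for node in net.nodes:
            if node in annotation.index:
                net.nodes[node]["trophic_group"] = annotation.loc[node, "trophic_group"]
    return net


# ---------------------------------------------------------------------------
# modules + topology


def detect_modules(net: nx.Graph, seed: int = 0):
    """Louvain-style multilevel modularity maximisation (unweighted).

    Returns ``(modules, Q)`` where ``modules`` maps node → module index and
    Q is the Newman-Girvan modularity of the partition.
    """
    communities = nx.community.louvain_communities(net, weight=None, seed=seed)
    q = nx.community.modularity(net, communities, weight=None)
    modules = {n: k for k, comm in enumerate(communities) for n in comm}
    return modules, float(q)


@dataclass(frozen=True)
class TopologyPanel:
    """Standard complexity metrics of one (unweighted) network."""

    total_nodes: int
    total_links: int
    positive_edge_fraction: float
    average_degree: float
    average_clustering_coefficient: float
    average_path_distance: float
    harmonic_geodesic_distance: float
    geodesic_efficiency: float
    connectedness: float
    modularity: float
    transitivity: float
    powerlaw_R2: float

    def as_dict(self) -> dict:
        return asdict(self)


def _degree_powerlaw_r2(net: nx.Graph) -> float:
    """R² of the OLS fit of log P(k) on log k over observed degrees ≥ 1."""
    degrees = np.array([d for _, d in net.degree()])
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if len(ks) < 3:
        return np.nan
    x = np.log(ks.astype(float))
    y = np.log(counts / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def topology_panel(net: nx.Graph, modularity: float | None = None, seed: int = 0) -> TopologyPanel:
    """Compute the complexity/topology panel for a signed network.

    Geodesics: ``average_path_distance`` averages over connected pairs only;
    ``harmonic_geodesic_distance`` is the harmonic mean of finite geodesics;
    ``geodesic_efficiency`` averages 1/d over *all* pairs (disconnected pairs
    contribute 0); ``connectedness`` is the fraction of pairs joined by a
    path.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    positive_fraction = float(np.mean([s > 0 for s in signs])) if signs else np.nan
    total_pairs = n * (n - 1) / 2
    path_sum = 0.0
    inv_sum = 0.0
    connected_pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, dist in lengths.items():
            if target == source or dist == 0:
                continue
            path_sum += dist
            inv_sum += 1.0 / dist
            connected_pairs += 1
    connected_pairs //= 2  # each unordered pair seen twice
    path_sum /= 2.0
    inv_sum /= 2.0
    if modularity is None:
        _, modularity = detect_modules(net, seed=seed)
    return TopologyPanel(
        total_nodes=n,
        total_links=m,
        positive_edge_fraction=positive_fraction,
        average_degree=2.0 * m / n,
        average_clustering_coefficient=float(nx.average_clustering(net)),
        average_path_distance=path_sum / connected_pairs if connected_pairs else np.nan,
        harmonic_geodesic_distance=connected_pairs / inv_sum if inv_sum else np.nan,
        geodesic_efficiency=inv_sum / total_pairs if total_pairs else np.nan,
        connectedness=connected_pairs / total_pairs if total_pairs else np.nan,
        modularity=float(modularity),
        transitivity=float(nx.transitivity(net)),
        powerlaw_R2=_degree_powerlaw_r2(net),
    )


# ---------------------------------------------------------------------------
# null ensembles + stability


def maslov_sneppen(net: nx.Graph, n_swaps_per_edge: int = 100, seed: int = 0) -> nx.Graph:
    """Degree-preserving double-edge-swap randomisation.

    Attempts ``n_swaps_per_edge × m`` swaps; candidates creating self-loops
    or parallel edges are rejected. If no swap ever succeeds (e.g. a star),
    the graph is returned unchanged with a warning. Edge attributes are not
    carried over (null graphs are topological baselines).
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    rewired = nx.Graph()
    rewired.add_nodes_from(net.nodes(data=True))
    rewired.add_edges_from(net.edges())
    edges = list(rewired.edges())
    m = len(edges)
    successes = 0
    for _ in range(n_swaps_per_edge * m):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d, c-b
        if len({a, b, c, d}) < 4:
            continue
        if rewired.has_edge(a, d) or rewired.has_edge(c, b):
            continue
        rewired.remove_edge(a, b)
        rewired.remove_edge(c, d)
        rewired.add_edge(a, d)
        rewired.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)
        successes += 1
    if successes == 0:
        warnings.warn("no valid Maslov-Sneppen swap exists; graph returned unchanged",
                      stacklevel=2)
    return rewired


def random_ensemble_panel(net: nx.Graph, n_random: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean ± sd of the topology panel over Maslov-Sneppen randomisations."""
    records = []
    for k in range(n_random):
        null = maslov_sneppen(net, seed=seed + k)
        records.append(topology_panel(null, seed=seed + k).as_dict())
    frame = pd.DataFrame(records)
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


def natural_connectivity(net: nx.Graph) -> float:
    """ln of the average eigenvalue exponential of the unweighted adjacency.

    Computed with a max-eigenvalue shift so large graphs do not overflow.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    adjacency = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(adjacency)
    shift = lam.max()
    return float(shift + np.log(np.exp(lam - shift).mean()))


@dataclass
class RobustnessCurve:
    """Stability under random node removal."""

    curve: pd.DataFrame  # fraction, lcc_mean, lcc_sd, nat_conn_mean, nat_conn_sd
    auc: float  # area under the mean largest-component curve


def robustness_curve(
    net: nx.Graph, fractions=None, n_reps: int = 100, seed: int = 0
) -> RobustnessCurve:
    """Random-extinction robustness.

    For each removal fraction f, ``⌊f·N⌋`` uniformly chosen nodes are
    deleted; the largest-component fraction (relative to the remaining
    nodes) and natural connectivity of the remnant are recorded, mean ± sd
    over ``n_reps`` replicates. The scalar robustness is the area under the
    mean largest-component curve (trapezoidal, normalised by the fraction
    range).
    """
    if fractions is None:
        fractions = np.arange(0.0, 0.8001, 0.05)
    fractions = np.asarray(list(fractions), float)
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        k = int(np.floor(f * n))
        lcc_vals, nc_vals = [], []
        reps = 1 if k == 0 else n_reps
        for _ in range(reps):
            if k:
                drop = set(rng.choice(n, size=k, replace=False))
                remnant = net.subgraph([nd for i, nd in enumerate(nodes) if i not in drop])
            else:
                remnant = net
            if remnant.number_of_nodes() == 0:
                lcc_vals.append(0.0)
                nc_vals.append(0.0)
                continue
            biggest = max(nx.connected_components(remnant), key=len)
            lcc_vals.append(len(biggest) / remnant.number_of_nodes())
            nc_vals.append(natural_connectivity(remnant))
        rows.append(
            {
                "fraction": f,
                "lcc_mean": float(np.mean(lcc_vals)),
                "lcc_sd": float(np.std(lcc_vals, ddof=1)) if len(lcc_vals) > 1 else 0.0,
                "nat_conn_mean": float(np.mean(nc_vals)),
                "nat_conn_sd": float(np.std(nc_vals, ddof=1)) if len(nc_vals) > 1 else 0.0,
            }
        )
    curve = pd.DataFrame(rows)
    span = curve["fraction"].iloc[-1] - curve["fraction"].iloc[0]
    auc = float(np.trapezoid(curve["lcc_mean"], curve["fraction"]) / span) if span else np.nan
    return RobustnessCurve(curve, auc)


# ---------------------------------------------------------------------------
# node roles


ROLE_ZI = 2.5
ROLE_PI = 0.62


def zi_pi(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module's mean
    and sd (sd = 0 → Zi = 0, logged); Pi = 1 − Σ_s (k_is / k_i)². Roles
    follow the conventional cutoffs: module hub (Zi ≥ 2.5, Pi < 0.62),
    connector (Zi < 2.5, Pi ≥ 0.62), network hub (both), else peripheral.
    Isolated nodes have undefined Pi and are reported peripheral.
    """
    missing = set(net.nodes) - set(modules)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} nodes")
    module_ids = sorted(set(modules.values()))
    within_degree = {}
    for node in net.nodes:
        own = modules[node]
        within_degree[node] = sum(1 for nb in net.neighbors(node) if modules[nb] == own)
    member_lists = {m: [n for n in net.nodes if modules[n] == m] for m in module_ids}
    rows = []
    for node in net.nodes:
        own = modules[node]
        peers = np.array([within_degree[p] for p in member_lists[own]], float)
        sd = peers.std(ddof=0)
        if sd == 0:
            logger.debug("module %s has constant within-degree; Zi set to 0", own)
            zi = 0.0
        else:
            zi = (within_degree[node] - peers.mean()) / sd
        k = net.degree(node)
        if k == 0:
            logger.warning("isolated node %s: Pi undefined, reported peripheral", node)
            pi = np.nan
            role = "peripheral"
        else:
            per_module = np.zeros(len(module_ids))
            for nb in net.neighbors(node):
                per_module[module_ids.index(modules[nb])] += 1
            pi = 1.0 - float(((per_module / k) ** 2).sum())
            if zi >= ROLE_ZI and pi >= ROLE_PI:
                role = "network_hub"
            elif zi >= ROLE_ZI:
                role = "module_hub"
            elif pi >= ROLE_PI:
                role = "connector"
            else:
                role = "peripheral"
        rows.append({"node": node, "module": own, "Zi": zi, "Pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


def annotate_network(net: nx.Graph, modules: dict, roles: pd.DataFrame) -> None:
    """Attach module / Zi / Pi / role attributes in place (for writing)."""
    for node in net.nodes:
        net.nodes[node]["module"] = modules[node]
        net.nodes[node]["Zi"] = float(roles.loc[node, "Zi"])
        net.nodes[node]["Pi"] = float(roles.loc[node, "Pi"])
        net.nodes[node]["role"] = roles.loc[node, "role"]


def trophic_edge_summary(net: nx.Graph, annotation: pd.DataFrame):
    """Edge counts by trophic-group pair and per-group degree shares.

    Returns ``(edge_matrix, degree_share)``: a symmetric group × group
    DataFrame of edge counts and a Series of each group's share of total
    degree (sums to 1).
    """
    def group_of(node):
        if node in net.nodes and "trophic_group" in net.nodes[node]:
            return net.nodes[node]["trophic_group"]
        if node in annotation.index:
            return annotation.loc[node, "trophic_group"]
        raise ValueError(f"node {node} lacks a trophic annotation")

    groups = sorted({group_of(n) for n in net.nodes})
    matrix = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for u, v in net.edges:
        gu, gv = group_of(u), group_of(v)
        matrix.loc[gu, gv] += 1
        if gu != gv:
            matrix.loc[gv, gu] += 1
    degree_total = sum(d for _, d in net.degree())
    share = pd.Series(0.0, index=groups)
    for node, degree in net.degree():
        share[group_of(node)] += degree
    if degree_total:
        share /= degree_total
    return matrix, share
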