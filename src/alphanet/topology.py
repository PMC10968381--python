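"""Graph topology of thresholded connectivity matrices.

Matrices are proportionally thresholded (top fraction of edges by weight,
weights kept) across a grid of ten sparsities from 0.05 to 0.50, then
characterized by the Onnela weighted clustering coefficient, weighted local
efficiency (path lengths 1/normalized-weight), shortest-path betweenness
centrality for hub detection, and binary rich-club curves normalized by
degree-preserving rewired null graphs.  Disconnected node pairs contribute
zero efficiency (infinite distance); connectedness is not enforced at low
sparsity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .io import Montage
from .spectral import two_sample_t

__all__ = [
    "DEFAULT_SPARSITIES",
    "ThresholdedGraph",
    "RichClubCurve",
    "HubSet",
    "proportional_threshold",
    "clustering_coefficient",
    "local_efficiency",
    "betweenness",
    "identify_hubs",
    "rich_club",
    "hemisphere_subnetwork",
    "rich_club_laterality",
    "subject_topology",
    "compare_topology_groups",
]

# ten proportional thresholds, 0.05 to 0.50
DEFAULT_SPARSITIES = tuple(np.round(np.arange(1, 11) * 0.05, 2))


@dataclass
class ThresholdedGraph:
    """Weighted undirected graph keeping the top-``sparsity`` fraction of edges.

    Edge attributes: ``weight`` (original), ``nweight`` (weight / max weight)
    and ``length`` (1 / nweight, the distance used for paths).
    """

    graph: nx.Graph
    sparsity: float
    labels: list[str]


def _matrix_and_labels(cm) -> tuple[np.ndarray, list[str]]:
    if isinstance(cm, ConnectivityMatrix):
        return cm.values, list(cm.channel_labels)
    matrix, labels = cm
    return np.asarray(matrix, dtype=float), list(labels)


def proportional_threshold(cm, sparsity: float) -> ThresholdedGraph:
    """Retain the ``round(s * n(n-1)/2)`` largest-weight edges.

    Ties are broken by lexicographic label order so the retained edge set is
    deterministic and nested across increasing sparsity.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    matrix, labels = _matrix_and_labels(cm)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    edges = sorted(
        ((matrix[i, j], labels[i], labels[j]) for i, j in zip(*iu)),
        key=lambda e: (-e[0], e[1], e[2]),
    )
    m = int(round(sparsity * n * (n - 1) / 2))
    kept = edges[:m]
    wmax = max((w for w, *_ in kept), default=1.0)
    wmax = wmax if wmax > 0 else 1.0
    g = nx.Graph()
    g.add_nodes_from(labels)
    for w, a, b in kept:
        nw = w / wmax
        g.add_edge(a, b, weight=w, nweight=nw,
                   length=(1.0 / nw) if nw > 0 else np.inf)
    return ThresholdedGraph(graph=g, sparsity=sparsity, labels=labels)


def clustering_coefficient(tg: ThresholdedGraph) -> tuple[dict, float]:
    """Onnela weighted clustering: geometric-mean triangle intensity with
    weights normalized to the graph maximum; degree < 2 nodes score 0.
    Returns (per-node dict, network mean)."""
    per_node = nx.clustering(tg.graph, weight="nweight")
    mean = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, mean


def local_efficiency(tg: ThresholdedGraph) -> tuple[dict, float]:
    """Weighted local efficiency: for each node, the mean inverse shortest
    path length among its neighbors within the neighbor-induced subgraph
    (lengths 1/normalized-weight); degree < 2 nodes score 0."""
    g = tg.graph
    per_node = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            per_node[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        total = 0.0
        for u, dists in nx.all_pairs_dijkstra_path_length(sub, weight="length"):
            for w, d in dists.items():
                if w != u and np.isfinite(d) and d > 0:
                    total += 1.0 / d
        per_node[v] = total / (k * (k - 1))
    mean = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, mean


def betweenness(tg: ThresholdedGraph) -> dict:
    """Unnormalized shortest-path betweenness with 1/normalized-weight edge
    lengths; equal-length paths split the count evenly."""
    return nx.betweenness_centrality(tg.graph, weight="length", normalized=False)


@dataclass
class HubSet:
    hubs: list[str]
    criterion: str
    values: dict = field(default_factory=dict)


def identify_hubs(values: dict, sd_multiplier: float = 1.0) -> HubSet:
    """Nodes whose betweenness strictly exceeds mean + ``sd_multiplier`` * SD."""
    if len(values) < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    arr = np.array(list(values.values()), dtype=float)
    cut = arr.mean() + sd_multiplier * arr.std()
    hubs = sorted(v for v, x in values.items() if x > cut)
    return HubSet(hubs=hubs,
                  criterion=f"betweenness > mean + {sd_multiplier:g} SD ({cut:.4g})",
                  values=dict(values))


@dataclass
class RichClubCurve:
    """Raw and normalized rich-club coefficients over degree levels ``k``.

    ``defined[k]`` is False where fewer than 2 nodes exceed degree k (raw
    curve undefined) or where the null mean vanishes (normalization
    undefined); such entries are NaN, not errors.
    """

    k: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray
    defined: np.ndarray
    n_nulls: int


def _raw_rich_club(g: nx.Graph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary rich-club phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1))."""
    deg = dict(g.degree())
    kmax = max(deg.values(), default=0)
    ks = np.arange(max(kmax, 1))
    phi = np.full(len(ks), np.nan)
    defined = np.zeros(len(ks), dtype=bool)
    for idx, k in enumerate(ks):
        rich = [v for v, d in deg.items() if d > k]
        if len(rich) < 2:
            continue
        e = g.subgraph(rich).number_of_edges()
        phi[idx] = 2.0 * e / (len(rich) * (len(rich) - 1))
        defined[idx] = True
    return ks, phi, defined


def rich_club(tg: ThresholdedGraph, n_nulls: int = 100, seed: int = 0) -> RichClubCurve:
    """Rich-club curve of the binary skeleton, normalized by the mean curve
    of ``n_nulls`` degree-preserving double-edge-swap rewirings (10 x E swaps
    each)."""
    if n_nulls < 10:
        raise ValueError("use at least 10 null graphs")
    g = nx.Graph(tg.graph.edges)  # binary skeleton
    g.add_nodes_from(tg.graph.nodes)
    ks, phi, defined = _raw_rich_club(g)
    e = g.number_of_edges()
    null_phis = np.full((n_nulls, len(ks)), np.nan)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    for i in range(n_nulls):
        null = g.copy()
        if e >= 2:
            try:
                nx.double_edge_swap(null, nswap=10 * e, max_tries=1000 * e,
                                    seed=int(rng.integers(2**31)))
            except nx.NetworkXException:
                pass  # no swappable edge pairs (e.g. complete graph)
        _, nphi, _ = _raw_rich_club(null)
        null_phis[i, : len(nphi)] = nphi
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN k levels
        null_mean = np.nanmean(null_phis, axis=0)
        phi_norm = phi / null_mean
    ok = defined & np.isfinite(phi_norm)
    phi_norm = np.where(ok, phi_norm, np.nan)
    return RichClubCurve(k=ks, phi=phi, phi_norm=phi_norm, defined=ok,
                         n_nulls=n_nulls)


def hemisphere_subnetwork(cm: ConnectivityMatrix, montage: Montage,
                          side: str) -> ConnectivityMatrix:
    """Restrict a connectivity matrix to one hemisphere's scalp channels
    (midline excluded)."""
    side_labels = montage.hemisphere_labels(side)
    keep = [l for l in cm.channel_labels if l in side_labels]
    if not keep:
        raise ValueError(f"no {side}-hemisphere channels in the matrix")
    idx = [cm.channel_labels.index(l) for l in keep]
    return ConnectivityMatrix(values=cm.values[np.ix_(idx, idx)].copy(),
                              band=cm.band, n_epochs=cm.n_epochs,
                              channel_labels=keep)


def rich_club_laterality(cm: ConnectivityMatrix, montage: Montage,
                         sparsity: float = 0.2, n_nulls: int = 50,
                         seed: int = 0) -> dict:
    """Mean normalized rich-club of the left vs right hemisphere subnetwork,
    compared over the k levels where both curves are defined."""
    out = {}
    curves = {}
    for i, side in enumerate(("left", "right")):
        sub = hemisphere_subnetwork(cm, montage, side)
        tg = proportional_threshold(sub, sparsity)
        curves[side] = rich_club(tg, n_nulls=n_nulls, seed=seed + i)
    kmax = min(len(curves["left"].k), len(curves["right"].k))
    both = curves["left"].defined[:kmax] & curves["right"].defined[:kmax]
    for side in ("left", "right"):
        vals = curves[side].phi_norm[:kmax][both]
        out[side] = float(np.mean(vals)) if vals.size else np.nan
    out["left_minus_right"] = out["left"] - out["right"]
    return out


def subject_topology(cm: ConnectivityMatrix,
                     sparsities=DEFAULT_SPARSITIES,
                     hub_sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Network-mean clustering and local efficiency plus per-node betweenness
    and hub flags across the sparsity grid; one tidy row per sparsity."""
    rows = []
    for s in sparsities:
        tg = proportional_threshold(cm, s)
        _, c_mean = clustering_coefficient(tg)
        _, e_mean = local_efficiency(tg)
        bc = betweenness(tg)
        hubs = identify_hubs(bc, sd_multiplier=hub_sd_multiplier)
        rows.append({"sparsity": s, "clustering": c_mean,
                     "local_efficiency": e_mean,
                     "hubs": ",".join(hubs.hubs),
                     "betweenness": bc})
    return pd.DataFrame(rows)


def compare_topology_groups(group_a: dict, group_b: dict,
                            sparsities=DEFAULT_SPARSITIES) -> pd.DataFrame:
    """Per-sparsity two-sample t for each metric plus an area-under-curve row.

    ``group_a``/``group_b`` map metric name -> (n_subjects, n_sparsities)
    array of per-subject network means.
    """
    sparsities = np.asarray(sparsities, dtype=float)
    rows = []
    for metric in group_a:
        a = np.asarray(group_a[metric], dtype=float)
        b = np.asarray(group_b[metric], dtype=float)
        if a.shape[1] != len(sparsities) or b.shape[1] != len(sparsities):
            raise ValueError(f"metric {metric}: columns must match the sparsity grid")
        t, p = two_sample_t(a, b)
        t, p = np.atleast_1d(t), np.atleast_1d(p)
        for s, ti, pi in zip(sparsities, t, p):
            rows.append({"metric": metric, "sparsity": s, "t": ti, "p": pi})
        auc_a = np.trapezoid(a, sparsities, axis=1)
        auc_b = np.trapezoid(b, sparsities, axis=1)
        t_auc, p_auc = two_sample_t(auc_a[:, None], auc_b[:, None])
        rows.append({"metric": metric, "sparsity": np.nan,
                     "t": float(t_auc), "p": float(p_auc)})
    return pd.DataFrame(rows)
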