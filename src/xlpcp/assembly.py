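"""Cohesiveness-based aggregation of peak-pair edges into complexes.

The thresholded interaction network has peaks as nodes and classifier scores
as edge weights.  Complex candidates are grown greedily from unclustered
seeds, maximizing the cohesiveness

    f(V) = w_in / (w_in + w_bound + penalty * |V|)

where ``w_in`` is the total edge weight inside the candidate and ``w_bound``
the total weight crossing its boundary.  Grown candidates with squared
overlap >= 0.8 are merged, a haircut removes weakly attached vertices, and
candidates below the minimum size ``s`` or weighted density ``d`` are
discarded.  Protein-level complexes are the deduplicated groups of the
member peaks, so one protein may legitimately appear in several complexes.

The density floor ``d`` and haircut strength are tuned by a 10 x 10 grid
search maximizing the number of gold-standard positive peak pairs placed in
a common complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class PredictedComplex:
    member_peaks: frozenset  # node ids
    member_groups: tuple[str, ...]  # deduplicated, sorted
    cohesiveness: float
    density: float


@dataclass
class GridSearchResult:
    best_d: float
    best_haircut: float
    objective: int
    table: pd.DataFrame  # columns d, haircut, objective, n_complexes
    complexes: list[PredictedComplex]  # at the optimum


def build_network(scored_pairs) -> nx.Graph:
    """Interaction network from thresholded scored pairs.

    Nodes are peaks keyed ``(group_id, apex_fraction)`` carrying the group
    id; parallel pairs between the same two peaks keep the larger weight.
    """
    g = nx.Graph()
    for sp in scored_pairs:
        a = (sp.pair.group_a, sp.pair.peak_a.apex_fraction)
        b = (sp.pair.group_b, sp.pair.peak_b.apex_fraction)
        if a == b:
            continue
        w = float(sp.score)
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    for node in g.nodes:
        g.nodes[node]["group_id"] = node[0]
    return g


def cohesiveness(graph: nx.Graph, nodes: set, penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty * |V|)."""
    w_in = w_bound = 0.0
    for u in nodes:
        for v, data in graph[u].items():
            if v in nodes:
                w_in += data["weight"] / 2.0
            else:
                w_bound += data["weight"]
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def grow_cluster(graph: nx.Graph, seed, penalty: float = 2.0) -> set:
    """Greedy cohesiveness maximization from a single seed node.

    At each step the best single addition of a boundary vertex or removal of
    an internal vertex is applied if it strictly increases cohesiveness;
    ties are broken deterministically by node id.  Incremental w_in/w_bound
    bookkeeping keeps each step linear in the boundary size.
    """
    nodes = {seed}
    w_in = 0.0
    w_bound = sum(d["weight"] for _, d in graph[seed].items())

    def f(wi: float, wb: float, size: int) -> float:
        denom = wi + wb + penalty * size
        return wi / denom if denom > 0 else 0.0

    current = f(w_in, w_bound, 1)
    while True:
        best = None  # (f, kind, node, new_w_in, new_w_bound)
        boundary = {v for u in nodes for v in graph[u] if v not in nodes}
        for v in sorted(boundary):
            w_to_in = sum(
                graph[v][u]["weight"] for u in graph[v] if u in nodes
            )
            w_to_out = sum(
                graph[v][u]["weight"] for u in graph[v] if u not in nodes
            )
            fi = f(w_in + w_to_in, w_bound - w_to_in + w_to_out, len(nodes) + 1)
            if best is None or fi > best[0]:
                best = (fi, "add", v, w_in + w_to_in, w_bound - w_to_in + w_to_out)
        if len(nodes) > 1:
            for v in sorted(nodes):
                w_to_in = sum(
                    graph[v][u]["weight"] for u in graph[v] if u in nodes
                )
                w_to_out = sum(
                    graph[v][u]["weight"] for u in graph[v] if u not in nodes
                )
                fi = f(w_in - w_to_in, w_bound + w_to_in - w_to_out, len(nodes) - 1)
                if best is None or fi > best[0]:
                    best = (fi, "remove", v, w_in - w_to_in, w_bound + w_to_in - w_to_out)
        if best is None or best[0] <= current + 1e-12:
            return nodes
        current, _, v, w_in, w_bound = best
        if best[1] == "add":
            nodes.add(v)
        else:
            nodes.discard(v)


def _overlap_sq(a: set, b: set) -> float:
    inter = len(a & b)
    return (inter * inter) / (len(a) * len(b)) if a and b else 0.0


def grow_and_merge(
    graph: nx.Graph, penalty: float = 2.0, overlap_merge: float = 0.8
) -> list[set]:
    """Growth phase over all seeds plus the overlap-merge step.

    Seeds are taken in order of decreasing weighted degree (ties by node
    id); nodes already claimed by a grown cluster are not reseeded.
    """
    if graph.number_of_nodes() == 0:
        return []
    order = sorted(
        graph.nodes, key=lambda n: (-graph.degree(n, weight="weight"), n)
    )
    grown: list[set] = []
    used: set = set()
    for seed in order:
        if seed in used:
            continue
        cluster = grow_cluster(graph, seed, penalty=penalty)
        if cluster not in grown:
            grown.append(cluster)
        used |= cluster

    # merge highly overlapping candidates (union-find over overlap >= 0.8)
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(grown)), 2):
            if _overlap_sq(grown[i], grown[j]) >= overlap_merge:
                grown[i] = grown[i] | grown[j]
                del grown[j]
                merged = True
                break
    return grown


def _haircut(graph: nx.Graph, nodes: set, haircut: float) -> set:
    """Drop vertices with internal weight below ``haircut`` times the
    average internal weight per vertex (single pass)."""
    if len(nodes) < 2 or haircut <= 0:
        return set(nodes)
    w_int = {
        v: sum(graph[v][u]["weight"] for u in graph[v] if u in nodes)
        for v in nodes
    }
    avg = sum(w_int.values()) / len(nodes)
    return {v for v in nodes if w_int[v] >= haircut * avg}


def _density(graph: nx.Graph, nodes: set) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    w_in = sum(
        graph[u][v]["weight"]
        for u, v in combinations(nodes, 2)
        if graph.has_edge(u, v)
    )
    return w_in / (k * (k - 1) / 2.0)


def _finalize(
    graph: nx.Graph,
    clusters: list[set],
    d: float,
    haircut: float,
    s: int,
    penalty: float,
) -> list[PredictedComplex]:
    out = []
    seen = set()
    for cluster in clusters:
        trimmed = _haircut(graph, cluster, haircut)
        if len(trimmed) < s:
            continue
        dens = _density(graph, trimmed)
        if dens < d:
            continue
        key = frozenset(trimmed)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            PredictedComplex(
                member_peaks=key,
                member_groups=tuple(
                    sorted({graph.nodes[v]["group_id"] for v in trimmed})
                ),
                cohesiveness=cohesiveness(graph, trimmed, penalty=penalty),
                density=dens,
            )
        )
    return sorted(out, key=lambda c: sorted(c.member_peaks))


def cluster_one(
    graph: nx.Graph,
    d: float = 0.3,
    haircut: float = 0.0,
    s: int = 2,
    overlap_merge: float = 0.8,
    penalty: float = 2.0,
) -> list[PredictedComplex]:
    """Full greedy-cohesiveness clustering: grow, merge, haircut, filter."""
    grown = grow_and_merge(graph, penalty=penalty, overlap_merge=overlap_merge)
    return _finalize(graph, grown, d=d, haircut=haircut, s=s, penalty=penalty)


def _pairs_coclustered(
    complexes: list[PredictedComplex], gold_pairs: set[frozenset]
) -> int:
    n = 0
    for pair in gold_pairs:
        a, b = tuple(pair)
        if any(
            a in c.member_peaks and b in c.member_peaks for c in complexes
        ):
            n += 1
    return n


def grid_search(
    graph: nx.Graph,
    gold_pairs: set[frozenset],
    d_values=None,
    haircut_values=None,
    s: int = 2,
    overlap_merge: float = 0.8,
    penalty: float = 2.0,
) -> GridSearchResult:
    """10 x 10 grid over (d, haircut) maximizing co-clustered gold pairs.

    The growth + merge phase does not depend on d or haircut, so it is
    computed once and the per-cell haircut/size/density filtering reapplied;
    the result is identical to running the full algorithm per cell.  Ties
    are broken toward smaller d, then smaller haircut.
    """
    d_values = (
        list(d_values) if d_values is not None
        else [round(0.1 * i, 1) for i in range(1, 11)]
    )
    haircut_values = (
        list(haircut_values) if haircut_values is not None
        else [round(0.1 * i, 1) for i in range(1, 11)]
    )
    grown = grow_and_merge(graph, penalty=penalty, overlap_merge=overlap_merge)

    rows = []
    best = None  # (objective, d, haircut, complexes)
    for d in sorted(d_values):
        for h in sorted(haircut_values):
            complexes = _finalize(graph, grown, d=d, haircut=h, s=s, penalty=penalty)
            obj = _pairs_coclustered(complexes, gold_pairs)
            rows.append((d, h, obj, len(complexes)))
            if best is None or obj > best[0]:
                best = (obj, d, h, complexes)
    table = pd.DataFrame(rows, columns=["d", "haircut", "objective", "n_complexes"])
    return GridSearchResult(
        best_d=best[1],
        best_haircut=best[2],
        objective=best[0],
        table=table,
        complexes=best[3],
    )


def complexes_to_table(complexes: list[PredictedComplex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "complex_id": f"C{i + 1:04d}",
                "members": ";".join(c.member_groups),
                "size": len(c.member_peaks),
                "density": c.density,
                "cohesiveness": c.cohesiveness,
            }
            for i, c in enumerate(complexes)
        ],
        columns=["complex_id", "members", "size", "density", "cohesiveness"],
    )


def export_network(graph: nx.Graph, nodes_path, edges_path) -> None:
    """Node/edge TSVs loadable by standard network viewers."""
    pd.DataFrame(
        [
            {"node": f"{n[0]}@{n[1]}", "group_id": n[0], "apex_fraction": n[1]}
            for n in sorted(graph.nodes)
        ]
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "source": f"{u[0]}@{u[1]}",
                "target": f"{v[0]}@{v[1]}",
                "weight": d["weight"],
            }
            for u, v, d in sorted(graph.edges(data=True))
        ]
    ).to_csv(edges_path, sep="\t", index=False)
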