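"""Spatial genome alignment: most-likely polymer paths through candidate spots.

Every candidate localization of locus order ``t`` becomes a node of a
directed acyclic graph; edges run strictly 5'->3' from order ``t`` to order
``t + c`` (1 <= c <= C) and are weighted by the negative-log Gaussian-chain
bond probability, gap-scaled for skipped loci.  A single source and sink with
terminal pseudo-bonds allow up to ``K`` loci to be skipped at either end.
The minimum-cost source->sink path is the maximum-likelihood polymer trace.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (ChainParams, expected_variance, gap_extension_cost,
                    neg_log_bond, terminal_pseudo_cost)
from .reference import ReferenceMap

__all__ = ["AlignmentGraph", "PolymerTrace", "build_graph", "init_source_sink",
           "shortest_path", "align"]


@dataclass
class PolymerTrace:
    """One aligned chromatin fiber.

    ``orders`` are the 1-based locus orders at which a spot was selected
    (strictly increasing); loci of the reference absent from ``orders`` are
    gaps.  ``score`` is the negative log of the product of all bond
    probabilities along the path (terminal pseudo-bonds included) and always
    equals ``sum(edge_costs)``.
    """

    chromosome: str
    cell_id: object
    orders: np.ndarray
    spot_ids: np.ndarray           # index labels into the originating spot table
    coords_nm: np.ndarray          # (n_assigned, 3)
    edge_costs: np.ndarray
    score: float
    n_loci: int                    # T of the reference

    @property
    def n_assigned(self) -> int:
        return int(self.orders.size)

    @property
    def n_skipped(self) -> int:
        return self.n_loci - self.n_assigned

    @property
    def normalized_score(self) -> float:
        """Score per assigned locus, the karyotype acceptance statistic."""
        return self.score / max(self.n_assigned, 1)

    def positions(self) -> np.ndarray:
        """(T, 3) coordinates in nm with NaN rows at gap loci."""
        out = np.full((self.n_loci, 3), np.nan)
        out[self.orders - 1] = self.coords_nm
        return out


@dataclass
class AlignmentGraph:
    """Edge-list DAG over candidate spots plus source/sink pseudo-nodes."""

    chromosome: str
    ref: ReferenceMap
    params: ChainParams
    node_order: np.ndarray         # 1-based locus order per internal node
    node_cand: np.ndarray          # candidate index within its order
    node_xyz_nm: np.ndarray
    node_sigma_nm: np.ndarray      # isotropic per-spot uncertainty (nm)
    node_spot_ids: np.ndarray
    edge_src: list = field(default_factory=list)
    edge_dst: list = field(default_factory=list)
    edge_cost: list = field(default_factory=list)
    has_terminals: bool = False

    @property
    def n_nodes(self) -> int:
        return int(self.node_order.size)

    @property
    def source(self) -> int:
        return self.n_nodes

    @property
    def sink(self) -> int:
        return self.n_nodes + 1

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


def _extract_nodes(spots: pd.DataFrame, params: ChainParams):
    """Deterministic node arrays from a per-cell, per-chromosome spot table."""
    if len(spots) == 0:
        raise ValueError("empty spot table: nothing to align")
    orders = spots["locus_order"].to_numpy(dtype=int)
    xyz = spots[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    sig_cols = ["sigma_x_nm", "sigma_y_nm", "sigma_z_nm"]
    if all(c in spots.columns for c in sig_cols):
        s = spots[sig_cols].to_numpy(dtype=float)
        sigma = np.sqrt(np.mean(s * s, axis=1))  # isotropic equivalent
    else:
        sigma = np.full(len(spots), params.sigma_default_nm, dtype=float)
    # stable sort by locus order keeps candidate indices reproducible
    srt = np.argsort(orders, kind="stable")
    orders, xyz, sigma = orders[srt], xyz[srt], sigma[srt]
    spot_ids = spots.index.to_numpy()[srt]
    cand = np.zeros_like(orders)
    for t in np.unique(orders):
        m = orders == t
        cand[m] = np.arange(m.sum())
    return orders, cand, xyz, sigma, spot_ids


def build_graph(spots: pd.DataFrame, ref: ReferenceMap, params: ChainParams) -> AlignmentGraph:
    """Construct the alignment DAG over all candidate spots.

    For every ordered pair of orders (t, t+c) with 1 <= c <= C, each
    candidate of t connects to each candidate of t+c with the gap-penalized
    bond cost: neg_log_bond(R, S^2(L, sigma_i, sigma_j)) plus
    (c-1) * gap_extension in affine mode, or scaled by gamma**(c-1) in
    geometric mode.  Loci with no candidates are bridgeable only by skip
    edges.
    """
    orders, cand, xyz, sigma, spot_ids = _extract_nodes(spots, params)
    T = ref.n_loci
    if orders.min() < 1 or orders.max() > T:
        raise ValueError("spot locus_order outside the reference range")
    g = AlignmentGraph(ref.chromosome, ref, params, orders, cand, xyz, sigma, spot_ids)

    ids_by_order: list[list[int]] = [[] for _ in range(T + 1)]
    for nid, t in enumerate(orders):
        ids_by_order[t].append(nid)

    src: list[int] = []
    dst: list[int] = []
    Ls: list[float] = []
    cs: list[int] = []
    pos = ref.positions_bp
    for t in range(1, T):
        a = ids_by_order[t]
        if not a:
            continue
        for c in range(1, min(params.C, T - t) + 1):
            b = ids_by_order[t + c]
            if not b:
                continue
            L = pos[t + c - 1] - pos[t - 1]
            nb = len(b)
            for u in a:
                src.extend([u] * nb)
                dst.extend(b)
            n_pairs = len(a) * nb
            Ls.extend([L] * n_pairs)
            cs.extend([c] * n_pairs)

    if src:
        si = np.asarray(src, dtype=np.int64)
        di = np.asarray(dst, dtype=np.int64)
        L_arr = np.asarray(Ls, dtype=float)
        c_arr = np.asarray(cs, dtype=float)
        R = np.linalg.norm(xyz[si] - xyz[di], axis=1) / params.pixel_nm
        S2 = expected_variance(L_arr, sigma[si], sigma[di], params)
        w = neg_log_bond(R, S2, params.spherical_term)
        if params.gap_mode == "affine":
            gap_ext = gap_extension_cost(float(np.median(ref.intervals())),
                                         params.sigma_default_nm, params)
            w = w + (c_arr - 1.0) * gap_ext
        else:
            w = params.gamma ** (c_arr - 1.0) * w
        np.maximum(w, 0.0, out=w)  # Dijkstra requires non-negative costs
        g.edge_src = si.tolist()
        g.edge_dst = di.tolist()
        g.edge_cost = w.tolist()
    return g


def init_source_sink(graph: AlignmentGraph) -> AlignmentGraph:
    """Attach terminal pseudo-bonds allowing up to K skipped loci at each end.

    The source connects to every candidate of orders 1..K+1 and every
    candidate of orders T-K..T connects to the sink.  Starting at locus 1
    (ending at locus T) is free; skipping ``k`` terminal loci costs the
    gap-scaled bond of the skipped genomic stretch evaluated at ``alpha``
    times its RMS displacement (an imaginary stretched segment).
    """
    params, ref = graph.params, graph.ref
    T = ref.n_loci
    if params.K >= T:
        raise ValueError("K must be smaller than the number of reference loci")
    pos = ref.positions_bp
    gap_ext = gap_extension_cost(float(np.median(ref.intervals())),
                                 params.sigma_default_nm, params)
    for nid in range(graph.n_nodes):
        t = int(graph.node_order[nid])
        sig = float(graph.node_sigma_nm[nid])
        if t <= params.K + 1:
            w = terminal_pseudo_cost(pos[t - 1] - pos[0], t - 1, sig, params,
                                     gap_extension=gap_ext)
            graph.edge_src.append(graph.source)
            graph.edge_dst.append(nid)
            graph.edge_cost.append(max(w, 0.0))
        if t >= T - params.K:
            w = terminal_pseudo_cost(pos[T - 1] - pos[t - 1], T - t, sig, params,
                                     gap_extension=gap_ext)
            graph.edge_src.append(nid)
            graph.edge_dst.append(graph.sink)
            graph.edge_cost.append(max(w, 0.0))
    graph.has_terminals = True
    return graph


def _tie_key(node: int, pred: np.ndarray, graph: AlignmentGraph):
    """(locus order, candidate index) sequence of the path into ``node``."""
    key = []
    v = node
    while v >= 0 and v != graph.source:
        if v < graph.n_nodes:
            key.append((int(graph.node_order[v]), int(graph.node_cand[v])))
        v = int(pred[v])
    return tuple(reversed(key))


def shortest_path(graph: AlignmentGraph, cell_id=None) -> PolymerTrace | None:
    """Minimum-cost source->sink path as a :class:`PolymerTrace`.

    Dijkstra with lexicographic (cost, locus order, candidate index) priority;
    equal-cost paths are resolved toward the lexicographically smallest
    (order, candidate) sequence, making results platform-stable.  Returns
    ``None`` when no source->sink path exists.
    """
    if not graph.has_terminals:
        raise ValueError("call init_source_sink before shortest_path")
    n = graph.n_nodes + 2
    src = np.asarray(graph.edge_src, dtype=np.int64)
    dst = np.asarray(graph.edge_dst, dtype=np.int64)
    cost = np.asarray(graph.edge_cost, dtype=float)
    order = np.argsort(src, kind="stable")
    src, dst, cost = src[order], dst[order], cost[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)

    T = graph.ref.n_loci
    t_of = np.empty(n, dtype=np.int64)
    t_of[: graph.n_nodes] = graph.node_order
    t_of[graph.source] = 0
    t_of[graph.sink] = T + 1
    i_of = np.zeros(n, dtype=np.int64)
    i_of[: graph.n_nodes] = graph.node_cand

    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    pred_cost = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    dist[graph.source] = 0.0
    heap = [(0.0, 0, 0, graph.source)]
    dst_l, cost_l = dst.tolist(), cost.tolist()
    while heap:
        d, _, _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == graph.sink:
            break
        for e in range(indptr[u], indptr[u + 1]):
            v = dst_l[e]
            if done[v]:
                continue
            nd = d + cost_l[e]
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                pred_cost[v] = cost_l[e]
                heapq.heappush(heap, (nd, int(t_of[v]), int(i_of[v]), v))
            elif nd == dist[v] and pred[v] != u:
                cand_key = _tie_key(u, pred, graph) + ((int(t_of[v]), int(i_of[v])),)
                cur_key = _tie_key(v, pred, graph)
                if cand_key < cur_key:
                    pred[v] = u
                    pred_cost[v] = cost_l[e]
    if not np.isfinite(dist[graph.sink]):
        return None

    path = []
    v = int(graph.sink)
    while v != graph.source:
        path.append(v)
        v = int(pred[v])
    path.reverse()
    nodes = [v for v in path if v < graph.n_nodes]
    edge_costs = np.array([pred_cost[v] for v in path])
    nodes_arr = np.asarray(nodes, dtype=np.int64)
    return PolymerTrace(
        chromosome=graph.chromosome,
        cell_id=cell_id,
        orders=graph.node_order[nodes_arr].astype(int),
        spot_ids=graph.node_spot_ids[nodes_arr],
        coords_nm=graph.node_xyz_nm[nodes_arr],
        edge_costs=edge_costs,
        score=float(dist[graph.sink]),
        n_loci=T,
    )


def align(spots: pd.DataFrame, ref: ReferenceMap, params: ChainParams,
          cell_id=None) -> PolymerTrace | None:
    """Trace the most likely polymer through a cell's candidate spots.

    Composition of :func:`build_graph`, :func:`init_source_sink` and
    :func:`shortest_path`.  A path assigning fewer than
    ``params.min_assigned_fraction`` of the reference loci is not a valid
    polymer and yields ``None``.
    """
    if len(spots) == 0:
        return None
    graph = init_source_sink(build_graph(spots, ref, params))
    trace = shortest_path(graph, cell_id=cell_id)
    if trace is None:
        return None
    if trace.n_assigned < math.ceil(params.min_assigned_fraction * ref.n_loci):
        return None
    return trace
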