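"""Multi-IBD clustering: haplotypes shared by three or more copies.

Pairwise segments are lifted to multi-way sharing by tiling each
chromosome into fixed windows, building a graph over haplotype copies
whose edges are the pairwise segments fully covering a window, and
taking connected components of size >= 3.  Runs of adjacent windows with
identical component membership merge into one cluster whose interval is
the intersection of every supporting segment (so each contributing pair
is IBD across the whole reported region).

Transitive (connected-component) grouping is the default — multi-IBD
tools chain pairwise sharing transitively — with an optional strict
clique requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .ibd import IBDSegment
from .markers import MarkerMap


@dataclass
class MultiIBDCluster:
    """A haplotype shared IBD by >= 3 haplotype copies.

    ``members`` are (individual id, haplotype index) pairs;
    ``carriers`` the distinct individuals; an individual appearing with
    both copies is IBD2 for the cluster haplotype.
    """

    chrom: str
    start_bp: int
    end_bp: int
    members: frozenset[tuple[str, int]]
    support: tuple[int, ...] = ()  # indices into the input segment list

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("a multi-IBD cluster needs >= 3 haplotype copies")
        if self.end_bp <= self.start_bp:
            raise ValueError("cluster interval must have positive length")

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(ind for ind, _ in self.members)

    @property
    def ibd2_carriers(self) -> frozenset[str]:
        counts: dict[str, int] = {}
        for ind, _ in self.members:
            counts[ind] = counts.get(ind, 0) + 1
        return frozenset(ind for ind, c in counts.items() if c >= 2)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_copies(self) -> int:
        return len(self.members)


def multi_ibd_clusters(
    segments: list[IBDSegment],
    marker_map: MarkerMap,
    min_copies: int = 3,
    window_bp: int = 250_000,
    require_clique: bool = False,
) -> list[MultiIBDCluster]:
    """Group one chromosome's pairwise segments into multi-IBD clusters.

    All segments must come from a single chromosome.  With
    ``require_clique`` every member pair must have a direct supporting
    segment (stricter than the transitive default).
    """
    if not segments:
        return []
    chroms = {s.chrom for s in segments}
    if len(chroms) > 1:
        raise ValueError(
            f"segments from multiple chromosomes {sorted(chroms)}; cluster one at a time"
        )
    chrom = chroms.pop()
    cidx = marker_map.chrom_indices(chrom)
    lo = int(marker_map.pos_bp[cidx].min())
    hi = int(marker_map.pos_bp[cidx].max())

    # window tiling of [lo, hi]
    n_windows = max(1, -(-(hi - lo) // window_bp))
    window_members: list[frozenset[tuple[str, int]] | None] = []
    window_edges: list[dict[frozenset, int]] = []
    for w in range(n_windows):
        wlo = lo + w * window_bp
        whi = min(hi, wlo + window_bp)
        g = nx.Graph()
        edge_support: dict[frozenset, int] = {}
        for k, s in enumerate(segments):
            if s.covers(wlo, whi):
                u, v = (s.id_a, s.hap_a), (s.id_b, s.hap_b)
                g.add_edge(u, v)
                edge_support.setdefault(frozenset((u, v)), k)
        comp = None
        for nodes in nx.connected_components(g):
            if len(nodes) >= min_copies:
                if require_clique and not _is_clique(g, nodes):
                    continue
                # one component per window per membership; keep all
                comp = comp or []
                comp.append(frozenset(nodes))
        window_members.append(comp)
        window_edges.append(edge_support)

    clusters: dict[tuple[frozenset, int, int], MultiIBDCluster] = {}
    # merge maximal runs of adjacent windows with identical membership
    active: dict[frozenset, tuple[int, set[int]]] = {}  # membership -> (start window, support)
    for w in range(n_windows + 1):
        here = set(window_members[w]) if w < n_windows and window_members[w] else set()
        for membership in list(active):
            if membership not in here:
                start_w, support = active.pop(membership)
                cl = _emit(chrom, membership, support, segments, lo, hi, start_w, w - 1, window_bp)
                if cl is not None:
                    clusters.setdefault((cl.members, cl.start_bp, cl.end_bp), cl)
        for membership in here:
            support = {
                k
                for edge, k in window_edges[w].items()
                if edge <= membership
            }
            if membership in active:
                active[membership][1].update(support)
            else:
                active[membership] = (w, set(support))
    return sorted(clusters.values(), key=lambda c: (c.start_bp, c.end_bp))


def _is_clique(g: nx.Graph, nodes) -> bool:
    return all(g.has_edge(u, v) for u, v in combinations(nodes, 2))


def _emit(chrom, membership, support, segments, lo, hi, w0, w1, window_bp):
    run_lo = lo + w0 * window_bp
    run_hi = min(hi, lo + (w1 + 1) * window_bp)
    start = run_lo
    end = run_hi
    # intersect with every supporting segment so each contributing pair is
    # IBD over the full reported interval
    for k in support:
        start = max(start, segments[k].start_bp)
        end = min(end, segments[k].end_bp)
    if end <= start:
        return None
    return MultiIBDCluster(
        chrom=chrom,
        start_bp=int(start),
        end_bp=int(end),
        members=frozenset(membership),
        support=tuple(sorted(support)),
    )


def clusters_to_frame(clusters: list[MultiIBDCluster]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i,
                "chrom": c.chrom,
                "start_bp": c.start_bp,
                "end_bp": c.end_bp,
                "n_copies": c.n_copies,
                "carriers": ",".join(sorted(c.carriers)),
                "ibd2_carriers": ",".join(sorted(c.ibd2_carriers)) or ".",
                "support_segments": ",".join(map(str, c.support)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "chrom",
            "start_bp",
            "end_bp",
            "n_copies",
            "carriers",
            "ibd2_carriers",
            "support_segments",
        ],
    )
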