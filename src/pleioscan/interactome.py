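"""Disease interactome construction, overlap statistics, and bridge analysis.

A disease *interactome* here is the star-union graph of the disease's
associated ("seed") genes and every protein linked to a seed by a
protein–protein interaction (PPI). Input edges carry a provenance tag —
``known`` (curated databases) or ``novel`` (computationally predicted) —
which is preserved on the graph and in all reports.

Overlap between two interactomes is scored with the upper-tail
hypergeometric test: given a universe of N genes, interactomes of sizes K
and n, and k shared genes, the tail probability P(X >= k) is computed in
log space so that extreme overlaps (p far below double-precision underflow)
remain representable. Bridges between interactomes — direct seed–seed
edges, shared interactors, and seed–intermediate–seed paths — are
enumerated exhaustively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

EDGE_TAGS = ("known", "novel")


@dataclass
class Interactome:
    """Seed genes plus the PPI star graph around them.

    ``graph`` is undirected; every edge touches at least one seed by
    construction and carries a ``tag`` attribute in {known, novel}.
    """

    seeds: frozenset[str]
    graph: nx.Graph
    rejected_edges: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes) | self.seeds

    @property
    def interactors(self) -> frozenset[str]:
        return frozenset(self.graph.nodes) - self.seeds

    def edge_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TAGS}
        for _, _, tag in self.graph.edges.data("tag"):
            counts[tag] += 1
        return counts

    def summary(self) -> dict[str, int]:
        counts = self.edge_counts()
        return {
            "n_seeds": len(self.seeds),
            "n_seeds_with_edges": len(self.seeds & set(self.graph.nodes)),
            "n_interactors": len(self.interactors),
            "n_known_edges": counts["known"],
            "n_novel_edges": counts["novel"],
            "rejected_edges": self.rejected_edges,
        }


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap record: k shared out of sizes K and n in universe N."""

    universe_n: int
    size_a: int
    size_b: int
    overlap_k: int
    log10_p: float

    @property
    def p_tail(self) -> float:
        """Linear-scale tail probability (0.0 when below double underflow)."""
        return 10.0 ** self.log10_p if self.log10_p > -300 else 0.0


@dataclass
class BridgeReport:
    """Connections between two interactomes in their union graph."""

    direct_edges: list[tuple[str, str]]
    common_interactors: set[str]
    two_step_paths: list[tuple[str, str, str]]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "direct_edges": pd.DataFrame(self.direct_edges,
                                         columns=["seed_a", "seed_b"]),
            "common_interactors": pd.DataFrame(
                sorted(self.common_interactors), columns=["gene"]
            ),
            "two_step_paths": pd.DataFrame(
                self.two_step_paths, columns=["seed_a", "intermediate", "seed_b"]
            ),
        }


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a tagged PPI edge list: TSV with columns gene_a, gene_b, tag."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(frame.columns[:3])
    return [
        (str(a), str(b), str(t))
        for a, b, t in frame[cols].itertuples(index=False)
    ]


def write_edge_list(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b", "tag"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(net: Interactome, path: str | Path) -> None:
    """Export edges in SIF format (node, interaction-type, node) for graph viewers."""
    with open(path, "w") as fh:
        for a, b, tag in sorted(net.graph.edges.data("tag")):
            fh.write(f"{a}\tpp_{tag}\t{b}\n")


def build_interactome(
    seeds: Iterable[str],
    edges: Iterable[tuple[str, str, str]],
    alias_map: Mapping[str, str] | None = None,
) -> Interactome:
    """Assemble the interactome of ``seeds`` from tagged edges.

    Only edges incident to a seed are retained (a disease interactome is the
    star around its seed genes); self-loops, rows with empty symbols, and
    unknown tags are rejected and counted. Duplicate edges collapse under
    symmetry — the first tag read wins. Gene identity is the case-preserved
    symbol string, optionally routed through ``alias_map`` first.
    """
    alias = alias_map or {}
    seed_set = frozenset(alias.get(s, s) for s in seeds if s)
    graph = nx.Graph()
    rejected = 0
    for a, b, tag in edges:
        a = alias.get(a, a)
        b = alias.get(b, b)
        if not a or not b or a == b or tag not in EDGE_TAGS:
            rejected += 1
            continue
        if a not in seed_set and b not in seed_set:
            continue
        if not graph.has_edge(a, b):
            graph.add_edge(a, b, tag=tag)
    return Interactome(seeds=seed_set, graph=graph, rejected_edges=rejected)


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------


def hypergeom_log10_sf(k: int, universe_n: int, size_a: int, size_b: int) -> float:
    """log10 of the upper-tail P(X >= k), X ~ Hypergeom(N, K, n).

    Delegates to the log-space survival function so that tails far below
    double-precision underflow stay finite; ``k = 0`` gives exactly 0.0
    (p = 1).
    """
    if k <= 0:
        return 0.0
    return float(hypergeom.logsf(k - 1, universe_n, size_a, size_b) / math.log(10))


def overlap_test(
    net_a: Interactome,
    net_b: Interactome,
    universe_n: int = 20_000,
    mode: str = "full",
) -> OverlapTest:
    """Hypergeometric overlap of two interactomes' gene sets.

    ``mode="full"`` (default) compares seeds+interactors; ``"interactors"``
    compares interactor sets only. ``universe_n`` defaults to 20,000, the
    approximate number of human protein-coding genes; it must cover the
    union of the two compared sets.
    """
    if mode == "full":
        set_a, set_b = net_a.nodes, net_b.nodes
    elif mode == "interactors":
        set_a, set_b = net_a.interactors, net_b.interactors
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if universe_n < len(set_a | set_b):
        raise ValueError(
            f"universe_n={universe_n} smaller than the union of the two sets "
            f"({len(set_a | set_b)})"
        )
    k = len(set_a & set_b)
    return OverlapTest(
        universe_n=universe_n,
        size_a=len(set_a),
        size_b=len(set_b),
        overlap_k=k,
        log10_p=hypergeom_log10_sf(k, universe_n, len(set_a), len(set_b)),
    )


def overlap_test_sizes(
    universe_n: int, size_a: int, size_b: int, overlap_k: int
) -> OverlapTest:
    """Overlap test from published sizes alone (no graphs needed)."""
    if overlap_k > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either set size")
    if universe_n < size_a + size_b - overlap_k:
        raise ValueError("universe smaller than the implied union")
    return OverlapTest(
        universe_n=universe_n,
        size_a=size_a,
        size_b=size_b,
        overlap_k=overlap_k,
        log10_p=hypergeom_log10_sf(overlap_k, universe_n, size_a, size_b),
    )


# ---------------------------------------------------------------------------
# bridges
# ---------------------------------------------------------------------------


def find_bridges(net_a: Interactome, net_b: Interactome) -> BridgeReport:
    """Enumerate all connections between two interactomes in their union graph.

    * ``direct_edges`` — union-graph edges joining an A seed to a B seed;
    * ``common_interactors`` — non-seed nodes adjacent to at least one seed
      of each side;
    * ``two_step_paths`` — every (A seed, intermediate, B seed) path through
      a common interactor, enumerated exhaustively.
    """
    union = nx.compose(net_a.graph, net_b.graph)
    seeds_a, seeds_b = net_a.seeds, net_b.seeds
    all_seeds = seeds_a | seeds_b

    direct = sorted(
        (a, b) if a in seeds_a else (b, a)
        for a, b in union.edges
        if (a in seeds_a and b in seeds_b) or (a in seeds_b and b in seeds_a)
    )

    common: set[str] = set()
    paths: list[tuple[str, str, str]] = []
    for node in union.nodes:
        if node in all_seeds:
            continue
        nbrs = set(union.neighbors(node))
        touch_a = sorted(nbrs & seeds_a)
        touch_b = sorted(nbrs & seeds_b)
        if touch_a and touch_b:
            common.add(node)
            paths.extend((sa, node, sb) for sa in touch_a for sb in touch_b)
    paths.sort()
    return BridgeReport(direct_edges=direct, common_interactors=common,
                        two_step_paths=paths)


@dataclass
class CandidateConnectivity:
    """How one candidate gene's interactors reach two disease interactomes."""

    candidate: str
    n_interactors: int
    isolated: bool
    seeds_a_reached: set[str]
    seeds_b_reached: set[str]
    shared_with_a: set[str]  # candidate interactors adjacent to an A seed
    shared_with_b: set[str]


def candidate_connectivity(
    candidates: Iterable[str],
    cand_edges: Iterable[tuple[str, str, str]],
    net_a: Interactome,
    net_b: Interactome,
) -> list[CandidateConnectivity]:
    """Connectivity of candidate genes to two disease interactomes.

    The candidates get their own interactome from ``cand_edges``; for each
    candidate the report counts its interactors, the A and B seeds reached
    through exactly one intermediate interactor, and the interactors it
    shares with each disease net. Candidates without edges are reported as
    isolated with zero counts.
    """
    cand_list = sorted(set(candidates))
    cand_net = build_interactome(cand_list, cand_edges)
    adj_a = _seed_adjacency(net_a)
    adj_b = _seed_adjacency(net_b)

    out = []
    for cand in cand_list:
        if cand in cand_net.graph:
            partners = set(cand_net.graph.neighbors(cand))
        else:
            partners = set()
        shared_a = {m for m in partners if m in adj_a}
        shared_b = {m for m in partners if m in adj_b}
        out.append(
            CandidateConnectivity(
                candidate=cand,
                n_interactors=len(partners),
                isolated=not partners,
                seeds_a_reached=set().union(*(adj_a[m] for m in shared_a))
                if shared_a else set(),
                seeds_b_reached=set().union(*(adj_b[m] for m in shared_b))
                if shared_b else set(),
                shared_with_a=shared_a,
                shared_with_b=shared_b,
            )
        )
    return out


def _seed_adjacency(net: Interactome) -> dict[str, set[str]]:
    """Map each node to the seeds of ``net`` it is directly adjacent to."""
    adj: dict[str, set[str]] = {}
    for seed in net.seeds:
        if seed not in net.graph:
            continue
        for nbr in net.graph.neighbors(seed):
            adj.setdefault(nbr, set()).add(seed)
    return adj
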