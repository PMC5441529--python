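"""Pathway enrichment over GMT gene sets with Benjamini–Hochberg correction.

For a query gene set of size n drawn from a universe of N genes, a pathway
of size K with k hits scores p_raw = P(X >= k) under the hypergeometric
distribution; the collection of raw p-values over all pathways with at
least one hit is then adjusted by the Benjamini–Hochberg step-up procedure,
which controls the false discovery rate across the tested pathways.

The module also implements the dual-disease merged pathway table: the hits
of two query sets on each pathway are partitioned into
exclusive-to-A / common / exclusive-to-B, the presentation used to compare
which parts of each pathway the two disease interactomes cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from pleioscan.interactome import hypergeom_log10_sf


@dataclass(frozen=True)
class PathwayResult:
    """One pathway's enrichment for one query set."""

    pathway_id: str
    genes_hit: frozenset[str]
    p_raw: float
    p_bh: float


@dataclass(frozen=True)
class MergedPathwayRow:
    """One pathway's hits partitioned between two query sets."""

    pathway_id: str
    p_a: float
    p_b: float
    genes_exclusive_a: frozenset[str]
    genes_common: frozenset[str]
    genes_exclusive_b: frozenset[str]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    gmt: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            gmt[parts[0]] = {g for g in parts[2:] if g}
    return gmt


def write_gmt(gmt: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gmt.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def enrich(
    gene_set: Iterable[str],
    gmt: Mapping[str, Iterable[str]],
    universe_n: int | None = None,
) -> list[PathwayResult]:
    """Hypergeometric enrichment of ``gene_set`` against every GMT pathway.

    ``universe_n`` defaults to the number of unique genes across the GMT;
    in that default mode the query is first restricted to that annotated
    universe (query genes no pathway could ever contain carry no evidence
    either way). One result is returned per pathway with at least one hit —
    all of them, regardless of significance — with BH-adjusted p-values
    computed across the full set of tested (hit) pathways. Results sort by
    ascending ``p_raw``, ties by pathway id.
    """
    query = set(gene_set)
    if universe_n is None:
        annotated = set().union(*gmt.values()) if gmt else set()
        universe_n = len(annotated)
        query &= annotated
    rows: list[tuple[str, frozenset[str], float]] = []
    for pid, genes in gmt.items():
        genes = set(genes)
        hits = frozenset(query & genes)
        if not hits:
            continue
        n_union = len(query | genes)
        if universe_n < n_union:
            raise ValueError(
                f"universe_n={universe_n} smaller than |query ∪ {pid}|={n_union}"
            )
        log10_p = hypergeom_log10_sf(len(hits), universe_n, len(genes), len(query))
        p_raw = min(1.0, 10.0 ** log10_p) if log10_p > -300 else 0.0
        rows.append((pid, hits, p_raw))
    if not rows:
        return []
    _, p_bh, _, _ = multipletests([r[2] for r in rows], method="fdr_bh")
    results = [
        PathwayResult(pathway_id=pid, genes_hit=hits, p_raw=p_raw, p_bh=float(adj))
        for (pid, hits, p_raw), adj in zip(rows, p_bh)
    ]
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results


def merge_pathway_tables(
    res_a: Sequence[PathwayResult],
    res_b: Sequence[PathwayResult],
) -> list[MergedPathwayRow]:
    """Merge two enrichment result sets into the exclusive/common partition.

    Both results must come from the same GMT. A pathway present in only one
    result gets the other side's p = 1 and an empty hit set there. Rows sort
    by min(p_a, p_b), ties by pathway id. Each row's hit partition is
    disjoint by construction and unions to (hits in A) ∪ (hits in B).
    """
    by_a = {r.pathway_id: r for r in res_a}
    by_b = {r.pathway_id: r for r in res_b}
    rows = []
    for pid in sorted(set(by_a) | set(by_b)):
        a, b = by_a.get(pid), by_b.get(pid)
        hits_a = a.genes_hit if a else frozenset()
        hits_b = b.genes_hit if b else frozenset()
        rows.append(
            MergedPathwayRow(
                pathway_id=pid,
                p_a=a.p_bh if a else 1.0,
                p_b=b.p_bh if b else 1.0,
                genes_exclusive_a=hits_a - hits_b,
                genes_common=hits_a & hits_b,
                genes_exclusive_b=hits_b - hits_a,
            )
        )
    rows.sort(key=lambda r: (min(r.p_a, r.p_b), r.pathway_id))
    return rows


def merged_to_frame(rows: Sequence[MergedPathwayRow]) -> pd.DataFrame:
    """Tabular merged view; also carries the per-partition counts for bar plots."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway_id,
                "p_a": r.p_a,
                "p_b": r.p_b,
                "n_exclusive_a": len(r.genes_exclusive_a),
                "n_common": len(r.genes_common),
                "n_exclusive_b": len(r.genes_exclusive_b),
                "genes_exclusive_a": ",".join(sorted(r.genes_exclusive_a)),
                "genes_common": ",".join(sorted(r.genes_common)),
                "genes_exclusive_b": ",".join(sorted(r.genes_exclusive_b)),
            }
            for r in rows
        ]
    )


def results_to_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway_id,
                "n_hits": len(r.genes_hit),
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
                "genes_hit": ",".join(sorted(r.genes_hit)),
            }
            for r in results
        ]
    )
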