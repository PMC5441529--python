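"""Reciprocal differential-expression intersection and connectivity scoring.

Two diseases with an inverse epidemiological relationship may show
*reciprocal* transcriptional signatures: genes over-expressed in one and
under-expressed in the other. Given two per-gene differential-expression
signatures, :func:`reciprocal_genes` extracts the two reciprocal sets
(up-in-A/down-in-B and down-in-A/up-in-B) over the shared gene universe.

The reciprocal signature can then be queried against a gene x perturbagen
matrix of expression responses (a connectivity-map style resource):
:func:`connectivity_score` ranks perturbagens by the Spearman rank
correlation between the query's signed scores and each perturbagen's
response over shared genes. Strongly negative scores flag perturbagens
whose response opposes — i.e. might reverse — the query signature; rank
correlation makes the score invariant to any monotone rescaling of either
side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    direction: str  # "up" | "down"
    score: float


@dataclass
class ExpressionSignature:
    """Per-gene differential-expression signature for one condition.

    One record per gene; ``direction`` is derived from the sign of
    ``score``, with an optional dead-zone ``epsilon`` below which a gene is
    treated as unchanged and excluded.
    """

    records: dict[str, GeneRecord]
    label: str = ""

    @classmethod
    def from_scores(
        cls,
        scores: Mapping[str, float],
        label: str = "",
        epsilon: float = 0.0,
    ) -> "ExpressionSignature":
        """Build a signature from signed per-gene scores.

        Genes with |score| <= ``epsilon`` are dropped (no confident
        direction call).
        """
        records = {}
        for gene, s in scores.items():
            s = float(s)
            if abs(s) <= epsilon:
                continue
            records[gene] = GeneRecord(gene, "up" if s > 0 else "down", s)
        return cls(records=records, label=label)

    @classmethod
    def read_tsv(
        cls, path: str | Path, label: str = "", epsilon: float = 0.0
    ) -> "ExpressionSignature":
        """Read a two-column (gene, score) or three-column (gene, direction,
        score) TSV; direction, when present, must match the score's sign."""
        frame = pd.read_csv(path, sep="\t")
        cols = list(frame.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: need at least (gene, score) columns")
        score_col = cols[-1]
        sig = cls.from_scores(
            dict(zip(frame[cols[0]].astype(str), frame[score_col].astype(float))),
            label=label,
            epsilon=epsilon,
        )
        if len(cols) >= 3:
            stated = dict(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str)))
            for gene, rec in sig.records.items():
                if stated.get(gene) not in (None, rec.direction):
                    raise ValueError(
                        f"{path}: {gene} direction {stated[gene]!r} contradicts "
                        f"score {rec.score}"
                    )
        return sig

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"gene": r.gene, "direction": r.direction, "score": r.score}
                for r in self.records.values()
            ]
        ).to_csv(path, sep="\t", index=False)

    @property
    def genes(self) -> set[str]:
        return set(self.records)

    def direction(self, gene: str) -> str:
        return self.records[gene].direction

    def scores(self) -> dict[str, float]:
        return {g: r.score for g, r in self.records.items()}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ConnectivityResult:
    """One perturbagen's rank-correlation score against the query signature."""

    perturbagen_id: str
    score: float
    n_genes_used: int


def reciprocal_genes(
    sig_a: ExpressionSignature, sig_b: ExpressionSignature
) -> tuple[set[str], set[str]]:
    """Reciprocally regulated genes over the shared gene universe.

    Returns ``(up_a_down_b, down_a_up_b)``; genes absent from either
    signature are ignored. Swapping the inputs swaps the two sets.
    """
    shared = sig_a.genes & sig_b.genes
    up_a_down_b = {
        g for g in shared
        if sig_a.direction(g) == "up" and sig_b.direction(g) == "down"
    }
    down_a_up_b = {
        g for g in shared
        if sig_a.direction(g) == "down" and sig_b.direction(g) == "up"
    }
    return up_a_down_b, down_a_up_b


def connectivity_score(
    query: ExpressionSignature,
    perturbagen_matrix: pd.DataFrame,
    min_shared: int = 3,
) -> list[ConnectivityResult]:
    """Rank perturbagens by Spearman correlation with the query signature.

    ``perturbagen_matrix`` is gene-indexed with one column per perturbagen.
    Each perturbagen is scored over the genes it shares with the query;
    perturbagens sharing fewer than ``min_shared`` genes are skipped with a
    warning. Results sort by descending score (ties by id): the head of the
    list mimics the query, the tail opposes it.
    """
    q = query.scores()
    shared_all = [g for g in perturbagen_matrix.index if g in q]
    results: list[ConnectivityResult] = []
    for pert in perturbagen_matrix.columns:
        col = perturbagen_matrix.loc[shared_all, pert].dropna()
        genes = list(col.index)
        if len(genes) < min_shared:
            logger.warning(
                "connectivity_score: %s shares %d < %d genes with the query; skipped",
                pert, len(genes), min_shared,
            )
            continue
        rho = spearmanr([q[g] for g in genes], col.to_numpy()).statistic
        results.append(
            ConnectivityResult(
                perturbagen_id=str(pert),
                score=float(rho),
                n_genes_used=len(genes),
            )
        )
    results.sort(key=lambda r: (-r.score, r.perturbagen_id))
    return results


def results_to_frame(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"perturbagen": r.perturbagen_id, "score": r.score,
             "n_genes_used": r.n_genes_used}
            for r in results
        ],
        columns=["perturbagen", "score", "n_genes_used"],
    )
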