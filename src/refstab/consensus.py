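"""Cross-method integration of the three stability algorithms.

The workflow: geNorm and NormFinder score every candidate; the ten
genes with the smallest summed (M + rho) score go forward to
BestKeeper; the three per-method rankings are then aggregated by mean
rank, and the final recommendation is geNorm's surviving pair together
with the V-series gene count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .data_io import ValidationError
from .genorm import GeNormResult

K_PRESELECT_DEFAULT = 10


@dataclass
class ConsensusReport:
    """Per-condition integration of geNorm, NormFinder and BestKeeper."""

    condition_set: str
    preselection: list[str]
    genorm_ranking: dict[str, int]
    normfinder_ranking: dict[str, int]
    bestkeeper_ranking: dict[str, int]
    aggregate_ranking: dict[str, int]
    recommended_pair: tuple[str, str]
    recommended_n: int
    v_series: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(
            self.aggregate_ranking, key=lambda g: (self.aggregate_ranking[g], g)
        )
        return pd.DataFrame(
            {
                "gene": genes,
                "genorm_rank": [self.genorm_ranking[g] for g in genes],
                "normfinder_rank": [self.normfinder_ranking[g] for g in genes],
                "bestkeeper_rank": [self.bestkeeper_ranking[g] for g in genes],
                "aggregate_rank": [self.aggregate_ranking[g] for g in genes],
            }
        )

    def to_dict(self) -> dict:
        return {
            "condition_set": self.condition_set,
            "preselection": list(self.preselection),
            "genorm_ranking": dict(self.genorm_ranking),
            "normfinder_ranking": dict(self.normfinder_ranking),
            "bestkeeper_ranking": dict(self.bestkeeper_ranking),
            "aggregate_ranking": dict(self.aggregate_ranking),
            "recommended_pair": list(self.recommended_pair),
            "recommended_n": self.recommended_n,
            "v_series": list(self.v_series),
        }


def preselect_topk(
    m_values: Mapping[str, float],
    stability_values: Mapping[str, float],
    k: int = K_PRESELECT_DEFAULT,
    method: str = "sum",
) -> list[str]:
    """Top-k genes by combined geNorm M and NormFinder rho.

    ``method='sum'`` (default) scores each gene by the literal sum
    M + rho; ``method='rank_sum'`` sums the within-method ranks instead,
    which is insensitive to the different scales of the two statistics.
    Smaller is better; ties break lexicographically.
    """
    genes_m = set(m_values)
    genes_s = set(stability_values)
    if genes_m != genes_s:
        raise ValidationError(
            f"gene sets differ: only in geNorm {sorted(genes_m - genes_s)}, "
            f"only in NormFinder {sorted(genes_s - genes_m)}"
        )
    if method == "sum":
        score = {g: m_values[g] + stability_values[g] for g in genes_m}
    elif method == "rank_sum":
        m_rank = {
            g: i for i, g in enumerate(sorted(genes_m, key=lambda g: (m_values[g], g)))
        }
        s_rank = {
            g: i
            for i, g in enumerate(
                sorted(genes_m, key=lambda g: (stability_values[g], g))
            )
        }
        score = {g: float(m_rank[g] + s_rank[g]) for g in genes_m}
    else:
        raise ValueError(f"unknown preselection method {method!r}")
    ordered = sorted(genes_m, key=lambda g: (score[g], g))
    return ordered[: min(k, len(ordered))]


def aggregate_ranks(
    rankings: Mapping[str, Mapping[str, int]],
    m_values: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """Mean rank across methods, ascending.

    Ties on mean rank are broken by geNorm M (if provided) and then
    lexicographically, so the output is a total order.
    """
    methods = list(rankings)
    if not methods:
        raise ValidationError("no rankings to aggregate")
    genes = set(rankings[methods[0]])
    for name in methods[1:]:
        if set(rankings[name]) != genes:
            raise ValidationError(
                f"ranking {name!r} covers a different gene set"
            )
    mean_rank = {
        g: sum(rankings[name][g] for name in methods) / len(methods) for g in genes
    }
    def key(g):
        m = m_values.get(g, 0.0) if m_values else 0.0
        return (mean_rank[g], m, g)
    ordered = sorted(genes, key=key)
    return {g: i + 1 for i, g in enumerate(ordered)}


def recommend_references(genorm_result: GeNormResult) -> tuple[tuple[str, str], int]:
    """Recommended reference pair (geNorm survivors) and gene count."""
    pair = tuple(genorm_result.gene_order[:2])
    if genorm_result.recommended_n is None:
        raise ValidationError("geNorm result lacks a V-series; run pairwise_v_series")
    return pair, int(genorm_result.recommended_n)
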