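"""geNorm expression-stability analysis.

For each pair of candidate genes j, k the pairwise variation V(j,k) is
the standard deviation across samples of log2(q_j/q_k).  A gene's
stability measure M_j is the mean of V(j,k) over all other genes k:
genes whose expression moves in proportion to the rest of the panel get
small M.  Ranking proceeds by stepwise exclusion — drop the gene with
the largest M, recompute, repeat until two genes survive; those two
cannot be ordered relative to each other and share rank 1.

The number of reference genes needed is decided by the pairwise
variation series V(n, n+1): the SD across samples of
log2(NF_n/NF_{n+1}), where NF_n is the geometric mean of the top-n
ranked genes in a sample.  The conventional cut-off is 0.15 — once
V(n, n+1) drops below it, the (n+1)-th gene adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ValidationError
from .efficiency import QuantityTable

V_THRESHOLD_DEFAULT = 0.15


@dataclass
class GeNormResult:
    """Stepwise geNorm output: M values, exclusion order, ranking, V-series."""

    m_values: dict[str, float]
    exclusion_order: list[str]
    ranking: dict[str, int]
    gene_order: list[str]  # most→least stable; first two are the tied survivors
    v_series: list[float] = field(default_factory=list)
    recommended_n: int | None = None

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.m_values, key=lambda g: (self.ranking[g], g))
        return pd.DataFrame(
            {
                "gene": genes,
                "M": [self.m_values[g] for g in genes],
                "rank": [self.ranking[g] for g in genes],
            }
        )

    def to_dict(self) -> dict:
        return {
            "m_values": dict(self.m_values),
            "exclusion_order": list(self.exclusion_order),
            "ranking": dict(self.ranking),
            "gene_order": list(self.gene_order),
            "v_series": list(self.v_series),
            "recommended_n": self.recommended_n,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GeNormResult":
        return cls(
            m_values={k: float(v) for k, v in payload["m_values"].items()},
            exclusion_order=list(payload["exclusion_order"]),
            ranking={k: int(v) for k, v in payload["ranking"].items()},
            gene_order=list(payload["gene_order"]),
            v_series=[float(v) for v in payload["v_series"]],
            recommended_n=payload.get("recommended_n"),
        )


def _as_frame(q: QuantityTable | pd.DataFrame) -> pd.DataFrame:
    return q.q if isinstance(q, QuantityTable) else q


def pairwise_variation(q_j, q_k) -> float:
    """SD (n−1 denominator) across samples of log2(q_j/q_k); symmetric."""
    a = np.asarray(q_j, dtype=float)
    b = np.asarray(q_k, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("quantity vectors must be 1-D of equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 samples for pairwise variation")
    if (a <= 0).any() or (b <= 0).any():
        raise ValidationError("quantities must be strictly positive")
    # log difference rather than log-of-ratio: exactly antisymmetric in
    # floating point, so swapping arguments gives the bit-identical SD
    return float(np.std(np.log2(a) - np.log2(b), ddof=1))


def genorm_m(q: QuantityTable | pd.DataFrame) -> pd.Series:
    """M per gene: mean over all other genes of the pairwise variation."""
    frame = _as_frame(q)
    k, n = frame.shape
    if k < 3:
        raise ValidationError(f"geNorm M needs >= 3 genes, got {k}")
    if n < 2:
        raise ValidationError(f"geNorm M needs >= 2 samples, got {n}")
    log_q = np.log2(frame.to_numpy(dtype=float))
    # V[j, k] = SD across samples of (log q_j − log q_k)
    diff = log_q[:, None, :] - log_q[None, :, :]
    v = diff.std(axis=2, ddof=1)
    m = (v.sum(axis=1)) / (k - 1)  # diagonal contributes 0
    return pd.Series(m, index=frame.index, name="M")


def genorm_rank(q: QuantityTable | pd.DataFrame) -> GeNormResult:
    """Stepwise exclusion ranking by M.

    The gene with the highest M is removed and M recomputed, until two
    genes remain; those survivors share rank 1.  Each gene's reported M
    is its value at the step of its exclusion (survivors: the final
    three-gene step).  Ties on M are broken by removing the
    reverse-lexicographically larger gene id, which makes runs
    reproducible regardless of input order.
    """
    frame = _as_frame(q)
    if frame.shape[0] < 3:
        raise ValidationError("geNorm ranking needs >= 3 genes")
    remaining = list(frame.index)
    exclusion: list[str] = []
    m_values: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m(frame.loc[remaining])
        worst_m = m.max()
        worst = max(g for g in remaining if m[g] == worst_m)
        if len(remaining) == 3:
            for g in remaining:
                m_values[g] = float(m[g])
        else:
            m_values[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    survivors = sorted(remaining)
    ranking = {g: 1 for g in survivors}
    for i, gene in enumerate(reversed(exclusion)):
        ranking[gene] = 3 + i
    gene_order = survivors + list(reversed(exclusion))
    return GeNormResult(
        m_values=m_values,
        exclusion_order=exclusion,
        ranking=ranking,
        gene_order=gene_order,
    )


def pairwise_v_series(
    q: QuantityTable | pd.DataFrame,
    result: GeNormResult,
    threshold: float = V_THRESHOLD_DEFAULT,
) -> GeNormResult:
    """Fill in V(n, n+1) for n = 2..k−1 and the recommended gene count.

    NF_n(s) is the geometric mean quantity of the top-n ranked genes in
    sample s.  recommended_n is the smallest n with V(n, n+1) below the
    threshold, or k if the series never drops below it.
    """
    frame = _as_frame(q)
    order = [g for g in result.gene_order if g in frame.index]
    k = len(order)
    if k < 3:
        raise ValidationError("V-series needs >= 3 ranked genes")
    log_q = np.log2(frame.loc[order].to_numpy(dtype=float))
    v_series: list[float] = []
    for n in range(2, k):
        log_nf_n = log_q[:n].mean(axis=0)
        log_nf_n1 = log_q[: n + 1].mean(axis=0)
        v_series.append(float(np.std(log_nf_n - log_nf_n1, ddof=1)))
    recommended = next(
        (n for n, v in zip(range(2, k), v_series) if v < threshold), k
    )
    result.v_series = v_series
    result.recommended_n = recommended
    return result


def genorm(
    q: QuantityTable | pd.DataFrame,
    v_threshold: float = V_THRESHOLD_DEFAULT,
) -> GeNormResult:
    """Full geNorm analysis: stepwise ranking plus the V-series."""
    result = genorm_rank(q)
    return pairwise_v_series(q, result, threshold=v_threshold)
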