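"""BestKeeper descriptive stability analysis on the Ct scale.

BestKeeper works directly on Ct values.  Each candidate gene is
summarised by descriptive statistics (geometric/arithmetic mean,
min/max, SD, CV); a per-sample *index* — the geometric mean Ct over all
candidates — serves as a common yardstick, and each gene is correlated
(Pearson) against it.  A good reference gene has a small Ct SD and a
high correlation with the index; genes with SD > 1 cycle are flagged
as unstable outright.

The final ranking is two-tier: genes whose correlation r reaches a
threshold (default 0.9) are ordered first by ascending SD, and the
remaining weakly correlated genes are appended ordered by descending r.
Low-r genes are thereby pushed to the bottom regardless of how quiet
their Ct is — a gene that does not track the panel cannot normalise it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CtTable, ValidationError

R_THRESHOLD_DEFAULT = 0.9
SD_FLAG_DEFAULT = 1.0

SdConvention = Literal["sd", "mad_geomean"]


@dataclass
class BestKeeperResult:
    """Per-gene descriptives, index correlation and two-tier ranking."""

    stats: pd.DataFrame  # gene-indexed: n, geo_mean, ar_mean, min, max, sd, cv, sd_flag
    correlations: pd.DataFrame  # gene-indexed: r, p_value
    index: pd.Series  # per-sample geometric mean Ct
    ranking: dict[str, int]
    r_threshold: float = R_THRESHOLD_DEFAULT

    def to_frame(self) -> pd.DataFrame:
        out = self.stats.join(self.correlations)
        out["rank"] = pd.Series(self.ranking)
        out = out.sort_values("rank")
        out.insert(0, "gene", out.index)
        return out.reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "stats": {g: self.stats.loc[g].to_dict() for g in self.stats.index},
            "correlations": {
                g: self.correlations.loc[g].to_dict() for g in self.correlations.index
            },
            "index": self.index.to_dict(),
            "ranking": dict(self.ranking),
            "r_threshold": self.r_threshold,
        }


def bk_descriptives(
    ct: CtTable | pd.DataFrame,
    sd_convention: SdConvention = "sd",
    sd_flag_threshold: float = SD_FLAG_DEFAULT,
) -> pd.DataFrame:
    """Per-gene descriptive statistics of raw Ct values.

    ``sd_convention`` selects between the sample standard deviation
    (n−1 denominator, default) and ``mad_geomean`` — the mean absolute
    deviation around the geometric mean, the dispersion used by the
    original BestKeeper spreadsheet.  CV is reported as a percentage of
    the arithmetic mean.  Genes with dispersion above
    ``sd_flag_threshold`` cycles are flagged unstable.
    """
    frame = ct.ct if isinstance(ct, CtTable) else ct
    if frame.isna().to_numpy().any():
        raise ValidationError("BestKeeper requires a complete Ct matrix")
    if (frame.to_numpy() <= 0).any():
        raise ValidationError("geometric mean undefined for non-positive Ct")
    if frame.shape[1] < 2:
        raise ValidationError("need >= 2 samples")
    values = frame.to_numpy(dtype=float)
    geo = np.exp(np.log(values).mean(axis=1))
    if sd_convention == "sd":
        sd = values.std(axis=1, ddof=1)
    elif sd_convention == "mad_geomean":
        sd = np.abs(values - geo[:, None]).mean(axis=1)
    else:
        raise ValueError(f"unknown sd convention {sd_convention!r}")
    ar = values.mean(axis=1)
    out = pd.DataFrame(
        {
            "n": values.shape[1],
            "geo_mean": geo,
            "ar_mean": ar,
            "min": values.min(axis=1),
            "max": values.max(axis=1),
            "sd": sd,
            "cv": 100.0 * sd / ar,
            "sd_flag": sd > sd_flag_threshold,
        },
        index=frame.index,
    )
    return out


def bk_index(ct: CtTable | pd.DataFrame) -> pd.Series:
    """BestKeeper index: per-sample geometric mean Ct over candidate genes."""
    frame = ct.ct if isinstance(ct, CtTable) else ct
    if frame.shape[0] == 0:
        raise ValidationError("empty gene set")
    if frame.isna().to_numpy().any():
        raise ValidationError("BestKeeper index requires a complete Ct matrix")
    values = frame.to_numpy(dtype=float)
    return pd.Series(
        np.exp(np.log(values).mean(axis=0)), index=frame.columns, name="bk_index"
    )


def bk_correlation(
    ct: CtTable | pd.DataFrame, index: pd.Series | None = None
) -> pd.DataFrame:
    """Pearson correlation of each gene's Ct with the BestKeeper index.

    p-values are two-sided from the t transform with n−2 degrees of
    freedom.  A gene (or index) with zero variance has no defined
    correlation; it is reported as NaN and later demoted to the second
    ranking tier.
    """
    frame = ct.ct if isinstance(ct, CtTable) else ct
    if index is None:
        index = bk_index(frame)
    idx = index.loc[frame.columns].to_numpy(dtype=float)
    rows = []
    for gene in frame.index:
        y = frame.loc[gene].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(idx) == 0:
            rows.append({"r": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(y, idx)
        rows.append({"r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows, index=frame.index)


def bk_rank(
    sd: Mapping[str, float] | pd.Series,
    r: Mapping[str, float] | pd.Series,
    r_threshold: float = R_THRESHOLD_DEFAULT,
) -> dict[str, int]:
    """Two-tier BestKeeper ranking from per-gene SD and index correlation.

    Tier 1: genes with r >= r_threshold, ascending SD.  Tier 2: the
    rest, descending r (undefined r sorts last).  Ties break
    lexicographically on gene id.  Ranks run 1..k across both tiers.
    """
    sd = pd.Series(sd, dtype=float)
    r = pd.Series(r, dtype=float)
    if set(sd.index) != set(r.index):
        raise ValidationError("SD and correlation cover different gene sets")
    genes = list(sd.index)
    tier1 = [g for g in genes if not np.isnan(r[g]) and r[g] >= r_threshold]
    tier2 = [g for g in genes if g not in tier1]
    tier1.sort(key=lambda g: (sd[g], g))
    tier2.sort(key=lambda g: (-r[g] if not np.isnan(r[g]) else np.inf, g))
    return {g: i + 1 for i, g in enumerate(tier1 + tier2)}


def bestkeeper(
    ct: CtTable | pd.DataFrame,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    sd_convention: SdConvention = "sd",
    sd_flag_threshold: float = SD_FLAG_DEFAULT,
) -> BestKeeperResult:
    """Full BestKeeper analysis of a candidate Ct matrix."""
    frame = ct.ct if isinstance(ct, CtTable) else ct
    stats_frame = bk_descriptives(frame, sd_convention, sd_flag_threshold)
    index = bk_index(frame)
    correlations = bk_correlation(frame, index)
    ranking = bk_rank(stats_frame["sd"], correlations["r"], r_threshold)
    return BestKeeperResult(
        stats=stats_frame,
        correlations=correlations,
        index=index,
        ranking=ranking,
        r_threshold=r_threshold,
    )
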