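"""NormFinder model-based stability estimation.

NormFinder treats log2 expression of gene i in sample j of group g as

    x_igj = alpha_ig + b_jg + eps_igj,    eps ~ N(0, sigma2_ig)

where b_jg is a sample-specific loading effect (removed by centering
each sample on its across-gene mean), alpha_ig carries a possible
systematic group difference, and sigma2_ig is the intragroup noise of
gene i in group g.  A stable reference gene has both a small intragroup
variance and a small systematic difference between groups.

The intergroup difference d_ig (deviation of the gene's group mean from
its overall mean) is shrunk toward zero in an empirical-Bayes fashion:
the spread of d across genes estimates a common intergroup variance
tau2_g, and each gene's observed d is attenuated by
tau2 / (tau2 + sigma2_ig/n_g), so that genes measured noisily in small
groups are not credited with spurious group effects.  The stability
value combines the magnitude of the shrunken difference with its
remaining uncertainty:

    rho_i = mean over groups of ( |d_shrunk_ig| + sqrt(v_ig) )

Lower rho means more stable.  With a single group rho reduces to the
intragroup SD of the centered values.

Because sample-centering mixes a slice of every gene's noise into every
other gene, the naive within-group variance of centered values is
biased; with k genes the unbiased reconstruction is

    sigma2_ig = max(0, (z_ig − z̄_g/(k−1)) · k/(k−2))

where z_ig is the plain sample variance of the centered values and z̄_g
its mean over genes (derived from E[z_ig] = sigma2_ig(1−2/k) + mean
sigma2/k under the model above; requires k >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SampleSheet, ValidationError
from .efficiency import QuantityTable


@dataclass
class NormFinderResult:
    """Per-gene stability rho with its variance-decomposition ingredients."""

    stability: dict[str, float]  # rho, log2 units; lower = more stable
    d: pd.DataFrame  # shrunken intergroup difference, gene × group
    sigma2: pd.DataFrame  # intragroup variance, gene × group
    tau2: dict[str, float]  # intergroup variance scale per group
    ranking: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.stability, key=lambda g: (self.ranking[g], g))
        return pd.DataFrame(
            {
                "gene": genes,
                "stability": [self.stability[g] for g in genes],
                "rank": [self.ranking[g] for g in genes],
            }
        )

    def to_dict(self) -> dict:
        return {
            "stability": dict(self.stability),
            "d": {g: self.d.loc[g].to_dict() for g in self.d.index},
            "sigma2": {g: self.sigma2.loc[g].to_dict() for g in self.sigma2.index},
            "tau2": dict(self.tau2),
            "ranking": dict(self.ranking),
        }


def _rank_ascending(values: dict[str, float]) -> dict[str, int]:
    ordered = sorted(values, key=lambda g: (values[g], g))
    return {g: i + 1 for i, g in enumerate(ordered)}


def normfinder_stability(
    q: QuantityTable | pd.DataFrame,
    groups: pd.Series | dict | SampleSheet,
) -> NormFinderResult:
    """Compute the NormFinder stability value rho for every gene.

    Parameters
    ----------
    q
        Complete genes × samples table of positive relative quantities.
    groups
        Group label per sample id (Series/dict), or a SampleSheet whose
        ``group`` column is used.  Every group needs >= 2 samples.
    """
    frame = q.q if isinstance(q, QuantityTable) else q
    if isinstance(groups, SampleSheet):
        groups = groups.groups()
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    missing = [s for s in frame.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    groups = groups.loc[frame.columns]
    if frame.isna().to_numpy().any():
        raise ValidationError("NormFinder requires a complete quantity table")
    k = frame.shape[0]
    if k < 3:
        raise ValidationError(f"NormFinder needs >= 3 genes, got {k}")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"groups with fewer than 2 samples: {list(small.index)}")

    x = np.log2(frame.to_numpy(dtype=float))
    x = x - x.mean(axis=0, keepdims=True)  # remove per-sample loading
    x = pd.DataFrame(x, index=frame.index, columns=frame.columns)

    group_names = list(pd.unique(groups))
    if len(group_names) == 1:
        sd = x.std(axis=1, ddof=1)
        stability = {g: float(sd[g]) for g in frame.index}
        ranking = _rank_ascending(stability)
        return NormFinderResult(
            stability=stability,
            d=pd.DataFrame(0.0, index=frame.index, columns=group_names),
            sigma2=pd.DataFrame({group_names[0]: sd**2}),
            tau2={group_names[0]: 0.0},
            ranking=ranking,
        )

    group_mean = pd.DataFrame(index=frame.index, columns=group_names, dtype=float)
    sigma2 = pd.DataFrame(index=frame.index, columns=group_names, dtype=float)
    n_g: dict[str, int] = {}
    for g in group_names:
        cols = groups.index[groups == g]
        block = x[cols]
        n_g[g] = len(cols)
        group_mean[g] = block.mean(axis=1)
        z = block.var(axis=1, ddof=1)
        # bias correction for the share of other genes' noise mixed in by
        # sample-centering; truncated at 0
        corrected = (z - z.mean() / (k - 1)) * k / (k - 2)
        sigma2[g] = corrected.clip(lower=0.0)

    overall = group_mean.mean(axis=1)  # unweighted across groups
    d = group_mean.sub(overall, axis=0)

    tau2: dict[str, float] = {}
    d_shrunk = pd.DataFrame(index=frame.index, columns=group_names, dtype=float)
    v = pd.DataFrame(index=frame.index, columns=group_names, dtype=float)
    for g in group_names:
        noise = sigma2[g] / n_g[g]
        tau2_g = max(0.0, float(d[g].var(ddof=1) - noise.mean()))
        tau2[g] = tau2_g
        factor = tau2_g / (tau2_g + noise) if tau2_g > 0 else noise * 0.0
        d_shrunk[g] = d[g] * factor
        v[g] = noise * factor

    rho = (d_shrunk.abs() + np.sqrt(v)).mean(axis=1)
    stability = {g: float(rho[g]) for g in frame.index}
    ranking = _rank_ascending(stability)
    return NormFinderResult(
        stability=stability,
        d=d_shrunk,
        sigma2=sigma2,
        tau2=tau2,
        ranking=ranking,
    )
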