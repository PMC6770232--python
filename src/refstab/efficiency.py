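"""Standard-curve calibration and Ct → relative-quantity conversion.

A serial dilution of template (typically five 10-fold steps) yields a
straight line of mean Ct against log10(relative concentration).  The
slope gives the amplification efficiency

    E = 10^(-1/slope) - 1

with E = 1 meaning perfect per-cycle doubling (slope -1/log10(2) ≈
-3.3219 cycles per decade).  Quantities recovered from the curve are
relative: they carry no absolute copy-number units, only ratios between
samples are meaningful — which is exactly what the downstream stability
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CT_MAX, CT_MIN, ValidationError, _delimiter_for, _to_float, CtTable


class CurveError(ValueError):
    """Raised for dilution series that cannot yield a valid standard curve."""


@dataclass
class DilutionSeries:
    """Replicate Ct measurements over a ladder of relative concentrations."""

    gene_id: str
    points: list[tuple[float, np.ndarray]]  # (relative concentration, Ct replicates)

    def __post_init__(self) -> None:
        concentrations = [c for c, _ in self.points]
        if len(set(concentrations)) < 3:
            raise CurveError(
                f"{self.gene_id}: need >= 3 distinct concentrations, "
                f"got {sorted(set(concentrations))}"
            )
        if any(c <= 0 for c in concentrations):
            raise CurveError(f"{self.gene_id}: concentrations must be positive")
        self.points = [
            (float(c), np.asarray(cts, dtype=float)) for c, cts in self.points
        ]
        for c, cts in self.points:
            if cts.size == 0:
                raise CurveError(f"{self.gene_id}: concentration {c} has no Ct values")
            if ((cts <= CT_MIN) | (cts > CT_MAX)).any():
                raise ValidationError(
                    f"{self.gene_id}: Ct outside ({CT_MIN}, {CT_MAX}] at concentration {c}"
                )


@dataclass
class StandardCurveFit:
    """Least-squares standard curve: Ct = intercept + slope·log10(conc)."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency": self.efficiency,
        }


@dataclass
class QuantityTable:
    """Genes × samples matrix of strictly positive relative quantities."""

    q: pd.DataFrame

    def __post_init__(self) -> None:
        q = self.q.astype(float)
        if q.isna().to_numpy().any():
            raise ValidationError("quantity table must be complete (no NaN)")
        if (q.to_numpy() <= 0).any():
            raise ValidationError("quantities must be strictly positive")
        self.q = q

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)

    def subset(self, genes=None, samples=None) -> "QuantityTable":
        frame = self.q
        if genes is not None:
            frame = frame.loc[list(genes)]
        if samples is not None:
            frame = frame[list(samples)]
        return QuantityTable(frame.copy())


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 for a negative slope."""
    if slope >= 0:
        raise CurveError(f"slope must be negative for a valid curve, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Ordinary least squares of mean Ct per dilution point on log10(conc).

    The fit uses the per-point mean of the replicate Cts (the usual
    standard-curve convention) so that R² reflects linearity of the
    ladder, not replicate scatter.
    """
    log_conc = np.array([np.log10(c) for c, _ in series.points])
    mean_ct = np.array([cts.mean() for _, cts in series.points])
    fit = stats.linregress(log_conc, mean_ct)
    if fit.slope >= 0:
        raise CurveError(
            f"{series.gene_id}: fitted slope {fit.slope:.4f} >= 0 — signal must "
            "increase (lower Ct) with template concentration"
        )
    return StandardCurveFit(
        gene_id=series.gene_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency_from_slope(float(fit.slope)),
    )


def read_dilution_series(path: str | Path) -> dict[str, DilutionSeries]:
    """Read ``gene,concentration,ct`` rows (replicates repeated) per gene."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    required = ["gene", "concentration", "ct"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: dilution series missing columns {missing}")
    raw = _to_float(raw, ["concentration", "ct"], path)
    out: dict[str, DilutionSeries] = {}
    for gene, grp in raw.groupby("gene", sort=False):
        points = [
            (conc, sub["ct"].to_numpy())
            for conc, sub in grp.groupby("concentration", sort=False)
        ]
        out[str(gene)] = DilutionSeries(str(gene), points)
    return out


def write_curve_fits(fits: Mapping[str, StandardCurveFit], path: str | Path) -> None:
    frame = pd.DataFrame([fits[g].to_dict() for g in fits])
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def ct_to_quantity(
    ct: CtTable,
    curves: Mapping[str, StandardCurveFit] | Mapping[str, float] | float,
    mode: Literal["curve", "delta_ct"] = "curve",
) -> QuantityTable:
    """Convert Ct values to relative quantities.

    mode="curve"
        q = 10^((ct - intercept)/slope) using each gene's fitted standard
        curve; q = 1 at the curve's intercept.
    mode="delta_ct"
        q = (1+E)^(ct_min - ct) where ct_min is the gene's minimum Ct
        across samples, so the most concentrated sample has q = 1.  This
        needs only an efficiency per gene (or one scalar for all genes).

    The two modes differ per gene only by a positive constant factor, so
    every scale-invariant statistic downstream (geNorm M and V,
    NormFinder stability) is identical under either.
    """
    ct.require_complete()
    if isinstance(curves, (int, float)):
        curves = {g: float(curves) for g in ct.gene_ids}
    missing = [g for g in ct.gene_ids if g not in curves]
    if missing:
        raise ValidationError(f"no curve/efficiency for genes: {missing}")
    rows = {}
    for gene in ct.gene_ids:
        values = ct.ct.loc[gene].to_numpy(dtype=float)
        spec = curves[gene]
        if mode == "curve":
            if not isinstance(spec, StandardCurveFit):
                raise TypeError(
                    f"mode='curve' requires StandardCurveFit per gene, got "
                    f"{type(spec).__name__} for {gene}"
                )
            rows[gene] = 10.0 ** ((values - spec.intercept) / spec.slope)
        elif mode == "delta_ct":
            eff = spec.efficiency if isinstance(spec, StandardCurveFit) else float(spec)
            if eff <= 0:
                raise ValidationError(f"{gene}: efficiency must be positive, got {eff}")
            rows[gene] = (1.0 + eff) ** (values.min() - values)
        else:
            raise ValueError(f"unknown conversion mode {mode!r}")
    frame = pd.DataFrame(rows, index=ct.sample_ids).T
    frame = frame.loc[ct.gene_ids]
    return QuantityTable(frame)
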