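"""Relative quantification by the 2^-ΔΔCt method.

For each biological replicate the target Ct is normalised against the
arithmetic mean Ct of the chosen reference genes (equivalent to the
geometric mean of their quantities):

    ΔCt  = Ct_target − mean(Ct_refs)
    ΔΔCt = ΔCt − mean(ΔCt over calibrator replicates)
    fold = 2^(−ΔΔCt)

Per condition, the reported fold change is the geometric mean of the
replicate fold changes (i.e. 2 to the minus mean ΔΔCt), which makes the
calibrator condition exactly 1 by construction; the spread is the SD of
the replicate fold changes.  The base 2 assumes perfect per-cycle
doubling; an amplification base of 1+E may be supplied for
efficiency-corrected estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CtTable, SampleSheet, ValidationError


@dataclass
class FoldChange:
    """Fold change of a target gene in one condition vs the calibrator."""

    target_gene: str
    condition: str
    reference_set: tuple[str, ...]
    calibrator_condition: str
    value: float
    spread: float
    n_replicates: int


@dataclass
class FoldChangeTable:
    """Fold changes for one target across all conditions."""

    rows: list[FoldChange]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [r.target_gene for r in self.rows],
                "condition": [r.condition for r in self.rows],
                "references": [",".join(r.reference_set) for r in self.rows],
                "calibrator": [r.calibrator_condition for r in self.rows],
                "fold_change": [r.value for r in self.rows],
                "spread": [r.spread for r in self.rows],
                "n_replicates": [r.n_replicates for r in self.rows],
            }
        )

    def to_dict(self) -> dict:
        return {
            r.condition: {"fold_change": r.value, "spread": r.spread}
            for r in self.rows
        }

    def by_condition(self) -> dict[str, FoldChange]:
        return {r.condition: r for r in self.rows}


def relative_expression(
    ct: CtTable,
    sheet: SampleSheet,
    target: str,
    refs: Sequence[str],
    calibrator: str,
    base: float = 2.0,
) -> FoldChangeTable:
    """2^-ΔΔCt fold changes of ``target`` per condition vs ``calibrator``.

    ``ct`` should hold one column per biological replicate (aggregate
    technical replicates first).  ``base`` is the assumed amplification
    factor per cycle (2.0 = the literal 2^-ΔΔCt; pass 1+E for an
    efficiency-corrected estimate applied to all genes).
    """
    refs = tuple(refs)
    if target in refs:
        raise ValidationError(f"target {target!r} cannot be one of its references")
    if target not in ct.gene_ids:
        raise ValidationError(f"target gene {target!r} not in Ct table")
    missing_refs = [g for g in refs if g not in ct.gene_ids]
    if missing_refs:
        raise ValidationError(f"reference genes not in Ct table: {missing_refs}")
    if base <= 1.0:
        raise ValidationError(f"amplification base must exceed 1, got {base}")
    sheet.validate_against(ct)
    meta = sheet.frame
    conditions = list(pd.unique(meta["condition"]))
    if calibrator not in conditions:
        raise ValidationError(
            f"calibrator condition {calibrator!r} not found (have {conditions})"
        )

    def delta_ct(sample_ids: list[str]) -> np.ndarray:
        t = ct.ct.loc[target, sample_ids].to_numpy(dtype=float)
        r = ct.ct.loc[list(refs), sample_ids].to_numpy(dtype=float).mean(axis=0)
        if np.isnan(t).any() or np.isnan(r).any():
            raise ValidationError(f"missing Ct among samples {sample_ids}")
        return t - r

    cal_samples = list(meta.loc[meta["condition"] == calibrator, "sample_id"])
    cal_delta = delta_ct(cal_samples)
    cal_mean = cal_delta.mean()

    rows: list[FoldChange] = []
    for condition in conditions:
        sample_ids = list(meta.loc[meta["condition"] == condition, "sample_id"])
        ddct = delta_ct(sample_ids) - cal_mean
        folds = base ** (-ddct)
        value = float(base ** (-ddct.mean()))  # geometric mean of replicate folds
        spread = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
        rows.append(
            FoldChange(
                target_gene=target,
                condition=condition,
                reference_set=refs,
                calibrator_condition=calibrator,
                value=value,
                spread=spread,
                n_replicates=len(folds),
            )
        )
    return FoldChangeTable(rows)
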