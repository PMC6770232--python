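"""End-to-end orchestration of the condition-wise stability analyses.

For each condition set (development stages, substrates, stresses) and
for the pooled "Total" the pipeline runs:

    Ct → quantities → geNorm → NormFinder → top-10 preselection →
    BestKeeper (on Ct of the preselected genes) → consensus

NormFinder groups are the condition levels within a set; for the pooled
analysis the condition sets themselves act as groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .bestkeeper import BestKeeperResult, bestkeeper
from .config import RunConfig
from .consensus import (
    ConsensusReport,
    aggregate_ranks,
    preselect_topk,
    recommend_references,
)
from .data_io import (
    CtTable,
    SampleSheet,
    ValidationError,
    aggregate_technical_replicates,
    read_ct_table,
    write_report,
)
from .efficiency import (
    QuantityTable,
    ct_to_quantity,
    fit_standard_curve,
    read_dilution_series,
)
from .genorm import GeNormResult, genorm
from .normfinder import NormFinderResult, normfinder_stability
from .synthetic import generate_ct_dataset, study_preset


@dataclass
class ConditionAnalysis:
    """All stage outputs for one condition subset."""

    condition_set: str
    genorm: GeNormResult
    normfinder: NormFinderResult
    bestkeeper: BestKeeperResult
    consensus: ConsensusReport


@dataclass
class PipelineResult:
    analyses: dict[str, ConditionAnalysis] = field(default_factory=dict)
    qc: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "analyses": {
                name: a.consensus.to_dict() for name, a in self.analyses.items()
            },
        }


def _restrict_ranking(ranking: Mapping[str, int], genes: list[str]) -> dict[str, int]:
    """Re-rank a subset 1..n preserving the original order (ties by id)."""
    ordered = sorted(genes, key=lambda g: (ranking[g], g))
    return {g: i + 1 for i, g in enumerate(ordered)}


def analyze_condition_set(
    name: str,
    ct: CtTable,
    q: QuantityTable,
    groups: pd.Series,
    config: RunConfig,
) -> ConditionAnalysis:
    """Run geNorm → NormFinder → preselect → BestKeeper → consensus."""
    gn = genorm(q, v_threshold=config.v_threshold)
    nf = normfinder_stability(q, groups)
    preselection = preselect_topk(
        gn.m_values, nf.stability, k=config.k_preselect, method=config.preselect_method
    )
    bk = bestkeeper(
        ct.subset(genes=preselection),
        r_threshold=config.r_threshold,
        sd_convention=config.sd_convention,
        sd_flag_threshold=config.sd_flag_threshold,
    )
    aggregate = aggregate_ranks(
        {
            "genorm": _restrict_ranking(gn.ranking, preselection),
            "normfinder": _restrict_ranking(nf.ranking, preselection),
            "bestkeeper": bk.ranking,
        },
        m_values=gn.m_values,
    )
    pair, recommended_n = recommend_references(gn)
    report = ConsensusReport(
        condition_set=name,
        preselection=preselection,
        genorm_ranking=_restrict_ranking(gn.ranking, preselection),
        normfinder_ranking=_restrict_ranking(nf.ranking, preselection),
        bestkeeper_ranking=bk.ranking,
        aggregate_ranking=aggregate,
        recommended_pair=pair,
        recommended_n=recommended_n,
        v_series=gn.v_series,
    )
    return ConditionAnalysis(
        condition_set=name, genorm=gn, normfinder=nf, bestkeeper=bk, consensus=report
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full condition-wise analysis described by ``config``."""
    # --- load or simulate ------------------------------------------------
    if config.ct_path is None:
        ct, sheet, _ = generate_ct_dataset(study_preset(config.seed))
    else:
        if config.sheet_path is None:
            raise ValidationError("sheet_path is required when ct_path is given")
        ct, sheet = read_ct_table(
            config.ct_path, layout=config.layout, sheet_path=config.sheet_path
        )

    # --- technical-replicate aggregation ---------------------------------
    qc = None
    if config.aggregate_technical and sheet.frame["tech_rep"].nunique() > 1:
        agg = aggregate_technical_replicates(ct, sheet, max_spread=config.max_spread)
        ct, sheet, qc = agg.ct, agg.sheet, agg.qc

    if config.drop_incomplete:
        ct = ct.drop_incomplete(config.drop_incomplete)
        if config.drop_incomplete == "samples":
            sheet = sheet.subset(ct.sample_ids)
    ct.require_complete()

    # --- Ct → quantity conversion ----------------------------------------
    if config.dilutions_path:
        series = read_dilution_series(config.dilutions_path)
        curves = {g: fit_standard_curve(s) for g, s in series.items()}
        q_all = ct_to_quantity(ct, curves, mode="curve")
    else:
        q_all = ct_to_quantity(ct, config.efficiency, mode="delta_ct")

    # --- condition subsets -------------------------------------------------
    meta = sheet.frame
    set_column = config.condition_set_column
    if set_column in meta.columns:
        sets = {
            name: list(pd.unique(grp["condition"]))
            for name, grp in meta.groupby(set_column, sort=False)
        }
    else:
        sets = {}

    result = PipelineResult(qc=qc)
    for name, conditions in sets.items():
        sample_ids = list(meta.loc[meta["condition"].isin(conditions), "sample_id"])
        sub_ct = ct.subset(samples=sample_ids)
        sub_q = q_all.subset(samples=sample_ids)
        groups = meta.set_index("sample_id").loc[sample_ids, "condition"]
        result.analyses[name] = analyze_condition_set(
            name, sub_ct, sub_q, groups, config
        )

    # pooled analysis: condition sets (if any) act as the groups
    if set_column in meta.columns and len(sets) > 1:
        total_groups = meta.set_index("sample_id")[set_column]
    else:
        total_groups = meta.set_index("sample_id")["condition"]
    result.analyses["Total"] = analyze_condition_set(
        "Total", ct, q_all, total_groups.loc[ct.sample_ids], config
    )

    result.manifest = {
        "config_digest": config.digest(),
        "refstab_version": __version__,
        "n_genes": len(ct.gene_ids),
        "n_samples": len(ct.sample_ids),
        "condition_sets": {k: sorted(v) for k, v in sets.items()},
    }

    if out_dir is not None:
        _write_outputs(result, Path(out_dir), config)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, analysis in result.analyses.items():
        prefix = out_dir / name.replace(" ", "_")
        write_report(analysis.genorm, prefix.with_suffix(".genorm.tsv"))
        write_report(analysis.normfinder, prefix.with_suffix(".normfinder.tsv"))
        write_report(analysis.bestkeeper, prefix.with_suffix(".bestkeeper.tsv"))
        write_report(analysis.consensus, prefix.with_suffix(".consensus.tsv"))
        write_report(analysis.consensus, prefix.with_suffix(".consensus.json"), "json")
    if result.qc is not None and len(result.qc):
        result.qc.to_csv(out_dir / "qc_flags.tsv", sep="\t", index=False)
    manifest = dict(result.manifest)
    manifest["config"] = config.to_dict()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
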