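"""Reading, validation and reporting of qRT-PCR experiment tables.

The central container is :class:`CtTable`, a genes × samples matrix of
cycle-threshold (Ct) values, paired with a :class:`SampleSheet` that maps
each sample to its biological condition, replicate structure and analysis
group.  RNA-seq expression contrasts live in :class:`RpkmTable`.

Ct values are PCR cycle numbers: every non-missing entry must lie in
``(0, 45]`` (45 cycles being the practical ceiling of a qPCR run).
Missing values are represented as NaN; the stability algorithms
downstream require complete matrices, so helpers are provided to either
fail loudly on missing cells or drop incomplete genes/samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

CT_MIN = 0.0
CT_MAX = 45.0

SHEET_COLUMNS = ("sample_id", "condition", "bio_rep", "tech_rep", "group")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a cell cannot be parsed, naming the offending row/column."""


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class CtTable:
    """Genes × samples matrix of cycle-threshold values.

    Parameters
    ----------
    ct
        DataFrame indexed by gene id with one column per sample id.
        NaN marks a missing measurement.
    """

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        ct = self.ct
        if ct.index.has_duplicates:
            dups = ct.index[ct.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if ct.columns.has_duplicates:
            dups = ct.columns[ct.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 genes and 2 samples, got {ct.shape[0]}×{ct.shape[1]}"
            )
        try:
            self.ct = ct.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric Ct value: {exc}") from exc
        values = self.ct.to_numpy()
        bad = ((values <= CT_MIN) | (values > CT_MAX)) & ~np.isnan(values)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"{self.ct.index[r]}/{self.ct.columns[c]}={values[r, c]}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(
                f"Ct values outside ({CT_MIN}, {CT_MAX}]: {', '.join(cells)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.ct.isna()

    def require_complete(self) -> None:
        """Raise :class:`ValidationError` listing every missing cell."""
        mask = self.ct.isna()
        if mask.to_numpy().any():
            cells = [
                f"{g}/{s}" for g in mask.index for s in mask.columns if mask.at[g, s]
            ]
            raise ValidationError(f"missing Ct values at: {', '.join(cells)}")

    def drop_incomplete(self, axis: Literal["genes", "samples"]) -> "CtTable":
        """Return a copy without genes (or samples) that contain missing Ct."""
        if axis == "genes":
            keep = ~self.ct.isna().any(axis=1)
            return CtTable(self.ct.loc[keep].copy())
        keep = ~self.ct.isna().any(axis=0)
        return CtTable(self.ct.loc[:, keep].copy())

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "CtTable":
        frame = self.ct
        if genes is not None:
            missing = [g for g in genes if g not in frame.index]
            if missing:
                raise KeyError(f"genes not in table: {missing}")
            frame = frame.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in frame.columns]
            if missing:
                raise KeyError(f"samples not in table: {missing}")
            frame = frame[list(samples)]
        return CtTable(frame.copy())


@dataclass
class SampleSheet:
    """Per-sample metadata: condition, replicate indices and analysis group."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        frame = self.frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["bio_rep"] = frame["bio_rep"].astype(int)
        frame["tech_rep"] = frame["tech_rep"].astype(int)
        if (frame["bio_rep"] < 1).any() or (frame["tech_rep"] < 1).any():
            raise ValidationError("bio_rep and tech_rep must be >= 1")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        triple = frame[["condition", "bio_rep", "tech_rep"]]
        if triple.duplicated().any():
            dups = triple[triple.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (condition, bio_rep, tech_rep): {dups}")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def validate_against(self, ct: CtTable) -> None:
        sheet_ids = set(self.sample_ids)
        table_ids = set(ct.sample_ids)
        if sheet_ids != table_ids:
            raise ValidationError(
                f"sample sheet / Ct table mismatch: only in sheet {sorted(sheet_ids - table_ids)}, "
                f"only in table {sorted(table_ids - sheet_ids)}"
            )

    def groups(self, column: str = "group") -> pd.Series:
        """Group label per sample id (for NormFinder-style analyses)."""
        return self.frame.set_index("sample_id")[column]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        wanted = set(sample_ids)
        return SampleSheet(
            self.frame[self.frame["sample_id"].isin(wanted)].reset_index(drop=True)
        )


@dataclass
class RpkmTable:
    """Long-format RNA-seq expression: one row per (gene, contrast)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "contrast", "rpkm_treatment", "rpkm_control"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"RPKM table missing columns: {missing}")
        frame = self.frame.copy()
        for col in ("rpkm_treatment", "rpkm_control"):
            frame[col] = frame[col].astype(float)
            if (frame[col] < 0).any():
                bad = frame.loc[frame[col] < 0, "gene"].tolist()
                raise ValidationError(f"negative RPKM for genes: {bad}")
        if frame[["gene", "contrast"]].duplicated().any():
            dups = (
                frame.loc[frame[["gene", "contrast"]].duplicated(), ["gene", "contrast"]]
                .to_records(index=False)
                .tolist()
            )
            raise ValidationError(f"duplicate (gene, contrast) rows: {dups}")
        self.frame = frame.reset_index(drop=True)


@dataclass
class AggregationResult:
    """Output of technical-replicate aggregation with its QC report."""

    ct: CtTable
    sheet: SampleSheet
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_delimiter_for(path), dtype=str)


def _to_float(frame: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    frame = frame.copy()
    for col in columns:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}: malformed numeric cell in column '{col}', row {row + 2} "
                f"(value {frame[col].iloc[row]!r})"
            )
        frame[col] = parsed
    return frame


def read_ct_table(
    path: str | Path,
    layout: Literal["wide", "long"] = "wide",
    sheet_path: str | Path | None = None,
) -> tuple[CtTable, SampleSheet | None]:
    """Read a Ct table in wide or long layout, optionally with its sample sheet.

    Wide layout: first column ``gene``, remaining columns are sample ids.
    Long layout: columns ``gene,sample,ct``.
    """
    path = Path(path)
    raw = _read_table(path)
    if layout == "wide":
        if raw.columns[0] != "gene":
            raise ParseError(f"{path}: wide layout requires first column 'gene'")
        samples = list(raw.columns[1:])
        raw = _to_float(raw, samples, path)
        matrix = raw.set_index("gene")[samples]
        matrix.index.name = None
        matrix.columns.name = None
    elif layout == "long":
        required = ["gene", "sample", "ct"]
        if list(raw.columns[:3]) != required:
            raise ParseError(f"{path}: long layout requires columns {required}")
        raw = _to_float(raw, ["ct"], path)
        if raw[["gene", "sample"]].duplicated().any():
            raise ValidationError(f"{path}: duplicate (gene, sample) rows")
        matrix = raw.pivot(index="gene", columns="sample", values="ct")
        # preserve first-appearance order rather than pivot's lexicographic order
        matrix = matrix.loc[
            raw["gene"].drop_duplicates().tolist(),
            raw["sample"].drop_duplicates().tolist(),
        ]
        matrix.index.name = None
        matrix.columns.name = None
    else:
        raise ValueError(f"unknown layout {layout!r}")
    table = CtTable(matrix)
    sheet = None
    if sheet_path is not None:
        sheet = read_sample_sheet(sheet_path)
        sheet.validate_against(table)
    return table, sheet


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    raw = _read_table(path)
    return SampleSheet(raw)


def read_rpkm_table(path: str | Path) -> RpkmTable:
    path = Path(path)
    raw = _read_table(path)
    raw = _to_float(raw, ["rpkm_treatment", "rpkm_control"], path)
    return RpkmTable(raw)


def aggregate_technical_replicates(
    ct: CtTable,
    sheet: SampleSheet,
    max_spread: float = 0.5,
) -> AggregationResult:
    """Average technical replicates to one column per (condition, bio_rep).

    Ct is averaged arithmetically (Ct is already a log-scale quantity).
    Triplets whose within-replicate range exceeds ``max_spread`` cycles are
    flagged in the QC report but still averaged — the flag is advisory,
    never an automatic drop.  A (condition, bio_rep) cell whose replicates
    are all missing raises an error naming the cell.
    """
    sheet.validate_against(ct)
    meta = sheet.frame
    new_columns: dict[str, pd.Series] = {}
    rows: list[dict] = []
    qc_rows: list[dict] = []
    for (condition, bio_rep), grp in meta.groupby(
        ["condition", "bio_rep"], sort=False
    ):
        sample_ids = list(grp["sample_id"])
        block = ct.ct[sample_ids]
        all_missing = block.isna().all(axis=1)
        if all_missing.any():
            genes = list(block.index[all_missing])
            raise ValidationError(
                f"all technical replicates missing for genes {genes} in "
                f"(condition={condition}, bio_rep={bio_rep})"
            )
        spread = block.max(axis=1) - block.min(axis=1)
        for gene in block.index[spread > max_spread]:
            qc_rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "bio_rep": bio_rep,
                    "spread": float(spread.loc[gene]),
                    "max_spread": max_spread,
                }
            )
        new_id = f"{condition}:b{bio_rep}"
        new_columns[new_id] = block.mean(axis=1)
        row = {
            "sample_id": new_id,
            "condition": condition,
            "bio_rep": int(bio_rep),
            "tech_rep": 1,
            "group": grp["group"].iloc[0],
        }
        for extra in meta.columns:
            if extra not in row:
                row[extra] = grp[extra].iloc[0]
        rows.append(row)
    agg_ct = CtTable(pd.DataFrame(new_columns))
    agg_sheet = SampleSheet(pd.DataFrame(rows))
    qc = pd.DataFrame(
        qc_rows, columns=["gene", "condition", "bio_rep", "spread", "max_spread"]
    )
    return AggregationResult(agg_ct, agg_sheet, qc)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    path = Path(path)
    out = ct.ct.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_delimiter_for(path), float_format="%.6g")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    path = Path(path)
    sheet.frame.to_csv(path, sep=_delimiter_for(path), index=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(result, path: str | Path, format: Literal["tsv", "json"] = "tsv") -> None:
    """Serialize any result object exposing ``to_frame``/``to_dict``.

    TSV output has a deterministic column order and 6-significant-digit
    floats, so identical results always produce byte-identical files.
    """
    path = Path(path)
    if format == "tsv":
        if not hasattr(result, "to_frame"):
            raise TypeError(f"{type(result).__name__} does not support TSV reports")
        frame = result.to_frame()
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        if not hasattr(result, "to_dict"):
            raise TypeError(f"{type(result).__name__} does not support JSON reports")
        payload = _round_floats(result.to_dict())
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
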