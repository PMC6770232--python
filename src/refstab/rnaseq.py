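"""RNA-seq fold-change screen of candidate reference genes.

A candidate is called *stable* in a contrast when the magnitude of its
log2 fold change between treatment and control RPKM is at most 1
(boundary inclusive — a clean two-fold change still counts as stable),
*up* above +1, *down* below −1.  With the default pseudocount of 0 a
zero RPKM on either side leaves the cell *undefined*; a positive
pseudocount makes the screen total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import RpkmTable, ValidationError

LFC_THRESHOLD = 1.0


@dataclass
class RpkmScreenResult:
    """log2 fold changes, per-cell classification and stability counts."""

    lfc: pd.DataFrame  # gene × contrast, NaN where undefined
    classification: pd.DataFrame  # gene × contrast of {stable,up,down,undefined}
    stable_counts: pd.Series  # per gene, number of contrasts classified stable
    pseudocount: float
    orientation: str = "treatment_over_control"

    def to_frame(self) -> pd.DataFrame:
        """Long format suitable for heat-map rendering."""
        rows = []
        for gene in self.lfc.index:
            for contrast in self.lfc.columns:
                rows.append(
                    {
                        "gene": gene,
                        "contrast": contrast,
                        "log2fc": self.lfc.at[gene, contrast],
                        "classification": self.classification.at[gene, contrast],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "pseudocount": self.pseudocount,
            "lfc": {
                g: {
                    c: (None if np.isnan(v) else float(v))
                    for c, v in self.lfc.loc[g].items()
                }
                for g in self.lfc.index
            },
            "classification": {
                g: self.classification.loc[g].to_dict()
                for g in self.classification.index
            },
            "stable_counts": {k: int(v) for k, v in self.stable_counts.items()},
        }


def screen(
    rpkm: RpkmTable,
    pseudocount: float = 0.0,
    threshold: float = LFC_THRESHOLD,
) -> RpkmScreenResult:
    """Classify every (gene, contrast) by |log2FC| against ``threshold``."""
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    frame = rpkm.frame
    lfc = pd.DataFrame(
        index=pd.unique(frame["gene"]), columns=pd.unique(frame["contrast"]),
        dtype=float,
    )
    for _, row in frame.iterrows():
        t = row["rpkm_treatment"] + pseudocount
        c = row["rpkm_control"] + pseudocount
        lfc.at[row["gene"], row["contrast"]] = (
            np.nan if (t == 0 or c == 0) else np.log2(t / c)
        )
    classification = pd.DataFrame(
        "undefined", index=lfc.index, columns=lfc.columns, dtype=object
    )
    classification[lfc.abs() <= threshold] = "stable"
    classification[lfc > threshold] = "up"
    classification[lfc < -threshold] = "down"
    stable_counts = (classification == "stable").sum(axis=1)
    return RpkmScreenResult(
        lfc=lfc,
        classification=classification,
        stable_counts=stable_counts,
        pseudocount=pseudocount,
    )
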