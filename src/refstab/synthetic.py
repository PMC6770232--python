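"""Synthetic qRT-PCR and RNA-seq data with known ground truth.

Every pipeline stage can be exercised end to end without any external
download: the generator emits Ct matrices with a realistic error
structure, dilution ladders for standard-curve fitting, and RPKM
contrast tables for the fold-change screen.

The Ct model is additive on the cycle scale (hence multiplicative on
quantities, the standard qPCR error model):

    Ct(g, s, t) = base_ct_g + loading(s) + shift_g(condition(s))
                  + N(0, noise_sd_g)        # biological, per (g, s)
                  + N(0, tech_noise_sd)     # technical, per well

``loading`` is a per-biological-sample offset shared by all genes —
exactly the nuisance that reference-gene normalisation must cancel.
``noise_sd_g`` and the per-condition shifts define the ground-truth
stability order: a perfectly stable reference gene has small noise and
no condition shift.

The default preset mirrors a typical mushroom reference-gene study:
18 candidates measured over three development stages, three growth
substrates and three stresses plus an untreated control, each in
biological and technical triplicate, with mean Ct spanning roughly
15–31 cycles and per-gene amplification efficiencies between 0.90 and
1.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CT_MAX, CT_MIN, CtTable, RpkmTable, SampleSheet, ValidationError
from .efficiency import DilutionSeries

# condition sets: development stages (DDS), substrates (DSB), stresses (DST)
PRESET_CONDITION_SETS: dict[str, tuple[str, ...]] = {
    "DDS": ("mycelium", "primordium", "fruiting_body"),
    "DSB": ("straw", "sawdust", "corn_stalk"),
    "DST": ("control", "heat", "cadmium", "trichoderma"),
}

# most→least stable under the preset truth
PRESET_STABILITY_ORDER = (
    "28S", "a-tub", "Actin", "b-tub", "RPA12", "UBI", "18S", "PPCI", "UBC",
    "EF", "TIF", "PP2A", "VPS28", "Ras", "MSF1", "CYPL", "SPRYP", "GPD",
)

# plausible mean expression levels (cycles) spanning the 15–31 window
PRESET_BASE_CT: dict[str, float] = {
    "EF": 15.5, "28S": 17.0, "Actin": 18.5, "GPD": 19.0, "a-tub": 20.0,
    "b-tub": 20.5, "UBI": 21.5, "18S": 16.0, "RPA12": 24.0, "UBC": 24.5,
    "MSF1": 27.0, "Ras": 26.0, "CYPL": 27.5, "PPCI": 23.0, "TIF": 25.0,
    "PP2A": 25.5, "VPS28": 26.5, "SPRYP": 30.5,
}

PRESET_EFFICIENCY: dict[str, float] = {
    "Actin": 0.961, "GPD": 0.941, "18S": 0.975, "28S": 0.906, "b-tub": 0.932,
    "a-tub": 0.949, "RPA12": 0.972, "EF": 0.966, "UBI": 0.960, "UBC": 0.956,
    "MSF1": 1.023, "Ras": 0.995, "SPRYP": 0.912, "CYPL": 0.929, "PPCI": 0.976,
    "TIF": 1.015, "PP2A": 1.009, "VPS28": 1.009,
}


@dataclass
class SyntheticTruth:
    """Generator parameters defining the ground-truth stability order."""

    base_ct: dict[str, float]
    noise_sd: dict[str, float]
    group_shift: dict[str, dict[str, float]]  # gene -> condition -> cycles
    efficiency: dict[str, float]
    tech_noise_sd: float = 0.1
    loading_sd: float = 0.3
    seed: int = 0
    condition_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(PRESET_CONDITION_SETS)
    )

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValidationError("noise_sd must be >= 0")
        if self.tech_noise_sd < 0 or self.loading_sd < 0:
            raise ValidationError("noise SDs must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.base_ct)

    @property
    def conditions(self) -> list[str]:
        return [c for cs in self.condition_sets.values() for c in cs]

    def stability_order(self) -> list[str]:
        """Expected order, most stable first: noise plus mean |shift|."""
        def score(g: str) -> float:
            shifts = self.group_shift.get(g, {})
            mean_shift = (
                float(np.mean([abs(v) for v in shifts.values()])) if shifts else 0.0
            )
            return self.noise_sd[g] + mean_shift
        return sorted(self.genes, key=lambda g: (score(g), g))

    def stable_pair(self) -> tuple[str, str]:
        order = self.stability_order()
        return (order[0], order[1])


def study_preset(seed: int = 0, shift_scale: float = 1.0) -> SyntheticTruth:
    """Default study-scale truth: 18 genes, 10 conditions, graded noise.

    Per-gene biological noise SDs run linearly from 0.05 to 0.90 cycles
    along the preset stability order; condition shifts grow with
    instability (the two most stable genes get none) and are drawn once
    from the seeded generator, then frozen in the returned truth.
    """
    rng = np.random.default_rng(seed)
    genes = list(PRESET_STABILITY_ORDER)
    noise_levels = np.linspace(0.05, 0.90, len(genes))
    noise_sd = {g: float(s) for g, s in zip(genes, noise_levels)}
    shift_amp = np.linspace(0.0, 1.2, len(genes)) * shift_scale
    shift_amp[:2] = 0.0  # designated stable pair: no condition effect at all
    conditions = [c for cs in PRESET_CONDITION_SETS.values() for c in cs]
    group_shift = {
        g: {c: float(amp * rng.standard_normal()) for c in conditions}
        for g, amp in zip(genes, shift_amp)
    }
    return SyntheticTruth(
        base_ct=dict(PRESET_BASE_CT),
        noise_sd=noise_sd,
        group_shift=group_shift,
        efficiency=dict(PRESET_EFFICIENCY),
        tech_noise_sd=0.1,
        loading_sd=0.3,
        seed=seed,
    )


def generate_ct_dataset(
    truth: SyntheticTruth,
    n_bio: int = 3,
    n_tech: int = 3,
    conditions: Sequence[str] | None = None,
) -> tuple[CtTable, SampleSheet, SyntheticTruth]:
    """Simulate a Ct table plus sample sheet from a :class:`SyntheticTruth`.

    One column is produced per (condition, bio_rep, tech_rep).  The
    sheet's ``group`` column defaults to the condition and an extra
    ``condition_set`` column records the DDS/DSB/DST membership.  Values
    falling outside the valid Ct range are clipped with a warning.
    """
    if n_bio < 1 or n_tech < 1:
        raise ValidationError("need at least one biological and technical replicate")
    rng = np.random.default_rng(truth.seed)
    if conditions is None:
        conditions = truth.conditions
    set_of = {
        c: name for name, cs in truth.condition_sets.items() for c in cs
    }
    genes = truth.genes
    columns: dict[str, np.ndarray] = {}
    rows: list[dict] = []
    base = np.array([truth.base_ct[g] for g in genes])
    noise = np.array([truth.noise_sd[g] for g in genes])
    clipped = 0
    for condition in conditions:
        shift = np.array(
            [truth.group_shift.get(g, {}).get(condition, 0.0) for g in genes]
        )
        for b in range(1, n_bio + 1):
            loading = rng.normal(0.0, truth.loading_sd)
            bio = rng.normal(0.0, noise)  # biological draw shared by tech reps
            for t in range(1, n_tech + 1):
                tech = rng.normal(0.0, truth.tech_noise_sd, size=len(genes))
                ct = base + loading + shift + bio + tech
                low, high = CT_MIN + 1e-6, CT_MAX
                clipped += int(((ct < low) | (ct > high)).sum())
                ct = np.clip(ct, low, high)
                sample_id = f"{condition}:b{b}:t{t}"
                columns[sample_id] = ct
                rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "bio_rep": b,
                        "tech_rep": t,
                        "group": condition,
                        "condition_set": set_of.get(condition, "other"),
                    }
                )
    if clipped:
        import warnings

        warnings.warn(f"{clipped} Ct values clipped to ({CT_MIN}, {CT_MAX}]")
    table = CtTable(pd.DataFrame(columns, index=genes))
    sheet = SampleSheet(pd.DataFrame(rows))
    return table, sheet, truth


def generate_dilution_series(
    efficiency: float,
    intercept: float = 30.0,
    noise_sd: float = 0.0,
    points: int = 5,
    replicates: int = 3,
    dilution_factor: float = 10.0,
    seed: int = 0,
    gene_id: str = "synthetic",
) -> DilutionSeries:
    """Simulate a serial-dilution ladder for standard-curve fitting.

    Ct(c) = intercept − log10(c)/log10(1+E) + N(0, noise_sd), with
    ``points`` concentrations 1, 1/f, 1/f², … measured in
    ``replicates`` wells each.
    """
    if efficiency <= 0 or efficiency > 1.2:
        raise ValidationError(f"efficiency must be in (0, 1.2], got {efficiency}")
    if points < 3:
        raise ValidationError("need >= 3 dilution points")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + efficiency)
    out = []
    for i in range(points):
        conc = dilution_factor ** (-i)
        mean_ct = intercept + slope * np.log10(conc)
        cts = mean_ct + rng.normal(0.0, noise_sd, size=replicates)
        out.append((conc, cts))
    return DilutionSeries(gene_id, out)


def generate_dilution_panel(
    truth: SyntheticTruth,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> dict[str, DilutionSeries]:
    """One five-point ladder per gene using the truth's efficiencies."""
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    return {
        g: generate_dilution_series(
            truth.efficiency[g],
            # cap so the deepest 10^-4 dilution (~14 cycles later) stays <= 45
            intercept=min(truth.base_ct[g] + 3.0, 30.0),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            gene_id=g,
        )
        for g in truth.genes
    }


def generate_rpkm_table(
    genes: Sequence[str],
    contrasts: Sequence[str],
    stable_fraction: float = 0.8,
    effect_range: tuple[float, float] = (1.2, 3.0),
    base_rpkm: float = 50.0,
    seed: int = 0,
) -> tuple[RpkmTable, pd.DataFrame]:
    """Simulate an RPKM contrast table with known stable/unstable labels.

    Stable genes draw |log2FC| uniformly in [0, 0.9]; unstable genes draw
    it from ``effect_range`` (which must sit above 1) with a random sign.
    Returns the table and a gene × contrast truth frame of labels.
    """
    if not 0.0 <= stable_fraction <= 1.0:
        raise ValidationError("stable_fraction must be in [0, 1]")
    lo, hi = effect_range
    if not (1.0 < lo <= hi):
        raise ValidationError(f"effect_range must satisfy 1 < lo <= hi, got {effect_range}")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_stable = int(round(stable_fraction * len(genes)))
    stable_genes = set(genes[:n_stable])
    rows = []
    labels = pd.DataFrame(index=genes, columns=list(contrasts), dtype=object)
    for gene in genes:
        for contrast in contrasts:
            if gene in stable_genes:
                lfc = rng.uniform(-0.9, 0.9)
                labels.at[gene, contrast] = "stable"
            else:
                lfc = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                labels.at[gene, contrast] = "up" if lfc > 0 else "down"
            control = base_rpkm * float(rng.lognormal(0.0, 0.25))
            rows.append(
                {
                    "gene": gene,
                    "contrast": contrast,
                    "rpkm_treatment": control * 2.0**lfc,
                    "rpkm_control": control,
                }
            )
    return RpkmTable(pd.DataFrame(rows)), labels
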