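# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Input model and conventions

A Ct value is the PCR cycle at which fluorescence crosses the detection
threshold; it is inversely and logarithmically related to the starting
template amount.  Valid Ct values lie in (0, 45] cycles.  Technical
replicates are averaged arithmetically *on the Ct scale* — Ct is already
logarithmic in template, so the arithmetic Ct mean corresponds to the
geometric mean of quantities, the convention used throughout the package.
Triplets whose within-replicate range exceeds `max_spread` (default 0.5
cycles, a common plate-QC rule of thumb) are flagged in a QC report but
still averaged: the flag is advisory and the package never silently drops
data.

Missing values are a hard error for the stability algorithms (geNorm and
NormFinder are defined on complete matrices); `drop_incomplete =
genes|samples` is the explicit escape hatch.  Silent imputation is not
offered because it biases exactly the variance statistics these methods
rank by.

The pipeline supports running either on technical-replicate means (default)
or on all replicate wells (`aggregate_technical: false`); the default keeps
the biological replicate as the unit of analysis so that technical
precision does not masquerade as biological stability.

## Efficiency calibration

Standard curves are ordinary least squares of the **per-point mean Ct**
against log10(relative concentration).  Fitting point means rather than
pooled replicate wells matches the standard-curve convention and makes R²
a measure of ladder linearity rather than well-to-well scatter.
Efficiency is `E = 10^(−1/slope) − 1`; a slope ≥ 0 (signal increasing with
dilution) is rejected as an invalid curve.  Fewer than three distinct
concentrations is an error.

Ct → quantity conversion has two modes that differ per gene only by a
positive constant, so all scale-invariant statistics downstream are
identical under either:

- `curve` (default): `q = 10^((Ct − intercept)/slope)`, anchored at q = 1
  at the curve intercept.
- `delta_ct`: `q = (1+E)^(Ct_min − Ct)`, anchored at q = 1 for the
  most-concentrated sample; needs only an efficiency, for datasets without
  a dilution series.

Quantities are *relative* — no absolute copy-number units are claimed.

## geNorm

Pairwise variation `V(j,k)` is the sample SD (n−1 denominator) across
samples of `log2 q_j − log2 q_k`; `M_j` is the mean of `V(j,k)` over all
partners.  Log base 2 and the n−1 denominator are the geNorm conventions.
Computing the log *difference* rather than the log of the ratio makes the
statistic exactly symmetric in floating point.

Ranking is stepwise: remove the highest-M gene, recompute, stop at two
genes.  The two survivors cannot be ordered by M and share rank 1 (the next
gene has rank 3).  Ties on M remove the reverse-lexicographically larger
gene id, so results are independent of input order.  Each gene's reported M
is the value at its exclusion step; survivors report their M from the final
three-gene step.

`V(n, n+1)` is the SD across samples of `log2(NF_n/NF_{n+1})` where `NF_n`
is the geometric mean quantity of the top-n genes; the recommended gene
count is the smallest n with `V(n, n+1) < 0.15` (the conventional
threshold, configurable), or the panel size if the series never crosses it.

## NormFinder

On x = log2 q, after centering each sample by its across-gene mean (which
removes loading effects), with groups g of size n_g and k genes:

1. group mean ȳ_ig, overall mean ȳ_i· (unweighted over groups — the
   intended designs are balanced), difference d_ig = ȳ_ig − ȳ_i·;
2. intragroup variance: the naive within-group sample variance z_ig of the
   centered values is biased because centering mixes 1/k of every gene's
   noise into every other gene; under the additive model
   E[z_ig] = σ²_ig(1 − 2/k) + σ̄²_g/k, inverting gives
   `σ̂²_ig = max(0, (z_ig − z̄_g/(k−1)) · k/(k−2))` (needs k ≥ 3).
   Monte-Carlo checks at the intended scale (k = 18, n = 9 per group) show
   the estimated intragroup SD is within a few percent of truth;
3. intergroup scale `τ̂²_g = max(0, var_genes(d_ig) − mean_genes(σ̂²_ig/n_g))`;
4. shrinkage `d̃_ig = d_ig · τ̂²_g/(τ̂²_g + σ̂²_ig/n_g)` with dispersion
   `v_ig = (σ̂²_ig/n_g) · τ̂²_g/(τ̂²_g + σ̂²_ig/n_g)`;
5. stability `ρ_i = mean_g(|d̃_ig| + √v_ig)`, ranked ascending.

With a single group, ρ reduces to the sample SD of the gene's centered
values.  Both variance estimates are truncated at zero.  In the pipeline
the NormFinder groups are the condition levels within a condition set; in
the pooled "Total" analysis the condition sets themselves are the groups.

## BestKeeper

Ct-scale descriptives per gene (geometric/arithmetic mean, min, max,
dispersion, CV as % of the arithmetic mean), the per-sample geometric-mean
index, and Pearson r of each gene against the index with a two-sided
p-value from the t transform (n−2 df).  Genes with dispersion > 1 cycle
are flagged unstable.

Two dispersion conventions are offered: `sd` (sample standard deviation,
default) and `mad_geomean` (mean absolute deviation around the geometric
mean, for strict compatibility with the original BestKeeper spreadsheet);
descriptions of BestKeeper disagree across secondary sources, and the
"SD > 1" flagging rule reads most naturally as a standard deviation.

The final ranking is two-tier: genes with r ≥ 0.9 ordered by ascending SD,
the remainder appended ordered by descending r (undefined r — zero-variance
gene or index — sorts last), ties broken lexicographically.  This encodes
the practice of treating weakly index-correlated genes as unusable
regardless of how quiet their Ct is.  The rule reproduces, position for
position, all four published ranking rows of the *L. edodes* worked example
shipped in `refstab.examples` (40/40 rank positions); the printed r values
of that example only constrain the tier threshold to roughly (0.90, 0.92),
and 0.9 is used as the round default, exposed as a flag.

BestKeeper runs on the ten candidates preselected by geNorm + NormFinder
(below), mirroring how the method is used in practice on a shortlist.

## Consensus

Preselection scores each gene by the literal sum M + ρ (the two statistics
are both in log2-expression units, and the literal sum is what the source
workflow describes); a `rank_sum` option is available for users worried
about the differing scales.  The default preselection is computed per
condition set.  The three per-method rankings, restricted to the
preselection, are aggregated by mean rank with ties broken by geNorm M and
then gene id — no formula for the narrative "based on the three analyses"
integration exists, and the mean rank is the simplest order-based choice.
The recommended pair is geNorm's surviving pair; the recommended count
comes from the V-series rule.

## 2^−ΔΔCt validation

Per biological replicate, `ΔCt = Ct_target − mean(Ct_refs)` (arithmetic
mean over references ≡ geometric mean of their quantities), and
`ΔΔCt = ΔCt − mean(ΔCt over calibrator replicates)`.  The per-condition
fold change is `base^(−mean ΔΔCt)` — the geometric mean of the replicate
fold changes — which makes the calibrator condition exactly 1 by
construction; the reported spread is the SD of the replicate fold changes.
The arithmetic mean of fold changes was deliberately not used for the point
estimate: it is biased upward under log-symmetric noise and would leave the
calibrator ≠ 1.  `base` defaults to 2.0 (the literal 2^−ΔΔCt); passing
1+E gives an efficiency-corrected estimate, with the caveat that a single
shared base is required for sample loading offsets to cancel exactly.

## RNA-seq screen

`lfc = log2((RPKM_t + pc)/(RPKM_c + pc))`; stable iff |lfc| ≤ 1
(boundary inclusive), up above, down below.  The pseudocount defaults to 0
with an explicit `undefined` class for zero denominators, because any
default pseudocount would silently pull genes toward "stable"; a positive
`--pseudocount` makes the screen total.  The numerator is always the
treatment member of the contrast and the orientation is recorded in the
output metadata.

## Synthetic data generator

The Ct model is additive on the cycle scale (multiplicative on
quantities, the standard qPCR error model):

    Ct(g, s, t) = base_ct_g + loading(s) + shift_g(condition(s))
                  + N(0, noise_sd_g) + N(0, tech_noise_sd)

with the biological draw shared across a sample's technical replicates and
`loading(s) ~ N(0, loading_sd)` shared across all genes of a biological
sample — exactly the nuisance reference-gene normalisation must cancel, and
a property test verifies that rankings and fold changes are invariant to it.

The default preset mirrors a typical 18-gene reference-gene study: three
development stages, three substrates, three stresses plus an untreated
control, 3 biological × 3 technical replicates (90 columns), base Ct values
spanning ≈15–31 cycles, per-gene efficiencies between 0.906 and 1.023.
Per-gene biological noise SDs run linearly 0.05–0.90 cycles along a fixed
stability order, condition shifts grow with instability up to ±1.2 cycles
(drawn once per seed and frozen in the returned truth), technical noise is
0.1 cycles and loading SD 0.3 cycles — all magnitudes chosen as typical of
plate qPCR data.  The two most stable genes get zero condition shift, making
them the designated ground-truth reference pair.

What the generator does **not** emulate: amplification-curve shape and Ct
calling, efficiency drift and inhibition, missing wells, plate/batch
structure beyond a scalar loading offset, heavy-tailed or correlated
noise between genes.  Passing tests on synthetic data therefore demonstrate
correctness of the statistics and recovery under the stated error model,
not robustness to every artifact of real plates.

## Problem sizes used in the automated checks

The test suite exercises: the 40-position published ranking example;
200 random 5-gene × 8-sample matrices against a brute-force geNorm oracle
(agreement to 1e−12); 200-seed NormFinder recovery at k = 10, n = 50 per
group with a +1 log2 shift; 100-seed efficiency recovery at Ct noise
SD 0.1; and 100 seeded end-to-end pipeline runs on the default preset
(the designated pair must be recommended in ≥ 90% of runs with a
two-gene recommendation).  These sizes keep the full suite under a minute
or two on one CPU while leaving the Monte-Carlo margins comfortable.

## Known limitations

- geNorm's M is known to favour co-regulated gene pairs; no co-regulation
  screen is included.
- NormFinder's unweighted overall mean assumes approximately balanced
  groups; strongly unbalanced designs would warrant a weighted variant.
- BestKeeper's two-tier ranking is a reconstruction of common practice;
  the original method's regression extensions beyond Pearson correlation
  are out of scope.
- p-values in BestKeeper assume independent Gaussian errors and are
  reported as computed, without multiplicity correction.
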