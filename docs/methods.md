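# Methods

## Overview

`gliohypoxia` implements a two-stage analysis. Stage one derives a hypoxia
response gene signature shared between two bulk RNA-seq
hypoxia-vs-normoxia contrasts of patient-derived glioblastoma stem cell
lines. Stage two applies that signature to single-cell RNA-seq data of
high-grade glioma patients: each tumor cell receives a module score for the
signature, cells above a calibrated threshold are called hypoxic, cells are
assigned one of the four glioma differentiation states (mesenchymal-like
MES, astrocyte-like AC, oligodendrocyte-precursor-like OPC, neural
progenitor-like NPC), and the state composition of hypoxic versus
non-hypoxic cells is compared per patient and between IDH-wildtype and
IDH-mutant patient groups.

## Shared-signature derivation

A gene is a DEG in one contrast when `|log2FC| > 1` and BH-adjusted
`p < 0.01`; both inequalities are strict, so a gene at exactly log2FC = 1
or padj = 0.01 is excluded. The multiple-testing procedure is
Benjamini–Hochberg step-up (the convention of the standard count-model DE
tools); when a table arrives without adjusted p-values they are computed
from the raw p-values over the whole table.

The shared signature is the symbol intersection of the two contrasts' DEG
sets restricted to genes with concordant sign ("opposing directionality"
means `sign(log2FC_A) != sign(log2FC_B)`; a zero log2FC cannot survive the
>1 filter, so no sign-of-zero rule is needed). The up-regulated subset of
the concordant intersection is the scoring signature. Symbols are matched
case-sensitively; readers offer an opt-in upper-casing flag for data whose
capitalisation is unreliable.

Over-representation of a query set in a gene-set library uses the
hypergeometric upper tail P(overlap >= k) on a user-supplied universe
(default: the genes detected in the expression matrix). The odds ratio
comes from the 2x2 membership table with Haldane's 0.5 correction when any
cell is zero, and library sets are ranked by
`combined_score = OR * (-ln p)`. This is a ranking heuristic, not a
calibrated statistic; the rank-based z-score variant used by some web
platforms is deliberately not reproduced.

## Quality control and normalisation

Cells are removed when `total_umi < 1000`, `n_genes_detected < 400` or
`mito_fraction > 0.25` (mitochondrial genes identified by the `MT-` symbol
prefix, configurable). The inequalities are strict in the removal
direction, so a cell at exactly 1000 UMIs, 400 genes and 25% mitochondrial
counts is retained. Log-normalisation is
`ln(1 + scale * count / total_umi)` with `scale = 10^4` (natural log);
both base and scale follow the convention of the standard single-cell
toolkits and are configurable. Scores are computed on pooled
log-normalised data without batch integration: integration in the emulated
workflow feeds only the embedding used for visualisation, which this
package does not produce.

## Module score

The score of signature S in cell c is

    score(c) = mean_{g in S} L[c, g] - mean_{d in D} L[c, d]

where L is the log-normalised layer and D is the pooled multiset of
control draws: genes are ranked by average expression over all cells (ties
broken by gene symbol), cut into `n_bins = 24` equal-frequency bins, and
each signature gene contributes `n_ctrl = 100` draws taken uniformly with
replacement from its own bin after excluding the signature's genes (so an
expression shift confined to the signature is not partially subtracted
from itself; the same convention as scanpy's gene-set scoring). If a bin
contains only signature genes, that gene's controls come from all
non-signature genes, with a warning.

Control draws are seeded per gene from a SHA-256 digest of
`(seed, signature name, gene symbol)`. Consequences: scores are
reproducible across runs and invariant to the order of genes and cells in
the matrix; and bit-level parity with any other implementation of the same
binned-control scheme (whose RNG streams differ) is intentionally out of
scope. Two analytic fixed points pin the procedure down: a constant matrix
scores exactly zero, and adding a constant c to the signature's entries
(or to every entry) shifts every score by exactly c (or zero).

## Hypoxia classification

VEGFA-positive cells (>= 2 raw UMIs, never normalised values) provide an
independent guide for how many cells a hypoxia threshold should select.
`calibrate_threshold` sweeps a grid (default 0.05–0.95, step 0.05) and
chooses the threshold whose above-threshold fraction is closest to the
overall marker-positive fraction, ties broken toward the lower threshold.
This makes explicit a selection that is usually done by eye on the guide
plot; a fixed threshold (0.25 for the shared glioma signature, 0.55 for a
HIF-metagene-style signature, which score on different scales) can always
be supplied instead. Classification is strict: hypoxic iff
`score > threshold`.

## State assignment and coordinates

The six state programs (MES1, MES2, AC, OPC, NPC1, NPC2) are module-scored
with the same parameters; the argmax labels the cell and MES1/MES2,
NPC1/NPC2 collapse to MES and NPC after the argmax. Exact ties are broken
by the fixed order MES1 < MES2 < AC < OPC < NPC1 < NPC2 and logged; ties
are a measure-zero event on real-valued scores and occur in practice only
on degenerate (constant) input.

The two-dimensional state representation uses
`y = max(OPC, NPCmax) - max(AC, MESmax)` and, within the winning
hemisphere, `x = sign(d) * log2(|d| + 1)` with `d = NPCmax - OPC` for
y > 0 and `d = MESmax - AC` otherwise. The axis orientation (NPC and MES
at x > 0, OPC and AC at x < 0) is a convention, stated here because the
quadrant plot's sign convention is not standardised.

## Shift analysis

Per stratum (pooled or per patient), the proportions of the four states
are computed separately within hypoxic and non-hypoxic cells; a stratum
with no cells in one class reports NaN with a warning rather than silent
zeros. The shift of a state is `delta = prop_hypoxic - prop_nonhypoxic`.
IDH-WT and IDH-MUT groups are compared per state by a two-sided Wilcoxon
rank-sum test on the per-patient deltas — the per-patient delta is the
statistic that directly operationalises per-patient shift line plots; the
per-patient hypoxic-class proportion alone is also available from the same
table. The exact permutation null is used when the combined sample is at
most 12 and tie-free; otherwise the normal approximation with tie and
continuity corrections. No multiplicity correction is applied across the
four states (none is conventional for this four-way descriptive
comparison); significance stars are 0.05 / 0.01 / 0.001.

## Synthetic data

The generator exists so that every stage is testable against known truth
without any external download. It emulates:

- **Cohort**: 11 patients (5 IDH-WT, 6 IDH-MUT), default 2777 cells each
  (~30,500 cells) over 2000 genes.
- **Counts**: negative binomial with mean mu and size r
  (`Var = mu + mu^2/r`, r = 2 by default). Per-gene baseline means are
  log-normal (meanlog −0.7, sdlog 1.0), giving ~1600 UMIs and ~800
  detected genes per cell — comfortably inside the QC gates, so QC is
  exercised by dedicated boundary fixtures rather than by attrition.
- **Programs**: six planted state programs of 30 genes each and a planted
  193-gene hypoxia program (head symbols VEGFA, SLC2A1, BNIP3, EGLN3 —
  the canonical angiogenesis/glycolysis/autophagy/HIF-feedback markers).
  Program membership multiplies the NB mean by `exp(effect)`; defaults are
  1.0 (state) and 1.4 (hypoxia) on the natural-log scale, i.e. roughly a
  log2 fold-change of 1.4–2 — the magnitude the DEG filter itself treats
  as differential.
- **Hypoxia coupling**: per-patient hypoxic fractions span 1.7–5.5% with a
  cohort mean near 3.8%. A hypoxic cell's state is redrawn from the
  IDH-group distribution: WT (MES .75/AC .15/OPC .03/NPC .07), MUT
  (MES .25/AC .35/OPC .10/NPC .30) against a shared baseline of
  (MES .249/AC .209/OPC .165/NPC .377). At the 5:6 cohort mix these pool
  to roughly MES 48% / AC 26% / OPC 7% / NPC 19% among hypoxic cells —
  the regime of interest: a strong WT MES shift, an AC shift confined to
  MUT patients.
- **Marker**: the VEGFA mean is 0.1 in non-hypoxic and 8.0 in hypoxic
  cells, so marker positivity (>= 2 UMIs) is tightly hypoxia-coupled, as
  required for the marker fraction to be a usable calibration guide.
- **Mitochondrial genes**: 13 genes (`MT-01`…`MT-13`) at constant mean,
  giving a ~6% mito fraction.
- **Bulk contrasts**: per gene, triplicate log2-expression replicates per
  condition with N(0, 0.2) noise around planted shifts of magnitude
  uniform in [1.8, 3.0]; p-values from a two-sample z-test at the known
  noise scale (a deliberately simple stand-in for a count-model fit that
  remains well-behaved with three replicates; the real count model is out
  of scope). The planted geometry (248 shared DEGs, 5 sign-discordant,
  193 up; 386 and 738 contrast-unique DEGs) reproduces the set algebra of
  the emulated experiment exactly, by construction.

What the generator does **not** emulate: per-cell library-size variation,
doublets, ambient RNA, batch effects beyond the patient label, dropout
beyond NB sampling, and correlation between state and hypoxia programs
(state programs may be configured to overlap the hypoxia program, but are
disjoint by default to keep recovery tests interpretable). Passing
recovery tests therefore demonstrates correctness of the pipeline's
logic under its own statistical assumptions, not robustness to the full
messiness of droplet data.

All randomness flows from the single seed in `SimConfig`; identical seeds
give bit-identical cohorts.

## Numerical and design notes

- Equal-frequency binning uses `bin = floor(rank * n_bins / n_genes)` on
  the (average, symbol)-sorted rank, so bins differ in size by at most one
  gene.
- `calibrate_threshold` breaks distance ties toward the lower threshold
  (the more inclusive classification).
- The hypergeometric p is clipped into `(0, 1]` before taking `-ln p`.
- An explicitly empty QC result is a warning, not an exception; downstream
  stages raise only when an operation becomes undefined.
- DEG tables must be per-gene unique; duplicated symbols are an error, not
  a silent aggregation.
- The 2×2 odds-ratio orientation is (query membership) × (set membership);
  with Haldane's correction it is finite for every table.
- Problem sizes used by the test suite: oracle comparisons run on matrices
  up to 50 genes × 20 cells; planted-truth recovery runs one full-size
  cohort (~30,500 cells × 2000 genes) plus 25 replicate cohorts at 1500
  cells/patient × 800 genes (the reduced size keeps replicate studies
  quick while leaving the per-patient rank-sum comparison well-powered).

## Known limitations

- The calibration rule formalises a visual selection; on data where the
  marker is weakly coupled to the signal of interest the guide fraction
  is a poor target, and a fixed threshold should be supplied.
- The module score's control draws differ from other implementations'
  RNG streams, so scores agree with them in distribution and fixed
  points, not bit-for-bit.
- The stand-in bulk DE test assumes known replicate noise; it exists only
  to feed the set-algebra stage from synthetic inputs.
- Enrichment ranking by OR × (−ln p) inherits the instability of odds
  ratios on tiny overlaps; the BH-adjusted p is reported alongside for
  calibrated inference.
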