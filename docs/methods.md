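# Methods

## Size-resolved particle classification

A sequenced pair's insert length is taken as the protected-DNA length of one
bound particle. The retained range is 20 bp – 1 kb, matching a gel size
selection. Classification uses two windows that serve different purposes and
deliberately coexist:

- **subNSP / nucleosomal split at 120 bp.** The split is a strict
  inequality: subNSP iff length < 120, so the partition is total (120 bp
  itself falls on the nucleosomal side).
- **Nucleosome order.** For length ≥ 120,
  `N̂ = round((L + linker)/(nuc_unit + linker))`, clamped to ≥ 1, with
  `nuc_unit = 150`, `linker = 30`. Rounding is `floor(x + 0.5)` so the
  half-way points (e.g. 240 bp → order 2) are deterministic across
  platforms. The mono band under this rule is ≈ [120, 240).
- **Dyad-midpoint window 150 ± 15 bp.** Midpoint (dyad) tracks use the
  tighter window; fragments of, say, 134 bp are classified mono but excluded
  from dyad mapping, where boundary heterogeneity would blur positioning.

Midpoints of even-length fragments round down — an arbitrary but fixed
convention. All internal coordinates are 0-based half-open (BED); 1-based
conversion happens only at the GFF3 and wiggle format boundaries. Duplicate
fragments are retained (no deduplication step exists in this protocol).

## Tracks and normalization

Midpoint tracks add one count at the fragment midpoint; raw track sums
therefore equal contributing fragment counts. Coverage tracks increment
every protected base, built by difference-array accumulation, which is
exactly (not approximately) the naive per-base loop. `normalize_per_million`
scales by 1e6 / retained fragments and refuses to run twice — depth
normalization is a one-shot state change, and silently re-scaling is a
common source of wrong figures.

**Normalization for differential-digestion comparisons.** Per-fragment
depth scaling is structurally confounded with digestion level: cleaving an
oligo-nucleosome into monomers multiplies the fragment count without
changing which bases stay protected, so two samples of equal sequencing
depth but different digestion have different per-fragment scale factors for
the *same* underlying occupancy. Window tests on coverage therefore
normalize each sample by its mean coverage over TSS-distal chromatin
(`stable_reference_scale`, exclusion radius 2.5 kb around every TSS
including non-shared-isoform genes): distal chromatin is dominated by
stable nucleosomes whose protection is invariant to digestion level, making
it an internal reference. Per-million scaling remains the default for all
single-sample tracks and for the digestion-correlation profile, where only
the across-sample ordering matters.

## Anchor-aligned profiles

Profile rows span `[pos − flank, pos + flank)` and are strand-oriented:
positive offsets point downstream, minus-strand rows are read right-to-left.
Cells outside the chromosome are missing (NaN), never zero — zero-filling
would fake occupancy dips at chromosome edges. Aggregation is a NaN-aware
column mean with per-column contributing counts. Exon-boundary profiles use
the same machinery with junction anchors; there is no special-case path.

## Differential digestion

- **Digestion index**: mono fraction of nucleosome-scale fragments,
  `|L ∈ [120, 180]| / |L ≥ 120|`. Complete digestion converts multi- to
  mono-nucleosomal fragments, so the index rises monotonically with
  digestion. The estimator is pluggable (any callable on the length vector)
  because it is a summary heuristic, not a calibrated measurement.
- **Per-bin correlation**: Pearson r between the per-sample digestion index
  and per-sample aggregate NSP occupancy in 10 bp bins, across ≥ 3 samples.
  Zero-variance bins are flagged undefined rather than given a fabricated r.
- **Window test**: Welch (unequal-variance) two-sample t on per-sample mean
  occupancy over 50 bp windows, minus1 = [−125, −75) and plus1 = [+75, +125)
  around the TSS — 50 bp windows centered on the −1/+1 dyad neighborhoods
  (dyads planted at ∓100). Welch is the safe default at n = 4 per group.
  Windows are configurable. A both-groups-constant, equal-means input is
  flagged degenerate instead of significant.
- **+1 position**: argmax of a 31 bp moving average over [0, +250]; box
  smoothing turns sharp peaks into plateaus, so the plateau center is
  reported. All-zero spans yield a missing value.

## Expression linkage

Expression quartiles are rank-based with ties broken by gene order
(deterministic); quartile sizes are balanced to within one gene. The TSS
subNSP peak is quantified by the Fisher excess kurtosis (biased moment form
m4/m2² − 3) of raw midpoint offsets in [−250, +50] — the window spans the
upstream footprint zone into the 5′ UTR. Genes with < 20 midpoints are
ineligible (fourth-moment estimates are unstable below ~20 observations)
and are excluded, never imputed. Both kurtosis and abundance are emitted;
the quartiling statistic is a configuration choice.

Per-gene subNSP log2 fold change pools replicates within condition and
compares counts-per-million with a pseudocount of 1:
`log2(CPM_light + 1) − log2(CPM_dark + 1)`. The difference-of-logs form
makes label-swap antisymmetry bit-exact. The fold-change trend uses
tricube-weighted local linear regression (loess, span 0.5 by default,
statsmodels lowess) evaluated on a grid, with a 95% percentile band over
500 case-bootstrap resamples and Spearman correlations over all points and
over the differential-expression-significant (FDR < 0.05) subset.

## subNSP position calling

The caller is intentionally simple and fully deterministic: 15 bp
moving-average smoothing of the depth-normalized subNSP midpoint track,
local maxima (plateau ties resolved leftmost) above a threshold, greedy
highest-first acceptance with ≥ 60 bp separation, chromosomes visited in
sorted order. The threshold is k = 4 × the genome-wide nonzero median of
the **raw** track. On sparse midpoint data the raw nonzero median equals a
single fragment's weight, so the threshold reads "at least four stacked
midpoints"; the median of the *smoothed* track collapses toward zero on
quiet genomes and would make any fixed k meaningless. Distance-to-CDS is
edge-to-edge against CDS features specifically (not gene or mRNA spans),
strand-ignored, zero inside a CDS; reported as the percentage of calls
beyond 10 kb and 100 kb. TFBS aggregation consumes site catalogs as BED6
(no motif scanning) and reports per-condition strand-oriented aggregates, a
light − dark difference profile, and the per-site matrix for heatmaps.

## The synthetic landscape

The simulator is the test bed for every stage; its defaults define the
study conditions.

**Geometry per gene** (strand-oriented, relative to TSS): a labile −1
nucleosome at −100 with occupancy 0.8 (low digest) vs 0.3 (high); a stable
array of 6 nucleosomes from +100 at 180 bp period (occupancy coupled to the
gene's recruitment focality, range ≈ 0.5–0.9, unchanged across digestion);
one subNSP footprint at −60, protected width drawn from [30, 110] bp.
Intergenic space carries non-linkable background nucleosomes every 600 bp
at occupancy 0.4, plus naked-DNA background fragments (uniform positions,
lengths uniform on [40, 400], 2/kb at low and 5/kb at high digest) as the
small-particle noise floor.

**Digestion model.** The landscape is digested in R independent rounds,
R chosen so the expected fragment yield (net of expected junction merging)
matches the requested depth; each template survives a round with
probability equal to its occupancy, so per-template counts are
Binomial(R, occupancy). Within a gene's array (the −1 plus the genic array,
in genomic order), adjacent survivors stay joined with per-junction
probability `p_link` (0.55 low, 0.10 high digest) — digestion level is a
single monotone knob. Merged runs give lengths ≈ N·150 + (N−1)·30. Fragment
boundaries receive independent rounded-Gaussian jitter (sd 8 bp, so mono
fragments span ≈ 135–165); a final 20 bp – 1 kb size selection mimics the
gel excision.

**Footprint focality and condition response.** Each gene draws a focality
`conc` ∈ [0.15, 0.9]: a bound footprint sits at the template center with
probability `conc`, else uniformly within ±120 bp. Focality is the planted
"sharpness" that kurtosis measures. Footprint survival falls to 0.35× under
high digest (labile small particles); light-responsive genes (half of all
genes) scale their dark-condition occupancy by 2^(−δ), δ ~ Normal(0, 1.5),
and `subnsp_dark_factor` can impose a hard occlusion (e.g. 0 for
light-only binding). Replicate-to-replicate biological variability raises
each gene's occupancies to a per-(sample, gene) power f ~ lognormal(0,
0.25), perturbing survival while keeping probabilities in [0, 1]; without
it, replicates would be binomially exact and sub-percent numerical residues
would register as "significant" in ways no real replicate set shows.

**Expression coupling.** Per-gene baseline means scale as
2^(3·(conc − mean conc)) around 200 counts (the within-sample
recruitment/expression association); the condition log2FC equals
1.0 × the planted footprint log2FC plus Normal(0, 0.25) noise. Counts are
negative-binomial (dispersion 0.05; Poisson below 1e-8) over 4 replicates
per condition. The bundled differential-expression table — Welch t on
log2(count + 1) with Benjamini–Hochberg adjustment — is plumbing that
stands in for an upstream count-model pipeline, adequate for synthetic
validation but not a reimplementation of one.

**What the simulator does not emulate** (so what passing tests do not
show): sequence-dependent MNase bias, mappability and repeat artifacts,
alignment errors, inter-gene distance/length heterogeneity of real
annotations, chromatin heterogeneity across cell populations beyond the
occupancy-noise model, and any isoform complexity (the shared-isoform flag
is planted, not inferred). Recovery rates measured here are upper bounds on
what identically parameterized real data would give.

## Problem sizes

Validation analyses run on toy genomes of 100–950 kb with 15–200 genes and
sample depths of 1e4–2e5 fragments; rate-style checks (window-test
significance, footprint recall) aggregate 25–50 seeded runs. These sizes
give the window tests and rank correlations comfortable power while keeping
every moment estimate in its stable regime.

## Known limitations

- The digestion index is uncalibrated: it orders samples correctly but its
  absolute value depends on the length mixture, not on enzyme units.
- The position caller has no local-background model; a strong broad slope
  under a peak can shift the summit by a few bp.
- `fragments_from_paired_bam` trusts the aligner's proper-pair flag and
  template length; chimeric or soft-clipped templates are not re-examined.
- Loess bootstrap bands are percentile intervals; they undercover slightly
  at the extreme ends of the grid where few points support the fit.
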