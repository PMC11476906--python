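# Methods

`sedncycle` implements the computational chain from meta-omic alignment
tables and sediment porewater profiles to per-cell nitrogen-cycle gene and
transcript abundances, expression scores, benthic fluxes, ordination
statistics, and co-expression networks, together with a synthetic study
generator that emulates a 12-lake sediment survey. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic data does and does not capture.

## Per-cell quantification model

The counting unit is the *insert* — the DNA fragment behind a merged read
pair or orphan read; each insert counts once regardless of paired-end
status. The chain is:

1. **Alignment filtering.** Keep insert-to-gene alignments with percent
   identity >= 95 and >= 45 aligned bases. Both cutoffs are inclusive and
   configurable (`min_identity`, `min_aligned_bases`).
2. **Counting with fractional allocation.** An insert aligning to exactly
   one gene contributes 1 to that gene. An insert aligning to several
   genes distributes its count across those genes in proportion to the
   genes' *unique* insert counts. Proportions are computed once from the
   unique counts (single pass, no EM iteration). If every target of an
   ambiguous insert has zero unique counts, the insert is split equally
   among its targets by default; a `discard` policy is available. Repeated
   (insert, gene) rows are deduplicated with a warning. Summed fractional
   counts always equal the number of distinct inserts kept.
3. **Length normalization.** Counts are divided by gene length (counts per
   base), removing the length bias of fragment sampling.
4. **KO aggregation.** Length-normalized abundances are summed over genes
   sharing a KEGG Orthology. Genes without a KO are excluded and their
   summed abundance reported as `unannotated_mass`.
5. **Per-cell normalization.** Abundances are divided by the median
   abundance of 10 universal single-copy marker genes, yielding genes/cell
   (metagenome) or transcripts/cell (metatranscriptome). The median uses
   the standard midpoint rule for the even marker count. The identities of
   the marker genes are treated as catalog flags, not named genes.

Per-cell values are invariant to sequencing depth: rescaling all
abundances (markers included) by any constant cancels exactly. Per-cell
normalization is applied after KO aggregation; when markers are single
genes the ratio is unaffected by the order of those two steps.

KO annotation of catalog genes uses the subject-coverage/bit-score rule:
a hit is accepted iff subject coverage >= 70% and bit score >= 50% of the
maximum expected bit score (both inclusive); among accepted hits the best
bit score wins, with exact ties broken by the lexicographically smallest
KO id for determinism.

Metatranscriptomic alignments pass through the same >= 95% / >= 45-base
filter as metagenomic ones (one pipeline for both layers).

## Expression scores and pathway summaries

The expression score of a key is the ratio of its metatranscriptomic to
its metagenomic per-cell abundance — transcripts per gene copy. It is
defined only where the metagenomic value is positive; transcripts without
detected gene copies are reported separately as "orphan transcription"
rather than folded into a ratio. The score is invariant to a common
rescaling of both layers and scales linearly with the transcript layer.

log2 transforms handle zeros by replacing them with half the smallest
positive value in the table (recorded in the output metadata); a
pseudocount policy is available. Ordinations of expression consume the raw
ratios (the exponential of the log2 scores).

Pathway summaries average per-cell values over the genes of each
N-transformation process: nitrification (amoABC, hao), the dual
NO3<->NO2 group (narG;nxrA, narH;nxrB — subunits shared between nitrate
reductase and nitrite oxidoreductase, reported once under their own label
and never double-counted), nitrate reduction (napAB, narI),
denitrification (nirS/K, norBC, nosZ), DNRA (nrfAH), and anammox (hzsABC,
hdh; the four-gene set is configurable, with a warning on non-default
sets). Abundance and transcription means run over *all* catalog genes of
a process (zeros included); expression means run over detected genes
only, with the detected count reported.

Lakes are classified as high or low N-transformation potential by whether
their mean per-cell abundance over all N-transformation genes strictly
exceeds 0.006 genes/cell.

## Benthic fluxes

Diffusive fluxes follow Fick's first law for sediments,
`J = -phi * Ds * dC/dz` with the Boudreau tortuosity correction
`Ds = D0 / (1 - ln(phi^2))`. Depth is positive downward with the
sediment-water interface (SWI) at 0, so a solute decreasing into the
sediment imports (J > 0) and an upward-diffusing solute exports (J < 0).
Units: concentrations in uM (mmol m^-3), gradients in mmol m^-4, fluxes
in mmol m^-2 d^-1.

Gradients are ordinary least-squares slopes over the first 3 porewater
points at or below the SWI (the bottom-water sample at -1 cm never enters
the fit). For O2 the slope is fit over the upper linear 50% of the oxic
zone of the microprofile. A perfectly flat window reports slope 0 with
R^2 = 1 by convention. O2 penetration depth is the first depth (linear
interpolation between bracketing points) where the concentration falls
below the detection limit (default 1 uM); profiles that never cross are
censored at the maximum depth, and on noisy non-monotone profiles the
first crossing is taken.

Default free-solution diffusivities at 5 degC (m^2 s^-1): O2 1.27e-9,
NO3- 0.98e-9, NH4+ 1.03e-9, SO4^2- 0.56e-9; porosity defaults to 0.9.
All of these, the gradient window, and the tortuosity model are explicit
configuration with the stated defaults, and are the package's own choices
of standard values.

Molar C/N is `(TOC/12.011) / (TN/14.007)` from weight-percent TOC and TN
(Redfield reference 6.6). Lake-level correlation screens use Pearson r on
pairwise-complete observations with two-sided t-distribution p-values;
zero-variance pairs are reported as NA with a reason.

## Community statistics

- **Bray-Curtis** dissimilarity backs the beta-diversity views; a pair of
  all-zero samples is set to 0 by convention with a warning.
- **NMDS** minimizes Kruskal stress-1 by isotonic-regression-based
  majorization (SMACOF). The first restart is initialized from classical
  scaling of the input distances, the rest from seeded random
  configurations; the best configuration is centered and rotated onto its
  principal axes with deterministic sign fixing. Adding restarts can only
  lower the reported stress, and results are reproducible given the seed.
- **PCA** (for lake categorization from porewater and OM variables)
  centers and optionally standardizes variables, dropping constant
  variables under scaling with a warning.
- **envfit** regresses each centered environmental variable on the
  ordination coordinates; r^2 is the squared multiple correlation and the
  p-value is the fraction of row-shuffled permutations with r^2 at least
  the observed value, with the +1 correction in numerator and
  denominator. Significant vectors default to p < 0.01 for display.
- **bioenv** exhaustively searches environmental-variable subsets (up to a
  configurable budget); each subset is scored by the Spearman rank
  correlation between community distances and Euclidean distances on
  z-scored variables, and the full ranking is returned.
- **PERMANOVA** partitions the total sum of squared distances into among-
  and within-group components (equivalent to the Gower-centered
  formulation) and permutes labels freely. Permutations are vectorized so
  calibration studies (1000 nulls x 999 permutations) take seconds.
  Type-I error of both permutation tests at alpha = 0.05 is verified to
  sit inside [0.03, 0.07] under the null.
- **Hierarchical clustering** uses average linkage on Euclidean distances;
  rows are pre-sorted by id so exact ties merge deterministically.
- **Co-expression networks** connect feature pairs whose Pearson
  correlation on pairwise-complete observations satisfies |r| >= 0.8 by
  default; the sign of r is retained on the edge and isolated nodes stay
  in the node list. The magnitude cutoff is the package's reading of the
  thresholding rule; an alternative p-value mode (two-sided, alpha
  configurable) is provided. Edges are invariant to sample order and to
  affine transforms of individual features.

Permutation counts default to 999 and every stochastic stage requires a
seed; the pipeline manifest records all thresholds and seeds, and reruns
are byte-identical.

## Synthetic study generator

The generator emulates the statistical structure of a 12-lake survey with
three lake archetypes of four lakes each — agriculture-influenced (BAL,
HAL, SEM, ZUG), pristine-alpine (BRI, LUC, SAR, WAL), and large-deep
(CON, GEN, MAG, NEU) — each lake sampled at two sediment depths (0-5 and
5-10 mm), giving 24 metagenome/metatranscriptome sample pairs.

**Gene truth.** Per-process mean genes/cell are 0.017 (nitrification),
0.004 (denitrification), 0.005 (nitrate reduction), and 0.004 (anammox)
for high-potential lakes versus 0.004, 0.002, 0.002, and 0.00005 for
low-potential lakes; the pristine-alpine lakes plus CON and NEU are
constructed high, the agriculture lakes plus GEN and MAG low, so the
0.006 genes/cell rule has a known ground-truth membership. The NO3<->NO2
(0.010/0.002) and DNRA (0.005/0.001) means are package defaults, chosen
once to keep the two classes on either side of the threshold; they are
not survey-derived. Per-gene copy numbers are log-normal around the
process mean with CV 0.3 (the dispersion model is an invention, exposed
in config). Transcripts are copies times a process-level expression rate
= mean transcripts/cell divided by mean genes/cell, with transcripts/cell
of 1.2 (nitrification), 0.1 (NO3<->NO2), and 0.04 (denitrification);
nitrate reduction 0.02, DNRA 0.005, and anammox 0.01 are package
defaults. Markers sit at exactly 1 copy/cell and 1 transcript/cell.

**Catalog.** 10 marker genes (~900 bp) plus two same-KO paralogs of each
of 20 N-cycle gene symbols (1000-2100 bp, deterministic lengths). Same-KO
paralogs are what make ambiguous mappings possible; the narG;nxrA and
narH;nxrB symbols genuinely share KOs between nitrate reductase and
nitrite oxidoreductase.

**Alignment tables.** Each insert picks a gene with probability
proportional to copy number (metaG) or transcript abundance (metaT) times
gene length. A fraction `f_ambiguous` (default 0.2) of inserts from genes
with a paralog is listed against both paralogs; because allocation splits
ambiguous inserts in proportion to unique counts, this scheme is unbiased
in expectation. Passing inserts draw identities uniformly in 95-100% and
45-150 aligned bases; a spiked 2% fails one of the two retention cutoffs
to exercise the filter. Defaults are 100 000 inserts per sample.

**Porewater.** O2 decays linearly from the bottom-water concentration to
zero at the archetype penetration depth (1.2 mm agriculture, 4.7 mm
pristine, 3.5 mm large-deep) on a 0.1 mm grid; NO3- and SO4^2- decay
exponentially below the SWI (agriculture oxidants deplete within ~0.5 cm;
pristine NO3- persists beyond 1 cm and SO4^2- to 5 cm); NH4+ rises as a
saturating exponential toward the archetype asymptote (500 uM
agriculture, exceeding 300 uM by 5 cm; 100-150 uM elsewhere). Profiles
are sampled on the 15-depth scheme (bottom water at -1 cm, 0.25 cm steps
to 2 cm, 0.5 cm steps to 5 cm) with Gaussian noise (default sd 2 uM).
Shape parameters were chosen once so that noise-free recovered fluxes
fall inside the observed survey ranges (O2 2.58-10.7, NO3- 0.21-3.14,
NH4+ -4.19 to -0.15 mmol m^-2 d^-1) with the import/export sign pattern.

**Bulk OM.** TOC/TN levels per archetype (6%/0.9% agriculture, 1%/0.13%
pristine, 3.5%/0.55% large-deep) with a mild downcore decline, d13C
increasing slightly with depth, d15N flat; the implied molar C/N ratios
average ~8 across the study with higher values in pristine lakes.

**What the generator does not emulate.** Read-level sequences and error
models, assembly and gene prediction, taxonomic structure, spatial
micro-heterogeneity, reaction-transport coupling in porewater (profiles
are parametric shapes, not solutions of a diagenetic model), seasonal
variation, and between-lake covariance beyond the archetype means.
Passing recovery tests therefore demonstrates that the estimators invert
this generative model at realistic sizes — not that field data meet the
model's assumptions.

## Problem sizes used in validation

The test suite and the acceptance script validate at these scales, chosen
as the smallest sizes at which the statistical checks are stable: 10
independently seeded studies at 100 000 inserts/sample and 20% ambiguity
for recovery (median relative error of per-cell copies <= 10%; lake
classification agreement); 1000 random tables up to 10^4 inserts for
count conservation; ~250 exhaustive small tables against a brute-force
allocation oracle; 500-1000 null replicates at 999 permutations for
calibration of envfit and PERMANOVA; 100 random matrices for network
contracts.

## Known limitations

- The fractional allocation is single-pass; a gene whose support is
  entirely ambiguous receives counts only through the equal-split
  fallback, and strongly asymmetric paralog pairs are resolved only as
  well as their unique counts allow.
- Flux estimates inherit the configured porosity and D0; no temperature
  or salinity corrections beyond the static 5 degC defaults.
- Expression ratios are undefined where gene copies are undetected;
  orphan transcription is reported but not modeled.
- bioenv's exhaustive search grows combinatorially; the evaluation budget
  guards against runaway subset counts rather than approximating.
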