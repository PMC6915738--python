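# Methods

## The problem

Expression quantitative trait locus (eQTL) mapping regresses the expression
level of every transcript (or exon) on the allele dosage of every SNP and
asks which of the resulting millions to billions of associations are real.
`mreqtl` implements two connected studies around this problem:

1. a **power study**: Monte-Carlo simulation of genotypes, eQTL
   architectures and expression under five generative scenarios, mass
   simple-linear-regression mapping with genome-scale Benjamini-Hochberg
   (BH) FDR control, and sensitivity/specificity scoring of the detections
   against the simulated truth over a grid of effect-size thresholds;
2. a **multi-region classification study**: per-region association lists
   from a ten-brain-region expression panel are collapsed over linkage
   disequilibrium (LD) into haplotype blocks, labelled cis/trans, combined
   across transcript and exon levels, and merged across regions into
   single-region (SR) and multi-region (MR) eQTL entities with sharing
   summaries and factorial cis/trans pattern models.

## Generative model of the power study

Per SNP *i* an allele frequency *p<sub>i</sub>* is drawn from
Beta(*a* = *b* = 0.7) and redrawn until it falls strictly inside
(0.05, 0.95); redrawing rather than clipping avoids probability atoms at
the bounds.  Dosages are Binomial(2, *p<sub>i</sub>*) under Hardy-Weinberg
equilibrium.  Each SNP receives a trans-eQTL probability from
Beta(0.0004, 10) — a heavy-tailed choice under which most SNPs have no
trans effects while a handful acquire hundreds to thousands (the vertical
"band" SNPs seen in genome-wide eQTL maps) — applied Bernoulli-wise across
all features; a cis-eQTL is planted on the index-matched diagonal pair
with probability 0.05 (the diagonal pairing is a design choice: the
cis-eligible pair set is not otherwise identified, and a configurable band
half-width around the diagonal is exposed for sensitivity analysis).
Effects at flagged pairs are N(0, σ<sub>β</sub>²) with σ<sub>β</sub> = 1.15
(0.85 in the low-variance scenario) and no minimum effect size.  Expression
is Y = G·B + H·D + E with iid N(0, 1) residuals; in the dominance scenario
D has N(0, 0.25²) deviations at the flagged pairs and H is the
heterozygosity recoding of G (1 where dosage = 1).  The default grid is
20,000 SNPs × 20,000 features, i.e. 4×10⁸ tests per replicate.

Scenario variants: **LD** replaces independent SNPs with a Gaussian-copula
construction (consecutive blocks of 10 SNPs, equicorrelated latent normals
at ρ = 0.8, thresholded at the Hardy-Weinberg genotype quantiles so the
marginals are exact); **GE** resamples each analysed dosage from a 3×3
row-stochastic confusion matrix (default ≈1 % misclassification with a
heterozygote bias; fully overridable) while the expression is generated
from the uncorrupted genotypes; **LV** lowers σ<sub>β</sub> to 0.85;
**Dom** adds the dominance deviations.  The LD block construction and the
genotyping-error rates are configuration-driven defaults, not calibrated
quantities.  Child random streams are spawned per component in a fixed
order, so LE and GE share identical architectures and expression for the
same seed and replicate *r* of any grid cell uses seed `base_seed + r`.

## Truth orientation: the "tip of the iceberg" regime

Under the aligned model above, large simulated effects are essentially
always detected: with n = 150, σ<sub>β</sub> = 1.15 and unit residual
noise, any |β| ≳ 1 yields t ≈ 7 or more against a BH boundary near
p ≈ 10⁻⁹, so sensitivity at |β| ≥ 2 approaches 1.  Published multi-region
brain eQTL power studies of this design, however, operate in a very
different regime: a few percent of true eQTLs detected overall, trans
truth essentially unrecoverable, and thousands of real associations
counted as false positives.  On a square SNP-by-feature grid that regime
is exactly what results when the truth roster is recorded with its SNP and
feature axes interchanged relative to the generated signals — a
convention slip that square matrices make silent, and that leaves the cis
diagonal (and therefore the entire detected-true set) invariant.

`SimulationConfig.truth_orientation` makes the convention explicit:
`"aligned"` (default) records the truth exactly as generated;
`"swapped"` records the mirrored roster while the expression keeps the
generated signals.  The study-reproduction configuration used by
`scripts/acceptance.py` runs the swapped convention, because that is the
operating regime whose headline numbers (≈98 % of simulated eQTLs
undetected; sensitivity below 0.14 everywhere on the k grid; specificity
above 0.9997 with thousands of nominal false positives) this package
reproduces and studies.  Both conventions are first-class; the scoring
machinery is identical.

## Mass mapping and genome-scale BH

For every pair, the slope, t statistic (t = r·√((n−2)/(1−r²))) and
two-sided Student-t p-value are computed from the Pearson correlation.
The 4×10⁸ correlations per replicate are computed chunk-wise as one BLAS
product per chunk; the full p-value vector is never materialised.  Pairs
with p ≤ 10⁻⁴ (validated, see below) are stored exactly; p-values in
(10⁻⁴, 0.1] enter a 10⁴-bin log-spaced histogram that bounds every
unstored pair's global rank; pairs with p > q can never satisfy the
step-up condition p₍ᵢ₎ ≤ i·q/m (since i ≤ m implies m·p/i ≥ p), so no
bookkeeping beyond 0.1 is needed for any FDR level ≤ 0.1.  At run time the
histogram certifies that no unstored pair can reach the BH boundary —
otherwise mapping fails loudly and asks for a larger storage threshold —
which makes the detection flags exactly those of textbook BH applied to
the dense p-value vector, at every scale.  Adjusted values are exact for
all detected pairs (the validated tail bound exceeds every detection
level); for stored-but-undetected pairs the unstored tail term uses the
histogram lower bound, so adjusted values above the largest detection
level are bin-resolution approximations.  Below `dense_limit` (4×10⁶
pairs, configurable) everything is stored and adjusted values are
textbook-exact everywhere.

The correlation screen can run in single precision
(`screen_dtype="float32"`, used by the acceptance script): every stored
pair is then recomputed in double precision, and because the detection
boundary (p ≈ 10⁻⁹ at genome scale) sits five orders of magnitude inside
the storage threshold, screen rounding cannot move a detectable pair out
of the stored set.  Degenerate (zero-variance, up to representation error)
SNPs or features receive p = 1 and are never detected.  Ties in p share
the step-up decision; output ordering is deterministic (p, then SNP id,
then feature id).  Correlations at |r| ≥ 1 − 10⁻¹⁵ map to the smallest
positive double rather than 0 so logarithms stay finite.

## Scoring

The truth set at threshold k is the set of flagged pairs with |β| ≥ k.
TP/FP/FN/TN are defined so TP+FP+FN+TN = m holds exactly at every k: a
detected pair whose true effect lies below k counts as a false positive at
that threshold.  This is the only convention compatible with the
identities Se = TP/(TP+FN) over truth-at-k and Sp = TN/(TN+FP) over the
full m-pair universe; the alternative reading (drop sub-threshold truth
from the universe) is available behind
`confusion_at_threshold(..., exclude_subthreshold_truth=True)`.
Sensitivity/specificity means are aggregated over replicates with
SE = SD/√n_reps; empty denominators yield NaN, never a silent zero.
The k grid defaults to 0–3 in 0.1 steps.  Per-replicate raw counts are
retained so new k or FDR grids can be re-scored without re-simulation.

## Classification pipeline

Within a region and level, detected associations for the same feature are
sorted by SNP position and chained into haplotype blocks while each
consecutive pair has dosage R² > 0.5 (strict); the record with the
smallest p (ties: smallest position, then lexicographic SNP id) represents
the block.  An all-pairs-to-members chaining rule is available behind
`chain_rule="all_pairs"`.  Cis/trans: same chromosome and
|SNP − feature start| < 10^6.5 bp (stored as the exact power, ≈3.162 Mb)
is cis; everything else trans; the distance anchor is the annotated
feature start (the exon's own start for exon-level records).  Level
combination within a transcript cluster: a transcript-level eQTL with an
exon-level eQTL of the same cluster at R² > 0.5 is "both" (together with
those exon records); otherwise "transcript-only"; exon-level eQTLs with no
matching transcript-level eQTL at the same haplotype are "exon-only".
SR/MR merging joins records across regions with the same feature id whose
SNPs are linked at R² > 0.5, by connected components on the union
genotype panel (all regions share one genotyping of the same
individuals); an entity present in one region is SR, otherwise MR.  The
summaries — per-region totals split cis/trans, SR totals, the
regions-count frequency table (where an MR entity in r regions contributes
r eQTLs to the cumulative column), pairwise sharing matrices,
1/2–5/6–10/>10 multiplicity bins with a Max column, and a JSON sharing
graph (nodes = regions with eQTL counts, edges = shared counts split
cis/trans) — are derived from the merged entities.

## Pattern models

The proportion of trans-acting eQTLs is modelled by a binomial GLM with
logit link (trans = 1) on region and feature chromosome, optionally with
their interaction, fitted by IRLS via statsmodels with treatment coding
(alphabetically first level as reference — only cell summaries are
interpreted, which are coding-invariant).  Fitted per-cell percentages
carry delta-method standard errors; cells observed at 0 % or 100 % trans
sit on the parameter boundary and are reported with an undefined SE, with
a separation flag on the fit.  |β| is modelled by OLS with least-squares
cell means ± SEs; empty cells are excluded with a warning.  Interaction
significance is a Wald test on the joint interaction block (for the OLS
model this is the exact F test).  No multiple-testing adjustment is
applied across the model fits.

## Synthetic multi-region panel

The fixture generator emulates the structure of a ten-region brain
expression panel: 134 individuals genotyped once and completely
(per-block base allele frequencies in (0.25, 0.75) with ±0.03 within-block
jitter; LD blocks of 4 SNPs at latent ρ = 0.95, so within-block dosage R²
sits safely above the 0.5 chaining threshold), per-region subsets of
realistic sizes (CRBL 130, FCTX 127, HIPP 122, MEDU 119, OCTX 129,
PUTM 129, SNIG 101, TCTX 119, THAL 124, WHMT 131), 40 transcript clusters
of 3–6 exons (two clusters forced to 24 and two to 20 exons to host the
dilution-based plantings below), and a default roster of 18 planted
eQTLs: four all-ten-region cis entries, single-region cis and trans
entries, cortical three-region MR entries, two-region trans MR entries,
exon-only and transcript-only entries.  Planted effects enter at the exon
level with |β| between 2.2 and 3.0 for all entries covered by the
recovery guarantee; transcript expression is the winsorised mean
(fraction 0.1, classical order-statistic convention — the
floor(f·n) most extreme values at each tail are replaced by the nearest
remaining order statistic) of the cluster's exons.  Level classes then
emerge from the summarisation itself: whole-cluster effects appear at
both levels; an effect confined to one exon of a 24-exon cluster is
diluted (and partially winsorised away) below transcript-level
detectability; a weak effect (β = 0.22) shared by 20 exons is
sub-detectable per exon but aggregates at the transcript level.  The two
dilution mechanisms depend on detection thresholds, so their *expected
level classes* are probabilistic for borderline draws; the deterministic
truth (SNP, cluster, regions, effect, cis/trans — all validated against
the generated genomic map at generation time) always holds, and the planted
recovery guarantee is restricted to |β| ≥ 2 entries.  MR plantings use the
same SNP in every region with identical per-region effects.  Everything is
byte-reproducible for a fixed seed.

What the fixtures do **not** emulate: real LD maps or recombination,
array-probe effects, batch/covariate structure (the emulated data are
treated as pre-residualised), missing genotypes (except as explicitly
constructed for filter tests), or realistic effect-size distributions —
planted effects are deliberately strong so that recovery failures indicate
pipeline defects, not power limits.  Passing the fixture round-trip
therefore validates bookkeeping (LD collapsing, labelling, merging,
region sets), not field-realistic detection rates.

## Problem sizes and replicate counts

The acceptance computation (`scripts/acceptance.py`) runs the LE scenario
at the full 20,000 × 20,000 size with 10 replicates per sample size
(n = 150, 250, 300) under the swapped truth convention — 10 replicates
give Monte-Carlo standard errors of roughly 0.001 on sensitivities near
0.05 and below 10⁻⁶ on specificities, ample for the quantities reported.
The test suite exercises the same code paths at 300²–3,000² grids plus
three full-size replicates, which keeps the default run inside a desk-time
budget.  Known limitations: the histogram-mode adjusted values above the
detection region are approximations (documented above); FDR levels above
0.1 in histogram mode are rejected rather than silently extrapolated; the
sharing graph is an export format, not a rendered visualisation.
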