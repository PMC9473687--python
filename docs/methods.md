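# Methods

This note documents the models, conventions and design choices behind
each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Exon model

Coordinates are 1-based inclusive throughout, matching the exon
numbering convention used in the titin literature. Exon boundaries must
tile the transcript exactly (any gap or overlap is a structural error,
not a warning, because a silent shift would mislabel every downstream
peptide). Translation starts at `cds_start` and stops at the first
in-frame stop codon; the stop position is recorded on the model and
trailing UTR is ignored. A residue whose codon spans an exon junction
is annotated with every exon its three nucleotides touch — the
maximally inclusive reading, so a junction peptide is attributed to
both exons rather than arbitrarily to one.

Renumbering to the genomic exon scheme takes an explicit mapping table
as the primary path; exact sequence matching against an ordered genomic
exon list is provided as a convenience with no alignment heuristics
(one mismatched nucleotide is an unmatched exon, and a sequence equal
to two genomic exons is an ambiguity error listing the candidates).
Genomic exons absent from the transcript simply have no preimage — the
mouse titin transcript used in this field contains 347 of 363 genomic
exons, so a partial image is the normal case, not an error.

Tryptic digestion cleaves after K or R except before P. With m missed
cleavages every run of 1..m+1 consecutive fragments is emitted. Each
peptide records `n_loci`, the number of occurrences of its sequence in
the protein; titin's Ig/PEVK repeat structure guarantees some repeated
peptides, and because their exon attribution is a union over loci they
are excluded from exon-specific quantification by default (a
configurable policy — the right choice is genuinely open, and the flag
makes the sensitivity checkable).

## LC-MS region quantification

The quantification convention, in order:

1. **Filter**: drop peptides whose median peak area over control
   samples is strictly below 1.5×10⁷ units (a value equal to the
   threshold is kept). Missing values are ignored in the median; a
   peptide absent from every control sample counts as below threshold.
2. **Normalize**: divide each sample's peak areas by that sample's mean
   over peptides mapping entirely within the constitutive region
   (default exons 256–363). This makes the constitutive mean exactly 1
   per sample and cancels any per-sample loading or instrument-response
   factor — the analysis is invariant to rescaling any sample column.
3. **Summarize**: per peptide and group, the median normalized
   abundance across that group's samples; per region, the mean and SD
   over member peptides of those medians. The percent difference is
   computed on this linear scale. A peptide belongs to a region iff its
   whole exon set lies inside the region (strict policy; an
   "any-overlap" flag exists). A region with no detected peptide in the
   reference group is flagged `undefined_reference` rather than given a
   percent difference.
4. **Test**: two-sample Student's t-test (Welch available) on the
   natural log of the per-peptide group medians — peak areas are
   multiplicative, and the ln transform makes them approximately
   normal. Non-positive values cannot be ln-transformed and are dropped
   with a logged count. Significance requires p < α/k with α = 0.05 and
   k = 2 regions tested.

Two caveats are inherent to this design and documented deliberately.
First, peptides — not animals — are the replication unit, so the test
speaks to measurement reproducibility across peptides, not biological
variation. Second, the two group vectors contain the *same* peptides,
so any per-peptide baseline heterogeneity (ionization efficiency)
appears in both and the unpaired test becomes conservative: with a
baseline ln-SD comparable to the noise the empirical type-I rate drops
far below α, and with the realistic baseline spread the generator uses
(ln-SD 0.5) small true effects can be non-significant at modest peptide
counts (visible in `analysis/02`). The type-I calibration reported by
the acceptance script therefore simulates the test's own null model
(no baseline heterogeneity), where the rate is ≈ α.

Sampling precision of the percent-difference estimator: with ln-noise
σ = 0.25, 30 peptides per region and 5 samples per group, the
medians-then-mean estimator has a per-replicate SD of ≈ 4.8 percentage
points (≈ 4.1 from the median-of-5 noise alone). It is unbiased — the
mean across seeds recovers the simulated effect to well under a point —
but single-draw values routinely land several points from the truth.
Tight recovery therefore needs replicate averaging or several-fold more
peptides/samples, not a different estimator.

## PSI analysis

The estimator divides inclusion evidence by two before forming the
ratio, because an included cassette exon contributes two junctions
(upstream and downstream) while skipping contributes one:
PSI = (I/2)/(I/2+S). The raw ratio I/(I+S) is available by flag; the
choice matters whenever I and S are on the same read scale. PSI with
zero total evidence is missing, never 0 — conflating "not expressed"
with "always skipped" would corrupt ΔPSI. Cited protocols differ in
length-normalization details; this package states its convention
prominently rather than guessing beyond it.

ΔPSI is the difference of group means (knockout − control), computed
per exon and per event. Events are contiguous exon ranges averaged per
sample; per-event comparisons are classical t-tests with samples as
replicates (n = 3/group in the motivating design) and no correction
across the three events, whose p-values are reported individually.
Event segmentation minimizes total within-segment sum of squared
deviations of per-exon mean PSI over all contiguous k-partitions by
exact dynamic programming (O(n²k)); ties break toward the earliest
boundaries so results are deterministic.

## Sarcomere morphometry

Inputs are 1-D multichannel intensity profiles with a pixel size — line
ROI extraction from images is upstream and out of scope. Peak detection
uses prominence ≥ 0.2 of the profile's dynamic range and a minimum
separation (defaults 1000 nm for Z-line channels, 200 nm for epitope
channels, whose doublets sit ~365–460 nm apart). Each maximum is
refined by a parabola through its three samples; the refinement is
exact for an on-grid symmetric peak and keeps sub-pixel bias well under
a nanometre for Gaussian peaks at 10 nm pixels, which matters because
epitope distances are reported on the nm scale. Spacings outside a
configurable physiological window (1.0–5.0 µm) are flagged and excluded
from summaries.

The variance F-test reports F = s²ₐ/s²ᵦ with df (nₐ−1, nᵦ−1) and a
two-sided p (twice the smaller tail); direction is preserved and the
conventional larger/smaller form is reported alongside. Equal sample
variances — including the degenerate all-identical noiseless case — give
F = 1, p = 1 exactly.

Epitope distances: for each Z peak, the nearest epitope peak on each
side within `max_half_sarcomere` (default 1500 nm) yields one distance
per half-sarcomere. Matching is greedy by increasing distance and each
epitope peak serves at most one Z peak, so a lone peak between two
Z-lines is counted once, for its nearer Z-line. Unmatched sides are
missing, not zero.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` (PCG64), emit
their `SimulationTruth` record alongside the data, and are bitwise
reproducible for a fixed seed. Defaults encode the study conditions the
analysis targets: knockout effects 1.18/1.16 on exon regions
70–79/80–88, ln-noise SD 0.25, per-peptide baselines log-normal
(ln-mean ln 8×10⁷, ln-SD 0.5 — peak areas spanning roughly an order of
magnitude, the scale on which the 1.5×10⁷ filter is meaningful); a
+0.3 PSI shift on exons 52–88 (0.4 → 0.7) over a 0.95-PSI background at
read depth 500; sarcomere means 2.12/2.28 µm; epitope offsets
182.4/229.5 nm with 10 nm localization noise, an 80 nm PSF sigma and
10 nm pixels. Group SDs of sarcomere length are 0.15 µm and
0.15·√3.62 µm — the source measurements report only mean ± SEM, so the
control SD is a choice on the healthy-muscle scale and the knockout SD
is set to realize the group variance ratio of 3.62.

The peptide generator digests a synthetic 363-exon, 60-codon-per-exon
transcript (titin's exon-count geometry, not its sequence), draws up to
30 unique peptides per effect region and all unique peptides from the
constitutive region (the real normalization uses every constitutive
peptide). The junction generator draws inclusion successes
binomially (optionally beta-binomially for overdispersion) and doubles
them for the two-junction convention. The profile generator sums
Gaussians at cumulatively jittered Z positions with flanking epitope
peaks and additive background noise.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: missing peptides (detection dropout, the
"no peptides detected in control" pattern), correlated noise across
samples or retention-time batch structure, junction-read mapping biases
and exon-length effects, non-Gaussian PSFs, photobleaching gradients,
or curved/overlapping myofibrils in line profiles.

## Numerical choices and degenerate inputs

* Medians over even sample counts are midpoints of the central pair;
  missing values are dropped first.
* Identical constant groups short-circuit to t = 0, p = 1 (the sample
  variance is 0 and the standard formula is indeterminate).
* Flat profiles yield zero peaks (not an error); a single Z peak warns
  and yields no lengths.
* Segmentation tie-break: earliest boundaries (strict `<` improvement
  during reconstruction).
* Parabolic refinement offsets are clipped to ±0.5 px.
* The DP and all statistics are deterministic; every stochastic step
  lives in the generators behind a seed.

## Problem sizes

Test and reproduction runs use the study-scale defaults: 3–5 samples
per group, 30 peptides per effect region (~500 with the constitutive
block), 61 exons at depth 100–500, and 250–300 sarcomeres per group
with 200-seed replication for rate estimates; the acceptance script
averages 20–100 replicates per reported quantity.

## Known limitations

* The deposited-layout peptide reader maps peptides by exact sequence
  match against the model protein; peptides with modifications encoded
  in the sequence string must be stripped upstream.
* Exon renumbering has no tolerance for sequence edits between
  transcript and genomic records (by design; a manual mapping table is
  the escape hatch).
* Event tests at n = 3/group have little power and no normality check;
  they mirror the motivating design rather than improve on it.
* The epitope matcher assumes epitope peaks flank Z-lines within one
  half-sarcomere; grossly disordered profiles yield sparse matches,
  which are reported but not modeled.
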