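# titinsplice

Links three layers of evidence about alternative splicing of titin's
I-band spring region in skeletal muscle: exon-resolved peptide
quantification from label-free LC-MS, percent-spliced-in (PSI) analysis
of RNA-seq junction counts, and sarcomere morphometry from
immunofluorescence line profiles. It is written for muscle biologists
who want to ask, end to end, whether a change in titin exon inclusion
at the mRNA level is visible in titin protein and in sarcomere
geometry.

## What it computes

**Exon-annotated protein model.** A transcript sequence plus an exon
boundary table is translated into a protein in which every residue
carries the set of genomic exon numbers its codon touches (junction
codons carry both exons). Transcript exon numbers are renumbered to the
genomic scheme (363 titin exons) via an explicit mapping table or exact
sequence matching. In-silico tryptic digestion (cleave after K/R, not
before P, configurable missed cleavages) and peptide lookup annotate
any peptide with its exon set and its number of loci in the protein;
multi-locus peptides are excluded from exon-specific quantification by
default.

**Region-level LC-MS quantification.** Peptides with a control-group
median peak area below 1.5×10⁷ units are excluded. Each remaining peak
area is normalized per sample by the mean peak area of peptides from
the constitutive region (exons 256–363, no evidence of alternative
splicing). For an exon region R and groups A (control) and B, each
peptide contributes its group-median normalized abundance m̃ᵖ; the
region summary is

    %diff(R) = 100 · (mean_B(m̃ᵖ) − mean_A(m̃ᵖ)) / mean_A(m̃ᵖ)

and the group comparison is a two-sample Student's t-test on
ln m̃ᵖ with significance threshold α/k (Bonferroni; α = 0.05, k = 2
regions detected in both groups → 0.025). Gel densitometry helpers
convert long-T1/short-T1/T2 band intensities into isoform fractions.

**PSI splicing analysis.** For exon e with inclusion-junction reads I
and skipping reads S, the two-inclusion-junction estimator is

    PSI = (I/2) / (I/2 + S)

(undefined, never 0, without evidence). ΔPSI is the knockout−control
difference of group means; contiguous exon ranges are aggregated into
events (defaults 52–69, 70–79, 80–88, together spanning the proximal-Ig
block 52–88) with per-event t-tests, and an exact dynamic program
partitions a range into k segments of similar PSI.

**Sarcomere morphometry.** Peaks in 1-D fluorescence profiles are
detected with prominence/separation filters and refined to sub-pixel
positions by three-point parabolic interpolation. Sarcomere length is
the spacing of successive Z-line (α-actinin) peaks; group variability is
compared with a two-sided F-test (F = s²ₐ/s²ᵦ); proximal-Ig length is
the distance from each Z-line peak to the nearest flanking titin
epitope peak (greedy nearest-pair matching, one epitope peak per
half-sarcomere).

**Synthetic data.** Seeded generators emulate all three inputs
(log-normal peptide tables with region effects, binomial junction
counts, Gaussian-peak-train line profiles) and return their ground
truth, so the full pipeline is testable without downloads.

## Worked example

```bash
python analysis/01_simulate_inputs.py     # synthetic study inputs -> results/data/
python analysis/02_proteomics_regions.py
python analysis/03_splicing_psi.py
python analysis/04_sarcomere_morphometry.py
```

prints, among other lines:

```
peptides: 507 read, 507 past the 1.5e7 filter, 143 exons covered
  exons 70-79: +21.1% (p=9.18e-02, adjusted alpha=0.025, significant=False)
  event 52-69: PSI 0.399 -> 0.700 (dPSI +0.302, p=1.70e-08)
similarity segmentation of exons 45-95 into 3: [(45, 51), (52, 88), (89, 95)]
control: 250 sarcomeres, length 2.120 +/- 0.149 um, proximal Ig 182.1 nm (SEM 0.55, n=502)
knockout: 250 sarcomeres, length 2.234 +/- 0.283 um, proximal Ig 229.1 nm (SEM 0.54, n=502)
variance F-test (control/knockout): F=0.276 (larger/smaller 3.62), p=8.96e-23
```

Reading: the simulated +18% protein effect on exons 70–79 is recovered
as +21.1% in this 3-vs-3 draw (single-draw spread is several points;
see `docs/methods.md`), the +0.3 PSI shift is found in every event and
the segmentation re-finds the 52–88 block, and the knockout profiles
show the configured longer, more variable sarcomeres with a ~47 nm
longer proximal-Ig epitope distance.

The same stages are scriptable via the `titinsplice` CLI
(`model-build`, `proteomics`, `splicing`, `morphometry`, `simulate`)
with a YAML config.

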