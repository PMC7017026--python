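# introscan

Detection and characterization of **introgressed regions in congenic
genomes** from single-sample SNP call sets, with strain-panel provenance
analysis and the downstream genotype–phenotype and expression statistics
used in modifier-locus studies.

## The problem

A congenic mouse line is expected to be genetically identical to its
recipient strain (e.g. C57BL/6J) outside the deliberately introgressed
interval. In practice, colonies can silently carry additional donor-derived
chromosomal segments — unplanned modifiers that alter phenotypes such as
XY gonadal sex reversal. Because the recipient background is inbred, such a
segment has an unmistakable signature in whole-genome sequencing of a single
animal: a dense cluster of SNP calls in the **heterozygous non-reference**
state. `introscan` turns that signature into a tested, reproducible
pipeline:

1. **discover** — filter SNP calls (caller status check, mapping-quality
   threshold, default < 200 removed), keep heterozygous calls, count them in
   fixed 1-Mb windows, call maximal runs of dense windows as introgressed
   segments (bridging the reference-homozygous blocks and variant-devoid
   gaps of a backcross mosaic), triage small isolated clusters as likely
   artifacts, and locate variant-devoid gaps inside the region.
2. **compare** — classify each segment SNP as *private* (carried by no
   strain of a genotype panel; default 36 inbred/wild-derived strains) or
   *shared*, rank strains by the fraction of segment alleles they carry, and
   map where private SNPs cluster.
3. **stats** — Fisher's exact test (2×2 and Freeman–Halton R×C by full
   enumeration, with a margin-fixed Monte-Carlo fallback for large tables),
   two-tailed Welch's *t*-test, and relative expression by the ΔΔCt method
   (fold change = 2^(−ΔΔCt), normalized to an endogenous control gene).
4. **simulate** — a first-class synthetic-data generator that plants a known
   introgression truth (mosaic blocks, devoid gaps, private-site region,
   artifact clusters, two-component quality scores), strain panels, phenotype
   cohorts and qPCR Ct tables, so every step is testable as planted-truth
   recovery.

The package is organized statsmodels-style: the scan is a model object
(`IntrogressionScan`) whose `fit()` returns a results object
(`IntrogressionScanResult`) carrying segments, density tracks, filter
diagnostics and a `summary()`.

## Worked example

The one-command demo simulates a congenic genome whose planted mosaic spans
38.2–75.7 Mb of chromosome 13 (with a 4.5 Mb variant-devoid gap around
51.8 Mb and private SNPs concentrated in 60–70 Mb), then runs all three
analysis stages:

```sh
introscan demo --outdir demo_out --seed 1
```

```
Introgression scan
==================
input calls:            28992
  failed status check:  602
  mapping quality < 200: 38
  removed (either):     621
retained calls:         28371
heterozygous non-ref:   28371
window size:            1000000 bp

segments called:        1 (1 introgressed, 0 artifact candidates)
largest introgressed:   13:38200072-75699079 (37.5 Mb, 28364 SNPs)

Strain-panel comparison
=======================
sites:           28364
  private:       9879
  shared:        18485

top strains by similarity:
   1. BALB/cJ              0.553
   ...

densest 10-Mb private span: starts 60 Mb (9879 private SNPs)
```

Reading the output: the scan recovered the planted segment to sub-window
accuracy (38.20–75.70 Mb, 37.5 Mb); 621 low-quality calls were removed by
the filters; BALB/cJ ranks first in allele sharing, as planted; and the
10-Mb span richest in panel-private SNPs starts at 60 Mb, matching the
planted private-site region. The stats report in
`demo_out/stats/stats_report.tsv` adds the exact test on genotype ×
phenotypic-sex counts (p ≈ 6e-11 for the planted sex-ratio difference), the
Monte-Carlo exact test on the 2×4 genotype × gonad-category table, and the
ΔΔCt fold change (0.489, i.e. the planted ~2-fold reduction) with its Welch
test.

Equivalent library code:

```python
from introscan import IntrogressionScan, SimulationConfig
from introscan.simulate import generate_congenic_callset

config = SimulationConfig(seed=1)
calls, truth = generate_congenic_callset(config)
result = IntrogressionScan(calls, config.chromosome_lengths).fit()
print(result.summary())
segment = result.largest_segment()
gaps = result.devoid_gaps(min_gap_bp=1_000_000)
```

Real data enter through `introscan.io.read_vcf` (single-sample VCF,
INFO/MQ quality scores), `read_strain_panel` (tab-delimited strain × site
0/1 table) and plain delimited cohort/Ct tables; outputs are BED segments
and tab-delimited density tracks with private/shared splits suitable as
Circos-style track data.

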